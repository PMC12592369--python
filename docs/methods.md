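# Methods

## Model

`dpmost` models longitudinal biomarker measurements of `J` subjects over `B`
biomarkers as noisy observations of monotone sigmoid trajectories on a
common long-term disease axis.  Each subject observes only a short window of
that axis; a subject-specific translation `tau_j` maps observed visit times
onto the axis (`phi_j(t) = t + tau_j`).  A trajectory component is the
three-parameter logistic

    S(t) = supremum / (1 + exp(-growth_rate * (t - midpoint)))

with lower asymptote 0, chosen as the minimal monotone-increasing form
parameterized by a midpoint, a growth rate and a supremum.

Subtype structure enters through a two-level mixture.  At the first level,
biomarker `b` follows one shared trajectory with probability `xi_b1` or
splits into two subtype-specific sub-trajectories with probability
`1 - xi_b1`.  At the second level, conditional on a split, subject `j`
follows branch 1 with probability `pi_j(2,1)` and branch 2 otherwise; the
branch probability is shared across biomarkers, which is what makes the
per-subject subtype assignment coherent.  Observation noise is i.i.d.
Gaussian with a per-biomarker standard deviation `sigma_b` shared by all
components.  The per-series likelihood multiplies Gaussian densities over
the subject's non-missing visits; visits with a missing value are skipped,
never imputed.

Estimation is maximum a posteriori.  The penalized objective adds to the
log-likelihood

    - beta_sigma * sum_b (ln sigma_b + 1 / sigma_b)     (inverse-gamma on sigma)
    + beta_xi    * sum_b xi_b1                          (truncated-Laplace sparsity
                                                         reward for the simpler,
                                                         no-split explanation)
    - beta_tau   * sum_j tau_j^2                        (Gaussian shrinkage of shifts)

with improper uniform priors on the sigmoid parameters and on `pi`
contributing nothing.  The truncated-Laplace normalizing constant is dropped
(constant in the parameters for fixed `beta_xi`).  `beta_xi` must satisfy
`0 < beta_xi < J`: within that range the stationary no-split probability is
a valid probability for any responsibility mass (the one-step fixed-point
iterate can still overshoot 1, which is why the update clamps).

Only the two-subtype model is implemented end to end; the data structures
carry the general parameter count formula
`B (3 M (M+1)/2 + 2) + J (M (M+1)/2 + 1)` but the fitting loop is the
`M = 2` algorithm used in all experiments.

## Fitting

One outer iteration applies

1. the fixed-point EM step `xi_b1 <- R_b / (J + (xi_b1 - 1) beta_xi)`, where
   `R_b` sums the single-trajectory responsibilities over subjects — the
   stationary condition of the sparsity-penalized expected complete-data
   objective;
2. the EM step for the branch probabilities, normalizing branch
   responsibilities summed over biomarkers (a subject with no split mass on
   any biomarker keeps its current value);
3. `N` inner sweeps of full-batch gradient ascent on the log-posterior,
   first in every `tau_j`, then per biomarker in the sigmoid parameters and
   noise SD.  Growth rates, suprema and sigmas are updated in log
   coordinates, which enforces positivity structurally.

Gradients are exact (they are verified against central finite differences
to 1e-5 relative in the test suite).  Learning rates multiply mean
gradients: each per-subject step is normalized by the subject's observation
count, and each trajectory component's step by that component's
responsibility-weighted observation count.  The per-component normalization
matters: without it, a component whose mixture weight collapses stops
receiving gradient and freezes wherever it happens to be, and the final
split/no-split comparison then reflects initialization luck rather than the
data.  Mixture weights are kept epsilon-interior (1e-6) during fitting for
the same reason.

Step-size control is trust-region flavored: an outer iteration that lowers
the objective is rolled back and the rates damped (x0.7), and each
successful iteration lets them recover (x1.05, capped at 4x the initial
value).  The iterate with the highest posterior is returned.  A restart
stops early when the relative objective change falls below `tol` or when
the best objective has not materially improved for 30 outer iterations.

Two families of discrete proposals, each accepted only when it increases
the posterior, escape the mixture's characteristic local optima.
*Component reseeding* (every 20 outer iterations) proposes copying the
dominant branch into a stale shared slot, and re-seeding both branches from
the shared curve with contrasted growth rates (mild 0.75x/1.33x and strong
0.6x/1.6x variants).  Because the barrier between an over-split state and
the no-split state lies in `xi` rather than in the curves — two overfit
branches hold `xi` near 0 even when the single curve plus the sparsity
reward scores higher — every candidate's mixture weights are re-equilibrated
(a few `xi`/`pi` EM steps with curves fixed) before the comparison.
*Split-host swapping* (panels of up to 3 biomarkers, where the trap occurs)
proposes moving the split from one biomarker to another with the partition
reset, against the lock-in where the subtype partition latches onto a noise
split of the wrong biomarker.

The procedure runs from `n_restarts` independent random initializations;
the restart with the highest final log-posterior wins, ties broken by the
lowest restart index.  After fitting, branch labels are made canonical
(branch 1 has the smaller growth rate on the biomarker with the highest
split probability); this is cosmetic, since the branch labels are
exchangeable.

### Initialization

`xi_b1 = pi_j = 0.5` (no prior subtype information), `tau_j = 0`, `sigma_b`
at the pooled empirical SD of the biomarker.  Sigmoid parameters are drawn
from Gaussians around coarse data statistics — midpoint around the observed
time midrange (SD a quarter of the range), supremum around the biomarker
maximum (SD the biomarker SD), growth rate around `2 / range` (SD half
that) — with rejection until positive.  A biomarker with fewer than two
distinct values has no defined SD and is rejected.

### Defaults and units

| parameter | default | meaning |
| --- | --- | --- |
| `beta_xi`, `beta_sigma` | `0.15 J` | penalty strengths, 15% of the cohort size |
| `beta_tau` | `1/(2*40^2) = 3.125e-4` | Gaussian shift prior with SD 40 time units |
| `lambda_theta`, `lambda_sigma` | 0.5 | curve / noise learning rates (on mean gradients) |
| `lambda_tau` | 0.05 | time-shift learning rate during full fits |
| `K` (`n_outer`) | 200 | outer EM iterations |
| `N` (`n_inner`) | 10 | gradient sweeps per outer iteration |
| `n_restarts` | 10 | random restarts |
| `tol` | 1e-6 | relative objective-change stop |

The library is unit-agnostic; the `beta_tau` default encodes a plausible
clinical staging range when time is measured in months.  The asymmetric
learning rates are deliberate.  The time shift is one free real parameter
per subject: letting it move as fast as the curve fit lets the model chase
noise subject by subject, and those solutions — which reach markedly higher
posteriors — wash out both the subtype partition and the split/no-split
decisions.  Treating the shifts as slow alignment refinements keeps the
trajectory fit in charge.  In *transfer* fitting the situation reverses:
every trajectory is frozen, the shift must carry a new subject across the
whole disease axis and can no longer drag curves with it, so there the shift
rate is large (0.5) and only `tau` and `pi` are optimized.

`beta_sigma > 1` is required by the inverse-gamma prior; with the
15%-of-cohort default this needs `J >= 7` (override `beta_sigma` explicitly
for smaller cohorts).

## Synthetic cohorts

The generator reproduces the benchmark protocol: 50 subjects split evenly
between two subtypes; 2, 5 or 7 biomarkers of which 1, 3 or 4 are
subtype-specific; 2, 5 or 7 visit times per subject drawn uniformly from
[0, 20] and sorted; noise variance 0.7, 0.5 or 0.2 (low/medium/high SNR).
The full factorial grid is 27 cells with a configurable replicate count.

Trajectory parameters are sampled per biomarker: midpoint ~ N(10, 3^2)
truncated to the window, supremum ~ |N(2, 0.5^2)|, growth rate ~
|N(0.6, 0.2^2)| floored at 0.1.  A subtype-specific biomarker draws two
independent parameter sets whose growth rates are at least 0.3 apart
(rejection), so the growth-rate error metric is well posed; the reference
protocol does not state its separation mechanism, and absolute accuracy
numbers shift with this choice even where qualitative orderings hold.

Visit times are absolute positions on the disease axis by default.  With
`recenter_times=True` each subject's times are shifted so the first visit
is 0 and the removed offset is recorded; this mode expresses the staging
problem — the subject's position must be recovered through `tau` — and is
used in the transfer experiments, mirroring an external cohort whose
clock starts at each patient's first visit.

What the generator does *not* emulate: irregular per-biomarker visit
schedules, non-Gaussian or heteroscedastic noise, unbalanced subtypes, more
than two subtypes, covariate effects, and informative dropout.  Passing
benchmarks on these cohorts demonstrates correct inference under the
model's own assumptions, not robustness to their violation.

## Metrics

*Growth-rate error*: the split-probability-weighted relative error between
estimated and true growth rates — the only trajectory parameter that
survives rescaling of the time axis.  Branch labels are exchangeable, so
the split term is scored under the better of the two branch-truth pairings.

*Subtype detection*: a biomarker is called subtype-specific iff its split
probability exceeds 0.5 (an exact tie resolves to no-split, the
conservative choice); the score is the fraction of biomarkers called
correctly.

*Subtype partition*: rank-based AUC of the per-subject branch-1
probabilities against the true labels, symmetrized as `max(AUC, 1 - AUC)`
because of label exchangeability.  A hard-assignment accuracy (threshold
0.5, best over the two label permutations) is also provided; the AUC is
the default scored metric.

*Wasserstein permutation test*: whether a discovered subgroup differs from
the full population in an ordered categorical covariate (e.g., risk-allele
copy number 0/1/2).  The statistic is the 1-D earth-mover distance with
unit ground metric between the subgroup's empirical distribution and the
population reference; the null draws random subgroups of the same size.
Because the distance is nonnegative, the two-sided test reduces to the
upper tail; the p-value `(1 + #{null >= observed}) / (1 + n_perm)` is valid
(super-uniform) by construction.

## Numerical choices

- Mixture terms are computed in log space with log-sum-exp; exponent
  differences are floored at -700 so responsibilities never form 0/0.
  Sub-floor split mass (below ~1e-250 per biomarker) is treated as exactly
  zero in the `pi` update, restoring the documented degenerate-case
  behavior.
- The forward pass and all gradient accumulators are computed in one fused
  compiled kernel (numba); the analytic gradients assembled from it are the
  exact gradients of the log-posterior.
- All randomness flows through a single seeded generator; identical seed,
  data and settings reproduce the fit bit for bit.
- Degenerate inputs fail loudly: empty datasets, non-increasing visit
  times, infinite values, constant biomarkers, inadmissible `beta_xi`.

## Benchmark problem sizes

The packaged benchmark (`scripts/acceptance.py`, mirrored by the heavier
tests) scores five grid cells at 20 replicates each with default
hyperparameters, the growth-rate-recovery trend over 2 -> 5 -> 7 visits at
10 replicates, transfer staging on one 50-subject cohort (30 train / 20
held out), and permutation-test calibration over 500 null runs with 1000
permutations each.  These sizes were chosen as the smallest at which the
replicate means are stable to well within the 0.1 comparison tolerance.

## Known limitations

- The two-subtype restriction is structural in the fitting loop; the types
  admit general `M` but no `M > 2` optimizer is provided.
- The MAP point estimate carries no posterior uncertainty; the split and
  subtype probabilities are mixture weights, not credible intervals.
- With two biomarkers and two visits per subject (the hardest cell) the
  split decision is near the information floor; expect detection little
  better than chance there.
- Identifiability: the absolute position of the time axis is fixed only by
  the shift prior; midpoints and suprema are therefore reported on the
  fitted axis, and only growth rates are compared against generating truth.
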