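"""MAP-EM fitting of the two-level mixture progression model.

The objective is the penalized log-posterior of :mod:`dpmost.model`.  One
outer iteration performs:

1. a fixed-point EM step for the per-biomarker no-split probabilities ``xi``
   (stationary point of the sparsity-penalized expected complete-data
   objective),
2. an EM step for the per-subject branch probabilities ``pi``,
3. ``N`` inner sweeps of gradient ascent, first on the time shifts ``tau``,
   then on the sigmoid parameters and noise SDs (positivity of growth rates,
   suprema and SDs is enforced by taking the gradient steps in log
   coordinates).

The procedure is restarted ``n_restarts`` times from independent random
initializations and the restart with the highest final log-posterior is
returned.  Learning rates are applied to observation-count-normalized mean
gradients (per-component counts for the trajectory parameters), which makes
the step sizes comparable across cohort sizes and keeps low-weight mixture
components training; if an outer iteration decreases the objective the step
is rolled back and the rates damped, recovering after later successes.  The
time-shift rate is deliberately an order of magnitude smaller than the curve
rates: shifts refine alignment, and letting them race the curve fit lets a
per-subject parameter absorb noise and wash out the subtype signal.
Periodic component-reseeding and split-host-swap proposals, accepted only on
posterior increase, escape the mixture's characteristic local optima.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import (
    Hyperparams,
    LongitudinalDataset,
    ModelParamsM2,
    _forward,
    log_posterior,
    log_prior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "DPMoSt",
    "default_hyperparams",
    "initialize",
    "update_xi",
    "update_pi",
    "gradient_step_tau",
    "gradient_step_theta_sigma",
    "fit",
    "fit_new_subjects",
]

_BETA_TAU_DEFAULT = 1.0 / (2.0 * 40.0**2)  # Gaussian time-shift prior, SD 40


@dataclass
class FitResult:
    """Outcome of a full multi-restart fit.

    ``split_probability[b] = 1 - xi_b1`` is the probability that biomarker
    ``b`` is subtype-specific; ``subtype_probability[j] = pi_j(2,1)`` the
    probability that subject ``j`` follows branch 1 given a split.
    """

    params: ModelParamsM2
    objective_trace: list[float]
    split_probability: np.ndarray
    subtype_probability: np.ndarray
    best_restart_index: int
    converged: bool
    n_iter: int
    restart_objectives: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.objective_trace)):
            raise ValueError("objective trace contains non-finite values")
        for arr in (self.split_probability, self.subtype_probability):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("probabilities must lie in [0, 1]")


def default_hyperparams(J: int, **overrides) -> Hyperparams:
    """Default hyperparameters for a cohort of ``J`` subjects.

    ``beta_xi = beta_sigma = 0.15 J`` and ``beta_tau = 1 / (2 * 40^2)``
    (a Gaussian time-shift prior with SD 40 time units).  Requires
    ``0.15 J > 1`` (i.e. J >= 7) unless ``beta_sigma`` is overridden.
    """
    beta = 0.15 * J
    defaults = dict(beta_sigma=beta, beta_xi=beta, beta_tau=_BETA_TAU_DEFAULT)
    defaults.update(overrides)
    if defaults["beta_sigma"] <= 1:
        raise ValueError(
            f"0.15 * J = {beta:.3g} <= 1: beta_sigma must exceed 1; "
            "use J >= 7 or override beta_sigma explicitly"
        )
    hyper = Hyperparams(**defaults)
    hyper.check_admissible(J)
    return hyper


def initialize(
    dataset: LongitudinalDataset, hyper: Hyperparams, rng: np.random.Generator
) -> ModelParamsM2:
    """Random initialization reflecting no prior subtype information.

    All no-split and branch probabilities start at 0.5, time shifts at 0, and
    each noise SD at the pooled empirical SD of its biomarker.  Sigmoid
    parameters are drawn from Gaussians centred on coarse data statistics,
    with rejection to keep growth rates and suprema positive.
    """
    J, B = dataset.n_subjects, dataset.n_biomarkers
    t = dataset.times_padded[np.isfinite(dataset.times_padded)]
    tmin, tmax = float(t.min()), float(t.max())
    trange = max(tmax - tmin, 1e-6)
    mid0 = 0.5 * (tmin + tmax)
    rate0 = 0.5 * 4.0 / trange  # transition spanning about twice the window

    sigma = np.empty(B)
    sup_mean = np.empty(B)
    for b in range(B):
        vals = dataset.values_padded[:, b, :][dataset.mask[:, b, :]]
        if np.unique(vals).size < 2:
            raise ValueError(
                f"biomarker {dataset.biomarker_names[b]!r} has < 2 distinct "
                "values; its SD is undefined"
            )
        sigma[b] = vals.std()
        sup_mean[b] = vals.max()

    def _positive(mean, sd, shape):
        out = mean + sd * rng.standard_normal(shape)
        for _ in range(200):  # rejection until every entry is positive
            bad = out <= 0
            if not bad.any():
                return out
            out = np.where(bad, mean + sd * rng.standard_normal(shape), out)
        return np.abs(out) + 1e-3

    midpoint = rng.normal(mid0, trange / 4.0, size=(B, 3))
    growth_rate = _positive(rate0, 0.5 * rate0, (B, 3))
    supremum = _positive(sup_mean[:, None], sigma[:, None], (B, 3))
    return ModelParamsM2(
        midpoint=midpoint,
        growth_rate=growth_rate,
        supremum=supremum,
        sigma=sigma,
        xi1=np.full(B, 0.5),
        tau=np.zeros(J),
        pi1=np.full(J, 0.5),
    )


def update_xi(
    dataset: LongitudinalDataset,
    params: ModelParamsM2,
    hyper: Hyperparams,
    fw: dict | None = None,
) -> np.ndarray:
    """One fixed-point EM step for the no-split probabilities.

    ``xi_b1 <- R_b / (J + (xi_b1 - 1) beta_xi)`` with ``R_b`` the summed
    single-trajectory responsibilities; the result is clamped to [0, 1].
    Requires the admissibility bound ``0 < beta_xi < J``.
    """
    J = dataset.n_subjects
    hyper.check_admissible(J)
    if fw is None:
        fw = _forward(dataset, params)
    R = fw["resp"][:, :, 0].sum(axis=0)  # (B,)
    denom = J + (params.xi1 - 1.0) * hyper.beta_xi
    return np.clip(R / denom, 0.0, 1.0)


def update_pi(
    dataset: LongitudinalDataset,
    params: ModelParamsM2,
    fw: dict | None = None,
) -> np.ndarray:
    """One EM step for the per-subject branch probabilities.

    Branch responsibilities are summed over biomarkers and normalized over
    the two branches; a subject with zero split mass on every biomarker keeps
    its current value.
    """
    if fw is None:
        fw = _forward(dataset, params)
    w1 = fw["resp"][:, :, 1].sum(axis=1)  # (J,)
    w2 = fw["resp"][:, :, 2].sum(axis=1)
    denom = w1 + w2
    # the density floor keeps responsibilities technically nonzero even when
    # there is no split mass at all; treat sub-floor mass as zero
    has_mass = denom > params.n_biomarkers * 1e-250
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_new = np.where(has_mass, w1 / np.where(has_mass, denom, 1.0), params.pi1)
    return np.clip(pi_new, 0.0, 1.0)


def _gradients(dataset: LongitudinalDataset, params: ModelParamsM2, hyper: Hyperparams, fw=None):
    """Exact gradients of the log-posterior in the raw coordinates.

    Returns a dict with keys ``midpoint``, ``growth_rate``, ``supremum``
    (each (B, 3)), ``sigma`` (B,) and ``tau`` (J,).
    """
    if fw is None:
        fw = _forward(dataset, params)
    resp = fw["resp"]
    A, Ct, D, SS = fw["A"], fw["Ct"], fw["D"], fw["SS"]
    sigma = params.sigma
    rate = params.growth_rate
    grad_mid = -(rate[None] * resp * A).sum(axis=0)
    grad_rate = (resp * Ct).sum(axis=0)
    grad_sup = (resp * D).sum(axis=0)
    N_b = fw["nobs"].sum(axis=0)  # (B,)
    grad_sigma = (
        -N_b / sigma
        + (resp * SS).sum(axis=(0, 2)) / sigma**3
        - hyper.beta_sigma * (1.0 / sigma - 1.0 / sigma**2)
    )
    grad_tau = (resp * rate[None] * A).sum(axis=(1, 2)) - 2.0 * hyper.beta_tau * params.tau
    return {
        "midpoint": grad_mid,
        "growth_rate": grad_rate,
        "supremum": grad_sup,
        "sigma": grad_sigma,
        "tau": grad_tau,
    }


def gradient_step_tau(
    dataset: LongitudinalDataset,
    params: ModelParamsM2,
    hyper: Hyperparams,
    fw: dict | None = None,
    lambda_tau: float | None = None,
) -> np.ndarray:
    """One ascent step on the log-posterior in every time shift ``tau_j``.

    The step is the per-subject mean gradient (total gradient divided by the
    subject's observation count) scaled by ``lambda_tau``.
    """
    if fw is None:
        fw = _forward(dataset, params)
    grads = _gradients(dataset, params, hyper, fw)
    if not np.all(np.isfinite(grads["tau"])):
        raise FloatingPointError("non-finite gradient in tau step")
    n_j = np.maximum(fw["nobs"].sum(axis=1), 1)
    lam = hyper.lambda_tau if lambda_tau is None else lambda_tau
    return params.tau + lam * grads["tau"] / n_j


def gradient_step_theta_sigma(
    dataset: LongitudinalDataset,
    params: ModelParamsM2,
    hyper: Hyperparams,
    fw: dict | None = None,
    lambda_theta: float | None = None,
    lambda_sigma: float | None = None,
) -> ModelParamsM2:
    """One ascent step per biomarker in the sigmoid parameters and noise SD.

    Growth rates, suprema and sigma are updated in log coordinates so they
    remain positive after any number of steps.
    """
    if fw is None:
        fw = _forward(dataset, params)
    grads = _gradients(dataset, params, hyper, fw)
    for key in ("midpoint", "growth_rate", "supremum", "sigma"):
        if not np.all(np.isfinite(grads[key])):
            raise FloatingPointError(f"non-finite gradient in {key}")
    N_b = np.maximum(fw["nobs"].sum(axis=0), 1)  # (B,)
    # per-component effective observation counts: preconditioning each
    # component's step by its own responsibility mass keeps low-weight
    # components training instead of freezing as their mixture weight shrinks
    eff = np.maximum((fw["resp"] * fw["nobs"][:, :, None]).sum(axis=0), 1.0)  # (B, 3)
    lam_t = hyper.lambda_theta if lambda_theta is None else lambda_theta
    lam_s = hyper.lambda_sigma if lambda_sigma is None else lambda_sigma
    out = params.copy()
    out.midpoint = params.midpoint + lam_t * grads["midpoint"] / eff
    # chain rule: d/d log(p) = p * d/dp
    out.growth_rate = params.growth_rate * np.exp(
        lam_t * params.growth_rate * grads["growth_rate"] / eff
    )
    out.supremum = params.supremum * np.exp(
        lam_t * params.supremum * grads["supremum"] / eff
    )
    out.sigma = params.sigma * np.exp(lam_s * params.sigma * grads["sigma"] / N_b)
    return out


def _relabel_branches(params: ModelParamsM2, split_prob: np.ndarray) -> ModelParamsM2:
    """Canonical branch labelling: branch 1 has the smaller growth rate on
    the biomarker with the highest split probability (cosmetic only)."""
    b_star = int(np.argmax(split_prob))
    if params.growth_rate[b_star, 1] > params.growth_rate[b_star, 2]:
        out = params.copy()
        for arr in (out.midpoint, out.growth_rate, out.supremum):
            arr[:, [1, 2]] = arr[:, [2, 1]]
        out.pi1 = 1.0 - out.pi1
        return out
    return params


def _equilibrate_weights(dataset, params, hyper, n=8):
    """Run the xi and pi EM steps to near-convergence, curves held fixed."""
    for _ in range(n):
        fw = _forward(dataset, params)
        params.xi1 = np.clip(update_xi(dataset, params, hyper, fw), 1e-6, 1 - 1e-6)
        params.pi1 = np.clip(update_pi(dataset, params, fw), 1e-6, 1 - 1e-6)
    return params


def _reseed_components(dataset, params, hyper):
    """Component-swap proposals judged after a short xi re-equilibration.

    Escapes two characteristic local optima of the mixture: a stale shared
    curve losing to two branches that have collapsed onto the same trajectory
    (proposal: copy the dominant branch into the shared slot), and stale
    over-fitted branches trapping the split probability even though a single
    shared curve plus the sparsity reward scores higher (proposal: re-seed
    both branches from the shared curve with perturbed growth rates).  Each
    candidate's no-split probabilities are re-equilibrated before comparison
    because the barrier between these optima lies in xi, not in the curves;
    a proposal is kept only if its posterior beats the re-equilibrated
    current state, so the accepted sequence is monotone in the objective.
    """
    params = _equilibrate_weights(dataset, params.copy(), hyper)
    obj = log_posterior(dataset, params, hyper)
    fw = _forward(dataset, params)
    mass = fw["resp"].sum(axis=0)  # (B, 3)
    for b in range(params.n_biomarkers):
        # shared slot <- dominant branch (rescues a stale shared curve)
        dominant = 1 + int(mass[b, 2] > mass[b, 1])
        cand = params.copy()
        cand.midpoint[b, 0] = cand.midpoint[b, dominant]
        cand.growth_rate[b, 0] = cand.growth_rate[b, dominant]
        cand.supremum[b, 0] = cand.supremum[b, dominant]
        cand = _equilibrate_weights(dataset, cand, hyper)
        o = log_posterior(dataset, cand, hyper)
        if o > obj:
            params, obj = cand, o
        # branches <- shared curve with mildly contrasted rates (lets the
        # sparsity reward close a spurious split)
        cand = params.copy()
        cand.midpoint[b, 1:] = cand.midpoint[b, 0]
        cand.supremum[b, 1:] = cand.supremum[b, 0]
        cand.growth_rate[b, 1] = 0.75 * cand.growth_rate[b, 0]
        cand.growth_rate[b, 2] = 4.0 / 3.0 * cand.growth_rate[b, 0]
        cand = _equilibrate_weights(dataset, cand, hyper)
        o = log_posterior(dataset, cand, hyper)
        if o > obj:
            params, obj = cand, o
        # branches <- strongly contrasted slow/fast pair around the shared
        # curve (reveals a genuine split hidden behind collapsed branches)
        cand = params.copy()
        cand.midpoint[b, 1:] = cand.midpoint[b, 0]
        cand.supremum[b, 1:] = cand.supremum[b, 0]
        cand.growth_rate[b, 1] = 0.6 * cand.growth_rate[b, 0]
        cand.growth_rate[b, 2] = 1.6 * cand.growth_rate[b, 0]
        cand = _equilibrate_weights(dataset, cand, hyper)
        o = log_posterior(dataset, cand, hyper)
        if o > obj:
            params, obj = cand, o
    return params


def _swap_split_host(dataset, params, hyper):
    """Pairwise split-host swap proposals, accepted on posterior increase.

    With few biomarkers the subtype partition can lock onto a noise split of
    the wrong biomarker, after which the truly subtype-specific biomarker
    cannot express its split under the entrenched partition.  For each
    ordered biomarker pair this proposes strongly contrasted branches at one
    and collapsed branches at the other, re-equilibrates the mixture weights,
    and keeps the candidate only if the posterior improves.
    """
    obj = log_posterior(dataset, params, hyper)
    B = params.n_biomarkers
    for b_new in range(B):
        for b_old in range(B):
            if b_old == b_new:
                continue
            cand = params.copy()
            cand.midpoint[b_new, 1:] = cand.midpoint[b_new, 0]
            cand.supremum[b_new, 1:] = cand.supremum[b_new, 0]
            cand.growth_rate[b_new, 1] = 0.6 * cand.growth_rate[b_new, 0]
            cand.growth_rate[b_new, 2] = 1.6 * cand.growth_rate[b_new, 0]
            cand.midpoint[b_old, 1:] = cand.midpoint[b_old, 0]
            cand.supremum[b_old, 1:] = cand.supremum[b_old, 0]
            cand.growth_rate[b_old, 1:] = cand.growth_rate[b_old, 0]
            cand.pi1 = np.full_like(cand.pi1, 0.5)
            cand = _equilibrate_weights(dataset, cand, hyper)
            o = log_posterior(dataset, cand, hyper)
            if o > obj:
                params, obj = cand, o
    return params


def _run_restart(dataset, hyper, rng, subject_batches=None):
    params = initialize(dataset, hyper, rng)
    obj = log_posterior(dataset, params, hyper)
    if not np.isfinite(obj):
        return None, [obj], False, 0
    trace = [obj]
    lam_t, lam_s, lam_tau = hyper.lambda_theta, hyper.lambda_sigma, hyper.lambda_tau
    lam_cap = 4.0 * max(lam_t, lam_s, lam_tau)
    best_obj, best_params, best_k = obj, params.copy(), 0
    converged = False
    k = 0
    for k in range(1, hyper.K):
        if k % 20 == 0:
            params = _reseed_components(dataset, params, hyper)
            # the wrong-host trap needs few biomarkers to lock in; the pair
            # sweep is quadratic in B, so only run it where it matters
            if k % 40 == 20 and dataset.n_biomarkers <= 3:
                params = _swap_split_host(dataset, params, hyper)
        prev = params.copy()
        try:
            fw = _forward(dataset, params)
            # keep mixture weights epsilon-interior so no component's
            # responsibilities (and hence gradients) freeze at exactly zero
            params.xi1 = np.clip(update_xi(dataset, params, hyper, fw), 1e-6, 1 - 1e-6)
            params.pi1 = np.clip(update_pi(dataset, params, fw), 1e-6, 1 - 1e-6)
            for _ in range(hyper.N):
                params.tau = gradient_step_tau(
                    dataset, params, hyper, lambda_tau=lam_tau
                )
                params = gradient_step_theta_sigma(
                    dataset, params, hyper, lambda_theta=lam_t, lambda_sigma=lam_s
                )
        except FloatingPointError as exc:  # pragma: no cover - defensive
            logger.warning("restart aborted at iteration %d: %s", k, exc)
            return None, trace, False, k
        new_obj = log_posterior(dataset, params, hyper)
        if not np.isfinite(new_obj):
            logger.warning("non-finite objective at iteration %d; aborting restart", k)
            return None, trace, False, k
        if new_obj < trace[-1]:
            # overshoot: roll back and damp the gradient steps; the EM steps
            # themselves are ascent steps, so a decrease implicates lambda
            params = prev
            lam_t *= 0.7
            lam_s *= 0.7
            lam_tau *= 0.7
            trace.append(trace[-1])
            if lam_t < 1e-6 * hyper.lambda_theta:
                converged = True
                break
            continue
        # successful step: allow the rates to recover up to a cap
        lam_t = min(lam_t * 1.05, lam_cap)
        lam_s = min(lam_s * 1.05, lam_cap)
        lam_tau = min(lam_tau * 1.05, lam_cap)
        trace.append(new_obj)
        if new_obj > best_obj + 100.0 * hyper.tol * (abs(new_obj) + 1.0):
            best_obj, best_params, best_k = new_obj, params.copy(), k
        elif new_obj > best_obj:
            best_obj, best_params = new_obj, params.copy()
        if abs(new_obj - trace[-2]) <= hyper.tol * (abs(new_obj) + 1.0):
            converged = True
            break
        if k - best_k > 30:
            # no material improvement for 30 outer iterations (including at
            # least one reseeding round): treat as converged
            converged = True
            break
    # return the best iterate seen; with damped steps the last iterate is
    # usually (but not guaranteed to be) the best
    if best_obj > trace[-1]:
        trace.append(best_obj)
    return best_params, trace, converged, k


def fit(dataset: LongitudinalDataset, hyper: Hyperparams) -> FitResult:
    """Multi-restart MAP-EM fit; returns the restart with the highest final
    log-posterior (ties broken by the lowest restart index)."""
    if dataset.n_subjects < 1:
        raise ValueError("dataset is empty")
    hyper.check_admissible(dataset.n_subjects)
    rng = np.random.default_rng(hyper.seed)
    best = None
    restart_objectives: list[float] = []
    for r in range(hyper.n_restarts):
        params, trace, converged, k = _run_restart(dataset, hyper, rng)
        final = trace[-1] if params is not None else -np.inf
        restart_objectives.append(float(final))
        if params is not None and (best is None or final > best[1][-1]):
            best = (params, trace, converged, k, r)
    if best is None:
        raise RuntimeError("all restarts diverged")
    params, trace, converged, k, r = best
    split_prob = 1.0 - params.xi1
    params = _relabel_branches(params, split_prob)
    return FitResult(
        params=params,
        objective_trace=[float(v) for v in trace],
        split_probability=split_prob,
        subtype_probability=params.pi1.copy(),
        best_restart_index=r,
        converged=converged,
        n_iter=k,
        restart_objectives=restart_objectives,
    )


def fit_new_subjects(
    frozen_params: ModelParamsM2,
    biomarker_names: list[str],
    new_dataset: LongitudinalDataset,
    hyper: Hyperparams | None = None,
) -> pd.DataFrame:
    """Stage new subjects under a frozen trained model.

    Trajectories, noise levels and split probabilities are held fixed; only
    the per-subject time shift and branch probability are re-estimated by
    alternating the ``pi`` EM step with gradient sweeps on ``tau``.  The new
    dataset's biomarkers must be a subset of the trained ones; missing
    biomarkers are simply skipped.

    The time-shift learning rate here is much larger than during training:
    with every trajectory frozen the shift is the only free real-valued
    parameter and must travel across the whole disease axis to stage a new
    subject, and it can no longer drag the curves along to overfit.

    Returns a frame with columns ``subject_id``, ``tau``,
    ``subtype_probability``.
    """
    overlap = [b for b in new_dataset.biomarker_names if b in biomarker_names]
    if not overlap:
        raise ValueError("no overlap between trained and new biomarkers")
    ds = (
        new_dataset
        if overlap == new_dataset.biomarker_names
        else new_dataset.subset_biomarkers(overlap)
    )
    idx = [biomarker_names.index(b) for b in overlap]
    J = ds.n_subjects
    params = ModelParamsM2(
        midpoint=frozen_params.midpoint[idx],
        growth_rate=frozen_params.growth_rate[idx],
        supremum=frozen_params.supremum[idx],
        sigma=frozen_params.sigma[idx],
        xi1=frozen_params.xi1[idx],
        tau=np.zeros(J),
        pi1=np.full(J, 0.5),
    )
    if hyper is None:
        hyper = Hyperparams(
            beta_sigma=2.0, beta_xi=0.5, beta_tau=_BETA_TAU_DEFAULT
        )  # beta_sigma / beta_xi are inert here (theta, sigma, xi frozen)
    if hyper.lambda_tau < 0.5:
        hyper = dataclasses.replace(hyper, lambda_tau=0.5)
    obj = log_posterior(ds, params, hyper)
    lam_tau = hyper.lambda_tau
    for _ in range(1, hyper.K):
        fw = _forward(ds, params)
        params.pi1 = update_pi(ds, params, fw)
        for _ in range(hyper.N):
            params.tau = gradient_step_tau(ds, params, hyper, lambda_tau=lam_tau)
        new_obj = log_posterior(ds, params, hyper)
        if abs(new_obj - obj) <= hyper.tol * (abs(new_obj) + 1.0):
            obj = new_obj
            break
        obj = new_obj
    return pd.DataFrame(
        {
            "subject_id": ds.subject_ids,
            "tau": params.tau,
            "subtype_probability": params.pi1,
        }
    )


class DPMoSt(BaseEstimator):
    """Disease-progression model with per-biomarker subtype discovery.

    A two-level mixture over sigmoid biomarker trajectories: each biomarker
    either follows one shared trajectory or splits into two subtype-specific
    sub-trajectories, and each subject receives a probability of belonging to
    either subtype together with a time shift staging it on the long-term
    disease axis.  Fitting is penalized MAP-EM (see module docstring).

    Parameters
    ----------
    beta_xi, beta_sigma : float or "auto"
        Penalty strengths; ``"auto"`` sets both to ``0.15 * n_subjects``.
    beta_tau : float
        Quadratic penalty on time shifts; default corresponds to a Gaussian
        prior with SD 40 time units.
    lambda_theta, lambda_sigma, lambda_tau : float
        Learning rates of the gradient sweeps.
    n_outer, n_inner : int
        Outer EM iterations (K) and inner gradient sweeps per outer (N).
    n_restarts : int
        Independent random initializations.
    tol : float
        Relative objective-change convergence tolerance.
    random_state : int or None
        Seed for the initialization draws.

    Attributes
    ----------
    params_ : ModelParamsM2
        Fitted parameter state.
    split_probability_ : pandas.Series
        Per-biomarker probability of being subtype-specific (``1 - xi_b1``).
    subtype_probability_ : pandas.Series
        Per-subject probability of branch 1 (``pi_j(2,1)``).
    tau_ : pandas.Series
        Per-subject time shift.
    objective_trace_ : list of float
        Log-posterior per outer iteration of the best restart.
    """

    def __init__(
        self,
        *,
        beta_xi="auto",
        beta_sigma="auto",
        beta_tau=_BETA_TAU_DEFAULT,
        lambda_theta=0.5,
        lambda_sigma=0.5,
        lambda_tau=0.05,
        n_outer=200,
        n_inner=10,
        n_restarts=10,
        tol=1e-6,
        random_state=None,
    ):
        self.beta_xi = beta_xi
        self.beta_sigma = beta_sigma
        self.beta_tau = beta_tau
        self.lambda_theta = lambda_theta
        self.lambda_sigma = lambda_sigma
        self.lambda_tau = lambda_tau
        self.n_outer = n_outer
        self.n_inner = n_inner
        self.n_restarts = n_restarts
        self.tol = tol
        self.random_state = random_state

    def _as_dataset(self, X) -> LongitudinalDataset:
        if isinstance(X, LongitudinalDataset):
            return X
        if isinstance(X, pd.DataFrame):
            return LongitudinalDataset.from_long(X)
        raise TypeError(
            "X must be a LongitudinalDataset or a long-format DataFrame "
            "with columns subject_id, biomarker, time, value"
        )

    def _hyper(self, J: int) -> Hyperparams:
        overrides = dict(
            beta_tau=self.beta_tau,
            lambda_theta=self.lambda_theta,
            lambda_sigma=self.lambda_sigma,
            lambda_tau=self.lambda_tau,
            K=self.n_outer,
            N=self.n_inner,
            n_restarts=self.n_restarts,
            tol=self.tol,
            seed=0 if self.random_state is None else int(self.random_state),
        )
        if self.beta_xi != "auto":
            overrides["beta_xi"] = float(self.beta_xi)
        if self.beta_sigma != "auto":
            overrides["beta_sigma"] = float(self.beta_sigma)
        return default_hyperparams(J, **overrides)

    def fit(self, X, y=None):
        """Fit the model to a long-format frame or LongitudinalDataset."""
        ds = self._as_dataset(X)
        hyper = self._hyper(ds.n_subjects)
        res = fit(ds, hyper)
        self.result_ = res
        self.params_ = res.params
        self.hyper_ = hyper
        self.biomarker_names_ = list(ds.biomarker_names)
        self.subject_ids_ = list(ds.subject_ids)
        self.split_probability_ = pd.Series(
            res.split_probability, index=self.biomarker_names_, name="split_probability"
        )
        self.subtype_probability_ = pd.Series(
            res.subtype_probability, index=self.subject_ids_, name="subtype_probability"
        )
        self.tau_ = pd.Series(res.params.tau, index=self.subject_ids_, name="tau")
        self.objective_trace_ = res.objective_trace
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        return self

    def stage(self, X) -> pd.DataFrame:
        """Stage new subjects under the frozen fitted model (transfer fit).

        Only the time shift and subtype probability of each new subject are
        estimated; trained trajectories, noise levels and split probabilities
        stay fixed.  The new data may contain a subset of the trained
        biomarkers.
        """
        self._check_fitted()
        ds = self._as_dataset(X)
        hyper = Hyperparams(
            beta_sigma=self.hyper_.beta_sigma,
            beta_xi=self.hyper_.beta_xi,
            beta_tau=self.hyper_.beta_tau,
            lambda_tau=self.hyper_.lambda_tau,
            K=self.hyper_.K,
            N=self.hyper_.N,
            tol=self.hyper_.tol,
        )
        return fit_new_subjects(self.params_, self.biomarker_names_, ds, hyper)

    def predict_subtype(self, X) -> pd.Series:
        """Hard subtype labels (0 = branch 2, 1 = branch 1) for new subjects."""
        staged = self.stage(X)
        return pd.Series(
            (staged["subtype_probability"].to_numpy() > 0.5).astype(int),
            index=staged["subject_id"],
            name="subtype",
        )

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood of ``X`` after staging its
        subjects under the frozen model."""
        self._check_fitted()
        ds = self._as_dataset(X)
        staged = fit_new_subjects(self.params_, self.biomarker_names_, ds)
        overlap = [b for b in ds.biomarker_names if b in self.biomarker_names_]
        sub = ds.subset_biomarkers(overlap)
        idx = [self.biomarker_names_.index(b) for b in overlap]
        params = ModelParamsM2(
            midpoint=self.params_.midpoint[idx],
            growth_rate=self.params_.growth_rate[idx],
            supremum=self.params_.supremum[idx],
            sigma=self.params_.sigma[idx],
            xi1=self.params_.xi1[idx],
            tau=staged["tau"].to_numpy(),
            pi1=staged["subtype_probability"].to_numpy(),
        )
        from .model import total_loglik

        return total_loglik(sub, params) / max(sub.n_observations, 1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("this DPMoSt instance is not fitted yet")
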