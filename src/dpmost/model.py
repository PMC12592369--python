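"""Core generative model: sigmoid trajectories and the two-level mixture.

The model describes longitudinal biomarker measurements of ``J`` subjects over
``B`` biomarkers.  Each biomarker follows a monotonically increasing logistic
(sigmoid) trajectory along a common long-term disease axis; every subject ``j``
observes only a short window of that axis, aligned through a subject-specific
time shift ``tau_j`` (``phi_j(t) = t + tau_j``).

Heterogeneity is captured by a two-level mixture.  At the first level each
biomarker ``b`` either follows one shared trajectory (probability ``xi_b1``)
or splits into two subtype-specific sub-trajectories (probability
``1 - xi_b1``).  At the second level, conditional on a split, each subject
belongs to branch 1 with probability ``pi_j21`` and to branch 2 otherwise.
Measurement noise is i.i.d. Gaussian with per-biomarker standard deviation
``sigma_b``.

This module holds the pure mathematics: trajectory evaluation, per-component
log-likelihoods, the mixture likelihood, the log-prior of the penalized MAP
objective, and parameter bookkeeping.  The fitting algorithm lives in
:mod:`dpmost.estimator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "SigmoidParams",
    "LongitudinalDataset",
    "ModelParamsM2",
    "Hyperparams",
    "sigmoid_value",
    "reparametrize_time",
    "component_loglik",
    "subject_biomarker_mixture_lik",
    "total_loglik",
    "log_prior",
    "log_posterior",
    "parameter_count",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of one logistic trajectory component.

    The trajectory is ``S(t) = supremum / (1 + exp(-growth_rate * (t - midpoint)))``,
    increasing from 0 (healthy) toward ``supremum`` (fully pathological).

    Parameters
    ----------
    midpoint : float
        Inflection time, in the units of the disease axis.
    growth_rate : float
        Progression speed (1 / time unit); must be positive.
    supremum : float
        Upper asymptote in biomarker units; must be positive.
    """

    midpoint: float
    growth_rate: float
    supremum: float

    def __post_init__(self) -> None:
        for name in ("midpoint", "growth_rate", "supremum"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.growth_rate <= 0:
            raise ValueError(f"growth_rate must be > 0, got {self.growth_rate}")
        if self.supremum <= 0:
            raise ValueError(f"supremum must be > 0, got {self.supremum}")


def sigmoid_value(t, params: SigmoidParams):
    """Evaluate the logistic trajectory at time(s) ``t``.

    Accepts a scalar or array ``t``; returns the same shape.  Strictly
    increasing in ``t``, with range ``(0, supremum)``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    out = params.supremum * expit(params.growth_rate * (t - params.midpoint))
    return float(out) if out.ndim == 0 else out


def reparametrize_time(t, tau):
    """Map observed time onto the disease axis: ``phi(t) = t + tau``."""
    t = np.asarray(t, dtype=float)
    if not (np.all(np.isfinite(t)) and np.isfinite(tau)):
        raise ValueError("time and tau must be finite")
    out = t + tau
    return float(out) if out.ndim == 0 else out


class LongitudinalDataset:
    """Per-subject, per-biomarker longitudinal measurements.

    Visit times are shared across biomarkers within a subject; individual
    biomarker values may be missing (NaN) at any visit.

    Parameters
    ----------
    subject_ids : sequence of str
        One identifier per subject.
    times : sequence of 1-D arrays
        Strictly increasing visit times per subject (arbitrary but common
        time unit).
    values : sequence of 2-D arrays
        Per subject an array of shape ``(n_biomarkers, n_visits)``; NaN marks
        a missing measurement.
    biomarker_names : sequence of str
        Ordered biomarker names, identical for all subjects.
    """

    def __init__(self, subject_ids, times, values, biomarker_names):
        self.subject_ids = [str(s) for s in subject_ids]
        self.biomarker_names = [str(b) for b in biomarker_names]
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if len(set(self.biomarker_names)) != len(self.biomarker_names):
            raise ValueError("duplicate biomarker names")
        B = len(self.biomarker_names)
        self.times = [np.asarray(t, dtype=float).ravel() for t in times]
        self.values = [np.asarray(v, dtype=float) for v in values]
        if len(self.times) != len(self.subject_ids) or len(self.values) != len(
            self.subject_ids
        ):
            raise ValueError("subject_ids, times and values lengths differ")
        for sid, t, v in zip(self.subject_ids, self.times, self.values):
            if t.size < 1:
                raise ValueError(f"subject {sid}: at least one visit required")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"subject {sid}: non-finite visit time")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"subject {sid}: times must be strictly increasing")
            if v.shape != (B, t.size):
                raise ValueError(
                    f"subject {sid}: values shape {v.shape} != ({B}, {t.size})"
                )
            finite = np.isfinite(v)
            if np.any(~finite & ~np.isnan(v)):
                raise ValueError(f"subject {sid}: non-finite (inf) value")
        self._build_padded()

    def _build_padded(self) -> None:
        J, B = self.n_subjects, self.n_biomarkers
        L = max(t.size for t in self.times)
        self.times_padded = np.full((J, L), np.nan)
        self.values_padded = np.full((J, B, L), np.nan)
        for j, (t, v) in enumerate(zip(self.times, self.values)):
            self.times_padded[j, : t.size] = t
            self.values_padded[j, :, : t.size] = v
        self.mask = np.isfinite(self.values_padded) & np.isfinite(
            self.times_padded[:, None, :]
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarker_names)

    @property
    def n_observations(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "LongitudinalDataset":
        """Build a dataset from a tidy long-format frame.

        Expects columns ``subject_id``, ``biomarker``, ``time``, ``value``.
        Duplicate ``(subject_id, biomarker, time)`` keys raise.
        """
        required = {"subject_id", "biomarker", "time", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["biomarker"] = df["biomarker"].astype(str)
        dup = df.duplicated(["subject_id", "biomarker", "time"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise ValueError(
                f"duplicate (subject_id, biomarker, time) keys at rows {rows}"
            )
        biomarkers = list(pd.unique(df["biomarker"]))
        subjects = list(pd.unique(df["subject_id"]))
        times, values = [], []
        for sid in subjects:
            sub = df[df["subject_id"] == sid]
            t = np.sort(pd.unique(sub["time"].astype(float)))
            wide = sub.pivot_table(
                index="biomarker", columns="time", values="value", aggfunc="first"
            ).reindex(index=biomarkers, columns=t)
            times.append(t)
            values.append(wide.to_numpy(dtype=float))
        return cls(subjects, times, values, biomarkers)

    def to_long(self) -> pd.DataFrame:
        """Export to tidy long format; missing values are omitted."""
        rows = []
        for sid, t, v in zip(self.subject_ids, self.times, self.values):
            for bi, name in enumerate(self.biomarker_names):
                for li in range(t.size):
                    if np.isfinite(v[bi, li]):
                        rows.append((sid, name, t[li], v[bi, li]))
        return pd.DataFrame(rows, columns=["subject_id", "biomarker", "time", "value"])

    def subset_subjects(self, indices: Iterable[int]) -> "LongitudinalDataset":
        idx = list(indices)
        return LongitudinalDataset(
            [self.subject_ids[i] for i in idx],
            [self.times[i] for i in idx],
            [self.values[i] for i in idx],
            self.biomarker_names,
        )

    def subset_biomarkers(self, names: Sequence[str]) -> "LongitudinalDataset":
        idx = [self.biomarker_names.index(n) for n in names]
        return LongitudinalDataset(
            self.subject_ids,
            self.times,
            [v[idx, :] for v in self.values],
            [self.biomarker_names[i] for i in idx],
        )


# Component axis convention used throughout: index 0 is the shared (single)
# trajectory, indices 1 and 2 are the two subtype branches.
@dataclass
class ModelParamsM2:
    """Full parameter state of the two-subtype model.

    Arrays ``midpoint``, ``growth_rate`` and ``supremum`` have shape
    ``(B, 3)`` with component axis [single, branch 1, branch 2]; ``sigma``
    and ``xi1`` have shape ``(B,)``; ``tau`` and ``pi1`` have shape ``(J,)``.
    ``xi1`` is the probability that biomarker ``b`` does NOT split; ``pi1`` is
    the probability that subject ``j`` follows branch 1 given a split.  The
    complements are never stored (they are determined by normalization).
    """

    midpoint: np.ndarray
    growth_rate: np.ndarray
    supremum: np.ndarray
    sigma: np.ndarray
    xi1: np.ndarray
    tau: np.ndarray
    pi1: np.ndarray

    def __post_init__(self) -> None:
        self.midpoint = np.asarray(self.midpoint, dtype=float)
        self.growth_rate = np.asarray(self.growth_rate, dtype=float)
        self.supremum = np.asarray(self.supremum, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.xi1 = np.asarray(self.xi1, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.pi1 = np.asarray(self.pi1, dtype=float)
        self.validate()

    def validate(self) -> None:
        B = self.sigma.shape[0]
        J = self.tau.shape[0]
        for name in ("midpoint", "growth_rate", "supremum"):
            arr = getattr(self, name)
            if arr.shape != (B, 3):
                raise ValueError(f"{name} must have shape ({B}, 3), got {arr.shape}")
        if self.xi1.shape != (B,) or self.pi1.shape != (J,):
            raise ValueError("xi1 / pi1 shape mismatch")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if np.any(self.growth_rate <= 0) or np.any(self.supremum <= 0):
            raise ValueError("growth rates and suprema must be > 0")
        if np.any((self.xi1 < 0) | (self.xi1 > 1)):
            raise ValueError("xi1 must lie in [0, 1]")
        if np.any((self.pi1 < 0) | (self.pi1 > 1)):
            raise ValueError("pi1 must lie in [0, 1]")

    @property
    def n_biomarkers(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.tau.shape[0]

    def theta_single(self, b: int) -> SigmoidParams:
        return SigmoidParams(
            self.midpoint[b, 0], self.growth_rate[b, 0], self.supremum[b, 0]
        )

    def theta_split(self, b: int) -> tuple[SigmoidParams, SigmoidParams]:
        return (
            SigmoidParams(self.midpoint[b, 1], self.growth_rate[b, 1], self.supremum[b, 1]),
            SigmoidParams(self.midpoint[b, 2], self.growth_rate[b, 2], self.supremum[b, 2]),
        )

    def copy(self) -> "ModelParamsM2":
        return ModelParamsM2(
            self.midpoint.copy(),
            self.growth_rate.copy(),
            self.supremum.copy(),
            self.sigma.copy(),
            self.xi1.copy(),
            self.tau.copy(),
            self.pi1.copy(),
        )

    def n_parameters(self) -> int:
        """Enumerated parameter count in the model's hierarchical convention.

        Per biomarker: the 3 sigmoid components x 3 scalars, the noise SD and
        the no-split probability.  Per subject: the time shift plus the full
        branch-probability hierarchy ``pi_j(m, k)`` for ``m <= 2`` (three
        entries, of which the stored ``pi1`` determines the rest).
        """
        B, J = self.n_biomarkers, self.n_subjects
        sigmoid_scalars = 3 * self.midpoint.shape[1]  # 3 scalars per component
        per_biomarker = sigmoid_scalars + 2  # + sigma + xi1
        pi_hierarchy = 1 + 2  # pi(1,1); pi(2,1), pi(2,2)
        return B * per_biomarker + J * (pi_hierarchy + 1)


@dataclass
class Hyperparams:
    """Hyperparameters of the penalized MAP objective and of the optimizer.

    ``beta_sigma`` scales the inverse-gamma penalty on the noise SDs (must
    exceed 1), ``beta_xi`` the sparsity reward for the no-split probabilities
    (admissible range ``0 < beta_xi < J``), and ``beta_tau`` the quadratic
    penalty on time shifts.  ``lambda_*`` are gradient-ascent learning rates,
    ``K`` the number of outer iterations, ``N`` the inner gradient sweeps per
    outer iteration, ``n_restarts`` the number of random restarts and ``tol``
    the relative objective-change convergence tolerance.
    """

    beta_sigma: float
    beta_xi: float
    beta_tau: float
    lambda_theta: float = 0.5
    lambda_sigma: float = 0.5
    lambda_tau: float = 0.05
    K: int = 200
    N: int = 10
    n_restarts: int = 10
    seed: int = 0
    tol: float = 1e-6
    batch_size: int | None = None  # optional mini-batch over subjects

    def __post_init__(self) -> None:
        if self.beta_sigma <= 1:
            raise ValueError("beta_sigma must be > 1 (inverse-gamma scale)")
        if self.beta_tau < 0:
            raise ValueError("beta_tau must be >= 0")
        for name in ("lambda_theta", "lambda_sigma", "lambda_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.K < 1 or self.N < 1 or self.n_restarts < 1:
            raise ValueError("K, N and n_restarts must be >= 1")

    def check_admissible(self, n_subjects: int) -> None:
        """Check the admissibility bound ``0 < beta_xi < J`` at fit time."""
        if not (0 < self.beta_xi < n_subjects):
            raise ValueError(
                f"beta_xi={self.beta_xi} violates the admissibility bound "
                f"0 < beta_xi < J (J={n_subjects})"
            )


def component_loglik(values, times, params: SigmoidParams, sigma: float, tau: float) -> float:
    """Gaussian log-likelihood of one subject-biomarker series under one component.

    ``sum_l log N(x(t_l); S(t_l + tau), sigma^2)`` over non-missing visits.
    Missing values (NaN) are skipped; an all-missing series contributes 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    values = np.asarray(values, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    if values.shape != times.shape:
        raise ValueError("values and times must have equal length")
    keep = np.isfinite(values)
    if not keep.any():
        return 0.0
    pred = sigmoid_value(reparametrize_time(times[keep], tau), params)
    resid = values[keep] - pred
    n = resid.size
    return float(-0.5 * n * (_LOG_2PI + 2 * math.log(sigma)) - np.sum(resid**2) / (2 * sigma**2))


def subject_biomarker_mixture_lik(
    values,
    times,
    params_b: tuple[SigmoidParams, SigmoidParams, SigmoidParams],
    xi_b1: float,
    pi_j21: float,
    sigma_b: float,
    tau_j: float,
) -> float:
    """Two-level mixture likelihood of one subject-biomarker series.

    ``xi_b1 * L_single + (1 - xi_b1) * (pi_j21 * L_branch1 + (1 - pi_j21) * L_branch2)``
    where each ``L`` is the exponentiated component log-likelihood.

    ``params_b`` is the (single, branch 1, branch 2) triple for biomarker
    ``b``.  Computed through log-sum-exp; always strictly positive on the
    returned (linear) scale up to floating-point underflow.
    """
    if not (0 <= xi_b1 <= 1 and 0 <= pi_j21 <= 1):
        raise ValueError("xi_b1 and pi_j21 must lie in [0, 1]")
    lls = np.array(
        [component_loglik(values, times, p, sigma_b, tau_j) for p in params_b]
    )
    with np.errstate(divide="ignore"):
        logw = np.array(
            [
                np.log(xi_b1),
                np.log1p(-xi_b1) + np.log(pi_j21),
                np.log1p(-xi_b1) + np.log1p(-pi_j21),
            ]
        )
    a = logw + lls
    amax = a.max()
    return float(np.exp(amax) * np.sum(np.exp(a - amax)))


def _forward(dataset: LongitudinalDataset, params: ModelParamsM2):
    """Evaluate all per-(subject, biomarker) mixture terms in one fused pass.

    Returns a dict with the component log-likelihoods ``ll`` (J, B, 3), the
    mixture log-density ``logp`` (J, B), the component responsibilities
    ``resp`` (J, B, 3), the observation counts ``nobs`` (J, B) and the
    gradient accumulators ``A``, ``Ct``, ``D``, ``SS`` (J, B, 3) documented
    in :mod:`dpmost._kernels`.
    """
    from ._kernels import forward_kernel

    ll, logp, resp, nobs, A, Ct, D, SS = forward_kernel(
        dataset.times_padded,
        dataset.values_padded,
        dataset.mask,
        params.midpoint,
        params.growth_rate,
        params.supremum,
        params.sigma,
        params.xi1,
        params.tau,
        params.pi1,
    )
    return {
        "ll": ll,
        "logp": logp,
        "resp": resp,
        "nobs": nobs,
        "A": A,
        "Ct": Ct,
        "D": D,
        "SS": SS,
    }


def total_loglik(dataset: LongitudinalDataset, params: ModelParamsM2) -> float:
    """Total data log-likelihood: sum over subjects and biomarkers of the
    log of the two-level mixture density (computed with log-sum-exp)."""
    return float(_forward(dataset, params)["logp"].sum())


def log_prior(params: ModelParamsM2, hyper: Hyperparams) -> float:
    """Additive penalty of the MAP objective.

    ``-beta_sigma * sum_b (ln sigma_b + 1/sigma_b) + beta_xi * sum_b xi_b1
    - beta_tau * sum_j tau_j^2``; the improper uniform priors on the sigmoid
    parameters and on ``pi`` contribute 0.
    """
    return float(
        -hyper.beta_sigma * np.sum(np.log(params.sigma) + 1.0 / params.sigma)
        + hyper.beta_xi * np.sum(params.xi1)
        - hyper.beta_tau * np.sum(params.tau**2)
    )


def log_posterior(
    dataset: LongitudinalDataset, params: ModelParamsM2, hyper: Hyperparams
) -> float:
    """Unnormalized log-posterior: ``total_loglik + log_prior``."""
    return total_loglik(dataset, params) + log_prior(params, hyper)


def parameter_count(B: int, J: int, M: int) -> int:
    """Total number of model parameters for ``B`` biomarkers, ``J`` subjects
    and ``M`` subtypes: ``B (3 M (M+1)/2 + 2) + J (M (M+1)/2 + 1)``."""
    if B < 1 or J < 1 or M < 1:
        raise ValueError("B, J and M must be positive integers")
    tri = M * (M + 1) // 2
    return B * (3 * tri + 2) + J * (tri + 1)
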