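"""Synthetic longitudinal cohorts with known subtype structure.

Generates the simulation conditions used to benchmark the model: 50-subject
cohorts observed at 2, 5 or 7 visits drawn uniformly from a 20-unit time
window, with 2, 5 or 7 biomarkers of which 1, 3 or 4 respectively are
subtype-specific, Gaussian measurement noise at variance 0.7, 0.5 or 0.2, and
subjects split evenly between two subtypes.  Visit times are absolute
positions on the disease axis; an optional per-subject re-centring (first
visit at 0) hides the absolute position so that it must be recovered through
the time shift, as in the staging experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .model import LongitudinalDataset, SigmoidParams, sigmoid_value

__all__ = ["SimulationConfig", "GroundTruth", "generate_dataset", "generate_grid"]

# number of subtype-specific biomarkers per cohort size
_SPECIFIC_PAIRING = {2: 1, 5: 3, 7: 4}

# sampling moments for trajectory parameters
_MID_MEAN, _MID_SD = 10.0, 3.0
_SUP_MEAN, _SUP_SD = 2.0, 0.5
_RATE_MEAN, _RATE_SD, _RATE_FLOOR = 0.6, 0.2, 0.1
_RATE_MIN_SEPARATION = 0.3  # between the two subtype growth rates of a split


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid."""

    n_subjects: int = 50
    n_timepoints: int = 5
    noise_variance: float = 0.2
    n_biomarkers: int = 5
    n_specific: int | None = None
    time_window: tuple[float, float] = (0.0, 20.0)
    recenter_times: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ValueError("n_subjects must be even and >= 2 (balanced subtypes)")
        if self.n_timepoints < 1 or self.n_biomarkers < 1:
            raise ValueError("n_timepoints and n_biomarkers must be >= 1")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be > 0")
        if self.time_window[1] <= self.time_window[0]:
            raise ValueError("empty time window")
        if self.resolved_specific > self.n_biomarkers:
            raise ValueError("n_specific cannot exceed n_biomarkers")

    @property
    def resolved_specific(self) -> int:
        if self.n_specific is not None:
            return self.n_specific
        try:
            return _SPECIFIC_PAIRING[self.n_biomarkers]
        except KeyError:
            raise ValueError(
                f"no default subtype-specific count for {self.n_biomarkers} "
                "biomarkers; set n_specific explicitly"
            ) from None


@dataclass
class GroundTruth:
    """Generating truth of a synthetic cohort.

    ``trajectories[b][s]`` holds the sigmoid of biomarker ``b`` for subtype
    ``s`` (identical objects for non-split biomarkers).  ``time_offset`` is
    the absolute time of each subject's first visit — the subject's true
    position on the disease axis, and the quantity removed from observed
    times when the cohort is generated with ``recenter_times``.
    """

    subtype_label: np.ndarray  # (J,) in {0, 1}
    split_flag: np.ndarray  # (B,) bool
    trajectories: list[tuple[SigmoidParams, SigmoidParams]]
    noise_sd: float
    time_offset: np.ndarray  # (J,)

    def true_growth_rates(self, b: int) -> tuple[float, float]:
        """(r_bar_b0, r_bar_b1): true growth rates of the two subtypes;
        identical when the biomarker does not split."""
        return (
            self.trajectories[b][0].growth_rate,
            self.trajectories[b][1].growth_rate,
        )


def _draw_sigmoid(rng: np.random.Generator, window) -> SigmoidParams:
    lo, hi = window
    mid = rng.normal(_MID_MEAN, _MID_SD)
    while not (lo <= mid <= hi):
        mid = rng.normal(_MID_MEAN, _MID_SD)
    sup = abs(rng.normal(_SUP_MEAN, _SUP_SD))
    while sup <= 0:
        sup = abs(rng.normal(_SUP_MEAN, _SUP_SD))
    rate = abs(rng.normal(_RATE_MEAN, _RATE_SD))
    while rate < _RATE_FLOOR:
        rate = abs(rng.normal(_RATE_MEAN, _RATE_SD))
    return SigmoidParams(mid, rate, sup)


def generate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[LongitudinalDataset, GroundTruth]:
    """Generate one synthetic cohort with ground truth.

    Subjects are split evenly between two subtypes; ``n_specific`` biomarkers
    receive two distinct trajectories (growth rates separated by at least
    0.3, enforced by rejection so the trajectory-error metric is well posed),
    the rest one shared trajectory.  Observations are the sigmoid value at
    the subject's absolute visit times plus Gaussian noise.  With
    ``recenter_times`` each subject's observed times are shifted so the first
    visit is 0, hiding the absolute position on the disease axis so that it
    must be recovered through the time shift (used by the staging
    experiments); by default absolute times are kept, as in the benchmark
    protocol.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    J, B = config.n_subjects, config.n_biomarkers
    n_spec = config.resolved_specific
    lo, hi = config.time_window
    noise_sd = float(np.sqrt(config.noise_variance))

    labels = np.zeros(J, dtype=int)
    labels[rng.choice(J, size=J // 2, replace=False)] = 1
    split_flag = np.zeros(B, dtype=bool)
    split_flag[rng.choice(B, size=n_spec, replace=False)] = True

    trajectories: list[tuple[SigmoidParams, SigmoidParams]] = []
    for b in range(B):
        if split_flag[b]:
            p0 = _draw_sigmoid(rng, config.time_window)
            p1 = _draw_sigmoid(rng, config.time_window)
            while abs(p0.growth_rate - p1.growth_rate) < _RATE_MIN_SEPARATION:
                p1 = _draw_sigmoid(rng, config.time_window)
            trajectories.append((p0, p1))
        else:
            p = _draw_sigmoid(rng, config.time_window)
            trajectories.append((p, p))

    times, values = [], []
    offsets = np.empty(J)
    for j in range(J):
        t_abs = np.sort(rng.uniform(lo, hi, size=config.n_timepoints))
        # ties under float64 uniforms are practically impossible; guard anyway
        while config.n_timepoints > 1 and np.any(np.diff(t_abs) <= 0):
            t_abs = np.sort(rng.uniform(lo, hi, size=config.n_timepoints))
        offsets[j] = t_abs[0]
        v = np.empty((B, config.n_timepoints))
        for b in range(B):
            traj = trajectories[b][labels[j]]
            v[b] = sigmoid_value(t_abs, traj) + rng.normal(
                0.0, noise_sd, size=config.n_timepoints
            )
        times.append(t_abs - t_abs[0] if config.recenter_times else t_abs)
        values.append(v)

    dataset = LongitudinalDataset(
        [f"s{j:03d}" for j in range(J)],
        times,
        values,
        [f"biomarker_{b}" for b in range(B)],
    )
    truth = GroundTruth(
        subtype_label=labels,
        split_flag=split_flag,
        trajectories=trajectories,
        noise_sd=noise_sd,
        time_offset=offsets,
    )
    return dataset, truth


def generate_grid(replicates: int = 100, base_seed: int = 0) -> list[SimulationConfig]:
    """Full factorial grid: biomarkers {2,5,7} x visits {2,5,7} x noise
    variance {0.7,0.5,0.2}, ``replicates`` seeds per cell."""
    configs = []
    cells = list(
        itertools.product((2, 5, 7), (2, 5, 7), (0.7, 0.5, 0.2))
    )
    for ci, (nb, tp, nv) in enumerate(cells):
        for r in range(replicates):
            configs.append(
                SimulationConfig(
                    n_biomarkers=nb,
                    n_timepoints=tp,
                    noise_variance=nv,
                    seed=base_seed + ci * replicates + r,
                )
            )
    return configs
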