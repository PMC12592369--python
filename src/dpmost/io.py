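"""Readers, writers, normalization and model serialization.

Longitudinal data travel as tidy long-format CSV (one row per subject x
biomarker x visit with columns ``subject_id, biomarker, time, value``), which
handles per-biomarker missingness natively.  Fitted models are serialized to
a JSON document carrying biomarker names, all sigmoid parameters, noise SDs,
split probabilities, hyperparameters and the library version, sufficient for
staging new subjects in a later session.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import Hyperparams, LongitudinalDataset, ModelParamsM2

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "normalize_severity",
    "inverse_normalize",
    "save_model",
    "load_model",
    "write_manifest",
]

_COLUMNS = ["subject_id", "biomarker", "time", "value"]


def read_long_csv(path) -> LongitudinalDataset:
    """Read a long-format CSV into a validated dataset.

    Empty value cells are treated as missing; non-numeric value or time
    entries raise with the offending row numbers (1-based, header excluded).
    Duplicate ``(subject_id, biomarker, time)`` keys raise.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "biomarker": str})
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    raw_value = df["value"]
    df["value"] = pd.to_numeric(raw_value, errors="coerce")
    bad = df["value"].isna() & raw_value.notna() & (raw_value.astype(str).str.strip() != "")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    bad |= df["time"].isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable numeric fields at line(s) {rows}")
    dup = df.duplicated(["subject_id", "biomarker", "time"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(
            f"{path}: duplicate (subject_id, biomarker, time) key at line {line}"
        )
    return LongitudinalDataset.from_long(df)


def write_long_csv(dataset: LongitudinalDataset, path) -> None:
    dataset.to_long().to_csv(path, index=False)


def normalize_severity(
    dataset: LongitudinalDataset, direction_map: dict[str, str] | None = None
) -> tuple[LongitudinalDataset, dict]:
    """Z-score every biomarker and orient it to increase with severity.

    ``direction_map`` maps biomarker name to ``"increase"`` (default) or
    ``"decrease"``; decreasing biomarkers are sign-flipped after z-scoring so
    every transformed biomarker rises from healthy to pathological, as the
    monotone-increasing trajectory model requires.  Returns the transformed
    dataset and a transform record usable with :func:`inverse_normalize`.
    """
    direction_map = direction_map or {}
    unknown = set(direction_map) - set(dataset.biomarker_names)
    if unknown:
        raise ValueError(f"direction map names unknown biomarkers: {sorted(unknown)}")
    record = {}
    new_values = [v.copy() for v in dataset.values]
    for b, name in enumerate(dataset.biomarker_names):
        pooled = dataset.values_padded[:, b, :][dataset.mask[:, b, :]]
        mean, sd = float(pooled.mean()), float(pooled.std())
        if sd == 0:
            raise ValueError(f"biomarker {name!r} has zero SD; cannot z-score")
        sign = -1.0 if direction_map.get(name, "increase") == "decrease" else 1.0
        for v in new_values:
            v[b] = sign * (v[b] - mean) / sd
        record[name] = {"mean": mean, "sd": sd, "sign": sign}
    out = LongitudinalDataset(
        dataset.subject_ids, dataset.times, new_values, dataset.biomarker_names
    )
    return out, record


def inverse_normalize(dataset: LongitudinalDataset, record: dict) -> LongitudinalDataset:
    """Undo :func:`normalize_severity` using its transform record."""
    new_values = [v.copy() for v in dataset.values]
    for b, name in enumerate(dataset.biomarker_names):
        r = record[name]
        for v in new_values:
            v[b] = v[b] / r["sign"] * r["sd"] + r["mean"]
    return LongitudinalDataset(
        dataset.subject_ids, dataset.times, new_values, dataset.biomarker_names
    )


def save_model(
    path,
    params: ModelParamsM2,
    biomarker_names: list[str],
    hyper: Hyperparams,
    subject_ids: list[str] | None = None,
) -> None:
    """Serialize a fitted model state to a JSON document."""
    doc = {
        "format": "dpmost-model",
        "version": __version__,
        "biomarker_names": list(biomarker_names),
        "subject_ids": list(subject_ids) if subject_ids is not None else None,
        "params": {
            "midpoint": params.midpoint.tolist(),
            "growth_rate": params.growth_rate.tolist(),
            "supremum": params.supremum.tolist(),
            "sigma": params.sigma.tolist(),
            "xi1": params.xi1.tolist(),
            "tau": params.tau.tolist(),
            "pi1": params.pi1.tolist(),
        },
        "hyperparams": dataclasses.asdict(hyper),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> tuple[ModelParamsM2, list[str], Hyperparams]:
    """Load a model saved with :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "dpmost-model":
        raise ValueError(f"{path}: not a dpmost model file")
    p = doc["params"]
    params = ModelParamsM2(
        midpoint=np.asarray(p["midpoint"]),
        growth_rate=np.asarray(p["growth_rate"]),
        supremum=np.asarray(p["supremum"]),
        sigma=np.asarray(p["sigma"]),
        xi1=np.asarray(p["xi1"]),
        tau=np.asarray(p["tau"]),
        pi1=np.asarray(p["pi1"]),
    )
    hyper = Hyperparams(**doc["hyperparams"])
    return params, doc["biomarker_names"], hyper


def write_manifest(path, **entries) -> None:
    """Write a small JSON run manifest (config, seed, version) next to an
    output so the run can be regenerated."""
    doc = {"version": __version__}
    doc.update(entries)
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
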