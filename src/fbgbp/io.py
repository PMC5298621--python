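"""Delimited-text and JSON serialization of records, beats and models.

Formats
-------
* Three-channel record: CSV with header ``time_s,v1,v2,v3``; the sampling
  rate is inferred from the time column and validated uniform.
* Beat matrix: CSV, one row per beat; optional leading ``subject_id``
  column, then ``x000..x{L-1}``, then ``reference_bp_mmHg`` when paired.
* References table: CSV ``record_id,subject_id,reference_bp_mmHg,split``.
* PLS model: JSON (arrays plus metadata).
* Bragg/experiment configuration: YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DomainError
from .interferometry import BraggConfig, ThreePhaseRecord
from .pls import BeatMatrix, PLSModel

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_beat_matrix_csv",
    "read_beat_matrix_csv",
    "write_references_csv",
    "read_references_csv",
    "save_model_json",
    "load_model_json",
    "load_bragg_config",
    "load_yaml_config",
]

_FLOAT_FMT = "%.10g"


def write_record_csv(record: ThreePhaseRecord, path) -> None:
    t = np.arange(len(record)) / record.fs
    df = pd.DataFrame(
        {"time_s": t, "v1": record.v1, "v2": record.v2, "v3": record.v3}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_record_csv(path) -> ThreePhaseRecord:
    df = pd.read_csv(path)
    required = {"time_s", "v1", "v2", "v3"}
    if not required.issubset(df.columns):
        raise DomainError(f"record CSV must have columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DomainError("record CSV needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
        raise DomainError("time column must be uniformly increasing")
    fs = 1.0 / dt.mean()
    return ThreePhaseRecord(
        v1=df["v1"].to_numpy(float),
        v2=df["v2"].to_numpy(float),
        v3=df["v3"].to_numpy(float),
        fs=fs,
    )


def write_beat_matrix_csv(bm: BeatMatrix, path) -> None:
    L = bm.X.shape[1]
    cols = {}
    if bm.subject_ids is not None:
        cols["subject_id"] = bm.subject_ids
    for j in range(L):
        cols[f"x{j:03d}"] = bm.X[:, j]
    cols["reference_bp_mmHg"] = bm.y
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_beat_matrix_csv(path) -> BeatMatrix:
    df = pd.read_csv(path)
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    if not xcols or "reference_bp_mmHg" not in df.columns:
        raise DomainError(
            "beat matrix CSV needs x000.. columns and reference_bp_mmHg"
        )
    xcols = sorted(xcols, key=lambda c: int(c[1:]))
    subject_ids = (
        df["subject_id"].to_numpy() if "subject_id" in df.columns else None
    )
    return BeatMatrix(
        X=df[xcols].to_numpy(float),
        y=df["reference_bp_mmHg"].to_numpy(float),
        subject_ids=subject_ids,
    )


def write_references_csv(rows: list[dict], path) -> None:
    pd.DataFrame(
        rows, columns=["record_id", "subject_id", "reference_bp_mmHg", "split"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_references_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"record_id", "subject_id", "reference_bp_mmHg", "split"}
    if not required.issubset(df.columns):
        raise DomainError(f"references CSV must have columns {sorted(required)}")
    return df


def save_model_json(model: PLSModel, path, meta: dict | None = None) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "regression_vector": model.regression_vector.tolist(),
        "n_factors": model.n_factors,
        "L": model.L,
        "software_version": __version__,
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model_json(path) -> PLSModel:
    payload = json.loads(Path(path).read_text())
    return PLSModel(
        x_mean=np.asarray(payload["x_mean"], float),
        y_mean=float(payload["y_mean"]),
        weights=np.asarray(payload["weights"], float),
        x_loadings=np.asarray(payload["x_loadings"], float),
        y_loadings=np.asarray(payload["y_loadings"], float),
        n_factors=int(payload["n_factors"]),
        regression_vector=np.asarray(payload["regression_vector"], float),
    )


def load_bragg_config(source) -> BraggConfig:
    """Build a BraggConfig from a YAML/JSON file path or a mapping."""
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    if not isinstance(source, dict):
        raise DomainError("Bragg config must be a mapping")
    kwargs = {}
    for key, name in (
        ("n_eff", "n_eff"),
        ("grating_spacing_m", "grating_spacing"),
        ("bragg_wavelength_m", "bragg_wavelength"),
        ("path_difference_m", "path_difference"),
    ):
        if key in source:
            kwargs[name] = float(source[key])
    return BraggConfig(**kwargs)


def load_yaml_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise DomainError("config file must contain a mapping")
    return cfg
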