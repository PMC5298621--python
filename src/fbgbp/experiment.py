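"""Individual-vs-pooled calibration experiment.

Reproduces the two-arm study design: for each subject, a calibration curve
is fit on that subject's 50 calibration records and evaluated on the same
subject's 25 validation records (individual curves); a single pooled curve
is fit on all 150 calibration records and evaluated both per subject and on
the pooled validation set (overall curve).  Validation is a genuinely held
out record set, not cross-validation.

Every record runs through the full measurement chain: three-phase
demodulation, phase-to-wavelength conversion, 0.5-5 Hz band-pass, beat
segmentation, ensemble averaging and normalization.  The resulting L-vector
beats are the explanatory variables of the PLS calibration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DomainError
from .interferometry import (
    BraggConfig,
    ThreePhaseRecord,
    demodulate_phase,
    phase_to_wavelength_shift,
)
from .pls import BeatMatrix, evaluate, fit_pls, predict, select_factors
from .pulse_processing import average_and_normalize, bandpass, segment_beats
from .synthetic import SubjectDataset, SubjectParams, default_subjects, simulate_subject

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "process_record",
    "build_beat_matrices",
    "summarize_datasets",
    "pool_summary_rows",
    "run_individual",
    "run_overall",
    "run_experiment",
    "write_report",
]

POOLED_LABEL = "Overall"


@dataclass
class ExperimentConfig:
    """Everything needed to run the two-arm calibration experiment."""

    subjects: list[SubjectParams] = field(default_factory=default_subjects)
    n_cal: int = 50
    n_val: int = 25
    duration_s: float = 20.0
    fs: float = 10_000.0
    bragg: BraggConfig = field(default_factory=BraggConfig)
    f_lo: float = 0.5
    f_hi: float = 5.0
    beat_length: int = 100
    anchor_fraction: float = 0.3
    normalize_each: bool = False
    alpha: float = 0.05
    k_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi < self.fs / 2:
            raise DomainError("need 0 < f_lo < f_hi < fs/2")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "subjects" in data:
            data["subjects"] = [
                s if isinstance(s, SubjectParams) else SubjectParams(**s)
                for s in data["subjects"]
            ]
        if "bragg" in data and not isinstance(data["bragg"], BraggConfig):
            data["bragg"] = BraggConfig(**data["bragg"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown experiment config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: conv(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, list):
                return [conv(v) for v in obj]
            return obj

        return conv(self)


@dataclass
class ExperimentReport:
    """Dataset summaries, per-curve results and per-record predictions."""

    summary_calibration: pd.DataFrame
    summary_validation: pd.DataFrame
    results: pd.DataFrame
    predictions: pd.DataFrame
    manifest: dict


def process_record(
    record: ThreePhaseRecord, config: ExperimentConfig
) -> np.ndarray:
    """Run one record through the measurement chain to a normalized beat."""
    phase = demodulate_phase(record)
    shift = phase_to_wavelength_shift(phase, config.bragg)
    sig = bandpass(shift.dlambda, shift.fs, config.f_lo, config.f_hi)
    beats = segment_beats(sig)
    nb = average_and_normalize(
        beats,
        L=config.beat_length,
        anchor_fraction=config.anchor_fraction,
        normalize_each=config.normalize_each,
    )
    return nb.samples


def build_beat_matrices(
    datasets: list[SubjectDataset], config: ExperimentConfig
) -> dict[str, dict[str, BeatMatrix]]:
    """Process every record of every subject into calibration/validation beats."""
    out: dict[str, dict[str, BeatMatrix]] = {}
    for ds in datasets:
        per = {}
        for split, records, refs in (
            ("calibration", ds.calibration_records, ds.calibration_bp),
            ("validation", ds.validation_records, ds.validation_bp),
        ):
            X = np.array([process_record(r, config) for r in records])
            per[split] = BeatMatrix(
                X=X, y=refs, subject_ids=np.full(len(refs), ds.subject_id)
            )
        out[ds.subject_id] = per
    return out


def _summary_row(subject: str, y: np.ndarray) -> dict:
    return {
        "subject": subject,
        "n": int(y.size),
        "max_mmHg": float(y.max()),
        "min_mmHg": float(y.min()),
        "mean_mmHg": float(y.mean()),
    }


def pool_summary_rows(rows: list[dict]) -> dict:
    """Combine per-subject summary rows into the pooled row.

    Pooled n is the sum, max/min the elementwise extrema, and the mean the
    n-weighted average of the subject means.
    """
    if not rows:
        raise DomainError("no summary rows to pool")
    n = sum(r["n"] for r in rows)
    return {
        "subject": POOLED_LABEL,
        "n": n,
        "max_mmHg": max(r["max_mmHg"] for r in rows),
        "min_mmHg": min(r["min_mmHg"] for r in rows),
        "mean_mmHg": sum(r["n"] * r["mean_mmHg"] for r in rows) / n,
    }


def summarize_datasets(
    datasets: list[SubjectDataset], split: str = "calibration"
) -> pd.DataFrame:
    """Per-subject and pooled n/max/min/mean of the reference pressures."""
    if not datasets:
        raise DomainError("no datasets to summarize")
    attr = {"calibration": "calibration_bp", "validation": "validation_bp"}[split]
    rows = [_summary_row(ds.subject_id, getattr(ds, attr)) for ds in datasets]
    rows.append(pool_summary_rows(rows))
    return pd.DataFrame(rows)


def _prediction_rows(curve, subject, split, y, yhat):
    return [
        {
            "record_id": f"{subject}_{split}_{i:03d}",
            "subject_id": subject,
            "curve": curve,
            "split": split,
            "reference_bp_mmHg": float(y[i]),
            "predicted_bp_mmHg": float(yhat[i]),
        }
        for i in range(len(y))
    ]


def _fit_curve(bm: BeatMatrix, config: ExperimentConfig):
    k_cap = min(config.k_max, bm.n - 2)
    k = select_factors(bm.X, bm.y, k_max=k_cap, alpha=config.alpha)
    return fit_pls(bm.X, bm.y, k), k


def run_individual(
    config: ExperimentConfig,
    beats: dict[str, dict[str, BeatMatrix]] | None = None,
    datasets: list[SubjectDataset] | None = None,
) -> ExperimentReport:
    """One calibration curve per subject, evaluated on that subject only."""
    datasets, beats = _materialize(config, beats, datasets)
    results, preds = [], []
    for ds in datasets:
        sid = ds.subject_id
        cal, val = beats[sid]["calibration"], beats[sid]["validation"]
        model, k = _fit_curve(cal, config)
        rep = evaluate(model, val.X, val.y)
        yhat = predict(model, val.X)
        curve = f"Individual {sid}"
        results.append(
            {
                "curve": curve,
                "evaluated_on": sid,
                "r": rep.r,
                "sep_mmHg": rep.sep,
                "bias_mmHg": rep.bias,
                "n_factors": k,
                "n": rep.n,
            }
        )
        preds += _prediction_rows(curve, sid, "validation", val.y, yhat)
    return _assemble(config, datasets, results, preds)


def run_overall(
    config: ExperimentConfig,
    beats: dict[str, dict[str, BeatMatrix]] | None = None,
    datasets: list[SubjectDataset] | None = None,
) -> ExperimentReport:
    """One pooled curve, evaluated per subject and on the pooled validation."""
    datasets, beats = _materialize(config, beats, datasets)
    if len(datasets) < 2:
        raise DomainError("the pooled arm needs at least 2 subjects")
    order = [ds.subject_id for ds in datasets]
    cal_X = np.vstack([beats[s]["calibration"].X for s in order])
    cal_y = np.concatenate([beats[s]["calibration"].y for s in order])
    cal_ids = np.concatenate(
        [beats[s]["calibration"].subject_ids for s in order]
    )
    pooled_cal = BeatMatrix(X=cal_X, y=cal_y, subject_ids=cal_ids)
    model, k = _fit_curve(pooled_cal, config)

    results, preds = [], []
    val_X = np.vstack([beats[s]["validation"].X for s in order])
    val_y = np.concatenate([beats[s]["validation"].y for s in order])
    for sid in order:
        val = beats[sid]["validation"]
        rep = evaluate(model, val.X, val.y)
        yhat = predict(model, val.X)
        results.append(
            {
                "curve": POOLED_LABEL,
                "evaluated_on": sid,
                "r": rep.r,
                "sep_mmHg": rep.sep,
                "bias_mmHg": rep.bias,
                "n_factors": k,
                "n": rep.n,
            }
        )
        preds += _prediction_rows(POOLED_LABEL, sid, "validation", val.y, yhat)
    pooled_rep = evaluate(model, val_X, val_y)
    results.append(
        {
            "curve": POOLED_LABEL,
            "evaluated_on": "pooled",
            "r": pooled_rep.r,
            "sep_mmHg": pooled_rep.sep,
            "bias_mmHg": pooled_rep.bias,
            "n_factors": k,
            "n": pooled_rep.n,
        }
    )
    return _assemble(config, datasets, results, preds)


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentReport:
    """Both arms on shared data: individual curves A/B/C plus the pooled curve."""
    config = config or ExperimentConfig()
    datasets = _simulate(config)
    beats = build_beat_matrices(datasets, config)
    ind = run_individual(config, beats=beats, datasets=datasets)
    ovr = run_overall(config, beats=beats, datasets=datasets)
    results = pd.concat([ind.results, ovr.results], ignore_index=True)
    preds = pd.concat([ind.predictions, ovr.predictions], ignore_index=True)
    return _assemble_frames(config, datasets, results, preds)


def _simulate(config: ExperimentConfig) -> list[SubjectDataset]:
    streams = np.random.SeedSequence(config.seed).spawn(len(config.subjects))
    return [
        simulate_subject(
            params,
            n_cal=config.n_cal,
            n_val=config.n_val,
            seed=int(streams[i].generate_state(1)[0] % (2**31)),
            duration_s=config.duration_s,
            fs=config.fs,
        )
        for i, params in enumerate(config.subjects)
    ]


def _materialize(config, beats, datasets):
    if datasets is None:
        datasets = _simulate(config)
    if beats is None:
        beats = build_beat_matrices(datasets, config)
    return datasets, beats


def _assemble(config, datasets, result_rows, pred_rows) -> ExperimentReport:
    return _assemble_frames(
        config, datasets, pd.DataFrame(result_rows), pd.DataFrame(pred_rows)
    )


def _assemble_frames(config, datasets, results, preds) -> ExperimentReport:
    return ExperimentReport(
        summary_calibration=summarize_datasets(datasets, "calibration"),
        summary_validation=summarize_datasets(datasets, "validation"),
        results=results,
        predictions=preds,
        manifest={
            "seed": config.seed,
            "software_version": __version__,
            "config": config.to_dict(),
        },
    )


def write_report(report: ExperimentReport, outdir) -> list[Path]:
    """Write summary/results/predictions CSVs and a JSON run manifest.

    Deterministic given the report: fixed float formatting, sorted manifest
    keys, no timestamps, so identical runs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    paths = []
    for name, df in (
        ("summary_calibration.csv", report.summary_calibration),
        ("summary_validation.csv", report.summary_validation),
        ("calibration_results.csv", report.results),
        ("predictions.csv", report.predictions),
    ):
        p = outdir / name
        df.to_csv(p, index=False, float_format=fmt)
        paths.append(p)
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(report.manifest, indent=1, sort_keys=True))
    paths.append(mp)
    return paths
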