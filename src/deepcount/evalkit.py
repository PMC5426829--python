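"""Evaluation statistics for counting methods.

Per-image accuracy is ``pa = (1 - |pc - ac| / |ac|) * 100`` where ``pc``
is the predicted and ``ac`` the actual count; it is 100 only for an
exact count, symmetric in over/under-counting, and deliberately not
clamped below zero.  Reports aggregate mean accuracy, MSE/RMSE of the
counts, and an ordinary least-squares fit of predicted on actual counts
with its R².
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .trainer import round_half_up


@dataclass
class EvalRecord:
    pc: float   # predicted count (possibly rounded)
    ac: int     # actual count, >= 1
    pa: float   # accuracy percent


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class EvalReport:
    records: list[EvalRecord]
    mean_accuracy: float
    mse: float
    rmse: float
    fit: RegressionFit | None
    method_name: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def write_csv(self, path: str | Path,
                  paths: Sequence[str] | None = None) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "ac", "pc", "pa"])
            for i, r in enumerate(self.records):
                name = paths[i] if paths else str(i)
                writer.writerow([name, r.ac, r.pc, f"{r.pa:.4f}"])


def accuracy_eq1(pc: float, ac: int) -> float:
    """Per-image counting accuracy in percent; ac must be >= 1."""
    if ac == 0:
        raise ValueError("accuracy is undefined for an actual count of 0")
    return (1.0 - abs(pc - ac) / abs(ac)) * 100.0


def linear_fit(pcs: Sequence[float], acs: Sequence[float]) -> RegressionFit:
    """OLS of predicted on actual counts; R² = 1 - SS_res/SS_tot."""
    pc = np.asarray(pcs, dtype=np.float64)
    ac = np.asarray(acs, dtype=np.float64)
    if pc.size != ac.size or pc.size < 2:
        raise ValueError("linear_fit requires >= 2 paired points")
    if np.all(ac == ac[0]):
        raise ValueError("actual counts are all equal; fit is degenerate")
    slope, intercept = np.polyfit(ac, pc, 1)
    resid = pc - (slope * ac + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((pc - pc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(float(slope), float(intercept), float(r2))


def evaluate_counts(pcs: Sequence[float], acs: Sequence[int],
                    method_name: str = "method",
                    rounding: bool = True) -> EvalReport:
    """Build an EvalReport from raw predictions and actual counts.

    Mean accuracy uses rounded predictions when ``rounding`` (integer
    counts are what a grower reads off); MSE/RMSE always use the raw
    predictions.
    """
    pcs = np.asarray(pcs, dtype=np.float64)
    acs = np.asarray(acs)
    if pcs.size == 0 or pcs.size != acs.size:
        raise ValueError("predictions and labels must be equal-length, nonempty")
    if np.any(acs < 1):
        raise ValueError(
            "actual count 0 present: exclude such images or regenerate "
            "(per-image accuracy divides by the actual count)")
    reported = round_half_up(pcs) if rounding else pcs
    records = [EvalRecord(float(p), int(a), accuracy_eq1(float(p), int(a)))
               for p, a in zip(reported, acs)]
    mse = float(np.mean((pcs - acs.astype(np.float64)) ** 2))
    fit = linear_fit(reported, acs) if pcs.size >= 2 and not np.all(
        acs == acs[0]) else None
    return EvalReport(
        records=records,
        mean_accuracy=float(np.mean([r.pa for r in records])),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        fit=fit,
        method_name=method_name,
    )


def evaluate_predictor(predictor: Callable[[np.ndarray], float], data,
                       rounding: bool = True,
                       method_name: str = "method") -> EvalReport:
    """Evaluate an image -> count callable over a dataset.

    ``data`` may be a DatasetManifest, a sequence of (image, count)
    pairs, or an (images, counts) array pair.
    """
    from .trainer import _as_arrays

    X, y = _as_arrays(data)
    pcs = np.array([float(predictor(img)) for img in X])
    return evaluate_counts(pcs, y.astype(int), method_name=method_name,
                           rounding=rounding)


def compare_methods(reports: Sequence[EvalReport]) -> list[dict]:
    """Comparison table rows (method, mean accuracy %, RMSE), sorted by
    accuracy descending."""
    if not reports:
        raise ValueError("need at least one report")
    rows = [{"method": r.method_name,
             "mean_accuracy": r.mean_accuracy,
             "rmse": r.rmse} for r in reports]
    return sorted(rows, key=lambda row: -row["mean_accuracy"])


def write_comparison_csv(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["method", "mean_accuracy", "rmse"])
        writer.writeheader()
        writer.writerows(rows)
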