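"""Accuracy metrics comparing pipeline estimates with simulated truth.

RMSE is root-mean-square: √(Σ(x̂ᵢ − xᵢ)²/n). Percent error defaults to the
mean per-element relative error |x̂ᵢ − xᵢ|/xᵢ × 100; an alternative mode
normalizes the RMSE by the mean truth, which is useful as a sensitivity
check when individual truths are near zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_csv

logger = logging.getLogger("hairmorph")

__all__ = [
    "ValidationReport",
    "rmse",
    "percent_error",
    "r_squared",
    "validate_curvature",
    "validate_section",
    "write_validation_report",
    "VALIDATION_REPORT_SCHEMA",
]

VALIDATION_REPORT_SCHEMA = ("metric", "rmse", "percent_error", "r_squared", "n")


@dataclass(frozen=True)
class ValidationReport:
    metric: str
    rmse: float
    percent_error: float
    r_squared: float  # NaN when undefined (n < 2 or zero variance)
    n: int


def _as_arrays(estimates, truths) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {tru.shape}")
    return est, tru


def rmse(estimates, truths) -> float:
    """Root of the mean squared estimate−truth difference (same units)."""
    est, tru = _as_arrays(estimates, truths)
    if est.size == 0:
        raise ValueError("rmse requires at least one pair")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def percent_error(estimates, truths, mode: str = "ratio") -> float:
    """Percent error of estimates against truths.

    ``"ratio"``: mean of |x̂ᵢ − xᵢ|/xᵢ × 100 over elements with nonzero
    truth (zero-truth elements are excluded with a warning).
    ``"rmse_norm"``: RMSE divided by the mean truth, × 100.
    """
    est, tru = _as_arrays(estimates, truths)
    if mode == "rmse_norm":
        denom = np.mean(tru)
        if denom == 0:
            raise ValueError("mean truth is zero; rmse_norm undefined")
        return float(rmse(est, tru) / abs(denom) * 100)
    if mode != "ratio":
        raise ValueError(f"unknown percent_error mode {mode!r}")
    nonzero = tru != 0
    if not nonzero.all():
        logger.warning("percent_error: excluding %d zero-truth elements", int((~nonzero).sum()))
    if not nonzero.any():
        raise ValueError("all truths are zero; ratio mode undefined")
    return float(np.mean(np.abs(est[nonzero] - tru[nonzero]) / np.abs(tru[nonzero])) * 100)


def r_squared(estimates, truths) -> float:
    """Squared Pearson correlation between estimates and truths."""
    est, tru = _as_arrays(estimates, truths)
    if est.size < 2:
        raise ValueError("r_squared requires n >= 2")
    if np.var(est) == 0 or np.var(tru) == 0:
        raise ValueError("r_squared undefined for zero-variance input")
    r = np.corrcoef(est, tru)[0, 1]
    return float(r * r)


def _paired_reports(
    merged: pd.DataFrame, pairs: list[tuple[str, str, str]]
) -> dict[str, ValidationReport]:
    out = {}
    for metric, est_col, truth_col in pairs:
        est = merged[est_col].to_numpy(float)
        tru = merged[truth_col].to_numpy(float)
        n = len(merged)
        try:
            r2 = r_squared(est, tru)
        except ValueError:
            logger.warning("r_squared undefined for %s (n=%d)", metric, n)
            r2 = math.nan
        out[metric] = ValidationReport(
            metric=metric,
            rmse=rmse(est, tru),
            percent_error=percent_error(est, tru),
            r_squared=r2,
            n=n,
        )
    return out


def _load(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(table)


def _merge_on_id(est: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    unmatched = sorted(set(est.image_id).symmetric_difference(truth.image_id))
    if unmatched:
        raise ValueError(f"image_ids without a match in both tables: {unmatched}")
    return est.merge(truth, on="image_id", suffixes=("_est", "_true")).sort_values("image_id")


def validate_curvature(summary, truth) -> dict[str, ValidationReport]:
    """Compare per-image mean curvature and mean length against truth.

    ``summary`` is the pipeline's per-image summary (CSV path or frame);
    ``truth`` the generator's per-element truth table, aggregated here to
    per-image true curvature and length. Returns reports keyed
    ``"curvature"`` and ``"length"``.
    """
    est = _load(summary)
    tru = _load(truth)
    tru_img = tru.groupby("image_id", as_index=False).agg(
        true_curvature_per_mm=("curvature_per_mm", "mean"),
        true_length_mm=("length_mm", "mean"),
    )
    merged = _merge_on_id(est, tru_img)
    return _paired_reports(
        merged,
        [
            ("curvature", "mean_curvature_per_mm", "true_curvature_per_mm"),
            ("length", "mean_length_mm", "true_length_mm"),
        ],
    )


def validate_section(summary, truth) -> dict[str, ValidationReport]:
    """Compare per-image area and eccentricity against the ellipse truth
    table. Returns reports keyed ``"area"`` and ``"eccentricity"``."""
    est = _load(summary)
    tru = _load(truth)[["image_id", "area_um2", "eccentricity"]]
    merged = _merge_on_id(est, tru)
    return _paired_reports(
        merged,
        [
            ("area", "area_um2_est", "area_um2_true"),
            ("eccentricity", "eccentricity_est", "eccentricity_true"),
        ],
    )


def write_validation_report(reports: dict[str, ValidationReport], path: str | Path) -> Path:
    rows = [
        {
            "metric": r.metric,
            "rmse": r.rmse,
            "percent_error": r.percent_error,
            "r_squared": r.r_squared,
            "n": r.n,
        }
        for r in reports.values()
    ]
    return write_csv(pd.DataFrame(rows), VALIDATION_REPORT_SCHEMA, path)
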