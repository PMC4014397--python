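"""Replicate error, prediction-error summaries, baselines, and violation flags."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .activity import ActivityCurve
from .prediction import WeightPrediction
from .superposition import WeightFit, relative_fit_error

__all__ = [
    "day_to_day_error",
    "baseline_exemplar_error",
    "prediction_error_summary",
    "flag_violations",
    "weight_table_summary",
]

VIOLATION_THRESHOLD = 0.2


def _symmetric_error(a: np.ndarray, b: np.ndarray) -> float:
    # the L2-ratio metric is asymmetric in its denominator; average both ways
    return 0.5 * (relative_fit_error(a, b) + relative_fit_error(b, a))


def day_to_day_error(replicate_curves: list[ActivityCurve]) -> float:
    """Mean pairwise relative discrepancy among replicate-day curves.

    The empirical noise floor against which fit errors are judged.  Each
    unordered replicate pair contributes the symmetric mean of the two
    one-way relative errors.  Returns NaN with fewer than two replicates.
    """
    if len(replicate_curves) < 2:
        return float("nan")
    keys = {(c.promoter, c.condition_set) for c in replicate_curves}
    if len(keys) > 1:
        raise ValueError(f"replicates span several promoter/conditions: {keys}")
    vals = [np.asarray(c.values, dtype=float) for c in replicate_curves]
    errs = [_symmetric_error(a, b) for a, b in combinations(vals, 2)]
    return float(np.mean(errs))


def baseline_exemplar_error(measured: ActivityCurve,
                            other_curves: list[ActivityCurve]) -> float:
    """Average error of 'predicting' a condition by any other condition's curve.

    For a promoter measured in condition X, every measured curve of that
    promoter in a *different* condition serves as an exemplar prediction;
    the statistic is the exhaustive mean of their relative errors against
    the measurement in X (deterministic — with 15 measured conditions
    this averages the 14 exemplar errors).
    """
    exemplars = [
        c for c in other_curves
        if c.promoter == measured.promoter and c.condition_set != measured.condition_set
    ]
    if not exemplars:
        raise ValueError("no exemplar curves from other conditions")
    errs = [relative_fit_error(c.values, measured.values) for c in exemplars]
    return float(np.mean(errs))


def prediction_error_summary(predictions: list[WeightPrediction],
                             bin_edges=None) -> dict:
    """Median prediction error per cocktail size plus a cumulative histogram.

    Returns ``{"medians": {size: median}, "cumulative": DataFrame}`` where
    the DataFrame holds, per cocktail size, the fraction of prediction
    errors at or below each bin edge (default edges: 0 to 1 in steps of
    0.05).  Sizes with no measured counterpart are reported as NaN.
    """
    if bin_edges is None:
        bin_edges = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    by_size: dict[int, list[float]] = {}
    for p in predictions:
        if p.relative_error_vs_measured is None:
            continue
        by_size.setdefault(len(p.target), []).append(p.relative_error_vs_measured)
    medians = {size: float(np.median(v)) for size, v in sorted(by_size.items())}
    rows = []
    for size, errs in sorted(by_size.items()):
        e = np.asarray(errs)
        for edge in bin_edges:
            rows.append(
                {
                    "cocktail_size": size,
                    "error_bin": float(edge),
                    "cumulative_fraction": float(np.mean(e <= edge)),
                }
            )
    return {"medians": medians, "cumulative": pd.DataFrame(rows)}


def flag_violations(fits: list[WeightFit],
                    threshold: float = VIOLATION_THRESHOLD) -> list[str]:
    """Promoters whose best linear-combination fit error exceeds a threshold.

    For each (promoter, target) the best (smallest) relative error among
    the linear models is taken; a promoter is flagged when any of its
    targets stays above the threshold — the sequential-regulation
    signature (the diauxie phenotype: a combined condition far from every
    weighted average of the single conditions).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    best: dict[tuple, float] = {}
    for f in fits:
        if f.model not in ("linear_unconstrained", "linear_superposition"):
            continue
        key = (f.promoter, f.target)
        best[key] = min(best.get(key, np.inf), f.relative_error)
    flagged = sorted({prom for (prom, _), err in best.items() if err > threshold})
    return flagged


def weight_table_summary(table: pd.DataFrame, error_column: str = "relative_error",
                         threshold: float = 0.2) -> dict:
    """Mean fit error and the fraction of fits below a threshold.

    Operates on a fitted-weights table (one row per promoter × combined
    condition, as written by the pipeline or supplied externally).
    """
    errs = pd.to_numeric(table[error_column], errors="coerce").dropna().to_numpy()
    if errs.size == 0:
        raise ValueError(f"no numeric values in column {error_column!r}")
    return {
        "mean_error": float(errs.mean()),
        "fraction_below_threshold": float(np.mean(errs < threshold)),
        "n_fits": int(errs.size),
    }
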