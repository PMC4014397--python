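"""Fitting combined-condition dynamics as mixtures of single-condition dynamics.

The central model: the activity curve of a promoter in a cocktail of
supplements, P_{1…N}(g), is a weighted combination of its curves in the
single-supplement conditions, all on the shared generation axis g:

    P_{1…N}(g) ≈ Σ_i w_i · P_i(g)

Three variants are fitted:

``linear_unconstrained``
    Error-in-variables (total least squares) regression: all curves are
    treated as equally noisy measurements; the weights come from the
    right singular vector belonging to the smallest singular value of
    the stacked [singles | target] matrix.  No sign or sum constraint.
``linear_superposition``
    Ordinary least squares subject to w_i ≥ 0 and Σ w_i = 1 — the curve
    in a cocktail is a *weighted average* of the single-condition curves.
    A pair has a single free parameter w ∈ [0, 1]; larger cocktails are
    solved exactly by active-set enumeration on the simplex.
``multiplicative``
    The target is modelled as the weighted geometric mean of the singles
    (simplex-constrained regression in the log domain); the fit error is
    still evaluated on the original linear scale.

Model comparison uses AIC = n·ln(RSS/n) + 2k under a Gaussian likelihood
with unknown common variance, where k counts free weight parameters
(N − 1 on the simplex, N unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .activity import ActivityCurve
from .plate import ConditionSet

__all__ = [
    "WeightFit",
    "SuperpositionModel",
    "fit_linear_unconstrained",
    "fit_linear_superposition",
    "fit_multiplicative",
    "relative_fit_error",
    "aic_compare",
    "weight_sum_statistics",
    "simplex_lstsq",
]

MODELS = ("linear_unconstrained", "linear_superposition", "multiplicative")
# Belsley's condition-index rule of thumb for serious collinearity; the
# unconstrained error-in-variables weights are ratio-like and blow up well
# before machine-precision rank deficiency.
COLLINEARITY_THRESHOLD = 30.0


def relative_fit_error(fit_curve, measured, norm: str = "l2") -> float:
    """Relative discrepancy between a fitted and a measured curve.

    Default is the L2 ratio ‖fit − measured‖₂ / ‖measured‖₂; ``norm="l1"``
    gives the mean-absolute analogue.  Errors if the measured curve is
    identically zero.
    """
    f = np.asarray(fit_curve, dtype=float)
    m = np.asarray(measured, dtype=float)
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {m.shape}")
    if norm == "l2":
        denom = np.linalg.norm(m)
        if denom == 0:
            raise ValueError("measured curve is identically zero")
        return float(np.linalg.norm(f - m) / denom)
    if norm == "l1":
        denom = np.mean(np.abs(m))
        if denom == 0:
            raise ValueError("measured curve is identically zero")
        return float(np.mean(np.abs(f - m)) / denom)
    raise ValueError(f"unknown norm {norm!r}")


@dataclass
class WeightFit:
    """Results of one mixture fit: weights, fit quality, model score.

    ``weights`` maps each single-condition label to its fitted weight.
    ``n_params`` is the number of free weight parameters entering AIC.
    """

    promoter: str
    target: ConditionSet
    model: str
    weights: dict[str, float]
    relative_error: float
    aic: float
    n_points: int
    rss: float = float("nan")
    fitted_curve: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.relative_error < 0:
            raise ValueError("relative_error must be >= 0")
        if self.model in ("linear_superposition", "multiplicative"):
            w = np.array(list(self.weights.values()))
            if np.any(w < -1e-8) or np.any(w > 1 + 1e-8):
                raise ValueError(f"simplex weights out of [0,1]: {self.weights}")
            if abs(w.sum() - 1) > 1e-8:
                raise ValueError(f"simplex weights do not sum to 1: {self.weights}")

    @property
    def weight_sum(self) -> float:
        return float(sum(self.weights.values()))

    @property
    def n_params(self) -> int:
        n = len(self.weights)
        return n - 1 if self.model in ("linear_superposition", "multiplicative") else n

    def summary(self) -> str:
        lines = [
            f"Mixture fit: {self.promoter} in {self.target}  [{self.model}]",
            "-" * 56,
        ]
        for label, w in self.weights.items():
            lines.append(f"  w[{label}] = {w: .4f}")
        lines += [
            f"  sum of weights  = {self.weight_sum: .4f}",
            f"  relative error  = {self.relative_error: .4f}",
            f"  AIC             = {self.aic: .2f}   (n={self.n_points}, k={self.n_params})",
        ]
        if self.metadata.get("collinear_warning"):
            lines.append("  warning: singles nearly collinear; weights ill-determined")
        return "\n".join(lines)


def _aic(rss: float, n: int, k: int) -> float:
    # Guard: a perfect fit has RSS 0; floor keeps the log finite.
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def tls_weights(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Total-least-squares coefficients of y on the columns of S.

    Right singular vector of the smallest singular value of [S | y],
    renormalized so the target coefficient is −1.  Equal error variances
    are assumed on every column.
    """
    stacked = np.column_stack([S, y])
    _, _, vt = np.linalg.svd(stacked, full_matrices=False)
    v = vt[-1]
    if abs(v[-1]) < 1e-14:
        # degenerate TLS (target orthogonal to the noise direction);
        # fall back to ordinary least squares
        return np.linalg.lstsq(S, y, rcond=None)[0]
    return -v[:-1] / v[-1]


def simplex_lstsq(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize ‖y − S w‖₂ subject to w ≥ 0, Σw = 1 (exact, deterministic).

    Solved by enumerating active sets: for every non-empty support the
    equality-constrained problem is a small KKT system; the best feasible
    solution wins, ties going to the smaller support.
    """
    m = S.shape[1]
    if m > 16:
        raise ValueError("active-set enumeration is for small mixtures (<=16 singles)")
    best: tuple[float, int, np.ndarray] | None = None
    idx = np.arange(m)
    for size in range(1, m + 1):
        for support in combinations(idx, size):
            sub = S[:, support]
            # KKT: [2 SᵀS  1; 1ᵀ 0] [w; λ] = [2 Sᵀy; 1]
            g = sub.T @ sub
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2 * g
            kkt[:size, size] = 1
            kkt[size, :size] = 1
            rhs = np.concatenate([2 * sub.T @ y, [1.0]])
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            w_sub = sol[:size]
            if np.any(w_sub < -1e-10) or abs(w_sub.sum() - 1) > 1e-8:
                continue
            resid = y - sub @ w_sub
            obj = float(resid @ resid)
            if best is None or obj < best[0] - 1e-12:
                w = np.zeros(m)
                w[list(support)] = np.clip(w_sub, 0, None)
                w /= w.sum()
                best = (obj, size, w)
    if best is None:  # numerically pathological; uniform fallback
        return np.full(m, 1.0 / m)
    return best[2]


class SuperpositionModel:
    """Mixture model of one combined-condition curve over single-condition curves.

    Parameters
    ----------
    target : ActivityCurve or 1-D array
        Measured dynamics in the combined condition.
    singles : list of ActivityCurve, or 2-D array (n_singles, n_grid)
        Single-condition dynamics on the identical shared grid.
    labels : list of str, optional
        Names of the single conditions; inferred from ActivityCurve
        condition sets when omitted.

    ``fit(method=...)`` returns a :class:`WeightFit`; ``fit_all()``
    fits every model variant for AIC comparison.
    """

    def __init__(self, target, singles, labels=None, promoter: str | None = None,
                 target_conditions: ConditionSet | None = None):
        if isinstance(target, ActivityCurve):
            self.y = np.asarray(target.values, dtype=float)
            promoter = promoter if promoter is not None else target.promoter
            target_conditions = (
                target_conditions if target_conditions is not None else target.condition_set
            )
            grid = target.generations
        else:
            self.y = np.asarray(target, dtype=float)
            grid = None
        cols, inferred = [], []
        for s in singles:
            if isinstance(s, ActivityCurve):
                if grid is not None and s.generations is not None and (
                    s.generations.size != grid.size or not np.allclose(s.generations, grid)
                ):
                    raise ValueError("singles are not on the target's shared grid")
                cols.append(np.asarray(s.values, dtype=float))
                inferred.append(str(s.condition_set))
            else:
                cols.append(np.asarray(s, dtype=float))
                inferred.append(None)
        self.S = np.column_stack(cols)
        if labels is None:
            if any(l is None for l in inferred):
                labels = [l if l is not None else f"s{i}" for i, l in enumerate(inferred)]
            else:
                labels = inferred
        if len(labels) != self.S.shape[1]:
            raise ValueError("one label per single condition required")
        self.labels = list(labels)
        self.promoter = promoter or ""
        self.target_conditions = (
            target_conditions
            if target_conditions is not None
            else ConditionSet(*[l for l in self.labels])
        )
        n, m = self.S.shape
        if self.y.size != n:
            raise ValueError("target and singles have different grid lengths")
        if n < m + 2:
            raise ValueError(f"need >= {m + 2} grid points for {m} singles, got {n}")

    # -- individual fitting methods -------------------------------------

    def fit(self, method: str = "linear_superposition", **kw) -> WeightFit:
        if method == "linear_unconstrained":
            return self._fit_unconstrained(**kw)
        if method == "linear_superposition":
            return self._fit_superposition(**kw)
        if method == "multiplicative":
            return self._fit_multiplicative(**kw)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, **kw) -> list[WeightFit]:
        return [self.fit(m, **kw) for m in MODELS]

    def _package(self, model: str, w: np.ndarray, fitted: np.ndarray,
                 metadata: dict | None = None) -> WeightFit:
        resid = fitted - self.y
        rss = float(resid @ resid)
        n = self.y.size
        weights = dict(zip(self.labels, (float(x) for x in w)))
        k = len(w) - 1 if model in ("linear_superposition", "multiplicative") else len(w)
        meta = metadata or {}
        if np.linalg.cond(self.S) > COLLINEARITY_THRESHOLD:
            meta["collinear_warning"] = True
        return WeightFit(
            promoter=self.promoter,
            target=self.target_conditions,
            model=model,
            weights=weights,
            relative_error=relative_fit_error(fitted, self.y),
            aic=_aic(rss, n, k),
            n_points=n,
            rss=rss,
            fitted_curve=fitted,
            metadata=meta,
        )

    def _fit_unconstrained(self) -> WeightFit:
        w = tls_weights(self.S, self.y)
        return self._package("linear_unconstrained", w, self.S @ w)

    def _fit_superposition(self) -> WeightFit:
        if self.S.shape[1] == 2:
            # pair: 1-D problem in w = w_first; closed-form projection onto [0,1]
            a, b = self.S[:, 0], self.S[:, 1]
            d = a - b
            dd = float(d @ d)
            w1 = 0.5 if dd == 0 else float(np.clip((self.y - b) @ d / dd, 0.0, 1.0))
            w = np.array([w1, 1 - w1])
        else:
            w = simplex_lstsq(self.S, self.y)
        return self._package("linear_superposition", w, self.S @ w)

    def _fit_multiplicative(self, floor_frac: float = 1e-6) -> WeightFit:
        cols = []
        for j in range(self.S.shape[1]):
            col = self.S[:, j]
            floored = np.maximum(col, floor_frac * col.max())
            if np.any(floored <= 0):
                raise ValueError("single curve non-positive even after flooring")
            cols.append(np.log(floored))
        yf = np.maximum(self.y, floor_frac * self.y.max())
        if np.any(yf <= 0):
            raise ValueError("target curve non-positive even after flooring")
        w = simplex_lstsq(np.column_stack(cols), np.log(yf))
        fitted = np.exp(np.column_stack(cols) @ w)
        return self._package("multiplicative", w, fitted)


# -- functional front-ends (operate on ActivityCurve lists) --------------


def fit_linear_unconstrained(target, singles, **kw) -> WeightFit:
    """Error-in-variables (TLS) mixture weights, unconstrained."""
    return SuperpositionModel(target, singles, **kw).fit("linear_unconstrained")


def fit_linear_superposition(target, singles, **kw) -> WeightFit:
    """Weighted-average fit: weights non-negative and summing to one."""
    return SuperpositionModel(target, singles, **kw).fit("linear_superposition")


def fit_multiplicative(target, singles, **kw) -> WeightFit:
    """Weighted-geometric-mean fit (simplex weights in the log domain)."""
    return SuperpositionModel(target, singles, **kw).fit("multiplicative")


def aic_compare(fits: list[WeightFit]) -> list[WeightFit]:
    """Rank fits of one target by AIC, ties toward fewer parameters."""
    if not fits:
        raise ValueError("no fits to compare")
    targets = {(f.promoter, f.target, f.n_points) for f in fits}
    if len(targets) > 1:
        raise ValueError("fits must share one target and grid to be AIC-comparable")
    return sorted(fits, key=lambda f: (f.aic, f.n_params))


def weight_sum_statistics(fits: list[WeightFit]) -> dict:
    """Distribution of Σw over unconstrained fits, and the positive fraction.

    Returns mean and sample (n−1) standard deviation of the per-fit weight
    sums, plus the fraction of individual weights above −0.05 — the
    weighted-average diagnostic: sums near one with mostly positive
    weights mean the unconstrained fits already behave like convex
    combinations.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if any(f.model != "linear_unconstrained" for f in fits):
        raise ValueError("weight-sum statistics are defined for unconstrained fits")
    sums = np.array([f.weight_sum for f in fits])
    all_w = np.concatenate([list(f.weights.values()) for f in fits])
    return {
        "mean_sum": float(sums.mean()),
        "sd_sum": float(sums.std(ddof=1)) if sums.size > 1 else float("nan"),
        "n_fits": int(sums.size),
        "fraction_weights_positive": float(np.mean(all_w > -0.05)),
    }
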