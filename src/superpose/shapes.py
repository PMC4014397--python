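"""Per-promoter principal-component curves across growth conditions.

A promoter measured in many condition sets yields a conditions × grid
matrix of activity curves on the shared generation axis.  An un-centered
singular value decomposition of that matrix gives the promoter's
*principal shape curves*; in the study system one or two such curves
explain almost all cross-condition variance, and the leading shape tracks
instantaneous growth rate.  The decomposition is un-centered because each
measured curve is modelled as a plain linear combination of the shapes
(no mean offset): a one-shape promoter is exactly "same shape, different
amplitude".  A ``center=True`` flag gives the conventional mean-centered
variant for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityCurve, GrowthRateCurve

__all__ = [
    "PrincipalShapes",
    "PromoterShapeModel",
    "condition_matrix",
    "principal_shapes",
    "explained_by_first_k",
    "randomized_null",
    "pc1_growth_correlation",
]


@dataclass
class PrincipalShapes:
    """Results of a per-promoter shape decomposition.

    Attributes
    ----------
    promoter : str
    components : (k, n_grid) ndarray
        Orthonormal principal shape curves (right singular vectors).
    variance_fractions : (k,) ndarray
        Share of total squared variation carried by each component,
        non-increasing, each in [0, 1].
    condition_loadings : (n_conditions, k) ndarray
        Coefficients reconstructing each condition row as
        ``loadings @ components`` (up to the unexplained residual).
    conditions : list
        Row labels (condition sets) in canonical order.
    centered : bool
        Whether the decomposition removed the mean curve first.
    """

    promoter: str
    components: np.ndarray
    variance_fractions: np.ndarray
    condition_loadings: np.ndarray
    conditions: list = field(default_factory=list)
    centered: bool = False
    mean_curve: np.ndarray | None = None

    def explained_by_first_k(self, k: int) -> float:
        return explained_by_first_k(self, k)

    def reconstruction(self) -> np.ndarray:
        rec = self.condition_loadings @ self.components
        if self.centered and self.mean_curve is not None:
            rec = rec + self.mean_curve
        return rec

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.variance_fractions.size + 1),
                "variance_fraction": self.variance_fractions,
                "cumulative": np.cumsum(self.variance_fractions),
            }
        )


class PromoterShapeModel:
    """Shape decomposition of one promoter's cross-condition dynamics.

    Parameters
    ----------
    curves_or_matrix : list of ActivityCurve, or 2-D array
        Either activity curves for a single promoter on an identical
        shared generation grid (replicate days are averaged per condition
        set), or a ready conditions × grid matrix.
    center : bool
        Subtract the mean curve before decomposing (default False).

    ``fit(k)`` returns a :class:`PrincipalShapes` results object.
    """

    def __init__(self, curves_or_matrix, center: bool = False, promoter: str = ""):
        if isinstance(curves_or_matrix, np.ndarray):
            self.matrix = np.asarray(curves_or_matrix, dtype=float)
            self.conditions = list(range(self.matrix.shape[0]))
            self.promoter = promoter
        else:
            self.matrix, self.conditions, self.promoter = _matrix_from_curves(
                curves_or_matrix
            )
        if self.matrix.ndim != 2:
            raise ValueError("condition matrix must be 2-D")
        self.center = center

    def fit(self, k: int | None = None) -> PrincipalShapes:
        m = self.matrix
        if not np.any(m):
            raise ValueError("all-zero condition matrix has no principal shapes")
        r = min(m.shape)
        if k is None:
            k = r
        if k < 1 or k > r:
            raise ValueError(f"k={k} out of range for {m.shape} matrix")
        mean = m.mean(axis=0) if self.center else None
        x = m - mean if self.center else m
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        total = float(np.sum(s**2))
        fractions = (s**2 / total) if total > 0 else np.zeros_like(s)
        loadings = u * s  # rows reconstruct as loadings @ vt
        return PrincipalShapes(
            promoter=self.promoter,
            components=vt[:k],
            variance_fractions=fractions[:k],
            condition_loadings=loadings[:, :k],
            conditions=list(self.conditions),
            centered=self.center,
            mean_curve=mean,
        )


def _matrix_from_curves(curves: list[ActivityCurve]):
    if not curves:
        raise ValueError("no curves supplied")
    promoters = {c.promoter for c in curves}
    if len(promoters) > 1:
        raise ValueError(f"curves span several promoters: {sorted(promoters)}")
    grid = curves[0].generations
    if grid is None:
        raise ValueError("curves must be on a shared generation grid")
    seen: set[tuple] = set()
    by_cond: dict = {}
    for c in curves:
        if c.generations is None or c.generations.size != grid.size or not np.allclose(
            c.generations, grid
        ):
            raise ValueError("curves are not on an identical shared grid")
        key = (c.condition_set, c.replicate_day)
        if key in seen:
            raise ValueError(
                f"duplicate (promoter, condition, day): {c.promoter}/{c.condition_set}"
                f"/day{c.replicate_day}"
            )
        seen.add(key)
        by_cond.setdefault(c.condition_set, []).append(c.values)
    conditions = sorted(by_cond, key=lambda cs: (len(cs), cs.labels))
    matrix = np.vstack([np.mean(by_cond[cs], axis=0) for cs in conditions])
    return matrix, conditions, promoters.pop()


def condition_matrix(curves: list[ActivityCurve]):
    """Conditions × grid matrix for one promoter, replicates averaged.

    Rows follow canonical condition-set order (by cocktail size, then
    alphabetically).  Returns ``(matrix, condition_sets)``.
    """
    matrix, conditions, _ = _matrix_from_curves(curves)
    return matrix, conditions


def principal_shapes(matrix: np.ndarray, k: int, center: bool = False,
                     promoter: str = "") -> PrincipalShapes:
    """Top-k principal shape curves of a conditions × grid matrix."""
    return PromoterShapeModel(matrix, center=center, promoter=promoter).fit(k)


def explained_by_first_k(shapes: PrincipalShapes, k: int) -> float:
    """Fraction of variance carried by the first k shape curves."""
    if k < 0 or k > shapes.variance_fractions.size:
        raise ValueError(f"k={k} exceeds available components")
    return float(np.sum(shapes.variance_fractions[:k]))


def randomized_null(
    matrix: np.ndarray, n_shuffles: int, seed, center: bool = False
) -> np.ndarray:
    """Null distribution of the first-2-shape variance fraction.

    Each shuffle independently permutes entries within every column (grid
    point) across conditions, destroying the coherence of rows while
    preserving each grid point's marginal, then recomputes the fraction of
    variance explained by two components.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    m = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = np.empty_like(m)
        for j in range(m.shape[1]):
            shuffled[:, j] = m[rng.permutation(m.shape[0]), j]
        fit = PromoterShapeModel(shuffled, center=center).fit()
        out[i] = explained_by_first_k(fit, min(2, fit.variance_fractions.size))
    return out


def pc1_growth_correlation(shapes: PrincipalShapes, growth: GrowthRateCurve) -> float:
    """Squared Pearson correlation of the leading shape with growth rate.

    Both curves must live on the same shared grid.  Returns NaN when
    either input has zero variance (the correlation is undefined).
    """
    pc1 = shapes.components[0]
    g = np.asarray(growth.values, dtype=float)
    if g.size != pc1.size:
        raise ValueError("growth-rate curve not on the shape grid")
    ok = np.isfinite(pc1) & np.isfinite(g)
    pc1, g = pc1[ok], g[ok]
    if pc1.size < 2 or np.std(pc1) == 0 or np.std(g) == 0:
        return float("nan")
    r = np.corrcoef(pc1, g)[0, 1]
    return float(r**2)
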