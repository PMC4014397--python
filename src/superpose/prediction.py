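"""Predicting cocktail mixture weights from lower-order cocktails.

An N-supplement cocktail can be decomposed in N ways — as supplement j
added to the (N−1)-cocktail missing j.  If every such decomposition obeys
weighted-average superposition and they all agree, the weights are
over-determined and the N-cocktail weights follow from the (N−1)-cocktail
weights alone:

    w_i = (N − 2) / ( Σ_{j≠i} 1 / w_i^(≠j)  −  1 )

where w_i^(≠j) is the weight of supplement i inside the cocktail missing
supplement j.  Self-consistency is exact: when simplex weights w* exist
with w_i^(≠j) = w*_i / (1 − w*_j) for every sub-cocktail, the formula
returns w* identically (substituting gives Σ_{j≠i} 1/w_i^(≠j) − 1 =
(N−2)/w*_i).  When only pair weights are measured, the formula is applied
iteratively: pairs give every triplet, predicted triplets give the
quadruplet, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityCurve
from .plate import ConditionSet
from .superposition import WeightFit, relative_fit_error

__all__ = [
    "WeightPrediction",
    "predict_weights",
    "predict_weights_iterative",
    "predict_dynamics",
]

ZERO_CLIP = 1e-6


@dataclass
class WeightPrediction:
    """Predicted cocktail weights and (optionally) the predicted curve."""

    promoter: str
    target: ConditionSet
    predicted_weights: dict[str, float]
    predicted_curve: np.ndarray | None = None
    relative_error_vs_measured: float | None = None

    def __post_init__(self) -> None:
        w = np.array(list(self.predicted_weights.values()))
        if np.any(w < -1e-8) or np.any(w > 1 + 1e-8):
            raise ValueError(f"predicted weights out of [0,1]: {self.predicted_weights}")
        if abs(w.sum() - 1) > 1e-8:
            raise ValueError(f"predicted weights do not sum to 1: {self.predicted_weights}")


def _as_weights(obj) -> dict[str, float]:
    return dict(obj.weights) if isinstance(obj, WeightFit) else dict(obj)


def predict_weights(lower_order: dict, target: ConditionSet | None = None,
                    clip_negative_inputs: bool = False) -> dict[str, float]:
    """Weights of an N-cocktail from the weights of all its (N−1)-cocktails.

    Parameters
    ----------
    lower_order : dict
        Maps each (N−1)-subset of the target (ConditionSet) to its fitted
        or predicted weights (a WeightFit or a plain label→weight dict).
    target : ConditionSet, optional
        Inferred as the union of the subset keys when omitted.

    A non-positive lower-order weight of supplement i propagates to
    w_i = 0 (a supplement absent from a sub-cocktail stays absent).
    With ``clip_negative_inputs=True`` — for weights coming from
    unconstrained fits — non-positive inputs are instead floored at 1e−6.
    The raw harmonic-form predictions are clipped to [0, 1] and
    renormalized to sum to one.
    """
    keys = [k if isinstance(k, ConditionSet) else ConditionSet(*k) for k in lower_order]
    if target is None:
        target = ConditionSet(*sorted({l for k in keys for l in k.labels}))
    n = len(target)
    if n < 3:
        raise ValueError("prediction needs a cocktail of >= 3 supplements")
    expected = set(target.subsets(n - 1))
    if set(keys) != expected:
        missing = sorted(str(s) for s in expected - set(keys))
        raise ValueError(f"missing (N-1)-cocktail weights for: {missing}")
    table = {k: _as_weights(v) for k, v in zip(keys, lower_order.values())}

    raw: dict[str, float] = {}
    for i in target.labels:
        inv_sum, dead = 0.0, False
        for j in target.labels:
            if j == i:
                continue
            sub = target.without(j)
            w_ij = float(table[sub].get(i, 0.0))
            if w_ij <= 0:
                if clip_negative_inputs:
                    w_ij = ZERO_CLIP
                else:
                    dead = True  # zero propagates: i carries no weight in a sub-cocktail
                    break
            inv_sum += 1.0 / w_ij
        raw[i] = 0.0 if dead else (n - 2) / (inv_sum - 1.0)

    clipped = {i: min(max(w, 0.0), 1.0) for i, w in raw.items()}
    total = sum(clipped.values())
    if total <= 0:
        # every supplement zeroed out: fall back to the uninformative uniform point
        return {i: 1.0 / n for i in target.labels}
    return {i: w / total for i, w in clipped.items()}


def predict_weights_iterative(pair_fits: dict, target: ConditionSet,
                              return_all: bool = False):
    """Cocktail weights from pair weights alone, level by level.

    All C(N,2) pair fits within the target must be supplied; triplet
    weights are predicted from pairs, quadruplet weights from the
    predicted triplets, up to the full target.
    """
    pairs = {
        (k if isinstance(k, ConditionSet) else ConditionSet(*k)): _as_weights(v)
        for k, v in pair_fits.items()
    }
    needed = set(target.subsets(2))
    missing = sorted(str(p) for p in needed - set(pairs))
    if missing:
        raise ValueError(f"missing pair fits for: {missing}")
    level: dict[ConditionSet, dict[str, float]] = {p: pairs[p] for p in needed}
    all_levels = dict(level)
    for size in range(3, len(target) + 1):
        nxt: dict[ConditionSet, dict[str, float]] = {}
        for sub in target.subsets(size):
            lower = {s: level[s] for s in sub.subsets(size - 1)}
            nxt[sub] = predict_weights(lower, target=sub)
        level = nxt
        all_levels.update(level)
    result = level[target]
    return (result, all_levels) if return_all else result


def predict_dynamics(predicted_weights: dict[str, float],
                     singles: list[ActivityCurve],
                     measured: ActivityCurve | None = None,
                     promoter: str = "",
                     target: ConditionSet | None = None) -> WeightPrediction:
    """Σ w_i · P_i on the shared grid, with error vs measurement if given."""
    by_label: dict[str, ActivityCurve] = {}
    for s in singles:
        if len(s.condition_set) != 1:
            raise ValueError(f"{s.condition_set} is not a single condition")
        by_label[s.condition_set.labels[0]] = s
    missing = sorted(set(predicted_weights) - set(by_label))
    if missing:
        raise ValueError(f"no single-condition curve for: {missing}")
    curve = sum(
        w * by_label[label].values for label, w in predicted_weights.items()
    )
    err = None
    if measured is not None:
        err = relative_fit_error(curve, measured.values)
        promoter = promoter or measured.promoter
        target = target or measured.condition_set
    if target is None:
        target = ConditionSet(*predicted_weights.keys())
    if not promoter and singles:
        promoter = singles[0].promoter
    return WeightPrediction(
        promoter=promoter,
        target=target,
        predicted_weights=dict(predicted_weights),
        predicted_curve=np.asarray(curve, dtype=float),
        relative_error_vs_measured=err,
    )
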