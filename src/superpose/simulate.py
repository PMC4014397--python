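"""Synthetic plate experiments with known ground truth.

The generator emulates the study design end to end: 96-well plates of
GFP reporter strains grown in every combination of four medium
supplements (4 singles, 6 pairs, 4 triplets, 1 quadruplet), sampled
every ~8 minutes through ~6 generations of logistic batch growth to a
final OD of ~0.15, with four replicate days.

Ground truth is built so the analysis pipeline's assumptions hold *by
construction*, making recovery tests meaningful:

* each promoter's activity across conditions lives in the span of one or
  two latent shape curves on the generation axis — the first shape is
  proportional to instantaneous growth rate (which for logistic growth
  is ``r·(1 − 2^(g−G))`` on the generation axis), the second a smooth
  bump at a promoter-specific generation;
* every combined condition's true curve is an exact simplex mixture of
  the single-condition curves, with the weight hierarchy derived from a
  single master simplex point per promoter (restriction + renormalize),
  so the pair→cocktail prediction identity holds exactly;
* replicate days multiply each well's activity by a log-normal factor
  (σ = 0.14, the study's day-to-day error scale), and OD/fluorescence
  carry per-timepoint measurement noise;
* a configurable number of *violator* promoters get switch-like
  (sequential-regulation, diauxie-style) dynamics in one designated
  pair, which no weighted average of their smooth single-condition
  curves can reproduce.

GFP accumulates as dG/dt = activity(g(t)) · OD(t), integrated by the
trapezoid rule on the sampling grid; a promoterless background well is
emitted per plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import ConditionSet, PlateSeries, write_plate_table

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_truth",
    "render_plate",
    "write_plates",
    "all_condition_sets",
]

LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated experiment."""

    labels: tuple[str, ...] = ("A", "B", "C", "D")
    n_promoters: int = 20
    n_days: int = 4
    n_violators: int = 1
    single_shape_fraction: float = 1 / 3  # promoters varying in amplitude only

    sampling_interval_min: float = 8.0
    carrying_capacity_od: float = 0.15
    generations_of_growth: float = 6.0  # initial OD = K / 2**G
    doubling_time_range_min: tuple[float, float] = (45.0, 95.0)
    max_duration_min: float = 22 * 60.0
    stationary_od_fraction: float = 0.995  # stop sampling once OD reaches this × K

    day_noise_sigma: float = 0.14  # total log-normal σ of the replicate-day factor
    # fraction of the day-factor variance shared across conditions for a
    # promoter on a given day (inoculum/instrument state), the rest being
    # condition-specific (media preparation, well effects)
    day_noise_shared_fraction: float = 2 / 3
    od_noise_cv: float = 0.01  # multiplicative OD measurement noise
    fluo_noise_frac: float = 0.005  # Gaussian σ as fraction of each well's signal range
    background_fluo: float = 100.0

    amp1_range: tuple[float, float] = (20.0, 100.0)  # loading on the growth shape
    # bump share of a two-shape promoter's curve norm, per condition: drawing
    # it wide makes shape change across conditions genuine (well-conditioned
    # singles), the defining feature of two-shape promoters
    bump_share_range: tuple[float, float] = (0.05, 0.85)
    bump_center_range: tuple[float, float] = (1.0, 5.0)
    bump_width_gen: float = 0.8

    violator_switch_range: tuple[float, float] = (2.5, 3.5)
    violator_switch_width: float = 0.25
    violator_low: float = 5.0
    violator_high: float = 120.0

    def validate(self) -> None:
        checks = {
            "n_promoters": self.n_promoters >= 1,
            "labels": len(self.labels) >= 2 and len(set(self.labels)) == len(self.labels),
            "n_days": self.n_days >= 1,
            "n_violators": 0 <= self.n_violators <= self.n_promoters,
            "single_shape_fraction": 0 <= self.single_shape_fraction <= 1,
            "carrying_capacity_od": self.carrying_capacity_od > 0,
            "generations_of_growth": self.generations_of_growth > 0,
            "doubling_time_range_min": 0 < self.doubling_time_range_min[0]
            <= self.doubling_time_range_min[1],
            "day_noise_sigma": self.day_noise_sigma >= 0,
            "sampling_interval_min": self.sampling_interval_min > 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid simulation config field: {name}")


def all_condition_sets(labels) -> list[ConditionSet]:
    """Every non-empty combination of the supplements, canonical order."""
    out = []
    for size in range(1, len(labels) + 1):
        out.extend(ConditionSet(*c) for c in combinations(sorted(labels), size))
    return out


@dataclass
class GrowthParams:
    rate_per_min: float  # exponential-phase specific growth rate (1/min)
    initial_od: float
    carrying_capacity: float
    duration_min: float

    def od(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k, x0, r = self.carrying_capacity, self.initial_od, self.rate_per_min
        e = np.exp(r * t)
        return k * x0 * e / (k + x0 * (e - 1.0))

    def generations(self, t) -> np.ndarray:
        return np.log2(self.od(t) / self.initial_od)

    def growth_rate(self, t) -> np.ndarray:
        return self.rate_per_min * (1.0 - self.od(t) / self.carrying_capacity)


@dataclass
class SyntheticTruth:
    """Latent shapes, true mixture weights, growth and noise parameters."""

    config: SimulationConfig
    promoters: list[str]
    # per promoter: loading on shape 1 (growth shape) per single-condition label
    amp1: dict[str, dict[str, float]]
    # per promoter: loading on shape 2 (bump) per label; all zero for 1-shape promoters
    amp2: dict[str, dict[str, float]]
    bump_center: dict[str, float]
    master_weights: dict[str, dict[str, float]]  # the simplex point behind all cocktails
    growth: dict[ConditionSet, GrowthParams]
    violators: dict[str, dict] = field(default_factory=dict)

    # -- true curves ----------------------------------------------------

    def shape1(self, g) -> np.ndarray:
        """Growth-tracking shape: 1 − 2^(g − G), the logistic rate profile."""
        g = np.asarray(g, dtype=float)
        return np.clip(1.0 - 2.0 ** (g - self.config.generations_of_growth), 0.0, None)

    def shape2(self, promoter: str, g) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        c, w = self.bump_center[promoter], self.config.bump_width_gen
        return np.exp(-0.5 * ((g - c) / w) ** 2)

    def single_curve(self, promoter: str, label: str, g) -> np.ndarray:
        return self.amp1[promoter][label] * self.shape1(g) + self.amp2[promoter][
            label
        ] * self.shape2(promoter, g)

    def weights_for(self, promoter: str, cond: ConditionSet) -> dict[str, float]:
        """True simplex weights of a cocktail: renormalized master restriction."""
        w = self.master_weights[promoter]
        total = sum(w[l] for l in cond.labels)
        return {l: w[l] / total for l in cond.labels}

    def activity(self, promoter: str, cond: ConditionSet, g) -> np.ndarray:
        """True activity of a promoter in a condition set on the generation axis."""
        v = self.violators.get(promoter)
        if v is not None and cond == v["condition"]:
            g = np.asarray(g, dtype=float)
            z = (g - v["switch_generation"]) / self.config.violator_switch_width
            return v["low"] + (v["high"] - v["low"]) / (1.0 + np.exp(-z))
        if len(cond) == 1:
            return self.single_curve(promoter, cond.labels[0], g)
        w = self.weights_for(promoter, cond)
        return sum(w[l] * self.single_curve(promoter, l, g) for l in cond.labels)

    def is_single_shape(self, promoter: str) -> bool:
        return all(v == 0 for v in self.amp2[promoter].values())

    # -- serialization --------------------------------------------------

    def weights_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.promoters:
            for cond in all_condition_sets(self.config.labels):
                if len(cond) < 2:
                    continue
                w = self.weights_for(p, cond)
                row = {"promoter": p, "conditions": str(cond)}
                row.update({f"w_{l}": w.get(l, np.nan) for l in self.config.labels})
                rows.append(row)
        return pd.DataFrame(rows)

    def promoters_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.promoters:
            row = {
                "promoter": p,
                "single_shape": self.is_single_shape(p),
                "bump_center": self.bump_center[p],
                "is_violator": p in self.violators,
            }
            for l in self.config.labels:
                row[f"amp1_{l}"] = self.amp1[p][l]
                row[f"amp2_{l}"] = self.amp2[p][l]
                row[f"master_w_{l}"] = self.master_weights[p][l]
            rows.append(row)
        return pd.DataFrame(rows)

    def growth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "conditions": str(c),
                    "rate_per_min": gp.rate_per_min,
                    "doubling_time_min": LN2 / gp.rate_per_min,
                    "initial_od": gp.initial_od,
                    "carrying_capacity": gp.carrying_capacity,
                    "duration_min": gp.duration_min,
                }
                for c, gp in self.growth.items()
            ]
        )

    def to_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.weights_frame().to_csv(outdir / "truth_weights.csv", index=False)
        self.promoters_frame().to_csv(outdir / "truth_promoters.csv", index=False)
        self.growth_frame().to_csv(outdir / "truth_growth.csv", index=False)


def generate_truth(
    n_promoters: int | None = None,
    labels=None,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a complete ground truth for one simulated experiment.

    About a third of promoters (``single_shape_fraction``) vary only in
    amplitude across conditions; the rest load on two shapes.  The last
    ``n_violators`` promoters additionally get sequential (switch-like)
    dynamics in the designated pair of the first two supplements.
    """
    config = config or SimulationConfig()
    if n_promoters is not None or labels is not None:
        kw = asdict(config)
        if n_promoters is not None:
            kw["n_promoters"] = n_promoters
        if labels is not None:
            kw["labels"] = tuple(labels)
        config = SimulationConfig(**kw)
    config.validate()
    rng = np.random.default_rng(seed)
    labels = tuple(sorted(config.labels))

    width = max(3, len(str(config.n_promoters)))
    promoters = [f"P{i:0{width}d}" for i in range(1, config.n_promoters + 1)]
    n_single = int(round(config.single_shape_fraction * config.n_promoters))
    single_shape = set(rng.choice(promoters, size=n_single, replace=False))

    g_ref = np.linspace(0.0, config.generations_of_growth, 601)
    s1_norm = float(
        np.linalg.norm(
            np.clip(1.0 - 2.0 ** (g_ref - config.generations_of_growth), 0.0, None)
        )
    )
    amp1, amp2, bump_center, master = {}, {}, {}, {}
    for p in promoters:
        amp1[p] = {l: float(rng.uniform(*config.amp1_range)) for l in labels}
        bump_center[p] = float(rng.uniform(*config.bump_center_range))
        if p in single_shape:
            amp2[p] = {l: 0.0 for l in labels}
        else:
            # loading chosen so the bump carries a condition-specific share
            # of the curve norm, comparable in scale to the growth shape
            c, w = bump_center[p], config.bump_width_gen
            s2_norm = float(np.linalg.norm(np.exp(-0.5 * ((g_ref - c) / w) ** 2)))
            amp2[p] = {
                l: float(
                    rng.uniform(*config.bump_share_range)
                    * amp1[p][l]
                    * s1_norm
                    / s2_norm
                )
                for l in labels
            }
        w = rng.dirichlet(np.ones(len(labels)))
        # keep the master point away from the simplex boundary so every
        # restriction weight is identifiable
        w = 0.9 * w + 0.1 / len(labels)
        master[p] = {l: float(x) for l, x in zip(labels, w)}

    violators: dict[str, dict] = {}
    designated = ConditionSet(labels[0], labels[1])
    for p in promoters[config.n_promoters - config.n_violators :]:
        violators[p] = {
            "condition": designated,
            "switch_generation": float(rng.uniform(*config.violator_switch_range)),
            "low": config.violator_low,
            "high": config.violator_high,
        }

    growth: dict[ConditionSet, GrowthParams] = {}
    k = config.carrying_capacity_od
    x0 = k / 2.0**config.generations_of_growth
    for cond in all_condition_sets(labels):
        tau = float(rng.uniform(*config.doubling_time_range_min))
        r = LN2 / tau
        frac = config.stationary_od_fraction
        # logistic time from x0 to frac·K
        t_end = (1.0 / r) * math.log((frac / (1 - frac)) * ((k - x0) / x0))
        t_end = min(t_end, config.max_duration_min)
        dt = config.sampling_interval_min
        duration = dt * math.ceil(t_end / dt)
        growth[cond] = GrowthParams(
            rate_per_min=r, initial_od=x0, carrying_capacity=k, duration_min=duration
        )

    return SyntheticTruth(
        config=config,
        promoters=promoters,
        amp1=amp1,
        amp2=amp2,
        bump_center=bump_center,
        master_weights=master,
        growth=growth,
        violators=violators,
    )


_WELL_ROWS = "ABCDEFGH"


def _well_ids(n: int) -> list[str]:
    if n > 96:
        raise ValueError("a plate holds at most 96 wells")
    return [f"{_WELL_ROWS[i // 12]}{i % 12 + 1}" for i in range(n)]


def render_plate(
    truth: SyntheticTruth, config: SimulationConfig | None = None, seed: int = 0
) -> dict[str, list[PlateSeries]]:
    """Render the full experiment: one plate per (condition set, day).

    Returns a dict keyed by plate id (``"<conditions>_day<d>"``) holding
    that plate's PlateSeries — every promoter plus one promoterless
    background-control well, all sharing the plate's time grid.  Promoter
    counts above 95 spill onto additional plates (each with its own
    control well).
    """
    config = config or truth.config
    rng = np.random.default_rng(seed)
    shared_frac = min(max(config.day_noise_shared_fraction, 0.0), 1.0)
    sigma_shared = config.day_noise_sigma * math.sqrt(shared_frac)
    sigma_cond = config.day_noise_sigma * math.sqrt(1.0 - shared_frac)
    # day factor shared by all conditions of a promoter measured that day
    shared_log = {
        (prom, day): sigma_shared * rng.standard_normal()
        for prom in truth.promoters
        for day in range(1, config.n_days + 1)
    }
    plates: dict[str, list[PlateSeries]] = {}
    for cond in all_condition_sets(config.labels):
        gp = truth.growth[cond]
        t = np.arange(0.0, gp.duration_min + 0.5 * config.sampling_interval_min,
                      config.sampling_interval_min)
        od_true = gp.od(t)
        gen_true = gp.generations(t)
        for day in range(1, config.n_days + 1):
            chunks = [
                truth.promoters[i : i + 95] for i in range(0, len(truth.promoters), 95)
            ]
            for ci, chunk in enumerate(chunks):
                plate_id = f"{cond}_day{day}" + (f"_p{ci + 1}" if len(chunks) > 1 else "")
                wells = _well_ids(len(chunk) + 1)
                series: list[PlateSeries] = []
                for well, prom in zip(wells, chunk):
                    f_day = math.exp(
                        shared_log[(prom, day)] + sigma_cond * rng.standard_normal()
                    )
                    act = f_day * truth.activity(prom, cond, gen_true)
                    dgdt = act * od_true
                    fluo_true = np.concatenate(
                        [[0.0], np.cumsum(0.5 * (dgdt[1:] + dgdt[:-1]) * np.diff(t))]
                    )
                    scale = max(fluo_true.max(), config.background_fluo)
                    fluo = (
                        fluo_true
                        + config.background_fluo
                        + config.fluo_noise_frac * scale * rng.standard_normal(t.size)
                    )
                    od = od_true * (1.0 + config.od_noise_cv * rng.standard_normal(t.size))
                    series.append(
                        PlateSeries(
                            well_id=well,
                            promoter=prom,
                            condition_set=cond,
                            replicate_day=day,
                            time_min=t,
                            od=np.clip(od, 1e-9, None),
                            fluo=fluo,
                        )
                    )
                ctrl_fluo = config.background_fluo * (
                    1.0 + config.fluo_noise_frac * rng.standard_normal(t.size)
                )
                ctrl_od = od_true * (1.0 + config.od_noise_cv * rng.standard_normal(t.size))
                series.append(
                    PlateSeries(
                        well_id=wells[-1],
                        promoter="control",
                        condition_set=cond,
                        replicate_day=day,
                        time_min=t,
                        od=np.clip(ctrl_od, 1e-9, None),
                        fluo=ctrl_fluo,
                        is_background_control=True,
                    )
                )
                plates[plate_id] = series
    return plates


def write_plates(plates: dict[str, list[PlateSeries]], outdir) -> list[tuple[Path, Path]]:
    """Write each plate to the wide-CSV dialect ``plate_io`` reads back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for plate_id, series in plates.items():
        safe = plate_id.replace("+", "")
        table = outdir / f"plate_{safe}.csv"
        pmap = outdir / f"map_{safe}.csv"
        write_plate_table(series, table, pmap)
        paths.append((table, pmap))
    return paths
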