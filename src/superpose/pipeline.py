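"""End-to-end orchestration: simulate → activity → pca → fit → predict → evaluate.

Each stage is a plain function taking and returning in-memory objects, so
library users can run any prefix of the pipeline; the CLI wraps these and
writes the CSV artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .activity import (
    ActivityCurve,
    GrowthRateCurve,
    growth_rate,
    promoter_activity,
    resample_to_common_grid,
    to_generation_axis,
)
from .plate import ConditionSet, PlateSeries, subtract_background
from .prediction import predict_dynamics, predict_weights_iterative
from .shapes import PromoterShapeModel, pc1_growth_correlation
from .simulate import SimulationConfig, generate_truth, render_plate
from .superposition import SuperpositionModel, weight_sum_statistics

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline"]

STEPS = ("simulate", "activity", "pca", "fit", "predict", "evaluate")


@dataclass
class PipelineConfig:
    """Analysis and simulation knobs for one pipeline run."""

    window: int = 17  # sliding-window width (samples) for derivatives
    n_grid_points: int = 100  # shared generation grid
    clip_negative_fluo: bool = False
    center_pca: bool = False
    violation_threshold: float = 0.2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sim_data = data.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim_data) - sim_known
        if bad:
            raise ValueError(f"unknown config fields: {sorted('simulation.' + b for b in bad)}")
        if "labels" in sim_data:
            sim_data["labels"] = tuple(sim_data["labels"])
        for tup in ("doubling_time_range_min", "amp1_range", "amp2_range",
                    "bump_center_range", "violator_switch_range"):
            if tup in sim_data:
                sim_data[tup] = tuple(sim_data[tup])
        cfg = cls(**data, simulation=SimulationConfig(**sim_data))
        if cfg.window < 3 or cfg.window % 2 == 0:
            raise ValueError("config field window: must be an odd integer >= 3")
        if cfg.n_grid_points < 2:
            raise ValueError("config field n_grid_points: must be >= 2")
        cfg.simulation.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["labels"] = list(d["simulation"]["labels"])
        return d


@dataclass
class PipelineRun:
    """Accumulated artifacts of a (possibly partial) pipeline run."""

    config: PipelineConfig
    seed: int
    truth: object = None
    plates: dict | None = None
    activity_curves: list[ActivityCurve] | None = None
    growth_curves: list[GrowthRateCurve] | None = None
    pca_summary: pd.DataFrame | None = None
    fits: list | None = None
    fits_table: pd.DataFrame | None = None
    predictions: list | None = None
    predictions_table: pd.DataFrame | None = None
    evaluation_summary: pd.DataFrame | None = None
    cumulative_histogram: pd.DataFrame | None = None
    baselines_table: pd.DataFrame | None = None

    def activity_table(self) -> pd.DataFrame:
        rows = []
        for c in self.activity_curves or []:
            rows.append(
                pd.DataFrame(
                    {
                        "promoter": c.promoter,
                        "condition_set": str(c.condition_set),
                        "day": c.replicate_day,
                        "generation": c.generations,
                        "time_min": c.time_min,
                        "activity": c.activity,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _simulate(run: PipelineRun) -> None:
    cfg = run.config
    run.truth = generate_truth(config=cfg.simulation, seed=run.seed)
    run.plates = render_plate(run.truth, cfg.simulation, seed=run.seed + 1)


def _activity(run: PipelineRun) -> None:
    cfg = run.config
    act_curves: list[ActivityCurve] = []
    grw_curves: list[GrowthRateCurve] = []
    for plate_id, series in run.plates.items():
        controls = [s for s in series if s.is_background_control]
        if not controls:
            raise ValueError(f"plate {plate_id} has no background-control well")
        control = controls[0]
        for s in series:
            if s.is_background_control:
                continue
            sub = subtract_background(s, control, clip_negative=cfg.clip_negative_fluo)
            ac = promoter_activity(sub, cfg.window)
            act_curves.append(to_generation_axis(ac, sub, cfg.window))
        gr = growth_rate(control, cfg.window)
        grw_curves.append(to_generation_axis(gr, control, cfg.window))
    everything = act_curves + grw_curves
    resampled = resample_to_common_grid(everything, cfg.n_grid_points)
    run.activity_curves = resampled[: len(act_curves)]
    run.growth_curves = resampled[len(act_curves) :]


def _day_averaged(curves: list[ActivityCurve]) -> dict[tuple[str, ConditionSet], ActivityCurve]:
    """Mean curve across replicate days per (promoter, condition)."""
    groups: dict[tuple[str, ConditionSet], list[ActivityCurve]] = {}
    for c in curves:
        groups.setdefault((c.promoter, c.condition_set), []).append(c)
    out = {}
    for key, cs in groups.items():
        mean = np.mean([c.values for c in cs], axis=0)
        out[key] = dataclasses.replace(cs[0], activity=mean, replicate_day=0)
    return out


def _mean_growth_curve(run: PipelineRun) -> GrowthRateCurve:
    mean = np.mean([g.values for g in run.growth_curves], axis=0)
    return dataclasses.replace(run.growth_curves[0], rate=mean, replicate_day=0)


def _pca(run: PipelineRun) -> None:
    cfg = run.config
    growth = _mean_growth_curve(run)
    by_prom: dict[str, list[ActivityCurve]] = {}
    for c in run.activity_curves:
        by_prom.setdefault(c.promoter, []).append(c)
    rows = []
    for prom in sorted(by_prom):
        model = PromoterShapeModel(by_prom[prom], center=cfg.center_pca)
        shapes = model.fit()
        vf = shapes.variance_fractions
        rows.append(
            {
                "promoter": prom,
                "var_frac_1": float(vf[0]) if vf.size >= 1 else np.nan,
                "var_frac_2": float(vf[1]) if vf.size >= 2 else 0.0,
                "explained_2pc": float(vf[: min(2, vf.size)].sum()),
                "pc1_growth_R2": pc1_growth_correlation(shapes, growth),
                "centered": cfg.center_pca,
            }
        )
    run.pca_summary = pd.DataFrame(rows)


def _fit(run: PipelineRun) -> None:
    averaged = _day_averaged(run.activity_curves)
    labels = sorted({cs.labels[0] for (_, cs) in averaged if len(cs) == 1})
    fits = []
    for (prom, cond), target in sorted(
        averaged.items(), key=lambda kv: (kv[0][0], len(kv[0][1]), kv[0][1].labels)
    ):
        if len(cond) < 2:
            continue
        singles = [averaged[(prom, ConditionSet(l))] for l in cond.labels
                   if (prom, ConditionSet(l)) in averaged]
        if len(singles) != len(cond):
            continue
        model = SuperpositionModel(target, singles)
        fits.extend(model.fit_all())
    run.fits = fits
    rows = []
    for f in fits:
        row = {
            "promoter": f.promoter,
            "conditions": str(f.target),
            "model": f.model,
            "relative_error": f.relative_error,
            "aic": f.aic,
            "n_points": f.n_points,
            "weight_sum": f.weight_sum,
        }
        row.update({f"w_{l}": f.weights.get(l, np.nan) for l in labels})
        rows.append(row)
    run.fits_table = pd.DataFrame(rows)


def _predict(run: PipelineRun) -> None:
    averaged = _day_averaged(run.activity_curves)
    pair_fits: dict[str, dict[ConditionSet, dict[str, float]]] = {}
    for f in run.fits:
        if f.model == "linear_superposition" and len(f.target) == 2:
            pair_fits.setdefault(f.promoter, {})[f.target] = f.weights
    predictions = []
    labels = sorted({cs.labels[0] for (_, cs) in averaged if len(cs) == 1})
    full = ConditionSet(*labels)
    for prom in sorted(pair_fits):
        pairs = pair_fits[prom]
        if set(pairs) != set(full.subsets(2)):
            continue
        _, levels = predict_weights_iterative(pairs, full, return_all=True)
        singles = [averaged[(prom, ConditionSet(l))] for l in labels]
        for size in range(3, len(labels) + 1):
            for target in full.subsets(size):
                w = levels[target]
                measured = averaged.get((prom, target))
                sub_singles = [s for s in singles if s.condition_set.labels[0] in target]
                predictions.append(
                    predict_dynamics(w, sub_singles, measured=measured,
                                     promoter=prom, target=target)
                )
    run.predictions = predictions
    rows = []
    for p in predictions:
        row = {
            "promoter": p.promoter,
            "conditions": str(p.target),
            "cocktail_size": len(p.target),
            "relative_error_vs_measured": p.relative_error_vs_measured,
        }
        row.update(
            {f"w_{l}": p.predicted_weights.get(l, np.nan) for l in labels}
        )
        rows.append(row)
    run.predictions_table = pd.DataFrame(rows)


def _evaluate(run: PipelineRun) -> None:
    cfg = run.config
    groups: dict[tuple[str, ConditionSet], list[ActivityCurve]] = {}
    for c in run.activity_curves:
        groups.setdefault((c.promoter, c.condition_set), []).append(c)
    rep_errors = [
        ev.day_to_day_error(cs) for cs in groups.values() if len(cs) >= 2
    ]
    averaged = _day_averaged(run.activity_curves)
    baselines = []
    for p in run.predictions or []:
        measured = averaged.get((p.promoter, p.target))
        if measured is None:
            continue
        others = [c for (prom, cond), c in averaged.items()
                  if prom == p.promoter and cond != p.target]
        baselines.append(
            {
                "promoter": p.promoter,
                "conditions": str(p.target),
                "cocktail_size": len(p.target),
                "baseline_error": ev.baseline_exemplar_error(measured, others),
                "prediction_error": p.relative_error_vs_measured,
            }
        )
    baselines = pd.DataFrame(baselines)
    summary = ev.prediction_error_summary(run.predictions or [])
    unconstrained = [f for f in (run.fits or []) if f.model == "linear_unconstrained"]
    wstats = (
        weight_sum_statistics(unconstrained)
        if unconstrained
        else {"mean_sum": np.nan, "sd_sum": np.nan, "n_fits": 0,
              "fraction_weights_positive": np.nan}
    )
    superp = [f for f in (run.fits or []) if f.model == "linear_superposition"]
    flagged = ev.flag_violations(superp, cfg.violation_threshold) if superp else []
    # fit error against each replicate day's curve (not just the day average):
    # this is the figure comparable to the day-to-day noise floor
    per_day = []
    for f in superp:
        reps = groups.get((f.promoter, f.target), [])
        if f.fitted_curve is None or not reps:
            continue
        per_day.append(
            float(np.mean([ev.relative_fit_error(f.fitted_curve, c.values) for c in reps]))
        )
    rows = [
        {"metric": "day_to_day_error_mean", "value": float(np.nanmean(rep_errors)) if rep_errors else np.nan},
        {"metric": "mean_fit_error_superposition",
         "value": float(np.mean([f.relative_error for f in superp])) if superp else np.nan},
        {"metric": "mean_fit_error_superposition_per_day",
         "value": float(np.mean(per_day)) if per_day else np.nan},
        {"metric": "fraction_fits_below_0.2",
         "value": float(np.mean([f.relative_error < 0.2 for f in superp])) if superp else np.nan},
        {"metric": "weight_sum_mean", "value": wstats["mean_sum"]},
        {"metric": "weight_sum_sd", "value": wstats["sd_sum"]},
        {"metric": "fraction_weights_positive", "value": wstats["fraction_weights_positive"]},
        {"metric": "n_flagged_violators", "value": float(len(flagged))},
        {"metric": "flagged_violators", "value": ";".join(flagged)},
    ]
    for size, med in summary["medians"].items():
        rows.append({"metric": f"median_prediction_error_size{size}", "value": med})
    if len(baselines):
        for size, grp in baselines.groupby("cocktail_size"):
            rows.append(
                {"metric": f"median_baseline_error_size{size}",
                 "value": float(grp["baseline_error"].median())}
            )
    run.evaluation_summary = pd.DataFrame(rows)
    run.cumulative_histogram = summary["cumulative"]
    run.baselines_table = baselines


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    steps=STEPS,
    plates: dict | None = None,
) -> PipelineRun:
    """Run the requested prefix of the pipeline.

    ``steps`` must be a prefix-closed subset of
    simulate→activity→pca→fit→predict→evaluate; pre-loaded plates may be
    supplied instead of the simulate step.
    """
    config = config or PipelineConfig()
    run = PipelineRun(config=config, seed=int(seed))
    steps = list(steps)
    bad = set(steps) - set(STEPS)
    if bad:
        raise ValueError(f"unknown pipeline steps: {sorted(bad)}")
    if plates is not None:
        run.plates = plates
    order = [s for s in STEPS if s in steps]
    for step in order:
        if step == "simulate":
            if plates is None:
                _simulate(run)
        elif step == "activity":
            if run.plates is None:
                raise ValueError("activity step needs plates (run simulate first)")
            _activity(run)
        elif step == "pca":
            _require(run.activity_curves, "pca", "activity")
            _pca(run)
        elif step == "fit":
            _require(run.activity_curves, "fit", "activity")
            _fit(run)
        elif step == "predict":
            _require(run.fits, "predict", "fit")
            _predict(run)
        elif step == "evaluate":
            _require(run.fits, "evaluate", "fit")
            if run.predictions is None:
                _predict(run)
            _evaluate(run)
    return run


def _require(obj, step: str, needs: str) -> None:
    if obj is None:
        raise ValueError(f"step {step!r} requires step {needs!r} to have run")


def write_outputs(run: PipelineRun, outdir) -> list[Path]:
    """Write every computed artifact as CSV; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df: pd.DataFrame | None, name: str):
        if df is not None and len(df):
            path = outdir / name
            df.to_csv(path, index=False)
            written.append(path)

    if run.truth is not None:
        run.truth.to_csv(outdir)
        written += [outdir / "truth_weights.csv", outdir / "truth_promoters.csv",
                    outdir / "truth_growth.csv"]
    if run.activity_curves is not None:
        _w(run.activity_table(), "activity_curves.csv")
    _w(run.pca_summary, "pca_summary.csv")
    _w(run.fits_table, "fits.csv")
    _w(run.predictions_table, "predictions.csv")
    _w(run.evaluation_summary, "evaluation_summary.csv")
    _w(run.cumulative_histogram, "cumulative_histogram.csv")
    _w(getattr(run, "baselines_table", None), "baseline_errors.csv")
    return written
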