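# superpose

Analysis of bacterial promoter-activity dynamics in combined growth
conditions: derive activity curves from plate-reader OD/GFP time series,
decompose each promoter's cross-condition dynamics into one or two
principal shape curves, fit combined-condition dynamics as weighted
averages (linear superposition) of single-condition dynamics, and predict
triplet/quadruplet dynamics from pairwise measurements alone.

The package is aimed at people analyzing fluorescent-reporter batch-growth
experiments — *E. coli* promoter libraries grown in 96-well plates through
exponential into stationary phase, sampled every ~8 minutes — who want to
ask how gene expression in a cocktail of supplements relates to expression
in each supplement alone. A full synthetic-plate simulator with known
ground truth backs every stage, so the whole pipeline is testable without
access to any particular laboratory dataset.

## The model

Promoter activity is the rate of GFP accumulation per unit cell density,

P(t) = (dG/dt) / OD(t),

estimated as the least-squares slope of fluorescence over a sliding window
(17 samples by default) divided by the mean OD over that window. Because
different media support different growth rates, curves are compared on a
**generation axis** g(t) = log2(OD(t)/OD(t₀)) rather than in clock time.

For a promoter measured in single conditions A, B, … the dynamics in a
combined condition is modelled as a weighted combination on the shared
generation axis:

P_{A+B}(g) ≈ w_A·P_A(g) + w_B·P_B(g)

Three model variants are fitted per (promoter, cocktail):

| model | constraint | free parameters (pair) |
|---|---|---|
| `linear_unconstrained` | none (total least squares / errors-in-variables) | 2 |
| `linear_superposition` | wᵢ ≥ 0, Σwᵢ = 1 (weighted average) | 1 |
| `multiplicative` | weighted geometric mean, simplex weights in log domain | 1 |

Models are compared by AIC = n·ln(RSS/n) + 2k. When the weights of every
(N−1)-cocktail are known, the N-cocktail weights follow from the
self-consistency of superposition:

w_i = (N−2) / ( Σ_{j≠i} 1/w_i^(≠j) − 1 )

where w_i^(≠j) is the weight of supplement i in the cocktail missing
supplement j. Applied iteratively, pair measurements alone predict
triplets, and predicted triplets predict the quadruplet.

## Worked example

Simulate a small experiment (6 promoters, 15 condition combinations of
4 supplements, 4 replicate days, 14% day-to-day noise), fit the pair
weights and predict the quadruplet from pairs:

```python
from superpose import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({"simulation": {"n_promoters": 6, "n_violators": 1}})
run = run_pipeline(cfg, seed=17)

fit = next(f for f in run.fits
           if f.promoter == "P005" and str(f.target) == "A+B"
           and f.model == "linear_superposition")
print(fit.summary())
```

```
Mixture fit: P005 in A+B  [linear_superposition]
--------------------------------------------------------
  w[A] =  0.4436
  w[B] =  0.5564
  sum of weights  =  1.0000
  relative error  =  0.0182
  AIC             = -4.30   (n=100, k=1)
  warning: singles nearly collinear; weights ill-determined
```

The fitted weighted average reproduces the measured A+B dynamics to 1.8%
(the simulation's true weights were A = 0.508, B = 0.492; the collinearity
warning notes that this promoter's two single-condition curves are similar
in shape, so the weights carry more uncertainty than the curve fit does).
Predicting the four-supplement cocktail from the six pair fits alone:

```python
pred = next(p for p in run.predictions
            if p.promoter == "P005" and str(p.target) == "A+B+C+D")
for label, w in pred.predicted_weights.items():
    print(f"  w[{label}] = {w:.3f}")
print(f"error vs measured: {pred.relative_error_vs_measured:.3f}")
```

```
  w[A] = 0.097   (true 0.105)
  w[B] = 0.104   (true 0.102)
  w[C] = 0.657   (true 0.655)
  w[D] = 0.142   (true 0.138)
error vs measured: 0.031
```

The predicted quadruplet dynamics lands within 3.1% of the measured curve —
several-fold better than the exemplar baseline ("predict condition X by
any other measured curve of the same promoter"), which sits near 20% on
this run. `run.evaluation_summary` collects these statistics; the
sequential-regulation violator planted in the simulation (a diauxie-like
promoter whose combined-condition dynamics is a switch, not a weighted
average) is the one promoter flagged by `flag_violations`.

## Command line

```sh
superpose all --config config.yaml --seed 17 --out results/
```

Subcommands `simulate | activity | pca | fit | predict | evaluate | all`
run prefixes of the pipeline and write CSV artifacts plus a run manifest
(seed, config hash, version). `--plates dir/` analyzes measured
`plate_*.csv` / `map_*.csv` pairs instead of simulating; all readers
accept gzip-compressed files.

## Layout

| module | contents |
|---|---|
| `superpose.plate` | `PlateSeries`, `ConditionSet`, plate-table/map I/O, background subtraction |
| `superpose.activity` | activity & growth-rate curves, generation axis, common-grid resampling |
| `superpose.shapes` | `PromoterShapeModel` → `PrincipalShapes` (per-promoter PCA, randomized null) |
| `superpose.superposition` | `SuperpositionModel` → `WeightFit` (TLS, simplex, multiplicative, AIC) |
| `superpose.prediction` | pair → triplet → quadruplet weight prediction, predicted dynamics |
| `superpose.evaluation` | day-to-day error, exemplar baseline, error summaries, violation flags |
| `superpose.simulate` | ground-truth generator and plate renderer |
| `superpose.pipeline` / `superpose.cli` | end-to-end orchestration and the `superpose` command |

See `docs/methods.md` for the modelling assumptions, the simulator's noise
model, and the numerical choices.
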