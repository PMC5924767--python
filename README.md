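# fintrack

Fine-scale movement analysis for GPS/time-depth-tagged marine mammals.

Snapshot-GPS and time-depth-recorder (TDR) tags on small cetaceans such
as harbour porpoises produce two awkward data streams: an *irregular*
series of noisy surface positions (a few fixes per hour, with
occasional kilometre-scale positional spikes) and a 1 Hz depth trace
mixing surface intervals with thousands of short dives. `fintrack`
turns these into population-level statements about how the environment
shapes movement:

1. **Track processing** — positional outliers are removed when a fix
   implies > 15 km/h from its predecessor *and* the track returns
   toward where it came from; everything within 24 h of tagging is
   discarded; the series is regularized to 15-min steps (±2 min;
   30/60-min variants for sensitivity) and summarized as movement speed
   (m s⁻¹) and absolute turning angle (0–180°).
2. **Dive processing** — a dive is any excursion > 2 m lasting ≥ 10 s;
   each dive yields duration, maximum depth, *wiggliness* (summed
   vertical distance over the bottom phase, a prey-chasing proxy) and
   post-dive surface duration; dives are condensed onto fixes (start
   within ±30 s) so they carry a position.
3. **Environmental annotation** — bathymetry, seabed slope and distance
   to coast from a ~300 m grid; hourly sea-surface temperature,
   salinity, height and current velocity from a ~7 km grid; plus hour
   of day.
4. **Inference** — each movement parameter y (log₁₀-transformed except
   turning angle) is modelled by generalized least squares with
   errors cov(e_a, e_b) = σ²·δ_g·δ_g'·ρ^|a−b| (AR(1) within individual,
   per-individual variance multipliers δ, maximum likelihood). All
   2^p subsets of the covariate set are fitted (SSH and hour of day as
   quadratic pairs), scored by AICc, and combined by model averaging:
   variable importance w₊(j) = Σ Akaike weights of models containing j,
   conditional averaged coefficients with unconditional SEs, and a
   95% CI rule for flagging effects. Collinear static covariates are
   split into a bathymetry set and a distance/slope/SST set, compared
   by minimum AICc.

Because real deployments of this kind are rarely shareable, the package
ships a first-class synthetic-data generator (`fintrack.synthetic`)
that emulates the whole observation process — smooth environmental
fields, a two-state correlated random walk, thinned 3-min GPS attempts
with ledgered spikes, and 1 Hz dive traces with ledgered true dives —
with known planted covariate effects, so every stage is validated
against truth (`fintrack.validation`).

## Worked example

```python
from fintrack.pipeline import RunConfig, run_pipeline
from fintrack.synthetic import SimConfig

cfg = RunConfig(
    sim=SimConfig(seed=42, n_individuals=3, duration_h=48.0),
    responses=("speed",), model_sets="A",
)
report = run_pipeline(cfg)
print("counts:", report.counts)
res = report.results["speed"]["A"]
cols = ["term", "column", "beta", "ci_low", "ci_high", "w_plus", "effect"]
print(res.table[cols].round(4).to_string(index=False))
print(f"mean R2 = {res.r2_mean:.2f} (min {res.r2_min:.2f}, max {res.r2_max:.2f})")
```

prints

```
counts: {'fixes_ingested': 728, 'depth_samples': 518400, 'outliers_removed': 12,
 'fixes_regularized': 183, 'steps': 55, 'dives_segmented': 3547,
 'dives_condensed': 140}
       term        column    beta  ci_low  ci_high  w_plus  effect
(Intercept)   (Intercept)  3.8849 -0.5873   8.3571     NaN   False
 bathymetry    bathymetry -0.0040 -0.0141   0.0061  0.2667   False
   salinity      salinity -0.1497 -0.2599  -0.0395  0.8379    True
        ssh           ssh -0.0621 -0.2046   0.0804  0.0910   False
        ssh         ssh^2  0.1027 -0.4556   0.6611  0.0910   False
   velocity      velocity -0.0229 -0.5553   0.5094  0.2156   False
hour_of_day   hour_of_day -0.0078 -0.0192   0.0036  0.1967   False
hour_of_day hour_of_day^2  0.0009 -0.0009   0.0027  0.1967   False
mean R2 = 0.05 (min 0.00, max 0.12)
```

Reading this: three simulated animals over 48 h yield 728 fixes, of
which 12 are removed as spikes and 183 survive 15-min regularization;
3547 dives are segmented and 140 fall within ±30 s of a retained fix.
For log₁₀ speed, salinity is the dominant covariate (w₊ = 0.84) with a
negative averaged coefficient of −0.15 log₁₀(m s⁻¹) per PSU whose 95%
CI excludes zero — the planted "porpoises slow down in saline water"
effect, recovered. The other covariates' CIs straddle zero at this
sample size.

The same stages are available from the shell:

```bash
fintrack simulate --seed 1 --out runs/sim
fintrack process-tracks --fixes runs/sim/fixes.csv --interval 15 --out runs/tracks
fintrack process-dives --depth runs/sim/depth.csv \
    --trajectory runs/tracks/trajectory.csv --out runs/dives
fintrack annotate --records runs/tracks/steps.csv \
    --static runs/sim/static.nc --dynamic runs/sim/dynamic.nc \
    --out runs/steps_annotated.csv
fintrack fit --table runs/steps_annotated.csv --response speed \
    --variables bathymetry,salinity,ssh,velocity,hour_of_day \
    --out runs/speed_averaged.csv
fintrack run-all --seed 1 --out runs/full      # everything in one go
```

## Layout

```
src/fintrack/
  synthetic.py     # fields, paths, GPS fixes, depth traces (+ ledgers)
  tracks.py        # outlier screen, 24 h discard, regularization, steps
  dives.py         # zero-offset check, segmentation, metrics, condensing
  environment.py   # slope, distance-to-coast, annotation, collinearity
  gls.py           # design building; ML GLS with AR(1) + variance weights
  inference.py     # enumeration, AICc weights, averaging, predictions
  validation.py    # simulation studies against planted truth
  pipeline.py      # end-to-end orchestration, fixtures
  cli.py           # `fintrack` command group
docs/methods.md    # models, assumptions, parameter choices, limitations
tests/             # unit, property and validation-battery tests
```
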