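# divebout

Dive, bout and behavioral-state analysis for time-depth-recorder (TDR)
records of diving predators, built around the workflow used to study
fine-scale variation in harbor seal foraging behavior.

## The problem

Archival TDR tags record depth every 10 s for months at a time. Turning
those traces into behavioral inference takes a chain of steps, each with
small conventions that matter for reproducibility:

1. **Zero-offset correction** — the pressure transducer's surface reading
   drifts; a rolling lower-percentile baseline restores "surface = 0 m".
2. **Dive extraction** — maximal submerged excursions, kept for shape
   analysis when deeper than 5 m with at least 5 depth readings.
3. **Shape metrics** — per dive: maximum depth, duration, bottom time
   (time at ≥ 85 % of maximum depth), wiggles (vertical reversals in the
   bottom phase), skew (ascent/descent rate ratio), and the ratios
   BTD, BTM, MDD. Square dives (high BTD) indicate foraging at depth;
   V-shaped dives indicate travel or exploration.
4. **Bout detection** — seals forage in runs of dives. A bout opens at
   four consecutive dives to ≥ 6 m and grows while each next surface
   interval x is *not* significantly greater than the previous within-bout
   intervals: with k intervals of mean m and SD s,

       t = (x − m) / (s·√(1 + 1/k)),   df = k − 1,   one-sided α = 0.05.

5. **Classification** — dives (and, separately, bouts via eight summary
   variables) are standardized, compressed by PCA keeping components that
   explain ≥ 80 % of variance, clustered by k-means over a range of k,
   validated by a linear discriminant trained on the cluster labels, and
   the most parsimonious solution kept. The wiggle count enters as a
   categorical wiggle-dive indicator alongside the PC scores.
6. **Behavioral model** — bout-type usage (shallow Type II vs deep
   Type I foraging bouts) is modeled as a Bayesian binomial GLMM,

       y_ij ~ Bernoulli(θ_ij),
       logit(θ_ij) = x_ij'β + α_i,
       β_k ~ N(0, 10²),   α_i ~ N(0, σ_α²),   σ_α ~ half-N(0, 5²),

   with haul-out site, season (breeding Jul–Oct vs non-breeding),
   light (day/night from monthly mean sunrise/sunset) and sex as fully
   interacting binary predictors and a per-seal random intercept, fitted
   by a Metropolis-within-Gibbs sampler. A positive coefficient shifts
   behavior from Type I toward Type II bouts; an effect is "significant"
   when its 95 % credible interval excludes zero.

Because raw biologging deployments are rarely redistributable, the
package includes a first-class synthetic-data module: parametric dive
templates (trapezoids, triangles, sinusoidal bottom wiggles) driven by
published dive/bout-type summaries, bout/gap structure with ground truth
carried in a sidecar table, and covariate/outcome generation from the
logistic model itself for parameter-recovery experiments.

## Worked example

```python
from divebout import (generate_trace, zero_offset_correct, detect_dives,
                      dive_table, detect_bouts, BoutTypeModel,
                      generate_outcomes)

trace, truth = generate_trace(n_bouts=20, seed=42, animal_id="S00")
corrected = zero_offset_correct(trace)
dives = dive_table(corrected, detect_dives(corrected))
bouts, unassigned = detect_bouts(dives)

outcomes, alpha_true, beta_true = generate_outcomes(seed=42)
res = BoutTypeModel.from_dataframe(outcomes).fit(
    draws=10_000, burn=10_000, seed=42
)
print(res.summary_frame().head(6).round(3))
```

prints

```
trace: 8155 samples at dt=10 s (22.7 h)
dives detected: 131
bouts: 20, dives outside bouts: 0

                Mean  0.025  0.975  significant
Intercept      1.323  0.575  2.066         True
Site1          1.510  0.319  2.705         True
Season1       -1.449 -1.998 -0.879         True
Light1        -0.902 -1.463 -0.345         True
Sex1          -5.129 -6.941 -3.482         True
Site1:Season1  1.528  0.377  2.616         True
```

The 20 generated bouts are recovered exactly and every dive falls inside
a bout (this record has no isolated dives). The model's posterior means
sit near the generating coefficients — e.g. Site 1.51 (true 1.188),
Season −1.45 (true −1.118) — with 95 % credible intervals that exclude
zero, and the random-effect scale is recovered as σ_α ≈ 0.84 against a
generating value of 0.9. Seal-level effects (Site, Sex) carry wider
intervals than within-seal effects because only 21 seals inform them.

A `divebout` command-line tool wraps each stage
(`divebout synth|zoc|dives|bouts|classify|bayes|run`); `divebout run
--outdir out/ --seed 1` executes the whole pipeline and writes per-stage
plain-text artifacts plus a run manifest.

## Layout

- `src/divebout/trace.py` — trace I/O, zero-offset correction, dive windows
- `src/divebout/dives.py` — shape metrics, season/light context
- `src/divebout/solar.py` — sunrise/sunset approximation
- `src/divebout/bouts.py` — sequential bout detection and summaries
- `src/divebout/classify.py` — PCA + k-means + discriminant validation
- `src/divebout/bayes.py` — the Bayesian bout-type model (Model/Results)
- `src/divebout/synth.py` — synthetic traces, metrics and outcomes
- `src/divebout/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
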