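# Methods notes

This note records the modeling assumptions, parameter choices and known
limitations behind `divebout`, in the spirit of a package's statistical
documentation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Trace processing

**Zero-offset correction.** Vendor ZOC software is closed; the standard
open reconstruction is a rolling lower-percentile surface baseline. We
use the 5th percentile of depth in a centred 2 h window (configurable),
subtract it, and clamp negative depths to zero. The window must span at
least 10 samples; at the default 10 s sampling it covers 720 samples, so
the percentile reflects surface visits rather than any single dive. This
removes constant offsets exactly and tracks slow (linear) drift to well
within the 0.5 m transducer resolution, which the tests verify against
generator ground truth.

**Dive windows.** A dive is a maximal run of samples deeper than a 2 m
surface threshold. The threshold separates submergence from surface
splash/noise and is deliberately distinct from the 5 m *analysis* filter:
dives are kept for shape analysis only when their maximum depth exceeds
5 m (strictly) and they contain at least 5 samples, because shorter
records do not resolve dive shape. Whether the 5 m exclusion applies
before or after correction is ambiguous in the tradition this follows;
we apply it after, which is the conservative choice (drift cannot delete
a real dive).

**Conventions.** Inclusive 0-based window indices; duration =
(samples in window) × dt; bottom phase = samples at ≥ 85 % of maximum
depth; descent rate = depth of the first bottom-phase sample over the
elapsed time from the window start (one dt if coincident), ascent rate
mirrored; skew1 = ascent/descent. A *wiggle* is a local depth minimum in
the plateau-collapsed bottom span whose adjacent fall and rise each
exceed 1 m — twice the transducer resolution, so sensor quantization
cannot fabricate wiggles. Both the excursion and the 85 % bottom
fraction are configurable.

## Bout detection

The sequential criterion follows the iterative tradition for pinniped
bout analysis. The published rule is under-specified on three points we
had to fix:

- *Sidedness and form of the t-test.* We use the one-sided
  single-new-observation (prediction-interval) form,
  t = (x − m)/(s√(1 + 1/k)) with k − 1 df, matching the directional
  wording "significantly greater". The bout-opening rule guarantees
  k ≥ 3 intervals of history, hence df ≥ 2.
- *Zero-variance history.* The statistic degenerates to ±∞; the sign of
  x − m decides (equal-to-mean joins).
- *Resumption.* After a bout closes, scanning resumes at the dive whose
  preceding interval failed; that dive may seed a new bout immediately.

One behavioral consequence of the literal seed rule (four consecutive
dives ≥ 6 m, their intervals unchecked) deserves note: a *deep* lone dive
adjacent to a bout cannot remain outside it — it simply seeds a bout with
whatever dives follow, and the long gap entering the seed's interval
history inflates the test's variance so far that subsequent bouts merge.
Dives genuinely outside bouts are therefore only identifiable when they
fail the seed rule, i.e. are shallower than the 6 m bout-start depth.
The synthetic generator models isolated dives accordingly, as single
shallow resting-type dives between the 5 m analysis threshold and the
6 m bout-start depth — consistent with the interpretation of out-of-bout
dives as haul-out- or resting-related behavior.

## Classification engine

Variables are standardized to zero mean and unit SD (so the pipeline is
invariant to affine rescaling of any input), compressed by PCA keeping
the smallest number of components whose cumulative explained variance
reaches 80 %, and clustered by k-means (k-means++ starts, 25 restarts,
fixed recorded seed). The eight numeric dive variables are max depth,
duration, bottom time, skew1, skew2, BTD, BTM and MDD; the wiggle count
is collapsed to a 0/1 wiggle-dive indicator, scaled to unit variance and
appended to the PC scores (and to the discriminant's feature set) rather
than entering the PCA. Bout classification uses the eight numeric bout
variables with no categorical passthrough.

Validation trains a linear discriminant on the cluster labels and scores
resubstitution agreement (leave-one-out by flag). When the pooled
within-class covariance is singular — typical once every cluster is
constant in the wiggle indicator — the discriminant falls back to a
ridge (shrinkage) estimator, logged and flagged on the solution.

**Parsimony and its limits.** "Fewest clusters with the highest
accuracy" is operationalized as: smallest k among solutions within a
tolerance (default 1.0 accuracy point) of the best. On *clean* synthetic
populations this rule cannot recover the generating k, for a structural
reason: k-means partitions are Voronoi and therefore linearly separable,
so a discriminant reproduces merged low-k solutions essentially as well
as the true-k solution and the accuracy profile is flat-to-decreasing in
k. The recovery claims the package does make — and tests — are that
k-means *at the generating k* recovers the generating classes (ARI
≥ 0.9 for six dive types at halved dispersion, ≈ 1.0 for three bout
types) with discriminant accuracy in the high 90s, the synthetic
analogue of high classification accuracy on real data. On real records,
where cluster shapes are curved and heteroscedastic, the accuracy
profile is informative in a way clean parametric mixtures cannot mimic.

**Type naming.** Dive clusters are named from their centroids: square
vs V at mean BTD 0.5, deep vs shallow at 20 m, wiggle vs non-wiggle at
an indicator mean of 0.5. Bout clusters: any cluster whose mean surface
interval exceeds its mean dive duration is the resting/haul-out class
(Type III); the remainder rank by mean depth then duration — deepest and
longest is Type I (deep foraging), then Type II.

**Scan ranges.** Dives scan k = 4–8 (previous work on this species
found five to seven types). Bouts scan k = 2–6, bracketing the expected
two-to-four behavioral bout classes.

## The Bayesian bout-type model

Bernoulli response per bout (1 = Type II), logit link — the effects are
reported on a logit scale, so the logit is the natural reading — with a
full-factorial design over four binary factors in a fixed column order
(intercept; site, season, light, sex; the six two-way, four three-way
and one four-way products). Treatment coding with alphabetical
references (Bird Rocks, breeding, day, female); sum coding available.
Priors: β ~ N(0, 10²) operationalizes "vague" on the logit scale;
α_i ~ N(0, σ_α²) with σ_α ~ half-N(0, 5²) in hierarchical mode, or σ_α
fixed in flat mode. A half-Normal scale prior is not conjugate, so σ_α
is updated by an adaptive Metropolis step on log σ_α (with Jacobian)
rather than a conjugate draw.

**Sampler.** A fixed Metropolis-within-Gibbs scan: componentwise
random-walk Metropolis for each β (per-component scales adapted toward
0.40 acceptance during burn-in only, then frozen, preserving the
stationary distribution), one vectorized Metropolis pass over the α_i
(valid because the likelihood factorizes over seals), the σ_α step, and
— where a design column is constant within every seal (intercept, sex,
site and their products) — an extra likelihood-invariant joint move that
shifts that β and counter-shifts all α_i, accepted on the prior ratio
alone. Without the joint moves the β/α trade-off along seal-level
columns mixes pathologically slowly; with them the full 16-parameter
model mixes well at chain lengths of 2×10⁴. The likelihood is
aggregated over unique (design cell, seal) combinations, which is exact
for a binomial likelihood and makes iteration cost independent of the
number of bouts; the linear predictor is maintained incrementally and
refreshed every 10³ iterations against float drift. Runs are
deterministic given the seed. Split-R̂ and ESS diagnostics come from
arviz on the half-split chain.

**Screening.** AIC/BIC variable selection fits candidate fixed-effect
structures (mains, two-way, full) by maximum likelihood with per-seal
indicator columns approximating the random effect — an approximation
that is adequate for *ranking* structures, which is all screening does.
Fitted probabilities are clipped at 10⁻¹⁰ before the log-likelihood is
evaluated so quasi-separation (flagged at |coef| > 15) degrades
gracefully instead of producing NaN criteria.

## Synthetic data

The generators encode the statistical structure the analysis assumes;
they are the package's test bench, not a tag-physics simulator.

- **Distributions.** Positive quantities (depths, durations, bottom
  times, skews, intervals, bout durations) are moment-matched
  lognormals: strictly positive, right-skewed like real dive data, and
  reproducing a published mean ± SD exactly. Published summaries supply
  the six dive-type and three bout-type parameterizations; a 0.5 SD
  scale gives the well-separated regime used in recovery tests.
- **Profiles.** Square dives are trapezoids, V dives triangles, wiggles
  sinusoidal plateau oscillations with amplitude capped at 15 % of
  maximum depth so every wiggle stays inside the bottom phase. The
  plateau length (B − 0.15·D)/0.85 reproduces a measured bottom time of
  exactly B, and splitting transit time in the ratio skew1 reproduces
  the drawn skew under the package's rate conventions — so zero-noise
  realized metrics match requested parameters to within one sample of
  quantization, which is tested.
- **Bout structure.** Within-bout surface intervals are lognormal per
  bout type; the gap after a bout is lognormal with mean
  max(600 s, 10× that type's interval mean) — a separated distribution
  that gives the sequential test signal, and places haul-out-scale gaps
  after resting bouts. Bout-type weights default to 0.60/0.39/0.01
  (deep foraging predominant, resting rare). Ground truth (shape ids,
  bout ids, realized boundaries, detectability under the standard
  filters) travels in a sidecar table, never inside the trace format.
- **Outcomes.** Covariate tables assign site and sex at the seal level
  (balanced alternation over 21 seals, mirroring a two-site mixed-sex
  deployment) and season/light per bout at 50 % frequencies; labels are
  drawn from the logistic model at the published posterior-mean
  coefficients (the two terms absent from the published model — the
  season×light two-way and the four-way — default to zero) with
  σ_α = 0.9, the scale implied by the published per-seal effects.

What the generators do *not* emulate: tag pressure-transducer noise
beyond constant/linear drift, wet/dry sensors, depth-dependent dive
curvature, temporal autocorrelation of bout types within a day, and
covariate-dependent dive shapes. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated statistical
structure, not field-data performance.

## Numerical choices

- Likelihood evaluations use `logaddexp`, stable to |η| far beyond 700.
- Credible intervals use linear-interpolation quantiles (`np.quantile`
  default); significance = the 95 % interval excludes zero (an interval
  touching zero is not significant).
- The bout test caches Student-t critical values per (α, df).
- Problem sizes in the validation suite — 1 000 oracle windows, 200
  random bout sequences, 3 000/1 500 classification observations, 50
  coverage replicates at 2×10⁴ draws — were chosen so the whole suite
  completes in minutes on one CPU while keeping Monte-Carlo error well
  inside the asserted tolerances; the sampler calibration check thins
  by 8 (4×10⁵ iterations for 5×10⁴ retained draws) so tail-quantile
  Monte-Carlo error is small against its 0.02 tolerance.

## Known limitations

- The parsimony selection is ill-posed on clean synthetic data (above);
  selected-k values reported by the acceptance script reflect that
  honestly rather than being tuned to a desired answer.
- Bout summaries treat any surface interval as eligible; haul-out (dry)
  periods are not modeled separately, so very long intervals appear as
  between-bout gaps or inside resting bouts.
- The screening fit's seal-indicator approximation overstates the
  effective parameter count relative to a true mixed-model fit; use it
  to order structures, not to interpret coefficients.
- Monthly-mean sunrise/sunset (by design, matching the procedure the
  package reproduces) misclassifies dives within a few minutes of the
  day/night boundary on individual days.
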