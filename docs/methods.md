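# Methods

This note documents the statistical machinery the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Detection prep

**Camera clusters.** Cameras sharing a landscape feature (waterhole,
riverbed, 4×4 track, game trail) within ~150 m are one sampling unit.
Because field teams typically draw clusters by hand, any deterministic rule
is acceptable; ours is greedy agglomeration: within each feature class,
cameras are processed in `camera_id` order, each unassigned camera seeds a
cluster, and the cluster absorbs any unassigned same-feature camera within
the radius of its running centroid (centroid recomputed after each
absorption, repeated until no camera qualifies). This is deterministic and
permutation-invariant. A user-supplied camera→cluster map overrides the
algorithm. Clusters larger than 9 cameras trigger a warning (field protocol
groups 1–9). Coordinates are planar metres; a helper converts lat/lon via a
local equirectangular approximation (sub-metre error at the 150 m scale).

**Independence rule.** Within each (cluster, species) stream, a detection
is retained iff it falls ≥ 30 min (configurable) after the previously
*retained* detection; the first is always retained. This is the
"gap-from-last-retained" reading rather than fixed calendar bins: it is
idempotent, and output size is monotone non-increasing in the window. A
`group_by="camera"` switch reproduces the no-clustering sensitivity
analysis.

**Effort and rates.** One camera-night = one operational calendar day of
one camera; partial first/last days count as one (no finer resolution is
defensible from deployment records). The detection-rate denominator is the
*sum of member-camera nights* (default), not unique cluster-active nights;
both conventions exist in the literature and the summed version matches the
"effort" notion used when cameras within a cluster sample different
micro-sites. Rates are 100 × count / camera-nights per cluster.

**Covariate transforms.** log(1+x) precedes z-scoring when both are
requested (stabilise skew first, then remove scale). Constant columns
requested for z-scoring are an error rather than silently producing NaNs.

## Diel overlap

Clock times map to angles, θ = 2π·(seconds since midnight)/86400 — naive
local time, since the quantity of interest is the local diel cycle.

**KDE.** The activity density is a von Mises kernel mixture,
f̂(θ) = n⁻¹ Σᵢ vM(θ; θᵢ, κ*). The kernel concentration comes from the
plug-in rule κ* = [3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^{2/5} (the asymptotic
MISE minimiser under a von Mises reference), with κ̂ the ML concentration
of the sample; adjust multipliers 0.8 (Δ̂₁) and 1.0 (Δ̂₄) follow the
convention for the two estimators. Grid evaluation uses linear binning plus
FFT circular convolution on a 512-point grid (spectrally accurate at any
realistic bandwidth, and fast enough to sit inside the bootstrap); the
density is renormalised so the trapezoidal circle integral is exactly 1.
Point evaluation interpolates the periodic grid; an exact mixture
evaluator is retained for verification. The kernel concentration is capped
at 10⁶, beyond which the estimate is numerically a point mass.

**Estimators.** Δ̂₁ integrates min(f̂, ĝ) on the grid; Δ̂₄ averages the
clipped density ratios at the observed points. Δ̂₁ is used when the smaller
sample is below 75 detections (the conventional small-sample threshold),
Δ̂₄ otherwise. CIs are nonparametric percentile bootstrap: each sample is
resampled with replacement at its own size, both densities refit, Δ
recomputed; 1000 iterations by default. The CI is clipped to [0, 1] and
widened to contain the point estimate if a finite-bootstrap quirk would
exclude it. Overlap categories: low [0, 0.5), moderate [0.5, 0.75], high
(0.75, 1].

**Circular means.** Mean activity time is atan2 of the mean resultant,
mapped to [0, 24) h; a zero resultant (e.g. an antipodal pair) raises an
explicit undefined-mean error. Bootstrap CIs are computed on signed
deviations from the point estimate and re-centred, so intervals wrap
correctly across midnight.

## Time-stratified case-crossover

Detections are floored to the hour on a per-cluster operational hour grid;
cluster-days are anchored at noon so one night's activity is not split.
Each focal-species detection hour is a case; its control pool is all
operational hours at the same cluster, same calendar year+month, same hour
of day, with no focal detection. Up to five controls are sampled without
replacement; the sampling RNG is keyed by (seed, stratum id) so each
stratum is reproducible independent of iteration order. Cases with empty
pools are dropped and counted.

Exposure is the time since the most recent predator detection at the
cluster, computed identically for case and control hours (the defining
time-stratified-referent feature): short [0, 6) h, delayed [6, 24) h,
reference otherwise. Windows are half-open. Same-hour predator
co-detections are ignored by default, for cases and controls alike: the
only timestamp-ordered alternative (count a same-hour predator for a case
when its raw time precedes the herbivore's) cannot be evaluated for
control hours, and that asymmetry measurably inflates odds ratios whenever
predators and prey co-occur by chance; it remains available as
`build_strata(same_hour_rule=True)` for sensitivity analysis. Control
hours with predator-only detections remain eligible — exposure is the
covariate, not an exclusion criterion.

**Conditional logistic regression** maximises
L(β) = Π_s exp(x_case·β)/Σ_{j∈s} exp(x_j·β) by Newton–Raphson with
step-halving, tolerance 1e-8 on the log-likelihood, ≤ 50 iterations;
standard errors from the inverse observed information. Indicators with no
within-stratum variation carry no information and are dropped with a
warning. Separation — all exposed units on one side — drives the MLE to
±∞; it is flagged per coefficient at |β| > 10 or SE > 100 and the estimate
reported as unstable (matched designs with rare exposure hit this
regularly). The likelihood-ratio test compares against the all-zero null,
whose per-stratum log-likelihood is −log(stratum size); Wald CIs use 1.96;
concordance credits case-beats-control pairs 1 and ties 0.5. The
implementation is cross-checked against statsmodels' ConditionalLogit in
the test suite.

## Hierarchical detection models

Daily cluster-level presence (day boundary midnight; the noon anchor
applies only to the case-crossover) is modelled as
logit P(y=1) = α + x·β + u_cluster + v_survey with u ~ N(0, σ_c),
v ~ N(0, σ_s); priors β ~ N(0, 2), α ~ N(0, 5), σ ~ Exponential(1).
Interactions must have both parents as main effects ("no pure
interactions"). Per-predator daily-presence indicators look back 24 h from
the day start.

**Sampler.** Adaptive Metropolis-within-Gibbs: a joint random-walk block on
(α, β) whose proposal covariance is the inverse Fisher information of the
logistic block (the conditional, given random effects, posterior
covariance — refreshed during warmup); simultaneous single-site updates of
the cluster and survey intercepts (their full conditionals factorise across
groups, so all groups are proposed and accepted/rejected in parallel);
log-scale random walks on σ_c, σ_s; and likelihood-invariant translation
moves along the (α, u) and (α, v) ridges, accepted on the prior ratio
alone, which break the near-nonidentifiability of the intercept with the
group means when groups are few. Proposal scales adapt only during warmup
(target acceptance 0.234 for the joint block, 0.44 for scalar moves), so
the post-warmup kernel is fixed and valid. Desk-scale default: 4 chains ×
2500 iterations, 1000 warmup. Convergence is checked with split-chain R-hat
and bulk ESS (Geyer initial-monotone-sequence estimator) for the intercept,
every β and both σs; R-hat ≥ 1.05 or ESS ≤ 400 reports a convergence
failure rather than silently returning draws.

**Downstream.** Bayes R² per draw is var(p̂)/(var(p̂) + mean(p̂(1−p̂)))
over observations, fitted probabilities including random effects. Effect
tiers: *strong* if the 95% CrI excludes 0; *moderate* if ≥ 90% of posterior
mass is on one side of 0; *weak* if |mean| ≥ 1.0 and the CrI bound on the
mean's side of zero is > 2 posterior-error units from zero while the other
bound is < 2 units (the "posterior error" unit is ambiguous in common
usage: we default to the Monte-Carlo standard error of the posterior mean,
with a switch to posterior sd); else *none*. Post hoc pruning drops
predictors whose posterior mean *and* 95%-CrI midpoint both lie inside
(−0.2, 0.2), then re-adds any main effect parenting a retained interaction.
Horseshoe-regularised fits and LOO/ELPD stacking are deliberately out of
scope; the module fits full, pruned ("post hoc") and null models and
reports Bayes R² for each.

Survey and cluster effects are crossed, not nested (equivalent when
clusters are unique to survey areas, as in the motivating design).

## Synthetic data generator

The generator defines the study conditions for every recovery test: 20
clusters × 2 cameras, 2 surveys × 120 dry-season days, a diurnal herbivore
community (von Mises diel profile centred 12.5 h, κ = 3) facing two
nocturnal predators (centred 2.5 h, κ = 2 — matching the observed
lion/hyena mean activity times of ~2.2–2.9 h), baseline hourly log-odds of
−3.5 to −5, covariate effects on the logit scale, and per-species cluster
(σ = 0.5) and survey (σ = 0.3) random intercepts. For every operational
hour, detection is Bernoulli with logit = base + x·β + u + v + log-density
diel offset (normalised so a uniform profile contributes 0), plus
log OR_short or log OR_delayed when a predator fired at the cluster within
the corresponding lag window (whole-hour lags 1–5 and 6–23, matching the
analysis's half-open hour bins). Timestamps are jittered uniformly within
the hour. Output is byte-identical under a fixed config.

Random intercepts are drawn independently per species: conditional on
predator history, species' detection processes are independent, which keeps
every downstream expectation analytically known (the true overlap is the
quadrature integral of the two configured densities; the true case-crossover
OR is the configured multiplier). Shared-intercept environments — where
productive sites attract predators and prey alike — are deliberately *not*
emulated; in real data such shared heterogeneity is absorbed by the
case-crossover's cluster-level stratification and the model's random
intercepts, but a residual within-stratum version of it (e.g. strata
bridging two surveys in the same calendar month) is a real-world
complication the generator excludes. Other non-emulated features: animal
movement and home ranges (no spatial autocorrelation between clusters),
camera viewshed and detection-distance variation, seasonal trends within a
survey, and clustered multi-animal passes (overdispersion beyond the
independence rule). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
these violations.

## Problem sizes and numerical choices

Recovery suites run at deliberately desk-scale sizes chosen to give stable
Monte-Carlo verdicts: 20 replicates for the case-crossover OR recovery
(median and CI coverage), 20 reduced-iteration MCMC replicates (2 chains ×
1500, 500 warmup) for covariate-effect recovery, n = 3000 cluster-days per
fit, and 1000-iteration bootstraps for overlap CIs. Tolerances follow the
estimator literature: overlap estimates within 0.03 of quadrature truth at
n = 1000; conditional-MLE closed-form agreement to 1e-6; likelihood
identities to 1e-8. Ties in clustering distance comparisons resolve by
camera-id order; degenerate inputs (constant covariates, zero resultant,
all-identical angles, empty strata) raise typed errors rather than
propagating NaNs.
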