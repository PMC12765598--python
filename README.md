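# fearscape

Analysis toolkit for camera-trap studies of predator–prey spatiotemporal
partitioning — the "landscape of fear" in multi-predator systems. Built for
ecologists analysing detection streams from clustered trail-camera surveys
(the motivating system: large herbivores such as gemsbok, mountain zebra and
giraffe sharing arid rangeland with lions and spotted hyenas), where prey are
expected to buffer predation risk in *time* (shifting diel activity away from
nocturnal carnivores) and to react to *recent* predator presence rather than
abandoning resource patches.

The package provides the full chain as an importable library:

1. **Detection prep** — camera clustering (same landscape feature within
   150 m → one sampling unit), effort accounting in camera-nights, the
   30-min independence rule (keep only the first detection of a species per
   30-min window per cluster), detection rates per 100 camera-nights, and
   log(1+x)/z-score covariate transforms.
2. **Diel activity overlap** — clock times mapped to the circle, von Mises
   kernel densities with a plug-in bandwidth, and the Ridout–Linkie overlap
   coefficients

   Δ̂₁ = ∫ min(f̂, ĝ) dθ (grid integration, smaller samples) and
   Δ̂₄ = ½[ mean_i min(1, ĝ(aᵢ)/f̂(aᵢ)) + mean_j min(1, f̂(bⱼ)/ĝ(bⱼ)) ]
   (larger samples),

   with 1000-iteration percentile-bootstrap CIs, circular mean activity
   times with wraparound-aware CIs, and categorisation as low (< 0.5),
   moderate (0.5–0.75) or high (> 0.75).
3. **Time-stratified case-crossover** — each hourly herbivore detection
   (case) is matched with up to five control hours from the same cluster,
   calendar month and hour of day; exposure is time since the last predator
   detection, short-term [0, 6) h or delayed [6, 24) h. A hand-authored
   conditional logistic regression (Newton–Raphson on the exact conditional
   likelihood, with separation detection) yields odds ratios, Wald CIs, a
   likelihood-ratio test and concordance.
4. **Hierarchical Bayesian detection models** — daily cluster-level
   presence modelled as Bernoulli with logit link, fixed covariate effects,
   and random intercepts for camera cluster and survey; priors
   Normal(0, 2) on slopes, Normal(0, 5) on the intercept, Exponential(1) on
   group sds. Sampled by adaptive Metropolis-within-Gibbs with R-hat/ESS
   convergence checks, plus Bayes R², a three-tier effect-strength
   classifier and post hoc pruning of near-zero predictors.
5. **Synthetic data** — an hourly Bernoulli detection-stream generator with
   von Mises diel profiles, covariate effects, per-species cluster/survey
   random intercepts and injected short-term post-predator avoidance with a
   known odds ratio, so every downstream estimate can be checked against
   ground truth.

## Worked example

`examples/03_case_crossover.py` simulates two 120-day surveys of 20 camera
clusters in which zebra hourly detection odds drop to a third (OR 0.33) for
six hours after any lion or hyena detection at the cluster, then recovers
the effect:

```
4405 case strata built, 0 dropped (no eligible controls)
                coef     se    or_         ci      p
effect
lion_short    -0.971  0.180  0.379  0.27-0.54  0.000
lion_delayed  -0.039  0.049  0.961  0.87-1.06  0.419
hyena_short   -1.082  0.165  0.339  0.25-0.47  0.000
hyena_delayed  0.004  0.044  1.004  0.92-1.09  0.929

LR chi2 = 95.97 on 4 df (p = 7.1e-20); concordance = 0.518; n-events = 4405
```

The two `*_short` odds ratios sit near the injected 0.33 with CIs excluding
1, while the `*_delayed` rows (no injected effect) sit near 1 — exactly the
"reactive, short-lived avoidance" signature the design is built to detect.
The other examples walk through detection prep (`01`), diel overlap against
its quadrature oracle (`02`) and the hierarchical model with tier
classification and pruning (`04`).

A thin CLI mirrors the stages for shell use:

```bash
fearscape simulate --seed 7 --out data/
fearscape run-all --config pipeline.yaml --out results/
```

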