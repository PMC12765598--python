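"""Case-crossover test of short-term herbivore avoidance after predator visits.

Simulates surveys in which zebra hourly detection odds drop to a third
(odds ratio 0.33) for six hours after a predator detection at the same
cluster, then recovers that effect with conditional logistic regression on
time-stratified case-control strata.
"""

from fearscape import (
    build_hourly_matrix,
    build_strata,
    cluster_cameras,
    filter_independent,
    fit_clogit,
    simulate,
)
from fearscape.case_crossover import results_table
from fearscape.synthetic_data import AvoidanceSpec, default_config

cfg = default_config(
    seed=21,
    avoidance=(AvoidanceSpec("zebra", "lion", or_short=0.33, or_delayed=1.0),
               AvoidanceSpec("zebra", "hyena", or_short=0.33, or_delayed=1.0)),
)
sim = simulate(cfg)
clusters = cluster_cameras(sim.deployments)
filtered = filter_independent(sim.detections, clusters)

matrix = build_hourly_matrix(filtered, clusters)
strata, n_dropped = build_strata(matrix, "zebra", ["lion", "hyena"], seed=1)
print(f"{len(strata)} case strata built, {n_dropped} dropped "
      "(no eligible controls)")

fit = fit_clogit(strata)
print(results_table(fit).round(3).to_string())
print(f"\nLR chi2 = {fit.lr_chi2:.2f} on {fit.lr_df} df (p = {fit.lr_p:.2g}); "
      f"concordance = {fit.concordance_:.3f}; n-events = {fit.n_events}")
print("\nThe *_short odds ratios should sit near the injected 0.33: zebra "
      "detection odds fall by two-thirds in the six hours after a predator "
      "passes. The *_delayed rows have no injected effect (OR ~ 1).")
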