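"""Diel activity overlap between a diurnal herbivore and a nocturnal predator.

Fits von Mises kernel densities to the two species' detection clock times,
estimates the Ridout-Linkie overlap coefficient with a bootstrap CI, and
categorises the overlap.
"""

import numpy as np

from fearscape import (
    AngularSample,
    cluster_cameras,
    estimate_overlap,
    filter_independent,
    simulate,
    to_radians,
)
from fearscape.synthetic_data import default_config, expected_overlap

cfg = default_config(seed=11)
sim = simulate(cfg)
clusters = cluster_cameras(sim.deployments)
filtered = filter_independent(sim.detections, clusters)

samples = {
    sp: AngularSample(np.array([to_radians(e.timestamp) for e in filtered
                                if e.species == sp]), sp)
    for sp in ("gemsbok", "lion")
}
res = estimate_overlap(samples["gemsbok"], samples["lion"],
                       n_boot=1000, seed=1)
truth = expected_overlap(cfg, "gemsbok", "lion")

print(f"gemsbok n={res.n_a}, lion n={res.n_b}; estimator {res.estimator}")
print(f"overlap Delta = {res.delta:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f}) -> {res.category}")
print(f"true overlap of the generating densities (quadrature): {truth:.3f}")
print(f"gemsbok mean activity time {res.mean_time_a[0]:.2f} h, "
      f"lion {res.mean_time_b[0]:.2f} h")
print("\nDelta is the shared area under the two 24-h activity densities: "
      "0 = fully partitioned schedules, 1 = identical schedules. A value "
      "near 0.1 with 'low' category reflects strong diel partitioning.")
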