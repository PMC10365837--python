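#!/usr/bin/env python
"""Presynaptic EM morphometry: simulate annotated terminals with vesicles at
controlled distances from the active zone, then recover per-zone counts,
areas and densities.

Writes results/em_zone_metrics.csv.
"""

import numpy as np
import pandas as pd

from axonquant import benchmarks, em, simulate

rows = []
for seed in range(20):
    geom, truth = simulate.simulate_em_synapse(seed=seed)
    m = em.synapse_metrics(geom)
    rows.append(
        {
            "seed": seed,
            "terminal_area_um2": m.terminal_area_um2,
            "density_per_um2": m.density_per_um2,
            "zone1": m.zone_counts[0],
            "zone2": m.zone_counts[1],
            "zone3": m.zone_counts[2],
            "beyond": m.n_beyond,
            "truth_zone1": int((truth.zones["zone"] == 0).sum()),
            "truth_zone2": int((truth.zones["zone"] == 1).sum()),
            "truth_zone3": int((truth.zones["zone"] == 2).sum()),
        }
    )
df = pd.DataFrame(rows)
df.to_csv("results/em_zone_metrics.csv", index=False)
exact = (
    (df["zone1"] == df["truth_zone1"])
    & (df["zone2"] == df["truth_zone2"])
    & (df["zone3"] == df["truth_zone3"])
).mean()
print(f"zone counts match truth exactly in {100 * exact:.0f}% of {len(df)} synapses")

mc = benchmarks.em_area_monte_carlo(seed=7, n_samples=500_000)
print(f"clipped zone areas vs rejection sampling: max relative error {100 * mc['max_rel_error']:.2f}%")
print(f"mean SV density {df['density_per_um2'].mean():.1f} vesicles/um^2 over simulated terminals")
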