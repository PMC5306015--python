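"""Compute the 24 landscape variables for a small simulated study.

One row per (site, period): 10 percent covers, and per component the
compositional (richness, Shannon diversity, evenness) and configurational
(LPI, mean patch size, edge density, shape index) heterogeneity variables.
"""

import farmscape as fs

cfg = fs.SimConfig(seed=11, n_sites=5, grid_size=30)
mosaics = fs.simulate_landscapes(cfg)
metrics = fs.metrics_table(mosaics)

print(metrics[["site_id", "period", "annual_dry_crops", "permanent_pastures",
               "nat_cover_diversity", "prod_edge_density", "prod_lpi"]].round(2))
print(f"\n{len(metrics)} rows ({metrics['site_id'].nunique()} sites x 2 periods), "
      f"{len(fs.ALL_VARIABLES)} landscape variables each.")
# Edge density is inter-category boundary length per hectare of buffer (m/ha);
# Shannon diversity is in nats, relative to the component's own area.
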