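"""Pool raw survey records into richness per site, period and habitat group.

Records are distinct (site, year, species) sightings; pooling the three years
of each period gives distinct-species counts for all / woodland / farmland /
steppe assemblages, with aquatic ("excluded") species dropped everywhere and
steppe birds counted as a subset of farmland birds.
"""

import pandas as pd

import farmscape as fs

pool = fs.make_species_pool()
truth = pd.DataFrame(
    [("s0", "T0", "woodland", 2), ("s0", "T0", "farmland", 8), ("s0", "T0", "steppe", 5),
     ("s0", "T1", "woodland", 4), ("s0", "T1", "farmland", 9), ("s0", "T1", "steppe", 6)],
    columns=["site_id", "period", "group", "richness"],
)
records = fs.simulate_survey(truth, pool, seed=3)
print(f"{len(records)} raw records, e.g.:")
print(records.head(5).to_string(index=False))

richness = fs.richness(records, pool)
print("\npooled richness:")
print(richness.to_string(index=False))
# 'all' equals woodland + farmland here because the synthetic pools are
# disjoint; steppe <= farmland by construction.
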