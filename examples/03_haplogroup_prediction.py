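"""STR-based Y-haplogroup prediction with a labeled reference panel.

Y haplogroups are SNP-defined clades, but within a clade STR haplotypes
cluster in repeat space, so a nearest-neighbor vote against a labeled
reference panel predicts the haplogroup of an STR-only profile. Here three
clades diverge deeply (t_split >> t_within); 30 references per clade are
kept as the panel and 500 held-out males are classified.
"""

import numpy as np

from ystrpop import (
    HaplogroupRefPanel,
    SimConfig,
    default_sim_panel,
    haplogroup_frequencies,
    predict_haplogroup,
    simulate_table,
)

panel = default_sim_panel(15)
cfg = SimConfig(
    panel=panel,
    populations=[("O2-M122", 197, "O2-M122"),
                 ("D-M174", 197, "D-M174"),
                 ("C-M216", 196, "C-M216")],
    mu=0.05,
    t_within=2.0,   # shallow within-clade depth
    t_split=60.0,   # deep clade splits
    seed=3,
)
table, _ = simulate_table(cfg)

records, queries = [], []
for pop in table.population_ids:
    rows = table.population(pop)
    records += [(pop, r) for r in rows[:30]]
    queries += rows[30:]
ref = HaplogroupRefPanel(records, locus_overlap_min=10)

calls = [predict_haplogroup(q, ref, k=5) for q in queries]
accuracy = np.mean([c.label == q.population_id for c, q in zip(calls, queries)])
freqs, rate = haplogroup_frequencies(calls)

print(f"{len(queries)} held-out queries against {len(records)} references")
print(f"assignment rate: {100 * rate:.2f}%")
print(f"true-label recovery: {100 * accuracy:.2f}%")
print("predicted haplogroup frequencies:")
for lab, f in freqs.items():
    print(f"  {lab}: {100 * f:.2f}%")
print()
print("With deep clade splits and shallow within-clade variation the k-NN")
print("vote recovers essentially every label; real panels are noisier.")
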