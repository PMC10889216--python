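#!/usr/bin/env python
"""Gene-order rearrangement typing across the 15-species panel.

Clusters the packaged planorbid gene orders into arrangement types,
detects the minimal transposition / reverse-transposition events of each
type against type A (the Bulinus arrangement), and tallies which genes
have moved anywhere in the family.

Writes results/arrangement_types.tsv and results/rearrangement_events.tsv.
"""

from pathlib import Path

import pandas as pd

from mitocompare.rearrangement import (cluster_types, detect_events,
                                       load_planorbid_orders,
                                       rearranged_gene_census)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

orders = load_planorbid_orders()
table = cluster_types(orders)
pd.DataFrame([{"type": label, "n_members": len(ids),
               "members": ",".join(ids)}
              for label, ids in table.types.items()]
             ).to_csv(OUT / "arrangement_types.tsv", sep="\t", index=False)

ref = table.representative("A")
rows = []
for label in table.types:
    if label == "A":
        continue
    for ev in detect_events(ref, table.representative(label)):
        rows.append({"type": label, "gene": ev.gene, "kind": ev.kind,
                     "source": "|".join(ev.source_junction),
                     "dest": "|".join(ev.dest_junction)})
events = pd.DataFrame(rows)
events.to_csv(OUT / "rearrangement_events.tsv", sep="\t", index=False)
census = rearranged_gene_census(table, "A")

print(f"{len(orders)} genomes form {len(table.types)} arrangement types: "
      f"{table.member_counts}")
for label in table.types:
    if label == "A":
        continue
    evs = events[events.type == label]
    kinds = evs.kind.str[0].map({"t": "transposition",
                                 "r": "reverse transposition"})
    print(f"  type {label} vs A: {len(evs)} events "
          f"({', '.join(k[0] + ':' + g for k, g in zip(kinds, evs.gene))})")
print(f"  genes ever rearranged: {len(census['tRNA'])} tRNAs "
      f"({', '.join(sorted(census['tRNA']))}) and "
      f"{', '.join(sorted(census['rRNA']))}; protein genes: "
      f"{sorted(census['PCG']) or 'none'}")
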