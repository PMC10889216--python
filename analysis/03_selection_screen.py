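#!/usr/bin/env python
"""Per-gene Ka/Ks selection screen on a simulated species panel.

Evolves the 13 PCGs along the family topology with per-gene dN/dS set to
the published per-gene averages, scores every ingroup species against the
outgroup reference with NG86, and averages within and across genera.  The
recovered per-gene ordering should reproduce the simulated regime: atp8
least constrained, cox1 most.

Writes results/kaks_per_species.tsv and results/kaks_overall.tsv.
"""

from pathlib import Path

from mitocompare.selection_kaks import genus_summary
from mitocompare.synthetic_data import (DEFAULT_OMEGA, SimulationSpec,
                                        evolve_panel)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

evolved = evolve_panel(SimulationSpec(seed=SEED))
sel = genus_summary(evolved.panel, evolved.pcg_alignments)
sel.per_species.to_csv(OUT / "kaks_per_species.tsv", sep="\t", index=False)
overall = sel.overall.to_frame()
overall["simulated_omega"] = [DEFAULT_OMEGA[g] for g in overall.index]
overall.to_csv(OUT / "kaks_overall.tsv", sep="\t")

n_pos = (sel.per_species["class"] == "positive").sum()
n_pur = (sel.per_species["class"] == "purifying").sum()
print(f"panel of {len(evolved.panel.ingroup)} species vs outgroup "
      f"{evolved.panel.outgroup_id} (seed {SEED})")
print(f"  gene-species estimates: {len(sel.per_species)} "
      f"({n_pur} purifying, {n_pos} positive)")
print(f"  highest mean Ka/Ks: {sel.overall.index[0]} "
      f"({sel.overall.iloc[0]:.3f}, simulated "
      f"{DEFAULT_OMEGA[sel.overall.index[0]]})")
print(f"  lowest mean Ka/Ks:  {sel.overall.index[-1]} "
      f"({sel.overall.iloc[-1]:.3f}, simulated "
      f"{DEFAULT_OMEGA[sel.overall.index[-1]]})")
rho = overall["mean_ratio"].rank().corr(
    overall["simulated_omega"].rank(), method="pearson")
print(f"  rank correlation (recovered vs simulated omega): {rho:.2f}")
print("  note: atp8 has only 37 codons, so its per-pair ratios are "
      "noisy and right-skewed; the extremes and ranking are what the "
      "screen is expected to recover")
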