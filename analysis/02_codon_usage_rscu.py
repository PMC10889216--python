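#!/usr/bin/env python
"""Codon usage and RSCU of the 13 protein-coding genes.

The reference annotation carries no sequence, so a synthetic genome is
generated honouring its gene layout (lengths, strands, start/stop codons)
and the reference base composition; codon counts, amino-acid frequencies,
and RSCU are then computed under the invertebrate mitochondrial code.

Writes results/rscu.tsv and results/amino_acid_frequencies.tsv.
"""

from pathlib import Path

from mitocompare.codon_tools import (amino_acid_frequencies, count_codons,
                                     rscu, top_codons)
from mitocompare.synthetic_data import SimulationSpec, simulate_genome

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

genome, report = simulate_genome(SimulationSpec(seed=SEED))
counts = count_codons(genome)
table = rscu(counts)
table.to_csv(OUT / "rscu.tsv", sep="\t")
freqs = amino_acid_frequencies(counts)
freqs.to_csv(OUT / "amino_acid_frequencies.tsv", sep="\t")

print(f"synthetic genome (seed {SEED}): {report['genome_length']} bp, "
      f"realized A+T {100 * report['realized_at_content']:.1f}%")
print(f"  total codons over 13 PCGs: {counts.total_codons}")
print(f"  top-3 amino acids: "
      f"{', '.join(freqs.index[:3])} "
      f"({', '.join(f'{v:.3f}' for v in freqs.iloc[:3])})")
print(f"  top-3 codons by RSCU:  {' '.join(top_codons(counts, 3, 'rscu'))}")
print(f"  top-3 codons by count: {' '.join(top_codons(counts, 3, 'count'))}")
print("  note: with iid codon draws the AT-rich codons dominate, as they "
      "do in the real genome; the specific top codons depend on the draw")
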