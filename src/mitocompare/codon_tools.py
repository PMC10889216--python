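"""Codon extraction, counting, amino-acid frequencies, and RSCU under the
invertebrate mitochondrial genetic code (NCBI translation table 5).

Table 5 reassigns AGA/AGG to Ser, ATA to Met, and TGA to Trp relative to the
standard code; its only stop codons are TAA and TAG.  Mitochondrial PCGs may
end in an incomplete stop (T or TA) that is completed to TAA by
polyadenylation; incomplete stops are dropped before counting, as are full
stops, so codon counts contain sense codons only.  Start codons are counted
as ordinary codons.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .genome_model import (MitoGenome, PCG_NAMES, ValidationError,
                           extract_gene_sequence)

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
GENETIC_CODE: dict[str, str] = dict(_TABLE5.forward_table)  # sense codons
STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

# synonymous families: amino acid -> codons, stop codons excluded
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(GENETIC_CODE[_codon], ())
    FAMILIES[GENETIC_CODE[_codon]] += (_codon,)


def translate(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValidationError(f"not an unambiguous codon: {codon!r}") from None


def extract_codons(gene_seq: str, start_codon: str, stop_codon: str,
                   gene: str = "?") -> list[str]:
    """Split a coding-strand PCG sequence into complete sense codons.

    The declared start codon must match the first triplet; the trailing stop
    (full TAA/TAG or incomplete TA/T) is dropped.  Internal in-frame stops
    are tolerated with a warning, as draft annotations contain them.
    """
    seq = gene_seq.upper()
    stop_codon = stop_codon.upper()
    if len(seq) % 3 != len(stop_codon) % 3:
        raise ValidationError(
            f"{gene}: length {len(seq)} inconsistent with stop "
            f"{stop_codon!r}")
    if not seq.endswith(stop_codon):
        raise ValidationError(
            f"{gene}: sequence does not end with declared stop "
            f"{stop_codon!r}")
    body = seq[:len(seq) - len(stop_codon)]
    if body[:3] != start_codon.upper():
        raise ValidationError(
            f"{gene}: first codon {body[:3]!r} is not the declared start "
            f"{start_codon!r}")
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    internal_stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if internal_stops:
        warnings.warn(f"{gene}: {len(internal_stops)} internal in-frame "
                      f"stop codon(s) at codon index {internal_stops}")
    return codons


@dataclass
class CodonCountTable:
    counts: Counter = field(default_factory=Counter)
    genetic_code_id: int = 5

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def per_amino_acid(self) -> Counter:
        totals: Counter = Counter()
        for codon, n in self.counts.items():
            totals[translate(codon)] += n
        return totals


def count_codons(genome: MitoGenome) -> CodonCountTable:
    """Pooled codon counts over the 13 PCGs, each read on its coding strand."""
    missing = [g for g in PCG_NAMES
               if g not in {f.name for f in genome.features}]
    if missing:
        raise ValidationError(f"{genome.id}: missing PCGs {missing}")
    table = CodonCountTable()
    for name in PCG_NAMES:
        f = genome.feature(name)
        codons = extract_codons(extract_gene_sequence(genome, name),
                                f.start_codon, f.stop_codon, gene=name)
        table.counts.update(c for c in codons if c not in STOP_CODONS)
    return table


def count_codon_list(codons) -> CodonCountTable:
    """Counts from an explicit codon list (stop codons excluded)."""
    table = CodonCountTable()
    table.counts.update(c.upper() for c in codons
                        if c.upper() not in STOP_CODONS)
    return table


def rscu(table: CodonCountTable) -> pd.DataFrame:
    """Relative synonymous codon usage.

    RSCU(c) = k * count(c) / sum of counts in c's synonymous family, where k
    is the family size; unobserved families yield null values with a warning.
    Within every observed family the mean RSCU is exactly 1.
    """
    rows = []
    for aa, codons in sorted(FAMILIES.items()):
        family_total = sum(table.counts.get(c, 0) for c in codons)
        if family_total == 0:
            warnings.warn(f"amino acid {aa}: family unobserved, RSCU null")
        for c in codons:
            n = table.counts.get(c, 0)
            value = (len(codons) * n / family_total) if family_total else None
            rows.append({"codon": c, "amino_acid": aa, "family_size":
                         len(codons), "count": n, "rscu": value})
    return pd.DataFrame(rows).set_index("codon")


def amino_acid_frequencies(table: CodonCountTable) -> pd.Series:
    """Per-amino-acid usage fractions (sum to 1)."""
    totals = table.per_amino_acid()
    grand = sum(totals.values())
    if grand == 0:
        raise ValidationError("empty codon counts")
    return (pd.Series(dict(totals), name="fraction")
            .sort_values(ascending=False) / grand)


def top_codons(table: CodonCountTable, k: int = 3,
               by: str = "rscu") -> list[str]:
    """Top-k codons by RSCU or by raw count (RNA alphabet, as usually
    plotted)."""
    df = rscu(table)
    df = df.sort_values([by, "count"], ascending=False)
    return [c.replace("T", "U") for c in df.index[:k]]
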