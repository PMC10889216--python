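"""Pairwise Ka/Ks estimation by the Nei-Gojobori (1986) counting method
under the invertebrate mitochondrial code, with Jukes-Cantor correction.

For each codon the number of synonymous sites is the expected fraction of
single-nucleotide changes that preserve the amino acid, summed over the
three positions; changes that would create a stop codon are excluded from
the denominator, so n + s = 3 exactly for every sense codon.  Differences
between a pair of codons are resolved by averaging the synonymous /
nonsynonymous step counts over all minimal mutational pathways with equal
weights, excluding pathways that pass through a stop codon.  Proportions
pN = Nd/N and pS = Sd/S are corrected with the Jukes-Cantor formula
K = -3/4 ln(1 - 4p/3).

Ka/Ks > 1 indicates positive selection, = 1 neutral evolution, and < 1
purifying selection; a tolerance band |ratio - 1| <= 0.05 is reported as
neutral since exact equality never occurs in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from .codon_tools import GENETIC_CODE, STOP_CODONS, translate
from .genome_model import SpeciesPanel, ValidationError

_BASES = "ACGT"
NEUTRAL_BAND = 0.05


class SaturationError(ValueError):
    """A difference proportion exceeds the Jukes-Cantor domain (p >= 3/4)."""


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one sense codon."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValidationError(f"stop codon {codon!r} has no site counts")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return 3.0 - s, s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) between two sense codons, averaged with equal weights over
    all orderings of the differing positions; orderings that pass through a
    stop codon are excluded (if every ordering does, all are kept)."""
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise ValidationError(f"stop codon {c!r} in pathway counting")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur, nd, sd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if ok else blocked).append((nd, sd))
    paths = valid or blocked
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: JC saturated")
    return 0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def classify(ratio: float | None) -> str:
    if ratio is None:
        return "NA"
    if abs(ratio - 1.0) <= NEUTRAL_BAND:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


@dataclass
class KaKsEstimate:
    gene: str
    query: str
    reference: str
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float

    @property
    def ratio(self) -> float | None:
        return None if self.Ks == 0 else self.Ka / self.Ks

    @property
    def classification(self) -> str:
        if self.Ka == self.Ks == 0:
            return "NA"
        return classify(self.ratio)


def _codons(seq) -> list[str]:
    if isinstance(seq, str):
        if len(seq) % 3:
            raise ValidationError("sequence length not a multiple of 3")
        return [seq[i:i + 3].upper() for i in range(0, len(seq), 3)]
    return [c.upper() for c in seq]


def _comparable(c: str) -> bool:
    return c in GENETIC_CODE  # sense, unambiguous, ungapped


def ng86_pair(seq1, seq2, gene: str = "?", query: str = "query",
              reference: str = "reference") -> KaKsEstimate:
    """NG86 estimate for an aligned codon-sequence pair.

    Codons containing gaps or ambiguity codes, and stop codons, are dropped
    pairwise (codon-wise deletion).
    """
    cod1, cod2 = _codons(seq1), _codons(seq2)
    if len(cod1) != len(cod2):
        raise ValidationError("aligned sequences differ in codon count")
    pairs = [(a, b) for a, b in zip(cod1, cod2)
             if _comparable(a) and _comparable(b)]
    if not pairs:
        raise ValidationError("zero comparable codons")
    n1 = sum(ng86_sites(a)[0] for a, _ in pairs)
    s1 = sum(ng86_sites(a)[1] for a, _ in pairs)
    n2 = sum(ng86_sites(b)[0] for _, b in pairs)
    s2 = sum(ng86_sites(b)[1] for _, b in pairs)
    N, S = (n1 + n2) / 2.0, (s1 + s2) / 2.0
    nd = sd = 0.0
    for a, b in pairs:
        dn, ds = pathway_differences(a, b)
        nd += dn
        sd += ds
    pN, pS = nd / N, sd / S if S else 0.0
    ka, ks = jukes_cantor(pN), jukes_cantor(pS)
    return KaKsEstimate(gene=gene, query=query, reference=reference,
                        n_codons=len(pairs), N=N, S=S, Nd=nd, Sd=sd,
                        pN=pN, pS=pS, Ka=ka, Ks=ks)


def codon_align_pair(codon_seq1: str, codon_seq2: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: align the translated amino-acid
    sequences globally, then back-thread the codons through the alignment.
    Stop codons translate to '*' and align like ordinary residues."""
    from .phylo_lite import align_pair

    def _translate(seq):
        return "".join(translate(c) if c in GENETIC_CODE or c in STOP_CODONS
                       else "X" for c in _codons(seq))

    aa1, aa2 = _translate(codon_seq1), _translate(codon_seq2)
    aln1, aln2, _ = align_pair(aa1, aa2)
    out1, out2 = [], []
    i = j = 0
    for x, y in zip(aln1, aln2):
        out1.append("---" if x == "-" else codon_seq1[3 * i:3 * i + 3])
        out2.append("---" if y == "-" else codon_seq2[3 * j:3 * j + 3])
        i += x != "-"
        j += y != "-"
    return "".join(out1), "".join(out2)


@dataclass
class GenusSelectionSummary:
    per_species: pd.DataFrame   # gene, species, genus, Ka, Ks, ratio, class
    per_genus: pd.DataFrame     # genus x gene mean ratios
    overall: pd.Series          # per-gene mean across genera, descending


def genus_summary(panel: SpeciesPanel, alignments: dict[str, dict[str, str]],
                  align: bool = False) -> GenusSelectionSummary:
    """Score every ingroup species' PCGs against the panel's reference
    (outgroup) sequence, then average ratios within genus and across genera.

    ``alignments`` maps gene -> taxon id -> codon sequence; sequences are
    assumed columnar unless ``align`` is set, in which case each pair is
    codon-aligned against the reference first.
    """
    if panel.outgroup_id is None:
        raise ValidationError("panel has no reference/outgroup id")
    ref = panel.outgroup_id
    rows = []
    for gene, seqs in sorted(alignments.items()):
        if ref not in seqs:
            raise ValidationError(f"{gene}: reference {ref} missing")
        for genome in panel.ingroup:
            if genome.id not in seqs:
                import warnings
                warnings.warn(f"{gene}: no sequence for {genome.id}, skipped")
                continue
            a, b = seqs[ref], seqs[genome.id]
            if align:
                a, b = codon_align_pair(a, b)
            est = ng86_pair(a, b, gene=gene, query=genome.id, reference=ref)
            rows.append({"gene": gene, "species": genome.taxon or genome.id,
                         "genus": genome.genus or genome.id,
                         "Ka": est.Ka, "Ks": est.Ks, "ratio": est.ratio,
                         "class": est.classification})
    per_species = pd.DataFrame(rows)
    defined = per_species.dropna(subset=["ratio"])
    per_genus = defined.pivot_table(index="genus", columns="gene",
                                    values="ratio", aggfunc="mean")
    overall = per_genus.mean(axis=0).sort_values(ascending=False)
    overall.name = "mean_ratio"
    return GenusSelectionSummary(per_species=per_species,
                                 per_genus=per_genus, overall=overall)
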