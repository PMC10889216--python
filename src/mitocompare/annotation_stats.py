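"""Per-genome composition, strand-skew, and gene-junction statistics.

Skews follow the standard strand-asymmetry formulas

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the major strand for whole-genome reports and on the coding
strand for per-gene reports.  Junctions between consecutive features are
scored as intergenic nucleotides:

    inc = start(next) - end(prev) - 1

positive = spacer, negative = overlap, zero = abutting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genome_model import (MitoGenome, ValidationError,
                           extract_gene_sequence)


@dataclass
class CompositionStats:
    a: float
    c: float
    g: float
    t: float
    other: float = 0.0

    @property
    def total(self) -> float:
        return self.a + self.c + self.g + self.t + self.other

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / (self.a + self.c + self.g + self.t)

    @property
    def at_skew(self) -> float | None:
        """(A - T)/(A + T); None when the genome has no A or T at all."""
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float | None:
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)

    def rounded(self) -> dict:
        """Report-precision view: percentages to 1 dp, skews to 3 dp."""
        def r3(x):
            return None if x is None else round(x, 3)
        return {
            "at_pct": round(100 * self.at_content, 1),
            "at_skew": r3(self.at_skew),
            "gc_skew": r3(self.gc_skew),
        }


def composition(seq_or_proportions) -> CompositionStats:
    """Composition and skews from a sequence, or from four proportions
    (mapping with keys A/C/G/T, e.g. printed percentages / 100)."""
    if isinstance(seq_or_proportions, dict):
        p = {k.upper(): float(v) for k, v in seq_or_proportions.items()}
        total = sum(p.get(b, 0.0) for b in "ACGT")
        if abs(total - 1.0) > 0.005:
            raise ValidationError(
                f"proportions sum to {total:.4f}, not 1 within 0.5%")
        stats = CompositionStats(p["A"], p["C"], p["G"], p["T"])
    else:
        seq = str(seq_or_proportions).upper()
        if not seq:
            raise ValidationError("empty sequence")
        counts = {b: seq.count(b) for b in "ACGT"}
        other = len(seq) - sum(counts.values())
        stats = CompositionStats(counts["A"], counts["C"], counts["G"],
                                 counts["T"], other=other)
    if stats.at_skew is None or stats.gc_skew is None:
        warnings.warn("degenerate composition: a skew is undefined")
    return stats


def per_gene_stats(genome: MitoGenome) -> pd.DataFrame:
    """One row per feature, computed on each gene's coding strand."""
    if genome.sequence is None:
        raise ValidationError(
            f"{genome.id}: per-gene stats need a sequence; use the "
            "junction/summary reports for sequence-free tables")
    rows = []
    for f in sorted(genome.features, key=lambda x: x.start):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = composition(extract_gene_sequence(genome, f.name))
        rows.append({"gene": f.name, "class": f.gene_class,
                     "strand": f.strand,
                     "length": f.length(genome.length),
                     **stats.rounded()})
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class Junction:
    upstream: str
    downstream: str
    inc: int

    @property
    def kind(self) -> str:
        return "spacer" if self.inc > 0 else (
            "overlap" if self.inc < 0 else "abutting")


@dataclass
class JunctionReport:
    junctions: list[Junction] = field(default_factory=list)

    def _of_kind(self, kind):
        return [j for j in self.junctions if j.kind == kind]

    @property
    def n_spacers(self) -> int:
        return len(self._of_kind("spacer"))

    @property
    def n_overlaps(self) -> int:
        return len(self._of_kind("overlap"))

    @property
    def total_spacer_bp(self) -> int:
        return sum(j.inc for j in self._of_kind("spacer"))

    @property
    def total_overlap_bp(self) -> int:
        return sum(-j.inc for j in self._of_kind("overlap"))

    @property
    def longest_spacer(self) -> Junction | None:
        spacers = self._of_kind("spacer")
        return max(spacers, key=lambda j: j.inc) if spacers else None

    @property
    def longest_overlap(self) -> Junction | None:
        overlaps = self._of_kind("overlap")
        return min(overlaps, key=lambda j: j.inc) if overlaps else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"upstream": j.upstream, "downstream": j.downstream,
              "inc": j.inc, "kind": j.kind} for j in self.junctions])


def junction_report(genome: MitoGenome, circular: bool = True
                    ) -> JunctionReport:
    """Intergenic/overlap accounting between consecutive features.

    In circular mode one extra wrap junction (last feature back to the
    first) is scored using the genome length.  max() in longest_spacer
    (min() in longest_overlap) keeps the first of tied candidates, so
    ties break deterministically in coordinate order.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    if len(feats) < 2:
        raise ValidationError(f"{genome.id}: need >= 2 features")
    spans = {(f.start, f.end) for f in feats}
    if len(spans) != len(feats):
        raise ValidationError(f"{genome.id}: duplicate feature span")
    report = JunctionReport()
    for prev, nxt in zip(feats, feats[1:]):
        report.junctions.append(
            Junction(prev.name, nxt.name, nxt.start - prev.end - 1))
    if circular:
        last, first = feats[-1], feats[0]
        wrap_inc = (genome.length - last.end) + (first.start - 1)
        report.junctions.append(Junction(last.name, first.name, wrap_inc))
    return report


def inc_column_summary(inc_values) -> dict:
    """Summarise an INC column taken as data (e.g. a published annotation
    table): counts and summed lengths of spacers and overlaps."""
    inc = list(inc_values)
    return {
        "n_spacers": sum(1 for v in inc if v > 0),
        "n_overlaps": sum(1 for v in inc if v < 0),
        "n_abutting": sum(1 for v in inc if v == 0),
        "total_spacer_bp": sum(v for v in inc if v > 0),
        "total_overlap_bp": sum(-v for v in inc if v < 0),
    }


def genome_summary(genome: MitoGenome) -> dict:
    """Totals by gene class, strand tallies, and per-class length extremes."""
    length = genome.length
    summary: dict = {"id": genome.id, "genome_length": length,
                     "n_features": len(genome.features)}
    for cls in ("PCG", "tRNA", "rRNA"):
        feats = [f for f in genome.features if f.gene_class == cls]
        if not feats:
            continue
        lens = {f.name: f.length(length) for f in feats}
        total = sum(lens.values())
        lo = min(lens, key=lambda k: (lens[k], k))
        hi = max(lens, key=lambda k: (lens[k], k))
        summary[cls] = {
            "count": len(feats),
            "total_bp": total,
            "fraction_of_genome": total / length,
            "shortest": (lo, lens[lo]),
            "longest": (hi, lens[hi]),
        }
    summary["major_strand_genes"] = sum(
        1 for f in genome.features if f.strand == "+")
    summary["minor_strand_genes"] = sum(
        1 for f in genome.features if f.strand == "-")
    if genome.sequence is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary["whole_genome"] = composition(genome.sequence).rounded()
    return summary
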