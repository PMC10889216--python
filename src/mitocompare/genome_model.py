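"""Core data model for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout, the dialect used by GenBank
feature tables and by the annotation tables this package consumes.  The
conversion to 0-based half-open slices happens only inside sequence
extraction.  A mitogenome is circular: a feature may wrap the origin, in
which case ``end < start`` and ``wraps_origin`` is set.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq


class ParseError(ValueError):
    """A file could not be parsed into the data model."""


class ValidationError(ValueError):
    """Parsed data violates an invariant of the data model."""


# the 37 canonical gene names of a complete molluscan mitogenome
PCG_NAMES = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNA_NAMES = ("rrnS", "rrnL")
TRNA_NAMES = tuple(
    "trn" + aa for aa in
    ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2", "M",
     "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
CANONICAL_GENES = PCG_NAMES + RRNA_NAMES + TRNA_NAMES

VALID_STOPS = ("TAA", "TAG", "TA", "T")

# anticodons (either reading convention) that resolve the duplicated
# leucine/serine tRNA isotypes
_ISOTYPE_BY_ANTICODON = {
    "trnL": {"CTA": "trnL1", "TAG": "trnL1", "TTA": "trnL2", "TAA": "trnL2"},
    "trnS": {"AGC": "trnS1", "GCT": "trnS1", "TCA": "trnS2", "TGA": "trnS2"},
}


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    data = importlib.resources.files("mitocompare").joinpath(
        "data/gene_synonyms.tsv").read_text()
    for line in data.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        synonym, canonical = line.split("\t")
        table[synonym.strip().lower()] = canonical.strip()
    for name in CANONICAL_GENES:  # canonical names map to themselves
        table.setdefault(name.lower(), name)
    return table


_SYNONYMS: dict[str, str] | None = None


def canonical_name(raw: str, anticodon: str | None = None) -> str | None:
    """Map a raw gene label onto the 37-name vocabulary.

    Case-insensitive and idempotent.  ``trnL``/``trnS`` without an isotype
    number are resolved by ``anticodon`` when one is given; otherwise the
    ambiguous base name is returned unresolved.  Returns ``None`` for labels
    absent from the synonym table.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    name = _SYNONYMS.get(raw.strip().lower())
    if name in ("trnL", "trnS") and anticodon:
        name = _ISOTYPE_BY_ANTICODON[name].get(anticodon.upper(), name)
    return name


@dataclass
class GeneFeature:
    """One annotated gene on the major strand coordinate system."""

    name: str
    start: int
    end: int
    strand: str           # '+' major (J) strand, '-' minor (N) strand
    gene_class: str       # 'PCG' | 'tRNA' | 'rRNA'
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    wraps_origin: bool = False
    mapped: bool = True   # False for features kept under a raw, unmapped name

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValidationError(
                    f"{self.name}: wrapping feature needs a genome length")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def validate(self, genome_length: int | None = None) -> None:
        if self.mapped and self.name not in CANONICAL_GENES:
            raise ValidationError(f"unknown gene name {self.name!r}")
        if self.strand not in "+-":
            raise ValidationError(f"{self.name}: bad strand {self.strand!r}")
        if self.gene_class not in ("PCG", "tRNA", "rRNA"):
            raise ValidationError(
                f"{self.name}: bad gene class {self.gene_class!r}")
        if not self.wraps_origin and self.end < self.start:
            raise ValidationError(
                f"{self.name}: end < start without wraps_origin")
        n = self.length(genome_length) if (
            genome_length or not self.wraps_origin) else None
        if n is not None and n <= 0:
            raise ValidationError(f"{self.name}: non-positive length")
        if self.gene_class == "tRNA" and n is not None and n < 50:
            raise ValidationError(f"{self.name}: tRNA shorter than 50 bp")
        if self.gene_class == "PCG":
            if not self.start_codon or not self.stop_codon:
                raise ValidationError(
                    f"{self.name}: PCG needs start and stop codons")
            if self.stop_codon not in VALID_STOPS:
                raise ValidationError(
                    f"{self.name}: stop codon {self.stop_codon!r} "
                    f"not in {VALID_STOPS}")
            if n is not None:
                # an incomplete stop leaves a 1- or 2-base remainder that is
                # completed by polyadenylation of the transcript
                if n % 3 != len(self.stop_codon) % 3:
                    raise ValidationError(
                        f"{self.name}: length {n} inconsistent with stop "
                        f"codon {self.stop_codon!r}")
        elif self.gene_class == "tRNA":
            if self.mapped and not self.anticodon:
                raise ValidationError(f"{self.name}: tRNA needs an anticodon")
        else:
            if self.start_codon or self.stop_codon or self.anticodon:
                raise ValidationError(
                    f"{self.name}: rRNA carries no codon/anticodon fields")


@dataclass
class MitoGenome:
    """A circular mitogenome: optional major-strand sequence plus features."""

    id: str
    taxon: str = ""
    genus: str = ""
    sequence: str | None = None
    declared_length: int | None = None
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Genome length: the sequence if present, else the declared length,
        else the maximum feature end."""
        if self.sequence is not None:
            return len(self.sequence)
        if self.declared_length is not None:
            return self.declared_length
        if not self.features:
            raise ValidationError(f"{self.id}: length is undetermined")
        return max(f.end for f in self.features)

    @property
    def is_complete(self) -> bool:
        names = {f.name for f in self.features if f.mapped}
        return names == set(CANONICAL_GENES)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.id}: no gene {name!r}")

    def validate(self) -> None:
        length = self.length
        seen: set[str] = set()
        for f in self.features:
            f.validate(length)
            if f.mapped:
                if f.name in seen:
                    raise ValidationError(
                        f"{self.id}: duplicate gene {f.name!r}")
                seen.add(f.name)
            if self.sequence is not None:
                if not (1 <= f.start <= length and 1 <= f.end <= length):
                    raise ValidationError(
                        f"{self.id}/{f.name}: coordinates outside sequence")
        if not self.is_complete:
            warnings.warn(f"{self.id}: incomplete genome "
                          f"({len(seen)}/37 canonical genes)")

    def gene_order(self):
        """Signed circular gene order, by coordinate."""
        from .rearrangement import GeneOrder  # local import: no cycle at load
        feats = sorted(self.features, key=lambda f: f.start)
        return GeneOrder(
            genome_id=self.id,
            tokens=[(f.name, f.strand) for f in feats if f.mapped],
        )


@dataclass
class SpeciesPanel:
    genomes: list[MitoGenome]
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate genome ids in panel")
        if self.outgroup_id is not None and self.outgroup_id not in ids:
            raise ValidationError(
                f"outgroup {self.outgroup_id!r} not in panel")

    def genome(self, gid: str) -> MitoGenome:
        for g in self.genomes:
            if g.id == gid:
                return g
        raise KeyError(gid)

    @property
    def ingroup(self) -> list[MitoGenome]:
        return [g for g in self.genomes if g.id != self.outgroup_id]


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene_sequence(genome: MitoGenome, name: str) -> str:
    """Coding-strand sequence of a gene: the major-strand slice for '+'
    features, its reverse complement for '-'.  Wrapping features are read
    across the origin."""
    if genome.sequence is None:
        raise ValidationError(f"{genome.id}: genome has no sequence")
    f = genome.feature(name)
    seq = genome.sequence
    if f.wraps_origin:
        major = seq[f.start - 1:] + seq[:f.end]
    else:
        major = seq[f.start - 1:f.end]
    return reverse_complement(major) if f.strand == "-" else major


# ----------------------------------------------------------------- file I/O

_TABLE_COLUMNS = ("gene", "start", "end", "strand", "class",
                  "start_codon", "stop_codon", "anticodon", "wraps")
_EMPTY = "."


def read_feature_table(path) -> MitoGenome:
    """Read a tab-separated feature table (header row required).

    Lines starting with ``#key=value`` carry genome metadata (id, taxon,
    genus, length).
    """
    meta = {"id": "unknown"}
    features: list[GeneFeature] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = set(_TABLE_COLUMNS[:5]) - set(header)
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, cells))
            try:
                start, end = int(row["start"]), int(row["end"])
            except (KeyError, ValueError):
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates") from None

            def cell(key):
                v = row.get(key, _EMPTY).strip()
                return None if v in (_EMPTY, "") else v

            feat = GeneFeature(
                name=row["gene"].strip(),
                start=start, end=end,
                strand=row["strand"].strip(),
                gene_class=row["class"].strip(),
                start_codon=cell("start_codon"),
                stop_codon=cell("stop_codon"),
                anticodon=cell("anticodon"),
                wraps_origin=cell("wraps") == "yes",
            )
            if feat.mapped and feat.name not in CANONICAL_GENES:
                feat.mapped = canonical_name(feat.name) is not None
                if feat.mapped:
                    feat.name = canonical_name(feat.name, feat.anticodon)
            features.append(feat)
    if not features:
        raise ParseError(f"{path}: no features")
    genome = MitoGenome(
        id=meta.get("id", "unknown"),
        taxon=meta.get("taxon", ""),
        genus=meta.get("genus", ""),
        declared_length=int(meta["length"]) if "length" in meta else None,
        features=sorted(features, key=lambda f: f.start),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genome.validate()
    return genome


def write_feature_table(genome: MitoGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#id={genome.id}\n")
        if genome.taxon:
            fh.write(f"#taxon={genome.taxon}\n")
        if genome.genus:
            fh.write(f"#genus={genome.genus}\n")
        if genome.declared_length is not None:
            fh.write(f"#length={genome.declared_length}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write("\t".join([
                f.name, str(f.start), str(f.end), f.strand, f.gene_class,
                f.start_codon or _EMPTY, f.stop_codon or _EMPTY,
                f.anticodon or _EMPTY, "yes" if f.wraps_origin else _EMPTY,
            ]) + "\n")


_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path) -> MitoGenome:
    """Read an annotated GenBank flat file, mapping gene labels onto the
    canonical vocabulary.  Unmapped features are retained (``mapped=False``)
    with a warning rather than dropped."""
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # biopython raises plain ValueError subclasses
        raise ParseError(f"{path}: not a readable GenBank record "
                         f"({exc})") from exc
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in _GENBANK_CLASS:
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or ["?"])[0]
        anticodon = None
        if "anticodon" in quals:
            ac = quals["anticodon"][0]
            anticodon = ac.split("seq:")[-1].strip("()").upper() \
                if "seq:" in ac else ac.strip("()").upper()
        name = canonical_name(raw, anticodon)
        parts = feat.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        wraps = len(parts) > 1 and end < start
        gf = GeneFeature(
            name=name or raw,
            start=start, end=end,
            strand="-" if feat.location.strand == -1 else "+",
            gene_class=_GENBANK_CLASS[feat.type],
            anticodon=anticodon if feat.type == "tRNA" else None,
            wraps_origin=wraps,
            mapped=name is not None and name in CANONICAL_GENES,
        )
        if gf.gene_class == "PCG":
            seq = str(feat.extract(record.seq)).upper()
            gf.start_codon = seq[:3]
            rem = len(seq) % 3
            gf.stop_codon = seq[-3:] if rem == 0 else seq[-rem:]
        if not gf.mapped:
            warnings.warn(f"{record.id}: unmapped or ambiguous gene label "
                          f"{raw!r} retained as-is")
        elif gf.name in seen:
            raise ValidationError(
                f"{record.id}: duplicate canonical gene {gf.name!r}")
        else:
            seen.add(gf.name)
        features.append(gf)
    genome = MitoGenome(
        id=record.id or record.name,
        taxon=record.annotations.get("organism", ""),
        genus=record.annotations.get("organism", "").split(" ")[0],
        sequence=str(record.seq).upper() if len(record.seq) else None,
        features=sorted(features, key=lambda f: f.start),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genome.validate()
    return genome


def write_gene_fasta(genome: MitoGenome, path) -> None:
    """Per-gene FASTA export of coding-strand sequences."""
    with open(path, "w") as fh:
        for f in sorted(genome.features, key=lambda x: x.start):
            seq = extract_gene_sequence(genome, f.name)
            fh.write(f">{genome.id}|{f.name}\n{seq}\n")
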