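"""Circular signed gene-order analysis: canonical normalization, detection
of single-gene transposition / reverse-transposition events, and clustering
of genomes into arrangement types.

A gene order is a circular signed permutation of gene names; orientation
'+' means the major strand.  Normalization rotates the circle so cox1 comes
first and, if cox1 reads '-', reflects the whole order and flips every sign
so cox1 reads '+'.  Two genomes share an arrangement type iff their
normalized orders are identical.

Event detection finds the smallest set of genes whose removal from both
circular orders leaves identical signed sequences; each removed gene is one
event, a reverse transposition when its orientation differs between the two
orders and a transposition otherwise.  Blocks that moved together are
reported as per-gene events.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations

from .genome_model import ValidationError

Token = tuple[str, str]  # (gene name, '+' | '-')


class ComplexRearrangementError(ValueError):
    """No explanation with at most `max_events` moved genes exists."""


@dataclass(frozen=True)
class GeneOrder:
    genome_id: str
    tokens: tuple[Token, ...]

    def __init__(self, genome_id: str, tokens) -> None:
        object.__setattr__(self, "genome_id", genome_id)
        object.__setattr__(self, "tokens",
                           tuple((str(g), str(s)) for g, s in tokens))
        names = [g for g, _ in self.tokens]
        if len(set(names)) != len(names):
            raise ValidationError(f"{genome_id}: duplicate gene tokens")
        for _, s in self.tokens:
            if s not in "+-":
                raise ValidationError(f"{genome_id}: bad orientation {s!r}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.tokens)

    def signs(self) -> dict[str, str]:
        return dict(self.tokens)

    def __str__(self) -> str:
        return " ".join(f"{s}{g}" for g, s in self.tokens)


def parse_order_line(line: str) -> GeneOrder:
    """Parse ``id +gene -gene ...`` (one genome per line)."""
    parts = line.split()
    if len(parts) < 2:
        raise ValidationError(f"order line too short: {line!r}")
    tokens = []
    for tok in parts[1:]:
        if tok[0] not in "+-":
            raise ValidationError(f"token {tok!r} lacks an orientation sign")
        tokens.append((tok[1:], tok[0]))
    return GeneOrder(genome_id=parts[0], tokens=tokens)


def read_orders(path_or_text) -> list[GeneOrder]:
    text = (path_or_text if "\n" in str(path_or_text) or
            str(path_or_text).lstrip().startswith("#")
            else open(path_or_text).read())
    orders = []
    for line in str(text).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            orders.append(parse_order_line(line))
    return orders


def load_planorbid_orders() -> list[GeneOrder]:
    """The 15 packaged planorbid gene orders (see data file for provenance)."""
    text = importlib.resources.files("mitocompare").joinpath(
        "data/planorbid_gene_orders.txt").read_text()
    return read_orders(text)


def normalize(order: GeneOrder) -> GeneOrder:
    """Canonical linearization: rotate to cox1; reflect and flip signs if
    cox1 reads '-'.  Pure and idempotent."""
    names = [g for g, _ in order.tokens]
    if "cox1" not in names:
        raise ValidationError(f"{order.genome_id}: cox1 absent, cannot "
                              "normalize")
    i = names.index("cox1")
    rotated = order.tokens[i:] + order.tokens[:i]
    if rotated[0][1] == "-":
        flipped = [(g, "+" if s == "-" else "-") for g, s in rotated]
        rotated = tuple([flipped[0]] + flipped[:0:-1])
    return GeneOrder(order.genome_id, rotated)


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str          # 'transposition' | 'reverse_transposition'
    gene: str
    source_junction: tuple[str, str]   # (left, right) neighbors in reference
    dest_junction: tuple[str, str]     # (left, right) neighbors in query


def _neighbors(tokens: tuple[Token, ...], gene: str) -> tuple[str, str]:
    names = [g for g, _ in tokens]
    i = names.index(gene)
    return names[i - 1], names[(i + 1) % len(names)]


def _signed_triples(tokens: tuple[Token, ...]) -> dict[str, tuple]:
    n = len(tokens)
    out = {}
    for i, (g, s) in enumerate(tokens):
        out[g] = (tokens[i - 1], s, tokens[(i + 1) % n])
    return out


def _delete(tokens: tuple[Token, ...], subset: frozenset[str]
            ) -> tuple[Token, ...]:
    return tuple(t for t in tokens if t[0] not in subset)


def _rotate_to(tokens: tuple[Token, ...], gene: str) -> tuple[Token, ...]:
    names = [g for g, _ in tokens]
    i = names.index(gene)
    return tokens[i:] + tokens[:i]


def gene_class_of(gene: str) -> str:
    if gene.startswith("trn"):
        return "tRNA"
    if gene.startswith("rrn"):
        return "rRNA"
    return "PCG"


def candidate_rank(gene: str) -> tuple[int, str]:
    """Subset-search ordering: tRNAs first, then rRNAs, then PCGs."""
    return ({"tRNA": 0, "rRNA": 1, "PCG": 2}[gene_class_of(gene)], gene)


def detect_events(reference: GeneOrder, query: GeneOrder,
                  max_events: int = 12) -> list[RearrangementEvent]:
    """Minimum-cardinality single-gene rearrangement events turning the
    reference circular order into the query's.

    Candidates are genes whose signed neighbourhood differs between the
    normalized orders; genes whose own orientation differs must move.  The
    search is exhaustive over candidate subsets, smallest first, ties broken
    by (gene class, gene name) — see ``candidate_rank``.
    """
    if reference.genes != query.genes:
        raise ValidationError(
            f"gene sets differ: {sorted(reference.genes ^ query.genes)}")
    ref, qry = normalize(reference), normalize(query)
    if ref.tokens == qry.tokens:
        return []
    triples_r, triples_q = _signed_triples(ref.tokens), _signed_triples(
        qry.tokens)
    signs_r, signs_q = ref.signs(), qry.signs()
    forced = sorted(g for g in signs_r
                    if g != "cox1" and signs_r[g] != signs_q[g])
    # Equal-size explanations are tie-broken by class first (tRNA, then
    # rRNA, then PCG), then gene name: single-gene moves in mitogenomes are
    # overwhelmingly tRNA events, so an explanation that relocates a protein
    # gene must not shadow an equally parsimonious tRNA-only one.
    candidates = sorted((g for g in triples_r
                         if g != "cox1" and triples_r[g] != triples_q[g]),
                        key=candidate_rank)
    optional = [g for g in candidates if g not in forced]

    def explains(subset: frozenset[str]) -> bool:
        a, b = _delete(ref.tokens, subset), _delete(qry.tokens, subset)
        return _rotate_to(a, "cox1") == _rotate_to(b, "cox1")

    chosen: frozenset[str] | None = None
    for k in range(len(forced), min(max_events, len(candidates)) + 1):
        for extra in combinations(optional, k - len(forced)):
            subset = frozenset(forced) | frozenset(extra)
            if explains(subset):
                chosen = subset
                break
        if chosen is not None:
            break
    if chosen is None:
        raise ComplexRearrangementError(
            f"{reference.genome_id} vs {query.genome_id}: no explanation "
            f"with <= {max_events} moved genes")
    events = []
    for g in sorted(chosen):
        kind = ("reverse_transposition" if signs_r[g] != signs_q[g]
                else "transposition")
        events.append(RearrangementEvent(
            kind=kind, gene=g,
            source_junction=_neighbors(ref.tokens, g),
            dest_junction=_neighbors(qry.tokens, g)))
    return events


@dataclass
class ArrangementTypeTable:
    types: dict[str, list[str]] = field(default_factory=dict)  # label -> ids
    signatures: dict[str, tuple[Token, ...]] = field(default_factory=dict)
    orders: dict[str, GeneOrder] = field(default_factory=dict)

    def label_of(self, genome_id: str) -> str:
        for label, members in self.types.items():
            if genome_id in members:
                return label
        raise KeyError(genome_id)

    def representative(self, label: str) -> GeneOrder:
        return self.orders[self.types[label][0]]

    @property
    def member_counts(self) -> dict[str, int]:
        return {label: len(ids) for label, ids in self.types.items()}


def cluster_types(orders: list[GeneOrder]) -> ArrangementTypeTable:
    """Group genomes by normalized-order signature; labels A, B, ... are
    assigned in order of first appearance."""
    table = ArrangementTypeTable()
    sig_to_label: dict[tuple, str] = {}
    for order in orders:
        sig = normalize(order).tokens
        if sig not in sig_to_label:
            label = chr(ord("A") + len(sig_to_label))
            sig_to_label[sig] = label
            table.types[label] = []
            table.signatures[label] = sig
        table.types[sig_to_label[sig]].append(order.genome_id)
        table.orders[order.genome_id] = order
    return table


def rearranged_gene_census(table: ArrangementTypeTable,
                           reference_type: str = "A") -> dict[str, set[str]]:
    """Union of genes moved in any arrangement type relative to the
    reference type, partitioned by gene class (tRNA / rRNA / PCG by name)."""
    ref = table.representative(reference_type)
    moved: set[str] = set()
    for label in table.types:
        if label == reference_type:
            continue
        for ev in detect_events(ref, table.representative(label)):
            moved.add(ev.gene)
    out: dict[str, set[str]] = {"tRNA": set(), "rRNA": set(), "PCG": set()}
    for g in moved:
        out[gene_class_of(g)].add(g)
    return out
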