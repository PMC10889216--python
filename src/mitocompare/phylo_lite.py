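"""Desk-scale distance phylogenetics: global pairwise alignment, distance
matrices, neighbor joining, supermatrix assembly, and topology comparison.

This deliberately replaces full Bayesian/ML tree inference with the
Saitou-Nei neighbor-joining algorithm on pairwise distances: fast, exact on
additive matrices, and sufficient for topology-level checks (monophyly,
Robinson-Foulds) on both simulated and fixture data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genome_model import ValidationError


# ------------------------------------------------------------ alignment

def align_pair(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
               gap: float = -2.0) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with linear gap penalty.

    Traceback is deterministic: diagonal preferred, then up (gap in b),
    then left (gap in a).
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap,
                              score[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(
        score[n, m])


# ------------------------------------------------------------ distances

def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among columns without gaps."""
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper())
             if x != "-" and y != "-"]
    if not pairs:
        raise ValidationError("no comparable columns")
    return sum(x != y for x, y in pairs) / len(pairs)


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected nucleotide distance; inf when saturated."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


def poisson_distance(p: float) -> float:
    """Poisson-corrected amino-acid distance; inf when saturated."""
    if p >= 1.0:
        return math.inf
    return -math.log(1 - p)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValidationError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValidationError("diagonal is not zero")

    @property
    def saturated(self) -> bool:
        return bool(np.isinf(self.matrix).any())

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def distance_matrix(seqs: dict[str, str], correction: str = "jc",
                    aligned: bool = True) -> DistanceMatrix:
    """Pairwise distances among sequences (columnar by default; set
    ``aligned=False`` to Needleman-Wunsch-align each pair first).

    correction: 'none' (p-distance), 'jc' (nucleotide), 'poisson'
    (amino acid).
    """
    correct = {"none": lambda p: p, "jc": jc_distance,
               "poisson": poisson_distance}[correction]
    ids = sorted(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[j]]
            if not aligned:
                a, b, _ = align_pair(a, b)
            d[i, j] = d[j, i] = correct(p_distance(a, b))
    return DistanceMatrix(ids=ids, matrix=d)


# ------------------------------------------------------------ trees

@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths, backed by a dendropy Tree."""

    tree: dendropy.Tree
    negative_lengths_clamped: bool = False

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        return cls(tree=t)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-side-agnostic canonical
        frozenset pair (represented by the side not containing the
        alphabetically first leaf)."""
        leaves = self.leaf_names
        anchor = min(leaves)
        splits: set[frozenset[str]] = set()
        t = self.tree.clone(depth=1)
        t.is_rooted = False
        t.update_bipartitions(suppress_unifurcations=True)
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if anchor in side:
                side = leaves - side
            if 1 < len(side) < len(leaves) - 1:
                splits.add(side)
        return splits


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q break deterministically on the lexicographically lowest
    (taxon id, taxon id) pair of cluster representatives.  Negative branch
    lengths are clamped to zero and flagged.
    """
    if len(d.ids) < 3:
        raise ValidationError("need >= 3 taxa")
    if d.saturated:
        raise ValidationError("saturated (infinite) distances present")
    # active clusters: representative id -> (newick subtree, member rep)
    dist = {(a, b): d.value(a, b) for a in d.ids for b in d.ids}
    nodes = {i: f"{_quote(i)}" for i in d.ids}
    active = sorted(d.ids)
    clamped = False

    def dd(a, b):
        return dist[(a, b)] if a != b else 0.0

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dd(a, b) for b in active) for a in active}
        best, best_q = None, None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * dd(a, b) - row_sum[a] - row_sum[b]
                key = tuple(sorted((a, b)))
                if best_q is None or q < best_q - 1e-12 or (
                        abs(q - best_q) <= 1e-12 and key < best):
                    best, best_q = key, q
        a, b = best
        via = dd(a, b)
        la = 0.5 * via + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = via - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"({nodes[a]}:{la:.10f},{nodes[b]}:{lb:.10f})"
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dd(a, c) + dd(b, c) - via)
            dist[(rep, c)] = dist[(c, rep)] = max(duc, 0.0)
        active = sorted(set(active) - {a, b} | {rep})
        nodes[rep] = new
    # final trifurcation: three-point pendant lengths
    a, b, c = active
    la = max((dd(a, b) + dd(a, c) - dd(b, c)) / 2, 0.0)
    lb = max((dd(a, b) + dd(b, c) - dd(a, c)) / 2, 0.0)
    lc = max((dd(a, c) + dd(b, c) - dd(a, b)) / 2, 0.0)
    newick = (f"({nodes[a]}:{la:.10f},{nodes[b]}:{lb:.10f},"
              f"{nodes[c]}:{lc:.10f});")
    out = PhyloTree.from_newick(newick)
    out.negative_lengths_clamped = clamped
    return out


def _quote(label: str) -> str:
    return f"'{label}'" if any(c in label for c in " ()[]:;,") else label


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of non-trivial bipartitions present in exactly one tree."""
    if t1.leaf_names != t2.leaf_names:
        raise ValidationError("leaf sets differ")
    return len(t1.bipartitions() ^ t2.bipartitions())


def check_monophyly(tree: PhyloTree, outgroup: str, group) -> bool:
    """True iff, after rooting on the outgroup, ``group`` forms a clade."""
    leaves = tree.leaf_names
    group = frozenset(group)
    if outgroup not in leaves:
        raise ValidationError(f"outgroup {outgroup!r} not in tree")
    if not group <= leaves:
        raise ValidationError("group is not a subset of the leaves")
    ingroup = leaves - {outgroup}
    if len(group) <= 1 or group == ingroup:
        return True
    # a clade of the outgroup-rooted tree = an unrooted split with one side
    # exactly `group` and the outgroup on the other side
    anchor = min(leaves)
    target = group if anchor not in group else leaves - group
    if outgroup in group:
        return False
    return target in tree.bipartitions() or (
        len(group) == len(leaves) - 1)


# ------------------------------------------------------------ supermatrix

@dataclass
class SupermatrixSpec:
    """Which partitions and codon positions enter a concatenated matrix.

    dataset ids: P123 (PCGs, all codon positions), P123R (+ rRNAs),
    P12 (PCGs, positions 1-2 only), P12R (P12 + rRNAs).  rRNA partitions
    are never codon-masked.
    """

    dataset: str
    include_rrna: bool
    drop_third_position: bool

    _KNOWN = ("P123", "P123R", "P12", "P12R")

    @classmethod
    def from_id(cls, dataset: str) -> "SupermatrixSpec":
        if dataset not in cls._KNOWN:
            raise ValidationError(
                f"unknown dataset {dataset!r}; expected one of {cls._KNOWN}")
        return cls(dataset=dataset, include_rrna=dataset.endswith("R"),
                   drop_third_position="12" in dataset and
                   "123" not in dataset)


@dataclass
class Supermatrix:
    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


def build_supermatrix(pcg_alignments: dict[str, dict[str, str]],
                      spec: SupermatrixSpec,
                      rrna_alignments: dict[str, dict[str, str]] | None = None
                      ) -> Supermatrix:
    """Concatenate per-gene alignments in alphabetical gene order, applying
    the spec's codon-position mask to PCG partitions.  Taxa missing from a
    partition are gap-filled with a warning."""
    import warnings

    blocks: list[tuple[str, dict[str, str]]] = sorted(pcg_alignments.items())
    if spec.include_rrna:
        blocks += sorted((rrna_alignments or {}).items())
    taxa = sorted({t for _, aln in blocks for t in aln})
    out = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for gene, aln in blocks:
        width = len(next(iter(aln.values())))
        if any(len(s) != width for s in aln.values()):
            raise ValidationError(f"{gene}: ragged alignment")
        is_pcg = gene in pcg_alignments
        if is_pcg and spec.drop_third_position:
            cols = [i for i in range(width) if i % 3 != 2]
        else:
            cols = list(range(width))
        for t in taxa:
            if t in aln:
                out[t].append("".join(aln[t][i] for i in cols))
            else:
                warnings.warn(f"{gene}: taxon {t} gap-filled")
                out[t].append("-" * len(cols))
        partitions.append((gene, pos + 1, pos + len(cols)))
        pos += len(cols)
    return Supermatrix(sequences={t: "".join(parts)
                                  for t, parts in out.items()},
                       partitions=partitions)
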