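"""Fixture and simulation inputs for the whole pipeline.

Three generators live here:

* ``make_table1_fixture`` — the published 37-gene annotation of the
  *Polypylis* sp. TS-2018 mitogenome (accession OR684570) as a feature
  table, without sequence.  This is the package's reference annotation.
* ``simulate_genome`` — a synthetic circular mitogenome honouring a gene
  layout: PCGs begin with their declared start codon, end with their
  declared (possibly incomplete) stop, and contain no internal stops;
  everything else is drawn from a target base composition.
* ``evolve_panel`` — codon sequences evolved along a fixed tree under an
  omega-thinned mutation process (synonymous changes accepted at the base
  rate, nonsynonymous at omega times it), recording realized substitution
  counts as ground truth for the Ka/Ks and phylogeny stages.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed yields the same output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codon_tools import GENETIC_CODE, STOP_CODONS
from .genome_model import (GeneFeature, MitoGenome, SpeciesPanel,
                           ValidationError, reverse_complement)
from .rearrangement import GeneOrder

# --------------------------------------------------------------- fixture
# The published annotation of Polypylis sp. TS-2018 (OR684570), one tuple
# per gene: (name, start, end, strand, class, start, stop, anticodon).
# Coordinates are 1-based inclusive on the major strand.
_TABLE1_ROWS = (
    ("nad6",  1,     450,   "+", "PCG",  "ATA", "TAA", None),
    ("nad5",  443,   2098,  "+", "PCG",  "TTG", "TAG", None),
    ("nad1",  2079,  2973,  "+", "PCG",  "ATG", "T",   None),
    ("nad4L", 2991,  3272,  "+", "PCG",  "ATA", "TAA", None),
    ("trnW",  3271,  3330,  "+", "tRNA", None,  None,  "TGA"),
    ("trnC",  3331,  3394,  "+", "tRNA", None,  None,  "TGC"),
    ("cob",   3410,  4468,  "+", "PCG",  "ATA", "TAG", None),
    ("trnD",  4464,  4527,  "+", "tRNA", None,  None,  "GAC"),
    ("trnF",  4524,  4591,  "+", "tRNA", None,  None,  "TTC"),
    ("cox2",  4593,  5237,  "+", "PCG",  "ATT", "TAA", None),
    ("trnY",  5241,  5303,  "+", "tRNA", None,  None,  "TAC"),
    ("trnG",  5298,  5363,  "+", "tRNA", None,  None,  "GGA"),
    ("trnH",  5357,  5426,  "+", "tRNA", None,  None,  "CAC"),
    ("trnQ",  5431,  5491,  "-", "tRNA", None,  None,  "CAA"),
    ("trnL2", 5487,  5553,  "-", "tRNA", None,  None,  "TTA"),
    ("atp8",  5549,  5662,  "-", "PCG",  "ATC", "TAA", None),
    ("trnN",  5664,  5732,  "-", "tRNA", None,  None,  "AAC"),
    ("atp6",  5733,  6366,  "-", "PCG",  "ATT", "T",   None),
    ("trnR",  6370,  6433,  "-", "tRNA", None,  None,  "CGA"),
    ("trnE",  6437,  6492,  "-", "tRNA", None,  None,  "GAA"),
    ("rrnS",  6493,  7201,  "+", "rRNA", None,  None,  None),
    ("trnM",  7202,  7264,  "-", "tRNA", None,  None,  "ATG"),
    ("nad3",  7267,  7611,  "-", "PCG",  "ATT", "TAA", None),
    ("trnS2", 7612,  7666,  "-", "tRNA", None,  None,  "TCA"),
    ("trnS1", 7666,  7725,  "+", "tRNA", None,  None,  "AGC"),
    ("nad4",  7725,  9029,  "+", "PCG",  "TTG", "TAA", None),
    ("trnT",  9041,  9105,  "-", "tRNA", None,  None,  "ACA"),
    ("cox3",  9106,  9883,  "-", "PCG",  "ATG", "T",   None),
    ("trnI",  9927,  9990,  "+", "tRNA", None,  None,  "ATC"),
    ("nad2",  9992,  10901, "+", "PCG",  "ATT", "T",   None),
    ("trnK",  10902, 10959, "+", "tRNA", None,  None,  "AAA"),
    ("cox1",  10959, 12491, "+", "PCG",  "ATC", "TAA", None),
    ("trnV",  12494, 12548, "+", "tRNA", None,  None,  "GTA"),
    ("rrnL",  12549, 13554, "+", "rRNA", None,  None,  None),
    ("trnL1", 13555, 13617, "+", "tRNA", None,  None,  "CTA"),
    ("trnA",  13614, 13680, "+", "tRNA", None,  None,  "GCA"),
    ("trnP",  13681, 13745, "+", "tRNA", None,  None,  "CCA"),
)

# The INC column as printed in the published annotation table, keyed by the
# gene on the downstream side of the junction (each row scores the junction
# to the previous gene; nad6's value is the wrap junction).  At 9 of the 36
# internal junctions this column is inconsistent with the printed
# coordinates; it is kept verbatim as reference data so reports can flag
# the mismatches.
TABLE1_PRINTED_INC = {
    "nad6": 0, "nad5": -8, "nad1": -20, "nad4L": 17, "trnW": -2, "trnC": 0,
    "cob": 15, "trnD": -1, "trnF": 0, "cox2": 1, "trnY": 8, "trnG": -1,
    "trnH": -7, "trnQ": 4, "trnL2": 0, "atp8": -2, "trnN": 1, "atp6": 0,
    "trnR": 3, "trnE": 3, "rrnS": 0, "trnM": 0, "nad3": 2, "trnS2": 0,
    "trnS1": -1, "nad4": -1, "trnT": 11, "cox3": 0, "trnI": 43, "nad2": 1,
    "trnK": 0, "cox1": -1, "trnV": 2, "rrnL": 0, "trnL1": 16, "trnA": 0,
    "trnP": 0,
}

# Genome lengths printed for OR684570 disagree internally: 13,749 bp in the
# abstract, 13,746 bp in the text, while the annotation table's last
# coordinate is 13,745.  All three are recorded; nothing here resolves it.
REPORTED_GENOME_LENGTHS = (13749, 13746, 13745)

FIXTURE_ID = "OR684570"
FIXTURE_TAXON = "Polypylis sp. TS-2018"

# §study panel: accession -> (species label, genus)
PANEL_TAXA = {
    "OR684570": ("Polypylis sp. TS-2018", "Polypylis"),
    "OX421510": ("Anisus vortex", "Anisus"),
    "MG431964": ("Biomphalaria choanomphala", "Biomphalaria"),
    "NC_005439": ("Biomphalaria glabrata", "Biomphalaria"),
    "MG431962": ("Biomphalaria pfeifferi", "Biomphalaria"),
    "MF480756": ("Biomphalaria straminea", "Biomphalaria"),
    "MG431963": ("Biomphalaria sudanica", "Biomphalaria"),
    "EF433576": ("Biomphalaria tenagophila", "Biomphalaria"),
    "MK414453": ("Bulinus globosus", "Bulinus"),
    "MK414450": ("Bulinus nasutus", "Bulinus"),
    "MK414449": ("Bulinus truncatus", "Bulinus"),
    "MK414451": ("Bulinus ugandae", "Bulinus"),
    "MW357851": ("Gyraulus sp.", "Gyraulus"),
    "KY514384": ("Planorbella duryi", "Planorbella"),
    "MW889961": ("Planorbella pilsbryi", "Planorbella"),
    "KP098540": ("Radix auricularia", "Radix"),
}
OUTGROUP_ID = "KP098540"

# The published family topology: Bulinus basal; Biomphalaria + Planorbella
# (Helisomatini) sister to Polypylis + (Anisus + Gyraulus).  Default branch
# lengths 0.05.
DEFAULT_TREE = (
    "(KP098540:0.05,(((MK414453:0.05,MK414450:0.05):0.05,"
    "(MK414449:0.05,MK414451:0.05):0.05):0.05,"
    "((((MG431964:0.05,NC_005439:0.05):0.05,(MG431962:0.05,"
    "(MF480756:0.05,(MG431963:0.05,EF433576:0.05):0.05):0.05):0.05):0.05,"
    "(KY514384:0.05,MW889961:0.05):0.05):0.05,"
    "(OR684570:0.05,(OX421510:0.05,MW357851:0.05):0.05):0.05):0.05):0.05);"
)

# Default per-gene dN/dS for the evolved panel: the published per-gene
# overall averages across genera, so simulations carry the study's
# selective regime (atp8 weakest purifying, cox1 strongest).
DEFAULT_OMEGA = {
    "atp8": 0.802, "nad6": 0.562, "nad2": 0.552, "nad4L": 0.523,
    "nad5": 0.422, "nad4": 0.407, "nad3": 0.372, "atp6": 0.328,
    "nad1": 0.307, "cox3": 0.159, "cob": 0.147, "cox2": 0.145,
    "cox1": 0.068,
}

# whole-mitogenome base composition of the reference annotation
DEFAULT_COMPOSITION = {"A": 0.333, "T": 0.420, "C": 0.115, "G": 0.133}


def make_table1_fixture() -> MitoGenome:
    """The 37-feature reference annotation (no sequence)."""
    feats = [GeneFeature(name=n, start=s, end=e, strand=st, gene_class=cls,
                         start_codon=sc, stop_codon=sp, anticodon=ac)
             for n, s, e, st, cls, sc, sp, ac in _TABLE1_ROWS]
    genome = MitoGenome(id=FIXTURE_ID, taxon=FIXTURE_TAXON,
                        genus="Polypylis", features=feats)
    genome.validate()
    return genome


# ------------------------------------------------------------- simulation

@dataclass
class SimulationSpec:
    """All knobs of the synthetic generators; the seed fully determines
    every output."""

    seed: int = 0
    features: tuple = _TABLE1_ROWS
    composition: dict = field(default_factory=lambda: dict(
        DEFAULT_COMPOSITION))
    tree_newick: str = DEFAULT_TREE
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    syn_rate: float = 1.0
    rearrangements: dict = field(default_factory=dict)  # taxon -> [events]

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 0.005:
            raise ValidationError("composition must sum to 1")
        if any(w <= 0 for w in self.omega.values()):
            raise ValidationError("omega values must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


_BASES = np.array(list("ACGT"))


def _draw_bases(rng, n: int, composition: dict) -> str:
    p = np.array([composition[b] for b in "ACGT"], dtype=float)
    p /= p.sum()
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def random_sense_codon(rng, composition: dict) -> str:
    """One codon drawn base-wise from the composition, rejecting stops."""
    while True:
        codon = _draw_bases(rng, 3, composition)
        if codon not in STOP_CODONS:
            return codon


def _coding_sequence(rng, length: int, start_codon: str, stop_codon: str,
                     composition: dict) -> str:
    """A PCG coding-strand sequence: declared start, stop-free body,
    declared (possibly incomplete) stop."""
    n_body = (length - len(stop_codon)) // 3
    codons = [start_codon] + [random_sense_codon(rng, composition)
                              for _ in range(n_body - 1)]
    return "".join(codons) + stop_codon


def simulate_genome(spec: SimulationSpec | None = None,
                    seed: int | None = None) -> tuple[MitoGenome, dict]:
    """Generate a circular mitogenome honouring the spec's gene layout.

    Gene lengths, order, strands and stop styles are preserved exactly.
    Junction overlaps in the template layout are infeasible for
    independently drawn coding sequences, so overlapping starts are shifted
    right to abut (a tolerance-limited layout repair); every shift is
    recorded in the returned report.

    Returns ``(genome, report)`` where ``report`` lists the applied shifts
    and the realized composition.
    """
    if spec is None:
        spec = SimulationSpec(seed=0 if seed is None else seed)
    rng = spec.rng()
    rows = sorted(spec.features, key=lambda r: r[1])
    # repair layout: clamp negative junctions to abutting
    placed: list[GeneFeature] = []
    shifts: dict[str, int] = {}
    prev_end_old = prev_end_new = 0
    for name, start, end, strand, cls, sc, sp, ac in rows:
        length = end - start + 1
        inc = start - prev_end_old - 1 if placed else 0
        new_start = prev_end_new + 1 + max(inc, 0)
        if new_start != start:
            shifts[name] = new_start - start
        placed.append(GeneFeature(name=name, start=new_start,
                                  end=new_start + length - 1, strand=strand,
                                  gene_class=cls, start_codon=sc,
                                  stop_codon=sp, anticodon=ac))
        prev_end_old, prev_end_new = end, new_start + length - 1
    genome_length = placed[-1].end  # wrap junction abuts, as in the template
    seq = np.empty(genome_length, dtype="<U1")
    seq[:] = list(_draw_bases(rng, genome_length, spec.composition))
    for f in placed:
        n = f.end - f.start + 1
        if f.gene_class == "PCG":
            coding = _coding_sequence(rng, n, f.start_codon, f.stop_codon,
                                      spec.composition)
        else:
            coding = _draw_bases(rng, n, spec.composition)
        major = coding if f.strand == "+" else reverse_complement(coding)
        seq[f.start - 1:f.end] = list(major)
    genome = MitoGenome(id=f"SIM-{spec.seed}", taxon="synthetic mitogenome",
                        genus="Synthetica", sequence="".join(seq),
                        features=placed)
    genome.validate()
    at = (genome.sequence.count("A") + genome.sequence.count("T")) / \
        genome_length
    report = {"seed": spec.seed, "shifts": shifts,
              "genome_length": genome_length, "realized_at_content": at}
    return genome, report


# ---------------------------------------------------------- codon evolution

def _mutate_codons(rng, codons: list[str], t: float, omega: float,
                   rate: float) -> tuple[list[str], int, int]:
    """Evolve a codon list along one branch of length ``t``.

    Mutations are proposed uniformly over positions and alternative bases
    at ``rate`` proposals per site per unit branch length; proposals
    creating stop codons are discarded, synonymous proposals are accepted
    at the base rate and nonsynonymous ones at ``omega`` times it (the
    proposal intensity is scaled so acceptance probabilities stay in
    [0, 1] for omega > 1).  Returns (codons, syn count, nonsyn count).
    """
    out = list(codons)
    scale = max(1.0, omega)
    n_sites = 3 * len(out)
    n_prop = rng.poisson(rate * scale * n_sites * t)
    syn = nonsyn = 0
    for _ in range(n_prop):
        site = int(rng.integers(n_sites))
        ci, pos = divmod(site, 3)
        codon = out[ci]
        alternatives = [b for b in "ACGT" if b != codon[pos]]
        new = codon[:pos] + alternatives[int(rng.integers(3))] + \
            codon[pos + 1:]
        if new in STOP_CODONS:
            continue
        if GENETIC_CODE[new] == GENETIC_CODE[codon]:
            if rng.random() < 1.0 / scale:
                out[ci] = new
                syn += 1
        else:
            if rng.random() < omega / scale:
                out[ci] = new
                nonsyn += 1
    return out, syn, nonsyn


def _mutate_nucleotides(rng, seq: str, t: float, rate: float) -> str:
    """Neutral nucleotide evolution (rRNA partitions)."""
    out = list(seq)
    n_prop = rng.poisson(rate * len(out) * t)
    for _ in range(n_prop):
        i = int(rng.integers(len(out)))
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


@dataclass
class EvolvedPanel:
    panel: SpeciesPanel
    pcg_alignments: dict[str, dict[str, str]]   # gene -> taxon -> codon seq
    rrna_alignments: dict[str, dict[str, str]]  # gene -> taxon -> seq
    tree_newick: str
    realized: dict[str, dict[str, tuple[int, int]]]  # gene -> branch -> (s,n)


def evolve_panel(spec: SimulationSpec | None = None,
                 seed: int | None = None,
                 n_codons: dict[str, int] | None = None) -> EvolvedPanel:
    """Evolve per-gene codon (and rRNA nucleotide) sequences along the
    spec's tree.  No indels, so alignments are columnar by construction.

    ``n_codons`` overrides per-gene codon counts (default: the template
    annotation's codon counts).
    """
    if spec is None:
        spec = SimulationSpec(seed=0 if seed is None else seed)
    rng = spec.rng()
    tree = dendropy.Tree.get(data=spec.tree_newick, schema="newick",
                             preserve_underscores=True)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    gene_sizes: dict[str, int] = {}
    rrna_sizes: dict[str, int] = {}
    for name, start, end, _, cls, _, sp, _ in spec.features:
        if cls == "PCG":
            gene_sizes[name] = (end - start + 1 - len(sp)) // 3
        elif cls == "rRNA":
            rrna_sizes[name] = end - start + 1
    if n_codons:
        gene_sizes = dict(n_codons)
        rrna_sizes = {}

    pcg_aln: dict[str, dict[str, str]] = {}
    rrna_aln: dict[str, dict[str, str]] = {}
    realized: dict[str, dict[str, tuple[int, int]]] = {}
    for gene in sorted(gene_sizes):
        omega = spec.omega.get(gene, 1.0)
        if omega <= 0:
            raise ValidationError(f"{gene}: omega must be > 0")
        root = [random_sense_codon(rng, spec.composition)
                for _ in range(gene_sizes[gene])]
        states: dict[int, list[str]] = {id(tree.seed_node): root}
        counts: dict[str, tuple[int, int]] = {}
        leaf_seqs: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            child, syn, nonsyn = _mutate_codons(rng, parent, t, omega,
                                                spec.syn_rate)
            states[id(node)] = child
            label = (node.taxon.label if node.is_leaf()
                     else f"node{len(counts)}")
            counts[label] = (syn, nonsyn)
            if node.is_leaf():
                leaf_seqs[node.taxon.label] = "".join(child)
        pcg_aln[gene] = leaf_seqs
        realized[gene] = counts
    for gene in sorted(rrna_sizes):
        root = _draw_bases(rng, rrna_sizes[gene], spec.composition)
        states = {id(tree.seed_node): root}
        leaf_seqs = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = node.edge.length or 0.0
            child = _mutate_nucleotides(rng, states[id(node.parent_node)],
                                        t, spec.syn_rate)
            states[id(node)] = child
            if node.is_leaf():
                leaf_seqs[node.taxon.label] = child
        rrna_aln[gene] = leaf_seqs

    genomes = []
    for tid in taxa:
        species, genus = PANEL_TAXA.get(tid, (tid, tid.split("_")[0]))
        genomes.append(MitoGenome(id=tid, taxon=species, genus=genus))
    panel = SpeciesPanel(
        genomes=genomes,
        outgroup_id=OUTGROUP_ID if OUTGROUP_ID in taxa else None)
    return EvolvedPanel(panel=panel, pcg_alignments=pcg_aln,
                        rrna_alignments=rrna_aln,
                        tree_newick=spec.tree_newick, realized=realized)


# ------------------------------------------------------- scripted events

def apply_scripted_rearrangements(order: GeneOrder, events) -> GeneOrder:
    """Apply transposition / reverse-transposition events in sequence.

    Each event is a mapping (or RearrangementEvent) with ``gene``, ``kind``
    and ``dest_junction`` = (left neighbor, right neighbor); the gene is cut
    out, flipped on reverse transposition, and inserted at the destination
    junction, which must be an adjacent pair at application time.
    """
    tokens = list(order.tokens)
    for ev in events:
        gene = ev["gene"] if isinstance(ev, dict) else ev.gene
        kind = ev["kind"] if isinstance(ev, dict) else ev.kind
        dest = tuple(ev["dest_junction"] if isinstance(ev, dict)
                     else ev.dest_junction)
        names = [g for g, _ in tokens]
        if gene not in names:
            raise ValidationError(f"event references absent gene {gene!r}")
        i = names.index(gene)
        g, sign = tokens.pop(i)
        if kind == "reverse_transposition":
            sign = "+" if sign == "-" else "-"
        elif kind != "transposition":
            raise ValidationError(f"unknown event kind {kind!r}")
        names = [x for x, _ in tokens]
        n = len(tokens)
        slots = [j for j in range(n)
                 if (names[j], names[(j + 1) % n]) == dest]
        if len(slots) != 1:
            raise ValidationError(
                f"destination junction {dest} is "
                f"{'ambiguous' if slots else 'absent'} for {gene!r}")
        tokens.insert(slots[0] + 1, (g, sign))
    return GeneOrder(order.genome_id, tokens)
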