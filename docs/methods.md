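# Methods

`mitocompare` is a desk-scale comparative-mitogenomics pipeline for small
circular mitochondrial genomes of the kind found in panpulmonate snails:
13.5–14.3 kb, 37 genes (13 protein-coding genes, 22 tRNAs, 2 rRNAs) on two
strands, AT-rich, with overlapping or abutting gene junctions and
incomplete stop codons. Its reference dataset is the packaged annotation
of the *Polypylis* sp. TS-2018 mitogenome (GenBank OR684570) and the
gene orders of 15 planorbid species. Everything below runs from that
packaged data and from seeded simulators; nothing is downloaded.

## Data model and conventions

Coordinates are 1-based inclusive on the major (J) strand, the dialect of
GenBank feature tables; conversion to 0-based half-open slices happens only
inside sequence extraction. A genome's length is taken from its sequence
when present, else from a declared length, else from the maximum feature
end. The reference annotation prints three mutually inconsistent genome
lengths (13,749 / 13,746 / 13,745 bp); the package records all three
(`REPORTED_GENOME_LENGTHS`) and uses the coordinate-derived 13,745 bp for
statistics, which changes no reported value at the printed precision.

Protein-coding genes must satisfy `length ≡ len(stop) (mod 3)`: a full
TAA/TAG stop leaves a multiple of three, while the incomplete stops TA and
T (completed to TAA by polyadenylation of the transcript) leave remainders
of two and one. Gene names are mapped onto the canonical 37-name
vocabulary through an editable synonym table
(`data/gene_synonyms.tsv`); the duplicated leucine/serine tRNAs are
resolved by anticodon, accepting both the codon-like and the
reverse-complement anticodon writing conventions, and are otherwise held
ambiguous rather than guessed.

## Composition and junction statistics

Strand skews use AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C); a skew
with an empty denominator is reported as null with a warning. Whole-genome
skews are computed on the major strand; per-gene statistics on each gene's
coding strand. Reports round percentages to 1 decimal and skews to 3;
internal values keep full precision.

Intergenic nucleotides between consecutive features are
`inc = start(next) − end(prev) − 1` (positive = spacer, negative =
overlap); circular mode adds the wrap junction from the last feature back
to the first. Ties for "longest" break on the first junction in coordinate
order. The published annotation's own INC column is internally
inconsistent with its coordinates at 8 of the 36 internal junctions (e.g.
trnD: coordinates give −5, column prints −1); the junction report
recomputes from coordinates and flags every mismatch, while the published
column is retained verbatim (`TABLE1_PRINTED_INC`) so its summary counts
(14 spacers, 10 overlaps) remain reproducible as data.

## Codon usage

The genetic code is fixed to NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG only),
taken from biopython. Codon extraction drops the trailing stop — full or
incomplete — keeps the start codon as an ordinary codon, and tolerates
internal in-frame stops with a warning because draft annotations contain
them. RSCU(c) = k·n(c)/Σ_family n over each synonymous family of size k,
pooled across the 13 PCGs; within every observed family the mean RSCU is
exactly 1, an unobserved codon in an observed family scores 0, and an
unobserved family yields nulls with a warning. Because prose and RSCU
plots can disagree on what "most used codon" means, reports carry both the
raw-count top-3 and the RSCU top-3.

## Ka/Ks (NG86)

Selection screening uses the Nei–Gojobori (1986) counting method. Per
codon, the synonymous site count is the expected synonymous fraction of
the three possible changes at each position, with changes that would
create a stop codon excluded from the denominator, so n + s = 3 exactly
for every sense codon. Differences between aligned codons are averaged
with equal weights over all orderings of the differing positions; an
ordering that passes through a stop codon is excluded (if all are blocked,
all are kept — a documented fallback that never triggers on sense-codon
pairs differing at ≤ 2 positions in practice). Codons with gaps or
ambiguity, and stop codons, are dropped pairwise. Proportions are
Jukes–Cantor corrected, K = −¾ ln(1 − 4p/3); p ≥ ¾ raises a saturation
error for that gene rather than a silent NaN. Note that very short inputs
can saturate legitimately — a single synonymous difference on one isolated
codon gives pS up to 3 — so toy examples need a few conserved codons
around the difference.

Classification uses Ka/Ks with a ±0.05 neutrality band (exact equality
never occurs in floating point): > 1.05 positive, < 0.95 purifying,
otherwise neutral; Ks = 0 yields an undefined ratio reported as NA. Panel
scoring is reference-pairwise — each ingroup species' 13 PCGs against the
designated outgroup (*Radix auricularia* stand-in in fixtures) — with
ratios averaged within genus and then across genera; an all-pairs mode is
available through `ng86_pair` directly. Codon alignments come from
aligning translated amino acids (Needleman–Wunsch) and back-threading
codons. Published per-gene DnaSP averages are treated as qualitative rank
anchors, not bit-exact targets: the exact algorithm variant and alignment
behind them are not fully specified, so reproducing their ranks (atp8
least constrained, cox1 most) is the supported claim.

## Gene-order rearrangements

A gene order is a circular signed permutation. Normalization rotates cox1
first and, if cox1 reads −, reflects the circle and flips all signs; it is
pure and idempotent, so rotation and strand-reading choices never matter.
Two genomes share an arrangement type iff their normalized orders are
identical; type labels A, B, … follow first appearance in input order.

Event detection covers the two event kinds observed in the panel —
single-gene transposition and reverse transposition (orientation flip) —
and finds the minimum-cardinality gene set whose deletion from both
circular orders leaves identical signed sequences. Genes whose orientation
differs are forced members; the exhaustive subset search (≤ 12 genes) runs
smallest-first with ties broken by (gene class: tRNA < rRNA < PCG, then
name). The class-first tie-break is deliberate: single-gene moves in
mitogenomes are overwhelmingly tRNA events, and on this panel a
name-lexicographic rule would prefer an equally parsimonious explanation
that relocates the protein gene cob instead of trnC/trnW. Blocks that
moved together are reported as per-gene events. Inversion-distance/DCJ
sorting and tandem-duplication–random-loss inference are out of scope.

The 15 packaged orders (`data/planorbid_gene_orders.txt`) derive from the
reference annotation (type E read directly from its coordinates and
strands) plus the described inter-type deltas; the file documents the
provenance of each type, including the one synthetic choice (trnD's source
junction in type A, which event detection is insensitive to).

## Phylogeny

Full Bayesian/ML inference is deliberately replaced by neighbor joining on
pairwise distances: p-distances (JC-corrected for nucleotides, Poisson for
amino acids; correction on by default) on columnar alignments, the
Saitou–Nei Q-criterion with deterministic lowest-id tie-breaks, negative
branch lengths clamped to zero with a flag, and a final trifurcation so
the output is properly unrooted. Supermatrices follow the four standard
datasets — P123 (13 PCGs, all codon positions), P123R (+ 2 rRNAs), P12 and
P12R (third codon positions of PCGs dropped; rRNAs never masked) — with
genes concatenated alphabetically and a partition map emitted. The
published matrix lengths are not targets: they depend on ClustalW
alignments of the real accessions, whereas simulated alignments here are
indel-free. Topology checks use Robinson–Foulds distance (bipartitions
present in exactly one tree) and outgroup-rooted monophyly.

## Synthetic data

The generators carry the study conditions so every stage is testable
offline; all randomness flows through `numpy.random.default_rng(seed)`
(integer-state, platform-independent).

* `simulate_genome` honours the reference layout — gene order, lengths,
  strands, start/stop codon styles — and the reference base composition
  (A .333, T .420, C .115, G .133). PCGs begin with their declared start,
  end with their declared stop style, and contain no internal stops
  (codons drawn base-wise with stop rejection); tRNAs, rRNAs and spacers
  are iid draws. The reference layout's junction overlaps are infeasible
  for independently drawn coding sequences, so overlapping starts are
  shifted right to abut and every shift is reported; lengths — hence codon
  counts — are preserved exactly.
* `evolve_panel` evolves codon sequences along the family topology
  (Bulinus basal; Biomphalaria + Planorbella sister to Polypylis +
  (Anisus + Gyraulus); default branch lengths 0.05) under an omega-thinned
  process: proposals uniform over sites and alternative bases, stop
  proposals discarded, synonymous changes accepted at the base rate and
  nonsynonymous at ω times it (intensity rescaled for ω > 1). This is a
  deliberate simplification of a full GY94 codon model — no
  transition/transversion bias, no codon-frequency stationarity, no indels
  — sufficient to give NG86 a known ground truth; realized per-branch
  substitution counts are recorded. Default per-gene ω values are the
  published per-gene averages, so simulations carry the study's selective
  regime. rRNA partitions evolve under neutral per-site substitution.
* `apply_scripted_rearrangements` moves genes to stated junctions,
  flipping orientation on reverse transposition, and refuses ambiguous or
  absent destinations.

What passing on synthetic data does not show: realistic among-site rate
variation, strand-asymmetric mutation, indels and alignment error, or base
composition heterogeneity among genes — conclusions about real genomes
still require the real accessions.

## Numerical and scale choices

Tolerance choices: NG86 neutrality band ±0.05; JC saturation at p ≥ 3/4;
NJ Q-comparison tolerance 1e-12 before the deterministic tie-break.
Problem sizes used in tests and the acceptance script — 320-codon genes,
20 replicates for ω recovery, 10 seeds for 16-taxon topology recovery —
are chosen so each property is decided by a comfortable margin at desk
scale. One statistical limit is respected rather than fought: at ω = 1.0
the ±0.05 neutrality band is several times narrower than the NG86 ratio's
sampling spread at a few hundred codons, so classification accuracy is
asserted only for ω values clear of the boundary (0.1 and 2.0), while
median recovery within ±30% is asserted for all three.

## Known limitations

* Annotations are consumed, not predicted; there is no de-novo gene
  finding, tRNA folding, or assembly.
* NG86 is a counting method; maximum-likelihood codon models and
  site-level selection tests are out of scope.
* NJ on pairwise distances replaces Bayesian/ML inference; no bootstrap
  supports or model selection.
* The rearrangement event model is restricted to single-gene
  transposition and reverse transposition, the only kinds observed in
  this panel.
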