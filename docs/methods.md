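# Methods

This note documents the models, rules and defaults behind ebopipe, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Genome model

Genomes are held as contigs plus strand-aware gene features in 0-based
half-open coordinates; the 1-based inclusive conventions of GenBank and
GFF3 are converted at the parsing boundary, which confines off-by-one
handling to two functions. Circular contigs permit origin-wrapping
features (`start > end`, span `(L − start) + end`); a GenBank
`join(X..L,1..Y)` on a circular record becomes one wrapped feature, never
two. Gene order is total and deterministic (start, then end, then gene
id), so every downstream computation is invariant to input feature order.
CDS translations missing from the annotation are computed with NCBI
translation table 11 (bacterial/plastid); the table is a parameter for
other compartments. Pseudogenes are kept in the gene order (they count as
intervening genes) but score as absent in presence/absence matrices, with
a footnote preserving the distinction.

## Marker assignment

Genes are scored against every family of a marker panel by affine-gap
local alignment (Smith–Waterman–Gotoh; BLOSUM62, gap open 11, extend 1 in
the BLAST cost convention, i.e. a gap of length *k* costs 11 + *k*).
Alignment is delegated to Biopython's C `PairwiseAligner`; the test suite
checks it against an independent plain-Python Gotoh implementation, which
is itself validated by exhaustive alignment-path enumeration at tiny
lengths. Non-canonical residues are masked to X, and X scores 0 against
everything, so partial or frame-shifted translations are penalized only by
what they lack.

Raw scores become bit scores via fixed Karlin–Altschul constants for
gapped BLOSUM62/11/1 (λ = 0.267, K = 0.041). The constants are not
estimated from the data because nothing downstream depends on absolute
E-values — only ranking and thresholding. A gene is labelled with its
best family when three thresholds clear:

| parameter | default | meaning |
|---|---|---|
| `min_bits` | 50 | noise floor for any assignment |
| `min_coverage` | 0.5 | fraction of the best seed covered; failures are flagged `partial` (fragments, frame shifts) rather than labelled |
| `min_margin` | 10 bits | best-vs-second-family gap; failures are flagged `ambiguous` |

The margin rule stands in for the manual curation an expert would apply to
borderline homologues; flagged records are written out so users can audit
them. Family assignment is best-seed (max over seeds), not profile-based:
panels here have few seeds per family, and profile/HMM search is out of
scope. Absence calls inherit the sensitivity of this single-pass search —
they are weaker evidence than absence confirmed by iterative
profile searches, and downstream outputs treat them as ordinary absences
only in the absence of an assembly-gap flag.

Precomputed BLAST tabular (outfmt 6) hits can be imported instead; they
pass through the identical best-family/threshold/margin selection.

## Clustering and architecture

Two markers chain into one cluster when **both** the number of non-marker
genes between them is ≤ `max_intervening` (default 3) and their nucleotide
gap is ≤ `max_gap_bp` (default 5000). The defaults were calibrated on the
documented cases the pipeline must separate: insertions of two or three
conserved foreign genes inside an operon must chain, while genes
physically separated from the rest of the cluster must not. Both knobs are
exposed on the command line because no published threshold exists for
"physically close". Chaining consecutive markers is equivalent to taking
connected components of the full pairwise predicate (the predicate is
monotone in rank distance); the test suite verifies this equivalence
exhaustively on random instances. On circular contigs the chain closes
around the ring; a whole-ring cluster is rotated to start after its
largest inter-member gap, with a rotation-invariant tie-break.

Architecture strings are this package's invention (grammar version 1,
recorded in output headers): members in reading order, lowercase =
antisense to the cluster's majority strand, `+k` = k inserted non-marker
genes. If the minus strand holds a strict majority the reading is
reversed and strands flipped; an exact strand tie resolves to the
lexicographically smaller of the two readings — arbitrary, but
deterministic and orientation-free. The invariance that motivates the
grammar (reverse-complement and rotation safety) is property-tested on
1000 randomized genomes.

Classification order: `absent` (no hits), then `partial` (≥ 1 panel
family missing genome-wide), then `single_operon` / `co_clustered_mixed_strand`
(one cluster, uniform vs mixed strands) / `split_cluster` (≥ 2 clusters).
A missing family takes precedence over the split/co-clustered distinction
because a genome that lacks a gene outright is a different biological
statement than one that merely rearranged it; the cluster details remain
available either way. The A and G accessory families are treated as one
mutually exclusive slot: a genome carrying G is not "partial" for lacking
A (and vice versa), and the variant field reports which form is present.
A singleton copy of a family that also occurs inside a multi-member
cluster is reported as a detached paralog; two copies both outside any
cluster stay ordinary singletons, none preferred.

`assembly_gap_suspected` is set when a family is missing *and* some
cluster ends within `edge_rank` (default 2) gene ranks of a linear-contig
end — the signature of an operon truncated by a sequencing gap. Circular
contigs have no ends and never trigger it. The flag feeds presence
matrices as *unknown* rather than absent, so draft assemblies do not
manufacture loss events.

## Gain/loss mapping

Dollo parsimony is the default criterion because gene-content evolution
for horizontally acquired operons is naturally a gains-then-losses story:
the character is gained once, on the branch above the MRCA of all present
leaves (ancestral at the root when that MRCA is the root), and the losses
are the maximal subtrees inside the gain clade whose scored leaves are all
absent. That loss set is the minimum compatible with a single gain; the
suite verifies it (and the Fitch implementation) against brute-force
enumeration over every rooted binary topology with up to five leaves plus
every six-leaf shape, crossed with every binary pattern — equivalent, up
to leaf relabelling, to sweeping all labeled six-leaf trees.

Consequences worth knowing:

* A character present in a single sampled leaf maps as a terminal-branch
  gain with zero losses. Reading it instead as an ancestral gene lost
  early requires outgroup knowledge that is not in the matrix; add
  outgroup taxa to the matrix to encode it.
* Losses that cover entire sibling subtrees merge into one deeper loss;
  a loss on one of two root children relocates the gain. The simulation
  tests assert exact recovery precisely on the identifiable cases and
  bound the reconstruction from above elsewhere.
* Unknown leaves are excluded from the MRCA and never create or block a
  loss by themselves.
* Soft polytomies are accepted; Fitch uses Hartigan's generalization, and
  losses on a polytomy's children count per branch.

Branch lengths are read and preserved but ignored by both criteria.

## Alignment trimming and concatenation

`trim_blocks` is a compact conserved-block filter in the Gblocks
tradition, with four parameters: a column is *conserved* when its most
frequent residue reaches `min_conserved` (0.5) of rows and its gap
fraction is at most `max_gap_frac` (0.5 — the relaxed allow-gaps-in-half
regime that keeps the maximal number of positions), *highly conserved* at
`min_flank` (0.85); kept blocks are maximal conserved runs of at least
`min_block` (5) columns after shrinking each run to highly conserved
terminal columns. Column-for-column parity with any external trimmer is a
non-goal; the rules are frozen by an independent straight-line oracle in
the tests, and trimming is idempotent.

Paralog selection is operationalized as: (1) the copy inside a
multi-member cluster, (2) the higher bit score, (3) the lexicographically
smaller gene id. The judgment call this replaces — which copy "behaves
more consistently" in single-gene trees — needs human tree inspection, so
the report marks every case where the cluster rule actually overrode the
score ranking.

Concatenation pads taxa missing from a family with gaps, records 1-based
inclusive partitions in input-family order, and emits relaxed PHYLIP plus
RAxML-style and NEXUS partition definitions. Residue content per taxon is
conserved exactly (property-tested). Phylogenetic inference itself is
deliberately external.

## Synthetic benchmark

The generator plants a marker cluster with a specified architecture into a
background of random genes, then emits standard files (GenBank,
GFF3+FASTA) plus a ground-truth JSON. Study conditions are encoded as
defaults, chosen once:

* **Panel**: synthetic seed proteins at realistic lengths — short,
  weakly constrained accessory genes (A: 120 aa, G: 110 aa) and a core of
  280–380 aa enzymes — generated from a fixed seed. No real seed
  sequences ship with the package; any user panel drops in via FASTA.
* **Marker divergence**: `identity` fixes the exact number of substituted
  positions; substitutions are drawn proportionally to BLOSUM62
  exchangeabilities, so divergent markers remain detectable the way real
  cross-phylum homologues are (uniform substitution would destroy
  detectability far faster than evolution does).
* **Background**: 150–450 aa random proteins, rejection-sampled to score
  below 30 bits against every panel seed, so false-positive labelling is a
  measurable quantity rather than an artifact of construction.
* **Layout**: ~20 background genes around the cluster, 50–300 bp
  intergenic spacers, back-translation through random synonymous codons of
  table 11.
* **Presence evolution**: single gain, per-branch irreversible loss with
  probability 1 − exp(−rate·length), branch lengths defaulting to 1 on
  cladograms.

Identical seeds give byte-identical output files.

What passing the benchmark shows: the pipeline's logic (coordinate
handling, chaining, canonicalization, classification, parsimony, matrix
bookkeeping) is correct on genomes whose generative process is known. What
it does not show: performance on real annotation noise — wrong gene
models, missed short ORFs, contaminated assemblies, compositional biases —
none of which the generator emulates. The alignment thresholds in
particular are tested at planted identities ≥ 0.7; markers diverged well
below that will drop to `partial`/unlabelled and should be rescued with
richer seed panels rather than threshold surgery.

## Problem sizes

Default verification sizes, chosen to exercise each property well past its
edge cases: 1000 randomized genomes for canonicalization invariance, 500
for cluster-oracle equivalence, ~4000 tree × pattern cases for the
parsimony sweep, 200 peptide pairs for the alignment oracle, 200 genomes
(1200 markers) for graded recovery, 50 random supermatrices. All regenerate
from a single seed in `scripts/acceptance.py`.

## Known limitations

* No HMM/profile search; sensitivity is bounded by best-seed pairwise
  alignment.
* No nucleotide-level search of unannotated regions: a gene absent from
  the annotation is absent to the pipeline.
* Inverted-repeat duplicates are surfaced as ordinary paralogs;
  deduplication is the caller's decision.
* The operon concept is purely structural (same strand + chaining); no
  promoter/terminator or expression evidence is consulted.
* Gblocks-style trimming here is a simplified four-parameter rule, not a
  reimplementation of any specific published tool.
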