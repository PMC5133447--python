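# ebopipe

Comparative-genomics tooling for surveying a multi-gene operon across
annotated genomes: marker-family homology assignment, gene-cluster synteny
detection and architecture classification, Dollo-parsimony mapping of gene
gains and losses on a fixed phylogeny, and paralog-aware supermatrix
preparation.

## The problem

Some eustigmatophyte algae carry, inside their plastid genome, a six-gene
cluster (the *ebo* operon, genes *eboA*–*eboF*) acquired horizontally from
a bacterium. Homologous clusters occur across many bacterial phyla, but in
varying states: the ancestral gene order `ABCDEF`, permuted orders
(`ABDEFC`, `FABDEC`, `DECABF`), foreign genes inserted into the operon,
members flipped to the opposite strand, clusters split across distant loci
or broken by contig ends, extra detached paralogs, and a variant in which
an unrelated accessory gene (*eboG*) replaces *eboA*. Surveying this
variation means answering, per genome: *which genes are present, how are
they arranged, and is the arrangement still one operon?* — and then, on a
species tree, *where were the genes gained and lost?*

ebopipe is for comparative genomicists who want that survey to be
reproducible code rather than a pile of one-off scripts. It works with any
marker panel, not just the six-gene cluster that motivated it.

## The computations

**Clustering.** Marker hits are chained along the gene order of each
contig: two markers join a cluster when at most `max_intervening`
non-marker genes (default 3) *and* at most `max_gap_bp` nucleotides
(default 5000) separate them. On circular contigs chaining runs on the
ring, so clusters may span the replication origin.

**Architecture strings.** Each cluster is canonicalized into a compact
string: one letter per member in reading order, lowercase for members
antisense to the cluster's majority strand, `+k` for a run of *k* inserted
non-marker genes. The reading direction is normalized (majority strand
forward), so reverse-complementing a genome or rotating a circular contig
never changes the string. `dABCEF` therefore means: a reversed D member
upstream of five co-oriented genes.

**Classification.** Per genome: `single_operon` (every panel family in one
uniform-strand cluster), `co_clustered_mixed_strand`, `split_cluster`,
`partial` (a family missing genome-wide) or `absent` — plus detached
paralog detection, the A/G variant call, and an assembly-gap flag when a
missing family coincides with a cluster sitting at a contig end.

**Gain/loss mapping.** Presence/absence characters are mapped on a rooted
tree under Dollo parsimony: a single gain on the branch above the MRCA of
the present leaves, and the provably minimal set of losses (the maximal
all-absent subtrees inside the gain clade). Unknown states (draft genomes)
impose no constraints. Fitch/Hartigan parsimony is available as a
sensitivity check.

**Supermatrix preparation.** Per-family protein alignments are trimmed to
conserved blocks, one gene per (taxon, family) is chosen with an
operon-aware paralog rule (in-cluster copy first, then bit score, then a
deterministic tie-break), and the alignments are concatenated into a
relaxed-PHYLIP supermatrix with RAxML/NEXUS partition definitions.

## Worked example

Simulate a genome whose operon carries two inserted foreign genes at 80%
marker identity, scan it against the panel, and classify the architecture:

```sh
ebo simulate --spec "ABC+2DEF" --identity 0.8 --seed 11 -o sim
ebo scan sim/sim11.gbk --panel sim/panel.faa -o scan
ebo arch sim/sim11.gbk --hits-dir scan --panel sim/panel.faa -o arch
```

`scan/sim11.hits.tsv` labels each planted marker with its family; the
realized identities sit at the requested 80% and every hit clears the
bit-score/coverage/margin thresholds:

```
gene_id      family  raw_score  bit_score  identity  status
sim11_g0010  A       510        201.06     0.8083    labelled
sim11_g0011  B       1472       571.62     0.8052    labelled
sim11_g0012  C       1291       501.90     0.8033    labelled
```

`arch/architecture.tsv` then gives the one-row verdict — the planted
architecture is recovered exactly, and the two inserted genes appear as
`+2` in the canonical string:

```
genome_id  ...  architecture  class          variant    missing  assembly_gap_suspected
sim11      ...  ABC+2DEF      single_operon  eboA_type  -        false
```

Mapping presence/absence on a five-taxon tree (`1`/`0`/`?` matrix):

```sh
ebo events --tree tree.nwk --matrix pm.tsv -o ev
```

```
character  gain_branch  loss_branches   n_losses
ebo        n3           n1              1
acpP       root         Vischeria;n1    2
```

Read: the operon was gained once on the branch `n3` (after the deepest
split) and lost once in the `n1` clade; *acpP* is ancestral at the root
and was lost twice independently — exactly the disjunct-presence reasoning
the Dollo criterion encodes. The same events are written as an annotated
Newick and drawn as a text tree.

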