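"""Shared builders for the test suite: tiny genomes assembled by hand."""

from __future__ import annotations

import math

from ebopipe.genome_io import Contig, GeneFeature, GenomeRecord
from ebopipe.markers import MarkerHit


def build_genome(
    entries,
    circular: bool = False,
    genome_id: str = "g1",
    contig_id: str = "c1",
    gene_len: int = 900,
    spacing: int = 100,
    tail: int = 0,
):
    """Construct a genome + labelled hits from (family_or_None, strand) pairs.

    Genes are laid head-to-tail with ``spacing`` bp between them; entries
    with a family code get a perfect labelled MarkerHit.
    """
    feats, hits = [], []
    pos = spacing
    for i, (fam, strand) in enumerate(entries):
        gid = f"{genome_id}_g{i:03d}"
        feats.append(GeneFeature(contig_id, pos, pos + gene_len, strand, gid, label=gid))
        if fam:
            hits.append(
                MarkerHit(genome_id, gid, fam, 1000, math.inf, 0.0, 1.0, 1.0, math.inf)
            )
        pos += gene_len + spacing
    genome = GenomeRecord(
        genome_id, genome_id, [Contig(contig_id, pos + tail, circular)], feats
    )
    genome.validate()
    return genome, hits


def multi_contig_genome(contig_entries, genome_id="g1", gene_len=900, spacing=100):
    """Like build_genome but one (entries, circular) pair per contig."""
    contigs, feats, hits = [], [], []
    n = 0
    for ci, (entries, circular) in enumerate(contig_entries):
        contig_id = f"c{ci + 1}"
        pos = spacing
        for fam, strand in entries:
            gid = f"{genome_id}_g{n:03d}"
            n += 1
            feats.append(GeneFeature(contig_id, pos, pos + gene_len, strand, gid, label=gid))
            if fam:
                hits.append(
                    MarkerHit(genome_id, gid, fam, 1000, math.inf, 0.0, 1.0, 1.0, math.inf)
                )
            pos += gene_len + spacing
        contigs.append(Contig(contig_id, pos, circular))
    genome = GenomeRecord(genome_id, genome_id, contigs, feats)
    genome.validate()
    return genome, hits


def random_marker_genome(rng, genome_id="rg"):
    """A random feature-level genome: markers + background on one contig.

    Returns (genome, hits).  Used by invariance and oracle property tests.
    """
    n_markers = int(rng.integers(1, 9))
    n_background = int(rng.integers(0, 32))
    families = list("ABCDEF")
    entries = [(None, 1)] * n_background
    slots = sorted(rng.choice(len(entries) + 1, size=n_markers, replace=True).tolist())
    for k, slot in enumerate(slots):
        fam = families[int(rng.integers(len(families)))]
        strand = 1 if rng.random() < 0.5 else -1
        entries.insert(min(slot + k, len(entries)), (fam, strand))
    circular = bool(rng.random() < 0.5)
    spacing = int(rng.integers(50, 400))
    return build_genome(
        entries, circular=circular, genome_id=genome_id, spacing=spacing,
        tail=int(rng.integers(0, 2000)),
    )
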