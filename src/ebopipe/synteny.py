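"""Genomic clustering of marker genes and operon-architecture classification.

Marker hits are chained along the gene order of each contig (single
linkage: two markers join one cluster when at most ``max_intervening``
non-marker genes and at most ``max_gap_bp`` nucleotides separate them; on
circular contigs the chaining runs on the ring and a cluster may wrap the
origin).  Each cluster is summarized as a canonical architecture string:

* one letter per member in reading order (the family code),
* lowercase for members antisense to the cluster's majority strand,
* ``+k`` for a run of k non-marker genes inserted between members,
* reading direction normalized so the majority strand reads forward
  (reverse-complementing a genome never changes the string); exact strand
  ties resolve to the lexicographically smaller of the two readings,
* wrapped clusters rotated to start after the largest inter-member gap.

Genomes are then classified as a single operon (one cluster, every panel
family present, uniform strand), a co-clustered arrangement with mixed
strands, a split cluster, partial (at least one family missing genome-wide)
or absent.  String grammar version: 1 (recorded in table headers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import GeneFeature, GenomeRecord, gene_order
from .markers import MarkerFamily, MarkerHit

GRAMMAR_VERSION = 1

DEFAULT_MAX_INTERVENING = 3
DEFAULT_MAX_GAP_BP = 5000
DEFAULT_EDGE_RANK = 2

CLASSES = ("single_operon", "co_clustered_mixed_strand", "split_cluster", "partial", "absent")
VARIANTS = ("eboA_type", "eboG_type", "both", "neither")


@dataclass
class ClusterMember:
    family: str
    strand: int
    gene_id: str
    rank: int


@dataclass
class ClusterCall:
    """One chained run of marker genes on a contig."""

    contig_id: str
    members: list[ClusterMember]
    intervening: list[list[str]]  # gene ids between successive members
    span_bp: int
    wrapped: bool = False
    edge_flags: str = "none"  # left_edge | right_edge | both | none
    n_genes_on_contig: int = 0
    circular_contig: bool = False

    @property
    def families(self) -> set[str]:
        return {m.family for m in self.members}

    @property
    def strands(self) -> set[int]:
        return {m.strand for m in self.members}


@dataclass
class ArchitectureCall:
    """Per-genome structured verdict on the marker-cluster architecture."""

    genome_id: str
    taxon: str
    clusters: list[ClusterCall]
    canonical_strings: list[str]
    arch_class: str
    variant: str
    detached_paralogs: list[tuple[str, str]]  # (family, gene_id)
    missing_families: list[str]
    assembly_gap_suspected: bool = False


# ---------------------------------------------------------------------------
# Clustering


def _gap_bp(a: GeneFeature, b: GeneFeature, contig_length: int, circular: bool) -> int:
    """Nucleotide gap from feature a to the next-ranked feature b (>= 0)."""
    a_end = a.end if not a.wrapped else a.end  # wrapped feature ends at a.end
    if not circular:
        return max(0, b.start - a_end)
    gap = (b.start - a_end) % contig_length
    # adjacent/overlapping features can yield a near-full-circle modular
    # value; treat anything overlapping as touching
    if gap > contig_length - max(a.span(contig_length), 1):
        return 0
    return gap


def cluster_markers(
    genome: GenomeRecord,
    hits: Iterable[MarkerHit],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[ClusterCall]:
    """Chain labelled marker hits into clusters along the gene order.

    Two markers adjacent in marker rank order join one cluster iff both the
    count of non-marker genes between them is <= ``max_intervening`` and
    their nucleotide gap is <= ``max_gap_bp``.  Singleton hits form
    singleton clusters.  On circular contigs chaining runs on the ring.
    """
    gene_ids = {f.gene_id for f in genome.features}
    by_gene: dict[str, MarkerHit] = {}
    for h in hits:
        if getattr(h, "status", "labelled") != "labelled":
            continue
        if h.gene_id not in gene_ids:
            raise ValueError(
                f"hit {h.gene_id!r} references no gene of genome {genome.genome_id!r}"
            )
        by_gene[h.gene_id] = h

    calls: list[ClusterCall] = []
    for contig in genome.contigs:
        order = gene_order(genome, contig.id)
        n = len(order)
        marker_ranks = [i for i, f in enumerate(order) if f.gene_id in by_gene]
        if not marker_ranks:
            continue
        m = len(marker_ranks)

        def pair_linked(ra: int, rb: int) -> bool:
            between = (rb - ra - 1) % n if contig.circular else rb - ra - 1
            gap = _gap_bp(order[ra], order[rb], contig.length, contig.circular)
            return between <= max_intervening and gap <= max_gap_bp

        linked = [pair_linked(marker_ranks[i], marker_ranks[i + 1]) for i in range(m - 1)]
        closes = (
            contig.circular and m > 1
            and pair_linked(marker_ranks[-1], marker_ranks[0])
        )

        groups: list[list[int]] = [[marker_ranks[0]]]
        for idx in range(m - 1):
            if linked[idx]:
                groups[-1].append(marker_ranks[idx + 1])
            else:
                groups.append([marker_ranks[idx + 1]])

        wrapped_idx = -1
        if closes and len(groups) > 1:
            # ring closure: the last group continues into the first across
            # the origin -> one cluster whose ranks cross the origin
            last = groups.pop()
            groups[0] = last + groups[0]
            wrapped_idx = 0
        elif closes and len(groups) == 1:
            # every inter-marker junction chains: the cluster is the whole
            # marker ring; rotate to start after the largest bp gap
            groups[0] = _rotate_ring(order, groups[0], contig.length)
            wrapped_idx = 0

        for gi, group in enumerate(groups):
            calls.append(
                _make_call(contig, order, group, by_gene, wrapped=(gi == wrapped_idx))
            )
    return calls


def _rotate_ring(order, ranks: list[int], contig_length: int) -> list[int]:
    """Rotate a whole-ring marker cluster to start after its largest gap.

    Ties on the bp gap resolve to the candidate start member with the
    smallest gene_id, which is invariant under contig rotation.
    """
    m = len(ranks)
    if m == 1:
        return ranks
    best = None
    for i in range(m):
        a, b = order[ranks[i]], order[ranks[(i + 1) % m]]
        gap = _gap_bp(a, b, contig_length, True)
        key = (-gap, b.gene_id)
        if best is None or key < best[0]:
            best = (key, (i + 1) % m)
    start = best[1]
    return ranks[start:] + ranks[:start]


def _make_call(
    contig, order, ranks: list[int], by_gene, wrapped: bool
) -> ClusterCall:
    n = len(order)
    members = []
    for r in ranks:
        f = order[r]
        members.append(ClusterMember(by_gene[f.gene_id].family, f.strand, f.gene_id, r))
    intervening: list[list[str]] = []
    for a, b in zip(ranks[:-1], ranks[1:]):
        if contig.circular:
            between = [(a + k + 1) % n for k in range((b - a - 1) % n)]
        else:
            between = list(range(a + 1, b))
        intervening.append([order[i].gene_id for i in between])
    first, last = order[ranks[0]], order[ranks[-1]]
    if contig.circular:
        span = (last.end - first.start) % contig.length
        if span == 0 and len(ranks) > 0:
            span = contig.length if len(ranks) > 1 else first.span(contig.length)
    else:
        span = last.end - first.start
    edge = "none"
    if not contig.circular:
        left = ranks[0] <= DEFAULT_EDGE_RANK
        right = (n - 1 - ranks[-1]) <= DEFAULT_EDGE_RANK
        edge = "both" if left and right else "left_edge" if left else "right_edge" if right else "none"
    return ClusterCall(
        contig_id=contig.id,
        members=members,
        intervening=intervening,
        span_bp=span,
        wrapped=wrapped or (len(ranks) > 1 and ranks != sorted(ranks)),
        edge_flags=edge,
        n_genes_on_contig=n,
        circular_contig=contig.circular,
    )


# ---------------------------------------------------------------------------
# Canonical architecture strings


def _reading(members: list[ClusterMember], gaps: list[int], reverse: bool) -> str:
    """Render one reading direction of a cluster as a string."""
    if reverse:
        members = members[::-1]
        gaps = gaps[::-1]
        sense = -1
    else:
        sense = 1
    tokens = []
    for i, mem in enumerate(members):
        if i > 0 and gaps[i - 1] > 0:
            tokens.append(f"+{gaps[i - 1]}")
        code = mem.family
        code = code.upper() if mem.strand == sense else code.lower()
        tokens.append(code)
    return "".join(tokens)


def architecture_string(cluster: ClusterCall) -> str:
    """Canonical string for a cluster (see module docstring for the grammar)."""
    if not cluster.members:
        raise ValueError("empty cluster")
    members = list(cluster.members)
    gaps = [len(g) for g in cluster.intervening]
    n_minus = sum(1 for m in members if m.strand == -1)
    n_plus = len(members) - n_minus
    if n_minus > n_plus:
        return _reading(members, gaps, reverse=True)
    if n_plus > n_minus:
        return _reading(members, gaps, reverse=False)
    return min(_reading(members, gaps, False), _reading(members, gaps, True))


def longest_uniform_strand_run(cluster: ClusterCall) -> int:
    """Length of the longest run of consecutive members on one strand.

    The size of the largest sub-arrangement that could still be one
    transcription unit inside a mixed-strand cluster.
    """
    if not cluster.members:
        return 0
    best = cur = 1
    for a, b in zip(cluster.members[:-1], cluster.members[1:]):
        cur = cur + 1 if a.strand == b.strand else 1
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# Classification


def classify(
    genome: GenomeRecord,
    clusters: list[ClusterCall],
    panel: Sequence[MarkerFamily] | Sequence[str],
) -> ArchitectureCall:
    """Assign the per-genome architecture class.

    Classes, tested in order: ``absent`` (no labelled hits);
    ``single_operon`` (every panel family in one uniform-strand cluster);
    ``co_clustered_mixed_strand`` (one cluster, all families present, but
    members on both strands); ``split_cluster`` (all families present but
    spread over >=2 clusters); ``partial`` (>=1 family missing
    genome-wide).  A singleton copy of a family that also occurs inside a
    multi-member cluster is reported as a detached paralog rather than as a
    cluster of its own.
    """
    codes = [f.code if isinstance(f, MarkerFamily) else str(f) for f in panel]
    clusters = sorted(
        clusters,
        key=lambda c: (c.contig_id, min(m.gene_id for m in c.members) if c.members else ""),
    )
    multi = [c for c in clusters if len(c.members) > 1]
    in_multi = {m.family for c in multi for m in c.members}
    detached: list[tuple[str, str]] = []
    kept: list[ClusterCall] = []
    for c in clusters:
        if len(c.members) == 1 and c.members[0].family in in_multi:
            detached.append((c.members[0].family, c.members[0].gene_id))
        else:
            kept.append(c)

    present = {m.family for c in kept for m in c.members} | {f for f, _ in detached}
    missing = sorted(c for c in codes if c not in present)
    # the A/G accessory genes are mutually exclusive operon variants: a
    # genome carrying one of them is not "partial" for lacking the other
    if "A" in codes and "G" in codes and ("A" in present or "G" in present):
        missing = [c for c in missing if c not in ("A", "G")]

    if not present:
        arch_class = "absent"
    elif missing:
        arch_class = "partial"
    elif len(kept) == 1:
        arch_class = (
            "single_operon" if len(kept[0].strands) == 1 else "co_clustered_mixed_strand"
        )
    else:
        arch_class = "split_cluster"

    if "A" in present and "G" in present:
        variant = "both"
    elif "A" in present:
        variant = "eboA_type"
    elif "G" in present:
        variant = "eboG_type"
    else:
        variant = "neither"

    return ArchitectureCall(
        genome_id=genome.genome_id,
        taxon=genome.taxon or genome.genome_id,
        clusters=kept,
        canonical_strings=[architecture_string(c) for c in kept],
        arch_class=arch_class,
        variant=variant,
        detached_paralogs=sorted(detached),
        missing_families=sorted(missing),
    )


def flag_assembly_gap(
    call: ArchitectureCall,
    genome: GenomeRecord,
    edge_rank: int = DEFAULT_EDGE_RANK,
) -> ArchitectureCall:
    """Suspect an assembly gap when a family is missing and a cluster sits
    within ``edge_rank`` gene ranks of a linear-contig end.

    Circular contigs have no ends and never trigger the flag.
    """
    suspected = False
    if call.missing_families:
        for c in call.clusters:
            if c.circular_contig or not c.members:
                continue
            ranks = [m.rank for m in c.members]
            n = c.n_genes_on_contig
            if min(ranks) <= edge_rank or (n - 1 - max(ranks)) <= edge_rank:
                suspected = True
                break
    call.assembly_gap_suspected = suspected
    return call


# ---------------------------------------------------------------------------
# Tables and JSON


def architecture_table(
    calls: Iterable[ArchitectureCall],
    panel: Sequence[MarkerFamily] | Sequence[str] = "ABCDEFG",
) -> pd.DataFrame:
    """One row per genome, the machine-readable architecture survey."""
    codes = [f.code if isinstance(f, MarkerFamily) else str(f) for f in panel]
    rows = []
    for call in sorted(calls, key=lambda c: c.genome_id):
        gene_by_family: dict[str, list[str]] = {c: [] for c in codes}
        for cl in call.clusters:
            for m in cl.members:
                gene_by_family.setdefault(m.family, []).append(m.gene_id)
        for fam, gid in call.detached_paralogs:
            gene_by_family.setdefault(fam, []).append(f"{gid}*")
        row = {"genome_id": call.genome_id, "taxon": call.taxon}
        for c in codes:
            row[f"gene_{c}"] = ";".join(gene_by_family.get(c, [])) or "-"
        row["architecture"] = ";".join(call.canonical_strings) or "-"
        row["class"] = call.arch_class
        row["variant"] = call.variant
        row["missing"] = ";".join(call.missing_families) or "-"
        row["assembly_gap_suspected"] = str(call.assembly_gap_suspected).lower()
        rows.append(row)
    cols = (
        ["genome_id", "taxon"]
        + [f"gene_{c}" for c in codes]
        + ["architecture", "class", "variant", "missing", "assembly_gap_suspected"]
    )
    return pd.DataFrame(rows, columns=cols)


def write_architecture_table(
    calls: Iterable[ArchitectureCall],
    path: str | Path,
    panel: Sequence[MarkerFamily] | Sequence[str] = "ABCDEFG",
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# architecture-string grammar v{GRAMMAR_VERSION}\n")
        architecture_table(calls, panel).to_csv(fh, sep="\t", index=False)


def read_architecture_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def call_to_json(call: ArchitectureCall) -> dict:
    return {
        "genome_id": call.genome_id,
        "taxon": call.taxon,
        "class": call.arch_class,
        "variant": call.variant,
        "canonical_strings": call.canonical_strings,
        "missing_families": call.missing_families,
        "assembly_gap_suspected": call.assembly_gap_suspected,
        "detached_paralogs": [list(d) for d in call.detached_paralogs],
        "clusters": [
            {
                "contig_id": c.contig_id,
                "wrapped": c.wrapped,
                "span_bp": c.span_bp,
                "edge_flags": c.edge_flags,
                "members": [
                    {
                        "family": m.family,
                        "strand": m.strand,
                        "gene_id": m.gene_id,
                        "rank": m.rank,
                    }
                    for m in c.members
                ],
                "intervening": c.intervening,
            }
            for c in call.clusters
        ],
    }


def write_calls_json(calls: Iterable[ArchitectureCall], path: str | Path) -> None:
    payload = {
        "grammar_version": GRAMMAR_VERSION,
        "calls": [call_to_json(c) for c in sorted(calls, key=lambda c: c.genome_id)],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
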