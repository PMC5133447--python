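"""Alignment trimming, paralog selection and partitioned concatenation.

The trimming step is a compact conserved-block filter in the Gblocks
tradition: a column is kept when it is conserved (most frequent residue at
or above ``min_conserved`` of rows and gap fraction at most
``max_gap_frac``), blocks of conserved columns must reach ``min_block``
columns, and each block is anchored by highly conserved (``min_flank``)
terminal columns.  The defaults encode the relaxed "allow gaps in up to
half the sequences" regime that keeps the maximal number of positions;
column-for-column parity with any external trimmer is a non-goal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO

GAP = "-"


@dataclass
class Alignment:
    """A per-family protein alignment: taxa and equal-length gapped rows."""

    family: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"alignment {self.family!r}: taxa/rows mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment {self.family!r}: unequal row lengths {lengths}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def read_alignment_fasta(path: str | Path, family: str | None = None) -> Alignment:
    aln = AlignIO.read(str(path), "fasta")
    return Alignment(
        family=family or Path(path).stem,
        taxa=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
    )


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


# ---------------------------------------------------------------------------
# Conserved-block trimming


def _column_class(column: str, min_conserved: float, min_flank: float,
                  max_gap_frac: float) -> int:
    """0 = rejected, 1 = conserved, 2 = highly conserved."""
    n = len(column)
    gaps = column.count(GAP) + column.count(".")
    residues = [c for c in column if c not in (GAP, ".")]
    if not residues or gaps / n > max_gap_frac:
        return 0
    top = Counter(residues).most_common(1)[0][1]
    freq = top / n
    if freq >= min_flank:
        return 2
    if freq >= min_conserved:
        return 1
    return 0


def trim_blocks(
    aln: Alignment,
    min_conserved: float = 0.5,
    min_flank: float = 0.85,
    max_gap_frac: float = 0.5,
    min_block: int = 5,
) -> tuple[Alignment, list[int]]:
    """Keep maximal runs of conserved columns anchored by conserved flanks.

    Returns the trimmed alignment and the (strictly increasing) kept column
    indices.  Idempotent: trimming a trimmed alignment changes nothing.
    """
    if not aln.rows or len(aln.rows) < 2:
        raise ValueError("trim_blocks needs an alignment with at least 2 rows")
    classes = [
        _column_class(aln.column(j), min_conserved, min_flank, max_gap_frac)
        for j in range(aln.n_columns)
    ]
    kept: list[int] = []
    j = 0
    while j < len(classes):
        if classes[j] == 0:
            j += 1
            continue
        k = j
        while k < len(classes) and classes[k] > 0:
            k += 1
        run = list(range(j, k))
        # anchor the run on highly conserved terminal columns
        while run and classes[run[0]] != 2:
            run.pop(0)
        while run and classes[run[-1]] != 2:
            run.pop()
        if len(run) >= min_block:
            kept.extend(run)
        j = k
    trimmed = Alignment(
        family=aln.family,
        taxa=list(aln.taxa),
        rows=["".join(r[j] for j in kept) for r in aln.rows],
    )
    return trimmed, kept


# ---------------------------------------------------------------------------
# Paralog selection


def select_paralogs(
    hits: Iterable,
    calls: Iterable,
) -> tuple[dict[tuple[str, str], str], list[dict]]:
    """Pick one gene per (taxon, family) among paralogous marker copies.

    Preference order: (1) a copy inside a multi-member cluster, (2) higher
    bit score, (3) lexicographically smaller gene id.  Returns the chosen
    gene per key plus a report of every discarded copy (with a note when
    the in-cluster rule actually overrode the score ranking).
    """
    in_cluster: dict[str, set[str]] = {}
    taxon_of: dict[str, str] = {}
    for call in calls:
        taxon_of[call.genome_id] = call.taxon
        genes = {
            m.gene_id
            for cl in call.clusters
            if len(cl.members) > 1
            for m in cl.members
        }
        in_cluster[call.genome_id] = genes

    candidates: dict[tuple[str, str], list] = {}
    for h in hits:
        if getattr(h, "status", "labelled") != "labelled":
            continue
        taxon = taxon_of.get(h.genome_id, h.genome_id)
        candidates.setdefault((taxon, h.family), []).append(h)

    chosen: dict[tuple[str, str], str] = {}
    discarded: list[dict] = []
    for key in sorted(candidates):
        cands = candidates[key]
        def pref(h):
            inside = h.gene_id in in_cluster.get(h.genome_id, set())
            return (0 if inside else 1, -h.bit_score, h.gene_id)
        ranked = sorted(cands, key=pref)
        best = ranked[0]
        chosen[key] = best.gene_id
        by_score = min(cands, key=lambda h: (-h.bit_score, h.gene_id))
        for h in ranked[1:]:
            discarded.append(
                {
                    "taxon": key[0],
                    "family": key[1],
                    "gene_id": h.gene_id,
                    "bit_score": h.bit_score,
                    "kept": best.gene_id,
                    "cluster_rule_decisive": by_score.gene_id != best.gene_id,
                }
            )
    return chosen, discarded


# ---------------------------------------------------------------------------
# Concatenation


@dataclass
class Supermatrix:
    """Concatenated per-family alignments with 1-based inclusive partitions."""

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (family, start, end)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def concatenate(
    alignments: Sequence[Alignment],
    taxa: Sequence[str] | None = None,
) -> Supermatrix:
    """Concatenate per-family alignments; absent taxa are gap-padded.

    Family order is the input order; partitions are recorded 1-based
    inclusive.  A taxon duplicated within one family is an error.
    """
    for aln in alignments:
        if len(set(aln.taxa)) != len(aln.taxa):
            dup = sorted({t for t in aln.taxa if aln.taxa.count(t) > 1})
            raise ValueError(f"alignment {aln.family!r}: duplicate taxa {dup}")
    if taxa is None:
        seen: list[str] = []
        for aln in alignments:
            for t in aln.taxa:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for aln in alignments:
        width = aln.n_columns
        lookup = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            rows[t].append(lookup.get(t, GAP * width))
        partitions.append((aln.family, offset + 1, offset + width))
        offset += width
    return Supermatrix(
        taxa=list(taxa),
        rows=["".join(rows[t]) for t in taxa],
        partitions=partitions,
    )


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: full taxon names, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.n_columns}\n")
        width = max((len(t) for t in sm.taxa), default=0)
        for taxon, row in zip(sm.taxa, sm.rows):
            fh.write(f"{taxon.ljust(width)}  {row}\n")


def write_partitions(sm: Supermatrix, path: str | Path, style: str = "raxml") -> None:
    """Partition definitions: RAxML lines or a NEXUS sets block."""
    if style == "raxml":
        lines = [f"PROT, {fam} = {start}-{end}" for fam, start, end in sm.partitions]
        text = "\n".join(lines) + "\n"
    elif style == "nexus":
        lines = ["#NEXUS", "begin sets;"]
        lines += [
            f"    charset {fam} = {start}-{end};" for fam, start, end in sm.partitions
        ]
        lines += ["end;"]
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown partition style {style!r}")
    Path(path).write_text(text)


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    """Re-parse a RAxML-style partition file (round-trip counterpart)."""
    parts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or not line.upper().startswith("PROT"):
            continue
        _, rest = line.split(",", 1)
        name, span = rest.split("=")
        start, end = span.strip().split("-")
        parts.append((name.strip(), int(start), int(end)))
    return parts
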