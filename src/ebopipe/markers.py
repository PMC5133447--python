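"""Marker-family assignment by local protein alignment.

Each annotated gene is scored against a panel of marker families (e.g. the
six-gene ebo panel, eboA-eboF, optionally the eboG accessory variant) with
affine-gap Smith-Waterman local alignment under BLOSUM62, and labelled with
the best-scoring family when it clears bit-score, seed-coverage and
best-vs-second-family margin thresholds.  Precomputed BLAST tabular
(outfmt 6) hits can be imported through the same selection rules.

Raw scores are converted to bit scores with fixed Karlin-Altschul constants
for gapped BLOSUM62/11/1 (lambda=0.267, K=0.041); only ranking and
thresholding depend on them, not any downstream statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, gene_order

LAMBDA = 0.267
K = 0.041

#: The 20 canonical amino acids; everything else is masked to X, and X
#: scores 0 against every residue.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_MIN_BITS = 50.0
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_MIN_MARGIN = 10.0

HIT_COLUMNS = [
    "genome_id", "gene_id", "family", "raw_score", "bit_score", "expect",
    "identity", "coverage", "margin", "status",
]


@dataclass
class MarkerFamily:
    """A marker family: single-letter code plus >=1 seed protein."""

    code: str
    seeds: list[tuple[str, str]]  # (seed_id, protein sequence)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError(f"family {self.code!r}: at least one seed required")


@dataclass
class MarkerHit:
    """A gene assigned (or near-assigned) to a marker family."""

    genome_id: str
    gene_id: str
    family: str
    raw_score: int
    bit_score: float
    expect: float
    identity: float
    coverage: float
    margin: float
    status: str = "labelled"  # labelled | ambiguous | partial


@dataclass
class LocalAlignment:
    raw_score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float
    n_columns: int


def sanitize(seq: str) -> str:
    """Uppercase and mask non-canonical residues (B, Z, U, O, *, ...) to X."""
    return "".join(c if c in AA20 else "X" for c in seq.upper())


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    """A substitution matrix with the X (mask) row/column zeroed."""
    m = substitution_matrices.load(name)
    if "X" in m.alphabet:
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(matrix)
    # BLAST convention: a gap of length k costs gap_open + k * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_score(query: str, target: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score only (no traceback; fast path)."""
    if not query or not target:
        raise ValueError("empty sequence")
    score = _aligner(matrix, gap_open, gap_extend).score(sanitize(query), sanitize(target))
    return int(round(score))


def local_align(query: str, target: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> LocalAlignment:
    """Optimal affine-gap local alignment (Smith-Waterman-Gotoh).

    Returns the raw score, the aligned spans on both sequences (0-based
    half-open) and the fraction of identical alignment columns.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    q, t = sanitize(query), sanitize(target)
    aln = _aligner(matrix, gap_open, gap_extend).align(q, t)[0]
    counts = aln.counts()
    qa, ta = aln.aligned
    return LocalAlignment(
        raw_score=int(round(aln.score)),
        query_start=int(qa[0][0]),
        query_end=int(qa[-1][1]),
        target_start=int(ta[0][0]),
        target_end=int(ta[-1][1]),
        identity=counts.identities / aln.length if aln.length else 0.0,
        n_columns=aln.length,
    )


def bit_score(raw: float, lambda_: float = LAMBDA, k: float = K) -> float:
    """Normalized score in bits: S' = (lambda * S - ln K) / ln 2."""
    if lambda_ <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    return (lambda_ * raw - math.log(k)) / math.log(2)


def expect(bits: float, m: int, n: int) -> float:
    """E-value for a bit score over a search space of m x n residues."""
    return m * n * 2.0 ** (-bits)


# ---------------------------------------------------------------------------
# Panels


def read_panel(path: str | Path) -> list[MarkerFamily]:
    """Read a marker panel from one multi-FASTA with ``CODE|seedid`` headers."""
    from Bio import SeqIO

    seeds_by_code: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"{path}: header {rec.id!r} lacks the 'CODE|seedid' family prefix"
            )
        code, seed_id = rec.id.split("|", 1)
        seeds_by_code.setdefault(code, []).append((seed_id, str(rec.seq)))
    if not seeds_by_code:
        raise ValueError(f"{path}: empty panel")
    return [
        MarkerFamily(code=c, seeds=seeds_by_code[c], name=c)
        for c in sorted(seeds_by_code)
    ]


def write_panel(panel: Sequence[MarkerFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in panel:
            for seed_id, seq in fam.seeds:
                fh.write(f">{fam.code}|{seed_id}\n{seq}\n")


def _seed_index(panel: Sequence[MarkerFamily]) -> dict[str, tuple[str, str]]:
    """seed_id -> (family code, sequence); also maps 'CODE|seed_id' keys."""
    idx: dict[str, tuple[str, str]] = {}
    for fam in panel:
        for seed_id, seq in fam.seeds:
            idx[seed_id] = (fam.code, seq)
            idx[f"{fam.code}|{seed_id}"] = (fam.code, seq)
    return idx


def _check_panel(panel: Sequence[MarkerFamily]) -> None:
    if not panel:
        raise ValueError("empty marker panel")
    codes = [f.code for f in panel]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate family codes in panel: {codes}")


# ---------------------------------------------------------------------------
# Assignment


def _resolve(genome_id: str, gene_id: str,
             scored: list[tuple[float, int, float, float, str]],
             min_bits: float, min_coverage: float, min_margin: float,
             ) -> MarkerHit | None:
    """Apply the best-family / threshold / margin rule to per-family scores.

    `scored`: (bit_score, raw, identity, coverage, family) per family,
    best seed only.  Returns None when nothing reaches ``min_bits``.
    """
    scored = sorted(scored, key=lambda s: (-s[0], s[4]))
    best = scored[0]
    if best[0] < min_bits:
        return None
    margin = best[0] - scored[1][0] if len(scored) > 1 else math.inf
    bits, raw, ident, cov, fam = best
    if cov < min_coverage:
        status = "partial"
    elif margin < min_margin:
        status = "ambiguous"
    else:
        status = "labelled"
    return MarkerHit(
        genome_id=genome_id, gene_id=gene_id, family=fam, raw_score=raw,
        bit_score=bits, expect=math.nan, identity=ident, coverage=cov,
        margin=margin, status=status,
    )


def assign_markers(
    genome: GenomeRecord,
    panel: Sequence[MarkerFamily],
    min_bits: float = DEFAULT_MIN_BITS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_margin: float = DEFAULT_MIN_MARGIN,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[MarkerHit]:
    """Label genes with marker families by best-seed local alignment.

    A gene is ``labelled`` with its best family iff the bit score reaches
    ``min_bits``, the best seed is covered to ``min_coverage`` and the gap
    to the second-best family is at least ``min_margin`` bits.  Fragments
    failing coverage are recorded as ``partial``; near-ties between
    families as ``ambiguous`` (mimicking manual curation of uncertain
    homologues).  Multiple genes per family are allowed (paralogs).
    Deterministic and invariant to input feature order.
    """
    _check_panel(panel)
    hits: list[MarkerHit] = []
    ordered = []
    for contig in genome.contigs:
        ordered.extend(gene_order(genome, contig.id))
    for feat in ordered:
        if feat.translation is None:
            continue
        prot = sanitize(feat.translation)
        if not prot:
            continue
        scored = []
        for fam in panel:
            best_raw, best_seed = -1, None
            for seed_id, seed in fam.seeds:
                raw = local_score(seed, prot, matrix, gap_open, gap_extend)
                if raw > best_raw:
                    best_raw, best_seed = raw, seed
            bits = bit_score(best_raw)
            scored.append((bits, best_raw, best_seed, fam.code))
        scored.sort(key=lambda s: (-s[0], s[3]))
        if scored[0][0] < min_bits:
            continue
        bits, raw, seed, code = scored[0]
        aln = local_align(seed, prot, matrix, gap_open, gap_extend)
        coverage = (aln.query_end - aln.query_start) / len(sanitize(seed))
        hit = _resolve(
            genome.genome_id, feat.gene_id,
            [(bits, raw, aln.identity, coverage, code)]
            + [(b, r, 0.0, 0.0, c) for b, r, _s, c in scored[1:]],
            min_bits, min_coverage, min_margin,
        )
        if hit is not None:
            hit.expect = expect(hit.bit_score, len(seed), len(prot))
            hits.append(hit)
    return hits


def import_hits_tsv(
    path: str | Path,
    panel: Sequence[MarkerFamily],
    min_bits: float = DEFAULT_MIN_BITS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_margin: float = DEFAULT_MIN_MARGIN,
    genome_id: str = "",
) -> list[MarkerHit]:
    """Import BLAST tabular (outfmt 6) hits through the assignment rules.

    Query ids must be panel seed ids (bare or ``CODE|seedid``); subject ids
    are gene ids.  Per gene, the best row per family feeds the same
    best-family / threshold / margin selection as :func:`assign_markers`.
    """
    _check_panel(panel)
    idx = _seed_index(panel)
    per_gene: dict[str, dict[str, tuple[float, int, float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns "
                    f"(BLAST outfmt 6), found {len(cols)}"
                )
            qseqid, sseqid = cols[0], cols[1]
            if qseqid not in idx:
                raise ValueError(
                    f"{path}:{lineno}: query id {qseqid!r} is not a panel seed id"
                )
            fam, seed = idx[qseqid]
            pident = float(cols[2]) / 100.0
            qstart, qend = int(cols[6]), int(cols[7])
            bits = float(cols[11])
            coverage = (qend - qstart + 1) / len(seed)
            raw = int(round((bits * math.log(2) + math.log(K)) / LAMBDA))
            fams = per_gene.setdefault(sseqid, {})
            if fam not in fams or bits > fams[fam][0]:
                fams[fam] = (bits, raw, pident, coverage)
    hits = []
    for gene_id in sorted(per_gene):
        scored = [
            (bits, raw, ident, cov, fam)
            for fam, (bits, raw, ident, cov) in per_gene[gene_id].items()
        ]
        hit = _resolve(genome_id, gene_id, scored, min_bits, min_coverage, min_margin)
        if hit is not None:
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Hit tables


def hits_table(hits: Iterable[MarkerHit]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": h.genome_id, "gene_id": h.gene_id, "family": h.family,
            "raw_score": h.raw_score, "bit_score": round(h.bit_score, 2),
            "expect": h.expect, "identity": round(h.identity, 4),
            "coverage": round(h.coverage, 4),
            "margin": h.margin if math.isfinite(h.margin) else math.inf,
            "status": h.status,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(hits: Iterable[MarkerHit], path: str | Path) -> None:
    hits_table(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[MarkerHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerHit(
            genome_id=str(r.genome_id), gene_id=str(r.gene_id), family=str(r.family),
            raw_score=int(r.raw_score), bit_score=float(r.bit_score),
            expect=float(r.expect), identity=float(r.identity),
            coverage=float(r.coverage), margin=float(r.margin), status=str(r.status),
        )
        for r in df.itertuples()
    ]
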