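"""Normalized annotated-genome model with GenBank and GFF3+FASTA readers.

All coordinates are 0-based half-open internally; the 1-based inclusive
conventions of GenBank and GFF3 are converted at the boundary.  Features on
circular contigs may wrap the replication origin, in which case
``start > end`` and the feature span is ``(length - start) + end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import BiopythonWarning, SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: GenBank/GFF3 feature types kept with their own kind; everything else
#: (except structural records like ``source``/``gene``/``region``) is ``other``.
KINDS = ("CDS", "rRNA", "tRNA", "other")

#: Default genetic code: bacterial/plastid (NCBI translation table 11).
DEFAULT_TABLE = 11

_SKIP_TYPES = {"source", "gene", "region", "exon", "mRNA", "chromosome", "intron"}


@dataclass
class Contig:
    """A replicon (chromosome, plasmid, contig or scaffold)."""

    id: str
    length: int
    circular: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id!r}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class GeneFeature:
    """A strand-aware gene feature in 0-based half-open coordinates.

    ``start > end`` encodes a feature wrapping the origin of a circular
    contig; :meth:`span` handles the modular arithmetic.
    """

    contig_id: str
    start: int
    end: int
    strand: int
    gene_id: str
    label: str = ""
    kind: str = "CDS"
    translation: str | None = None
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"feature {self.gene_id!r}: strand must be +1 or -1")
        if self.kind not in KINDS:
            raise ValueError(f"feature {self.gene_id!r}: unknown kind {self.kind!r}")
        if self.start == self.end:
            raise ValueError(f"feature {self.gene_id!r}: empty interval")

    @property
    def wrapped(self) -> bool:
        return self.start > self.end

    def span(self, contig_length: int | None = None) -> int:
        """Feature length in bp; needs ``contig_length`` when wrapped."""
        if not self.wrapped:
            return self.end - self.start
        if contig_length is None:
            raise ValueError(
                f"feature {self.gene_id!r} wraps the origin; contig length required"
            )
        return (contig_length - self.start) + self.end


@dataclass
class GenomeRecord:
    """An annotated genome: contigs plus gene features."""

    genome_id: str
    taxon: str
    contigs: list[Contig] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"genome {self.genome_id!r}: no contig {contig_id!r}")

    def validate(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.genome_id!r}: duplicate contig ids")
        gids = [f.gene_id for f in self.features]
        if len(set(gids)) != len(gids):
            dup = sorted({g for g in gids if gids.count(g) > 1})
            raise ValueError(f"genome {self.genome_id!r}: duplicate gene ids {dup}")
        by_id = {c.id: c for c in self.contigs}
        for f in self.features:
            if f.contig_id not in by_id:
                raise ValueError(
                    f"feature {f.gene_id!r} references unknown contig {f.contig_id!r}"
                )
            c = by_id[f.contig_id]
            if f.wrapped:
                if not c.circular:
                    raise ValueError(
                        f"feature {f.gene_id!r} wraps but contig {c.id!r} is linear"
                    )
            elif not (0 <= f.start < f.end <= c.length):
                raise ValueError(
                    f"feature {f.gene_id!r}: interval [{f.start},{f.end}) outside "
                    f"contig {c.id!r} of length {c.length}"
                )


def translate_cds(nt: str, table: int = DEFAULT_TABLE) -> str:
    """Translate a CDS nucleotide string; ambiguous codons become X.

    A trailing stop is stripped; internal stops (pseudogenes, frame shifts)
    are kept as ``*`` so that downstream scoring sees the break.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        aa = str(Seq(nt).translate(table=table))
    return aa[:-1] if aa.endswith("*") else aa


def feature_nt(feature: GeneFeature, contig: Contig) -> str:
    """Extract the sense-strand nucleotide sequence of a feature."""
    if contig.sequence is None:
        raise ValueError(f"contig {contig.id!r} has no sequence")
    if feature.wrapped:
        nt = contig.sequence[feature.start :] + contig.sequence[: feature.end]
    else:
        nt = contig.sequence[feature.start : feature.end]
    if feature.strand == -1:
        nt = str(Seq(nt).reverse_complement())
    return nt


# ---------------------------------------------------------------------------
# GenBank


def _convert_location(loc, contig_length: int, circular: bool) -> tuple[int, int]:
    """Collapse a Biopython location to (start, end), wrapping when needed."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        first, last = parts[0], parts[-1]
        if circular and int(last.end) == contig_length and int(first.start) == 0:
            # join(X..length,1..Y) spanning the origin -> one wrapped feature
            return int(last.start), int(first.end)
        return int(loc.start), int(loc.end)
    return int(loc.start), int(loc.end)


def read_genbank(
    path: str | Path,
    genome_id: str | None = None,
    table: int = DEFAULT_TABLE,
) -> GenomeRecord:
    """Read a GenBank flat file into the normalized genome model.

    GenBank's 1-based inclusive coordinates become 0-based half-open;
    circularity comes from the LOCUS topology token; ``join()`` features
    spanning the origin of a circular contig become a single wrapped
    feature.  CDS translations are taken from the record when present and
    otherwise translated with `table` (default: bacterial/plastid code).
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"{path}: malformed GenBank record: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no GenBank records found (missing LOCUS line?)")

    gid = genome_id or path.stem
    taxon = records[0].annotations.get("organism", "") or ""
    genome = GenomeRecord(genome_id=gid, taxon=taxon)
    seen_ids: set[str] = set()
    for rec in records:
        circular = rec.annotations.get("topology", "linear") == "circular"
        seq = str(rec.seq) if len(rec.seq) else None
        contig = Contig(id=rec.id or rec.name, length=len(rec.seq), circular=circular, sequence=seq)
        genome.contigs.append(contig)
        n = 0
        for f in rec.features:
            if f.type in _SKIP_TYPES:
                continue
            kind = f.type if f.type in ("CDS", "rRNA", "tRNA") else "other"
            start, end = _convert_location(f.location, contig.length, circular)
            strand = -1 if f.location.strand == -1 else 1
            q = f.qualifiers
            gene_id = (q.get("locus_tag") or q.get("gene") or [f"{contig.id}_f{n}"])[0]
            while gene_id in seen_ids:
                gene_id = f"{gene_id}.{n}"
            seen_ids.add(gene_id)
            label = (q.get("gene") or q.get("product") or [""])[0]
            pseudo = "pseudo" in q or "pseudogene" in q
            translation = None
            if kind == "CDS":
                if "translation" in q:
                    translation = q["translation"][0]
                elif seq is not None:
                    feat = GeneFeature(contig.id, start, end, strand, gene_id, kind="CDS")
                    translation = translate_cds(feature_nt(feat, contig), table=table)
            genome.features.append(
                GeneFeature(
                    contig_id=contig.id,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=gene_id,
                    label=label,
                    kind=kind,
                    translation=translation,
                    pseudo=pseudo,
                )
            )
            n += 1
    genome.validate()
    return genome


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write the genome back out as a GenBank flat file (one record per contig)."""
    records = []
    for contig in genome.contigs:
        seq = Seq(contig.sequence if contig.sequence is not None else "N" * contig.length)
        rec = SeqRecord(seq, id=contig.id, name=contig.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if contig.circular else "linear"
        if genome.taxon:
            rec.annotations["organism"] = genome.taxon
        for f in genome.features:
            if f.contig_id != contig.id:
                continue
            strand = f.strand
            if f.wrapped:
                loc = CompoundLocation(
                    [
                        SimpleLocation(f.start, contig.length, strand),
                        SimpleLocation(0, f.end, strand),
                    ]
                )
            else:
                loc = SimpleLocation(f.start, f.end, strand)
            ftype = f.kind if f.kind != "other" else "misc_feature"
            sf = SeqFeature(loc, type=ftype)
            sf.qualifiers["locus_tag"] = [f.gene_id]
            if f.label:
                sf.qualifiers["gene"] = [f.label]
            if f.translation is not None:
                sf.qualifiers["translation"] = [f.translation]
            if f.pseudo:
                sf.qualifiers["pseudo"] = [""]
            rec.features.append(sf)
        records.append(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# GFF3 + FASTA


def read_gff_fasta(
    gff: str | Path,
    fasta: str | Path,
    genome_id: str | None = None,
    taxon: str = "",
    table: int = DEFAULT_TABLE,
) -> GenomeRecord:
    """Read a GFF3 annotation plus its FASTA into the normalized model.

    Circularity is taken from a ``region`` feature carrying
    ``Is_circular=true``; contigs default to linear.  Attributes other than
    ID, gene and product are ignored.
    """
    import gffutils

    gff = Path(gff)
    fasta = Path(fasta)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    if not seqs:
        raise ValueError(f"{fasta}: no FASTA records")

    db = gffutils.create_db(
        str(gff), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    circular: set[str] = set()
    for region in db.features_of_type("region"):
        if "true" in [v.lower() for v in region.attributes.get("Is_circular", [])]:
            circular.add(region.seqid)

    gid = genome_id or gff.stem
    genome = GenomeRecord(genome_id=gid, taxon=taxon)
    for sid, seq in seqs.items():
        genome.contigs.append(
            Contig(id=sid, length=len(seq), circular=sid in circular, sequence=seq)
        )

    seen: set[str] = set()
    n = 0
    for f in db.all_features(order_by=("seqid", "start", "end")):
        if f.featuretype in _SKIP_TYPES or f.featuretype == "region":
            continue
        kind = f.featuretype if f.featuretype in ("CDS", "rRNA", "tRNA") else "other"
        if f.seqid not in seqs:
            raise ValueError(
                f"{gff}: feature {f.id or f.featuretype!r} references seqid "
                f"{f.seqid!r} absent from {fasta.name}"
            )
        start, end = f.start - 1, f.end
        strand = -1 if f.strand == "-" else 1
        gene_id = (f.attributes.get("ID") or f.attributes.get("gene") or [f"{f.seqid}_f{n}"])[0]
        while gene_id in seen:
            gene_id = f"{gene_id}.{n}"
        seen.add(gene_id)
        label = (f.attributes.get("gene") or f.attributes.get("product") or [""])[0]
        pseudo = "pseudogene" in (f.attributes.get("gene_biotype", []) or []) or (
            "true" in [v.lower() for v in f.attributes.get("pseudo", [])]
        )
        feat = GeneFeature(
            contig_id=f.seqid,
            start=start,
            end=end,
            strand=strand,
            gene_id=gene_id,
            label=label,
            kind=kind,
            pseudo=pseudo,
        )
        if kind == "CDS":
            feat.translation = translate_cds(
                feature_nt(feat, genome.contig(f.seqid)), table=table
            )
        genome.features.append(feat)
        n += 1
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# Coordinate transforms (used heavily by invariance checks)


def reverse_complement_genome(genome: GenomeRecord) -> GenomeRecord:
    """The same genome with every contig reverse-complemented.

    Interval [s, e) maps to [L - e, L - s) with the strand flipped; the
    formula also holds for origin-wrapping features.
    """
    out = GenomeRecord(genome_id=genome.genome_id, taxon=genome.taxon)
    lengths = {}
    for c in genome.contigs:
        seq = str(Seq(c.sequence).reverse_complement()) if c.sequence else None
        out.contigs.append(Contig(id=c.id, length=c.length, circular=c.circular, sequence=seq))
        lengths[c.id] = c.length
    for f in genome.features:
        L = lengths[f.contig_id]
        out.features.append(
            GeneFeature(
                contig_id=f.contig_id,
                start=(L - f.end) % L if f.end != L else 0,
                end=L - f.start,
                strand=-f.strand,
                gene_id=f.gene_id,
                label=f.label,
                kind=f.kind,
                translation=f.translation,
                pseudo=f.pseudo,
            )
        )
    out.validate()
    return out


def rotate_contig(genome: GenomeRecord, contig_id: str, offset: int) -> GenomeRecord:
    """Rotate a circular contig so old position ``offset`` becomes 0.

    Features crossing the new origin become wrapped (start > end).
    """
    out = GenomeRecord(genome_id=genome.genome_id, taxon=genome.taxon)
    for c in genome.contigs:
        if c.id != contig_id:
            out.contigs.append(c)
            continue
        if not c.circular:
            raise ValueError(f"contig {c.id!r} is linear; rotation undefined")
        seq = c.sequence[offset:] + c.sequence[:offset] if c.sequence else None
        out.contigs.append(Contig(id=c.id, length=c.length, circular=True, sequence=seq))
    for f in genome.features:
        if f.contig_id != contig_id:
            out.features.append(f)
            continue
        L = genome.contig(contig_id).length
        start = (f.start - offset) % L
        end = (f.end - offset) % L
        if end == 0:
            end = L
        out.features.append(
            GeneFeature(
                contig_id=f.contig_id, start=start, end=end, strand=f.strand,
                gene_id=f.gene_id, label=f.label, kind=f.kind,
                translation=f.translation, pseudo=f.pseudo,
            )
        )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Ordering and tables


def gene_order(genome: GenomeRecord, contig_id: str) -> list[GeneFeature]:
    """Features of one contig in deterministic genomic order.

    Sorted by start, ties broken by end then gene_id.  On circular contigs
    the returned list is a ring: callers index ranks modulo ``len(order)``.
    Permuting the genome's feature list never changes the result.
    """
    genome.contig(contig_id)  # raises KeyError if absent
    feats = [f for f in genome.features if f.contig_id == contig_id]
    return sorted(feats, key=lambda f: (f.start, f.end, f.gene_id))


def feature_table(genomes: Iterable[GenomeRecord]) -> pd.DataFrame:
    """Normalized feature table: one row per gene in rank order."""
    rows = []
    for g in genomes:
        for contig in g.contigs:
            for rank, f in enumerate(gene_order(g, contig.id)):
                rows.append(
                    {
                        "genome_id": g.genome_id,
                        "contig_id": contig.id,
                        "rank": rank,
                        "start": f.start,
                        "end": f.end,
                        "strand": "+" if f.strand == 1 else "-",
                        "gene_id": f.gene_id,
                        "label": f.label,
                        "kind": f.kind,
                    }
                )
    cols = [
        "genome_id", "contig_id", "rank", "start", "end",
        "strand", "gene_id", "label", "kind",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    feature_table(genomes).to_csv(path, sep="\t", index=False)
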