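"""GTF/FASTA I/O, transcript models and genome<->transcript coordinate maps.

Internal coordinates are 0-based half-open throughout; GTF I/O converts
to/from the 1-based inclusive convention of the format.  An exon junction
"at j" sits between transcript nucleotides j-1 and j, i.e. j equals the
cumulative length of the preceding exons.  All downstream-junction distance
arithmetic in :mod:`translon.nmd_features` uses this single convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExonInterval",
    "TranscriptModel",
    "SplicedSequence",
    "read_gtf",
    "read_fasta",
    "extract_spliced_sequence",
    "genomic_to_transcript",
    "transcript_to_genomic",
    "transcript_interval_to_genomic",
    "write_gtf",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_TABLE_COLUMNS",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonInterval:
    """A genomic exon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"exon start must precede end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """An ordered exon chain on one strand.

    ``exons`` are listed in 5'->3' *transcript* order: genomic starts
    strictly increase along the list on the plus strand and strictly
    decrease on the minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[ExonInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for e in self.exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}{e.strand} "
                    f"does not match transcript {self.chrom}{self.strand}"
                )
        starts = [e.start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if len(self.exons) > 1 and not ordered:
            raise ValueError(
                f"transcript {self.transcript_id}: exons not in transcript order"
            )
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic_sorted, genomic_sorted[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def junctions(self) -> Tuple[int, ...]:
        """Transcript coordinates of exon-exon boundaries (prefix sums)."""
        out: List[int] = []
        acc = 0
        for e in self.exons[:-1]:
            acc += len(e)
            out.append(acc)
        return tuple(out)


@dataclass(frozen=True)
class SplicedSequence:
    """The 5'->3' spliced transcript sequence plus its junction coordinates."""

    transcript_id: str
    seq: str
    junctions: Tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.seq)
        for j in self.junctions:
            if not 0 < j < n:
                raise ValueError(
                    f"{self.transcript_id}: junction {j} outside (0, {n})"
                )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_gtf(
    path: str | os.PathLike,
    with_cds: bool = False,
):
    """Read a GTF/GFF3-attribute annotation into transcript models.

    Returns a dict ``gene_id -> [TranscriptModel, ...]``.  With
    ``with_cds=True`` additionally returns ``transcript_id -> [(start, end),
    ...]`` of 0-based half-open CDS spans, for use as the published
    Reference ORF source (see
    :func:`translon.start_harmonization.reference_orf_from_gtf`); CDS/UTR
    lines are otherwise ignored for structure.

    Both ``key "value";`` (GTF) and ``key=value`` (GFF3) attribute syntax
    are accepted; exon lines must carry ``transcript_id`` and ``gene_id``.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: Dict[str, List[ExonInterval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    cds: Dict[str, List[Tuple[int, int]]] = {}

    def _ids(feat) -> Tuple[str, str]:
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError:
            raise ValueError(
                f"{path}: {feat.featuretype} line at {feat.seqid}:"
                f"{feat.start}-{feat.end} lacks transcript_id"
            ) from None
        try:
            gid = feat.attributes["gene_id"][0]
        except KeyError:
            raise ValueError(
                f"{path}: {feat.featuretype} line at {feat.seqid}:"
                f"{feat.start}-{feat.end} lacks gene_id"
            ) from None
        return tid, gid

    for feat in db.features_of_type("exon"):
        tid, gid = _ids(feat)
        iv = ExonInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        prev = meta.get(tid)
        if prev is None:
            meta[tid] = (gid, feat.seqid, feat.strand)
        elif prev[1] != feat.seqid or prev[2] != feat.strand:
            raise ValueError(
                f"transcript {tid}: exons on mixed chromosomes/strands"
            )
        exons.setdefault(tid, []).append(iv)

    for feat in db.features_of_type("CDS"):
        tid, _ = _ids(feat)
        cds.setdefault(tid, []).append((feat.start - 1, feat.end))

    genes: Dict[str, List[TranscriptModel]] = {}
    for tid in sorted(exons):
        gid, chrom, strand = meta[tid]
        ivs = sorted(exons[tid], key=lambda e: e.start, reverse=strand == "-")
        model = TranscriptModel(tid, gid, chrom, strand, tuple(ivs))
        genes.setdefault(gid, []).append(model)

    for tid in cds:
        cds[tid] = sorted(cds[tid])

    if with_cds:
        return genes, cds
    return genes


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Load a FASTA file as ``{name: uppercase sequence}``.

    Record names are the first whitespace-delimited token of the header;
    duplicate names are an error.
    """
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate FASTA record name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


# ---------------------------------------------------------------------------
# Sequence extraction and coordinate maps
# ---------------------------------------------------------------------------

def extract_spliced_sequence(
    t: TranscriptModel, genome: Mapping[str, str]
) -> SplicedSequence:
    """Concatenate exon sequences 5'->3'; minus-strand exons are
    reverse-complemented."""
    if t.chrom not in genome:
        raise KeyError(f"transcript {t.transcript_id}: {t.chrom} not in genome")
    chrom_seq = genome[t.chrom]
    parts: List[str] = []
    for e in t.exons:
        if e.end > len(chrom_seq):
            raise ValueError(
                f"transcript {t.transcript_id}: exon [{e.start}, {e.end}) "
                f"beyond end of {t.chrom} ({len(chrom_seq)} nt)"
            )
        s = chrom_seq[e.start : e.end]
        parts.append(reverse_complement(s) if t.strand == "-" else s)
    return SplicedSequence(t.transcript_id, "".join(parts), t.junctions)


def genomic_to_transcript(t: TranscriptModel, gpos: int) -> Optional[int]:
    """Transcript coordinate of the base at ``gpos``, or None if intronic/
    outside the transcript."""
    acc = 0
    for e in t.exons:
        if e.start <= gpos < e.end:
            if t.strand == "+":
                return acc + (gpos - e.start)
            return acc + (e.end - 1 - gpos)
        acc += len(e)
    return None


def transcript_to_genomic(t: TranscriptModel, tpos: int) -> int:
    """Genomic position of transcript base ``tpos``; inverse of
    :func:`genomic_to_transcript` on exonic positions."""
    if not 0 <= tpos < t.spliced_length:
        raise ValueError(
            f"transcript {t.transcript_id}: position {tpos} outside "
            f"[0, {t.spliced_length})"
        )
    acc = 0
    for e in t.exons:
        if tpos < acc + len(e):
            off = tpos - acc
            if t.strand == "+":
                return e.start + off
            return e.end - 1 - off
        acc += len(e)
    raise AssertionError("unreachable")


def transcript_interval_to_genomic(
    t: TranscriptModel, start: int, end: int
) -> List[Tuple[int, int]]:
    """Project a transcript-space interval [start, end) onto genomic
    0-based half-open intervals, one per overlapped exon, returned in
    transcript 5'->3' order."""
    if not 0 <= start <= end <= t.spliced_length:
        raise ValueError(
            f"transcript {t.transcript_id}: interval [{start}, {end}) outside "
            f"[0, {t.spliced_length}]"
        )
    out: List[Tuple[int, int]] = []
    acc = 0
    for e in t.exons:
        lo = max(start, acc)
        hi = min(end, acc + len(e))
        if lo < hi:
            if t.strand == "+":
                out.append((e.start + (lo - acc), e.start + (hi - acc)))
            else:
                out.append((e.end - (hi - acc), e.end - (lo - acc)))
        acc += len(e)
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_gtf(
    genes: Mapping[str, Sequence[TranscriptModel]],
    orfs: Mapping[str, object],
    path: str | os.PathLike,
    source: str = "translon",
) -> None:
    """Write exon lines plus CDS lines (ORF minus stop codon) as GTF.

    ``orfs`` maps transcript_id to an OrfAnnotation or None (noncoding:
    exon lines only).  Records are ordered by gene_id, transcript_id, then
    transcript 5'->3'.  The frame column of each CDS segment is
    ``(3 - cumulative CDS length before the segment % 3) % 3``.
    """
    known = {t.transcript_id for models in genes.values() for t in models}
    for tid, orf in orfs.items():
        if orf is not None and tid not in known:
            raise ValueError(f"ORF for unknown transcript {tid}")

    def line(t: TranscriptModel, feat: str, gs: int, ge: int, frame: str) -> str:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        return "\t".join(
            [t.chrom, source, feat, str(gs + 1), str(ge), ".", t.strand, frame, attrs]
        )

    with open(path, "w") as fh:
        for gid in sorted(genes):
            for t in sorted(genes[gid], key=lambda m: m.transcript_id):
                for e in t.exons:
                    fh.write(line(t, "exon", e.start, e.end, ".") + "\n")
                orf = orfs.get(t.transcript_id)
                if orf is None:
                    continue
                cds_end = orf.stop_end - 3 if orf.has_stop else orf.stop_end
                if cds_end <= orf.start:
                    continue
                acc = 0
                for gs, ge in transcript_interval_to_genomic(t, orf.start, cds_end):
                    frame = (3 - acc % 3) % 3
                    fh.write(line(t, "CDS", gs, ge, str(frame)) + "\n")
                    acc += ge - gs


FEATURE_TABLE_COLUMNS = [
    "transcript_id",
    "gene_id",
    "stop_class",
    "utr5_length",
    "utr3_length",
    "dist_stop_to_last_dEJ",
    "n_dEJ",
    "kozak_match",
    "Translation",
]


def write_feature_table(records: Iterable, path: str | os.PathLike) -> None:
    """Write per-transcript NMD feature records as CSV.

    One row per transcript; the final "Translation" column holds the
    predicted protein sequence.  Non-applicable numeric fields (e.g. the
    dEJ distance of a transcript with a normal stop and no downstream
    junction) are left empty.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "stop_class": r.stop_class.label,
                "utr5_length": r.utr5_length,
                "utr3_length": r.utr3_length,
                "dist_stop_to_last_dEJ": r.dist_stop_to_last_dej,
                "n_dEJ": r.n_dej,
                "kozak_match": r.kozak_match,
                "Translation": r.protein,
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature CSV back, indexed by transcript_id."""
    df = pd.read_csv(path, dtype={"transcript_id": str, "gene_id": str})
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature-table columns {missing}")
    return df.set_index("transcript_id", drop=False)
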