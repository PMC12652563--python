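"""Gene-level authentic start-codon selection and isoform harmonization.

The ribosome initiates at the same start codon regardless of downstream
splicing, so per-transcript longest-ORF annotation systematically picks
internal methionines on isoforms where alternative splicing truncates the
main ORF.  The Revised annotation instead selects, per gene, the start
codon whose own-transcript ORF encodes the longest protein across all
isoforms, and imposes that genomic start position on every isoform that
retains it.  The Reference mode is the conventional independent
longest-ORF-per-transcript annotation, either recomputed or taken from the
CDS lines of a published GTF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .annotation_io import (
    SplicedSequence,
    TranscriptModel,
    extract_spliced_sequence,
    genomic_to_transcript,
    transcript_to_genomic,
)
from .orf_discovery import (
    DEFAULT_MIN_PROTEIN_LEN,
    STOP_CODONS,
    OrfAnnotation,
    longest_orf,
    orf_from_start,
    translate,
)

__all__ = [
    "Mode",
    "HarmonizationStatus",
    "GeneStartAssignment",
    "AnnotationSet",
    "annotate_reference",
    "annotate_revised",
    "select_gene_start",
    "apply_authentic_start",
    "reference_orf_from_gtf",
]

logger = logging.getLogger(__name__)


class Mode(Enum):
    REFERENCE = "reference"
    REVISED = "revised"


class HarmonizationStatus(Enum):
    HARMONIZED = "HARMONIZED"
    FALLBACK_OWN_LONGEST = "FALLBACK_OWN_LONGEST"
    NONCODING = "NONCODING"


@dataclass
class GeneStartAssignment:
    """The gene-level authentic start codon and each isoform's outcome.

    ``authentic_start_genomic`` is the genomic position of the A of the
    AUG (with chrom/strand); None when the gene has no qualifying ORF.
    """

    gene_id: str
    chrom: str
    strand: str
    authentic_start_genomic: Optional[int]
    source_transcript_id: Optional[str]
    per_transcript_status: Dict[str, HarmonizationStatus] = field(default_factory=dict)


@dataclass
class AnnotationSet:
    """One complete ORF annotation of a transcriptome."""

    mode: Mode
    orfs: Dict[str, Optional[OrfAnnotation]]
    assignments: Dict[str, GeneStartAssignment] = field(default_factory=dict)
    invalid: Set[str] = field(default_factory=set)


def _spliced_seqs(
    models: Sequence[TranscriptModel], genome: Mapping[str, str]
) -> Dict[str, SplicedSequence]:
    return {t.transcript_id: extract_spliced_sequence(t, genome) for t in models}


def annotate_reference(
    genes: Mapping[str, Sequence[TranscriptModel]],
    genome: Mapping[str, str],
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
) -> AnnotationSet:
    """Longest-ORF-per-transcript annotation, independently per isoform."""
    orfs: Dict[str, Optional[OrfAnnotation]] = {}
    for gid in sorted(genes):
        for t in genes[gid]:
            seq = extract_spliced_sequence(t, genome)
            orfs[t.transcript_id] = longest_orf(seq, min_protein_len)
    return AnnotationSet(Mode.REFERENCE, orfs)


def select_gene_start(
    gene_models: Sequence[TranscriptModel],
    seqs: Mapping[str, SplicedSequence],
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
) -> GeneStartAssignment:
    """Pick the start codon yielding the longest protein gene-wide.

    Each isoform contributes its own longest ORF as a candidate; the
    winner is the candidate with the longest own-transcript protein
    (stop-terminated preferred), ties broken by 5'-most genomic position
    in transcription direction, then lexicographic transcript id.
    """
    if not gene_models:
        raise ValueError("gene with no transcripts")
    first = gene_models[0]
    assignment = GeneStartAssignment(
        first.gene_id, first.chrom, first.strand, None, None
    )
    candidates: List[Tuple[int, bool, int, str]] = []
    for t in gene_models:
        orf = longest_orf(seqs[t.transcript_id], min_protein_len)
        if orf is None:
            continue
        gpos = transcript_to_genomic(t, orf.start)
        candidates.append((orf.protein_length, orf.has_stop, gpos, t.transcript_id))
    if not candidates:
        for t in gene_models:
            assignment.per_transcript_status[t.transcript_id] = (
                HarmonizationStatus.NONCODING
            )
        return assignment
    # 5'-most in transcription direction: smaller genomic position on "+",
    # larger on "-".
    sign = 1 if first.strand == "+" else -1
    plen, has_stop, gpos, tid = min(
        candidates, key=lambda c: (-c[0], not c[1], sign * c[2], c[3])
    )
    assignment.authentic_start_genomic = gpos
    assignment.source_transcript_id = tid
    return assignment


def apply_authentic_start(
    t: TranscriptModel,
    seq: SplicedSequence,
    assignment: GeneStartAssignment,
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
) -> Tuple[Optional[OrfAnnotation], HarmonizationStatus]:
    """Impose the gene's authentic start on one isoform.

    If the authentic genomic position falls in an exon of ``t`` and the
    spliced sequence reads ATG there, the ORF runs from that ATG to the
    first in-frame stop (HARMONIZED, no length re-filter).  Otherwise the
    isoform keeps its own longest ORF (FALLBACK_OWN_LONGEST), or is
    NONCODING when it has none.
    """
    gpos = assignment.authentic_start_genomic
    if gpos is not None and t.chrom == assignment.chrom and t.strand == assignment.strand:
        tpos = genomic_to_transcript(t, gpos)
        if tpos is not None and seq.seq[tpos : tpos + 3] == "ATG":
            return (
                orf_from_start(seq, tpos),
                HarmonizationStatus.HARMONIZED,
            )
    own = longest_orf(seq, min_protein_len)
    if own is None:
        return None, HarmonizationStatus.NONCODING
    return own, HarmonizationStatus.FALLBACK_OWN_LONGEST


def _strand_groups(
    models: Sequence[TranscriptModel],
) -> List[Tuple[str, List[TranscriptModel]]]:
    """Split a gene's isoforms by (chrom, strand); annotation errors where
    a gene id spans strands are processed per group with a warning."""
    groups: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in models:
        groups.setdefault((t.chrom, t.strand), []).append(t)
    if len(groups) == 1:
        return [(models[0].gene_id, list(models))]
    gid = models[0].gene_id
    logger.warning(
        "gene %s has isoforms on %d chrom/strand combinations; "
        "harmonizing each group separately",
        gid,
        len(groups),
    )
    return [
        (f"{gid}:{chrom}:{strand}", ms)
        for (chrom, strand), ms in sorted(groups.items())
    ]


def annotate_revised(
    genes: Mapping[str, Sequence[TranscriptModel]],
    genome: Mapping[str, str],
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
) -> AnnotationSet:
    """Authentic-start annotation: select per gene, apply per isoform."""
    orfs: Dict[str, Optional[OrfAnnotation]] = {}
    assignments: Dict[str, GeneStartAssignment] = {}
    for gid in sorted(genes):
        for key, group in _strand_groups(genes[gid]):
            seqs = _spliced_seqs(group, genome)
            assignment = select_gene_start(group, seqs, min_protein_len)
            for t in group:
                orf, status = apply_authentic_start(
                    t, seqs[t.transcript_id], assignment, min_protein_len
                )
                orfs[t.transcript_id] = orf
                assignment.per_transcript_status[t.transcript_id] = status
            assignments[key] = assignment
    return AnnotationSet(Mode.REVISED, orfs, assignments)


def reference_orf_from_gtf(
    genes: Mapping[str, Sequence[TranscriptModel]],
    cds_records: Mapping[str, Sequence[Tuple[int, int]]],
    genome: Mapping[str, str],
) -> AnnotationSet:
    """Build the Reference annotation from the CDS lines of a published
    GTF instead of recomputing longest ORFs.

    CDS spans (0-based half-open genomic, stop codon excluded as written
    by GFFread-style converters; a trailing stop codon inside the CDS is
    also accepted) are mapped into transcript coordinates.  Transcripts
    whose CDS does not map onto their exons, is not a whole number of
    codons, does not begin with ATG, or is not followed by a valid stop
    codon are flagged invalid with a warning.  Transcripts without CDS are
    noncoding.
    """
    orfs: Dict[str, Optional[OrfAnnotation]] = {}
    annotation = AnnotationSet(Mode.REFERENCE, orfs)
    for gid in sorted(genes):
        for t in genes[gid]:
            tid = t.transcript_id
            spans = cds_records.get(tid)
            if not spans:
                orfs[tid] = None
                continue
            seq = extract_spliced_sequence(t, genome)
            tcoords: List[int] = []
            ok = True
            for gs, ge in spans:
                a = genomic_to_transcript(t, gs)
                b = genomic_to_transcript(t, ge - 1)
                if a is None or b is None:
                    ok = False
                    break
                tcoords.extend((a, b))
            if not ok:
                logger.warning("transcript %s: CDS outside exons; flagged invalid", tid)
                orfs[tid] = None
                annotation.invalid.add(tid)
                continue
            t0, t1 = min(tcoords), max(tcoords) + 1
            span_len = t1 - t0
            if span_len != sum(ge - gs for gs, ge in spans):
                logger.warning(
                    "transcript %s: CDS segments not contiguous in transcript "
                    "space; flagged invalid",
                    tid,
                )
                orfs[tid] = None
                annotation.invalid.add(tid)
                continue
            # Accept stop either just after the span or as its last codon.
            if seq.seq[t1 : t1 + 3] in STOP_CODONS:
                stop_end = t1 + 3
            elif span_len >= 6 and seq.seq[t1 - 3 : t1] in STOP_CODONS:
                stop_end = t1
            else:
                logger.warning(
                    "transcript %s: CDS not followed by a stop codon; "
                    "flagged invalid",
                    tid,
                )
                orfs[tid] = None
                annotation.invalid.add(tid)
                continue
            if (stop_end - t0) % 3 != 0 or seq.seq[t0 : t0 + 3] != "ATG":
                logger.warning(
                    "transcript %s: CDS frame/start invalid; flagged invalid", tid
                )
                orfs[tid] = None
                annotation.invalid.add(tid)
                continue
            try:
                protein = translate(seq.seq[t0:stop_end])
            except ValueError:
                logger.warning(
                    "transcript %s: internal stop within annotated CDS; "
                    "flagged invalid",
                    tid,
                )
                orfs[tid] = None
                annotation.invalid.add(tid)
                continue
            orfs[tid] = OrfAnnotation(tid, t0, stop_end, True, protein)
    return annotation
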