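"""Stop-codon classification and NMD-relevant transcript features.

A stop codon is called PTC_dEJ when at least one exon junction lies at
least ``dej_threshold`` (default 50) nucleotides downstream of it in the
spliced transcript — the exon-junction-complex model of NMD targeting.
The distance runs from ``stop_end`` (the first nucleotide after the stop
codon) to the junction coordinate; the threshold is inclusive.  A junction
exactly at ``stop_end`` counts as downstream with distance 0 and therefore
never triggers PTC_dEJ at the default threshold.  Stopless ORFs are
NO_STOP and excluded from NORMAL/PTC_dEJ tallies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .annotation_io import (
    SplicedSequence,
    TranscriptModel,
    extract_spliced_sequence,
)
from .kozak_scan import kozak_match
from .orf_discovery import OrfAnnotation
from .start_harmonization import AnnotationSet

__all__ = [
    "StopClass",
    "NmdFeatureRecord",
    "DEFAULT_DEJ_THRESHOLD",
    "classify_stop",
    "utr_metrics",
    "build_feature_records",
]

DEFAULT_DEJ_THRESHOLD = 50


class StopClass(Enum):
    NORMAL = "Normal"
    PTC_DEJ = "PTC_dEJ"
    NO_STOP = "No_stop"
    NONCODING = "Noncoding"

    @property
    def label(self) -> str:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "StopClass":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"unknown stop class {label!r}")


@dataclass(frozen=True)
class NmdFeatureRecord:
    """Per-transcript NMD feature row (one line of the feature CSV)."""

    transcript_id: str
    gene_id: str
    stop_class: StopClass
    utr5_length: Optional[int]
    utr3_length: Optional[int]
    dist_stop_to_last_dej: Optional[int]
    n_dej: int
    kozak_match: Optional[bool]
    protein: Optional[str]


def classify_stop(
    orf: Optional[OrfAnnotation],
    seq: SplicedSequence,
    dej_threshold: int = DEFAULT_DEJ_THRESHOLD,
) -> Tuple[StopClass, Optional[int], int]:
    """Classify an ORF's stop codon against the downstream-junction rule.

    Returns (stop class, distance from stop_end to the last downstream
    junction or None when there is none, count of downstream junctions).
    """
    if orf is None:
        return StopClass.NONCODING, None, 0
    if not orf.has_stop:
        return StopClass.NO_STOP, None, 0
    downstream = [j for j in seq.junctions if j > orf.stop_end]
    # A junction exactly at stop_end is downstream with distance 0.
    at_boundary = [j for j in seq.junctions if j == orf.stop_end]
    downstream += at_boundary
    if not downstream:
        return StopClass.NORMAL, None, 0
    dist = max(downstream) - orf.stop_end
    n = len(downstream)
    if dist >= dej_threshold:
        return StopClass.PTC_DEJ, dist, n
    return StopClass.NORMAL, dist, n


def utr_metrics(
    orf: Optional[OrfAnnotation], seq: SplicedSequence
) -> Tuple[Optional[int], Optional[int]]:
    """(5'UTR length, 3'UTR length) in nt; 3'UTR is 0 for stopless ORFs,
    both None for noncoding transcripts."""
    if orf is None:
        return None, None
    utr5 = orf.start
    utr3 = len(seq) - orf.stop_end if orf.has_stop else 0
    return utr5, utr3


def build_feature_records(
    annotation: AnnotationSet,
    genes: Mapping[str, Sequence[TranscriptModel]],
    genome: Mapping[str, str],
    dej_threshold: int = DEFAULT_DEJ_THRESHOLD,
) -> List[NmdFeatureRecord]:
    """One record per transcript, ordered by (gene_id, transcript_id)."""
    records: List[NmdFeatureRecord] = []
    for gid in sorted(genes):
        for t in sorted(genes[gid], key=lambda m: m.transcript_id):
            seq = extract_spliced_sequence(t, genome)
            orf = annotation.orfs.get(t.transcript_id)
            stop_class, dist, n_dej = classify_stop(orf, seq, dej_threshold)
            utr5, utr3 = utr_metrics(orf, seq)
            kozak = (
                kozak_match(seq.seq, orf.start).match if orf is not None else None
            )
            records.append(
                NmdFeatureRecord(
                    transcript_id=t.transcript_id,
                    gene_id=gid,
                    stop_class=stop_class,
                    utr5_length=utr5,
                    utr3_length=utr3,
                    dist_stop_to_last_dej=dist,
                    n_dej=n_dej,
                    kozak_match=kozak,
                    protein=orf.protein if orf is not None else None,
                )
            )
    return records
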