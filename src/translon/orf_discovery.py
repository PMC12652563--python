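"""Open-reading-frame enumeration, ranking and translation.

Only AUG starts and the three standard stop codons are considered, on the
sense strand.  Candidates without an in-frame stop before the 3' end are
kept (``has_stop=False``, truncated to complete codons) so that fragmentary
transcript models remain annotatable; downstream stop-class logic assigns
them NO_STOP and excludes them from PTC tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

from Bio.Seq import Seq

from .annotation_io import SplicedSequence

__all__ = ["OrfAnnotation", "find_orfs", "longest_orf", "orf_from_start", "translate"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

#: Default minimum protein length (aa) for main-ORF candidate filtering.
DEFAULT_MIN_PROTEIN_LEN = 30


@dataclass(frozen=True)
class OrfAnnotation:
    """One ORF in transcript coordinates.

    ``start`` is the A of the AUG (0-based); ``stop_end`` is one past the
    last base of the stop codon, or one past the last complete codon when
    ``has_stop`` is false.  ``protein`` excludes the stop.
    """

    transcript_id: str
    start: int
    stop_end: int
    has_stop: bool
    protein: str

    @property
    def cds_length(self) -> int:
        return self.stop_end - self.start

    @property
    def protein_length(self) -> int:
        return len(self.protein)


def translate(cds: str) -> str:
    """Standard-genetic-code translation of complete codons.

    A single trailing stop codon is dropped; an internal stop raises; any
    codon containing N translates to "X".  Codons containing a valid stop
    are the only source of "*" from the standard table, so ambiguity (N)
    never masks a stop.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon: {len(cds)} nt")
    trimmed = cds[: 3 * (len(cds) // 3)]
    prot = str(Seq(trimmed).translate())
    star = prot.find("*")
    if star != -1 and star != len(prot) - 1:
        raise ValueError(f"internal stop codon at nt {3 * star}")
    return prot[:-1] if prot.endswith("*") else prot


def _seq_str(seq: Union[SplicedSequence, str]) -> str:
    return seq.seq if isinstance(seq, SplicedSequence) else seq


def _tid(seq: Union[SplicedSequence, str]) -> str:
    return seq.transcript_id if isinstance(seq, SplicedSequence) else ""


def orf_from_start(
    seq: Union[SplicedSequence, str], start: int, transcript_id: Optional[str] = None
) -> OrfAnnotation:
    """Extend the ATG at ``start`` to the first in-frame stop, or to the
    last complete codon before the 3' end (stopless)."""
    s = _seq_str(seq)
    if s[start : start + 3] != START_CODON:
        raise ValueError(f"no ATG at transcript position {start}")
    tid = transcript_id if transcript_id is not None else _tid(seq)
    n = len(s)
    j = start + 3
    while j + 3 <= n:
        if s[j : j + 3] in STOP_CODONS:
            stop_end = j + 3
            return OrfAnnotation(tid, start, stop_end, True, translate(s[start:stop_end]))
        j += 3
    stop_end = start + 3 * ((n - start) // 3)
    return OrfAnnotation(tid, start, stop_end, False, translate(s[start:stop_end]))


def find_orfs(
    seq: Union[SplicedSequence, str], min_protein_len: int = 1
) -> List[OrfAnnotation]:
    """One candidate per ATG occurrence, sense strand only.

    Candidates whose protein is shorter than ``min_protein_len`` amino
    acids are dropped.  N-containing triplets are never treated as starts
    or stops.
    """
    if min_protein_len < 1:
        raise ValueError("min_protein_len must be >= 1")
    s = _seq_str(seq)
    out: List[OrfAnnotation] = []
    i = s.find(START_CODON)
    while i != -1:
        orf = orf_from_start(s, i, _tid(seq))
        if orf.protein_length >= min_protein_len:
            out.append(orf)
        i = s.find(START_CODON, i + 1)
    return out


def longest_orf(
    seq: Union[SplicedSequence, str], min_protein_len: int = 1
) -> Optional[OrfAnnotation]:
    """The candidate maximizing protein length.

    Ties prefer stop-terminated over stopless candidates, then the 5'-most
    start.  Returns None when no candidate survives the length filter.
    """
    candidates = find_orfs(seq, min_protein_len)
    if not candidates:
        return None
    return min(
        candidates, key=lambda o: (-o.protein_length, not o.has_stop, o.start)
    )
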