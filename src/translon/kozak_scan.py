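"""Kozak consensus-context matching around start codons.

The consensus is matched as the pattern RNNATGGV (R = A/G, V = A/C/G)
anchored with the literal ATG at the start codon: position -3 relative to
the A must be a purine, position +4 must be G and position +5 must not be
T.  This is the standard Kozak register and the only alignment of the
pattern in which "ATG" is literal.  The context is only assessable when
the transcript provides >=3 nt upstream of the A and >=2 nt after the G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple, Union

from .annotation_io import SplicedSequence

__all__ = ["KozakResult", "kozak_match", "kozak_rate"]


@dataclass(frozen=True)
class KozakResult:
    transcript_id: str
    start: int
    has_context: bool
    match: bool


def kozak_match(
    seq: Union[SplicedSequence, str], start: int, transcript_id: str = ""
) -> KozakResult:
    """Match RNNATGGV around the ATG at ``start``.

    Raises when ``seq[start:start+3]`` is not ATG; a window that exceeds
    the sequence bounds yields ``has_context=False`` (and no match).
    """
    if isinstance(seq, SplicedSequence):
        transcript_id = transcript_id or seq.transcript_id
        s = seq.seq
    else:
        s = seq
    if s[start : start + 3] != "ATG":
        raise ValueError(f"no ATG at position {start}")
    has_context = start >= 3 and start + 5 <= len(s)
    match = (
        has_context
        and s[start - 3] in "AG"
        and s[start + 3] == "G"
        and s[start + 4] in "ACG"
    )
    return KozakResult(transcript_id, start, has_context, match)


def kozak_rate(
    annotation,
    seqs: Mapping[str, Union[SplicedSequence, str]],
    ids: Optional[Iterable[str]] = None,
) -> Tuple[int, int, Optional[float]]:
    """(matched, total, fraction) over transcripts with an ORF.

    ``ids`` restricts the tally (e.g. to the set of transcripts whose ORF
    start changed between two annotations); the fraction is None for an
    empty set.
    """
    universe = set(ids) if ids is not None else None
    matched = total = 0
    for tid, orf in annotation.orfs.items():
        if orf is None:
            continue
        if universe is not None and tid not in universe:
            continue
        total += 1
        if kozak_match(seqs[tid], orf.start, tid).match:
            matched += 1
    return matched, total, (matched / total if total else None)
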