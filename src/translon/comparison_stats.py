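"""Reference-vs-Revised annotation comparison and NMD enrichment statistics.

The enrichment logic follows the observation that after NMD inhibition
direct targets rise in steady-state abundance while indirect (trans)
effects move transcripts in both directions.  The NMD enrichment factor is
the up/down ratio of PTC_dEJ transcripts divided by the up/down ratio of
normal-stop transcripts; values above 1 indicate that transcripts carrying
the exon-junction NMD trigger are preferentially up-regulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .nmd_features import NmdFeatureRecord, StopClass
from .start_harmonization import AnnotationSet

__all__ = [
    "DeStatus",
    "DeRecord",
    "TransitionTable",
    "EnrichmentReport",
    "Utr3Comparison",
    "read_de_table",
    "classify_de",
    "intersect_universe",
    "transition_table",
    "changed_start_set",
    "enrichment_report",
    "compare_enrichment",
    "utr3_comparison",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 1.0


class DeStatus(Enum):
    UP = "UP"
    DOWN = "DOWN"
    NO_CHANGE = "NO_CHANGE"


@dataclass(frozen=True)
class DeRecord:
    transcript_id: str
    qval: float
    log2fc: float
    status: DeStatus


def read_de_table(
    path,
    id_col: str = "transcript_id",
    qval_col: str = "qval",
    lfc_col: str = "log2fc",
) -> pd.DataFrame:
    """Read a differential-transcript-expression table (CSV or TSV).

    Column names are configurable; the result is normalised to columns
    transcript_id / qval / log2fc.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in (id_col, qval_col, lfc_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE-table column(s) {missing}")
    out = df[[id_col, qval_col, lfc_col]].copy()
    out.columns = ["transcript_id", "qval", "log2fc"]
    out["transcript_id"] = out["transcript_id"].astype(str)
    return out


def classify_de(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> List[DeRecord]:
    """UP iff qval < alpha and log2fc > lfc_threshold; DOWN iff qval <
    alpha and log2fc < -lfc_threshold; otherwise NO_CHANGE.  All
    inequalities are strict."""
    records: List[DeRecord] = []
    for i, row in enumerate(table.itertuples(index=False)):
        q, lfc = float(row.qval), float(row.log2fc)
        if not (math.isfinite(q) and 0.0 <= q <= 1.0 and math.isfinite(lfc)):
            raise ValueError(
                f"malformed DE row {i}: qval={row.qval!r} log2fc={row.log2fc!r}"
            )
        if q < alpha and lfc > lfc_threshold:
            status = DeStatus.UP
        elif q < alpha and lfc < -lfc_threshold:
            status = DeStatus.DOWN
        else:
            status = DeStatus.NO_CHANGE
        records.append(DeRecord(str(row.transcript_id), q, lfc, status))
    return records


# ---------------------------------------------------------------------------
# Annotation-set comparison (transition table, changed starts)
# ---------------------------------------------------------------------------

def _by_tid(features: Iterable[NmdFeatureRecord]) -> Dict[str, NmdFeatureRecord]:
    return {r.transcript_id: r for r in features}


_CLASSIFIABLE = (StopClass.NORMAL, StopClass.PTC_DEJ)


def intersect_universe(
    a_features: Iterable[NmdFeatureRecord],
    b_features: Iterable[NmdFeatureRecord],
) -> Set[str]:
    """Transcript ids with a classifiable stop (Normal or PTC_dEJ) in both
    feature sets — the like-for-like comparison universe."""
    a = _by_tid(a_features)
    b = _by_tid(b_features)
    return {
        tid
        for tid in a.keys() & b.keys()
        if a[tid].stop_class in _CLASSIFIABLE and b[tid].stop_class in _CLASSIFIABLE
    }


@dataclass(frozen=True)
class TransitionTable:
    """Stop-class cross-tabulation between two annotations (a -> b)."""

    normal_to_normal: int
    normal_to_ptc: int
    ptc_to_normal: int
    ptc_to_ptc: int
    universe: frozenset

    @property
    def total(self) -> int:
        return (
            self.normal_to_normal
            + self.normal_to_ptc
            + self.ptc_to_normal
            + self.ptc_to_ptc
        )

    def as_dict(self) -> Dict[str, int]:
        return {
            "normal_to_normal": self.normal_to_normal,
            "normal_to_ptc_dej": self.normal_to_ptc,
            "ptc_dej_to_normal": self.ptc_to_normal,
            "ptc_dej_to_ptc_dej": self.ptc_to_ptc,
        }


def transition_table(
    a_features: Iterable[NmdFeatureRecord],
    b_features: Iterable[NmdFeatureRecord],
) -> TransitionTable:
    a = _by_tid(a_features)
    b = _by_tid(b_features)
    universe = intersect_universe(a.values(), b.values())
    counts = {(x, y): 0 for x in _CLASSIFIABLE for y in _CLASSIFIABLE}
    for tid in universe:
        counts[(a[tid].stop_class, b[tid].stop_class)] += 1
    return TransitionTable(
        normal_to_normal=counts[(StopClass.NORMAL, StopClass.NORMAL)],
        normal_to_ptc=counts[(StopClass.NORMAL, StopClass.PTC_DEJ)],
        ptc_to_normal=counts[(StopClass.PTC_DEJ, StopClass.NORMAL)],
        ptc_to_ptc=counts[(StopClass.PTC_DEJ, StopClass.PTC_DEJ)],
        universe=frozenset(universe),
    )


def changed_start_set(
    a: AnnotationSet,
    b: AnnotationSet,
    universe: Optional[Iterable[str]] = None,
) -> Set[str]:
    """Ids whose ORF start transcript-coordinate differs between the two
    annotation sets.  Restricted to ``universe`` when given, else to ids
    with an ORF in both sets."""
    if universe is None:
        ids = {
            tid
            for tid, orf in a.orfs.items()
            if orf is not None and b.orfs.get(tid) is not None
        }
    else:
        ids = set(universe)
    out = set()
    for tid in ids:
        oa, ob = a.orfs.get(tid), b.orfs.get(tid)
        if oa is None or ob is None:
            continue
        if oa.start != ob.start:
            out.add(tid)
    return out


# ---------------------------------------------------------------------------
# Enrichment over a DE table
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    """Up/no-change/down x stop-class counts with ratios, the NMD
    enrichment factor, and a two-sided Fisher exact p on the
    (up, down) x (PTC_dEJ, normal) table."""

    counts: Dict[Tuple[str, str], int]
    n_dropped: int
    ratio_ptc: Optional[float]
    ratio_normal: Optional[float]
    nmd_enrichment_factor: Optional[float]
    factor_undefined: bool
    fisher_p: float

    def count(self, status: DeStatus, stop_class: StopClass) -> int:
        return self.counts.get((status.value, stop_class.label), 0)

    @property
    def up_ptc(self) -> int:
        return self.count(DeStatus.UP, StopClass.PTC_DEJ)

    @property
    def down_ptc(self) -> int:
        return self.count(DeStatus.DOWN, StopClass.PTC_DEJ)

    @property
    def up_normal(self) -> int:
        return self.count(DeStatus.UP, StopClass.NORMAL)

    @property
    def down_normal(self) -> int:
        return self.count(DeStatus.DOWN, StopClass.NORMAL)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for status in DeStatus:
            for cls in _CLASSIFIABLE:
                rows.append(
                    {
                        "de_status": status.value,
                        "stop_class": cls.label,
                        "n": self.counts.get((status.value, cls.label), 0),
                    }
                )
        return pd.DataFrame(rows)


def enrichment_report(
    de_records: Sequence[DeRecord],
    features: Iterable[NmdFeatureRecord],
) -> EnrichmentReport:
    """Crosstab DE status against stop class and compute the NMD
    enrichment factor.

    DE ids absent from the feature table (or without a classifiable stop)
    are dropped and counted; a zero denominator flags the factor undefined
    rather than raising.
    """
    feats = _by_tid(features)
    counts: Dict[Tuple[str, str], int] = {}
    dropped = 0
    for rec in de_records:
        f = feats.get(rec.transcript_id)
        if f is None or f.stop_class not in _CLASSIFIABLE:
            dropped += 1
            continue
        key = (rec.status.value, f.stop_class.label)
        counts[key] = counts.get(key, 0) + 1
    if dropped:
        logger.info("enrichment_report: dropped %d DE ids without classifiable features", dropped)

    up_ptc = counts.get((DeStatus.UP.value, StopClass.PTC_DEJ.label), 0)
    down_ptc = counts.get((DeStatus.DOWN.value, StopClass.PTC_DEJ.label), 0)
    up_norm = counts.get((DeStatus.UP.value, StopClass.NORMAL.label), 0)
    down_norm = counts.get((DeStatus.DOWN.value, StopClass.NORMAL.label), 0)

    ratio_ptc = up_ptc / down_ptc if down_ptc else None
    ratio_normal = up_norm / down_norm if down_norm else None
    undefined = down_ptc == 0 or down_norm == 0 or up_norm == 0
    factor: Optional[float]
    if undefined:
        factor = None
    else:
        factor = (up_ptc / down_ptc) / (up_norm / down_norm)
    _, fisher_p = stats.fisher_exact(
        [[up_ptc, up_norm], [down_ptc, down_norm]], alternative="two-sided"
    )
    return EnrichmentReport(
        counts=counts,
        n_dropped=dropped,
        ratio_ptc=ratio_ptc,
        ratio_normal=ratio_normal,
        nmd_enrichment_factor=factor,
        factor_undefined=undefined,
        fisher_p=float(fisher_p),
    )


def compare_enrichment(
    a_report: EnrichmentReport, b_report: EnrichmentReport
) -> Tuple[float, bool]:
    """Two-sided Fisher exact p comparing the up/down PTC_dEJ split of two
    reports.  Returns (p, degenerate) where degenerate marks a zero margin
    (p is then 1 by convention)."""
    table = np.array(
        [
            [a_report.up_ptc, a_report.down_ptc],
            [b_report.up_ptc, b_report.down_ptc],
        ]
    )
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        return 1.0, True
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), False


@dataclass(frozen=True)
class Utr3Comparison:
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    n: int
    p: Optional[float]


def utr3_comparison(
    de_records: Sequence[DeRecord],
    a_features: Iterable[NmdFeatureRecord],
    b_features: Iterable[NmdFeatureRecord],
    paired: bool = True,
) -> Optional[Utr3Comparison]:
    """Compare 3'UTR lengths of up-regulated transcripts under two
    annotations.

    The same UP transcripts are measured under both annotations, so the
    default test is the paired two-sided Wilcoxon signed-rank test;
    ``paired=False`` switches to the rank-sum (Mann-Whitney) test.
    Returns None when no paired UP transcript exists; with n == 1 (or all
    paired differences zero for the signed-rank test) the summary is
    reported with p = None / 1 respectively.
    """
    a = _by_tid(a_features)
    b = _by_tid(b_features)
    xs: List[float] = []
    ys: List[float] = []
    for rec in de_records:
        if rec.status is not DeStatus.UP:
            continue
        fa, fb = a.get(rec.transcript_id), b.get(rec.transcript_id)
        if fa is None or fb is None:
            continue
        if fa.utr3_length is None or fb.utr3_length is None:
            continue
        xs.append(float(fa.utr3_length))
        ys.append(float(fb.utr3_length))
    n = len(xs)
    if n == 0:
        return None
    xa, ya = np.asarray(xs), np.asarray(ys)
    p: Optional[float]
    if n == 1:
        p = None
    elif paired:
        diffs = ya - xa
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(xa, ya, alternative="two-sided").pvalue)
    else:
        p = float(stats.mannwhitneyu(xa, ya, alternative="two-sided").pvalue)
    return Utr3Comparison(
        mean_a=float(xa.mean()),
        mean_b=float(ya.mean()),
        median_a=float(np.median(xa)),
        median_b=float(np.median(ya)),
        n=n,
        p=p,
    )
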