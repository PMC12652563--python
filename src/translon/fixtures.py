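"""Synthetic genome + multi-isoform GTF generator with built-in ground truth.

Each gene carries a canonical isoform with a designed main ORF and,
depending on the event type, a second isoform produced by intron
retention, alternative acceptor-site usage, or exon skipping.  Retained
introns and acceptor extensions start with a stop block that terminates
translation in every reading frame, so the Revised (authentic-start) ORF
of the event isoform ends early with an exon junction >= 50 nt downstream
(a planted PTC_dEJ), while a planted in-frame internal ATG gives the
Reference (longest-ORF) annotation a longer downstream ORF with a
normal-looking stop — the misannotation pattern the harmonizer corrects.
The exon-skipping event shifts frame and yields a PTC_dEJ under *both*
annotations.

All filler sequence (UTRs, introns, CDS filler codons) is drawn from
{C, G, T} only, so the sole ATG and stop triplets in any transcript are
the planted ones and the emitted TruthTable is exact by construction.
A single seeded pseudo-random stream drives every choice; the same spec
and seed reproduce byte-identical output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
from random import Random

from .annotation_io import (
    ExonInterval,
    TranscriptModel,
    reverse_complement,
    write_gtf,
)
from .orf_discovery import OrfAnnotation

__all__ = [
    "Event",
    "FixtureSpec",
    "FixtureResult",
    "generate_fixture",
    "generate_de_table",
    "score_against_truth",
]

#: Stop codons in all three reading frames (TAA at offsets 0, 4 and 8).
STOP_BLOCK = "TAACTAACTAA"

_FILLER_ALPHABET = "CGT"
_SAFE_CODONS = [a + b + c for a in "CGT" for b in "CGT" for c in "CGT"]

GENES_PER_CHROM = 100


class Event(Enum):
    NONE = "NONE"
    INTRON_RETENTION = "INTRON_RETENTION"
    ALT_ACCEPTOR = "ALT_ACCEPTOR"
    EXON_SKIP = "EXON_SKIP"


@dataclass
class FixtureSpec:
    """Parameters of a synthetic transcriptome.

    ``isoform_events`` weights the alternative-splicing event planted per
    gene; ``kozak_prob`` is the probability that a gene's authentic start
    is given a strong Kozak context.
    """

    n_genes: int = 200
    isoform_events: Dict[Event, float] = field(
        default_factory=lambda: {
            Event.NONE: 0.25,
            Event.INTRON_RETENTION: 0.30,
            Event.ALT_ACCEPTOR: 0.25,
            Event.EXON_SKIP: 0.20,
        }
    )
    utr5_range: Tuple[int, int] = (12, 30)
    utr3_range: Tuple[int, int] = (30, 60)
    intergenic_gap: int = 100
    fraction_minus_strand: float = 0.4
    kozak_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(w < 0 for w in self.isoform_events.values()) or (
            sum(self.isoform_events.values()) <= 0
        ):
            raise ValueError("event weights must be nonnegative with positive sum")
        if self.utr5_range[0] < 4 or self.utr5_range[0] > self.utr5_range[1]:
            raise ValueError("utr5_range must be a valid range with min >= 4")
        if self.utr3_range[0] < 10 or self.utr3_range[0] > self.utr3_range[1]:
            raise ValueError("utr3_range must be a valid range with min >= 10")
        if self.intergenic_gap < 1:
            raise ValueError("intergenic_gap must be positive")
        if not 0 <= self.fraction_minus_strand <= 1:
            raise ValueError("fraction_minus_strand must be in [0, 1]")
        if not 0 <= self.kozak_prob <= 1:
            raise ValueError("kozak_prob must be in [0, 1]")


@dataclass
class _GeneDesign:
    gene_seq: str  # transcript-orientation genomic sequence of the locus
    # isoform name suffix -> gene-local (offset, length) exon segments,
    # 5'->3' transcript order
    isoforms: Dict[str, List[Tuple[int, int]]]
    truth_rows: List[Dict]  # per-isoform expectations, transcript coords


def _filler(rng: Random, n: int, first: Optional[str] = None) -> str:
    if n <= 0:
        return ""
    chars = [rng.choice(_FILLER_ALPHABET) for _ in range(n)]
    if first is not None:
        chars[0] = first
    return "".join(chars)


def _codons(rng: Random, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def _utr5(rng: Random, spec: FixtureSpec, kozak: bool) -> str:
    n = rng.randint(*spec.utr5_range)
    r3 = "G" if kozak else rng.choice("CT")
    return _filler(rng, n - 3) + r3 + _filler(rng, 2)


def _first_codon(rng: Random, kozak: bool) -> str:
    # Kozak needs +4 = G and +5 in {A,C,G}; second base restricted to C/G
    # so no ATG can arise across the codon boundary.
    if kozak:
        return "G" + rng.choice("CG") + rng.choice(_FILLER_ALPHABET)
    return "C" + _filler(rng, 2)


def _utr3(rng: Random, spec: FixtureSpec) -> str:
    return _filler(rng, rng.randint(*spec.utr3_range), first="C")


def _build_three_exon_gene(
    rng: Random, spec: FixtureSpec, event: Event, kozak: bool
) -> _GeneDesign:
    """NONE, INTRON_RETENTION and ALT_ACCEPTOR genes (3 exons)."""
    a1 = rng.randint(15, 25)
    a2 = rng.randint(15, 25)
    a3 = rng.randint(25, 35)
    u5 = _utr5(rng, spec, kozak)
    e1 = u5 + "ATG" + _first_codon(rng, kozak) + _codons(rng, a1 - 1)
    with_internal = event in (Event.INTRON_RETENTION, Event.ALT_ACCEPTOR)
    if with_internal:
        # Planted in-frame internal Met; the following codon starts with C
        # so the internal start never matches the Kozak consensus.
        e2 = "ATG" + "C" + _filler(rng, 2) + _codons(rng, a2 - 2)
    else:
        e2 = _codons(rng, a2)
    e3 = _codons(rng, a3) + "TAA" + _utr3(rng, spec)

    if event is Event.INTRON_RETENTION:
        i1 = STOP_BLOCK + _filler(rng, 46, first="C") + "CCC"  # 60 nt
    elif event is Event.ALT_ACCEPTOR:
        ext = STOP_BLOCK + _filler(rng, 6, first="C") + "CCC"  # 20 nt
        i1 = _filler(rng, 37, first="C") + ext  # 57 nt
    else:
        i1 = _filler(rng, 50, first="C")
    i2 = _filler(rng, 50, first="C")

    len_e1, len_i1, len_e2, len_e3 = len(e1), len(i1), len(e2), len(e3)
    off_e2 = len_e1 + len_i1
    off_e3 = off_e2 + len_e2 + len(i2)
    gene_seq = e1 + i1 + e2 + i2 + e3

    u5len = len(u5)
    k_total = 1 + a1 + a2 + a3
    canon_stop_end = u5len + 3 * (k_total + 1)
    canonical = {
        "event": event.value,
        "ref_start": u5len,
        "ref_stop_end": canon_stop_end,
        "ref_class": "Normal",
        "ref_kozak": kozak,
        "ref_protein_len": k_total,
        "rev_start": u5len,
        "rev_stop_end": canon_stop_end,
        "rev_class": "Normal",
        "rev_kozak": kozak,
        "rev_protein_len": k_total,
        "rev_status": "HARMONIZED",
    }

    isoforms = {"1": [(0, len_e1), (off_e2, len_e2), (off_e3, len_e3)]}
    truth_rows = [dict(canonical, suffix="1")]

    if event is Event.INTRON_RETENTION:
        isoforms["2"] = [(0, len_e1 + len_i1 + len_e2), (off_e3, len_e3)]
        internal_start = len_e1 + len_i1
        truth_rows.append(
            {
                "suffix": "2",
                "event": event.value,
                "ref_start": internal_start,
                "ref_stop_end": internal_start + 3 * (a2 + a3) + 3,
                "ref_class": "Normal",
                "ref_kozak": False,
                "ref_protein_len": a2 + a3,
                "rev_start": u5len,
                "rev_stop_end": len_e1 + 3,
                "rev_class": "PTC_dEJ",
                "rev_kozak": kozak,
                "rev_protein_len": 1 + a1,
                "rev_status": "HARMONIZED",
            }
        )
    elif event is Event.ALT_ACCEPTOR:
        d = 20
        isoforms["2"] = [(0, len_e1), (off_e2 - d, d + len_e2), (off_e3, len_e3)]
        internal_start = len_e1 + d
        truth_rows.append(
            {
                "suffix": "2",
                "event": event.value,
                "ref_start": internal_start,
                "ref_stop_end": internal_start + 3 * (a2 + a3) + 3,
                "ref_class": "Normal",
                "ref_kozak": False,
                "ref_protein_len": a2 + a3,
                "rev_start": u5len,
                "rev_stop_end": len_e1 + 3,
                "rev_class": "PTC_dEJ",
                "rev_kozak": kozak,
                "rev_protein_len": 1 + a1,
                "rev_status": "HARMONIZED",
            }
        )

    return _GeneDesign(gene_seq, isoforms, truth_rows)


def _build_skip_gene(rng: Random, spec: FixtureSpec, kozak: bool) -> _GeneDesign:
    """EXON_SKIP genes (4 exons; skipping exon 2 shifts frame by one)."""
    a1 = rng.randint(28, 36)
    a2 = rng.randint(10, 16)
    g = rng.randint(2, 6)
    r = rng.randint(16, 22)
    a4 = rng.randint(5, 10)
    u5 = _utr5(rng, spec, kozak)
    e1 = u5 + "ATG" + _first_codon(rng, kozak) + _codons(rng, a1 - 1)
    e2 = _codons(rng, a2) + rng.choice(_FILLER_ALPHABET)  # 3*a2 + 1 nt
    # "CTAACC" reads CTA ACC in the canonical frame but contains TAA in
    # the +1-shifted frame created by skipping exon 2.
    e3 = _filler(rng, 2) + _codons(rng, g) + "CTAACC" + _codons(rng, r)
    e4 = _codons(rng, a4) + "TAA" + _utr3(rng, spec)
    i1 = _filler(rng, 50, first="C")
    i2 = _filler(rng, 50, first="C")
    i3 = _filler(rng, 50, first="C")

    len_e1, len_e2, len_e3, len_e4 = len(e1), len(e2), len(e3), len(e4)
    off_e2 = len_e1 + len(i1)
    off_e3 = off_e2 + len_e2 + len(i2)
    off_e4 = off_e3 + len_e3 + len(i3)
    gene_seq = e1 + i1 + e2 + i2 + e3 + i3 + e4

    u5len = len(u5)
    k_total = a1 + a2 + g + r + a4 + 4
    canon_stop_end = u5len + 3 * (k_total + 1)
    truth_rows = [
        {
            "suffix": "1",
            "event": Event.EXON_SKIP.value,
            "ref_start": u5len,
            "ref_stop_end": canon_stop_end,
            "ref_class": "Normal",
            "ref_kozak": kozak,
            "ref_protein_len": k_total,
            "rev_start": u5len,
            "rev_stop_end": canon_stop_end,
            "rev_class": "Normal",
            "rev_kozak": kozak,
            "rev_protein_len": k_total,
            "rev_status": "HARMONIZED",
        },
        {
            "suffix": "2",
            "event": Event.EXON_SKIP.value,
            "ref_start": u5len,
            "ref_stop_end": len_e1 + 3 * g + 6,
            "ref_class": "PTC_dEJ",
            "ref_kozak": kozak,
            "ref_protein_len": a1 + g + 2,
            "rev_start": u5len,
            "rev_stop_end": len_e1 + 3 * g + 6,
            "rev_class": "PTC_dEJ",
            "rev_kozak": kozak,
            "rev_protein_len": a1 + g + 2,
            "rev_status": "HARMONIZED",
        },
    ]
    isoforms = {
        "1": [(0, len_e1), (off_e2, len_e2), (off_e3, len_e3), (off_e4, len_e4)],
        "2": [(0, len_e1), (off_e3, len_e3), (off_e4, len_e4)],
    }
    return _GeneDesign(gene_seq, isoforms, truth_rows)


@dataclass
class FixtureResult:
    genome: Dict[str, str]
    genes: Dict[str, List[TranscriptModel]]
    truth: pd.DataFrame
    spec: FixtureSpec

    def write(self, out_dir: str | os.PathLike) -> Dict[str, Path]:
        """Write genome.fa, annotation.gtf (exons plus Reference-ORF CDS
        lines, usable as a published-annotation stand-in) and truth.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gtf": out / "annotation.gtf",
            "truth": out / "truth.csv",
        }
        with open(paths["genome"], "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        ref_orfs = {
            row.transcript_id: OrfAnnotation(
                row.transcript_id,
                int(row.ref_start),
                int(row.ref_stop_end),
                True,
                "",
            )
            for row in self.truth.itertuples(index=False)
        }
        write_gtf(self.genes, ref_orfs, paths["gtf"], source="translon_fixture")
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def generate_fixture(
    spec: FixtureSpec, out_dir: Optional[str | os.PathLike] = None
) -> FixtureResult:
    """Generate a synthetic genome, transcript models and TruthTable.

    Deterministic given ``spec.seed``; with ``out_dir`` the standard
    FASTA/GTF/CSV files are also written.
    """
    spec.validate()
    rng = Random(spec.seed)
    events = list(spec.isoform_events.keys())
    weights = [spec.isoform_events[e] for e in events]

    chrom_parts: Dict[str, List[str]] = {}
    chrom_cursor: Dict[str, int] = {}
    genes: Dict[str, List[TranscriptModel]] = {}
    truth_rows: List[Dict] = []

    for idx in range(spec.n_genes):
        gene_id = f"SYNG{idx + 1:05d}"
        chrom = f"chr{idx // GENES_PER_CHROM + 1}"
        event = rng.choices(events, weights)[0]
        kozak = rng.random() < spec.kozak_prob
        strand = "-" if rng.random() < spec.fraction_minus_strand else "+"

        if event is Event.EXON_SKIP:
            design = _build_skip_gene(rng, spec, kozak)
        else:
            design = _build_three_exon_gene(rng, spec, event, kozak)

        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.get(chrom, 0)
        gap = _filler(rng, spec.intergenic_gap)
        parts.append(gap)
        g0 = cursor + len(gap)
        locus_len = len(design.gene_seq)
        parts.append(
            design.gene_seq if strand == "+" else reverse_complement(design.gene_seq)
        )
        chrom_cursor[chrom] = g0 + locus_len

        models: List[TranscriptModel] = []
        for suffix in sorted(design.isoforms):
            segments = design.isoforms[suffix]
            exons = []
            for off, ln in segments:
                if strand == "+":
                    exons.append(ExonInterval(chrom, g0 + off, g0 + off + ln, "+"))
                else:
                    exons.append(
                        ExonInterval(
                            chrom, g0 + locus_len - off - ln, g0 + locus_len - off, "-"
                        )
                    )
            models.append(
                TranscriptModel(f"{gene_id}.{suffix}", gene_id, chrom, strand, tuple(exons))
            )
        genes[gene_id] = models
        for row in design.truth_rows:
            row = dict(row)
            suffix = row.pop("suffix")
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": f"{gene_id}.{suffix}",
                    "chrom": chrom,
                    "strand": strand,
                    **row,
                }
            )

    genome = {c: "".join(chrom_parts[c]) for c in chrom_parts}
    truth = pd.DataFrame(truth_rows)
    result = FixtureResult(genome, genes, truth, spec)
    if out_dir is not None:
        result.write(out_dir)
    return result


def generate_de_table(
    truth: pd.DataFrame,
    p_up_ptc: float = 0.30,
    p_up_normal: float = 0.15,
    p_down: float = 0.15,
    seed: int = 0,
    out_path: Optional[str | os.PathLike] = None,
) -> Tuple[pd.DataFrame, Optional[float]]:
    """Plant a differential-expression table over the fixture transcripts.

    Per transcript, UP is drawn with probability ``p_up_ptc`` or
    ``p_up_normal`` depending on its planted Revised stop class, DOWN with
    ``p_down``, otherwise NO_CHANGE; q-values and log2 fold changes are
    drawn to satisfy the standard thresholds (q < 0.05, |log2FC| > 1) for
    the assigned status.  Returns the table and the expected NMD
    enrichment factor (p_up_ptc/p_down)/(p_up_normal/p_down); with
    ``out_path`` the table is written as CSV together with a
    ``<out_path>.expected.json`` sidecar.
    """
    for p in (p_up_ptc, p_up_normal, p_down):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = Random(seed)
    rows = []
    for row in truth.itertuples(index=False):
        p_up = p_up_ptc if row.rev_class == "PTC_dEJ" else p_up_normal
        u = rng.random()
        if u < p_up:
            qval = rng.uniform(1e-6, 0.04)
            lfc = rng.uniform(1.5, 5.0)
        elif u < p_up + p_down:
            qval = rng.uniform(1e-6, 0.04)
            lfc = -rng.uniform(1.5, 5.0)
        else:
            qval = rng.uniform(0.1, 0.95)
            lfc = rng.uniform(-0.8, 0.8)
        rows.append(
            {"transcript_id": row.transcript_id, "qval": qval, "log2fc": lfc}
        )
    df = pd.DataFrame(rows)
    expected = (
        (p_up_ptc / p_down) / (p_up_normal / p_down)
        if p_down > 0 and p_up_normal > 0
        else None
    )
    if out_path is not None:
        df.to_csv(out_path, index=False)
        with open(f"{out_path}.expected.json", "w") as fh:
            json.dump(
                {
                    "expected_enrichment_factor": expected,
                    "p_up_ptc": p_up_ptc,
                    "p_up_normal": p_up_normal,
                    "p_down": p_down,
                },
                fh,
                indent=2,
            )
    return df, expected


def score_against_truth(
    result: FixtureResult,
    min_protein_len: int = 30,
    dej_threshold: int = 50,
) -> Dict:
    """Run the full annotation pipeline on a fixture and compare every
    transcript's Reference and Revised ORF, stop class, Kozak match and
    harmonization status against the TruthTable.

    Returns a dict with totals, the number of exactly matching
    transcripts, per-field mismatch examples, and the computed annotation
    sets / feature records for reuse.
    """
    from .nmd_features import build_feature_records
    from .start_harmonization import annotate_reference, annotate_revised

    ref = annotate_reference(result.genes, result.genome, min_protein_len)
    rev = annotate_revised(result.genes, result.genome, min_protein_len)
    ref_feats = {
        r.transcript_id: r
        for r in build_feature_records(ref, result.genes, result.genome, dej_threshold)
    }
    rev_feats = {
        r.transcript_id: r
        for r in build_feature_records(rev, result.genes, result.genome, dej_threshold)
    }

    mismatches: List[Dict] = []
    n = 0
    for row in result.truth.itertuples(index=False):
        n += 1
        tid = row.transcript_id
        problems: List[str] = []
        for mode, ann, feats in (("ref", ref, ref_feats), ("rev", rev, rev_feats)):
            orf = ann.orfs.get(tid)
            feat = feats[tid]
            exp_start = getattr(row, f"{mode}_start")
            exp_stop = getattr(row, f"{mode}_stop_end")
            exp_class = getattr(row, f"{mode}_class")
            exp_kozak = bool(getattr(row, f"{mode}_kozak"))
            exp_plen = getattr(row, f"{mode}_protein_len")
            if orf is None:
                problems.append(f"{mode}: no ORF")
                continue
            if orf.start != exp_start:
                problems.append(f"{mode}_start {orf.start} != {exp_start}")
            if orf.stop_end != exp_stop:
                problems.append(f"{mode}_stop_end {orf.stop_end} != {exp_stop}")
            if orf.protein_length != exp_plen:
                problems.append(
                    f"{mode}_protein_len {orf.protein_length} != {exp_plen}"
                )
            if feat.stop_class.label != exp_class:
                problems.append(f"{mode}_class {feat.stop_class.label} != {exp_class}")
            if bool(feat.kozak_match) != exp_kozak:
                problems.append(f"{mode}_kozak {feat.kozak_match} != {exp_kozak}")
        gid = row.gene_id
        assignment = rev.assignments.get(gid)
        if assignment is None:
            problems.append("rev: missing gene assignment")
        else:
            status = assignment.per_transcript_status.get(tid)
            if status is None or status.value != row.rev_status:
                problems.append(f"rev_status {status} != {row.rev_status}")
        if problems:
            mismatches.append({"transcript_id": tid, "problems": problems})
    return {
        "n": n,
        "matched": n - len(mismatches),
        "mismatches": mismatches,
        "reference": ref,
        "revised": rev,
        "reference_features": ref_feats,
        "revised_features": rev_feats,
    }
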