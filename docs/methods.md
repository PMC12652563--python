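# Methods

## Transcript model and coordinates

A transcript is an ordered chain of exons on one strand of one sequence.
Internally all coordinates are 0-based half-open; GTF I/O converts to and
from the format's 1-based inclusive convention. An exon junction "at j"
lies between spliced-transcript nucleotides j−1 and j, i.e. j equals the
cumulative length of the preceding exons; every downstream-distance
computation uses this single convention. On read, exon lines define the
structure; CDS lines are used only when explicitly requested as the
published ORF source. Both `key "value";` and `key=value` attribute
dialects are accepted (annotations often pass through GFF3→GTF
conversion); writing emits GTF only. Transcripts with zero exon records,
or exons on mixed chromosomes/strands, are rejected rather than skipped.

## ORF discovery

Candidates are enumerated at every ATG on the sense strand and extended
codon-by-codon to the first in-frame TAA/TAG/TGA, or to the last complete
codon before the 3′ end (`has_stop=False`). Only ATG starts and the three
standard stops are considered; upstream-ORF cataloguing, non-AUG
initiation, frameshifting and selenocysteine are out of scope. Codons
containing N are never a start or a stop and translate to X — a
conservative choice that prevents ambiguity from fabricating or
destroying termination. The *longest* ORF maximizes protein length, with
ties resolved by preferring stop-terminated candidates and then the
5′-most start. The minimum protein length for main-ORF candidates
defaults to 30 aa (exposed as `--min-protein-len`); this filters
spurious micro-ORFs during start selection. Once a start has been chosen
for a transcript, harmonization never re-filters the resulting ORF by
length — a truncated 10-aa product of an authentic start is a legitimate
(and NMD-relevant) annotation.

## Gene-level start selection (Revised mode)

Each isoform contributes its own longest ORF as a candidate; candidate
starts are compared by the length of the protein they encode *in their
own transcript* (stop-terminated preferred), with ties broken by the
5′-most genomic position in transcription direction and then by
lexicographic transcript id. Identity of a start across isoforms is
defined genomically — same chromosome, strand and position of the A of
the AUG — not by transcript coordinate. The winning start is imposed on
every isoform whose spliced sequence contains that genomic position and
reads ATG there; the ORF then runs to the first in-frame stop in *that*
isoform, which is where intron retention or an alternative acceptor
produces the premature stop. Isoforms that splice the authentic start
out (or in which the codon is disrupted) keep their own longest ORF and
are flagged `FALLBACK_OWN_LONGEST`, preserving auditability; isoforms
with no candidate at all are `NONCODING`. Kozak context is *not* used in
start selection — it is reported as a downstream quality metric only.
Genes whose isoforms span multiple strands or chromosomes (annotation
errors) are harmonized per (chromosome, strand) group with a warning.

Two consequences follow and are used as test invariants: a Revised ORF is
never longer than the recomputed Reference ORF of the same transcript
(equal exactly when the starts coincide), and all harmonized isoforms of
a gene share one genomic start.

## Stop classification and NMD features

A stop codon is `PTC_dEJ` when at least one junction lies at least 50 nt
downstream of `stop_end` (the first nucleotide after the stop codon);
the threshold is inclusive at 50 and configurable (`--dej-threshold`).
The 50 nt default operationalizes the 50–55 nt exon-junction-complex
rule at its conventional lower edge. A junction exactly at `stop_end`
counts as downstream with distance 0, so it can never trigger a PTC call
at the default threshold. Stopless ORFs are `NO_STOP` and excluded from
both Normal and PTC_dEJ tallies in every downstream statistic; absent
ORFs are `Noncoding`. The feature table also reports 5′UTR length (=
ORF start), 3′UTR length (= spliced length − stop_end; 0 for stopless),
the distance to the last downstream junction, the downstream-junction
count, the Kozak match, and the protein sequence ("Translation" column).
No "long 3′UTR" cutoff is applied — lengths are reported, not
thresholded, since no principled universal cutoff exists.

## Kozak matching

`RNNATGGV` is anchored with the literal ATG at the start codon: position
−3 ∈ {A,G}, +4 = G, +5 ∈ {A,C,G}. This is the standard Kozak register
and the only alignment in which the ATG of the pattern is literal. A
start within 3 nt of the 5′ end or 2 nt of the 3′ end has no assessable
context and counts as a non-match. Rate comparisons between two
annotations are computed over the set of transcripts whose ORF start
changed, since unchanged starts carry identical contexts by construction.

## DE classification and enrichment

A transcript is UP when q < α (default 0.05) and log2FC > 1, DOWN when
q < α and log2FC < −1, strict inequalities throughout. The published
threshold statement is symmetric in magnitude; the DOWN bound is read as
−1 (a literal "< 1" would make nearly every transcript differentially
expressed). The NMD enrichment factor is
(up_PTC/down_PTC)/(up_normal/down_normal); it is undefined (flagged, not
raised) when down_PTC, down_normal or up_normal is 0, and 0 when only
up_PTC is 0. Inference uses the two-sided Fisher exact test on the
(up, down) × (PTC_dEJ, normal) table; two annotations are compared by a
Fisher test on their (up_PTC, down_PTC) splits, returning p = 1 with a
degeneracy flag on zero margins. The 3′UTR comparison measures the *same*
up-regulated transcripts under two annotations, so the default test is
the paired two-sided Wilcoxon signed-rank test (`paired=False` switches
to rank-sum); all values enter the test (outlier trimming is a plotting
concern only). DE ids absent from the feature table are dropped and
counted, mirroring like-for-like universe filtering: comparisons run
over transcripts classifiable (Normal or PTC_dEJ) in both annotations.

## Synthetic fixtures

The generator emulates the situation the method addresses: multi-isoform
genes where alternative splicing truncates the main ORF. Per gene it
draws one event type — none (canonical isoform only), intron retention,
alternative acceptor (both: a retained segment beginning with a stop
block terminates the authentic-start ORF ≥ 50 nt upstream of a remaining
junction, while a planted in-frame internal ATG gives the longest-ORF
annotation a longer, normal-looking ORF), or exon skipping (a
frame-shifting skip whose PTC is shared by both annotations). Defaults:
200 genes, event weights 0.25/0.30/0.25/0.20 (intron retention the most
frequent PTC-generating event, as in plant transcriptomes), 40% of genes
on the minus strand, strong Kozak context planted with probability 0.5,
5′UTRs of 12–30 nt and 3′UTRs of 30–60 nt, coding exons of roughly
30–110 codons — compact loci chosen so that desk-scale runs stay in the
thousands of transcripts.

All filler sequence is drawn from {C,G,T}, so the only ATG/stop triplets
in any transcript are the planted ones and the truth table (per-isoform
expected start, stop, stop class, Kozak match, protein length and
harmonization status under both modes) is exact by construction rather
than computed by the code under test. This idealisation is deliberate
and bounds what fixture tests show: real transcriptomes have uniform
base composition, many competing ORFs, non-ATG annotation artefacts and
noisy structures, which the fixtures do not emulate; fixture passes
demonstrate algorithmic correctness, not robustness to annotation noise.
The planted DE table draws UP with probability `p_up_ptc` or
`p_up_normal` conditioned on the planted Revised stop class and DOWN
with probability `p_down`, giving an expected enrichment factor of
`p_up_ptc / p_up_normal` at equal `p_down`; q-values and fold changes
are drawn inside the classification regions so planting is exact at the
thresholds. With the default probabilities (0.30/0.15/0.15) at 2000
genes, the recovered factor has a relative Monte-Carlo standard error of
about 10–12% per draw; recovery tests therefore average three seeded
replicates, which places the ±20% check at roughly three standard
errors.

## Numerical and procedural choices

- Deterministic ordering everywhere: genes and transcripts sorted by id,
  GTF records by (gene, transcript, transcript 5′→3′), one seeded
  `random.Random` stream per fixture. Reruns are byte-identical.
- CDS lines written as ORF minus stop codon, split across exons, with
  the standard frame column ((3 − cumulative CDS nt mod 3) mod 3); on
  read, CDS with the stop either excluded or included is accepted, and
  CDS failing structural checks (outside exons, non-contiguous, not a
  whole number of codons, no ATG, no valid stop, internal stop) flags
  the transcript invalid with a warning instead of failing the run.
- Problem sizes in tests and the acceptance script (200–2000 genes,
  ≈350–3500 transcripts) were chosen as the smallest sizes at which the
  Monte-Carlo checks above are well powered.

## Known limitations

- Sense-strand, ATG-initiated, standard-code ORFs only.
- The harmonizer requires the authentic start to map onto an exonic ATG;
  it does not check reading-frame compatibility across isoforms beyond
  the scan from the mapped start itself.
- The fixture generator does not plant PTC→Normal transitions (rare in
  real re-annotations); that transition cell is exercised by hand-built
  unit fixtures only.
- No expression-level or read-level simulation: the DE table plants
  statuses directly, so enrichment recovery tests the statistics, not a
  quantification pipeline.
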