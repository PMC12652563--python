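import pytest
from hypothesis import HealthCheck, settings

from translon import ExonInterval, TranscriptModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Two-isoform gene with an alternative acceptor site: the second isoform's
# own longest ORF starts at an internal ATG, but the gene-level authentic
# start truncates it to a single methionine.
MICRO_GENOME = "AAAATG" + "GA" + "TGATTTAT" + "GGAGGAGTGATTT"
T1_SEQ = "AAAATGGAGGAGGAGTGATTT"
T2_SEQ = "AAAATGTGATTTATGGAGGAGTGATTT"


@pytest.fixture
def micro_gene():
    genome = {"chr1": MICRO_GENOME}
    t1 = TranscriptModel(
        "g1.t1",
        "g1",
        "chr1",
        "+",
        (ExonInterval("chr1", 0, 8, "+"), ExonInterval("chr1", 16, 29, "+")),
    )
    t2 = TranscriptModel(
        "g1.t2",
        "g1",
        "chr1",
        "+",
        (ExonInterval("chr1", 0, 6, "+"), ExonInterval("chr1", 8, 29, "+")),
    )
    return genome, {"g1": [t1, t2]}


@pytest.fixture
def micro_gene_files(tmp_path, micro_gene):
    genome, genes = micro_gene
    fasta = tmp_path / "genome.fa"
    fasta.write_text(">chr1\n" + genome["chr1"] + "\n")
    gtf = tmp_path / "micro.gtf"
    lines = []
    for gid, models in genes.items():
        for t in models:
            for e in t.exons:
                lines.append(
                    f"chr1\ttest\texon\t{e.start + 1}\t{e.end}\t.\t+\t.\t"
                    f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
                )
    gtf.write_text("\n".join(lines) + "\n")
    return fasta, gtf
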