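import pandas as pd
import pytest

from matecall.genotypes import Thresholds
from matecall.synthetic_data import SimConfig, simulate_genomes


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=40, snp_rate=0.02, seed=11, n_libraries=2)


@pytest.fixture(scope="session")
def small_genomes(small_config):
    return simulate_genomes(small_config)


@pytest.fixture()
def toy_models():
    """Two genes on opposite strands plus an overlapping gene pair."""
    from matecall.transcripts import TranscriptModels

    exons = pd.DataFrame(
        [
            # gA: plus strand, two exons, longest tx length 400+200=600
            dict(gene_id="gA", transcript_id="gA.t1", chrom="2L", strand="+",
                 exon_start=1001, exon_end=1400),
            dict(gene_id="gA", transcript_id="gA.t1", chrom="2L", strand="+",
                 exon_start=1601, exon_end=1800),
            # shorter isoform of gA covering part of the intron
            dict(gene_id="gA", transcript_id="gA.t2", chrom="2L", strand="+",
                 exon_start=1001, exon_end=1500),
            # gB: minus strand single exon, length 1000
            dict(gene_id="gB", transcript_id="gB.t1", chrom="2L", strand="-",
                 exon_start=5001, exon_end=6000),
            # gC/gD overlap each other on opposite strands
            dict(gene_id="gC", transcript_id="gC.t1", chrom="3R", strand="+",
                 exon_start=100, exon_end=700),
            dict(gene_id="gD", transcript_id="gD.t1", chrom="3R", strand="-",
                 exon_start=500, exon_end=900),
        ]
    )
    return TranscriptModels.from_tables(exons)
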