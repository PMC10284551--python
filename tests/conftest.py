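import numpy as np
import pytest

from ribostall.io_formats import Genome, TranscriptModel, CoverageTrack
from ribostall.synthetic import SimConfig, make_genome, simulate_coverage


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 50 genes, 10 planted 5-codon CAG tracts,
    5x stalls at 20x depth, 3 ribo + 2 RNA-seq libraries."""
    cfg = SimConfig(seed=11)
    genome, annotation, truth = make_genome(cfg)
    ribo = {
        f"ribo{i + 1}": simulate_coverage(genome, annotation, truth, cfg, "ribo", i)
        for i in range(cfg.n_ribo_libs)
    }
    rna = {
        f"rna{i + 1}": simulate_coverage(genome, annotation, truth, cfg, "rna", i)
        for i in range(cfg.n_rna_libs)
    }
    return cfg, genome, annotation, truth, ribo, rna


@pytest.fixture
def toy_transcript():
    """Two-exon plus-strand transcript with a spliced CDS of 36 nt."""
    return TranscriptModel(
        gene_id="gA",
        transcript_id="gA.t1",
        chrom="chr1",
        strand="+",
        exons=[(0, 30), (60, 90)],
        cds=(9, 75),
    )


@pytest.fixture
def flat_track():
    return CoverageTrack({"chr1": np.full(120, 2.0)})
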