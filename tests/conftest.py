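import pytest

from circseq import simdata


@pytest.fixture(scope="session")
def detection_setup():
    """A detection-scale benchmark: 50 planted circRNAs, error-free reads,
    at least 5 junction reads per circRNA and sample."""
    cfg = simdata.SimConfig(
        seed=7,
        n_chrom=2,
        chrom_len=150_000,
        n_genes=60,
        n_circ=50,
        comparisons=(),
        groups=(("Exp", 2), ("Sham", 2)),
        mean_junction_reads=5.0,
        min_junction_reads=5,
        background_reads_per_sample=100,
    )
    genome, model = simdata.simulate_genome(cfg)
    truth = simdata.plant_circrnas(genome, model, cfg)
    reads, provenance = simdata.simulate_junction_reads(truth, genome, cfg)
    return cfg, genome, model, truth, reads


@pytest.fixture(scope="session")
def small_pipeline_overrides():
    """SimConfig overrides that keep pipeline tests fast."""
    return dict(
        n_chrom=2,
        chrom_len=100_000,
        n_genes=30,
        n_circ=40,
        background_reads_per_sample=50,
        n_sets=10,
        n_triads=4,
        n_mirna=12,
        n_mrna=20,
    )
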