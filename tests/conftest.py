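"""Shared fixtures: small deterministic simulations and one full
pipeline run reused by the acceptance tests."""

import pytest

import repeatscope as rs


@pytest.fixture(scope="session")
def small_config():
    """A compact planted genome exercised by several unit tests."""
    return rs.SimulationConfig(
        genome_length=120_000,
        seed=7,
        families=[
            rs.RepeatFamilySpec("gA", "LTR-Gypsy", full_copies=10, ltr_length=300,
                                internal_length=2000, solo_ltr_copies=5, divergence=0.01),
            rs.RepeatFamilySpec("mA", "MITE", full_copies=20, element_length=400,
                                divergence=0.01),
        ],
        gene_count=4,
        gene_length=1500,
        tandem_specs=[rs.TandemSpec(unit_length=50, unit_count=10, array_copies=3)],
        organellar_length=10_000,
        organellar_read_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    library = rs.build_repeat_library(small_config)
    truth = rs.plant_genome(library, small_config)
    return library, truth


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the standard 1 Mb simulated study."""
    config = rs.default_config(seed=1, genome_length=1_000_000)
    return config, rs.run_all(config)


def random_reads_from(seq, n, length, rng, prefix="r"):
    """Error-free reads sampled uniformly from one source sequence."""
    reads = []
    for i in range(n):
        start = int(rng.integers(0, len(seq) - length + 1))
        fragment = seq[start : start + length]
        if rng.random() < 0.5:
            fragment = rs.revcomp(fragment)
        reads.append(rs.Read(f"{prefix}{i:05d}", fragment, ("nuclear", start, start + length, "+")))
    return reads
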