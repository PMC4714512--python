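import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tssenrich as te

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome():
    return te.GenomeModel((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded genome / gene / expression / read set shared across tests."""
    genome, genes = te.generate_genome(2, 500_000, 100, seed=11)
    expr = te.simulate_expression(genes, zero_fraction=0.2, seed=12)
    spec = te.EnrichmentSpec(kernel_offset=500, kernel_width=500,
                             amplitude=30.0, coupling_mode="independent")
    chip = te.simulate_reads(genome, genes, expr, spec, background_depth=10.0,
                             fragment_length=200, seed=13)
    inp = te.simulate_reads(genome, genes, expr, None, background_depth=10.0,
                            fragment_length=200, seed=14)
    return genome, genes, expr, chip, inp


def make_signal(values: dict[str, np.ndarray], bin_size: int = 1000):
    return te.SignalTrack(bin_size=bin_size,
                          values={c: np.asarray(v, dtype=float)
                                  for c, v in values.items()})


def chip_minus_input(chip: pd.DataFrame, inp: pd.DataFrame,
                     genome: te.GenomeModel, bin_size: int = 1000):
    return te.subtract_control(
        te.rpkm_normalize(te.count_reads_in_bins(chip, genome, bin_size)),
        te.rpkm_normalize(te.count_reads_in_bins(inp, genome, bin_size)))
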