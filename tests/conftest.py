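import pandas as pd
import pytest

from cghcnv import GenomeSpec, SimulationConfig, design_probes


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec((("chr1", 500_000), ("chr2", 400_000)))


@pytest.fixture(scope="session")
def small_design(small_genome):
    return design_probes(small_genome, mean_spacing=1650, probe_length=60,
                         jitter_fraction=0.2, seed=7)


@pytest.fixture
def clean_config():
    """No noise, no artifacts: intensities carry pure copy-number signal."""
    return SimulationConfig(noise_sd=0.0, probe_effect_sd=0.0,
                            dye_bias=(1.0, 1.0), gradient_amplitude=0.0,
                            seed=0)


@pytest.fixture
def empty_truth():
    return pd.DataFrame(columns=["chrom", "start", "end", "copies"])


def make_truth(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "copies"])
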