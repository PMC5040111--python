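import numpy as np
import pytest

from warmclip.design import FactorialDesign
from warmclip import synthetic_data as sd
from warmclip import teco_inversion as ti


@pytest.fixture(scope="session")
def design6() -> FactorialDesign:
    return FactorialDesign(n_blocks=6)


@pytest.fixture(scope="session")
def true_params() -> ti.TecoParameters:
    return ti.TecoParameters(
        q10=2.5, k_foliage=5e-3, k_root=2e-3, k_litter=8e-3,
        k_fast=1e-3, k_slow=5e-5, k_passive=1e-6,
    )


@pytest.fixture(scope="session")
def short_drivers() -> ti.DriverSeries:
    days = np.arange(365)
    temp = 16.3 - 10.0 * np.cos(2 * np.pi * days / 365.0)
    cin = np.maximum(2.0 - np.cos(2 * np.pi * days / 365.0), 0.0)
    return ti.DriverSeries(temperature=temp, c_input=cin)


@pytest.fixture(scope="session")
def clean_fixture(design6):
    """Probe fixture with no QC failures, one subgrid, one replicate."""
    spec = sd.ArrayFixtureSpec(
        n_genes=8, probes_per_gene=3, n_subgrids=1, seed=7,
        flag_rate=0.0, low_snr_rate=0.0,
    )
    return spec, sd.generate_geochip_fixture(spec, design6)


@pytest.fixture(scope="session")
def messy_fixture(design6):
    """Probe fixture with flags, low-SNR spots, replicates, and subgrids."""
    spec = sd.ArrayFixtureSpec(
        n_genes=12, probes_per_gene=4, n_subgrids=3, seed=13,
        flag_rate=0.1, low_snr_rate=0.15, n_technical_replicates=2,
    )
    return spec, sd.generate_geochip_fixture(spec, design6)
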