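import numpy as np
import pytest

from hydr.spectra import Spectrum, analysis_grid
from hydr.synthetic import (
    default_osmolyte_truth,
    default_peptide_truth,
    make_binary_series,
)


@pytest.fixture(scope="session")
def grid():
    return analysis_grid()


@pytest.fixture(scope="session")
def peptide_truth():
    return default_peptide_truth()


@pytest.fixture(scope="session")
def osmolyte_truth():
    return default_osmolyte_truth()


@pytest.fixture(scope="session")
def peptide_series(peptide_truth):
    return make_binary_series(peptide_truth)


@pytest.fixture(scope="session")
def osmolyte_series(osmolyte_truth):
    return make_binary_series(osmolyte_truth)


@pytest.fixture
def gaussian_band(grid):
    """Unit-amplitude Gaussian band centred at 2500 cm^-1 with fwhh 160."""
    sigma = 160.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return Spectrum(grid, np.exp(-0.5 * ((grid - 2500.0) / sigma) ** 2), role="affected")
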