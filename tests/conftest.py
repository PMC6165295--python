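import numpy as np
import pytest

import afdecon as af
from afdecon import reference


@pytest.fixture(scope="session")
def serum_lib():
    return af.default_library("serum")


@pytest.fixture(scope="session")
def liver_lib():
    return af.default_library("liver")


@pytest.fixture(scope="session")
def liver_sham_means():
    """Published liver sham group-mean contributions (%)."""
    return {k: v for k, (v, _) in reference.LIVER_CONTRIBUTIONS["sham"].items()}


@pytest.fixture
def smooth_serum_spectrum(serum_lib):
    """Noise-free synthetic serum spectrum (24 h BDL-like contributions)."""
    contribs = {k: v for k, (v, _) in reference.SERUM_CONTRIBUTIONS["bdl24"].items()}
    return af.generate_spectrum(
        serum_lib, contribs, total_area=3720.0, noise_sigma=0.0, seed=0
    )


@pytest.fixture
def triangle_spectrum():
    return af.Spectrum(np.array([400.0, 500.0, 600.0]), np.array([1.0, 2.0, 1.0]))
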