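import numpy as np
import pandas as pd
import pytest

import libsionome as lb
from libsionome.spectra import SpectrumSet


@pytest.fixture(scope="session")
def library():
    return lb.default_line_library()


@pytest.fixture(scope="session")
def default_shots():
    """The default synthetic study: paper_n80 preset, seed 1, default noise."""
    return lb.generate_study(lb.paper_n80(seed=1))


@pytest.fixture(scope="session")
def analysis(default_shots):
    """Cropped, 4-shot-averaged, area-normalized analysis spectra (80 rows)."""
    return lb.preprocess(default_shots)


@pytest.fixture(scope="session")
def intensity_table(analysis, library):
    return lb.build_intensity_table(analysis, library)


@pytest.fixture(scope="session")
def tiny_shots():
    """One biological replicate per class: 4 mounts x 16 shots."""
    return lb.generate_study(lb.paper_n80(seed=3, n_biological=1))


@pytest.fixture(scope="session")
def noiseless_shots():
    """Zero-noise study, two replicates per class (spectra identical within class)."""
    return lb.generate_study(
        lb.paper_n80(seed=7, n_biological=2), noise=lb.NoiseConfig.zero()
    )


def make_set(wavelengths, rows, meta=None):
    """Helper: build a SpectrumSet from a list of intensity rows."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if meta is None:
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(rows))]})
    return SpectrumSet(np.asarray(wavelengths, dtype=float), rows, meta)
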