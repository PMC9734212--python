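import numpy as np
import pytest

import beechroma as bc


@pytest.fixture(scope="session")
def context():
    """Default Apis viewing context: D65, flat grey 0.2 background,
    nomogram receptors on the 300-700 nm working grid."""
    return bc.pipeline.RunConfig().build_context()


@pytest.fixture(scope="session")
def locus_table(context):
    """Spectral-locus table (max-distance flux mode), cached on the context."""
    return bc.spectral_locus(context)


@pytest.fixture(scope="session")
def random_reflectances(context):
    """Fifty broadband synthetic reflectance spectra (Gaussian bumps over a
    pedestal), the stand-ins for measured pigment stimuli."""
    rng = np.random.default_rng(20220359)
    grid = context.grid
    curves = []
    for i in range(50):
        vals = np.full(grid.shape, rng.uniform(0.03, 0.3))
        for _ in range(rng.integers(1, 4)):
            centre = rng.uniform(330.0, 640.0)
            width = rng.uniform(15.0, 80.0)
            amp = rng.uniform(0.05, 0.6)
            vals = vals + amp * np.exp(-0.5 * ((grid - centre) / width) ** 2)
        vals = np.clip(vals, 0.0, 1.0)
        curves.append(bc.SpectralCurve(grid, vals, "reflectance", f"synth_{i}"))
    return curves
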