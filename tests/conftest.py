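import numpy as np
import pandas as pd
import pytest

from leafspec.containers import SpectraMatrix
from leafspec.simulate import (
    SpectraParams,
    TraitParams,
    make_design,
    simulate_spectra,
    simulate_traits,
    subsample_measured,
)


def planted_band_data(n=120, p=100, seed=0, noise=0.02,
                      bands=None, coefs=(1.0, 0.8, -0.6)):
    """High-SNR regression fixture: y depends on a few known bands only.

    Default informative bands sit at 20%, 50% and 80% of the grid
    (20/50/80 for p=100).
    """
    if bands is None:
        bands = (p // 5, p // 2, (4 * p) // 5)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = sum(c * X[:, b] for b, c in zip(bands, coefs))
    y = y + rng.standard_normal(n) * noise
    return X, y


@pytest.fixture(scope="session")
def planted():
    X, y = planted_band_data(seed=0)
    Xv, yv = planted_band_data(seed=1)
    return X, y, Xv, yv


@pytest.fixture(scope="session")
def small_trial():
    """A reduced synthetic trial: 12 families x 3 reps x 4 trees."""
    design = make_design(12, 3, 4)
    traits = simulate_traits(design, TraitParams(), seed=10)
    spectra = simulate_spectra(traits, SpectraParams(), seed=11)
    measured = subsample_measured(design, 72, seed=12)
    return design, traits, spectra, measured


@pytest.fixture(scope="session")
def spectra_10x234():
    """Ten smooth synthetic spectra on the default instrument grid."""
    params = SpectraParams(noise_sd=0.0, scatter_sd=0.0)
    traits = pd.DataFrame(
        {
            "tree_id": [f"S{i}" for i in range(10)],
            "anth": np.linspace(1, 4, 10),
            "flav": np.linspace(4, 1, 10),
            "chl": np.linspace(2, 3, 10),
        }
    )
    return simulate_spectra(traits, params, seed=0)


def as_spectra(X, start=1100.0, step=6.0, ids=None):
    n, p = X.shape
    return SpectraMatrix(
        values=X,
        wavelengths=start + step * np.arange(p),
        sample_ids=ids or [f"S{i}" for i in range(n)],
    )
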