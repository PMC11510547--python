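import numpy as np
import pandas as pd
import pytest

from chemoextract import datasets
from chemoextract.design import FactorSpec, build_full_factorial
from chemoextract.synthetic import (
    default_ccd_design,
    default_factorial_design,
    factorial_factors,
)


@pytest.fixture(scope="session")
def antioxidant_ccd():
    """The packaged 22-run antioxidant CCD: (design, response Y)."""
    return datasets.load_antioxidant_ccd()


@pytest.fixture(scope="session")
def dpph_points():
    return datasets.load_dpph_points()


@pytest.fixture()
def factorial():
    """Replicated 3^3 factorial with the two aborted runs removed (34 runs)."""
    return default_factorial_design()


@pytest.fixture()
def plain_factorial():
    """Unreplicated 27-run factorial."""
    return build_full_factorial(factorial_factors())


@pytest.fixture()
def ccd_design():
    return default_ccd_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240925)


def make_spectra_with_band_effect(design, effect_scale=1.0, noise_sd=0.02,
                                  lo=330.0, hi=370.0, seed=0):
    """Spectra whose temperature effect is confined exactly to [lo, hi] nm.

    A raised-cosine bump supported on [lo, hi] is added for the low
    temperature level and subtracted elsewhere, on top of a fixed base
    spectrum and white noise. Returns (SpectraSet, boolean in-band mask).
    """
    from chemoextract.spectral_asca import SpectraSet

    rng = np.random.default_rng(seed)
    wl = np.arange(220.0, 400.0 + 0.5, 1.0)
    in_band = (wl >= lo) & (wl <= hi)
    bump = np.zeros_like(wl)
    bump[in_band] = 0.5 * (1 - np.cos(2 * np.pi * (wl[in_band] - lo) / (hi - lo)))
    base = np.exp(-0.5 * ((wl - 280.0) / 30.0) ** 2)
    levels = design.natural["T"]
    low = levels == levels.min()
    sign = np.where(low.to_numpy(), 1.0, -0.5)
    X = base[None, :] + effect_scale * sign[:, None] * bump[None, :]
    X = X + rng.normal(0.0, noise_sd, X.shape)
    ab = pd.DataFrame(X, index=design.run_ids, columns=wl)
    return SpectraSet(ab, design.natural.astype(str)), in_band
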