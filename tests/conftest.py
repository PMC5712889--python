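"""Shared fixtures: small synthetic instruments for fast tests.

The full-size default scenario (801-channel master, 700 samples) is reserved
for the acceptance tests; everything else runs on miniature instrument
profiles so the unit suite stays fast.
"""

import numpy as np
import pytest

from nirtransfer import SpectraSet
from nirtransfer.simulate import (
    AnalyteModel,
    InstrumentProfile,
    generate_paired_dataset,
)


def small_analyte() -> AnalyteModel:
    return AnalyteModel(
        band_centers=(1050.0, 1185.0, 1450.0),
        band_fwhm=(40.0, 45.0, 60.0),
        band_amp_per_unit=(0.004, 0.005, -0.004),
        interferent_centers=(1250.0,),
        interferent_fwhm=(80.0,),
        interferent_amp_sd=(0.02,),
        beer_nonlinearity=0.0,
    )


def small_master_profile() -> InstrumentProfile:
    return InstrumentProfile(
        grid=np.arange(1000.0, 1601.0, 10.0),
        smoothing_fwhm=6.0,
        noise_sd=0.002,
    )


def small_slave_profile() -> InstrumentProfile:
    wavenumbers = np.arange(10010.0, 6240.0, -40.0)
    return InstrumentProfile(
        grid=np.sort(1e7 / wavenumbers),
        gain=1.1,
        baseline_offset=0.05,
        wavelength_shift=1.5,
        smoothing_fwhm=10.0,
        noise_sd=0.002,
        response_tilt=0.1,
        response_curve=-0.1,
    )


def small_pair(n: int = 80, seed: int = 0) -> tuple[SpectraSet, SpectraSet]:
    return generate_paired_dataset(
        n,
        master_profile=small_master_profile(),
        slave_profile=small_slave_profile(),
        seed=seed,
        analyte=small_analyte(),
    )


@pytest.fixture(scope="session")
def pair80():
    return small_pair(80, seed=0)


@pytest.fixture
def simple_spectra() -> SpectraSet:
    rng = np.random.default_rng(7)
    wl = np.linspace(1000.0, 1100.0, 21)
    return SpectraSet(
        wavelengths=wl,
        absorbance=rng.normal(0.5, 0.1, size=(6, wl.size)),
        reference=rng.uniform(10, 20, size=6),
    )
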