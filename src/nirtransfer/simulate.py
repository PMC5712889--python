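"""Seeded simulator of paired master/slave NIR spectra of fruit samples.

The generator emulates the study design this package targets: the same set
of grape berries measured on two rather different spectrometers — a portable
grating instrument on a uniform 1 nm grid (1000-1800 nm) acting as master,
and a benchtop Fourier-transform instrument whose grid is uniform in
wavenumber (hence non-uniform in nm) acting as slave — together with a
refractometer reference of soluble solids content (SSC, %Brix).

Clean spectra are sums of Gaussian absorption bands in the sugar/water
overtone region (a mix of broad and narrow features between 1050 and
1740 nm) whose amplitudes follow SSC through a mildly saturating Beer's-law
response, on top of a broad SSC-independent water background.  Per-sample
nuisance structure (multiplicative scatter, baseline offsets, a set of
SSC-independent interferent bands overlapping the analyte bands) makes the
regression problem non-trivial; SNV is expected to remove the scatter
terms, as on real data.

Each instrument observes the same clean spectrum through its own profile:
resolution blur, wavelength registration shift, smooth wavelength-dependent
detector response (a constant gain would be erased by SNV; a smooth response
curve is what actually separates detector technologies), baseline, and
i.i.d. noise.  Everything is deterministic given (seed, configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .spectra import SpectraSet

__all__ = [
    "AnalyteModel",
    "InstrumentProfile",
    "generate_reference",
    "generate_clean_spectrum",
    "measure",
    "generate_paired_dataset",
    "default_analyte_model",
    "default_master_profile",
    "default_slave_profile",
    "default_dense_grid",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _gaussian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    s = fwhm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((grid - center) / s) ** 2)


@dataclass
class AnalyteModel:
    """Spectral model: absorbance(lambda) = background + SSC * sum of bands.

    Band positions sit in the sugar/water overtone region; widths and
    per-unit amplitudes are simulator defaults chosen to give a realistic
    signal-to-noise regime, not measured constants.  The mix of broad and
    narrow analyte bands, overlapped by SSC-independent interferents, means
    the predictive information is spread over the full grid rather than
    concentrated in a few channels.
    """

    band_centers: tuple = (
        1050.0, 1118.0, 1185.0, 1395.0, 1450.0, 1549.0, 1581.0, 1613.0, 1740.0
    )
    band_fwhm: tuple = (30.0, 14.0, 35.0, 28.0, 45.0, 12.0, 12.0, 14.0, 24.0)
    # absorbance per %Brix
    band_amp_per_unit: tuple = (
        0.0030, 0.0028, 0.0040, 0.0022, -0.0035, 0.0030, 0.0035, 0.0028, 0.0020
    )
    bg_centers: tuple = (970.0, 1450.0, 1790.0)
    bg_fwhm: tuple = (90.0, 160.0, 140.0)
    bg_amps: tuple = (0.18, 0.90, 0.30)
    bg_offset: float = 0.35
    bg_slope: float = 1e-4  # per nm, centered at 1300 nm
    # Beer's-law saturation: band response uses ssc - k*(ssc - 12.9)^2, a
    # mild downward bend at high concentration (why an RBF model is the
    # better fit on data like this)
    beer_nonlinearity: float = 0.018
    # per-sample nuisance structure (SSC-independent)
    interferent_centers: tuple = (
        1060.0, 1140.0, 1210.0, 1250.0, 1290.0, 1330.0, 1380.0,
        1425.0, 1520.0, 1565.0, 1610.0, 1680.0, 1735.0, 1790.0,
    )
    interferent_fwhm: tuple = (
        20.0, 25.0, 18.0, 55.0, 22.0, 30.0, 20.0,
        35.0, 25.0, 20.0, 45.0, 28.0, 22.0, 30.0,
    )
    interferent_amp_sd: tuple = (
        0.006, 0.008, 0.007, 0.015, 0.006, 0.010, 0.007,
        0.009, 0.008, 0.006, 0.012, 0.008, 0.007, 0.009,
    )
    bg_amp_jitter_sd: float = 0.02  # relative jitter of the water background
    scatter_mult_sd: float = 0.04  # multiplicative scatter (SNV target)
    scatter_add_sd: float = 0.01  # additive offset (SNV target)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.band_fwhm + self.bg_fwhm):
            raise ValueError("band widths must be positive")
        if not any(a != 0 for a in self.band_amp_per_unit):
            raise ValueError("at least one band amplitude must depend on SSC")


@dataclass
class InstrumentProfile:
    """How an instrument observes a clean spectrum.

    ``response_tilt``/``response_curve`` are relative linear/quadratic terms
    of a smooth detector-response curve over the grid span; both zero means
    a flat (constant-gain) response.
    """

    grid: np.ndarray
    gain: float = 1.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0  # per nm, centered mid-grid
    wavelength_shift: float = 0.0  # nm
    smoothing_fwhm: float = 0.0  # nm of resolution blur
    noise_sd: float = 0.0  # absorbance units
    response_tilt: float = 0.0
    response_curve: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("instrument grid must be strictly increasing")
        if self.noise_sd < 0 or self.smoothing_fwhm < 0:
            raise ValueError("noise_sd and smoothing_fwhm must be >= 0")

    def response(self) -> np.ndarray:
        mid = 0.5 * (self.grid[0] + self.grid[-1])
        half = 0.5 * (self.grid[-1] - self.grid[0])
        u = (self.grid - mid) / half if half > 0 else np.zeros_like(self.grid)
        return self.gain * (1.0 + self.response_tilt * u + self.response_curve * u**2)


def default_analyte_model() -> AnalyteModel:
    return AnalyteModel()


def default_master_profile() -> InstrumentProfile:
    """Portable grating instrument: 1000-1800 nm at 1 nm."""
    return InstrumentProfile(
        grid=np.arange(1000.0, 1801.0, 1.0),
        gain=1.0,
        smoothing_fwhm=6.0,
        noise_sd=0.003,
    )


def default_slave_profile() -> InstrumentProfile:
    """Benchtop FT instrument: uniform in wavenumber (10010 to 5550 cm^-1,
    4 cm^-1 step, i.e. ~999-1802 nm with non-uniform nm spacing), coarser
    optical resolution, shifted wavelength registration, and a smoothly
    tilted detector response."""
    wavenumbers = np.arange(10010.0, 5550.0 - 1e-9, -4.0)
    return InstrumentProfile(
        grid=np.sort(1e7 / wavenumbers),
        gain=1.25,
        baseline_offset=0.15,
        baseline_slope=4e-4,
        wavelength_shift=3.0,
        smoothing_fwhm=10.0,
        noise_sd=0.003,
        response_tilt=0.25,
        response_curve=-0.30,
    )


def default_dense_grid() -> np.ndarray:
    """Internal high-resolution grid the clean spectra live on."""
    return np.arange(820.0, 1850.0 + 1e-9, 0.5)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_reference(
    n: int,
    seed=0,
    mean: float = 19.1,
    sd: float = 2.0,
    low: float = 12.9,
    high: float = 23.2,
) -> np.ndarray:
    """SSC reference values: Normal(mean, sd) truncated to [low, high]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_clean_spectrum(
    ssc, model: AnalyteModel, grid: np.ndarray
) -> np.ndarray:
    """Noise-free absorbance for SSC value(s) on ``grid``.

    Returns one row per SSC value (a 1-D vector for a scalar input).
    """
    grid = np.asarray(grid, dtype=float)
    ssc_arr = np.atleast_1d(np.asarray(ssc, dtype=float))
    bg = model.bg_offset + model.bg_slope * (grid - 1300.0)
    for c, w, a in zip(model.bg_centers, model.bg_fwhm, model.bg_amps):
        bg = bg + a * _gaussian(grid, c, w)
    signature = np.zeros_like(grid)
    for c, w, a in zip(model.band_centers, model.band_fwhm, model.band_amp_per_unit):
        signature = signature + a * _gaussian(grid, c, w)
    response = ssc_arr - model.beer_nonlinearity * (ssc_arr - 12.9) ** 2
    out = bg[None, :] + response[:, None] * signature[None, :]
    return out[0] if np.isscalar(ssc) or np.ndim(ssc) == 0 else out


def measure(
    clean: np.ndarray,
    dense_grid: np.ndarray,
    profile: InstrumentProfile,
    seed=0,
) -> np.ndarray:
    """Observe clean spectra (rows on ``dense_grid``) through an instrument.

    Pipeline: Gaussian resolution blur (fwhm), sampling at grid +
    wavelength_shift by linear interpolation, wavelength-dependent response
    gain, baseline (offset + slope), additive i.i.d. Gaussian noise.
    """
    rng = _rng(seed)
    dense_grid = np.asarray(dense_grid, dtype=float)
    clean = np.atleast_2d(np.asarray(clean, dtype=float))
    sample_at = profile.grid + profile.wavelength_shift
    if sample_at[0] < dense_grid[0] or sample_at[-1] > dense_grid[-1]:
        raise ValueError(
            "instrument grid (plus shift) extends beyond the dense grid span"
        )
    if profile.smoothing_fwhm > 0:
        step = dense_grid[1] - dense_grid[0]
        sigma_pts = profile.smoothing_fwhm * _FWHM_TO_SIGMA / step
        blurred = gaussian_filter1d(clean, sigma_pts, axis=1, mode="nearest")
    else:
        blurred = clean
    resampled = np.empty((clean.shape[0], profile.grid.size))
    for r in range(clean.shape[0]):
        resampled[r] = np.interp(sample_at, dense_grid, blurred[r])
    mid = 0.5 * (profile.grid[0] + profile.grid[-1])
    baseline = profile.baseline_offset + profile.baseline_slope * (profile.grid - mid)
    out = resampled * profile.response()[None, :] + baseline[None, :]
    if profile.noise_sd > 0:
        out = out + rng.normal(0.0, profile.noise_sd, size=out.shape)
    return out


def generate_paired_dataset(
    n: int,
    master_profile: InstrumentProfile | None = None,
    slave_profile: InstrumentProfile | None = None,
    seed: int = 0,
    analyte: AnalyteModel | None = None,
    dense_grid: np.ndarray | None = None,
    reference_noise_sd: float = 0.12,
) -> tuple[SpectraSet, SpectraSet]:
    """Same samples observed through two instruments.

    Returns (master, slave) SpectraSets sharing sample ids and the reported
    reference vector (true SSC plus reference-method noise; the default sd
    of 0.12 matches a ~0.3 %Brix laboratory error averaged over triplicate
    readings).
    """
    master_profile = master_profile or default_master_profile()
    slave_profile = slave_profile or default_slave_profile()
    analyte = analyte or default_analyte_model()
    grid = default_dense_grid() if dense_grid is None else np.asarray(dense_grid, float)
    rng = _rng(seed)

    ssc = generate_reference(n, rng)
    clean = generate_clean_spectrum(ssc, analyte, grid)

    # per-sample nuisance structure, shared by both instruments
    for c, w, a_sd in zip(
        analyte.interferent_centers, analyte.interferent_fwhm, analyte.interferent_amp_sd
    ):
        amps = rng.normal(0.0, a_sd, size=n)
        clean = clean + amps[:, None] * _gaussian(grid, c, w)[None, :]
    jitter = rng.normal(0.0, analyte.bg_amp_jitter_sd, size=n)
    water = _gaussian(grid, analyte.bg_centers[1], analyte.bg_fwhm[1])
    clean = clean + (analyte.bg_amps[1] * jitter)[:, None] * water[None, :]
    mult = 1.0 + rng.normal(0.0, analyte.scatter_mult_sd, size=n)
    add = rng.normal(0.0, analyte.scatter_add_sd, size=n)
    clean = clean * mult[:, None] + add[:, None]

    reported = ssc + rng.normal(0.0, reference_noise_sd, size=n)
    ids = [f"s{i + 1:04d}" for i in range(n)]
    master = SpectraSet(
        wavelengths=master_profile.grid,
        absorbance=measure(clean, grid, master_profile, rng),
        sample_ids=ids,
        reference=reported,
    )
    slave = SpectraSet(
        wavelengths=slave_profile.grid,
        absorbance=measure(clean, grid, slave_profile, rng),
        sample_ids=ids,
        reference=reported,
    )
    return master, slave
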