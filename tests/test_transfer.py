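import numpy as np
import pytest

from nirtransfer import (
    SpectraSet,
    TransferModel,
    apply_transfer,
    build_common_pds,
    build_pds,
    common_wavelengths,
    interpolate_to_grid,
    linear_interp_pds,
)
from tests.conftest import small_pair


def affine_set(slave_grid, slopes, intercepts):
    slave_grid = np.asarray(slave_grid, float)
    A = np.outer(slopes, slave_grid) + np.asarray(intercepts)[:, None]
    return SpectraSet(wavelengths=slave_grid, absorbance=A)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def test_interpolation_exact_on_affine_spectra():
    rng = np.random.default_rng(0)
    slave_grid = np.sort(rng.uniform(900.0, 1900.0, size=40))
    slopes = rng.normal(size=5)
    icpts = rng.normal(size=5)
    s = affine_set(slave_grid, slopes, icpts)
    query = np.sort(rng.uniform(slave_grid[0], slave_grid[-1], size=25))
    out = interpolate_to_grid(s, query)
    expected = np.outer(slopes, query) + icpts[:, None]
    assert np.allclose(out.absorbance, expected, rtol=0, atol=1e-9)


def test_interpolation_node_queries_bit_preserving():
    rng = np.random.default_rng(1)
    slave_grid = np.sort(rng.uniform(1000.0, 1800.0, size=30))
    s = SpectraSet(wavelengths=slave_grid, absorbance=rng.normal(size=(4, 30)))
    nodes = slave_grid[[0, 3, 17, 29]]
    out = interpolate_to_grid(s, nodes)
    assert np.array_equal(out.absorbance, s.absorbance[:, [0, 3, 17, 29]])


def test_interpolation_rejects_extrapolation():
    s = affine_set(np.array([1000.0, 1100.0]), [1.0], [0.0])
    with pytest.raises(ValueError, match="extrapolation"):
        interpolate_to_grid(s, np.array([999.0, 1050.0]))


# ---------------------------------------------------------------------------
# PDS
# ---------------------------------------------------------------------------

def identical_standards(n=12, p=15, seed=2):
    rng = np.random.default_rng(seed)
    wl = np.arange(1000.0, 1000.0 + p)
    m = SpectraSet(wavelengths=wl, absorbance=rng.normal(0.5, 0.2, size=(n, p)))
    return m


@pytest.mark.parametrize("intercept", [True, False])
def test_identity_transfer_exact(intercept):
    m = identical_standards()
    t = build_pds(m, m.copy(), half_width=0, intercept=intercept)
    assert np.array_equal(t.F, np.eye(m.n_wavelengths))
    if intercept:
        assert np.all(t.intercepts == 0.0)
    out = apply_transfer(t, m)
    assert np.array_equal(out.absorbance, m.absorbance)


@pytest.mark.parametrize("intercept", [True, False])
def test_scalar_gain_inverted(intercept):
    m = identical_standards(seed=3)
    s = m.with_absorbance(2.0 * m.absorbance)
    t = build_pds(m, s, half_width=0, intercept=intercept)
    assert np.allclose(np.diag(t.F), 0.5, atol=1e-10)
    out = apply_transfer(t, s)
    assert np.allclose(out.absorbance, m.absorbance, atol=1e-10)


def test_pds_additive_offset_absorbed_only_with_intercept():
    m = identical_standards(seed=4)
    s = m.with_absorbance(m.absorbance + 0.75)
    t = build_pds(m, s, half_width=0, intercept=True)
    assert np.allclose(apply_transfer(t, s).absorbance, m.absorbance, atol=1e-10)


def test_pds_mild_instrument_pair_reduces_spectral_rmse():
    # synthetic pair (gain 1.1, +0.5 nm shift, mild baseline): mean spectral
    # RMSE of transferred vs master <= 20% of the untransferred RMSE
    from nirtransfer.simulate import (
        InstrumentProfile,
        generate_paired_dataset,
    )
    from tests.conftest import small_analyte

    grid = np.arange(1000.0, 1501.0, 2.0)
    mp = InstrumentProfile(grid=grid, smoothing_fwhm=4.0, noise_sd=0.0005)
    sp = InstrumentProfile(
        grid=grid,
        gain=1.1,
        baseline_offset=0.02,
        baseline_slope=1e-5,
        wavelength_shift=0.5,
        smoothing_fwhm=4.0,
        noise_sd=0.0005,
    )
    master, slave = generate_paired_dataset(
        40, master_profile=mp, slave_profile=sp, seed=5, analyte=small_analyte()
    )
    m_std, s_std = master.take(range(25)), slave.take(range(25))
    m_test, s_test = master.take(range(25, 40)), slave.take(range(25, 40))
    untransferred_rmse = np.sqrt(
        np.mean((s_test.absorbance - m_test.absorbance) ** 2)
    )
    for hw in (5, 10, 15):
        t = build_pds(m_std, s_std, half_width=hw)
        moved = apply_transfer(t, s_test)
        rmse = np.sqrt(np.mean((moved.absorbance - m_test.absorbance) ** 2))
        assert rmse <= 0.2 * untransferred_rmse, hw


def test_pds_band_structure():
    m = identical_standards(n=10, p=12, seed=6)
    s = m.with_absorbance(m.absorbance * 1.2 + 0.01)
    hw = 2
    t = build_pds(m, s, half_width=hw)
    p = m.n_wavelengths
    for i in range(p):
        outside = np.ones(p, dtype=bool)
        outside[max(0, i - hw) : min(p, i + hw + 1)] = False
        assert np.all(t.F[outside, i] == 0.0), i


def test_pds_input_validation():
    m = identical_standards(n=5)
    with pytest.raises(ValueError, match="half_width"):
        build_pds(m, m, half_width=-1)
    with pytest.raises(ValueError, match="at least 3"):
        build_pds(m.take([0, 1]), m.take([0, 1]), half_width=0)
    with pytest.raises(ValueError, match="sample order"):
        build_pds(m, m.take([0, 1, 2]), half_width=0)
    other = SpectraSet(
        wavelengths=m.wavelengths + 0.5, absorbance=m.absorbance
    )
    with pytest.raises(ValueError, match="master wavelength grid"):
        build_pds(m, other, half_width=0)


# ---------------------------------------------------------------------------
# linear interpolation-PDS and common-wavelengths baseline
# ---------------------------------------------------------------------------

def test_linear_interp_pds_consumes_raw_slave_grid():
    master, slave = small_pair(40, seed=7)
    m_std, s_std = master.take(range(20)), slave.take(range(20))
    t = linear_interp_pds(m_std, s_std, half_width=3)
    assert t.method == "linear_interp_pds"
    out = apply_transfer(t, slave.take(range(20, 40)))
    assert np.array_equal(out.wavelengths, master.wavelengths)
    # transferred spectra approximate the master spectra
    m_test = master.take(range(20, 40))
    err = np.sqrt(np.mean((out.absorbance - m_test.absorbance) ** 2))
    raw = interpolate_to_grid(slave.take(range(20, 40)), master.wavelengths)
    err_raw = np.sqrt(np.mean((raw.absorbance - m_test.absorbance) ** 2))
    assert err < err_raw


def test_common_wavelengths_matching_properties():
    gridA = np.array([1000.0, 1001.0, 1002.0, 1010.0])
    gridB = np.array([1000.06, 1001.5, 1002.04, 1009.98, 1010.01])
    pairs = common_wavelengths(gridA, gridB, tolerance=0.1)
    # one-to-one, within tolerance, sorted by gridA index
    a_idx = [a for a, _ in pairs]
    b_idx = [b for _, b in pairs]
    assert a_idx == sorted(a_idx)
    assert len(set(a_idx)) == len(a_idx) and len(set(b_idx)) == len(b_idx)
    for a, b in pairs:
        assert abs(gridA[a] - gridB[b]) <= 0.1
    # nearest-first: 1010 pairs with 1010.01 (d=.01), not 1009.98 (d=.02)
    assert (3, 4) in pairs
    assert (0, 0) in pairs and (2, 2) in pairs
    assert all(a != 1 for a, _ in pairs)  # 1001.0 has no partner within 0.1


def test_common_pds_uses_matched_channels_only():
    master, slave = small_pair(40, seed=8)
    pairs = common_wavelengths(master.wavelengths, slave.wavelengths, 0.5)
    assert len(pairs) >= 3
    m_std, s_std = master.take(range(25)), slave.take(range(25))
    t = build_common_pds(m_std, s_std, tolerance=0.5, half_width=2)
    assert t.method == "common_pds"
    assert t.master_grid.size == len(pairs)
    out = apply_transfer(t, slave.take(range(25, 40)))
    assert out.n_wavelengths == len(pairs)
    with pytest.raises(ValueError, match="common wavelengths"):
        build_common_pds(m_std, s_std, tolerance=0.0, half_width=2)


def test_transfer_model_serialization_roundtrip(tmp_path):
    master, slave = small_pair(30, seed=9)
    m_std, s_std = master.take(range(20)), slave.take(range(20))
    rest = slave.take(range(20, 30))
    for t in (
        linear_interp_pds(m_std, s_std, half_width=2),
        build_common_pds(m_std, s_std, tolerance=0.5, half_width=2),
    ):
        p = tmp_path / f"{t.method}.json"
        t.save(p)
        t2 = TransferModel.load(p)
        assert np.array_equal(
            apply_transfer(t, rest).absorbance, apply_transfer(t2, rest).absorbance
        )


def test_apply_transfer_grid_checks():
    master, slave = small_pair(20, seed=10)
    t = linear_interp_pds(master.take(range(10)), slave.take(range(10)), half_width=1)
    wrong = SpectraSet(
        wavelengths=slave.wavelengths[:-1], absorbance=slave.absorbance[:, :-1]
    )
    with pytest.raises(ValueError, match="slave grid"):
        apply_transfer(t, wrong)
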