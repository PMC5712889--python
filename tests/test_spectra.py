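import numpy as np
import pytest

from nirtransfer import SpectraSet, read_spectra, write_spectra
from nirtransfer.spectra import ReplicateTable, SpectraFormatError, read_replicates


def test_roundtrip_preserves_float64_exactly(tmp_path, simple_spectra):
    p = tmp_path / "s.csv"
    write_spectra(simple_spectra, p)
    back = read_spectra(p, reference_column="reference")
    assert np.array_equal(back.wavelengths, simple_spectra.wavelengths)
    assert np.array_equal(back.absorbance, simple_spectra.absorbance)
    assert np.array_equal(back.reference, simple_spectra.reference)
    assert back.sample_ids == simple_spectra.sample_ids


def test_read_without_reference(tmp_path, simple_spectra):
    p = tmp_path / "s.csv"
    s = SpectraSet(
        wavelengths=simple_spectra.wavelengths,
        absorbance=simple_spectra.absorbance,
    )
    write_spectra(s, p)
    back = read_spectra(p)
    assert back.reference is None
    assert np.array_equal(back.absorbance, s.absorbance)


def test_unnamed_reference_column_is_an_error(tmp_path, simple_spectra):
    p = tmp_path / "s.csv"
    write_spectra(simple_spectra, p)
    with pytest.raises(SpectraFormatError, match="non-numeric"):
        read_spectra(p)  # 'reference' header cannot parse as a wavelength


def test_wavenumber_headers_are_converted(tmp_path):
    p = tmp_path / "wn.csv"
    p.write_text("id,10000,8000,5000\na,0.1,0.2,0.3\n")
    s = read_spectra(p, wavenumber=True)
    assert np.allclose(s.wavelengths, [1000.0, 1250.0, 2000.0])
    # columns are reordered to the ascending-nm grid
    assert np.allclose(s.absorbance, [[0.1, 0.2, 0.3]])


def test_descending_columns_are_sorted(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("id,1100,1000\na,0.2,0.1\n")
    s = read_spectra(p)
    assert np.array_equal(s.wavelengths, [1000.0, 1100.0])
    assert np.array_equal(s.absorbance, [[0.1, 0.2]])


def test_duplicate_wavelengths_rejected(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("id,1000,1000\na,0.1,0.2\n")
    with pytest.raises(SpectraFormatError, match="duplicate"):
        read_spectra(p)


def test_missing_values_rejected(tmp_path):
    p = tmp_path / "nan.csv"
    p.write_text("id,1000,1100\na,0.1,\n")
    with pytest.raises(SpectraFormatError, match="missing"):
        read_spectra(p)


def test_missing_reference_column_rejected(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("id,1000\na,0.1\n")
    with pytest.raises(SpectraFormatError, match="reference column"):
        read_spectra(p, reference_column="ssc")


def test_too_few_columns_rejected(tmp_path):
    p = tmp_path / "one.csv"
    p.write_text("id\na\n")
    with pytest.raises(SpectraFormatError):
        read_spectra(p)


def test_spectraset_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        SpectraSet(wavelengths=[2.0, 1.0], absorbance=[[0.1, 0.2]])
    with pytest.raises(ValueError, match="columns"):
        SpectraSet(wavelengths=[1.0, 2.0], absorbance=[[0.1]])
    with pytest.raises(ValueError, match="non-finite"):
        SpectraSet(wavelengths=[1.0, 2.0], absorbance=[[0.1, np.nan]])
    with pytest.raises(ValueError, match="reference length"):
        SpectraSet(wavelengths=[1.0], absorbance=[[0.1]], reference=[1.0, 2.0])


def test_take_and_with_absorbance(simple_spectra):
    sub = simple_spectra.take([2, 0])
    assert sub.n_samples == 2
    assert sub.sample_ids == [simple_spectra.sample_ids[2], simple_spectra.sample_ids[0]]
    assert np.array_equal(sub.absorbance[0], simple_spectra.absorbance[2])
    assert sub.reference[1] == simple_spectra.reference[0]

    new = simple_spectra.with_absorbance(simple_spectra.absorbance * 2.0)
    assert np.array_equal(new.absorbance, simple_spectra.absorbance * 2.0)
    assert new.sample_ids == simple_spectra.sample_ids
    # mutation of the copy must not touch the original
    c = simple_spectra.copy()
    c.absorbance[0, 0] = 99.0
    assert simple_spectra.absorbance[0, 0] != 99.0


def test_default_sample_ids():
    s = SpectraSet(wavelengths=[1.0, 2.0], absorbance=np.zeros((3, 2)))
    assert s.sample_ids == ["s0001", "s0002", "s0003"]


def test_read_replicates(tmp_path):
    p = tmp_path / "rep.csv"
    p.write_text("id,y1,y2,y3\na,1.0,1.2,\nb,2.0,2.1,2.2\n")
    t = read_replicates(p)
    assert isinstance(t, ReplicateTable)
    assert t.sample_ids == ["a", "b"]
    assert t.values.shape == (2, 3)
    assert np.isnan(t.values[0, 2])
    with pytest.raises(SpectraFormatError):
        (tmp_path / "bad.csv").write_text("id,y1\na,1.0\n")
        read_replicates(tmp_path / "bad.csv")
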