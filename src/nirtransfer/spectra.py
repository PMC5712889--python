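"""Spectra containers and delimited-text I/O.

The universal currency of the package is the :class:`SpectraSet`: a strictly
increasing wavelength grid (nm), an absorbance matrix (samples x wavelengths),
sample identifiers, and an optional vector of reference analyte values
(e.g. soluble solids content in %Brix).

The on-disk exchange format is plain CSV: first column the sample id, an
optional named reference column, and one numeric column per wavelength with
the wavelength (nm) as header.  Fourier-transform instruments are specified
on a wavenumber grid; ``read_spectra(..., wavenumber=True)`` converts the
header via lambda[nm] = 1e7 / nu[cm^-1] on read so all downstream math runs
in nm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReplicateTable",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "read_replicates",
]


class SpectraFormatError(ValueError):
    """Raised when a spectra file violates the exchange format."""


@dataclass
class SpectraSet:
    """Absorbance spectra on a common wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, one entry per absorbance column.
    absorbance
        Matrix of shape (n_samples, n_wavelengths); unitless absorbance.
    sample_ids
        One label per row.  Defaults to ``s0001`` ... if omitted.
    reference
        Optional per-sample analyte values (reference-method measurements).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("non-finite wavelengths")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite absorbance values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1:04d}" for i in range(self.absorbance.shape[0])]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float).ravel()
            if self.reference.size != self.absorbance.shape[0]:
                raise ValueError("reference length does not match number of rows")
            if not np.all(np.isfinite(self.reference)):
                raise ValueError("non-finite reference values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def take(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (copy), carrying ids and reference values along."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=self.absorbance[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            reference=None if self.reference is None else self.reference[idx].copy(),
        )

    def with_absorbance(
        self, absorbance: np.ndarray, wavelengths: np.ndarray | None = None
    ) -> "SpectraSet":
        """Same samples, new absorbance matrix (and optionally new grid)."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy() if wavelengths is None else np.asarray(wavelengths, float),
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            reference=None if self.reference is None else self.reference.copy(),
        )

    def copy(self) -> "SpectraSet":
        return self.take(np.arange(self.n_samples))


@dataclass
class ReplicateTable:
    """Repeated reference measurements per sample (for SEL estimation).

    ``values`` is (n_samples, n_replicates); missing replicates are NaN.
    Each usable row must hold at least two finite replicates.
    """

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")


def read_spectra(
    path: str | Path,
    reference_column: str | None = None,
    wavenumber: bool = False,
) -> SpectraSet:
    """Read a spectra CSV.

    First column is the sample id; ``reference_column`` names an optional
    analyte column; every other header must parse as a numeric wavelength.
    Columns are reordered so the grid is ascending.  With ``wavenumber=True``
    headers are cm^-1 and converted to nm.
    """
    # pandas silently renames duplicate headers ("1000", "1000.1"), so the
    # duplicate check must run on the raw header line
    with open(path, newline="") as fh:
        raw_header = next(csv.reader(fh), [])
    try:
        # round_trip parsing so write -> read preserves float64 exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise SpectraFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectraFormatError("need at least an id column and one wavelength column")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    header = raw_header[1:]
    reference = None
    keep = np.ones(len(header), dtype=bool)
    if reference_column is not None:
        if reference_column not in header:
            raise SpectraFormatError(f"reference column {reference_column!r} not found")
        ref_pos = header.index(reference_column)
        reference = df.iloc[:, 1 + ref_pos].to_numpy(dtype=float)
        keep[ref_pos] = False
    try:
        wl = np.array([float(h) for h, k in zip(header, keep) if k])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
    if wavenumber:
        wl = 1e7 / wl
    if np.unique(wl).size != wl.size:
        raise SpectraFormatError("duplicate wavelengths in header")
    df = df.iloc[:, 1:].loc[:, keep]
    absorbance = df.to_numpy(dtype=float)
    if np.isnan(absorbance).any():
        raise SpectraFormatError("missing or non-numeric absorbance values (ragged rows?)")
    order = np.argsort(wl)
    return SpectraSet(
        wavelengths=wl[order],
        absorbance=absorbance[:, order],
        sample_ids=sample_ids,
        reference=reference,
    )


def write_spectra(
    s: SpectraSet,
    path: str | Path,
    reference_column: str = "reference",
) -> None:
    """Write a SpectraSet as CSV readable by :func:`read_spectra`.

    Numeric fields use 17 significant digits, so a round trip preserves
    float64 values exactly.
    """
    cols: dict[str, object] = {"id": s.sample_ids}
    if s.reference is not None:
        cols[reference_column] = s.reference
    for k, wl in enumerate(s.wavelengths):
        cols[np.format_float_positional(wl, trim="-")] = s.absorbance[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_replicates(path: str | Path) -> ReplicateTable:
    """Read a replicate table CSV with columns id,y1,y2,... (NaN allowed)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 3:
        raise SpectraFormatError("replicate table needs an id column and >=2 replicate columns")
    return ReplicateTable(
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
        values=df.iloc[:, 1:].to_numpy(dtype=float),
    )
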