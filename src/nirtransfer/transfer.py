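"""Calibration transfer between spectrometers.

Piecewise direct standardization (PDS) regresses, for every master channel
``i``, the master standards' column ``i`` on the slave standards' window of
columns ``[i - j, i + k]``, and assembles the per-channel regression vectors
``b_i`` into a banded transformation matrix ``F`` so that a slave spectrum
row ``x`` maps to the master response space as ``x @ F``.

Classical PDS requires both instruments to share one wavelength grid.  The
linear interpolation-PDS method removes that requirement: slave spectra are
first resampled onto the master grid by exact two-point linear interpolation
(for a master wavelength ``c`` bracketed by adjacent slave wavelengths
``i < c < j``: ``slope = (y_j - y_i)/(j - i)``, ``intercept = y_j - slope*j``,
``y_c = slope*c + intercept``), and PDS then corrects the remaining
photometric/resolution differences.  The common-wavelengths-reserved-PDS
baseline instead discards all channels that the two grids do not (nearly)
share and runs PDS on the retained channels only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .regression import nipals_pls1
from .spectra import SpectraSet

__all__ = [
    "InterpolationMap",
    "TransferModel",
    "interpolate_to_grid",
    "build_pds",
    "linear_interp_pds",
    "build_common_pds",
    "common_wavelengths",
    "apply_transfer",
]


@dataclass
class InterpolationMap:
    """Per master wavelength: the bracketing adjacent slave channels used by
    the two-point linear rule (node hits are copied bit-for-bit)."""

    slave_grid: np.ndarray
    master_grid: np.ndarray
    left_index: np.ndarray  # index i of the bracketing pair (i, i+1)
    exact_index: np.ndarray  # slave index for node hits, -1 otherwise

    def apply(self, absorbance: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(absorbance, dtype=float))
        if A.shape[1] != self.slave_grid.size:
            raise ValueError(
                f"expected {self.slave_grid.size} slave channels, got {A.shape[1]}"
            )
        li = self.left_index
        ri = li + 1
        lam_i = self.slave_grid[li]
        lam_j = self.slave_grid[ri]
        yi = A[:, li]
        yj = A[:, ri]
        slope = (yj - yi) / (lam_j - lam_i)
        intercept = yj - slope * lam_j
        out = slope * self.master_grid + intercept
        hit = self.exact_index >= 0
        if hit.any():
            out[:, hit] = A[:, self.exact_index[hit]]
        return out


def _make_interpolation_map(slave_grid: np.ndarray, master_grid: np.ndarray) -> InterpolationMap:
    slave_grid = np.asarray(slave_grid, dtype=float)
    master_grid = np.asarray(master_grid, dtype=float)
    out_of_range = (master_grid < slave_grid[0]) | (master_grid > slave_grid[-1])
    if out_of_range.any():
        bad = master_grid[out_of_range]
        raise ValueError(
            "master wavelengths outside the slave grid span "
            f"[{slave_grid[0]:g}, {slave_grid[-1]:g}] nm would require "
            f"extrapolation: {bad[:10].tolist()}"
        )
    pos = np.searchsorted(slave_grid, master_grid, side="left")
    exact = np.full(master_grid.size, -1, dtype=int)
    node = (pos < slave_grid.size) & (slave_grid[np.minimum(pos, slave_grid.size - 1)] == master_grid)
    exact[node] = pos[node]
    left = np.clip(pos - 1, 0, slave_grid.size - 2)
    # for node hits the bracket is irrelevant; keep it valid
    return InterpolationMap(
        slave_grid=slave_grid,
        master_grid=master_grid,
        left_index=left,
        exact_index=exact,
    )


def interpolate_to_grid(slave: SpectraSet, master_grid: np.ndarray) -> SpectraSet:
    """Resample slave spectra onto ``master_grid`` by two-point linear
    interpolation; ids and reference values are carried along."""
    imap = _make_interpolation_map(slave.wavelengths, master_grid)
    return slave.with_absorbance(imap.apply(slave.absorbance), wavelengths=imap.master_grid)


@dataclass
class TransferModel:
    """Slave -> master spectral mapping.

    ``F`` is square (master grid length); row ``r``'s nonzeros are confined
    to columns ``[r - half_width, r + half_width]`` by construction (band
    clipped at the edges).  ``interp_map`` (linear_interp_pds) or
    ``column_indices`` (common_pds) describe how raw slave spectra are
    brought onto the channels F consumes; ``intercepts`` is the optional
    additive correction.
    """

    method: str
    master_grid: np.ndarray
    slave_grid: np.ndarray
    half_width: int
    F: np.ndarray
    intercepts: np.ndarray | None = None
    interp_map: InterpolationMap | None = None
    column_indices: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "transfer",
            "method": self.method,
            "master_grid": self.master_grid.tolist(),
            "slave_grid": self.slave_grid.tolist(),
            "half_width": int(self.half_width),
            "F": self.F.tolist(),
            "intercepts": None if self.intercepts is None else self.intercepts.tolist(),
            "column_indices": None if self.column_indices is None else self.column_indices.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferModel":
        m = cls(
            method=d["method"],
            master_grid=np.asarray(d["master_grid"], float),
            slave_grid=np.asarray(d["slave_grid"], float),
            half_width=int(d["half_width"]),
            F=np.asarray(d["F"], float),
            intercepts=None if d.get("intercepts") is None else np.asarray(d["intercepts"], float),
            column_indices=None if d.get("column_indices") is None else np.asarray(d["column_indices"], int),
        )
        if m.method == "linear_interp_pds":
            m.interp_map = _make_interpolation_map(m.slave_grid, m.master_grid)
        return m

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TransferModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _pds_band(
    master: np.ndarray,
    slave: np.ndarray,
    half_width: int,
    n_window_components: int | None,
    intercept: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-channel window PLS regressions assembled into the banded F."""
    n, p = master.shape
    F = np.zeros((p, p))
    intercepts = np.zeros(p) if intercept else None
    for i in range(p):
        lo = max(0, i - half_width)
        hi = min(p, i + half_width + 1)
        Xw = slave[:, lo:hi]
        yv = master[:, i]
        ncomp = hi - lo if n_window_components is None else min(n_window_components, hi - lo)
        try:
            beta = nipals_pls1(Xw, yv, ncomp, center=intercept)[-1]
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"window PLS failed at channel {i}") from exc
        if not np.all(np.isfinite(beta)):
            raise RuntimeError(f"window PLS produced non-finite coefficients at channel {i}")
        F[lo:hi, i] = beta
        if intercept:
            intercepts[i] = yv.mean() - Xw.mean(axis=0) @ beta
    return F, intercepts


def build_pds(
    master_std: SpectraSet,
    slave_std_on_master_grid: SpectraSet,
    half_width: int,
    n_window_components: int | None = 2,
    intercept: bool = True,
) -> TransferModel:
    """Classical PDS between two standard sets sharing the master grid.

    ``n_window_components`` is clipped to the window size (None = full
    window).  With ``intercept`` (the default) each window regression is fit
    on centered data and an additive per-channel correction is stored; this
    also absorbs baseline differences that SNV does not remove.  An
    identical pair with half_width 0 still yields F = identity and zero
    intercepts exactly.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if master_std.n_samples < 3:
        raise ValueError("need at least 3 standardization samples")
    if master_std.n_samples != slave_std_on_master_grid.n_samples:
        raise ValueError("standard sets must share the sample order")
    if master_std.n_wavelengths != slave_std_on_master_grid.n_wavelengths or not np.array_equal(
        master_std.wavelengths, slave_std_on_master_grid.wavelengths
    ):
        raise ValueError("standard sets must share the master wavelength grid")
    F, intercepts = _pds_band(
        master_std.absorbance,
        slave_std_on_master_grid.absorbance,
        half_width,
        n_window_components,
        intercept,
    )
    return TransferModel(
        method="pds",
        master_grid=master_std.wavelengths.copy(),
        slave_grid=slave_std_on_master_grid.wavelengths.copy(),
        half_width=int(half_width),
        F=F,
        intercepts=intercepts,
    )


def linear_interp_pds(
    master_std: SpectraSet,
    slave_std: SpectraSet,
    master_grid: np.ndarray | None = None,
    half_width: int = 10,
    n_window_components: int | None = 2,
    intercept: bool = True,
) -> TransferModel:
    """Wavelength correction by linear interpolation followed by PDS.

    The returned model records the interpolation map, so
    :func:`apply_transfer` consumes raw slave spectra on the slave grid.
    """
    if master_grid is None:
        master_grid = master_std.wavelengths
    master_grid = np.asarray(master_grid, dtype=float)
    if not np.array_equal(master_std.wavelengths, master_grid):
        raise ValueError("master standards must live on the target master grid")
    imap = _make_interpolation_map(slave_std.wavelengths, master_grid)
    slave_on_master = slave_std.with_absorbance(
        imap.apply(slave_std.absorbance), wavelengths=master_grid
    )
    model = build_pds(
        master_std, slave_on_master, half_width, n_window_components, intercept
    )
    model.method = "linear_interp_pds"
    model.slave_grid = slave_std.wavelengths.copy()
    model.interp_map = imap
    return model


def common_wavelengths(
    gridA: np.ndarray, gridB: np.ndarray, tolerance: float
) -> list[tuple[int, int]]:
    """Nearest-first one-to-one matching of wavelengths across two grids.

    Returns index pairs (a, b) with |gridA[a] - gridB[b]| <= tolerance, each
    channel matched at most once, closest pairs matched first; the result is
    sorted by the gridA index.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    gridA = np.asarray(gridA, dtype=float)
    gridB = np.asarray(gridB, dtype=float)
    candidates: list[tuple[float, int, int]] = []
    pos = np.searchsorted(gridB, gridA)
    for a, p in enumerate(pos):
        for b in range(max(0, p - 2), min(gridB.size, p + 2)):
            d = abs(gridA[a] - gridB[b])
            if d <= tolerance:
                candidates.append((d, a, b))
    candidates.sort()
    usedA = set()
    usedB = set()
    pairs: list[tuple[int, int]] = []
    for _, a, b in candidates:
        if a in usedA or b in usedB:
            continue
        usedA.add(a)
        usedB.add(b)
        pairs.append((a, b))
    pairs.sort()
    return pairs


def build_common_pds(
    master_std: SpectraSet,
    slave_std: SpectraSet,
    tolerance: float = 0.1,
    half_width: int = 10,
    n_window_components: int | None = 2,
    intercept: bool = True,
) -> TransferModel:
    """Common-wavelengths-reserved-PDS baseline: keep only the (near-)shared
    channels of both grids and run PDS on those, discarding the rest."""
    pairs = common_wavelengths(master_std.wavelengths, slave_std.wavelengths, tolerance)
    if len(pairs) < 2:
        raise ValueError(
            f"only {len(pairs)} common wavelengths at tolerance {tolerance} nm"
        )
    ia = np.array([a for a, _ in pairs], dtype=int)
    ib = np.array([b for _, b in pairs], dtype=int)
    master_common = SpectraSet(
        wavelengths=master_std.wavelengths[ia],
        absorbance=master_std.absorbance[:, ia],
        sample_ids=list(master_std.sample_ids),
    )
    slave_common = master_common.with_absorbance(slave_std.absorbance[:, ib])
    F, intercepts = _pds_band(
        master_common.absorbance,
        slave_common.absorbance,
        half_width,
        n_window_components,
        intercept,
    )
    return TransferModel(
        method="common_pds",
        master_grid=master_std.wavelengths[ia].copy(),
        slave_grid=slave_std.wavelengths.copy(),
        half_width=int(half_width),
        F=F,
        intercepts=intercepts,
        column_indices=ib,
    )


def apply_transfer(t: TransferModel, slave: SpectraSet) -> SpectraSet:
    """Map slave spectra into the master response space.

    For ``linear_interp_pds`` the input lives on the raw slave grid; for
    ``common_pds`` the matched slave channels are extracted; for plain
    ``pds`` the input must already share the master grid.
    """
    if t.interp_map is not None:
        if not np.array_equal(slave.wavelengths, t.slave_grid):
            raise ValueError("slave grid differs from the grid the model was built from")
        X = t.interp_map.apply(slave.absorbance)
    elif t.column_indices is not None:
        if not np.array_equal(slave.wavelengths, t.slave_grid):
            raise ValueError("slave grid differs from the grid the model was built from")
        X = slave.absorbance[:, t.column_indices]
    else:
        if not np.array_equal(slave.wavelengths, t.master_grid):
            raise ValueError("spectra must share the grid the PDS model was built on")
        X = slave.absorbance
    out = X @ t.F
    if t.intercepts is not None:
        out = out + t.intercepts
    return slave.with_absorbance(out, wavelengths=t.master_grid.copy())
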