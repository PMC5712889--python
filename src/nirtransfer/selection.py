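"""Kennard-Stone sample selection.

The Kennard-Stone algorithm picks a representative subset by a greedy
max-min rule on Euclidean distances between spectra: the first two selected
samples are the globally farthest pair; each subsequent pick maximizes its
minimum distance to the already-selected set.  It is used both to split a
dataset into calibration/prediction sets and to pick standardization
(transfer-standard) samples from the calibration set.

Ties are broken by the smallest index at every argmax, so selection is fully
deterministic and invariant to the random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet

__all__ = ["SelectionResult", "kennard_stone", "ks_split", "select_standardization"]


@dataclass
class SelectionResult:
    """Outcome of a sequential selection: chosen indices in pick order plus
    the remaining indices in original order."""

    selected_indices: list[int]
    remaining_indices: list[int]


def _as_matrix(s) -> np.ndarray:
    if isinstance(s, SpectraSet):
        return s.absorbance
    return np.atleast_2d(np.asarray(s, dtype=float))


def kennard_stone(s, n_select: int) -> SelectionResult:
    """Greedy max-min (Kennard-Stone) selection of ``n_select`` rows."""
    X = _as_matrix(s)
    n = X.shape[0]
    n_select = int(n_select)
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")

    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    # farthest pair; np.argmax returns the first (row-major) maximum, i.e.
    # the smallest (i, j) on ties
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if i > j:
        i, j = j, i
    selected = [int(i), int(j)]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i, j]] = True
    mind2 = np.minimum(d2[i], d2[j])

    while len(selected) < n_select:
        cand = np.where(in_set, -np.inf, mind2)
        k = int(np.argmax(cand))
        selected.append(k)
        in_set[k] = True
        np.minimum(mind2, d2[k], out=mind2)

    remaining = [int(k) for k in range(n) if not in_set[k]]
    return SelectionResult(selected_indices=selected, remaining_indices=remaining)


def ks_split(s: SpectraSet, n_calibration: int) -> tuple[SpectraSet, SpectraSet]:
    """Split into a Kennard-Stone calibration set and the remaining
    prediction set; reference values are carried along."""
    if not 2 <= n_calibration < s.n_samples:
        raise ValueError(
            f"n_calibration must be in [2, {s.n_samples - 1}], got {n_calibration}"
        )
    res = kennard_stone(s, n_calibration)
    return s.take(res.selected_indices), s.take(res.remaining_indices)


def select_standardization(calibration: SpectraSet, n_std: int) -> SelectionResult:
    """Kennard-Stone subset of the calibration set, used as the set of
    transfer standards measured on both instruments."""
    if not 2 <= n_std <= calibration.n_samples:
        raise ValueError(
            f"n_std must be in [2, {calibration.n_samples}], got {n_std}"
        )
    return kennard_stone(calibration, n_std)
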