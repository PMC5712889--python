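"""Spectral pretreatments: moving-average smoothing, SNV, mean normalization.

All steps preserve the wavelength grid and matrix shape.  The conventional
chain for NIR modelling here is smoothing followed by standard normal
variate (SNV); mean normalization brings spectra from different instruments
onto a common scale and is useful in chains that do not end in SNV (SNV is
invariant to per-spectrum positive scaling, so normalizing before SNV is a
no-op).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "DegenerateRowError",
    "moving_average",
    "snv",
    "mean_normalize",
    "PreprocessPlan",
]


class DegenerateRowError(ValueError):
    """A spectrum is constant (SNV) or has zero mean (mean normalization)."""


def _ma_matrix(x: np.ndarray, window: int) -> np.ndarray:
    # Truncated (shrinking) window at the edges: the mean is taken over the
    # in-range points only, so no out-of-range absorbance is fabricated.
    # Even windows take one extra point on the left.
    n = x.shape[1]
    left = window // 2 if window % 2 == 0 else (window - 1) // 2
    right = window - 1 - left
    csum = np.concatenate(
        [np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1
    )
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    counts = hi - lo + 1
    return (csum[:, hi + 1] - csum[:, lo]) / counts


def moving_average(s: SpectraSet, window: int) -> SpectraSet:
    """Centered moving-average smoothing with ``window`` points per spectrum."""
    window = int(window)
    if window < 1 or window > s.n_wavelengths:
        raise ValueError(
            f"window must be in [1, {s.n_wavelengths}], got {window}"
        )
    if window == 1:
        return s.copy()
    return s.with_absorbance(_ma_matrix(s.absorbance, window))


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per spectrum, subtract mean and divide by
    the sample standard deviation (n-1 denominator)."""
    if s.n_wavelengths < 2:
        raise ValueError("SNV needs at least two wavelengths")
    mean = s.absorbance.mean(axis=1, keepdims=True)
    sd = s.absorbance.std(axis=1, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        raise DegenerateRowError(
            f"constant spectrum (zero variance) for sample(s): "
            f"{[s.sample_ids[i] for i in bad[:5]]}"
        )
    return s.with_absorbance((s.absorbance - mean) / sd)


def mean_normalize(s: SpectraSet) -> SpectraSet:
    """Divide each spectrum by its own mean, so all rows have mean 1."""
    mean = s.absorbance.mean(axis=1, keepdims=True)
    bad = np.nonzero(mean.ravel() == 0)[0]
    if bad.size:
        raise DegenerateRowError(
            f"zero-mean spectrum for sample(s): {[s.sample_ids[i] for i in bad[:5]]}"
        )
    return s.with_absorbance(s.absorbance / mean)


@dataclass
class PreprocessPlan:
    """Ordered list of pretreatment steps.

    Each step is ``("moving_average", {"window": w})``, ``("snv", {})`` or
    ``("mean_normalize", {})``; the config form (YAML/JSON) is a list whose
    items are step names or one-key mappings, e.g.::

        - moving_average: {window: 3}
        - snv
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)

    _FUNCS = {
        "moving_average": moving_average,
        "snv": snv,
        "mean_normalize": mean_normalize,
    }

    def apply(self, s: SpectraSet) -> SpectraSet:
        out = s
        for name, kwargs in self.steps:
            if name not in self._FUNCS:
                raise ValueError(f"unknown preprocessing step {name!r}")
            out = self._FUNCS[name](out, **kwargs)
        return out

    @classmethod
    def from_config(cls, items: Iterable) -> "PreprocessPlan":
        steps: list[tuple[str, dict]] = []
        for item in items:
            if isinstance(item, str):
                steps.append((item, {}))
            elif isinstance(item, dict) and len(item) == 1:
                ((name, kwargs),) = item.items()
                steps.append((name, dict(kwargs or {})))
            else:
                raise ValueError(f"bad preprocessing step spec: {item!r}")
        return cls(steps)

    def to_config(self) -> list:
        return [name if not kwargs else {name: dict(kwargs)} for name, kwargs in self.steps]
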