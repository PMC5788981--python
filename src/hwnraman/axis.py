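"""Wavenumber grids for high-wavenumber Raman spectra.

All spectra in the package live on a shared, strictly increasing, uniformly
spaced grid of Raman shifts (cm^-1). The default grid covers the
high-wavenumber window 2600-3800 cm^-1 at ~1.8 cm^-1 per channel, which is
where the CH-stretch lipid/protein bands and the water OH band sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberAxis", "make_axis", "DEFAULT_START", "DEFAULT_STOP", "DEFAULT_SPACING"]

DEFAULT_START = 2600.0
DEFAULT_STOP = 3800.0
DEFAULT_SPACING = 1.8

_UNIFORMITY_RTOL = 1e-9


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing, uniformly spaced grid of Raman shifts (cm^-1)."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least two wavenumber values")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("axis must be strictly increasing")
        step = d[0]
        if np.any(np.abs(d - step) > _UNIFORMITY_RTOL * abs(step)):
            raise ValueError("axis must be uniformly spaced")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window_mask(self, center: float, half_width: float) -> np.ndarray:
        """Boolean mask of channels with |wavenumber - center| <= half_width."""
        return np.abs(self.values - center) <= half_width

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop


def make_axis(
    start_cm1: float = DEFAULT_START,
    stop_cm1: float = DEFAULT_STOP,
    spacing_cm1: float = DEFAULT_SPACING,
) -> WavenumberAxis:
    """Build a uniform wavenumber grid from ``start_cm1`` with the given spacing.

    The grid runs from ``start_cm1`` in steps of ``spacing_cm1`` up to the last
    point that does not exceed ``stop_cm1``; its length is
    ``floor((stop - start) / spacing) + 1``. The default arguments give the
    667-channel high-wavenumber grid used throughout the package.
    """
    if spacing_cm1 <= 0:
        raise ValueError(f"spacing must be positive, got {spacing_cm1}")
    if stop_cm1 <= start_cm1:
        raise ValueError("stop must exceed start")
    # floor() on the exact span; guard against floating-point undershoot of an
    # integer channel count (e.g. 1200/1.8).
    n = int(np.floor((stop_cm1 - start_cm1) / spacing_cm1 + 1e-12)) + 1
    values = start_cm1 + spacing_cm1 * np.arange(n)
    return WavenumberAxis(values)
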