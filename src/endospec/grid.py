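"""Uniform wavenumber axes for ATR-FTIR spectra.

Every spectrum handled by this package lives on a shared, strictly
increasing, uniformly spaced axis in reciprocal centimetres.  The default
instrument emulation spans 400-4000 cm^-1 with 7,469 absorbance points
(spacing ~0.482 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridError(ValueError):
    """Raised for non-positive spans or fewer than two grid points."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1, inclusive of both endpoints."""

    lo: float
    hi: float
    n_points: int
    values: np.ndarray = field(repr=False, compare=False)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n_points - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


def build_grid(lo: float, hi: float, n_points: int) -> WavenumberGrid:
    """Build a uniform inclusive grid from ``lo`` to ``hi`` cm^-1.

    Parameters
    ----------
    lo, hi : float
        Endpoints in cm^-1; ``hi`` must exceed ``lo``.
    n_points : int
        Number of grid points, at least 2; both endpoints are grid points.
    """
    if hi <= lo:
        raise GridError(f"grid span must be positive, got [{lo}, {hi}]")
    if int(n_points) < 2:
        raise GridError(f"grid needs at least 2 points, got {n_points}")
    values = np.linspace(float(lo), float(hi), int(n_points))
    return WavenumberGrid(float(lo), float(hi), int(n_points), values)


def default_grid() -> WavenumberGrid:
    """The default instrument axis: 400-4000 cm^-1, 7,469 points."""
    return build_grid(400.0, 4000.0, 7469)
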