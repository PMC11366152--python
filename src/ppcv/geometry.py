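"""DART volume-scan geometry.

A dense B-scan (DB) OCTA DART volume covers a narrow peripapillary strip —
by default 10° × 0.5°, i.e. ~3 mm × 0.15 mm — with ``n_slices`` closely
spaced B-scans of ``n_ascans`` A-scans each.  The inter-slice spacing Δh
(default 6 μm) is the quadrature step of the volume integral
V = ∫ A(x) dx computed downstream.

Axis convention used throughout the package (all lengths in μm unless a
field name says mm):

* ``x`` — slice-advance direction, perpendicular to the B-scan plane;
  slice *i* (0-based) sits at ``x_i = i · Δh``.
* ``u`` — lateral position within a B-scan (the A-scan direction),
  ``0 ≤ u ≤ lateral_extent``.
* ``z`` — axial depth within a B-scan, ``0 ≤ z ≤ axial_extent``.

Image arrays are indexed ``[slice, row, col]`` with row ↔ z and col ↔ u.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError

QUADRANTS = ("TS", "TI", "NS", "NI")
#: quadrants whose records are pooled as the nasal hemisphere
NASAL_QUADRANTS = ("NS", "NI")


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of one DART volume scan."""

    lateral_extent_mm: float = 3.0
    n_ascans: int = 512
    axial_extent_mm: float = 0.35
    axial_pixel_um: float = 3.9
    n_slices: int = 25
    slice_spacing_um: float = 6.0
    quadrant: str = "TS"

    def __post_init__(self):
        if self.n_slices < 2:
            raise ConfigurationError("n_slices must be >= 2 (need at least one trapezoid)")
        for name in ("lateral_extent_mm", "axial_extent_mm", "axial_pixel_um", "slice_spacing_um"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive finite number")
        if self.n_ascans < 1:
            raise ConfigurationError("n_ascans must be >= 1")
        if self.quadrant not in QUADRANTS:
            raise ConfigurationError(f"quadrant must be one of {QUADRANTS}, got {self.quadrant!r}")

    # --- derived quantities -------------------------------------------------
    @property
    def lateral_extent_um(self) -> float:
        return self.lateral_extent_mm * 1000.0

    @property
    def axial_extent_um(self) -> float:
        return self.axial_extent_mm * 1000.0

    @property
    def lateral_pixel_um(self) -> float:
        """Lateral pixel pitch (μm/px); 3 mm / 512 ≈ 5.86 μm by default."""
        return self.lateral_extent_um / self.n_ascans

    @property
    def n_axial_px(self) -> int:
        return int(round(self.axial_extent_um / self.axial_pixel_um))

    @property
    def slab_depth_um(self) -> float:
        """Extent of the scanned slab along x: (n_slices − 1) · Δh."""
        return (self.n_slices - 1) * self.slice_spacing_um

    @property
    def slice_positions_um(self) -> np.ndarray:
        """x_i = i · Δh for i = 0 … n_slices − 1 (the integral runs a → b)."""
        return np.arange(self.n_slices) * self.slice_spacing_um

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)


def dart_acquisition_totals(
    n_positions: int = 25,
    repeats: int = 3,
    n_quadrants: int = 4,
) -> int:
    """Total number of OCT B-scans acquired for one DART volume scan session.

    Each of the ``n_positions`` B-scan positions is acquired ``repeats``
    times (the device averages 3–25 repeats per position) in each of the
    ``n_quadrants`` peripapillary quadrants: 25 × 3 × 4 = 300 up to
    25 × 25 × 4 = 2500 B-scans in total.
    """
    if n_positions < 1 or repeats < 1 or n_quadrants < 1:
        raise ConfigurationError("acquisition counts must be positive")
    return n_positions * repeats * n_quadrants
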