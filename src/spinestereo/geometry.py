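"""Sphere/disc conversions between 2D profile measures and 3D head measures.

Spine heads are approximated by spheres and synaptic contacts by discs, so
that quantities measured on single thin sections (profile areas, PSD and
apposition lengths) can be placed on a common scale with quantities measured
on reconstructed volumes (head volumes, apposition surfaces):

* a head volume ``V`` maps to the area of the sphere's equatorial disc,
  ``A = pi * (3V / 4pi)^(2/3)``, the largest profile a section can show;
* a measured profile area ``A`` maps back to the volume of the sphere whose
  largest section it is, ``V = (4/3) pi (A/pi)^(3/2)``;
* a measured synaptic length ``L`` (PSD length or apposition length) maps to
  the area of the disc having ``L`` as its diameter, ``pi (L/2)^2``.

All conversions accept scalars or array-likes and are vectorised; lengths
are in micrometres, areas in square micrometres, volumes in cubic
micrometres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Literal

import numpy as np

from .errors import DomainError

__all__ = [
    "HeadMeasure",
    "sphere_radius_from_volume",
    "sphere_volume_from_radius",
    "volume_to_equivalent_area",
    "area_to_equivalent_volume",
    "length_to_disc_area",
    "report_round",
]

Units = Literal["um", "um2", "um3"]
Source = Literal["measured_2d", "measured_3d", "derived"]


@dataclass(frozen=True)
class HeadMeasure:
    """A single morphometric quantity with its units and provenance.

    ``units`` is one of ``um`` (length), ``um2`` (area), ``um3`` (volume);
    ``source`` records whether the value was measured on a micrograph,
    measured on a reconstruction, or derived by a conversion.
    """

    value: float
    units: Units
    source: Source = "derived"

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 0:
            raise DomainError(f"measure must be finite and >= 0, got {self.value}")
        if self.units not in ("um", "um2", "um3"):
            raise DomainError(f"unknown units {self.units!r}")


def _validated(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise DomainError(f"{name} must be finite and >= 0")
    return arr


def _as_input(x, arr: np.ndarray):
    # return a plain float for scalar inputs, an ndarray otherwise
    return float(arr) if np.ndim(x) == 0 else arr


def sphere_radius_from_volume(volume):
    """Radius (um) of the sphere with the given volume (um^3): (3V/4pi)^(1/3)."""
    v = _validated(volume, "volume")
    return _as_input(volume, np.cbrt(3.0 * v / (4.0 * np.pi)))


def sphere_volume_from_radius(radius):
    """Volume (um^3) of a sphere of the given radius (um)."""
    r = _validated(radius, "radius")
    return _as_input(radius, 4.0 / 3.0 * np.pi * r**3)


def volume_to_equivalent_area(volume):
    """Equatorial-disc area (um^2) of the sphere with the given volume (um^3).

    This is the 3D -> 2D direction: the largest section a sphere of volume
    ``V`` can produce, ``pi * (3V/4pi)^(2/3)``. Strictly increasing in ``V``.
    """
    v = _validated(volume, "volume")
    r = np.cbrt(3.0 * v / (4.0 * np.pi))
    return _as_input(volume, np.pi * r**2)


def area_to_equivalent_volume(area):
    """Volume (um^3) of the sphere whose largest section has the given area (um^2).

    This is the 2D -> 3D direction, the exact inverse of
    :func:`volume_to_equivalent_area`: ``(4/3) pi (A/pi)^(3/2)``.
    """
    a = _validated(area, "area")
    r = np.sqrt(a / np.pi)
    return _as_input(area, 4.0 / 3.0 * np.pi * r**3)


def length_to_disc_area(length):
    """Area (um^2) of the disc with the given length (um) as its diameter.

    Applied to PSD lengths this yields PSD_S, to apposition lengths SAL_S:
    the 2D counterparts of the apposition surface measured on volumes.
    """
    length_arr = _validated(length, "length")
    return _as_input(length, np.pi * (length_arr / 2.0) ** 2)


def report_round(x: float, ndigits: int = 3) -> float:
    """Round half-to-even at ``ndigits`` decimals, for printed reports.

    Internal computation is always full precision; this matches the
    precision at which morphometric tables are conventionally printed.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))
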