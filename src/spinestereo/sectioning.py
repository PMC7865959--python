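"""Virtual TEM sectioning: cut slabs through a synthetic neuropil.

A transmission-EM micrograph of a thin section is modelled as the
projection of everything inside a slab ``[z0, z0 + thickness)`` onto the
x-y plane, restricted to a rectangular field of view. For each spine head
(a sphere) intersecting the slab, the observed head profile is the largest
circle of the sphere-slab intersection — the projection through the slab's
thickness, which slightly overestimates a true infinitely-thin cut (the
Holmes effect). The PSD appears as a line whose length is modelled as the
chord of the PSD cap's rim circle cut by the slab; the synaptic apposition
length (SAL) is derived from the PSD chord by dividing by a per-profile
ratio drawn from a Beta distribution with mean 0.75 (the observed mean
PSD-to-apposition length ratio), so every emitted profile satisfies
``psd_length <= sal_length``. Profiles whose PSD chord falls below a
visibility threshold are dropped, standing in for the requirement that a
synapse be unambiguously identifiable on the image.

Shaft synapses are not sectioned: their PSDs sit on dendritic shafts this
model does not represent. This leaves the 2D density estimate slightly
below the all-synapse ground truth, matching the direction observed when
stereological estimates are compared with volume counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .synthetic import NeuropilVolume, Spine3D

__all__ = [
    "SectionPlane",
    "Profile2D",
    "Micrograph",
    "SectioningCriteria",
    "slab_sphere_profile",
    "psd_cap_rim",
    "psd_chord_in_slab",
    "sample_section_planes",
    "section_volume",
]


@dataclass(frozen=True)
class SectionPlane:
    """One slab + field of view. Thickness defaults to 0.065 um (a 60-70 nm
    ultrathin section); the slab occupies the half-open interval
    [z0, z0 + thickness)."""

    z0: float
    field_origin: tuple[float, float]
    field_size: tuple[float, float]
    thickness: float = 0.065

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigError("slab thickness must be positive")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ConfigError("field size must be positive")

    @property
    def z1(self) -> float:
        return self.z0 + self.thickness

    @property
    def area(self) -> float:
        return self.field_size[0] * self.field_size[1]


@dataclass
class Profile2D:
    """One sectioned spine head as measured on a micrograph.

    ``x``, ``y`` and ``radius`` locate the head profile disc on the section
    plane; they are carried so that counting-frame rules can be applied
    geometrically downstream.
    """

    spine_id: int | None
    head_area: float  # um^2
    psd_length: float  # um
    sal_length: float  # um
    touches_exclusion_edge: bool = False
    micrograph_id: int = 0
    x: float = math.nan
    y: float = math.nan

    @property
    def radius(self) -> float:
        return math.sqrt(self.head_area / math.pi)


@dataclass
class Micrograph:
    """A sampled 2D field: its slab, area and the profiles it contains."""

    id: int
    plane: SectionPlane
    profiles: list[Profile2D] = field(default_factory=list)

    @property
    def area(self) -> float:
        return self.plane.area


@dataclass(frozen=True)
class SectioningCriteria:
    """Inclusion rules and measurement model for virtual sectioning.

    ``psd_visibility_min`` (um) drops profiles whose PSD chord is too short
    to identify a synapse on the image (default 0.05, below the smallest
    PSD length observed on real sections). ``sal_ratio_mean`` and
    ``sal_ratio_concentration`` parametrise the Beta distribution of the
    per-profile PSD/SAL length ratio. ``frame_mode`` selects how profiles
    touching the field border are flagged: ``"unbiased"`` flags contact
    with the two exclusion edges (left + bottom) of an unbiased counting
    frame, ``"all_edges"`` flags contact with any border. ``exact_arc``
    replaces the rim-chord stand-in by the in-slab rim arc length.
    """

    psd_visibility_min: float = 0.05
    sal_ratio_mean: float = 0.75
    sal_ratio_concentration: float = 10.0
    frame_mode: str = "unbiased"
    exact_arc: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.sal_ratio_mean < 1):
            raise ConfigError("sal_ratio_mean must lie in (0, 1)")
        if self.sal_ratio_concentration <= 0:
            raise ConfigError("sal_ratio_concentration must be positive")
        if self.frame_mode not in ("unbiased", "all_edges"):
            raise ConfigError(f"unknown frame_mode {self.frame_mode!r}")

    @property
    def beta_ab(self) -> tuple[float, float]:
        nu = self.sal_ratio_concentration
        return self.sal_ratio_mean * nu, (1.0 - self.sal_ratio_mean) * nu


def slab_sphere_profile(
    center: tuple[float, float, float], radius: float, plane: SectionPlane
) -> float | None:
    """Projected profile area of a sphere seen through a slab, or None.

    If the slab contains the sphere's equatorial plane the projection is
    the full equatorial disc (area pi r^2); otherwise the largest circle of
    the sphere-slab intersection, at the nearer slab face: pi (r^2 - d^2)
    with d the distance from the centre to that face. None when the sphere
    misses the slab entirely.
    """
    if radius <= 0:
        raise ConfigError("sphere radius must be positive")
    zc = center[2]
    if plane.z0 <= zc <= plane.z1:
        return math.pi * radius * radius
    d = plane.z0 - zc if zc < plane.z0 else zc - plane.z1
    if d >= radius:
        return None
    return math.pi * (radius * radius - d * d)


def psd_cap_rim(head_radius: float, sas_area: float) -> tuple[float, float]:
    """(cap height h, rim-circle radius a) for a cap of area ``sas_area``
    on a sphere of radius ``head_radius`` (cap area = 2 pi R h)."""
    h = min(sas_area / (2.0 * math.pi * head_radius), 2.0 * head_radius)
    a2 = max(2.0 * head_radius * h - h * h, 0.0)
    return h, math.sqrt(a2)


def psd_chord_in_slab(
    spine: Spine3D, plane: SectionPlane, exact_arc: bool = False
) -> float | None:
    """Apparent PSD length of a spine's cap on a slab section, or None.

    The cap's rim circle (radius ``a``, centred at ``R - h`` along the PSD
    axis) is cut by the slab. The observed length is the rim chord at the
    slab offset — zero offset (full diameter ``2a``) when the rim centre's
    z lies inside the slab, otherwise the chord at the in-plane offset
    corresponding to the distance to the nearer slab face. With
    ``exact_arc`` the in-slab arc length of the rim circle is returned
    instead of the chord.
    """
    R = spine.head_radius
    if not np.isfinite(R):
        return None  # shaft synapse: no head, not sectioned
    h, a = psd_cap_rim(R, spine.sas_area)
    if a <= 0:
        return None
    nz = spine.psd_axis[2]
    rim_z = spine.center[2] + (R - h) * nz
    tilt = math.sqrt(max(1.0 - nz * nz, 0.0))  # in-plane tilt factor

    if plane.z0 <= rim_z <= plane.z1:
        delta = 0.0
    else:
        delta = plane.z0 - rim_z if rim_z < plane.z0 else rim_z - plane.z1

    if tilt < 1e-9:
        # rim circle lies (numerically) in a horizontal plane: seen whole or not at all
        return 2.0 * a if delta == 0.0 else None
    off = delta / tilt
    if off >= a:
        return None
    if not exact_arc:
        return 2.0 * math.sqrt(a * a - off * off)
    # in-slab arc: z along the rim is rim_z + a*tilt*sin(theta); the slab admits
    # |sin(theta)| up to s_hi and (signed) down to s_lo
    amp = a * tilt
    s_lo = (plane.z0 - rim_z) / amp
    s_hi = (plane.z1 - rim_z) / amp
    s_lo, s_hi = max(s_lo, -1.0), min(s_hi, 1.0)
    if s_hi <= s_lo:
        return None
    # measure of theta in [0, 2pi) with sin(theta) in [s_lo, s_hi]
    theta = 2.0 * (math.asin(s_hi) - math.asin(s_lo))
    return a * theta


def _disc_intersects_rect(
    x: float, y: float, r: float, origin: tuple[float, float], size: tuple[float, float]
) -> bool:
    dx = max(origin[0] - x, 0.0, x - (origin[0] + size[0]))
    dy = max(origin[1] - y, 0.0, y - (origin[1] + size[1]))
    return dx * dx + dy * dy <= r * r


def _touches_exclusion(
    x: float, y: float, r: float, plane: SectionPlane, mode: str
) -> bool:
    x0, y0 = plane.field_origin
    w, hgt = plane.field_size
    if mode == "unbiased":
        return x - r <= x0 or y - r <= y0
    # all_edges: literal reading — anything not fully inside the field is excluded
    return x - r <= x0 or y - r <= y0 or x + r >= x0 + w or y + r >= y0 + hgt


def sample_section_planes(
    volume: NeuropilVolume,
    n: int,
    field_size: tuple[float, float] = (5.0, 5.0),
    thickness: float = 0.065,
    seed: int = 0,
    margin: float = 0.45,
) -> list[SectionPlane]:
    """Draw ``n`` random fields of view inside the volume.

    Fields are inset by ``margin`` (um) from the box faces so that the
    sampled neuropil is surrounded by populated tissue on all sides, as a
    field on a real grid square is; the default margin exceeds the largest
    head radius the generator can produce.
    """
    if n < 1:
        raise ConfigError("need at least one section plane")
    Lx, Ly, Lz = volume.extent
    w, hgt = field_size
    if w + 2 * margin > Lx or hgt + 2 * margin > Ly or thickness + 2 * margin > Lz:
        raise ConfigError(
            f"field {field_size} / thickness {thickness} with margin {margin} "
            f"does not fit in extent {volume.extent}"
        )
    rng = np.random.default_rng(seed)
    planes = []
    for _ in range(n):
        x0 = rng.uniform(margin, Lx - margin - w)
        y0 = rng.uniform(margin, Ly - margin - hgt)
        z0 = rng.uniform(margin, Lz - margin - thickness)
        planes.append(
            SectionPlane(z0=z0, field_origin=(x0, y0), field_size=(w, hgt), thickness=thickness)
        )
    return planes


def section_volume(
    volume: NeuropilVolume,
    planes: Sequence[SectionPlane],
    criteria: SectioningCriteria | None = None,
    seed: int = 0,
) -> list[Micrograph]:
    """Section a neuropil with the given slabs and emit measurement tables.

    For every spine-head/slab intersection the head profile area, PSD chord
    and derived SAL are measured; a profile is emitted when its disc
    intersects the field of view and its PSD chord reaches the visibility
    threshold. ``touches_exclusion_edge`` is set from the field border
    according to ``criteria.frame_mode``. Deterministic for a fixed seed.
    """
    if len(planes) == 0:
        raise ConfigError("empty plane list")
    criteria = criteria or SectioningCriteria()
    rng = np.random.default_rng(seed)
    a_beta, b_beta = criteria.beta_ab

    micrographs: list[Micrograph] = []
    for mid, plane in enumerate(planes):
        mg = Micrograph(id=mid, plane=plane)
        for spine in volume.spines:
            if spine.on_shaft:
                continue
            area = slab_sphere_profile(spine.center, spine.head_radius, plane)
            if area is None:
                continue
            psd = psd_chord_in_slab(spine, plane, exact_arc=criteria.exact_arc)
            if psd is None or psd < criteria.psd_visibility_min:
                continue
            ratio = rng.beta(a_beta, b_beta)
            sal = psd / ratio
            x, y = spine.center[0], spine.center[1]
            r = math.sqrt(area / math.pi)
            if not _disc_intersects_rect(x, y, r, plane.field_origin, plane.field_size):
                continue
            mg.profiles.append(
                Profile2D(
                    spine_id=spine.id,
                    head_area=area,
                    psd_length=psd,
                    sal_length=sal,
                    touches_exclusion_edge=_touches_exclusion(x, y, r, plane, criteria.frame_mode),
                    micrograph_id=mid,
                    x=x,
                    y=y,
                )
            )
        micrographs.append(mg)
    return micrographs
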