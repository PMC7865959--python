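"""Synapse density estimation: 2D size-frequency stereology and 3D counts.

Two estimators of the number of synapses per unit volume:

* **Size-frequency method** (2D): on micrographs sampled with an unbiased
  counting frame, the numerical density is ``Na = (Nd / A) / d`` where
  ``Nd`` is the number of synaptic profiles not touching the frame's
  exclusion edges, ``A`` the total sampled area (um^2) and ``d`` the mean
  PSD length (um) of the counted profiles. The mean profile length serves
  as the mean height of the objects along the sectioning axis, converting
  a per-area profile count into a per-volume object count.

* **Direct 3D count**: synapses are counted inside a subvolume of a
  reconstructed (here: synthetic) block with three excluding planes — the
  planes through the box's low-x, low-y and low-z faces, by convention.
  Under the default ``brick`` rule a spine is counted when its head
  intersects the box and does not cross any of the three (extended)
  excluding planes: the classical unbiased counting brick, in which every
  object of a tiled tissue is counted exactly once. A stricter
  ``centroid`` variant additionally requires the SAS centroid to lie
  inside the box; it undercounts boundary-crossing heads and is kept for
  comparison. Shaft synapses (no head) are counted by their position.
  The count divided by the subvolume's volume gives the density; shaft
  synapses can be included (an all-synapses count) or not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigError, EstimationError
from .sectioning import Micrograph, Profile2D
from .synthetic import NeuropilVolume, Spine3D

__all__ = [
    "CountingFrame",
    "DensityEstimate",
    "profile_touches_exclusion",
    "apply_counting_frame",
    "size_frequency_density",
    "count_density_3d",
]

FrameMode = Literal["unbiased", "all_edges"]


@dataclass(frozen=True)
class CountingFrame:
    """Rectangular counting frame with two adjacent exclusion edges.

    By the standard unbiased-frame convention the left and bottom edges are
    forbidden: a profile touching either is not counted, while profiles
    crossing the top or right (inclusion) edges are. The ``all_edges`` mode
    instead rejects any profile not fully inside the frame — the literal
    "not touching the edges" reading, which undercounts.
    """

    origin: tuple[float, float]
    size: tuple[float, float]
    mode: FrameMode = "unbiased"

    def __post_init__(self) -> None:
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise ConfigError("counting frame size must be positive")
        if self.mode not in ("unbiased", "all_edges"):
            raise ConfigError(f"unknown frame mode {self.mode!r}")

    @property
    def area(self) -> float:
        return self.size[0] * self.size[1]


@dataclass(frozen=True)
class DensityEstimate:
    """A synapse density (per um^3) with its method and inputs."""

    na: float
    method: Literal["size_frequency_2d", "count_3d_spines", "count_3d_all"]
    n_counted: int
    area_or_volume_examined: float  # um^2 for 2D, um^3 for 3D
    mean_psd_length: float = math.nan  # um, size-frequency only


def profile_touches_exclusion(profile: Profile2D, frame: CountingFrame) -> bool:
    """Whether a profile's head disc touches the frame's forbidden edges."""
    x, y, r = profile.x, profile.y, profile.radius
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ConfigError("profile carries no position; cannot apply a counting frame")
    x0, y0 = frame.origin
    if frame.mode == "unbiased":
        return x - r <= x0 or y - r <= y0
    w, h = frame.size
    return x - r <= x0 or y - r <= y0 or x + r >= x0 + w or y + r >= y0 + h


def apply_counting_frame(
    profiles: Iterable[Profile2D], frame: CountingFrame
) -> list[Profile2D]:
    """Profiles intersecting the frame and not touching its exclusion edges."""
    out = []
    for p in profiles:
        x0, y0 = frame.origin
        w, h = frame.size
        dx = max(x0 - p.x, 0.0, p.x - (x0 + w))
        dy = max(y0 - p.y, 0.0, p.y - (y0 + h))
        if dx * dx + dy * dy > p.radius**2:
            continue
        if not profile_touches_exclusion(p, frame):
            out.append(p)
    return out


def size_frequency_density(
    profiles: Sequence[Profile2D],
    total_area: float,
    frames: Sequence[CountingFrame] | None = None,
) -> DensityEstimate:
    """Size-frequency estimate Na = (Nd / A) / d from 2D profiles.

    ``Nd`` counts the profiles not touching an exclusion edge and ``d`` is
    the mean PSD length over those counted profiles (a single global mean,
    not per-micrograph). When ``frames`` is given (one per micrograph, in
    micrograph-id order) the exclusion flags are recomputed geometrically;
    otherwise each profile's stored ``touches_exclusion_edge`` is used.
    """
    if total_area <= 0:
        raise ConfigError("total_area must be positive")
    if frames is not None:
        by_id = {i: f for i, f in enumerate(frames)}
        counted = [
            p
            for p in profiles
            if p.micrograph_id in by_id
            and not profile_touches_exclusion(p, by_id[p.micrograph_id])
        ]
    else:
        counted = [p for p in profiles if not p.touches_exclusion_edge]
    if not counted:
        raise EstimationError("no countable profiles: mean PSD length is undefined")
    d = float(np.mean([p.psd_length for p in counted]))
    nd = len(counted)
    return DensityEstimate(
        na=(nd / total_area) / d,
        method="size_frequency_2d",
        n_counted=nd,
        area_or_volume_examined=total_area,
        mean_psd_length=d,
    )


def _sas_centroid(spine: Spine3D) -> np.ndarray:
    """Centroid of the SAS: for heads, the cap-surface centroid along the
    PSD axis (at R - h/2 from the centre); for shaft synapses, the synapse
    position itself."""
    c = np.asarray(spine.center, dtype=float)
    if spine.on_shaft:
        return c
    r = spine.head_radius
    h = min(spine.sas_area / (2.0 * math.pi * r), 2.0 * r)
    return c + np.asarray(spine.psd_axis) * (r - h / 2.0)


def count_density_3d(
    volume: NeuropilVolume | Sequence[Spine3D],
    subvolume: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    include_shaft: bool = False,
    rule: Literal["brick", "centroid"] = "brick",
) -> DensityEstimate:
    """Direct count of synapses in a subvolume, with three excluding planes.

    Under ``rule="brick"`` (default) a spine head is counted when its
    sphere intersects the box and does not cross the three extended
    excluding planes (low-x, low-y, low-z) — unbiased for a subvolume
    surrounded by tissue. ``rule="centroid"`` instead requires the SAS
    centroid inside the box (plus the same exclusion), which undercounts
    at the boundary. Shaft synapses are points, counted by position, and
    only when ``include_shaft``.
    """
    if rule not in ("brick", "centroid"):
        raise ConfigError(f"unknown counting rule {rule!r}")
    if isinstance(volume, NeuropilVolume):
        spines = volume.spines
        if subvolume is None:
            subvolume = ((0.0, 0.0, 0.0), volume.extent)
    else:
        spines = list(volume)
        if subvolume is None:
            raise ConfigError("a subvolume box is required when passing a bare spine table")
    lo = np.asarray(subvolume[0], dtype=float)
    hi = np.asarray(subvolume[1], dtype=float)
    if np.any(hi <= lo):
        raise ConfigError(f"degenerate subvolume {subvolume}")
    vol = float(np.prod(hi - lo))

    n = 0
    for s in spines:
        if s.on_shaft:
            if not include_shaft:
                continue
            c = np.asarray(s.center, dtype=float)
            if np.any(c < lo) or np.any(c >= hi):
                continue
            n += 1
            continue
        c = np.asarray(s.center, dtype=float)
        r = s.head_radius
        # head crosses an extended excluding (low) plane -> never counted
        if np.any(c - r < lo):
            continue
        # head must appear in the box: sphere-box intersection
        gap = np.maximum(np.maximum(lo - c, 0.0), c - hi)
        if float(np.dot(gap, gap)) > r * r:
            continue
        if rule == "centroid":
            cen = _sas_centroid(s)
            if np.any(cen < lo) or np.any(cen >= hi):
                continue
        n += 1
    return DensityEstimate(
        na=n / vol,
        method="count_3d_all" if include_shaft else "count_3d_spines",
        n_counted=n,
        area_or_volume_examined=vol,
    )
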