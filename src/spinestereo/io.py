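"""Measurement-table schemas, validation and run configuration.

All files use comma-separated values, ``.`` decimal, UTF-8, mandatory
header; lengths are um, areas um^2, volumes um^3 everywhere (no nm).

Profile tables (2D measurements, one row per sectioned synapse)::

    spine_id, micrograph_id, head_area_um2, psd_length_um, sal_length_um,
    excluded [, x_um, y_um]

Spine tables (3D measurements, one row per reconstructed synapse)::

    spine_id, volume_um3, sas_um2, on_shaft, x, y, z
    [, axis_x, axis_y, axis_z, shape_class]

Shaft synapses carry an empty ``volume_um3``; coordinate columns may be
empty for density-only workflows that never place spines in space.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import TableFormatError
from .sectioning import Profile2D
from .synthetic import Spine3D

__all__ = [
    "PROFILE_COLUMNS",
    "SPINE_COLUMNS",
    "read_profile_table",
    "write_profile_table",
    "read_spine_table",
    "write_spine_table",
    "RunConfig",
]

PROFILE_COLUMNS = [
    "spine_id",
    "micrograph_id",
    "head_area_um2",
    "psd_length_um",
    "sal_length_um",
    "excluded",
]
SPINE_COLUMNS = ["spine_id", "volume_um3", "sas_um2", "on_shaft", "x", "y", "z"]

_CAP_COEF = (36.0 * math.pi) ** (1.0 / 3.0)  # 4 pi R^2 = coef * V^(2/3)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path: Path, allow_nan: bool = False) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(vals) & df[col].notna().to_numpy()
    if bad.any():
        rows = np.flatnonzero(bad).tolist()
        raise TableFormatError(f"{path}: non-numeric value in column {col!r}, row(s) {rows}")
    if not allow_nan and np.isnan(vals).any():
        rows = np.flatnonzero(np.isnan(vals)).tolist()
        raise TableFormatError(f"{path}: empty cell in column {col!r}, row(s) {rows}")
    return vals


def read_profile_table(path: str | Path) -> list[Profile2D]:
    """Read and validate a 2D profile table.

    Rows with non-positive sizes or ``psd_length_um > sal_length_um`` are
    rejected with their row indices (0-based data rows).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise TableFormatError(f"{path}: table has no data rows")
    _require_columns(df, PROFILE_COLUMNS, path)
    area = _numeric(df, "head_area_um2", path)
    psd = _numeric(df, "psd_length_um", path)
    sal = _numeric(df, "sal_length_um", path)
    errors = []
    for i in range(len(df)):
        if area[i] <= 0 or psd[i] <= 0 or sal[i] <= 0:
            errors.append(f"row {i}: sizes must be positive")
        elif psd[i] > sal[i]:
            errors.append(f"row {i}: psd_length_um {psd[i]} exceeds sal_length_um {sal[i]}")
    if errors:
        raise TableFormatError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    has_xy = "x_um" in df.columns and "y_um" in df.columns
    x = _numeric(df, "x_um", path, allow_nan=True) if has_xy else np.full(len(df), np.nan)
    y = _numeric(df, "y_um", path, allow_nan=True) if has_xy else np.full(len(df), np.nan)
    excluded = df["excluded"].astype(bool).to_numpy()
    return [
        Profile2D(
            spine_id=None if pd.isna(df["spine_id"].iloc[i]) else int(df["spine_id"].iloc[i]),
            head_area=float(area[i]),
            psd_length=float(psd[i]),
            sal_length=float(sal[i]),
            touches_exclusion_edge=bool(excluded[i]),
            micrograph_id=int(df["micrograph_id"].iloc[i]),
            x=float(x[i]),
            y=float(y[i]),
        )
        for i in range(len(df))
    ]


def write_profile_table(profiles: Sequence[Profile2D], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "spine_id": [p.spine_id for p in profiles],
            "micrograph_id": [p.micrograph_id for p in profiles],
            "head_area_um2": [repr(p.head_area) for p in profiles],
            "psd_length_um": [repr(p.psd_length) for p in profiles],
            "sal_length_um": [repr(p.sal_length) for p in profiles],
            "excluded": [int(p.touches_exclusion_edge) for p in profiles],
            "x_um": [repr(p.x) for p in profiles],
            "y_um": [repr(p.y) for p in profiles],
        }
    )
    df.to_csv(path, index=False)


def read_spine_table(path: str | Path) -> list[Spine3D]:
    """Read and validate a 3D spine table.

    Spine-head rows need a positive volume and an SAS within the
    spherical-cap bound 4*pi*R^2; shaft rows have an empty volume.
    Coordinates may be empty (density-only mode: positions NaN).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise TableFormatError(f"{path}: table has no data rows")
    _require_columns(df, SPINE_COLUMNS, path)
    vol = _numeric(df, "volume_um3", path, allow_nan=True)
    sas = _numeric(df, "sas_um2", path)
    on_shaft = df["on_shaft"].astype(bool).to_numpy()
    coords = {c: _numeric(df, c, path, allow_nan=True) for c in ("x", "y", "z")}
    has_axis = all(c in df.columns for c in ("axis_x", "axis_y", "axis_z"))
    axes = (
        {c: _numeric(df, c, path, allow_nan=True) for c in ("axis_x", "axis_y", "axis_z")}
        if has_axis
        else None
    )
    errors = []
    for i in range(len(df)):
        if sas[i] <= 0:
            errors.append(f"row {i}: sas_um2 must be positive")
        if not on_shaft[i]:
            if np.isnan(vol[i]) or vol[i] <= 0:
                errors.append(f"row {i}: spine-head row needs a positive volume_um3")
            elif sas[i] > _CAP_COEF * vol[i] ** (2.0 / 3.0) * (1 + 1e-9):
                errors.append(
                    f"row {i}: sas_um2 {sas[i]} exceeds the sphere-surface bound for "
                    f"volume_um3 {vol[i]}"
                )
        elif not np.isnan(vol[i]):
            errors.append(f"row {i}: shaft synapse must not carry a head volume")
    if errors:
        raise TableFormatError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    spines = []
    for i in range(len(df)):
        axis = (
            (float(axes["axis_x"][i]), float(axes["axis_y"][i]), float(axes["axis_z"][i]))
            if axes is not None
            else (0.0, 0.0, 1.0)
        )
        shape = None
        if "shape_class" in df.columns and isinstance(df["shape_class"].iloc[i], str):
            shape = df["shape_class"].iloc[i]
        spines.append(
            Spine3D(
                id=int(df["spine_id"].iloc[i]),
                head_volume=float(vol[i]),
                sas_area=float(sas[i]),
                psd_axis=axis,
                on_shaft=bool(on_shaft[i]),
                shape_class=shape,
                center=(float(coords["x"][i]), float(coords["y"][i]), float(coords["z"][i])),
            )
        )
    return spines


def write_spine_table(spines: Sequence[Spine3D], path: str | Path) -> None:
    """Write the full spine schema; lossless under read_spine_table."""

    def num(v: float) -> str:
        v = float(v) if v is not None else None
        return "" if (v is None or math.isnan(v)) else repr(v)

    df = pd.DataFrame(
        {
            "spine_id": [s.id for s in spines],
            "volume_um3": [num(s.head_volume) for s in spines],
            "sas_um2": [num(s.sas_area) for s in spines],
            "on_shaft": [int(s.on_shaft) for s in spines],
            "x": [num(s.center[0]) for s in spines],
            "y": [num(s.center[1]) for s in spines],
            "z": [num(s.center[2]) for s in spines],
            "axis_x": [num(s.psd_axis[0]) for s in spines],
            "axis_y": [num(s.psd_axis[1]) for s in spines],
            "axis_z": [num(s.psd_axis[2]) for s in spines],
            "shape_class": [s.shape_class or "" for s in spines],
        }
    )
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run byte-for-byte."""

    seed: int = 0
    density: float = 2.0  # synapses per um^3
    extent: tuple[float, float, float] = (10.0, 10.0, 1.9)  # um; 190 um^3
    n_micrographs: int = 75
    field_size: tuple[float, float] = (5.0, 5.0)  # um
    thickness: float = 0.065  # um
    frame_mode: str = "unbiased"
    #: inset (um) of the 3D counting subvolume from the block faces, so the
    #: counted box is surrounded by populated tissue; exceeds the largest
    #: head radius the generator can produce
    count_margin: float = 0.45
    simulation: dict[str, Any] = field(default_factory=dict)  # PopulationParams overrides
    sectioning: dict[str, Any] = field(default_factory=dict)  # SectioningCriteria overrides
    outdir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["field_size"] = list(self.field_size)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TableFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "extent" in raw:
            raw["extent"] = tuple(raw["extent"])
        if "field_size" in raw:
            raw["field_size"] = tuple(raw["field_size"])
        return cls(**raw)
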