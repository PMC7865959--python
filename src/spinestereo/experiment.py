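"""End-to-end experiment drivers binding the pipeline stages together.

The reference experiment mirrors a paired 2D/3D study of the same tissue:
one synthetic neuropil block is generated at a known synapse density, the
2D arm sections it into random micrograph fields and estimates density
with the size-frequency method, and the 3D arm counts synapses directly
inside the block (with the three excluding planes), with and without the
shaft synapses. The morphometry experiment additionally collects the
2D and 3D measurement tables and runs the comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RunConfig
from .sectioning import (
    Micrograph,
    Profile2D,
    SectioningCriteria,
    sample_section_planes,
    section_volume,
)
from .stereology import DensityEstimate, count_density_3d, size_frequency_density
from .synthetic import NeuropilVolume, PopulationParams, make_neuropil

__all__ = ["DensityExperiment", "run_density_experiment"]


@dataclass
class DensityExperiment:
    """Everything one paired 2D/3D run produced."""

    config: RunConfig
    volume: NeuropilVolume
    micrographs: list[Micrograph]
    estimate_2d: DensityEstimate
    estimate_3d_spines: DensityEstimate
    estimate_3d_all: DensityEstimate

    @property
    def profiles(self) -> list[Profile2D]:
        return [p for m in self.micrographs for p in m.profiles]

    @property
    def total_area(self) -> float:
        return sum(m.area for m in self.micrographs)

    @property
    def true_density(self) -> float:
        return self.volume.true_density


def run_density_experiment(config: RunConfig | None = None, seed: int | None = None) -> DensityExperiment:
    """Run the paired 2D/3D density comparison on one synthetic block.

    Defaults (from :class:`RunConfig`): a 190 um^3 block at 2.0
    synapses/um^3, sectioned into 75 random 5 x 5 um fields of 65 nm
    slabs (about 1900 um^2 of neuropil), against a direct count over the
    full block. ``seed`` overrides the config's seed.
    """
    config = config or RunConfig()
    if seed is not None:
        config = RunConfig(**{**config.__dict__, "seed": seed})
    ss = np.random.SeedSequence(config.seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss]

    params = PopulationParams(**config.simulation) if config.simulation else None
    volume = make_neuropil(config.density, config.extent, params=params, seed=sub[0])
    planes = sample_section_planes(
        volume,
        config.n_micrographs,
        field_size=config.field_size,
        thickness=config.thickness,
        seed=sub[1],
    )
    crit_kwargs = dict(config.sectioning)
    crit_kwargs.setdefault("frame_mode", config.frame_mode)
    criteria = SectioningCriteria(**crit_kwargs)
    micrographs = section_volume(volume, planes, criteria=criteria, seed=sub[2])

    profiles = [p for m in micrographs for p in m.profiles]
    total_area = sum(m.area for m in micrographs)
    est_2d = size_frequency_density(profiles, total_area)
    # count inside an interior brick so the counted box is surrounded by tissue
    m = config.count_margin
    sub = ((m, m, m), tuple(e - m for e in config.extent))
    est_3d = count_density_3d(volume, subvolume=sub, include_shaft=False)
    est_3d_all = count_density_3d(volume, subvolume=sub, include_shaft=True)
    return DensityExperiment(
        config=config,
        volume=volume,
        micrographs=micrographs,
        estimate_2d=est_2d,
        estimate_3d_spines=est_3d,
        estimate_3d_all=est_3d_all,
    )
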