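import numpy as np
import pytest

from spinestereo.synthetic import (
    NeuropilVolume,
    PopulationParams,
    Spine3D,
    generate_population,
    place_in_volume,
)


@pytest.fixture(scope="session")
def default_params() -> PopulationParams:
    return PopulationParams()


@pytest.fixture(scope="session")
def population_340() -> list[Spine3D]:
    """Default population at the reference 3D sample size."""
    return generate_population(340, seed=1)


@pytest.fixture(scope="session")
def small_scene() -> NeuropilVolume:
    """A small placed neuropil for sectioning/counting tests."""
    spines = generate_population(120, seed=11)
    return place_in_volume(spines, extent=(6.0, 6.0, 2.0), seed=12)


def make_head(
    id: int = 0,
    volume: float = 0.066,
    sas: float = 0.089,
    axis=(0.0, 0.0, 1.0),
    center=(0.0, 0.0, 0.0),
) -> Spine3D:
    """Hand-built spine head for geometric unit tests."""
    axis = np.asarray(axis, dtype=float)
    axis = tuple(axis / np.linalg.norm(axis))
    return Spine3D(
        id=id, head_volume=volume, sas_area=sas, psd_axis=axis, on_shaft=False, center=tuple(center)
    )
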