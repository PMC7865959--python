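"""Virtual sectioning: slab-sphere geometry, PSD chords, inclusion rules."""

import math

import numpy as np
import pytest
from scipy import integrate

from spinestereo.errors import ConfigError
from spinestereo import geometry
from spinestereo.sectioning import (
    Micrograph,
    SectioningCriteria,
    SectionPlane,
    psd_cap_rim,
    psd_chord_in_slab,
    sample_section_planes,
    section_volume,
    slab_sphere_profile,
)
from spinestereo.synthetic import NeuropilVolume, generate_population, place_in_volume
from conftest import make_head


def plane(z0=0.0, thickness=0.065, origin=(-10.0, -10.0), size=(20.0, 20.0)):
    return SectionPlane(z0=z0, thickness=thickness, field_origin=origin, field_size=size)


def mc_projected_area(center_z, radius, pl, n=250_000, seed=0):
    """Monte-Carlo oracle: area of the sphere-slab projection by sampling
    (x, y) points and checking any-z membership on a fine grid in the slab."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-radius, radius, n)
    y = rng.uniform(-radius, radius, n)
    zs = np.linspace(pl.z0, pl.z0 + pl.thickness, 64)
    r2 = radius * radius
    best = np.min((zs - center_z) ** 2)  # nearest slab z to the centre
    inside = x * x + y * y <= r2 - best
    return 4.0 * radius * radius * inside.mean()


class TestSlabSphereProfile:
    def test_equatorial_circle_inside_slab(self):
        area = slab_sphere_profile((0, 0, 0.03), 0.3, plane())
        assert area == pytest.approx(math.pi * 0.09, rel=1e-12)

    def test_offset_circle_of_intersection(self):
        # centre 0.25 above the slab top face
        pl = plane(z0=0.0, thickness=0.065)
        area = slab_sphere_profile((0, 0, pl.z1 + 0.25), 0.3, pl)
        assert area == pytest.approx(math.pi * (0.09 - 0.0625), rel=1e-12)
        assert area == pytest.approx(0.0864, abs=2e-4)

    def test_miss_returns_none(self):
        pl = plane()
        assert slab_sphere_profile((0, 0, pl.z1 + 0.5), 0.3, pl) is None
        assert slab_sphere_profile((0, 0, pl.z0 - 0.31), 0.3, pl) is None

    @pytest.mark.parametrize("zc", [0.02, 0.1, 0.25, -0.15])
    def test_matches_monte_carlo_projection(self, zc):
        pl = plane()
        got = slab_sphere_profile((0, 0, zc), 0.3, pl)
        ref = mc_projected_area(zc, 0.3, pl)
        assert got == pytest.approx(ref, rel=0.02)

    def test_mean_area_over_random_slabs_matches_quadrature(self):
        """Empirical mean profile area over many random slab offsets equals
        the slab-corrected expectation from 1D quadrature (2% at 1e5 slabs)."""
        R, t = 0.25, 0.065
        zlo, zhi = -R - t, R  # slab z0 range that intersects the sphere at z=0

        def area_of(z0):  # independent piecewise closed form, written out here
            if z0 <= 0.0 <= z0 + t:
                return math.pi * R * R
            d = min(abs(z0), abs(z0 + t))
            return math.pi * (R * R - d * d) if d < R else 0.0

        expected, _ = integrate.quad(area_of, zlo, zhi)
        expected /= zhi - zlo

        rng = np.random.default_rng(123)
        z0s = rng.uniform(zlo, zhi, 100_000)
        areas = np.array(
            [a if (a := slab_sphere_profile((0, 0, 0), R, plane(z0=z0))) is not None else 0.0
             for z0 in z0s]
        )
        assert areas.mean() == pytest.approx(expected, rel=0.02)

    def test_bad_radius(self):
        with pytest.raises(ConfigError):
            slab_sphere_profile((0, 0, 0), 0.0, plane())


class TestPsdChord:
    def test_bisected_in_plane_axis_gives_rim_diameter(self):
        """Slab through the rim centre, PSD axis in-plane: full rim diameter."""
        s = make_head(volume=0.066, sas=0.089, axis=(1.0, 0.0, 0.0), center=(0, 0, 0.03))
        pl = plane()
        _, a = psd_cap_rim(s.head_radius, s.sas_area)
        # rim centre sits at z = 0.03 (axis has no z component) -> inside slab
        assert psd_chord_in_slab(s, pl) == pytest.approx(2 * a, rel=1e-12)

    def test_cap_missing_slab_returns_none(self):
        s = make_head(axis=(0, 0, 1.0), center=(0, 0, -0.5))
        assert psd_chord_in_slab(s, plane()) is None

    def test_offset_chord_shorter_than_diameter(self):
        s = make_head(axis=(1.0, 0, 0), center=(0, 0, 0.2))
        _, a = psd_cap_rim(s.head_radius, s.sas_area)
        chord = psd_chord_in_slab(s, plane())
        assert chord is not None and 0 < chord < 2 * a

    @pytest.mark.parametrize("axis,cz", [((1.0, 0, 0), 0.12), ((0.6, 0, 0.8), 0.05),
                                         ((1.0, 0, 0), 0.03)])
    def test_exact_arc_matches_dense_sampling_oracle(self, axis, cz):
        """Exact-arc mode equals the rim-circle arc length inside the slab,
        measured by a fine polyline over the parametrised circle."""
        s = make_head(axis=axis, center=(0, 0, cz))
        pl = plane()
        arc = psd_chord_in_slab(s, pl, exact_arc=True)
        R = s.head_radius
        h, a = psd_cap_rim(R, s.sas_area)
        n = np.asarray(s.psd_axis)
        # orthonormal basis of the rim plane
        u = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-12:
            u = np.cross(n, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        th = np.linspace(0, 2 * math.pi, 2_000_001)
        pts_z = (np.asarray(s.center) + (R - h) * n)[2] + a * (
            u[2] * np.cos(th) + v[2] * np.sin(th)
        )
        in_slab = (pts_z >= pl.z0) & (pts_z <= pl.z1)
        oracle = a * 2 * math.pi * in_slab.mean()
        if arc is None:
            assert oracle < 1e-3
        else:
            assert arc == pytest.approx(oracle, rel=5e-3)

    def test_cap_rim_geometry(self):
        R = 0.2
        h, a = psd_cap_rim(R, 2 * math.pi * R * 0.05)  # cap of height 0.05
        assert h == pytest.approx(0.05)
        assert a == pytest.approx(math.sqrt(2 * R * 0.05 - 0.05**2))


class TestSectionVolume:
    def test_empty_volume_all_micrographs_empty(self):
        vol = NeuropilVolume(extent=(6, 6, 2), spines=[], seed=0)
        pls = [plane(z0=0.5, origin=(1, 1), size=(3, 3))]
        mgs = section_volume(vol, pls, seed=0)
        assert all(len(m.profiles) == 0 for m in mgs)

    def test_empty_plane_list_rejected(self, small_scene):
        with pytest.raises(ConfigError):
            section_volume(small_scene, [], seed=0)

    def test_psd_never_longer_than_sal(self, small_scene):
        pls = sample_section_planes(small_scene, 30, field_size=(3, 3), seed=7)
        mgs = section_volume(small_scene, pls, seed=8)
        profs = [p for m in mgs for p in m.profiles]
        assert profs
        assert all(0 < p.psd_length <= p.sal_length for p in profs)
        assert all(p.head_area > 0 for p in profs)

    def test_visibility_threshold_enforced(self, small_scene):
        pls = sample_section_planes(small_scene, 30, field_size=(3, 3), seed=7)
        mgs = section_volume(small_scene, pls, seed=8)
        assert all(p.psd_length >= 0.05 for m in mgs for p in m.profiles)

    def test_no_profile_from_sphere_missing_slab(self, small_scene):
        """Brute-force cross-check: every emitted profile's source sphere
        really intersects its slab."""
        pls = sample_section_planes(small_scene, 20, field_size=(3, 3), seed=3)
        mgs = section_volume(small_scene, pls, seed=4)
        by_id = {s.id: s for s in small_scene.spines}
        checked = 0
        for m in mgs:
            for p in m.profiles:
                s = by_id[p.spine_id]
                zc, r = s.center[2], s.head_radius
                assert m.plane.z0 - r < zc < m.plane.z1 + r
                checked += 1
        assert checked > 0

    def test_deterministic_given_seed(self, small_scene):
        pls = sample_section_planes(small_scene, 10, field_size=(3, 3), seed=5)
        a = section_volume(small_scene, pls, seed=6)
        b = section_volume(small_scene, pls, seed=6)
        assert [(p.spine_id, p.head_area, p.sal_length) for m in a for p in m.profiles] == [
            (p.spine_id, p.head_area, p.sal_length) for m in b for p in m.profiles
        ]

    def test_shaft_synapses_not_sectioned(self):
        sp = generate_population(300, seed=31)
        vol = place_in_volume(sp, extent=(6, 6, 2), seed=32)
        pls = sample_section_planes(vol, 40, field_size=(3, 3), seed=33)
        mgs = section_volume(vol, pls, seed=34)
        shaft_ids = {s.id for s in vol.spines if s.on_shaft}
        assert shaft_ids
        assert all(p.spine_id not in shaft_ids for m in mgs for p in m.profiles)

    def test_2d_underestimates_3d_head_size(self, small_scene):
        """Random sectioning makes mean profile area fall below the
        equivalent area of the mean true head volume."""
        pls = sample_section_planes(small_scene, 60, field_size=(3, 3), seed=9)
        mgs = section_volume(small_scene, pls, seed=10)
        areas = np.array([p.head_area for m in mgs for p in m.profiles])
        mean_v = np.mean([s.head_volume for s in small_scene.spines if s.is_head])
        assert areas.mean() < geometry.volume_to_equivalent_area(mean_v)


class TestPlanes:
    def test_field_must_fit_extent(self, small_scene):
        with pytest.raises(ConfigError):
            sample_section_planes(small_scene, 5, field_size=(10.0, 10.0), seed=0)

    def test_criteria_validation(self):
        with pytest.raises(ConfigError):
            SectioningCriteria(sal_ratio_mean=1.5)
        with pytest.raises(ConfigError):
            SectioningCriteria(frame_mode="sideways")
        with pytest.raises(ConfigError):
            SectionPlane(z0=0, field_origin=(0, 0), field_size=(1, 1), thickness=-1)
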