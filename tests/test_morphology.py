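import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flyatlas.atlas_io import Pointcloud
from flyatlas.morphology import (
    DISK_RADIUS_UM,
    MeshError,
    density_map,
    egg_length,
    local_density,
    mesh_faces,
    shape_profile,
    surface_area,
)
from flyatlas.synthetic import SyntheticSpec, ellipsoid_area, generate_atlas


def _sphere_atlas(n=1500, r=100.0, seed=17):
    spec = SyntheticSpec(
        seed=seed, n_species=1, species_names=("sph",),
        egg_length=(2 * r,), max_radius=(r,), n_nuclei=(n,),
        shift_field=(0.0,), temporal_offset=(0,), furrow_depressions=())
    atlas, _ = generate_atlas(spec, 0)
    return atlas


def _as_pointcloud(atlas):
    return Pointcloud(
        species=atlas.species, stage=88.0, cohort=6,
        ids=np.arange(atlas.n_nuclei), coords=atlas.positions[-1],
        expr=atlas.E[:, :, -1], genes=list(atlas.genes),
        neighbors=list(atlas.neighbors), dorsal=atlas.dorsal,
        anterior=atlas.anterior)


class TestSurfaceArea:
    def test_single_triangle_half_square_micron(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        adj = [np.array([1, 2]), np.array([0, 2]), np.array([0, 1])]
        pc = Pointcloud("tri", 0.0, 1, np.arange(3), coords,
                        np.ones((3, 1)), ["g"], neighbors=adj)
        assert len(mesh_faces(pc.neighbors)) == 1
        assert np.isclose(surface_area(pc), 0.5)

    def test_tetrahedron_keeps_all_faces(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        adj = [np.array([1, 2, 3]), np.array([0, 2, 3]),
               np.array([0, 1, 3]), np.array([0, 1, 2])]
        pc = Pointcloud("tet", 0.0, 1, np.arange(4), coords,
                        np.ones((4, 1)), ["g"], neighbors=adj)
        assert len(mesh_faces(pc.neighbors)) == 4
        # 3 right triangles of area 1/2 plus the sqrt(3)/2 diagonal face
        assert np.isclose(surface_area(pc), 1.5 + np.sqrt(3) / 2)

    def test_sphere_area_within_2pct(self):
        atlas = _sphere_atlas(n=1500, r=100.0)
        assert abs(surface_area(atlas) / (4 * np.pi * 100.0 ** 2) - 1) < 0.02

    def test_prolate_ellipsoid_area_within_2pct(self, uniform_atlas):
        spec, atlas = uniform_atlas
        a, b = spec.egg_length[0] / 2, spec.max_radius[0]
        # Thomsen approximation as an independent closed-form oracle
        p = 1.6075
        ap_, bp = a ** p, b ** p
        thomsen = 4 * np.pi * ((ap_ * bp + ap_ * bp + bp * bp) / 3) ** (1 / p)
        assert abs(surface_area(atlas) / thomsen - 1) < 0.02

    def test_non_manifold_mesh_lists_edges(self):
        # book of three triangles sharing edge (0,1): that edge sits in
        # three faces, which no surface allows
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [5.0, 5, 5]])
        adj = [np.array([1, 2, 3, 4]), np.array([0, 2, 3, 4]),
               np.array([0, 1]), np.array([0, 1]), np.array([0, 1]),
               np.array([], dtype=int)]
        pc = Pointcloud("book", 0.0, 1, np.arange(6), coords,
                        np.ones((6, 1)), ["g"],
                        neighbors=[a for a in adj])
        with pytest.raises(MeshError) as err:
            surface_area(pc)
        assert (0, 1) in err.value.offending_edges

    def test_rigid_motion_invariance(self, uniform_atlas):
        _, atlas = uniform_atlas
        pc = _as_pointcloud(atlas)
        base = surface_area(pc)
        R = Rotation.from_euler("zyx", [1.0, 0.5, -0.4]).as_matrix()
        pc2 = _as_pointcloud(atlas)
        pc2.coords = pc.coords @ R.T + np.array([3.0, -8.0, 11.0])
        assert np.isclose(surface_area(pc2), base, rtol=1e-9)


class TestLocalDensity:
    def test_isolated_nucleus_density(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        dens = local_density(coords)
        assert np.allclose(dens, 1.0 / (np.pi * DISK_RADIUS_UM ** 2))

    def test_planar_grid_density(self):
        # uniform planar lattice, spacing 5 um -> density ~ 1/25 per um^2
        xs = np.arange(-60.0, 61.0, 5.0)
        X, Y = np.meshgrid(xs, xs)
        coords = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        center = np.argmin(np.abs(coords[:, 0]) + np.abs(coords[:, 1]))
        dens = local_density(coords)
        assert abs(dens[center] * 25.0 - 1) < 0.10

    def test_mean_density_conserves_count(self, uniform_atlas):
        _, atlas = uniform_atlas
        dens = local_density(atlas)
        expected = atlas.n_nuclei / surface_area(atlas)
        assert abs(dens.mean() / expected - 1) < 0.05


class TestDensityMap:
    def test_uniform_embryo_gives_flat_map(self, uniform_atlas):
        _, atlas = uniform_atlas
        dm = density_map([_as_pointcloud(atlas)], cohort=6, grid=(20, 8))
        vals = dm.values
        assert vals.min() > 0
        assert vals.std() / vals.mean() < 0.15

    def test_map_average_is_linear(self, uniform_atlas):
        _, atlas = uniform_atlas
        pc = _as_pointcloud(atlas)
        pc3 = _as_pointcloud(atlas)
        pc3.coords = pc.coords / np.sqrt(3.0)  # 3x the surface density
        one = density_map([pc], cohort=6, grid=(10, 4)).values
        three = density_map([pc3], cohort=6, grid=(10, 4)).values
        both = density_map([pc, pc3], cohort=6, grid=(10, 4)).values
        assert np.allclose(both, (one + three) / 2)

    def test_furrow_minimum_near_truth(self, small_atlas):
        # cephalic-furrow ring at ap ~ 0.32: map minimum lands close to it
        _, atlas, _ = small_atlas
        dm = density_map([_as_pointcloud(atlas)], cohort=6, grid=(25, 4))
        profile = dm.values.mean(axis=1)
        ap_min = dm.ap_centers[np.argmin(np.where(
            (dm.ap_centers > 0.1) & (dm.ap_centers < 0.9), profile, np.inf))]
        assert abs(ap_min - 0.32) < 0.08

    def test_empty_cohort_rejected(self, uniform_atlas):
        _, atlas = uniform_atlas
        with pytest.raises(ValueError, match="cohort"):
            density_map([_as_pointcloud(atlas)], cohort=2)


class TestEggLengthAndShape:
    def test_cylinder_length(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 400)
        coords = np.column_stack([
            np.r_[rng.uniform(0, 400.0, 398), 0.0, 400.0],
            40 * np.sin(np.r_[theta[:398], 0.0, 0.0]),
            40 * np.cos(np.r_[theta[:398], 0.0, 0.0])])
        assert abs(egg_length(coords) - 400.0) < 1.0

    def test_generator_truth_recovered_within_1pct(self, uniform_atlas):
        spec, atlas = uniform_atlas
        assert abs(egg_length(atlas) / spec.egg_length[0] - 1) < 0.01

    def test_rotation_invariance(self, uniform_atlas):
        _, atlas = uniform_atlas
        coords = atlas.positions[-1]
        R = Rotation.from_euler("xyz", [0.2, 0.9, -1.5]).as_matrix()
        assert np.isclose(egg_length(coords @ R.T + 5.0), egg_length(coords),
                          rtol=1e-9)

    def test_shape_profile_radius(self, uniform_atlas):
        spec, atlas = uniform_atlas
        prof = shape_profile(atlas, n_bins=20)
        mid = np.nanmax(prof["mean_radius"])
        assert abs(mid / spec.max_radius[0] - 1) < 0.05
        assert np.nanmax(prof["dorsal_extent"]) > 0
        assert np.nanmin(prof["ventral_extent"]) < 0


def test_area_scales_with_length():
    # family of scaled embryos: surface area vs egg length is near-linear
    # in the scaling regime the species span (shared shape, stretched)
    lengths = [300.0, 400.0, 500.0]
    areas = []
    for L in lengths:
        spec = SyntheticSpec(
            seed=23, n_species=1, species_names=("s",), egg_length=(L,),
            max_radius=(L / 5,), n_nuclei=(800,), shift_field=(0.0,),
            temporal_offset=(0,), furrow_depressions=())
        atlas, _ = generate_atlas(spec, 0)
        areas.append(surface_area(atlas))
    ratios = np.diff(areas) / np.diff(np.square(lengths))
    # uniform stretch: area grows as length^2 with a shared constant
    assert abs(ratios[0] / ratios[1] - 1) < 0.05
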