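import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flyatlas.atlas_io import Atlas
from flyatlas.exprdist import (
    displacement_field,
    expression_distance,
    local_best_match,
    normalize_expression,
    spatial_match,
    weighted_displacement,
)
from flyatlas.synthetic import SyntheticSpec, generate_atlas


@pytest.fixture(scope="module")
def norm_pair(atlas_pair):
    ref, tgt, _ = atlas_pair
    return normalize_expression(ref), normalize_expression(tgt)


class TestNormalize:
    def test_max_is_one(self, atlas_pair):
        ref = normalize_expression(atlas_pair[0])
        maxes = ref.E.max(axis=0)
        assert np.allclose(maxes[maxes > 0], 1.0)

    def test_closed_form(self):
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = 1.0
        pos[0, 1, 1] = 0.5
        E = np.array([[[2.0]], [[4.0]]])
        a = Atlas("x", pos, E, ["g"])
        out = normalize_expression(a)
        assert np.allclose(out.E.ravel(), [0.5, 1.0])

    def test_all_zero_gene_unchanged_with_warning(self):
        pos = np.random.default_rng(0).normal(size=(1, 5, 3))
        E = np.zeros((5, 1, 1))
        a = Atlas("x", pos, E, ["g"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_expression(a)
        assert np.array_equal(out.E, E)


class TestExpressionDistance:
    def test_identical_cells_zero(self, norm_pair):
        ref, _ = norm_pair
        assert expression_distance(ref, 5, ref, 5) == 0.0

    def test_closed_form_single_entry(self):
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = 1.0
        pos[0, 0, 1] = 1.0
        E = np.array([[[1.0]], [[0.5]]])
        a = Atlas("x", pos, E, ["g"])
        assert np.isclose(expression_distance(a, 0, a, 1), 0.25)

    def test_symmetric_nonnegative_additive(self, norm_pair):
        ref, tgt = norm_pair
        rng = np.random.default_rng(3)
        genes = list(ref.genes)
        half, rest = genes[:4], genes[4:]
        for i, j in zip(rng.integers(0, ref.n_nuclei, 10),
                        rng.integers(0, tgt.n_nuclei, 10)):
            d = expression_distance(ref, i, tgt, j)
            assert d >= 0
            assert np.isclose(d, expression_distance(tgt, j, ref, i))
            assert np.isclose(
                d,
                expression_distance(ref, i, tgt, j, genes=half)
                + expression_distance(ref, i, tgt, j, genes=rest))
            # additive across cohorts too
            assert np.isclose(
                d,
                expression_distance(ref, i, tgt, j, cohorts=[1, 2, 3])
                + expression_distance(ref, i, tgt, j, cohorts=[4, 5, 6]))

    def test_missing_gene_rejected(self, norm_pair):
        ref, tgt = norm_pair
        with pytest.raises(KeyError):
            expression_distance(ref, 0, tgt, 0, genes=["nope"])


class TestSpatialMatch:
    def test_self_match_is_identity(self, norm_pair):
        ref, _ = norm_pair
        idx, dist = spatial_match(ref, ref)
        assert np.array_equal(idx, np.arange(ref.n_nuclei))
        assert np.allclose(dist, 0.0)

    def test_translation_invariance(self, norm_pair):
        ref, tgt = norm_pair
        shifted = Atlas(tgt.species, tgt.positions + np.array([50.0, -20, 7]),
                        tgt.E, list(tgt.genes), egg_length=tgt.egg_length)
        idx0, _ = spatial_match(ref, tgt)
        idx1, _ = spatial_match(ref, shifted)
        assert np.array_equal(idx0, idx1)

    def test_identical_geometry_matches_true_counterpart(self, norm_pair):
        # the pair shares nuclei by construction: matching is >= 99% identity
        ref, tgt = norm_pair
        idx, _ = spatial_match(ref, tgt)
        assert (idx == np.arange(ref.n_nuclei)).mean() >= 0.99


class TestLocalBestMatch:
    def test_identical_atlases_all_zero(self, norm_pair):
        ref, _ = norm_pair
        res = local_best_match(ref, ref, k=10)
        assert np.allclose(res.local_best_dist, 0.0)
        assert np.allclose(res.spatial_dist, 0.0)

    def test_local_never_exceeds_spatial(self, norm_pair):
        ref, tgt = norm_pair
        res = local_best_match(ref, tgt, k=30)
        assert np.all(res.local_best_dist <= res.spatial_dist + 1e-12)
        assert np.median(res.local_best_dist) <= np.median(res.spatial_dist)

    def test_matches_brute_force_double_loop(self):
        # 200-nucleus toys: independent exhaustive oracle over the k
        # candidate set, built without KD-trees
        spec = SyntheticSpec(
            seed=31, n_species=2, species_names=("r", "t"),
            egg_length=(400.0, 400.0), max_radius=(80.0, 80.0),
            n_nuclei=(200, 200), shift_field=(0.0, 0.03),
            temporal_offset=(0, 0))
        ref = normalize_expression(generate_atlas(spec, 0)[0])
        tgt = normalize_expression(generate_atlas(spec, 1)[0])
        k = 30
        res = local_best_match(ref, tgt, k=k)

        def scaled(a):
            p = a.positions[-1]
            return (p - p.mean(axis=0)) / a.egg_length

        q, t = scaled(ref), scaled(tgt)
        R = ref.expression_vectors()
        T = tgt.expression_vectors()
        for i in range(ref.n_nuclei):
            order = np.argsort(((t - q[i]) ** 2).sum(axis=1))[:k]
            best = min(float(((R[i] - T[j]) ** 2).sum()) for j in order)
            assert np.isclose(res.local_best_dist[i], best, atol=1e-12)

    def test_small_target_warns_and_uses_all(self, norm_pair):
        spec = SyntheticSpec(
            seed=37, n_species=1, species_names=("mini",),
            egg_length=(400.0,), max_radius=(80.0,), n_nuclei=(20,),
            shift_field=(0.0,), temporal_offset=(0,))
        mini = normalize_expression(generate_atlas(spec, 0)[0])
        with pytest.warns(UserWarning, match="< k"):
            res = local_best_match(mini, mini, k=30)
        assert np.allclose(res.local_best_dist, 0.0)


class TestWeightedDisplacement:
    def test_equidistant_candidates_give_centroid(self):
        pos = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]])
        d = np.full(4, 0.3)
        disp = weighted_displacement(pos, d, np.zeros(3), m=4)
        assert np.allclose(disp, pos.mean(axis=0))

    def test_exact_match_short_circuits(self):
        pos = np.array([[5.0, 0, 0], [9, 9, 9]])
        d = np.array([0.0, 0.4])
        disp = weighted_displacement(pos, d, np.array([1.0, 0, 0]), m=2)
        assert np.allclose(disp, [4.0, 0, 0])

    def test_recovers_known_ap_shift(self, norm_pair):
        # target domains shifted +2% EL: median AP displacement within
        # 0.5% EL of the truth
        ref, tgt = norm_pair
        res = local_best_match(ref, tgt, k=30, m=10)
        ap_shift = np.median(res.displacement[:, 0]) / tgt.egg_length
        assert abs(ap_shift - 0.02) < 0.005


class TestDisplacementField:
    def test_zero_displacement_zero_magnitude(self, norm_pair):
        ref, _ = norm_pair
        res = local_best_match(ref, ref, k=10)
        field = displacement_field(res, ref)
        assert np.allclose(field["magnitude"], 0.0, atol=1e-9)

    def test_pure_ap_shift_direction(self, norm_pair):
        # per-nucleus tangential jitter cancels in aggregate: the mean
        # displacement vector points along +AP with the true magnitude
        ref, tgt = norm_pair
        res = local_best_match(ref, tgt, k=30)
        field = displacement_field(res, ref)
        mean_disp = res.displacement.mean(axis=0)
        angle = np.arctan2(np.linalg.norm(mean_disp[1:]), mean_disp[0])
        assert angle < np.radians(15)
        true_um = 0.02 * tgt.egg_length
        assert abs(np.median(field["ap_component"]) - true_um) < 2.0
        # most individual moves still lean along the AP axis
        assert (np.abs(field["direction"]) < np.pi / 3).mean() > 0.5

    def test_magnitude_rotation_invariant(self, norm_pair):
        ref, tgt = norm_pair
        R = Rotation.from_euler("xyz", [0.3, -0.8, 1.4]).as_matrix()

        def rot(a):
            return Atlas(a.species, a.positions @ R.T, a.E, list(a.genes),
                         egg_length=a.egg_length,
                         dorsal=None if a.dorsal is None else R @ a.dorsal,
                         anterior=None if a.anterior is None else R @ a.anterior)

        res = local_best_match(ref, tgt, k=30)
        res_r = local_best_match(rot(ref), rot(tgt), k=30)
        assert np.allclose(np.linalg.norm(res.displacement, axis=1),
                           np.linalg.norm(res_r.displacement, axis=1),
                           atol=1e-6)


def test_distance_monotone_in_shift_magnitude():
    # synthetic phylogeny: larger domain shifts -> larger median spatial D
    spec = SyntheticSpec(
        seed=41, n_species=4, species_names=("s0", "s1", "s2", "s3"),
        egg_length=(400.0,) * 4, max_radius=(80.0,) * 4, n_nuclei=(800,) * 4,
        shift_field=(0.0, 0.01, 0.02, 0.04), temporal_offset=(0,) * 4)
    atlases = [normalize_expression(generate_atlas(spec, s)[0])
               for s in range(4)]
    meds = []
    for tgt in atlases[1:]:
        res = local_best_match(atlases[0], tgt, k=30)
        meds.append(np.median(res.spatial_dist))
    assert meds == sorted(meds)
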