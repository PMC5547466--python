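"""Signal-to-class mapping, neighbor statistics and distance analyses."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import topomap as tm
from topomap.classify import ClassMap
from topomap.spots import Spot, SpotSet

SPACING = (125.0, 39.5, 39.5)


def _spot(voxels, intensities, channel="g"):
    return Spot(channel, np.asarray(voxels), np.asarray(intensities, float),
                SPACING)


def _flat_map(labels_1d, n_classes=7):
    labels = np.asarray(labels_1d, np.int16).reshape(1, 1, -1)
    return ClassMap(labels, n_classes)


class TestSpotClassDistribution:
    def test_all_voxels_in_one_class(self):
        cmap = _flat_map([2, 2, 2, 2])
        spots = SpotSet("g", [_spot([[0, 0, 0], [0, 0, 1]], [5.0, 7.0])])
        prof = tm.spot_class_distribution(spots, cmap)
        np.testing.assert_allclose(prof.fractions, [0, 1, 0, 0, 0, 0, 0])

    def test_weighted_tally_hand_computed(self):
        cmap = _flat_map([2, 5])
        equal = SpotSet("g", [_spot([[0, 0, 0], [0, 0, 1]], [1.0, 1.0])])
        prof = tm.spot_class_distribution(equal, cmap)
        np.testing.assert_allclose(prof.fractions, [0, 0.5, 0, 0, 0.5, 0, 0])
        skewed = SpotSet("g", [_spot([[0, 0, 0], [0, 0, 1]], [3.0, 1.0])])
        prof = tm.spot_class_distribution(skewed, cmap)
        np.testing.assert_allclose(prof.fractions, [0, 0.75, 0, 0, 0.25, 0, 0])
        counted = tm.spot_class_distribution(skewed, cmap, weighting="count")
        np.testing.assert_allclose(counted.fractions, [0, 0.5, 0, 0, 0.5, 0, 0])

    def test_spots_proportional_to_dapi_recover_profile(self):
        """Spots sampled uniformly over the mask (hence proportionally to
        the DAPI class fractions) reproduce the DAPI profile within 3
        binomial standard errors per class."""
        profs, fracs, n_tot = [], [], 0
        for seed in range(5):
            cfg = tm.PhantomConfig(seed=300 + seed, spot_class_probs=None)
            r = tm.generate_phantom(cfg)
            ss = tm.spots_from_truth(r.truth, "ch1")
            profs.append(
                tm.spot_class_distribution(
                    ss, r.truth.class_map, weighting="count"
                ).fractions
            )
            fracs.append(tm.truth_class_fractions(r.truth).fractions)
            n_tot += len(ss)
        s, d = np.mean(profs, axis=0), np.mean(fracs, axis=0)
        se = np.sqrt(d * (1 - d) / n_tot)
        assert np.all(np.abs(s - d) < 3 * se)

    def test_empty_spot_set_raises(self):
        with pytest.raises(tm.EmptyProfileError):
            tm.spot_class_distribution(SpotSet("g"), _flat_map([1, 2]))


class TestEnrichment:
    def test_identical_profiles_give_zero(self):
        p = tm.ClassProfile(np.full(7, 1 / 7), "g")
        np.testing.assert_allclose(
            tm.enrichment_profile(p, p).points, np.zeros(7), atol=1e-12
        )

    def test_hand_computed_difference(self):
        d = tm.ClassProfile([0.5, 0.5], "dapi")
        s = tm.ClassProfile([0.8, 0.2], "g")
        np.testing.assert_allclose(
            tm.enrichment_profile(s, d).points, [30.0, -30.0]
        )

    def test_sums_to_zero(self, default_phantom):
        d = tm.truth_class_fractions(default_phantom.truth)
        ss = tm.spots_from_truth(default_phantom.truth, "ch1")
        s = tm.spot_class_distribution(
            ss, default_phantom.truth.class_map, weighting="count"
        )
        assert tm.enrichment_profile(s, d).points.sum() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_mismatched_k_raises(self):
        with pytest.raises(ValueError):
            tm.enrichment_profile(
                tm.ClassProfile([1.0]), tm.ClassProfile([0.5, 0.5])
            )


class TestNeighborMatrix:
    def test_homogeneous_map_is_identity_row(self):
        labels = np.full((4, 4, 4), 3, np.int16)
        nb = tm.neighbor_class_matrix(
            ClassMap(labels, 7), tm.NucleusMask(np.ones((4, 4, 4), bool))
        )
        expected = np.zeros(7)
        expected[2] = 1.0
        np.testing.assert_allclose(nb.matrix[2], expected)
        assert np.all(np.isnan(nb.matrix[0]))  # absent class rows undefined

    def test_checkerboard_alternates(self):
        zi, yi, xi = np.indices((4, 6, 6))
        labels = ((zi + yi + xi) % 2 + 1).astype(np.int16)
        nb = tm.neighbor_class_matrix(
            ClassMap(labels, 2), tm.NucleusMask(np.ones((4, 6, 6), bool))
        )
        np.testing.assert_allclose(nb.matrix, [[0, 1], [1, 0]])

    def test_rows_sum_to_one(self, default_phantom):
        nb = tm.neighbor_class_matrix(
            default_phantom.truth.class_map, default_phantom.truth.mask
        )
        present = ~np.isnan(nb.matrix[:, 0])
        np.testing.assert_allclose(
            nb.matrix[present].sum(axis=1), 1.0, atol=1e-12
        )

    def test_layered_phantom_diagonally_dominant(self, single_cdc_phantom):
        """Most neighbors share the voxel's own class; the off-diagonal
        mass concentrates on the adjacent classes."""
        nb = tm.neighbor_class_matrix(
            single_cdc_phantom.truth.class_map, single_cdc_phantom.truth.mask
        )
        m = nb.matrix
        for k in range(7):
            if np.isnan(m[k, 0]):
                continue
            assert np.argmax(m[k]) == k
            off = m[k].copy()
            off[k] = 0.0
            adjacent = sum(
                off[j] for j in (k - 1, k + 1) if 0 <= j < 7
            )
            assert adjacent == pytest.approx(off.sum(), abs=1e-9)

    def test_nearest_mode_two_classes(self):
        labels = np.ones((2, 2, 4), np.int16)
        labels[..., 2:] = 2
        nb = tm.neighbor_class_matrix(
            ClassMap(labels, 2), tm.NucleusMask(np.ones((2, 2, 4), bool)),
            mode="nearest",
        )
        np.testing.assert_allclose(nb.matrix, [[0, 1], [1, 0]])


class TestMinClassDistances:
    def test_face_adjacent_single_step(self):
        labels = np.zeros((1, 1, 4), np.int16)
        labels[0, 0, :] = [2, 3, 3, 3]
        table = tm.min_class_distances(ClassMap(labels, 7), 2, SPACING)
        assert table.mean_nm[2] == pytest.approx(39.5)
        assert table.mean_nm[1] == pytest.approx(0.0)
        assert np.isnan(table.mean_nm[6])  # class 7 absent -> undefined

    def test_matches_brute_force_oracle(self):
        """Anisotropic EDT equals all-pairs minimal distances on random
        small maps."""
        rng = np.random.default_rng(2)
        for _ in range(3):
            labels = rng.integers(1, 5, size=(9, 12, 14)).astype(np.int16)
            cmap = ClassMap(labels, 4)
            table = tm.min_class_distances(cmap, 2, SPACING)
            src = np.argwhere(labels == 2) * np.array(SPACING)
            for j in range(1, 5):
                tgt = np.argwhere(labels == j) * np.array(SPACING)
                expected = cdist(src, tgt).min(axis=1).mean()
                assert table.mean_nm[j - 1] == pytest.approx(
                    expected, abs=1e-6
                )

    def test_single_cdc_distances_increase_with_class(self, single_cdc_phantom):
        """Mean distance from the decondensed outer shell (class 2) to
        deeper classes grows strictly with compaction class; reaching the
        core costs a few hundred nanometres."""
        table = tm.min_class_distances(
            single_cdc_phantom.truth.class_map, 2, (50.0, 39.5, 39.5)
        )
        means = table.mean_nm
        assert np.all(np.diff(means[1:]) > 0)
        # five ~80 nm shells separate class 2 from the class-7 core
        assert 200.0 < means[6] < 800.0

    def test_absent_source_class_raises(self):
        labels = np.ones((2, 2, 2), np.int16)
        with pytest.raises(ValueError, match="absent"):
            tm.min_class_distances(ClassMap(labels, 7), 5, SPACING)


class TestCentroidDistances:
    def test_single_pair(self):
        iso = (100.0, 100.0, 100.0)
        a = SpotSet("g", [Spot("g", [[0, 0, 0]], [1.0], iso)])
        b = SpotSet("r", [Spot("r", [[0, 0, 4]], [1.0], iso)])
        np.testing.assert_allclose(tm.nn_centroid_distances(a, b), [400.0])

    def test_coincident_centroids(self):
        a = SpotSet("g", [_spot([[1, 1, 1]], [1.0])])
        b = SpotSet("r", [_spot([[1, 1, 1]], [1.0], "r")])
        np.testing.assert_allclose(tm.nn_centroid_distances(a, b), [0.0])

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(4)
        ia = rng.integers(0, 20, size=(6, 3))
        ib = rng.integers(0, 20, size=(5, 3))
        a = SpotSet("g", [_spot([i], [1.0]) for i in ia])
        b = SpotSet("r", [_spot([i], [1.0], "r") for i in ib])
        got = tm.nn_centroid_distances(a, b)
        expected = cdist(
            ia * np.array(SPACING), ib * np.array(SPACING)
        ).min(axis=1)
        np.testing.assert_allclose(got, expected)

    def test_empty_sets_raise(self):
        a = SpotSet("g", [_spot([[0, 0, 0]], [1.0])])
        with pytest.raises(ValueError):
            tm.nn_centroid_distances(a, SpotSet("r"))


class TestReplicatePairs:
    @staticmethod
    def _set_from_x_nm(xs_nm):
        # 1 nm voxels along x make centroid positions explicit
        return SpotSet(
            "g",
            [Spot("g", [[0, 0, int(x)]], [1.0], (1.0, 1.0, 1.0))
             for x in xs_nm],
        )

    def test_pair_below_cutoff(self):
        ss = self._set_from_x_nm([0, 300])
        np.testing.assert_allclose(tm.replicate_pair_distances(ss), [300.0])

    def test_pair_above_cutoff_excluded(self):
        ss = self._set_from_x_nm([0, 800])
        assert len(tm.replicate_pair_distances(ss)) == 0

    def test_mutual_pairs_enumerated(self):
        """Two mutual pairs at 200 and 450 nm, cross distances > 1 um."""
        ss = self._set_from_x_nm([0, 200, 5000, 5450])
        got = sorted(tm.replicate_pair_distances(ss))
        np.testing.assert_allclose(got, [200.0, 450.0])


def test_expected_site_count():
    assert tm.expected_site_count([2] * 6) == 12  # six diploid loci
    assert tm.expected_site_count([2] * 2) == 4   # two diploid loci
    assert tm.expected_site_count([]) == 0
    with pytest.raises(ValueError):
        tm.expected_site_count([2, -1])


def test_extended_fiber_length():
    assert tm.extended_fiber_length(10.0) == pytest.approx(500.0)
    assert tm.extended_fiber_length(0.2) == pytest.approx(10.0)
    assert tm.extended_fiber_length(12.0) == pytest.approx(600.0)
    with pytest.raises(ValueError):
        tm.extended_fiber_length(-1.0)
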