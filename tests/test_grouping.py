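"""Spectral grouping by k-means and LMLSD key-band selection."""

import numpy as np
import pytest

from pssahcs import (
    ConstantBandError,
    HyperspectralCube,
    band_distance,
    generate_cube,
    group_bands_kmeans,
    lmlsd_score,
    select_key_bands,
    tea_like_spec,
)
from pssahcs.blocking import make_plan
from pssahcs.grouping import SpectralGrouping
from conftest import make_cube
from oracles import band_distance_oracle, lmlsd_oracle


class TestBandDistance:
    def test_identical_images_have_zero_distance(self):
        cube = make_cube(np.random.default_rng(0), a=6, b=6, c=2)
        assert band_distance(cube, 0, cube.band_float(0)) == 0.0

    def test_unit_offset_closed_form(self):
        """Images differing by 1 at every pixel of a 128x256 band are
        sqrt(128*256) ~ 181.019 apart."""
        data = np.zeros((128, 256, 1), dtype=np.uint16)
        cube = HyperspectralCube(data=data, bit_depth=12)
        centroid = np.ones((128, 256))
        assert band_distance(cube, 0, centroid) == pytest.approx(
            np.sqrt(128 * 256), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_literal_transcription(self, seed):
        rng = np.random.default_rng(seed)
        cube = make_cube(rng, a=9, b=11, c=1)
        centroid = rng.normal(2000, 300, size=(9, 11))
        got = band_distance(cube, 0, centroid)
        want = band_distance_oracle(cube.band_float(0), centroid)
        assert got == pytest.approx(want, rel=1e-9)

    def test_shape_mismatch_raises(self):
        cube = make_cube(np.random.default_rng(1), a=4, b=4, c=1)
        with pytest.raises(ValueError, match="shape"):
            band_distance(cube, 0, np.zeros((3, 3)))


class TestKmeansGrouping:
    def test_duplicate_templates_recovered_exactly(self):
        """Bands that are exact copies of two template images cluster into
        the two duplicate sets (zero within-cluster distance)."""
        rng = np.random.default_rng(2)
        t1 = rng.integers(0, 4096, size=(8, 8)).astype(np.uint16)
        t2 = rng.integers(0, 4096, size=(8, 8)).astype(np.uint16)
        data = np.stack([t1, t1, t1, t2, t2], axis=2)
        cube = HyperspectralCube(data=data, bit_depth=12)
        g = group_bands_kmeans(cube, k=2, seed=0)
        assert g.groups == [[0, 1, 2], [3, 4]]

    def test_k_equal_bands_gives_singletons(self):
        cube = make_cube(np.random.default_rng(3), a=6, b=6, c=5)
        g = group_bands_kmeans(cube, k=5, seed=0)
        assert g.groups == [[z] for z in range(5)]

    @pytest.mark.parametrize("k", [3, "auto"])
    def test_planted_partition_recovered(self, k, small_tea):
        cube, truth = small_tea
        g = group_bands_kmeans(cube, k=k, seed=1)
        assert g.groups == truth.grouping.groups

    def test_grouping_is_partition_even_without_contiguity(self):
        cube, _ = generate_cube(tea_like_spec(a=32, b=32, c=10, seed=9))
        g = group_bands_kmeans(cube, k=4, seed=5, contiguity=False)
        seen = sorted(z for grp in g.groups for z in grp)
        assert seen == list(range(10))

    def test_objective_nonincreasing_across_iterations(self):
        """Lloyd iterations never increase the within-cluster sum of
        squared distances."""
        from pssahcs.grouping import _kmeanspp_init, _lloyd

        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(mu, 1.0, size=(6, 20)) for mu in (0, 5, 10)])
        centroids = _kmeanspp_init(X, 3, rng)

        objectives = []
        cents = centroids.copy()
        labels = None
        for _ in range(10):
            d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2, axis=1)
            objectives.append(float(d2[np.arange(len(X)), new_labels].sum()))
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(3):
                members = X[labels == j]
                if len(members):
                    cents[j] = members.mean(axis=0)
        assert all(b <= a + 1e-9 for a, b in zip(objectives, objectives[1:]))
        final_labels, _ = _lloyd(X, centroids.copy(), 300)
        d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        assert float(
            d2[np.arange(len(X)), final_labels].sum()
        ) <= objectives[0] + 1e-9

    def test_k_out_of_range_raises(self):
        cube = make_cube(np.random.default_rng(4), c=3)
        with pytest.raises(ValueError, match="k must be"):
            group_bands_kmeans(cube, k=4, seed=0)

    def test_agrees_with_reference_kmeans_on_planted_preset(self, small_tea):
        """Independent cross-check: scikit-learn's k-means over the same
        vectorized band images finds the identical partition of the
        planted preset."""
        from sklearn.cluster import KMeans

        cube, truth = small_tea
        X = cube.data.reshape(-1, cube.bands).T.astype(float)
        labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(X)
        ref_groups = sorted(
            (sorted(np.nonzero(labels == j)[0].tolist()) for j in set(labels)),
            key=lambda g: g[0],
        )
        ours = group_bands_kmeans(cube, k=3, seed=1)
        assert ours.groups == ref_groups == truth.grouping.groups


class TestLmlsd:
    def test_matches_literal_transcription_single_interval(self):
        """16x16 i.i.d.-noise band, 2x2 tiling of 8x8 sub-blocks,
        n_intervals=1: R equals the all-blocks mean/std ratio."""
        rng = np.random.default_rng(5)
        data = rng.integers(500, 3500, size=(16, 16, 1)).astype(np.uint16)
        cube = HyperspectralCube(data=data, bit_depth=12)
        plan = make_plan(16, 16, 8)
        score = lmlsd_score(cube, 0, plan, n_intervals=1)
        blocks = [np.asarray(b) for b in plan.to_blocks(cube.band_float(0))]
        r, m_mean, d_mean = lmlsd_oracle(blocks, 1)
        assert score.R == pytest.approx(r, rel=1e-9)
        assert score.M_mean == pytest.approx(m_mean, rel=1e-9)
        assert score.D_mean == pytest.approx(d_mean, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_literal_transcription_ten_intervals(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(100, 4000, size=(24, 24, 1)).astype(np.uint16)
        cube = HyperspectralCube(data=data, bit_depth=12)
        plan = make_plan(24, 24, 6)
        score = lmlsd_score(cube, 0, plan, n_intervals=10)
        blocks = [np.asarray(b) for b in plan.to_blocks(cube.band_float(0))]
        r, _, _ = lmlsd_oracle(blocks, 10)
        assert score.R == pytest.approx(r, rel=1e-9)

    @pytest.mark.parametrize("sigma", [5.0, 20.0, 50.0])
    def test_noisier_copy_of_same_band_scores_lower(self, sigma):
        """Adding i.i.d. noise to a fixed near-homogeneous band lowers R.

        LMLSD estimates the noise floor from the flattest sub-blocks, so
        the base band is kept nearly homogeneous (5 DN texture, the flat
        imaging-stage background the estimator keys on) and small noise
        then dominates every sub-block's standard deviation."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = 2000 + 5 * np.random.default_rng(99).normal(size=(64, 64))
            noisy = base + rng.normal(0.0, sigma, size=(64, 64))
            data = np.stack(
                [np.clip(np.round(base), 0, 4095),
                 np.clip(np.round(noisy), 0, 4095)],
                axis=2,
            ).astype(np.uint16)
            cube = HyperspectralCube(data=data, bit_depth=12)
            plan = make_plan(64, 64, 8)
            clean_r = lmlsd_score(cube, 0, plan).R
            noisy_r = lmlsd_score(cube, 1, plan).R
            assert clean_r > noisy_r

    def test_all_constant_blocks_raise(self):
        data = np.full((8, 8, 1), 100, dtype=np.uint16)
        cube = HyperspectralCube(data=data, bit_depth=12)
        with pytest.raises(ConstantBandError):
            lmlsd_score(cube, 0, make_plan(8, 8, 4))

    def test_modal_tie_breaks_to_lower_interval(self):
        """Two equally populated std intervals: the lower one wins."""
        blocks = np.zeros((8, 8, 1), dtype=np.uint16)
        # two 4x4 sub-blocks with low std, two with high std
        blocks[0:4, 0:4, 0] = np.tile([100, 102], (4, 2))
        blocks[0:4, 4:8, 0] = np.tile([100, 102], (4, 2))
        blocks[4:8, 0:4, 0] = np.tile([100, 300], (4, 2))
        blocks[4:8, 4:8, 0] = np.tile([100, 300], (4, 2))
        cube = HyperspectralCube(data=blocks, bit_depth=12)
        score = lmlsd_score(cube, 0, make_plan(8, 8, 4), n_intervals=2)
        assert score.modal_interval[0] == pytest.approx(score.block_stds.min())


class TestKeyBandSelection:
    def test_singleton_group_takes_its_band(self, small_tea):
        cube, _ = small_tea
        grouping = SpectralGrouping(
            groups=[[z] for z in range(cube.bands)],
            key_bands=[None] * cube.bands,
            k=cube.bands,
            seed=0,
        )
        g = select_key_bands(cube, grouping, make_plan(64, 64, 8))
        assert g.key_bands == list(range(cube.bands))

    def test_noise_free_band_wins_group(self):
        """In a 5-band group where one band is noise-free, that band is
        selected as key over 20 seeds."""
        wins = 0
        for seed in range(20):
            cube, truth = generate_cube(
                tea_like_spec(a=64, b=64, c=5, seed=seed, n_groups=1,
                              noise_std=60.0)
            )
            # preset marks bands 0,1,3,4 noisy; band 2 is the clean one
            g = select_key_bands(cube, truth.grouping, make_plan(64, 64, 8))
            wins += g.key_bands[0] == 2
        assert wins >= 18

    def test_tie_breaks_to_smaller_band_index(self):
        """Two identical bands tie in R; the smaller index is chosen."""
        rng = np.random.default_rng(8)
        band = rng.integers(100, 4000, size=(16, 16)).astype(np.uint16)
        data = np.stack([band, band], axis=2)
        cube = HyperspectralCube(data=data, bit_depth=12)
        grouping = SpectralGrouping(
            groups=[[0, 1]], key_bands=[None], k=1, seed=0
        )
        g = select_key_bands(cube, grouping, make_plan(16, 16, 8))
        assert g.key_bands == [0]
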