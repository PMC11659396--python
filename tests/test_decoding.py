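import numpy as np
import pytest

from twdfc_parcel.decoding import (
    bh_adjust,
    decode_clusters,
    inverse_distance_map,
    load_default_stoplist,
    sa_permutation_pvalue,
    screen_terms,
    track_weighted_scalar_map,
    variogram_surrogates,
)
from twdfc_parcel.imaging import BundleMask, Tractogram, VolumeGrid, streamline_voxels
from twdfc_parcel.phantom import generate_term_library


class TestInverseDistanceMap:
    def test_centroid_voxel_scores_one(self, unit_grid):
        m = inverse_distance_map(np.array([2.0, 3.0, 4.0]), unit_grid)
        assert m[2, 3, 4] == pytest.approx(1.0)

    def test_one_mm_away_scores_half(self, unit_grid):
        m = inverse_distance_map(np.array([2.0, 3.0, 4.0]), unit_grid)
        assert m[3, 3, 4] == pytest.approx(0.5)

    def test_strictly_decreasing_along_ray(self, unit_grid):
        m = inverse_distance_map(np.array([0.0, 0.0, 0.0]), unit_grid)
        ray = m[np.arange(8), 0, 0]
        assert np.all(np.diff(ray) < 0)

    def test_masked_outside_is_zero(self, unit_grid):
        mask = np.zeros(unit_grid.shape, bool)
        mask[0, 0, 0] = True
        m = inverse_distance_map(
            np.array([0.0, 0.0, 0.0]), unit_grid, BundleMask(mask, unit_grid)
        )
        assert m[0, 0, 0] > 0 and m[1:].max() == 0

    def test_non_finite_centroid_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            inverse_distance_map(np.array([np.nan, 0, 0]), unit_grid)


class TestTrackWeightedScalarMap:
    def test_constant_scalar_paints_constant(self, unit_grid):
        tract = Tractogram([np.array([[1.0, 1, 1], [5.0, 5, 5]])], unit_grid)
        out = track_weighted_scalar_map(np.full(unit_grid.shape, 3.3), tract, unit_grid)
        finite = out[np.isfinite(out)]
        assert finite.size and np.allclose(finite, 3.3)

    def test_two_voxel_crossing_with_equal_samples(self, unit_grid):
        scalar = np.zeros(unit_grid.shape)
        scalar[0, 0, 0] = 1.0
        scalar[1, 0, 0] = 3.0
        # arc samples at -0.25, 0.25, 0.75, 1.25: two per voxel
        tract = Tractogram([np.array([[-0.25, 0, 0], [1.25, 0, 0]])], unit_grid)
        out = track_weighted_scalar_map(scalar, tract, unit_grid)
        assert out[0, 0, 0] == pytest.approx(2.0)
        assert out[1, 0, 0] == pytest.approx(2.0)

    def test_untraversed_voxels_are_missing(self, unit_grid):
        tract = Tractogram([np.array([[0.0, 0, 0], [2.0, 0, 0]])], unit_grid)
        out = track_weighted_scalar_map(np.ones(unit_grid.shape), tract, unit_grid)
        assert np.isnan(out[7, 7, 7])

    def test_matches_brute_force_oracle(self, unit_grid):
        from twdfc_parcel.imaging import resample_polyline, world_to_voxel

        rng = np.random.default_rng(0)
        scalar = rng.standard_normal(unit_grid.shape)
        sls = [0.5 + rng.uniform(0, 6.5, size=(4, 3)) for _ in range(12)]
        tract = Tractogram(sls, unit_grid)
        got = track_weighted_scalar_map(scalar, tract, unit_grid)
        # oracle: per-streamline weight then per-voxel loop
        sums = np.zeros(unit_grid.shape)
        counts = np.zeros(unit_grid.shape)
        for sl in sls:
            pts = resample_polyline(sl, 0.5)
            idx = world_to_voxel(pts, unit_grid)
            idx = idx[np.all((idx >= 0) & (idx < np.array(unit_grid.shape)), axis=1)]
            w = np.mean([scalar[tuple(i)] for i in idx])
            for v in map(tuple, streamline_voxels(sl, unit_grid)):
                sums[v] += w
                counts[v] += 1
        exp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        assert np.allclose(got, exp, atol=1e-10, equal_nan=True)

    def test_empty_tractogram_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            track_weighted_scalar_map(
                np.ones(unit_grid.shape), Tractogram([], unit_grid), unit_grid
            )


class TestScreenTerms:
    def _setup(self, unit_grid):
        rng = np.random.default_rng(0)
        gm = BundleMask(np.ones(unit_grid.shape, bool), unit_grid)
        dmap = inverse_distance_map(np.array([3.0, 3.0, 3.0]), unit_grid)
        library = {f"term {i}": rng.standard_normal(unit_grid.shape) for i in range(30)}
        return gm, dmap, library

    def test_identical_term_ranked_first(self, unit_grid):
        gm, dmap, library = self._setup(unit_grid)
        library["the match"] = dmap.copy()
        out = screen_terms({1: dmap}, library, gm, top_n=5, stoplist=[])
        assert out[0] == "the match"

    def test_duplicates_across_clusters_appear_once(self, unit_grid):
        gm, dmap, library = self._setup(unit_grid)
        out = screen_terms({1: dmap, 2: dmap}, library, gm, top_n=10, stoplist=[])
        assert len(out) == len(set(out))

    def test_stoplist_removes_substring_matches(self, unit_grid):
        gm, dmap, library = self._setup(unit_grid)
        library["Left Cortex"] = dmap.copy()
        out = screen_terms(
            {1: dmap}, library, gm, top_n=5, stoplist=["left", "cortex"]
        )
        assert "Left Cortex" not in out

    def test_default_stoplist_loads(self):
        stop = load_default_stoplist()
        assert "left" in stop and "cortex" in stop

    def test_empty_library_rejected(self, unit_grid):
        gm, dmap, _ = self._setup(unit_grid)
        with pytest.raises(ValueError):
            screen_terms({1: dmap}, {}, gm)


def _smooth_field(shape, rng, fwhm_vox=2.5):
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), fwhm_vox / 2.3548)
    return (f - f.mean()) / f.std()


class TestVariogramSurrogates:
    def _coords_values(self, seed=0, n=12):
        grid = VolumeGrid((n, n, 4), np.eye(4))
        rng = np.random.default_rng(seed)
        field = _smooth_field(grid.shape, rng)
        vox = np.argwhere(np.ones(grid.shape, bool))
        return grid.voxel_centers_mm(vox), field.ravel()

    def test_value_multiset_preserved(self):
        coords, y = self._coords_values()
        surr = variogram_surrogates(y, coords, n=5, seed=1)
        for s in surr:
            assert np.allclose(np.sort(s), np.sort(y))

    def test_deterministic_given_seed(self):
        coords, y = self._coords_values()
        a = variogram_surrogates(y, coords, n=4, seed=2)
        b = variogram_surrogates(y, coords, n=4, seed=2)
        assert np.array_equal(a, b)

    def test_variogram_matched_within_tolerance(self):
        from scipy.spatial.distance import pdist

        coords, y = self._coords_values(seed=3)
        surr = variogram_surrogates(y, coords, n=20, seed=4)
        iu, ju = np.triu_indices(len(y), k=1)
        rng = np.random.default_rng(0)
        keep = rng.choice(iu.size, 20000, replace=False)
        iu, ju = iu[keep], ju[keep]
        d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        dmax = np.quantile(d, 0.7)
        sel = d <= dmax
        iu, ju, d = iu[sel], ju[sel], d[sel]
        bins = np.minimum((d / dmax * 10).astype(int), 9)

        cnt = np.bincount(bins, minlength=10)

        def vario(v):
            dif = (v[iu] - v[ju]) ** 2
            return (0.5 * np.bincount(bins, dif, 10) / np.maximum(cnt, 1))[cnt > 0]

        g_emp = vario(y)
        g_sur = np.mean([vario(s) for s in surr], axis=0)
        rel_err = np.abs(g_sur - g_emp) / g_emp
        assert rel_err.mean() < 0.15

    def test_constant_map_rejected(self):
        coords, y = self._coords_values()
        with pytest.raises(ValueError):
            variogram_surrogates(np.ones_like(y), coords, n=2, seed=0)


class TestPermutationPvalue:
    def test_all_exceeded_gives_minimum_p(self):
        surr = np.random.default_rng(0).uniform(-0.1, 0.1, 1000)
        assert sa_permutation_pvalue(0.5, surr) == pytest.approx(1 / 1001)

    def test_null_observation_gives_p_near_one(self):
        surr = np.random.default_rng(1).standard_normal(500) * 0.3
        assert sa_permutation_pvalue(0.0, surr) == pytest.approx(1.0)

    def test_hand_counted_six_surrogates(self):
        surr = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -0.3])
        assert sa_permutation_pvalue(0.25, surr) == pytest.approx(3 / 7)


def brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for rank_i, idx in enumerate(order):
        q[idx] = min(
            min(m * p[j] / (list(order).index(j) + 1) for j in order[rank_i:]), 1.0
        )
    return q


class TestBhAdjust:
    def test_hand_example_all_equal_after_adjustment(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04, atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.001, 1.0, size=rng.integers(3, 20))
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.001, 1.0, 15)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestDecodeClusters:
    @pytest.fixture(scope="class")
    def decode_setup(self, small_spec, small_subject):
        tract, _, truth = small_subject
        grid = tract.reference_grid
        library, gm = generate_term_library(truth, grid, 3, 10, 6.0, seed=1)
        # anti-term: negated proximity to cluster 1
        idm = inverse_distance_map(truth.cluster_centroids_mm[0], grid)
        library["anti term"] = -(idm - idm.mean()) / idm.std()
        bundle = BundleMask(truth.bundle_label_per_voxel > 0, grid)
        df = decode_clusters(
            truth.cluster_centroids_mm,
            library,
            tract,
            gm,
            bundle,
            grid,
            n_surrogates=120,
            seed=5,
            screen=False,
        )
        return df, truth

    def test_signal_terms_peak_at_their_cluster(self, decode_setup):
        df, truth = decode_setup
        for i in range(3):
            rows = df[df["term"] == f"signal term {i}"]
            assert rows.loc[rows["r"].idxmax(), "cluster"] == i + 1
            # the target-cluster correlation clears the SA-preserving null
            assert rows.loc[rows["r"].idxmax(), "p_perm"] < 0.1

    def test_anti_constructed_term_is_negative(self, decode_setup):
        df, _ = decode_setup
        r = df.query("term == 'anti term' and cluster == 1")["r"].item()
        assert r < 0

    def test_r2_is_squared_r(self, decode_setup):
        df, _ = decode_setup
        assert np.allclose(df["r2"], df["r"] ** 2, atol=1e-12)

    def test_term_order_invariance(self, small_subject):
        tract, _, truth = small_subject
        grid = tract.reference_grid
        library, gm = generate_term_library(truth, grid, 1, 4, 6.0, seed=2)
        bundle = BundleMask(truth.bundle_label_per_voxel > 0, grid)
        kw = dict(
            tractogram=tract, gm_mask=gm, bundle_mask=bundle, grid=grid,
            n_surrogates=60, seed=3, screen=False,
        )
        a = decode_clusters(truth.cluster_centroids_mm, library, **kw)
        rev = dict(reversed(list(library.items())))
        b = decode_clusters(truth.cluster_centroids_mm, rev, **kw)
        a = a.sort_values(["cluster", "term"]).reset_index(drop=True)
        b = b.sort_values(["cluster", "term"]).reset_index(drop=True)
        assert np.allclose(a["r"], b["r"])
        assert np.allclose(a["p_perm"], b["p_perm"])
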