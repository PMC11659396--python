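import numpy as np
import pytest

from twdfc_parcel.imaging import BoldSeries, BundleMask, Tractogram, VolumeGrid
from twdfc_parcel.twdfc import (
    WindowSpec,
    compute_static_tw,
    compute_twdfc,
    concatenate_runs,
    endpoint_series,
    streamline_voxels,
    window_length_from_seconds,
    windowed_pearson,
)


class TestWindowedPearson:
    def test_identical_series_give_one(self):
        x = np.array([1.0, 2, 1, 3, 2, 4])
        assert np.allclose(windowed_pearson(x, x, WindowSpec(3)), 1.0)

    def test_negated_series_give_minus_one(self):
        x = np.array([1.0, 2, 1, 3, 2, 4])
        assert np.allclose(windowed_pearson(x, -x, WindowSpec(3)), -1.0)

    def test_hand_computed_example(self):
        r = windowed_pearson([1, 2, 3, 4], [1, 3, 2, 4], WindowSpec(3))
        assert np.allclose(r, [0.5, 0.5], atol=1e-12)

    def test_zero_variance_window_flagged_missing(self):
        r = windowed_pearson([1.0, 1, 1, 2], [0.0, 1, 2, 3], WindowSpec(3))
        assert np.isnan(r[0]) and np.isfinite(r[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            windowed_pearson([1, 2, 3], [1, 2, 3, 4], WindowSpec(3))

    def test_matches_corrcoef_on_random_series(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 50))
        w = WindowSpec(8, stride_tp=3)
        got = windowed_pearson(x, y, w)
        exp = [
            np.corrcoef(x[s : s + 8], y[s : s + 8])[0, 1]
            for s in range(0, 50 - 8 + 1, 3)
        ]
        assert np.allclose(got, exp, atol=1e-12)


class TestWindowLength:
    @pytest.mark.parametrize(
        "target,tr,expected", [(40.0, 1.4, 29), (40.0, 1.0, 40), (39.6, 0.72, 55)]
    )
    def test_published_window_lengths(self, target, tr, expected):
        assert window_length_from_seconds(target, tr) == expected

    def test_invalid_durations(self):
        with pytest.raises(ValueError):
            window_length_from_seconds(0, 1.0)


def _single_streamline_setup(T=30, seed=0):
    grid = VolumeGrid((6, 6, 6), np.eye(4))
    rng = np.random.default_rng(seed)
    bold = BoldSeries(rng.standard_normal(grid.shape + (T,)), 1.0, grid)
    sl = np.array([[1.0, 1.0, 1.0], [4.0, 1.0, 1.0]])
    return grid, bold, Tractogram([sl], grid)


class TestEndpointSeries:
    def test_exact_center_returns_voxel_series(self):
        grid, bold, tract = _single_streamline_setup()
        X, Y, valid = endpoint_series(tract, bold)
        assert valid[0]
        assert np.array_equal(X[0], bold.data[1, 1, 1])
        assert np.array_equal(Y[0], bold.data[4, 1, 1])

    def test_near_center_snaps_to_nearest_voxel(self):
        grid, bold, _ = _single_streamline_setup()
        tract = Tractogram([np.array([[1.4, 1.0, 1.0], [4.0, 1.0, 1.0]])], grid)
        X, _, valid = endpoint_series(tract, bold)
        assert valid[0] and np.array_equal(X[0], bold.data[1, 1, 1])

    def test_endpoints_outside_mask_flag_invalid(self):
        grid, bold, tract = _single_streamline_setup()
        mask = BundleMask(np.zeros(grid.shape, bool), grid)
        _, _, valid = endpoint_series(tract, bold, mask)
        assert not valid[0]

    def test_empty_tractogram_rejected(self):
        grid, bold, _ = _single_streamline_setup()
        with pytest.raises(Exception):
            endpoint_series(Tractogram([], grid), bold)


def brute_force_twdfc(bold, tract, window):
    """Per-voxel loop oracle using np.corrcoef over explicit windows."""
    X, Y, valid = endpoint_series(tract, bold)
    T = bold.n_timepoints
    L, s = window.length_tp, window.stride_tp
    starts = range(0, T - L + 1, s)
    out = np.full(bold.grid.shape + (len(starts),), np.nan)
    for ix in np.ndindex(bold.grid.shape):
        rs = []
        for j in range(len(tract)):
            if not valid[j]:
                continue
            vox = set(map(tuple, streamline_voxels(tract.streamlines[j], bold.grid)))
            if ix not in vox:
                continue
            rs.append(
                [np.corrcoef(X[j, w : w + L], Y[j, w : w + L])[0, 1] for w in starts]
            )
        if rs:
            out[ix] = np.nanmean(np.array(rs), axis=0)
    return out


def brute_force_static(bold, tract):
    X, Y, valid = endpoint_series(tract, bold)
    out = np.full(bold.grid.shape + (bold.n_timepoints,), np.nan)
    for ix in np.ndindex(bold.grid.shape):
        series = []
        for j in range(len(tract)):
            if not valid[j]:
                continue
            vox = set(map(tuple, streamline_voxels(tract.streamlines[j], bold.grid)))
            if ix in vox:
                series.append(0.5 * (X[j] + Y[j]))
        if series:
            out[ix] = np.mean(series, axis=0)
    return out


def random_instance(seed, n_streamlines=10, T=40):
    grid = VolumeGrid((6, 6, 6), np.eye(4))
    rng = np.random.default_rng(seed)
    bold = BoldSeries(rng.standard_normal(grid.shape + (T,)), 1.0, grid)
    sls = [0.5 + rng.uniform(0, 5, size=(4, 3)) for _ in range(n_streamlines)]
    return bold, Tractogram(sls, grid)


class TestComputeTwdfc:
    def test_single_streamline_paints_its_windowed_r(self):
        grid, bold, tract = _single_streamline_setup()
        w = WindowSpec(8)
        X, Y, _ = endpoint_series(tract, bold)
        expected = windowed_pearson(X[0], Y[0], w)
        series = compute_twdfc(bold, tract, w)
        vox = streamline_voxels(tract.streamlines[0], grid)
        for v in vox:
            assert np.allclose(series.data[tuple(v)], expected, atol=1e-12)

    def test_two_streamlines_average_on_shared_voxel(self):
        grid = VolumeGrid((6, 6, 6), np.eye(4))
        rng = np.random.default_rng(1)
        data = rng.standard_normal(grid.shape + (20,))
        bold = BoldSeries(data, 1.0, grid)
        sl1 = np.array([[1.0, 2, 2], [4.0, 2, 2]])
        sl2 = np.array([[2.0, 1, 2], [2.0, 4, 2]])  # crosses sl1 at (2,2,2)
        tract = Tractogram([sl1, sl2], grid)
        w = WindowSpec(6)
        X, Y, _ = endpoint_series(tract, bold)
        r1 = windowed_pearson(X[0], Y[0], w)
        r2 = windowed_pearson(X[1], Y[1], w)
        series = compute_twdfc(bold, tract, w)
        assert np.allclose(series.data[2, 2, 2], 0.5 * (r1 + r2), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        bold, tract = random_instance(seed)
        w = WindowSpec(8)
        got = compute_twdfc(bold, tract, w).data
        exp = brute_force_twdfc(bold, tract, w)
        assert np.allclose(got, exp, atol=1e-10, equal_nan=True)

    def test_values_within_correlation_bounds(self):
        bold, tract = random_instance(99)
        data = compute_twdfc(bold, tract, WindowSpec(5)).data
        finite = data[np.isfinite(data)]
        assert finite.size and np.all(finite >= -1) and np.all(finite <= 1)

    def test_invariant_to_orientation_and_affine_rescale(self):
        bold, tract = random_instance(7)
        w = WindowSpec(8)
        base = compute_twdfc(bold, tract, w).data
        flipped = Tractogram([s[::-1] for s in tract.streamlines], tract.reference_grid)
        assert np.allclose(
            compute_twdfc(bold, flipped, w).data, base, atol=1e-10, equal_nan=True
        )
        rescaled = BoldSeries(3.0 * bold.data + 11.0, bold.tr_s, bold.grid)
        assert np.allclose(
            compute_twdfc(rescaled, tract, w).data, base, atol=1e-8, equal_nan=True
        )


class TestComputeStaticTw:
    def test_single_streamline_endpoint_mean(self):
        grid, bold, tract = _single_streamline_setup()
        out = compute_static_tw(bold, tract)
        a = bold.data[1, 1, 1]
        b = bold.data[4, 1, 1]
        for v in streamline_voxels(tract.streamlines[0], grid):
            assert np.allclose(out[tuple(v)], 0.5 * (a + b), atol=1e-12)

    def test_constant_bold_paints_constant(self):
        grid = VolumeGrid((6, 6, 6), np.eye(4))
        bold = BoldSeries(np.full(grid.shape + (10,), 5.0), 1.0, grid)
        tract = Tractogram([np.array([[1.0, 1, 1], [4.0, 4, 4]])], grid)
        out = compute_static_tw(bold, tract)
        finite = out[np.isfinite(out)]
        assert np.allclose(finite, 5.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        bold, tract = random_instance(seed + 50)
        got = compute_static_tw(bold, tract)
        exp = brute_force_static(bold, tract)
        assert np.allclose(got, exp, atol=1e-10, equal_nan=True)


class TestConcatenateRuns:
    def test_self_concatenation_doubles_windows(self):
        bold, tract = random_instance(3)
        s = compute_twdfc(bold, tract, WindowSpec(8))
        cat = concatenate_runs([s, s])
        assert cat.n_windows == 2 * s.n_windows

    def test_single_run_identity(self):
        bold, tract = random_instance(4)
        s = compute_twdfc(bold, tract, WindowSpec(8))
        cat = concatenate_runs([s])
        assert np.array_equal(cat.data, s.data, equal_nan=True)

    def test_order_permutes_but_preserves_values(self):
        bold1, tract = random_instance(5)
        bold2 = BoldSeries(bold1.data[..., ::-1].copy(), bold1.tr_s, bold1.grid)
        a = compute_twdfc(bold1, tract, WindowSpec(8))
        b = compute_twdfc(bold2, tract, WindowSpec(8))
        ab = concatenate_runs([a, b]).data
        ba = concatenate_runs([b, a]).data
        assert np.array_equal(np.sort(ab, axis=3), np.sort(ba, axis=3), equal_nan=True)

    def test_mismatched_windows_rejected(self):
        bold, tract = random_instance(6)
        a = compute_twdfc(bold, tract, WindowSpec(8))
        b = compute_twdfc(bold, tract, WindowSpec(9))
        with pytest.raises(ValueError):
            concatenate_runs([a, b])
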