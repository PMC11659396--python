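"""Track-weighted dynamic functional connectivity (tw-dFC).

Each bundle voxel gets a window-resolved time series: for every sliding
window, the value is the mean windowed Pearson correlation between the two
endpoint BOLD series of the streamlines traversing that voxel. A "static"
track-weighted companion paints the mean endpoint BOLD signal instead of its
windowed correlation, giving a static-FC benchmark over the same geometry.

Windows are rectangular with unit default stride; the window FC metric is
Pearson correlation. Windows in which either series has zero variance are
flagged missing (NaN), as are voxels traversed by no valid streamline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .imaging import BoldSeries, BundleMask, Tractogram, endpoints, streamline_voxels, world_to_voxel


@dataclass(frozen=True)
class WindowSpec:
    """A rectangular sliding window over the BOLD time axis."""

    length_tp: int
    shape: str = "rectangular"
    stride_tp: int = 1

    def __post_init__(self):
        if self.length_tp < 3:
            raise ValueError("window length must be >= 3 time points")
        if self.stride_tp < 1:
            raise ValueError("stride must be >= 1")
        if self.shape != "rectangular":
            raise ValueError("only rectangular windows are supported")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints < self.length_tp:
            raise ValueError("series shorter than window")
        return (n_timepoints - self.length_tp) // self.stride_tp + 1


@dataclass
class TwDfcSeries:
    """4-D field of windowed endpoint FC per bundle voxel per window.

    ``data`` has shape grid.shape + (n_windows,); voxels outside the traversed
    bundle are NaN across all windows. ``mask`` marks traversed voxels.
    """

    data: np.ndarray
    window: WindowSpec
    grid: "VolumeGrid"
    mask: BundleMask

    @property
    def n_windows(self) -> int:
        return self.data.shape[3]


def window_length_from_seconds(target_s: float, tr_s: float) -> int:
    """Window length in time points nearest to a target duration."""
    if target_s <= 0 or tr_s <= 0:
        raise ValueError("durations must be positive")
    x = target_s / tr_s
    return int(np.floor(x + 0.5))


def _batch_windowed_stats(X: np.ndarray, L: int, stride: int):
    """Per-window sums and sums of squares via cumulative sums. X: (n, T)."""
    c1 = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X], axis=1), axis=1)
    c2 = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X * X], axis=1), axis=1)
    starts = np.arange(0, X.shape[1] - L + 1, stride)
    s1 = c1[:, starts + L] - c1[:, starts]
    s2 = c2[:, starts + L] - c2[:, starts]
    return s1, s2, starts


def windowed_pearson_batch(X: np.ndarray, Y: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Windowed Pearson r for paired rows of X and Y; (n, n_windows) output.

    Zero-variance windows yield NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    L, stride = window.length_tp, window.stride_tp
    if X.shape[1] < L:
        raise ValueError("series shorter than window")
    sx, sxx, starts = _batch_windowed_stats(X, L, stride)
    sy, syy, _ = _batch_windowed_stats(Y, L, stride)
    cxy = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X * Y], axis=1), axis=1)
    sxy = cxy[:, starts + L] - cxy[:, starts]
    cov = sxy - sx * sy / L
    vx = sxx - sx * sx / L
    vy = syy - sy * sy / L
    # guard tiny negatives from cancellation
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    denom = np.sqrt(vx * vy)
    tol = L * 1e-12 * (1.0 + np.maximum(np.abs(sx / L), np.abs(sy / L)) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r[denom <= tol] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def windowed_pearson(x: np.ndarray, y: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Per-window Pearson correlation between two equal-length series."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    y = np.asarray(y, dtype=float).reshape(1, -1)
    return windowed_pearson_batch(x, y, window)[0]


def endpoint_series(
    tractogram: Tractogram, bold: BoldSeries, brain_mask: BundleMask | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample each streamline's endpoint BOLD series at the nearest voxel.

    Returns (X, Y, valid): (n_streamlines, T) arrays of first/last endpoint
    series and a boolean validity flag. A streamline is invalid if either
    endpoint maps outside the grid or outside ``brain_mask``.
    """
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    grid = bold.grid
    firsts = np.array([endpoints(s)[0] for s in tractogram.streamlines])
    lasts = np.array([endpoints(s)[1] for s in tractogram.streamlines])
    shape = np.asarray(grid.shape)
    T = bold.n_timepoints
    n = len(tractogram)
    X = np.zeros((n, T))
    Y = np.zeros((n, T))
    valid = np.ones(n, dtype=bool)
    for pts, out in ((firsts, X), (lasts, Y)):
        idx = world_to_voxel(pts, grid)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if brain_mask is not None:
            in_mask = np.zeros(n, dtype=bool)
            ii = idx[inside]
            in_mask[inside] = brain_mask.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        else:
            in_mask = inside
        ok = inside & in_mask
        valid &= ok
        ii = idx[ok]
        out[ok] = bold.data[ii[:, 0], ii[:, 1], ii[:, 2], :]
    return X, Y, valid


def _traversal_matrix(tractogram: Tractogram, valid: np.ndarray) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse (n_voxels_flat, n_valid) incidence of streamline voxel traversal."""
    grid = tractogram.reference_grid
    rows, cols = [], []
    valid_idx = np.flatnonzero(valid)
    for j, s_idx in enumerate(valid_idx):
        vox = streamline_voxels(tractogram.streamlines[s_idx], grid)
        if vox.shape[0] == 0:
            continue
        flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), grid.shape)
        rows.append(flat)
        cols.append(np.full(flat.size, j))
    if not rows:
        raise ValueError("no valid streamline traverses the grid")
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    B = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(grid.n_voxels, valid_idx.size)
    )
    return B, valid_idx


def _paint(B: sparse.csr_matrix, values: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Average per-streamline window/time values onto traversed voxels.

    ``values``: (n_valid, n_cols); NaN entries are excluded from the mean.
    Returns grid_shape + (n_cols,) with NaN where no finite value contributes.
    """
    finite = np.isfinite(values)
    sums = B @ np.where(finite, values, 0.0)
    counts = B @ finite.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out.reshape(grid_shape + (values.shape[1],))


def compute_twdfc(
    bold: BoldSeries,
    tractogram: Tractogram,
    window: WindowSpec,
    brain_mask: BundleMask | None = None,
) -> TwDfcSeries:
    """tw-dFC: per voxel and window, the mean windowed endpoint Pearson r of
    traversing streamlines."""
    X, Y, valid = endpoint_series(tractogram, bold, brain_mask)
    if not valid.any():
        raise ValueError("no streamline has both endpoints inside the brain mask")
    R = windowed_pearson_batch(X[valid], Y[valid], window)
    B, _ = _traversal_matrix(tractogram, valid)
    data = _paint(B, R, bold.grid.shape)
    mask = BundleMask(np.isfinite(data).any(axis=3), bold.grid)
    return TwDfcSeries(data, window, bold.grid, mask)


def compute_static_tw(
    bold: BoldSeries,
    tractogram: Tractogram,
    brain_mask: BundleMask | None = None,
) -> np.ndarray:
    """Static track-weighted signal: per voxel and time point, the mean over
    traversing streamlines of the average of the two endpoint BOLD values."""
    X, Y, valid = endpoint_series(tractogram, bold, brain_mask)
    if not valid.any():
        raise ValueError("no streamline has both endpoints inside the brain mask")
    S = 0.5 * (X[valid] + Y[valid])
    B, _ = _traversal_matrix(tractogram, valid)
    return _paint(B, S, bold.grid.shape)


def concatenate_runs(runs: list[TwDfcSeries]) -> TwDfcSeries:
    """Concatenate tw-dFC runs along the window axis."""
    if not runs:
        raise ValueError("empty run list")
    first = runs[0]
    for r in runs[1:]:
        if r.grid != first.grid or r.window != first.window:
            raise ValueError("runs differ in grid or window spec")
        if r.mask.data.shape != first.mask.data.shape:
            raise ValueError("runs differ in mask shape")
    data = np.concatenate([r.data for r in runs], axis=3)
    mask = BundleMask(
        np.logical_or.reduce([r.mask.data for r in runs]), first.grid
    )
    return TwDfcSeries(data, first.window, first.grid, mask)
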