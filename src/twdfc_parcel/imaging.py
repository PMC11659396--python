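"""Volume and tractogram containers, geometry, and file I/O.

Coordinate conventions follow NIfTI: the 4x4 affine maps 0-based voxel
*indices* to world-mm coordinates of voxel centers. Streamlines are polylines
in world mm and must be pre-aligned to the BOLD grid (registration is out of
scope). Nearest-voxel rounding is half-away-from-zero so that examples on
integer-spaced grids are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate spatial inputs (singular affine, empty polyline...)."""


class FormatError(IOError):
    """Raised when an on-disk volume or tractogram cannot be parsed."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with an affine mapping indices to world mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        if any(s <= 0 for s in shape) or len(shape) != 3:
            raise GeometryError(f"invalid grid shape {shape}")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel centers for (N, 3) integer indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def all_centers_mm(self) -> np.ndarray:
        """(prod(shape), 3) world coordinates of every voxel center, C-order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_centers_mm(idx)

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )


@dataclass
class Tractogram:
    """An ordered collection of streamlines (polylines in world mm)."""

    streamlines: list[np.ndarray]
    reference_grid: VolumeGrid

    def __post_init__(self):
        cleaned = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise GeometryError(f"streamline {i} must be an (n>=2, 3) polyline")
            if not np.isfinite(s).all():
                raise GeometryError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(s)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class BoldSeries:
    """A 4-D BOLD series (3 space + time) with its repetition time."""

    data: np.ndarray
    tr_s: float
    grid: VolumeGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[:3] != self.grid.shape:
            raise GeometryError(
                f"BOLD spatial shape {self.data.shape[:3]} != grid {self.grid.shape}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BundleMask:
    """A binary 3-D mask on a grid."""

    data: np.ndarray
    grid: VolumeGrid

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise GeometryError("mask shape does not match grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def world_to_voxel(points: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Map world-mm points to nearest voxel indices (half-away-from-zero).

    Indices may fall outside ``grid.shape``; bounds handling is the caller's
    responsibility.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(pts).all():
        raise GeometryError("points contain non-finite coordinates")
    inv = np.linalg.inv(grid.affine)
    cont = pts @ inv[:3, :3].T + inv[:3, 3]
    # round half away from zero (np.round would round half to even)
    idx = np.sign(cont) * np.floor(np.abs(cont) + 0.5)
    return idx.astype(np.int64)


def endpoints(streamline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two terminal vertices of a polyline."""
    s = np.asarray(streamline, dtype=float)
    return s[0].copy(), s[-1].copy()


def resample_polyline(streamline: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps, keeping both ends."""
    s = np.asarray(streamline, dtype=float)
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise GeometryError("zero-length polyline")
    t = np.arange(0.0, total, step_mm)
    if t[-1] < total:
        t = np.concatenate([t, [total]])
    out = np.empty((t.size, 3))
    for ax in range(3):
        out[:, ax] = np.interp(t, arc, s[:, ax])
    return out


def streamline_voxels(streamline: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Voxels traversed by a streamline, as a (n, 3) unique index array.

    Traversal is exact: each polyline segment is walked through the voxel
    partition (a voxel is traversed whenever the segment enters the cube of
    points nearest to its center), and out-of-bounds voxels are dropped.
    Equivalent to the limit of dense resampling + nearest-voxel mapping.

    Implementation: all boundary-plane crossings (half-integer continuous
    voxel coordinates) are located on a global arc parameter u = segment
    index + within-segment fraction; midpoints of consecutive crossings
    identify the traversed voxels.
    """
    s = np.asarray(streamline, dtype=float)
    if np.linalg.norm(np.diff(s, axis=0), axis=1).sum() <= 0:
        raise GeometryError("zero-length polyline")
    inv = np.linalg.inv(grid.affine)
    sv = s @ inv[:3, :3].T + inv[:3, 3]  # continuous voxel coordinates
    n_seg = len(sv) - 1
    a = sv[:-1]  # (n_seg, 3)
    d = np.diff(sv, axis=0)
    us = [np.arange(n_seg + 1, dtype=float)]  # vertex breakpoints
    for ax in range(3):
        lo = np.minimum(a[:, ax], a[:, ax] + d[:, ax])
        hi = np.maximum(a[:, ax], a[:, ax] + d[:, ax])
        first = np.floor(lo + 0.5) + 0.5
        cnt = np.maximum(0.0, np.ceil(hi - first)).astype(int)
        total = int(cnt.sum())
        if total == 0:
            continue
        seg = np.repeat(np.arange(n_seg), cnt)
        within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        planes = first[seg] + within
        t = (planes - a[seg, ax]) / d[seg, ax]
        us.append(seg + np.clip(t, 0.0, 1.0))
    u = np.unique(np.concatenate(us))
    um = 0.5 * (u[:-1] + u[1:])
    um = um[np.diff(u) > 1e-12]
    seg = np.minimum(um.astype(int), n_seg - 1)
    frac = um - seg
    pts = a[seg] + frac[:, None] * d[seg]
    idx = (np.sign(pts) * np.floor(np.abs(pts) + 0.5)).astype(np.int64)
    shape = np.asarray(grid.shape)
    idx = idx[np.all((idx >= 0) & (idx < shape), axis=1)]
    if idx.size == 0:
        return idx.reshape(0, 3)
    return np.unique(idx, axis=0)


def group_bundle_mask(masks: list[BundleMask], inclusion_fraction: float = 0.75) -> BundleMask:
    """Group mask: voxels present in >= inclusion_fraction of subjects.

    The comparison is inclusive, so with 4 subjects and the default 0.75 a
    voxel present in exactly 3 subjects is included.
    """
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise GeometryError("all masks must share one grid")
    counts = np.sum([m.data for m in masks], axis=0)
    frac = counts / len(masks)
    return BundleMask(frac >= inclusion_fraction - 1e-12, grid)


# ---------------------------------------------------------------------------
# File I/O (NIfTI volumes, TCK/TRK tractograms)
# ---------------------------------------------------------------------------

def write_volume(path: str | Path, data: np.ndarray, grid: VolumeGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    grid = VolumeGrid(tuple(data.shape[:3]), img.affine)
    return data, grid


def write_tractogram(path: str | Path, tractogram: Tractogram) -> None:
    path = str(path)
    sl = nib.streamlines.Tractogram(tractogram.streamlines, affine_to_rasmm=np.eye(4))
    if path.endswith(".tck"):
        nib.streamlines.save(sl, path)
    elif path.endswith(".trk"):
        grid = tractogram.reference_grid
        header = {
            "voxel_sizes": grid.voxel_sizes.astype(np.float32),
            "voxel_to_rasmm": grid.affine.astype(np.float32),
            "dimensions": np.asarray(grid.shape, dtype=np.int16),
        }
        nib.streamlines.save(sl, path, header=header)
    else:
        raise FormatError(f"unsupported tractogram extension: {path}")


def read_tractogram(path: str | Path, reference_grid: VolumeGrid) -> Tractogram:
    try:
        tf = nib.streamlines.load(str(path))
        streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    except Exception as exc:
        raise FormatError(f"cannot read tractogram {path}: {exc}") from exc
    return Tractogram(streamlines, reference_grid)
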