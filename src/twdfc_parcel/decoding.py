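"""Meta-analytic functional decoding of bundle clusters.

Each cluster is summarized by an inverse-distance map 1/(1+d) from its
centroid. After grey-matter-masked screening of a term-map library (top-n
correlated terms per cluster, deduplicated, anatomy stoplist removed), each
surviving term map is converted to a track-weighted term map by averaging the
map along each streamline and painting the mean back onto traversed voxels.
Cluster-term similarity is the Pearson r between the cluster's inverse-
distance map and the track-weighted term map over the bundle mask; effect
size is R^2.

Inference respects spatial autocorrelation: the null distribution of r comes
from variogram-matched surrogates of the cluster map (value permutations
smoothed over a bank of spatial and tract-topology kernels, mixed with
non-negative weights fitted to the empirical variogram, rank re-mapped to
the original value distribution), with a two-sided permutation p and
Benjamini-Hochberg correction across all (cluster, term) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .imaging import (
    BundleMask,
    Tractogram,
    VolumeGrid,
    resample_polyline,
    streamline_voxels,
    world_to_voxel,
)


def load_default_stoplist() -> list[str]:
    """Anatomy/localization stoplist shipped with the package (editable)."""
    text = resources.files("twdfc_parcel").joinpath("data/stoplist.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def inverse_distance_map(
    centroid_mm: np.ndarray, grid: VolumeGrid, mask: BundleMask | None = None
) -> np.ndarray:
    """Proximity map 1/(1 + d_mm) to a centroid; zero outside the mask."""
    centroid = np.asarray(centroid_mm, dtype=float)
    if not np.isfinite(centroid).all():
        raise ValueError("centroid must be finite")
    d = np.linalg.norm(grid.all_centers_mm() - centroid, axis=1).reshape(grid.shape)
    out = 1.0 / (1.0 + d)
    if mask is not None:
        if mask.n_voxels == 0:
            raise ValueError("empty mask")
        out = np.where(mask.data, out, 0.0)
    return out


def track_weighted_scalar_map(
    scalar: np.ndarray, tractogram: Tractogram, grid: VolumeGrid
) -> np.ndarray:
    """Project a 3-D scalar map onto the tractogram (tckmap -scalar_map style).

    Per streamline: sample the scalar at the nearest voxel of arc-length
    resampled points (step 0.5 x min voxel edge, out-of-bounds samples
    dropped) and take the mean as the streamline weight. Per voxel: mean
    weight over traversing streamlines (exact traversal, as in tw-dFC);
    untraversed voxels are NaN.
    """
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    scalar = np.asarray(scalar, dtype=float)
    if scalar.shape != grid.shape:
        raise ValueError("scalar map shape does not match grid")
    step = 0.5 * float(grid.voxel_sizes.min())
    shape = np.asarray(grid.shape)
    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape)
    for sl in tractogram.streamlines:
        pts = resample_polyline(sl, step)
        idx = world_to_voxel(pts, grid)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[inside]
        if idx.shape[0] == 0:
            continue
        weight = scalar[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
        vox = streamline_voxels(sl, grid)
        sums[vox[:, 0], vox[:, 1], vox[:, 2]] += weight
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def screen_terms(
    distance_maps: dict[int, np.ndarray],
    term_library: dict[str, np.ndarray],
    gm_mask: BundleMask,
    top_n: int = 20,
    stoplist: list[str] | None = None,
) -> list[str]:
    """Top-n GM-masked correlated terms per cluster, deduplicated, stoplisted.

    Stoplist matching is case-insensitive substring matching, mirroring a
    manual screen of anatomy/localization terms.
    """
    if not term_library:
        raise ValueError("empty term library")
    if stoplist is None:
        stoplist = load_default_stoplist()
    stop_lower = [s.lower() for s in stoplist]
    gm = gm_mask.data
    selected: list[str] = []
    names = list(term_library)
    term_vals = np.array([term_library[n][gm] for n in names])
    for cid in sorted(distance_maps):
        dvals = distance_maps[cid][gm]
        dz = dvals - dvals.mean()
        tz = term_vals - term_vals.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rs = (tz @ dz) / (
                np.linalg.norm(tz, axis=1) * np.linalg.norm(dz)
            )
        rs = np.nan_to_num(rs, nan=-np.inf)
        for j in np.argsort(-rs)[:top_n]:
            selected.append(names[j])
    out: list[str] = []
    for name in selected:
        low = name.lower()
        if name in out:
            continue
        if any(s in low for s in stop_lower):
            continue
        out.append(name)
    if not out:
        raise ValueError("no terms survive screening")
    return out


# ---------------------------------------------------------------------------
# Spatial-autocorrelation-preserving surrogates
# ---------------------------------------------------------------------------

def _binned_variogram(
    diffs_sq: np.ndarray, bin_idx: np.ndarray, n_bins: int
) -> np.ndarray:
    """Mean semivariance per distance bin. diffs_sq: (n_pairs,) or (n_pairs, m)."""
    if diffs_sq.ndim == 1:
        sums = np.bincount(bin_idx, weights=diffs_sq, minlength=n_bins)
        cnts = np.bincount(bin_idx, minlength=n_bins)
        return 0.5 * sums / np.maximum(cnts, 1)
    out = np.empty((n_bins, diffs_sq.shape[1]))
    cnts = np.bincount(bin_idx, minlength=n_bins)
    for b in range(n_bins):
        sel = bin_idx == b
        out[b] = diffs_sq[sel].mean(axis=0) if sel.any() else 0.0
    return 0.5 * out


def _normalized_kernel(D: np.ndarray, scale: float) -> np.ndarray:
    K = np.exp(-0.5 * (D / max(scale, 1e-9)) ** 2)
    return K / K.sum(axis=1, keepdims=True)


def variogram_surrogates(
    values: np.ndarray,
    coords_mm: np.ndarray,
    n: int = 1000,
    seed: int = 0,
    n_bins: int = 25,
    kernel_scales: np.ndarray | None = None,
    max_pairs: int = 20000,
    aux_coords: np.ndarray | None = None,
    aux_quantiles: tuple[float, ...] = (0.2, 0.35, 0.5),
) -> np.ndarray:
    """SA-preserving surrogate maps by variogram matching: (n, V) array.

    Each surrogate is a multi-scale random field: independent permutations of
    the map values are smoothed by Gaussian distance-kernel regression at
    each bandwidth of a kernel bank, and combined (plus a white nugget) with
    non-negative weights fitted once per ensemble so that the mixture's
    binned variogram matches the empirical variogram in count-weighted least
    squares. Finally each draw is re-mapped by rank onto the original value
    distribution, so every surrogate has exactly the original value multiset.
    Deterministic given ``seed``.

    Maps restricted to a streamline bundle decorrelate along the tract
    topology, not Euclidean distance (two ends of one arc co-vary, while
    nearby voxels of different sub-bundles do not). ``aux_coords`` therefore
    accepts an auxiliary embedding (e.g. a spectral embedding of streamline
    co-traversal); kernels at the ``aux_quantiles`` of its pairwise
    distances join the bank, letting the fit allocate variance to
    tract-level structure that no isotropic spatial kernel can express.
    """
    from scipy.optimize import nnls

    y = np.asarray(values, dtype=float)
    coords = np.asarray(coords_mm, dtype=float)
    V = y.size
    if y.std() == 0:
        raise ValueError("constant map has no surrogate ensemble")
    if V < 10:
        raise ValueError("mask too small for variogram estimation")
    rng = np.random.default_rng(seed)
    D = cdist(coords, coords)
    offdiag = D[np.triu_indices(V, k=1)]
    if kernel_scales is None:
        lo = 1.5 * offdiag[offdiag > 0].min()
        kernel_scales = np.geomspace(lo, np.quantile(offdiag, 0.4), 3)
    kernels = [_normalized_kernel(D, s) for s in kernel_scales]
    if aux_coords is not None:
        Da = cdist(aux_coords, aux_coords)
        offa = Da[np.triu_indices(V, k=1)]
        offa = offa[offa > 0]
        for q in aux_quantiles:
            kernels.append(_normalized_kernel(Da, float(np.quantile(offa, q))))

    # subsampled pair set shared by the empirical and surrogate variograms
    iu, ju = np.triu_indices(V, k=1)
    if iu.size > max_pairs:
        keep = rng.choice(iu.size, size=max_pairs, replace=False)
        iu, ju = iu[keep], ju[keep]
    d_pairs = D[iu, ju]
    d_max = np.quantile(d_pairs, 0.9)
    sel = d_pairs <= d_max
    iu, ju, d_pairs = iu[sel], ju[sel], d_pairs[sel]
    bin_idx = np.minimum((d_pairs / d_max * n_bins).astype(int), n_bins - 1)
    counts_b = np.bincount(bin_idx, minlength=n_bins)
    occupied = counts_b > 0
    onehot = np.zeros((bin_idx.size, n_bins))
    onehot[np.arange(bin_idx.size), bin_idx] = 1.0
    onehot = onehot[:, occupied]
    counts = counts_b[occupied]

    def vario(M: np.ndarray) -> np.ndarray:
        """Binned variograms of the rows of M: (m, n_occupied_bins)."""
        sums = ((M[:, iu] - M[:, ju]) ** 2) @ onehot
        return 0.5 * sums / np.maximum(counts, 1)

    y_std = y.std()
    yz = (y - y.mean()) / y_std
    gamma_emp = vario(yz[None, :])[0]

    def smoothed_perms(K: np.ndarray, m: int) -> np.ndarray:
        P = np.array([rng.permutation(yz) for _ in range(m)])
        Z = P @ K.T
        Z -= Z.mean(axis=1, keepdims=True)
        sd = Z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return Z / sd

    centered = coords - coords.mean(axis=0)
    span = np.abs(centered).max()

    def random_trends(m: int) -> np.ndarray:
        """Unit-variance large-scale trend fields: random-direction linear
        gradients and random-center radial gradients, half and half."""
        gdir = rng.standard_normal((m, 3))
        gdir /= np.linalg.norm(gdir, axis=1, keepdims=True)
        centers = rng.uniform(-1.2, 1.2, size=(m, 3)) * span
        radial = rng.random(m) < 0.5
        T = np.empty((m, V))
        for i in range(m):
            t = (
                -np.linalg.norm(centered - centers[i], axis=1)
                if radial[i]
                else centered @ gdir[i]
            )
            sd = t.std()
            T[i] = (t - t.mean()) / (sd if sd > 0 else 1.0)
        return T

    # ensemble-level fit: one non-negative weight per component, so every
    # draw shares the same composition (a heterogeneous ensemble would mix
    # over- and under-smoothed members and distort the permutation null).
    # Kernel columns are the analytic expected variograms of a smoothed
    # white field, 0.5*(C_ii + C_jj) - C_ij with C = K K^T, normalized to
    # unit mean variance -- exact up to O(1/V) permutation corrections and
    # free of pilot-sampling noise.
    columns = [np.ones_like(gamma_emp)]
    for K in kernels:
        C = K @ K.T
        diag = np.diag(C)
        g = (0.5 * (diag[iu] + diag[ju]) - C[iu, ju]) / diag.mean()
        columns.append((g @ onehot) / np.maximum(counts, 1))
    n_pilot = 60
    columns.append(vario(random_trends(n_pilot)).mean(axis=0))
    A = np.column_stack(columns)
    w_bins = np.sqrt(counts)
    weights, _ = nnls(A * w_bins[:, None], gamma_emp * w_bins)

    y_sorted = np.sort(y)
    out = np.empty((n, V))
    chunk = 250
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        cand = np.sqrt(weights[0]) * rng.standard_normal((m, V))
        for j, K in enumerate(kernels):
            if weights[j + 1] <= 1e-12:
                continue
            cand = cand + np.sqrt(weights[j + 1]) * smoothed_perms(K, m)
        if weights[-1] > 1e-12:
            cand = cand + np.sqrt(weights[-1]) * random_trends(m)
        ranks = np.argsort(np.argsort(cand, axis=1), axis=1)
        out[start : start + m] = y_sorted[ranks]
    return out


def co_traversal_embedding(
    tractogram: Tractogram, voxels: np.ndarray, grid: VolumeGrid, dims: int = 8
) -> np.ndarray:
    """Spectral embedding of voxels by shared streamline traversal.

    Voxels traversed by similar sets of streamlines land close together; the
    embedding distance captures the tract topology (along-arc proximity,
    across-bundle separation) that Euclidean distance misses. Used as the
    auxiliary metric for SA-preserving surrogates on bundle masks.
    """
    from .twdfc import _traversal_matrix

    B, _ = _traversal_matrix(tractogram, np.ones(len(tractogram), dtype=bool))
    flat = np.ravel_multi_index((voxels[:, 0], voxels[:, 1], voxels[:, 2]), grid.shape)
    inc = np.asarray(B[flat].todense())
    norms = np.linalg.norm(inc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    P = inc / norms
    S = P @ P.T
    evals, evecs = np.linalg.eigh(S)
    return evecs[:, -dims:] * np.sqrt(np.maximum(evals[-dims:], 0.0))


def sa_permutation_pvalue(observed_r: float, surrogate_rs: np.ndarray) -> float:
    """Two-sided permutation p: (#{|r_surr| >= |r_obs|} + 1) / (n + 1)."""
    surr = np.asarray(surrogate_rs, dtype=float)
    exceed = int(np.sum(np.abs(surr) >= abs(observed_r)))
    return (exceed + 1) / (surr.size + 1)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _masked_corr(a: np.ndarray, b: np.ndarray) -> float:
    az = a - a.mean()
    bz = b - b.mean()
    den = np.linalg.norm(az) * np.linalg.norm(bz)
    if den == 0:
        return np.nan
    return float(az @ bz / den)


def decode_clusters(
    centroids_mm: np.ndarray,
    term_library: dict[str, np.ndarray],
    tractogram: Tractogram,
    gm_mask: BundleMask,
    bundle_mask: BundleMask,
    grid: VolumeGrid,
    n_surrogates: int = 1000,
    seed: int = 0,
    top_n: int = 20,
    stoplist: list[str] | None = None,
    screen: bool = True,
) -> pd.DataFrame:
    """Full decoding: screen -> track-weight -> correlate -> SA inference -> BH.

    Returns a DataFrame with one row per (cluster, term): r, r2, p_perm,
    p_adj, n_surrogates. Clusters are numbered 1..c in centroid order.
    """
    dist_full = {
        cid + 1: inverse_distance_map(c, grid) for cid, c in enumerate(centroids_mm)
    }
    if screen:
        terms = screen_terms(dist_full, term_library, gm_mask, top_n, stoplist)
    else:
        terms = list(term_library)
    tw_maps = {
        t: track_weighted_scalar_map(term_library[t], tractogram, grid) for t in terms
    }
    bm = bundle_mask.data
    valid = bm & np.all([np.isfinite(tw_maps[t]) for t in terms], axis=0)
    vox = np.argwhere(valid)
    coords = grid.voxel_centers_mm(vox)
    embedding = co_traversal_embedding(tractogram, vox, grid)
    rows = []
    for cid in sorted(dist_full):
        dvals = dist_full[cid][valid]
        surr = variogram_surrogates(
            dvals,
            coords,
            n=n_surrogates,
            seed=seed + 1000 * cid,
            aux_coords=embedding,
        )
        surr_z = surr - surr.mean(axis=1, keepdims=True)
        surr_z /= np.linalg.norm(surr_z, axis=1, keepdims=True)
        for t in terms:
            tv = tw_maps[t][valid]
            r = _masked_corr(dvals, tv)
            tz = tv - tv.mean()
            nrm = np.linalg.norm(tz)
            surr_rs = surr_z @ (tz / nrm) if nrm > 0 else np.zeros(n_surrogates)
            rows.append(
                {
                    "cluster": cid,
                    "term": t,
                    "r": r,
                    "r2": r**2,
                    "p_perm": sa_permutation_pvalue(r, surr_rs),
                    "n_surrogates": n_surrogates,
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_perm"].to_numpy())
    return df
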