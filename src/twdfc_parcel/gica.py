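"""Spatial group ICA: subject PCA, group PCA, Infomax, back-reconstruction.

The pipeline mirrors the standard group spatial ICA framework for 4-D fMRI
style data: (1) per-subject temporal PCA of the (windows x voxels) matrix to
``n_pc`` components; (2) row-concatenation across subjects and a second PCA
to ``k`` group directions; (3) Infomax ICA in that low-dimensional space,
yielding k independent spatial maps; (4) subject-specific maps and time
courses by dual regression, optionally refined with a group-information-
guided independence step; (5) subject maps averaged and z-scored into group
z-maps.

Every in-mask voxel series is standardized (mean 0, sd 1 over windows)
before PCA. ICA components are sign-oriented to positive skewness; component
order follows the group PCA directions and is otherwise arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import BundleMask


class IcaConvergenceError(RuntimeError):
    """Infomax failed to converge within the iteration budget."""


@dataclass
class ComponentSet:
    """Group ICA output over a fixed voxel support.

    group_zmaps: (k, V) z-scored spatial maps; subject_maps / timecourses are
    per-subject (k, V) and (k, n_windows) arrays aligned component-wise with
    the group maps. ``signs`` records any sign flips applied after ICA.
    """

    k: int
    group_zmaps: np.ndarray
    subject_maps: list[np.ndarray]
    subject_timecourses: list[np.ndarray]
    mask: BundleMask | None = None
    signs: np.ndarray | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.signs is None:
            self.signs = np.ones(self.k)

    def flip_sign(self, component: int) -> None:
        """Resolve ICA sign indeterminacy manually for one component."""
        self.group_zmaps[component] *= -1
        for m in self.subject_maps:
            m[component] *= -1
        for t in self.subject_timecourses:
            t[component] *= -1
        self.signs[component] *= -1


def standardize_voxels(data: np.ndarray) -> np.ndarray:
    """Standardize each column (voxel series) to mean 0, sd 1.

    Zero-variance columns are zeroed with a warning (they carry no dynamic
    signal; the group mask should exclude them upstream).
    """
    data = np.asarray(data, dtype=float)
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    dead = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))  # constant up to roundoff
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance voxel series zeroed")
        sd = np.where(dead, 1.0, sd)
    return (data - mu) / sd


def subject_reduce(data: np.ndarray, n_pc: int = 50) -> tuple[np.ndarray, dict]:
    """Temporal PCA of one subject's (n_windows, V) matrix.

    Returns (reduced, record): ``reduced`` is (n_pc, V), rows being principal
    temporal projections ordered by decreasing explained variance; ``record``
    carries the standardization and spectrum for provenance.
    """
    data = np.asarray(data, dtype=float)
    W, V = data.shape
    if n_pc > min(W, V):
        raise ValueError(f"n_pc={n_pc} exceeds min(n_windows, V)={min(W, V)}")
    Z = standardize_voxels(data)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    reduced = s[:n_pc, None] * Vt[:n_pc]
    record = {
        "singular_values": s,
        "explained_variance": s**2 / W,
        "n_pc": n_pc,
    }
    return reduced, record


def group_reduce(subject_reductions: list[np.ndarray], k: int) -> np.ndarray:
    """Second-stage PCA of the row-concatenated subject reductions: (k, V)."""
    X = np.concatenate(subject_reductions, axis=0)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds concatenated rows {X.shape[0]}")
    # no further centering: subject rows derive from voxel-standardized data,
    # and an uncentered SVD keeps the single-subject case an exact identity
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return s[:k, None] * Vt[:k]


def _orient_positive_skew(S: np.ndarray, *mats: np.ndarray) -> np.ndarray:
    """Flip each component so its map skewness is >= 0; returns the signs."""
    centered = S - S.mean(axis=1, keepdims=True)
    skew = (centered**3).mean(axis=1)
    signs = np.where(skew < 0, -1.0, 1.0)
    S *= signs[:, None]
    for m in mats:
        m *= signs[:, None]
    return signs


def infomax_ica(
    X: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 1024,
    tol: float = 1e-6,
    lr: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extended Infomax ICA (natural-gradient updates, annealed rate).

    X: (k', V) matrix of reduced data; samples are voxels. Returns
    (S, A, signs): unit-variance independent spatial maps (k, V), the mixing
    matrix A with X ~= A @ S, and the positive-skewness sign flips applied.

    The extended variant switches each component's nonlinearity by the sign
    of a kurtosis-based stability statistic, separating sub-Gaussian as well
    as super-Gaussian sources (spatial component maps over a bundle are often
    multi-modal, hence sub-Gaussian). The learning rate is annealed on
    overshoot and when the gradient direction reverses.
    """
    X = np.asarray(X, dtype=float)
    kp, V = X.shape
    if k > kp:
        raise ValueError(f"k={k} exceeds data dimension {kp}")
    Xc = X - X.mean(axis=1, keepdims=True)
    U0, s0, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s0 > max(s0) * 1e-10
    if keep.sum() < k:
        raise ValueError("data rank below requested k")
    P = (U0[:, :k] / (s0[:k] / np.sqrt(V))).T  # whitening: (k, k')
    Z = P @ Xc  # (k, V), identity covariance

    rng = np.random.default_rng(seed)
    eye = np.eye(k)
    converged = False
    step_norm = np.inf
    best_W, best_step = None, np.inf
    for restart in range(3):
        W = np.eye(k) + 0.05 * rng.standard_normal((k, k))
        rate = lr
        prev_grad = None
        stat_ema = None
        for _ in range(max_iter):
            Uc = W @ Z
            th = np.tanh(Uc)
            # stability statistic: positive for super-, negative for
            # sub-Gaussian sources; EMA-smoothed so its sign cannot flip
            # back and forth on sampling noise near zero kurtosis
            stat = (1.0 - th**2).mean(axis=1) * (Uc**2).mean(axis=1) - (
                th * Uc
            ).mean(axis=1)
            stat_ema = stat if stat_ema is None else 0.9 * stat_ema + 0.1 * stat
            kappa = np.where(stat_ema >= 0, 1.0, -1.0)
            grad = (eye - (kappa[:, None] * th) @ Uc.T / V - Uc @ Uc.T / V) @ W
            step = rate * grad
            step_norm = np.linalg.norm(step) / np.linalg.norm(W)
            if not np.isfinite(step_norm) or step_norm > 1.0:
                rate *= 0.5  # overshoot: anneal and retry
                if rate < 1e-10:
                    break
                prev_grad = None
                continue
            # damp oscillations: cool when the gradient reverses direction
            if prev_grad is not None and np.sum(grad * prev_grad) < 0:
                rate *= 0.9
            prev_grad = grad
            W = W + step
            if step_norm < tol:
                converged = True
                break
        if step_norm < best_step:
            best_step, best_W = step_norm, W
        if converged:
            break
    if not converged:
        # a small oscillating weight change is a flat plateau (typical when k
        # exceeds the true structure and components are interchangeable), not
        # a failure; accept the best restart with a warning
        if best_step < 1e3 * tol:
            warnings.warn(
                f"Infomax stopped on a plateau (weight change {best_step:.2e})"
            )
            W = best_W
        else:
            raise IcaConvergenceError(
                f"Infomax did not converge in {max_iter} iterations x 3 restarts "
                f"(last step {best_step:.2e})"
            )
    S = W @ Z
    sd = S.std(axis=1, keepdims=True)
    S = S / sd
    Wtot = (W / sd) @ P  # (k, k') so S = Wtot @ Xc
    A = np.linalg.pinv(Wtot)  # (k', k)
    signs = _orient_positive_skew(S)
    A *= signs[None, :]
    return S, A, signs


def dual_regression(
    group_maps: np.ndarray, subject_data: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage least squares: time courses then subject maps.

    subject_data: (n_windows, V) standardized matrix; group_maps: (k, V).
    """
    G = np.asarray(group_maps, dtype=float)
    D = np.asarray(subject_data, dtype=float)
    tc, *_ = np.linalg.lstsq(G.T, D.T, rcond=None)  # (k, n_windows)
    gram = tc @ tc.T
    if np.linalg.cond(gram) > 1e10:
        raise np.linalg.LinAlgError("rank-deficient time courses in dual regression")
    maps = np.linalg.solve(gram, tc @ D)  # (k, V)
    return maps, tc


def gig_ica_backreconstruct(
    group_maps: np.ndarray,
    subject_data: np.ndarray,
    corr_floor: float = 0.7,
    max_iter: int = 60,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Group-information-guided subject maps: independence refined under a
    correspondence constraint to the group map.

    Each subject map is optimized by one-unit fixed-point negentropy ascent
    (tanh contrast) in the subject's whitened spatial subspace, initialized
    from the dual-regression solution; after each update the map is blended
    back toward the initializer just enough to keep its correlation with the
    group map at or above ``corr_floor``.
    """
    G = np.asarray(group_maps, dtype=float)
    D = np.asarray(subject_data, dtype=float)
    k, V = G.shape
    r = min(D.shape[0], max(k, 20))
    Dc = D - D.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    r = min(r, int((s > s[0] * 1e-10).sum()))
    Z = np.sqrt(V) * Vt[:r]  # whitened spatial subspace, unit-variance rows

    Gz = (G - G.mean(axis=1, keepdims=True)) / G.std(axis=1, keepdims=True)
    init_maps, _ = dual_regression(G, D)

    def unit(w):
        n = np.linalg.norm(w)
        return w / n if n > 0 else w

    # negentropy proxy: squared deviation of E[log cosh u] from its Gaussian
    # expectation (~0.3746 for a standard normal)
    gauss_ref = 0.37457
    def contrast(w):
        return (np.mean(np.log(np.cosh(w @ Z))) - gauss_ref) ** 2

    maps = np.empty((k, V))
    for c in range(k):
        w0 = unit(Z @ init_maps[c] / V)
        w = w0.copy()
        for _ in range(max_iter):
            u = w @ Z
            gu = np.tanh(u)
            w_new = unit(Z @ gu / V - (1.0 - gu**2).mean() * w)
            # correspondence constraint: blend toward the initializer
            for mu in np.linspace(0.0, 1.0, 11):
                w_try = unit((1 - mu) * w_new + mu * w0)
                s_try = w_try @ Z
                if abs(np.corrcoef(s_try, Gz[c])[0, 1]) >= corr_floor:
                    w_new = w_try
                    break
            else:
                w_new = w0
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < tol:
                w = w_new
                break
            w = w_new
        # accept the refinement only if it increased non-Gaussianity; with a
        # (near-)Gaussian component the fixed point is undefined and the
        # regression initializer is already the constrained optimum
        if contrast(w) <= contrast(w0) * (1.0 + 1e-6):
            w = w0
        s_map = w @ Z
        if np.corrcoef(s_map, Gz[c])[0, 1] < 0:
            s_map = -s_map
        # rescale to the dual-regression map's scale
        s_map = s_map / s_map.std() * init_maps[c].std()
        maps[c] = s_map
    tc, *_ = np.linalg.lstsq(maps.T, D.T, rcond=None)
    return maps, tc


def back_reconstruct(
    group_maps: np.ndarray,
    subject_data: np.ndarray,
    method: str = "dual-regression",
    corr_floor: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-specific maps and time courses from group maps."""
    if method == "dual-regression":
        return dual_regression(group_maps, subject_data)
    if method == "gig-ica":
        return gig_ica_backreconstruct(group_maps, subject_data, corr_floor=corr_floor)
    raise ValueError(f"unknown back-reconstruction method: {method}")


def group_zmaps(
    subject_maps: list[np.ndarray],
    subject_timecourses: list[np.ndarray] | None = None,
    mask: BundleMask | None = None,
    signs: np.ndarray | None = None,
) -> ComponentSet:
    """Average subject maps and z-score over voxels into group z-maps."""
    if not subject_maps:
        raise ValueError("need at least one subject")
    mean_map = np.mean(subject_maps, axis=0)
    sd = mean_map.std(axis=1, keepdims=True)
    if np.any(sd <= 1e-12):
        raise ValueError("degenerate component: subject maps cancel to a constant")
    z = (mean_map - mean_map.mean(axis=1, keepdims=True)) / sd
    return ComponentSet(
        k=z.shape[0],
        group_zmaps=z,
        subject_maps=list(subject_maps),
        subject_timecourses=list(subject_timecourses or []),
        mask=mask,
        signs=signs,
    )


def mean_timecourse_correlation(components: ComponentSet) -> float:
    """Mean |Pearson r| over component pairs, averaged across subjects.

    The absolute value is taken because ICA component signs are arbitrary.
    Pairs involving a constant time course are dropped.
    """
    if components.k < 2:
        raise ValueError("need k >= 2 components")
    per_subject = []
    for tc in components.subject_timecourses:
        sd = tc.std(axis=1)
        vals = []
        for i in range(components.k):
            for j in range(i + 1, components.k):
                if sd[i] <= 0 or sd[j] <= 0:
                    continue
                vals.append(abs(np.corrcoef(tc[i], tc[j])[0, 1]))
        if vals:
            per_subject.append(np.mean(vals))
    if not per_subject:
        raise ValueError("all component time-course pairs are degenerate")
    return float(np.mean(per_subject))


def group_ica_pipeline(
    subject_matrices: list[np.ndarray],
    k: int,
    seed: int,
    n_pc: int = 50,
    method: str = "dual-regression",
    mask: BundleMask | None = None,
) -> ComponentSet:
    """Full five-step group spatial ICA over standardized subject matrices.

    subject_matrices: per subject (n_windows, V) over a common voxel support.
    """
    n_pc_eff = min(n_pc, min(min(m.shape) for m in subject_matrices))
    reductions = [subject_reduce(m, n_pc_eff)[0] for m in subject_matrices]
    X = group_reduce(reductions, min(k * 4, len(reductions) * n_pc_eff))
    S, _, signs = infomax_ica(X, k, seed)
    maps, tcs = [], []
    for m in subject_matrices:
        sm, tc = back_reconstruct(S, standardize_voxels(m), method=method)
        maps.append(sm)
        tcs.append(tc)
    return group_zmaps(maps, tcs, mask=mask, signs=signs)
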