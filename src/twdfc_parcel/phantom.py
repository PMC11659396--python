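"""Synthetic multi-subject bundle phantom with known latent-mode structure.

The phantom emulates the data a bundle-specific tw-dFC study consumes: per
subject, an arc-shaped streamline bundle (several sub-bundles stacked along
the ventral->dorsal axis) plus a 4-D BOLD series in which the two endpoint
regions of each sub-bundle carry signals whose *windowed correlation* is
driven by a small number of shared latent modes.

Construction of a correlated endpoint pair at target correlation rho(t):

    x(t) = sign(rho) * sqrt(|rho(t)|) * c(t) + sqrt(1 - |rho(t)|) * e_x(t)
    y(t) =             sqrt(|rho(t)|) * c(t) + sqrt(1 - |rho(t)|) * e_y(t)

with c a shared standard-normal latent per sub-bundle and e_* idiosyncratic
white noise per voxel, so that corr(x, y) = rho(t) by construction. The
target follows the latent modes:

    rho_i(t) = base_corr + amp * sum_m loadings[i, m] * mode_m(t)

where the modes are low-pass-filtered random walks (cutoff at the analysis
window time-scale) so that sliding-window FC can track them. A small multiple
of the mode drive is also added to the mean signal of the endpoint voxels
(``mean_signal_gain``) so that a static (non-windowed) track-weighted analysis
sees the same component structure. Observation noise of scale ``noise_sd`` is
added to every voxel, which attenuates realized correlations by
1 / (1 + noise_sd**2).

Everything is a pure function of (spec, subject_index, session): modes and
geometry derive from ``spec.seed`` alone and are shared across subjects;
per-subject noise derives from the subject index; the session index gives
independent noise for test-retest designs.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, gaussian_filter1d

from .imaging import (
    BoldSeries,
    BundleMask,
    GeometryError,
    Tractogram,
    VolumeGrid,
    streamline_voxels,
)
from .twdfc import WindowSpec


def default_mode_loadings(n_bundles: int, n_modes: int) -> tuple[tuple[float, ...], ...]:
    """Anti-loaded default: bundle b loads on mode b; surplus bundles load
    negatively on all modes so every bundle is separable in mode space."""
    rows = []
    for b in range(n_bundles):
        if b < n_modes:
            row = [0.0] * n_modes
            row[b] = 1.0
        else:
            # anti-loaded: negative weight on every mode, predominantly on
            # one of them so the bundle's time course stays nearly collinear
            # with a single mode (an equal anti-loading would make this
            # bundle's time course a 45-degree mode mixture, which no
            # component decomposition could assign to either mode)
            lead = b % n_modes
            row = [-0.15] * n_modes
            row[lead] = -0.5
        rows.append(tuple(row))
    return tuple(rows)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort. All fields hashable for caching."""

    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 2.0
    n_bundles: int = 3
    streamlines_per_bundle: int = 200
    n_subjects: int = 12
    n_timepoints: int = 300
    tr_s: float = 2.0
    n_modes: int = 2
    mode_loadings: tuple[tuple[float, ...], ...] | None = None
    base_corr: float = 0.45
    amp: float = 0.4
    noise_sd: float = 0.3
    subject_jitter_mm: float = 0.5
    mean_signal_gain: float = 0.5
    mode_smooth_tp: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_bundles < 2:
            raise ValueError("need at least 2 bundles")
        for name in ("streamlines_per_bundle", "n_subjects", "n_timepoints", "n_modes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.base_corr < 1.0):
            raise ValueError("base_corr must lie in (0, 1)")
        if self.amp < 0 or self.noise_sd < 0 or self.subject_jitter_mm < 0:
            raise ValueError("amp, noise_sd and subject_jitter_mm must be >= 0")
        if not (self.base_corr + self.amp < 1.0 and self.base_corr - self.amp > -1.0):
            raise ValueError("base_corr +/- amp must stay inside (-1, 1)")
        if self.mode_loadings is None:
            object.__setattr__(
                self,
                "mode_loadings",
                default_mode_loadings(self.n_bundles, self.n_modes),
            )
        L = np.asarray(self.mode_loadings, dtype=float)
        if L.shape != (self.n_bundles, self.n_modes):
            raise ValueError(
                f"mode_loadings must be {self.n_bundles} x {self.n_modes}, got {L.shape}"
            )
        if np.abs(L).max() > 1.0:
            raise ValueError("mode_loadings entries must lie in [-1, 1]")
        object.__setattr__(
            self, "mode_loadings", tuple(tuple(float(v) for v in row) for row in L)
        )
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    @property
    def loadings(self) -> np.ndarray:
        return np.asarray(self.mode_loadings, dtype=float)

    @property
    def smooth_tp(self) -> int:
        """Low-pass cutoff of the latent modes, in time points (~40 s)."""
        if self.mode_smooth_tp is not None:
            return int(self.mode_smooth_tp)
        return max(3, int(round(40.0 / self.tr_s)))

    def make_grid(self) -> VolumeGrid:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return VolumeGrid(self.grid_shape, aff)


@dataclass
class PhantomTruth:
    """Ground truth shared by all subjects of a cohort."""

    bundle_label_per_streamline: np.ndarray  # (n_streamlines,), 1..n_bundles
    bundle_label_per_voxel: np.ndarray  # 3-D int field, 0 = background
    mode_timecourses: np.ndarray  # (n_modes, n_timepoints), zero mean
    cluster_centroids_mm: np.ndarray  # (n_bundles, 3)
    endpoint_voxels: np.ndarray  # (n_patch_voxels, 3) signal-carrying voxels
    rho_timecourses: np.ndarray  # (n_bundles, n_timepoints) target correlations


def windowed_modes(truth: PhantomTruth, window: WindowSpec) -> np.ndarray:
    """Latent modes averaged over each sliding window: (n_modes, n_windows)."""
    L, stride = window.length_tp, window.stride_tp
    T = truth.mode_timecourses.shape[1]
    starts = np.arange(0, T - L + 1, stride)
    c = np.cumsum(
        np.concatenate(
            [np.zeros((truth.mode_timecourses.shape[0], 1)), truth.mode_timecourses],
            axis=1,
        ),
        axis=1,
    )
    return (c[:, starts + L] - c[:, starts]) / L


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _patch_offsets(radii: tuple[int, int, int] = (1, 1, 1)) -> np.ndarray:
    ext = tuple(2 * r + 1 for r in radii)
    return np.indices(ext).reshape(3, -1).T - np.asarray(radii)


@functools.lru_cache(maxsize=8)
def _template_geometry(spec: PhantomSpec):
    """Per-bundle endpoint patch voxels, template streamlines (mm), labels.

    Bundle b arcs from a frontal patch to a temporal patch at a fixed
    ventral->dorsal level; streamline endpoints scatter within the 3x3x3
    patches with sub-voxel jitter so each endpoint's nearest voxel is a
    signal-carrying patch voxel.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size_mm
    if nx < 10 or ny < 10 or nz < 4 * spec.n_bundles:
        raise GeometryError(
            f"grid {spec.grid_shape} too small for {spec.n_bundles} stacked bundles"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    z_levels = [
        int(round((b + 1) * nz / (spec.n_bundles + 1))) for b in range(spec.n_bundles)
    ]
    if len(set(z_levels)) < spec.n_bundles or min(z_levels) < 1 or max(z_levels) > nz - 2:
        raise GeometryError("cannot place disjoint endpoint patches along z")
    patch_sets = []  # (frontal voxels, temporal voxels) per bundle
    streamlines = []
    labels = []
    y_front, y_temp = 3, ny - 4
    x_base = 3
    # unequal sub-bundle calibre (middle widest, top thinnest): footprint
    # asymmetry is what makes the component maps identifiable by ICA, and
    # real sub-bundles differ in calibre anyway
    thickness = [1.0, 1.7, 1.0]
    patch_radii = [(1, 1, 1), (2, 2, 1), (1, 1, 1)]
    for b, zb in enumerate(z_levels):
        th = thickness[b % len(thickness)]
        offsets = _patch_offsets(patch_radii[b % len(patch_radii)])
        fc = np.array([x_base, y_front, zb])
        tc = np.array([x_base, y_temp, zb])
        fvox = np.clip(fc + offsets, 0, [nx - 1, ny - 1, nz - 1])
        tvox = np.clip(tc + offsets, 0, [nx - 1, ny - 1, nz - 1])
        fvox = np.unique(fvox, axis=0)
        tvox = np.unique(tvox, axis=0)
        patch_sets.append((fvox, tvox))
        for _ in range(spec.streamlines_per_bundle):
            a_vox = fvox[rng.integers(len(fvox))] + rng.uniform(-0.45, 0.45, 3)
            c_vox = tvox[rng.integers(len(tvox))] + rng.uniform(-0.45, 0.45, 3)
            ctrl = np.array(
                [nx - 3 + rng.normal(0, 0.8 * th),
                 (y_front + y_temp) / 2 + rng.normal(0, 0.8 * th),
                 zb + rng.normal(0, 0.5 * th)]
            )
            t = np.linspace(0.0, 1.0, 40)[:, None]
            pts_vox = (1 - t) ** 2 * a_vox + 2 * t * (1 - t) * ctrl + t**2 * c_vox
            streamlines.append(pts_vox * vs)  # diagonal affine: mm = vox * size
            labels.append(b + 1)
    # patches of different bundles must not overlap
    all_patch = np.concatenate([np.concatenate(p) for p in patch_sets])
    if len(np.unique(all_patch, axis=0)) != len(all_patch):
        raise GeometryError("endpoint patches overlap between bundles")
    return patch_sets, streamlines, np.asarray(labels)


@functools.lru_cache(maxsize=8)
def _template_truth(spec: PhantomSpec) -> PhantomTruth:
    grid = spec.make_grid()
    patch_sets, streamlines, labels = _template_geometry(spec)
    counts = np.zeros((spec.n_bundles,) + spec.grid_shape, dtype=np.int32)
    for sl, lab in zip(streamlines, labels):
        vox = streamline_voxels(sl, grid)
        counts[lab - 1, vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    total = counts.sum(axis=0)
    # majority bundle among traversing streamlines; ties -> lowest bundle index
    label_vol = np.where(total > 0, np.argmax(counts, axis=0) + 1, 0)
    centroids = np.zeros((spec.n_bundles, 3))
    for b in range(spec.n_bundles):
        vox = np.argwhere(label_vol == b + 1)
        centroids[b] = grid.voxel_centers_mm(vox).mean(axis=0)
    modes = _modes(spec)
    rho = spec.base_corr + spec.amp * (spec.loadings @ modes)
    if np.abs(rho).max() >= 1.0:
        raise ValueError("target endpoint correlation leaves (-1, 1); reduce amp")
    patch_vox = np.concatenate([np.concatenate(p) for p in patch_sets])
    return PhantomTruth(
        bundle_label_per_streamline=labels,
        bundle_label_per_voxel=label_vol,
        mode_timecourses=modes,
        cluster_centroids_mm=centroids,
        endpoint_voxels=patch_vox,
        rho_timecourses=rho,
    )


@functools.lru_cache(maxsize=8)
def _modes(spec: PhantomSpec) -> np.ndarray:
    """Latent modes: low-pass-filtered random walks, zero mean, max |.| = 1.

    Modes are mutually orthogonalized (Gram-Schmidt) so they represent
    distinct latent processes; smooth low-dimensional series would otherwise
    correlate appreciably by chance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 22]))
    steps = rng.standard_normal((spec.n_modes, spec.n_timepoints))
    walks = np.cumsum(steps, axis=1)
    smooth = gaussian_filter1d(walks, sigma=spec.smooth_tp / 2.0, axis=1, mode="nearest")
    smooth -= smooth.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(smooth.T)
    modes = q.T * np.sign(np.diag(smooth @ q)[:, None])  # keep original polarity
    modes -= modes.mean(axis=1, keepdims=True)
    peak = np.abs(modes).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return modes / peak


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(
    spec: PhantomSpec, subject_index: int, session: int = 0
) -> tuple[Tractogram, BoldSeries, PhantomTruth]:
    """One subject's tractogram and BOLD series, plus the cohort-shared truth."""
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    grid = spec.make_grid()
    patch_sets, template, labels = _template_geometry(spec)
    truth = _template_truth(spec)

    # subject anatomy: per-bundle rigid jitter, fixed across sessions
    rng_anat = np.random.default_rng(np.random.SeedSequence([spec.seed, 33, subject_index]))
    shifts = rng_anat.normal(0.0, spec.subject_jitter_mm, size=(spec.n_bundles, 3))
    streamlines = [sl + shifts[lab - 1] for sl, lab in zip(template, labels)]
    tract = Tractogram(streamlines, grid)

    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 44, subject_index, session])
    )
    T = spec.n_timepoints
    data = rng.standard_normal(spec.grid_shape + (T,)) * spec.noise_sd
    rho = truth.rho_timecourses
    drive = spec.loadings @ truth.mode_timecourses  # (n_bundles, T)
    sq_shared = np.sign(rho) * np.sqrt(np.abs(rho))
    sq_noise = np.sqrt(1.0 - np.abs(rho))
    for b in range(spec.n_bundles):
        c = rng.standard_normal(T)
        for side in range(2):
            vox = patch_sets[b][side]
            e = rng.standard_normal((len(vox), T))
            # shared latent enters side 0 with the sign of rho so the cross
            # correlation equals rho even when rho < 0
            shared = (sq_shared[b] if side == 0 else np.sqrt(np.abs(rho[b]))) * c
            x = shared + sq_noise[b] * e + spec.mean_signal_gain * drive[b]
            data[vox[:, 0], vox[:, 1], vox[:, 2], :] += x
    bold = BoldSeries(data, spec.tr_s, grid)
    return tract, bold, truth


def generate_cohort(
    spec: PhantomSpec, subject_offset: int = 0, session: int = 0
) -> tuple[list[tuple[Tractogram, BoldSeries]], PhantomTruth]:
    """A cohort of ``spec.n_subjects`` subjects sharing one PhantomTruth.

    ``subject_offset`` shifts the subject index range, giving an independent
    cohort with the same ground truth (for cross-cohort validation);
    ``session`` gives an independent noise realization per subject (for
    test-retest designs).
    """
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    subjects = []
    truth = None
    for i in range(spec.n_subjects):
        tract, bold, truth = generate_phantom(spec, subject_offset + i, session)
        subjects.append((tract, bold))
    return subjects, truth


def generate_term_library(
    truth: PhantomTruth,
    grid: VolumeGrid,
    n_signal: int,
    n_noise: int,
    smooth_fwhm_mm: float,
    seed: int,
    signal_noise: float = 0.3,
) -> tuple[dict[str, np.ndarray], BundleMask]:
    """Named 3-D term maps plus a grey-matter mask.

    Signal terms are noisy affine transforms of one cluster's inverse-distance
    map (so a zero-noise signal term correlates perfectly with its source);
    noise terms are Gaussian random fields smoothed to the same FWHM. The GM
    mask covers the endpoint patches, dilated by two voxels.
    """
    if smooth_fwhm_mm < 0:
        raise ValueError("smooth_fwhm_mm must be >= 0")
    if n_signal < 0 or n_noise < 0:
        raise ValueError("term counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    sigma_vox = smooth_fwhm_mm / 2.3548 / grid.voxel_sizes

    def smooth_field():
        f = rng.standard_normal(grid.shape)
        if smooth_fwhm_mm > 0:
            f = gaussian_filter(f, sigma=sigma_vox, mode="nearest")
        sd = f.std()
        return (f - f.mean()) / (sd if sd > 0 else 1.0)

    centers = grid.all_centers_mm()
    n_clusters = truth.cluster_centroids_mm.shape[0]
    library: dict[str, np.ndarray] = {}
    for i in range(n_signal):
        centroid = truth.cluster_centroids_mm[i % n_clusters]
        d = np.linalg.norm(centers - centroid, axis=1).reshape(grid.shape)
        idm = 1.0 / (1.0 + d)
        base = (idm - idm.mean()) / idm.std()
        library[f"signal term {i}"] = base + signal_noise * smooth_field()
    for j in range(n_noise):
        library[f"noise term {j:02d}"] = smooth_field()

    gm = np.zeros(grid.shape, dtype=bool)
    ev = truth.endpoint_voxels
    gm[ev[:, 0], ev[:, 1], ev[:, 2]] = True
    gm = binary_dilation(gm, iterations=2)
    return library, BundleMask(gm, grid)


# ---------------------------------------------------------------------------
# On-disk phantom (NIfTI / TCK / TSV / JSON)
# ---------------------------------------------------------------------------

def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> None:
    """Write the full cohort plus truth and term library to a directory."""
    from .imaging import write_tractogram, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = spec.make_grid()
    subjects, truth = generate_cohort(spec)
    for i, (tract, bold) in enumerate(subjects):
        write_volume(out / f"sub-{i:02d}_bold.nii.gz", bold.data, grid)
        write_tractogram(out / f"sub-{i:02d}_bundle.tck", tract)
    write_volume(out / "truth_labels.nii.gz", truth.bundle_label_per_voxel, grid)
    sidecar = {
        "tr_s": spec.tr_s,
        "n_subjects": spec.n_subjects,
        "seed": spec.seed,
        "mode_timecourses": truth.mode_timecourses.tolist(),
        "cluster_centroids_mm": truth.cluster_centroids_mm.tolist(),
        "bundle_label_per_streamline": truth.bundle_label_per_streamline.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    library, gm = generate_term_library(
        truth, grid, n_signal=spec.n_bundles, n_noise=40, smooth_fwhm_mm=3 * spec.voxel_size_mm,
        seed=spec.seed,
    )
    terms = out / "terms"
    terms.mkdir(exist_ok=True)
    rows = ["term\tfilename"]
    for k, (name, vol) in enumerate(library.items()):
        fname = f"term_{k:03d}.nii.gz"
        write_volume(terms / fname, vol, grid)
        rows.append(f"{name}\t{fname}")
    (terms / "manifest.tsv").write_text("\n".join(rows) + "\n")
    write_volume(out / "gm_mask.nii.gz", gm.data.astype(np.float32), grid)
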