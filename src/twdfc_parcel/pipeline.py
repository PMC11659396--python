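"""End-to-end orchestration: phantom -> tw-dFC -> group ICA -> k selection
-> parcellation -> decoding, with seeding and JSON provenance.

The pipeline operates on one bundle per run (a bilateral study simply runs it
once per hemisphere from config). All stages are pure functions of the config
and its seeds; the report is reproducible byte-for-byte under fixed seeds.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .decoding import decode_clusters
from .gica import group_ica_pipeline, mean_timecourse_correlation, standardize_voxels
from .imaging import BundleMask, group_bundle_mask
from .model_selection import dimensionality_report
from .parcellation import parcellate
from .phantom import (
    PhantomSpec,
    generate_cohort,
    generate_term_library,
    windowed_modes,
)
from .twdfc import WindowSpec, compute_static_tw, compute_twdfc, window_length_from_seconds


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    window_s: float = 40.0
    k_values: tuple[int, ...] = (2, 3, 4, 5)
    c_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_pc: int = 50
    br_method: str = "dual-regression"
    inclusion_fraction: float = 0.75
    n_surrogates: int = 500
    n_signal_terms: int = 3
    n_noise_terms: int = 40
    term_smooth_fwhm_mm: float = 6.0
    run_decoding: bool = True
    use_retest: bool = True
    use_cross_cohort: bool = True
    use_static: bool = True
    seed: int = 0

    def window_spec(self, tr_s: float) -> WindowSpec:
        return WindowSpec(window_length_from_seconds(self.window_s, tr_s))


def cohort_matrices(
    subjects, window: WindowSpec, inclusion_fraction: float = 0.75
):
    """Per-subject standardized (n_windows, V) matrices over the group mask.

    The group mask keeps voxels traversed in >= inclusion_fraction of
    subjects and with nonzero tw-dFC variance in every subject.
    """
    series = [compute_twdfc(bold, tract, window) for tract, bold in subjects]
    gmask = group_bundle_mask([s.mask for s in series], inclusion_fraction)
    m = gmask.data.copy()
    for s in series:
        vals = s.data[m]
        finite = np.all(np.isfinite(vals), axis=1)
        sd = np.where(finite, np.where(np.isfinite(vals), vals, 0.0).std(axis=1), 0.0)
        bad = ~finite | (sd <= 0)
        if bad.any():
            mm = np.argwhere(m)[bad]
            m[mm[:, 0], mm[:, 1], mm[:, 2]] = False
    mask = BundleMask(m, series[0].grid)
    mats = [standardize_voxels(s.data[m].T) for s in series]
    return mats, mask, series


def matrices_on_mask(subjects, window: WindowSpec, mask: BundleMask):
    """Standardized tw-dFC matrices for a cohort on a *fixed* voxel support.

    Voxels of the reference mask that a subject's bundle does not traverse
    (possible when the mask comes from another cohort or session) carry no
    signal and are zero-filled.
    """
    mats = []
    for tract, bold in subjects:
        s = compute_twdfc(bold, tract, window)
        vals = s.data[mask.data].T
        vals = np.where(np.isfinite(vals), vals, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-filled voxels are expected here
            mats.append(standardize_voxels(vals))
    return mats


def static_matrices(subjects, mask: BundleMask):
    """Standardized static track-weighted matrices on a fixed voxel support."""
    mats = []
    for tract, bold in subjects:
        vol = compute_static_tw(bold, tract)
        vals = vol[mask.data].T  # (T, V)
        vals = np.where(np.isfinite(vals), vals, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mats.append(standardize_voxels(vals))
    return mats


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full phantom-driven pipeline; returns the report dict."""
    t0 = time.time()
    spec = config.phantom
    grid = spec.make_grid()
    window = config.window_spec(spec.tr_s)

    subjects, truth = generate_cohort(spec)
    mats, mask, _ = cohort_matrices(subjects, window, config.inclusion_fraction)

    retest_pair = None
    if config.use_retest:
        retest_subjects, _ = generate_cohort(spec, session=1)
        retest_pair = (mats, matrices_on_mask(retest_subjects, window, mask))

    second = None
    if config.use_cross_cohort:
        cohort_b, _ = generate_cohort(spec, subject_offset=spec.n_subjects)
        second = matrices_on_mask(cohort_b, window, mask)

    static = static_matrices(subjects, mask) if config.use_static else None

    report_ms = dimensionality_report(
        mats,
        list(config.k_values),
        config.seed,
        retest_pair=retest_pair,
        second_cohort=second,
        static=static,
        n_pc=config.n_pc,
        method=config.br_method,
    )
    chosen_k = report_ms.chosen_k

    components = group_ica_pipeline(
        mats, chosen_k, config.seed + 7, n_pc=config.n_pc, method=config.br_method,
        mask=mask,
    )
    tc_corr = mean_timecourse_correlation(components) if chosen_k >= 2 else None

    mask_voxels = np.argwhere(mask.data)
    parc = parcellate(
        components, grid, mask_voxels, c_range=list(config.c_range),
        seed=config.seed + 13,
    )

    truth_labels = truth.bundle_label_per_voxel[mask.data]
    from sklearn.metrics import adjusted_rand_score

    ari = float(adjusted_rand_score(truth_labels, parc.labels))

    # component time courses vs ground-truth latent modes
    modes_w = windowed_modes(truth, window)
    from .model_selection import match_components

    tc_stack = np.mean(components.subject_timecourses, axis=0)
    mode_match = None
    if tc_stack.shape[0] == modes_w.shape[0]:
        _, mode_match = match_components(tc_stack, modes_w)

    report = {
        "version": __version__,
        "seed": config.seed,
        "phantom_seed": spec.seed,
        "window_length_tp": window.length_tp,
        "n_mask_voxels": int(mask.n_voxels),
        "k_values": list(config.k_values),
        "metrics": {
            name: {str(k): v for k, v in vals.items()}
            for name, vals in report_ms.metrics().items()
        },
        "chosen_k": chosen_k,
        "mean_timecourse_corr": tc_corr,
        "mode_match_abs_r": mode_match,
        "silhouette_by_c": {str(c): s for c, s in parc.silhouette_by_c.items()},
        "chosen_c": parc.c,
        "parcellation_ari": ari,
        "cluster_centroids_mm": parc.centroids_mm.tolist(),
    }

    if config.run_decoding:
        library, gm = generate_term_library(
            truth,
            grid,
            n_signal=config.n_signal_terms,
            n_noise=config.n_noise_terms,
            smooth_fwhm_mm=config.term_smooth_fwhm_mm,
            seed=spec.seed,
        )
        template_tract = subjects[0][0]
        decode = decode_clusters(
            parc.centroids_mm,
            library,
            template_tract,
            gm,
            mask,
            grid,
            n_surrogates=config.n_surrogates,
            seed=config.seed + 29,
        )
        sig = decode[decode["term"].str.startswith("signal")]
        report["decoding"] = {
            "n_pairs": int(len(decode)),
            "n_terms": int(decode["term"].nunique()),
            "n_signal_significant": int(
                (sig.sort_values("r", ascending=False).groupby("term").head(1)["p_adj"] < 0.05).sum()
            ),
            "max_signal_r": float(sig["r"].max()) if len(sig) else None,
        }
    else:
        decode = None

    report["runtime_s"] = round(time.time() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .imaging import write_volume

        write_volume(out / "parcellation.nii.gz", parc.labels_volume, grid)
        zvol = np.full(grid.shape + (components.k,), np.nan)
        zvol[mask.data] = components.group_zmaps.T
        write_volume(out / "component_zmaps.nii.gz", np.nan_to_num(zvol), grid)
        if decode is not None:
            decode.to_csv(out / "decoding.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
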