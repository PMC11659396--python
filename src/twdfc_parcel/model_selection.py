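"""Data-driven choice of the ICA model order k.

Five measures are computed for each candidate k: split-half similarity,
test-retest similarity, cross-cohort similarity, similarity to a static
track-weighted ICA, and the mean pairwise component time-course correlation
(lower is better, read as temporal independence). The consensus rule picks
the k preferred by the most measures, breaking ties toward the smaller k.

All spatial similarities are mean matched absolute Pearson correlations
between group z-maps: components of two runs are paired one-to-one by the
Hungarian algorithm on |r|, which makes the measure invariant to ICA sign
and order indeterminacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gica import group_ica_pipeline, mean_timecourse_correlation


@dataclass
class SimilarityReport:
    k_values: list[int]
    split_half: dict[int, float] = field(default_factory=dict)
    test_retest: dict[int, float] = field(default_factory=dict)
    cross_cohort: dict[int, float] = field(default_factory=dict)
    static_similarity: dict[int, float] = field(default_factory=dict)
    timecourse_corr: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None

    def metrics(self) -> dict[str, dict[int, float]]:
        return {
            "split_half": self.split_half,
            "test_retest": self.test_retest,
            "cross_cohort": self.cross_cohort,
            "static_similarity": self.static_similarity,
            "timecourse_corr": self.timecourse_corr,
        }


def match_components(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal one-to-one component pairing maximizing total |r|.

    Returns (assignment, mean matched |r|): assignment[i] is the row of B
    paired with row i of A.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"component sets differ in shape: {A.shape} vs {B.shape}")
    k = A.shape[0]
    Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    C = np.abs(Az @ Bz.T) / A.shape[1]
    rows, cols = linear_sum_assignment(-C)
    assignment = np.empty(k, dtype=int)
    assignment[rows] = cols
    return assignment, float(C[rows, cols].mean())


def split_half_similarity(
    subject_matrices: list[np.ndarray], k: int, seed: int, **ica_kw
) -> float:
    """Group ICA on two random halves of the cohort; matched map similarity.

    With an odd cohort one random subject is dropped.
    """
    n = len(subject_matrices)
    if n < 4:
        raise ValueError("need at least 4 subjects for a split-half estimate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if n % 2:
        order = order[:-1]
    half = len(order) // 2
    cs1 = group_ica_pipeline([subject_matrices[i] for i in order[:half]], k, seed, **ica_kw)
    cs2 = group_ica_pipeline([subject_matrices[i] for i in order[half:]], k, seed + 1, **ica_kw)
    return match_components(cs1.group_zmaps, cs2.group_zmaps)[1]


def test_retest_similarity(
    test_matrices: list[np.ndarray],
    retest_matrices: list[np.ndarray],
    k: int,
    seed: int,
    **ica_kw,
) -> float:
    """Matched similarity of group maps from paired test and retest sessions."""
    if len(test_matrices) != len(retest_matrices):
        raise ValueError("test and retest cohorts must be paired (same subjects)")
    cs1 = group_ica_pipeline(test_matrices, k, seed, **ica_kw)
    cs2 = group_ica_pipeline(retest_matrices, k, seed + 1, **ica_kw)
    return match_components(cs1.group_zmaps, cs2.group_zmaps)[1]


def cross_cohort_similarity(
    cohort_a: list[np.ndarray], cohort_b: list[np.ndarray], k: int, seed: int, **ica_kw
) -> float:
    """Matched similarity of group maps from two independent cohorts."""
    cs1 = group_ica_pipeline(cohort_a, k, seed, **ica_kw)
    cs2 = group_ica_pipeline(cohort_b, k, seed + 1, **ica_kw)
    return match_components(cs1.group_zmaps, cs2.group_zmaps)[1]


def static_similarity(
    dynamic_matrices: list[np.ndarray],
    static_matrices: list[np.ndarray],
    k: int,
    seed: int,
    **ica_kw,
) -> float:
    """Similarity between tw-dFC ICA maps and static track-weighted ICA maps."""
    cs_dyn = group_ica_pipeline(dynamic_matrices, k, seed, **ica_kw)
    cs_sta = group_ica_pipeline(static_matrices, k, seed + 1, **ica_kw)
    return match_components(cs_dyn.group_zmaps, cs_sta.group_zmaps)[1]


def select_k(report: SimilarityReport) -> int:
    """Consensus model order: the k most metrics prefer.

    Spatial-similarity metrics vote for their argmax; the time-course
    correlation votes for its argmin (lower correlation = more independent).
    Vote ties break toward the smaller k.
    """
    votes: list[int] = []
    for name, values in report.metrics().items():
        if not values:
            continue
        ks = sorted(values)
        scores = np.array([values[k] for k in ks])
        if name == "timecourse_corr":
            scores = -scores
        best = max(scores)
        votes.append(min(k for k, s in zip(ks, scores) if s == best))
    if not votes:
        raise ValueError("no metrics available")
    counts: dict[int, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == top)
    report.chosen_k = chosen
    return chosen


def dimensionality_report(
    primary: list[np.ndarray],
    k_values: list[int],
    seed: int,
    retest_pair: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
    second_cohort: list[np.ndarray] | None = None,
    static: list[np.ndarray] | None = None,
    **ica_kw,
) -> SimilarityReport:
    """All available similarity metrics across candidate k values."""
    report = SimilarityReport(k_values=list(k_values))
    for i, k in enumerate(k_values):
        s = seed + 100 * i
        report.split_half[k] = split_half_similarity(primary, k, s, **ica_kw)
        if retest_pair is not None:
            report.test_retest[k] = test_retest_similarity(
                retest_pair[0], retest_pair[1], k, s + 10, **ica_kw
            )
        if second_cohort is not None:
            report.cross_cohort[k] = cross_cohort_similarity(
                primary, second_cohort, k, s + 20, **ica_kw
            )
        if static is not None:
            report.static_similarity[k] = static_similarity(
                primary, static, k, s + 30, **ica_kw
            )
        cs = group_ica_pipeline(primary, k, s + 40, **ica_kw)
        if k >= 2:
            report.timecourse_corr[k] = mean_timecourse_correlation(cs)
    select_k(report)
    return report
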