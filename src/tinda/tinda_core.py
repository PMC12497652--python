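"""Fractional-occupancy asymmetry: interval halving and group edge statistics.

For each reference state ``m``, every inter-state interval (the span strictly
between two successive visits of ``m``) is split evenly in half.  The
asymmetry ``A[m, n]`` is the mean, over ``m``'s intervals, of the fractional
occupancy of state ``n`` in the first half minus the second half.  A positive
entry means ``n`` tends to follow ``m``; a negative entry means it tends to
precede it.  Because the states are mutually exclusive and the reference
state never occurs strictly inside its own intervals, every row of ``A`` sums
to zero and ``A[m, m] = 0``.

Group-level inference tests each off-diagonal edge against zero with a
two-tailed one-sample t-test across subjects, Bonferroni-corrected over the
``K² − K`` edges, and summarizes significant edges in a signed edge matrix
``E`` (+1 significant positive, −1 significant negative, 0 otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .statecourse_io import (
    IntervalSet,
    StateCourseError,
    StateTimeCourse,
    extract_intervals,
)

__all__ = [
    "AsymmetryMatrix",
    "GroupAsymmetry",
    "split_interval_halves",
    "compute_fo_asymmetry",
    "asymmetry_from_intervals",
    "segment_restricted_asymmetry",
    "group_asymmetry_test",
]


@dataclass
class AsymmetryMatrix:
    """Per-subject K×K fractional-occupancy asymmetry.

    Rows belonging to reference states with no usable interval are NaN
    (undefined), never silently zero.
    """

    A: np.ndarray
    n_intervals_used: np.ndarray
    subject_id: str = ""

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def defined_rows(self) -> np.ndarray:
        return self.n_intervals_used > 0


@dataclass
class GroupAsymmetry:
    """Cohort-level edge statistics and the signed edge matrix E."""

    mean_A: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    alpha: float
    E: np.ndarray
    n_subjects: int
    n_tests: int


def split_interval_halves(span: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Equal contiguous halves of a half-open span; ``None`` if too short.

    Odd-length spans drop the single middle sample so that both halves have
    exactly ``duration // 2`` samples.
    """
    a, b = span
    d = b - a
    if d < 2:
        return None
    h = d // 2
    return (a, a + h), (b - h, b)


def _half_occupancy_diffs(cum: np.ndarray, ivs: IntervalSet) -> np.ndarray:
    """(n_usable, K) matrix of first-half minus second-half FO per interval."""
    t1, t2 = ivs.halves()
    h = (t1[:, 1] - t1[:, 0]).astype(float)[:, None]
    fo1 = (cum[t1[:, 1]] - cum[t1[:, 0]]) / h
    fo2 = (cum[t2[:, 1]] - cum[t2[:, 0]]) / h
    return fo1 - fo2


def _cumulative_counts(labels: np.ndarray, K: int) -> np.ndarray:
    """(T+1, K) cumulative per-state sample counts; row t counts samples < t."""
    onehot = np.zeros((labels.size + 1, K))
    onehot[np.arange(1, labels.size + 1), labels - 1] = 1.0
    return np.cumsum(onehot, axis=0)


def asymmetry_from_intervals(
    stc: StateTimeCourse,
    interval_sets: list[IntervalSet],
    weight_by_duration: bool = False,
) -> AsymmetryMatrix:
    """Asymmetry matrix from explicitly supplied per-state interval sets.

    The workhorse behind :func:`compute_fo_asymmetry`; exposed so that
    restricted analyses (duration bins, task segments) can feed filtered
    intervals through the identical computation.
    """
    K = stc.K
    if len(interval_sets) != K:
        raise StateCourseError(f"expected {K} interval sets, got {len(interval_sets)}")
    cum = _cumulative_counts(stc.labels, K)
    A = np.full((K, K), np.nan)
    n_used = np.zeros(K, dtype=np.int64)
    for ivs in interval_sets:
        m = ivs.reference_state - 1
        usable = ivs.usable
        if not usable.any():
            continue
        diffs = _half_occupancy_diffs(cum, ivs)
        if weight_by_duration:
            w = ivs.durations[usable].astype(float)
            A[m] = (diffs * w[:, None]).sum(axis=0) / w.sum()
        else:
            A[m] = diffs.mean(axis=0)
        A[m, m] = 0.0  # exact: reference never occurs inside its own intervals
        n_used[m] = int(usable.sum())
    return AsymmetryMatrix(A=A, n_intervals_used=n_used, subject_id=stc.subject_id)


def compute_fo_asymmetry(
    stc: StateTimeCourse, weight_by_duration: bool = False
) -> AsymmetryMatrix:
    """The TINDA statistic: K×K fractional-occupancy asymmetry for one subject.

    Each interval contributes equally to the row mean regardless of its
    duration (set ``weight_by_duration`` to weight by interval length
    instead).  Rows of states with fewer than two visits are undefined (NaN).
    """
    interval_sets = [extract_intervals(stc, m) for m in range(1, stc.K + 1)]
    return asymmetry_from_intervals(stc, interval_sets, weight_by_duration)


def segment_restricted_asymmetry(
    stc: StateTimeCourse, segments: list[tuple[int, int]]
) -> AsymmetryMatrix:
    """TINDA using only intervals fully inside one of the given segments.

    Used for trial-restricted analyses, e.g. fixed-length epochs preceding a
    behavioural event.  Each segment is scanned independently; intervals can
    never straddle two segments.
    """
    restricted = StateTimeCourse(
        labels=stc.labels,
        fs=stc.fs,
        K=stc.K,
        subject_id=stc.subject_id,
        segment_mask=sorted(segments),
    )
    out = compute_fo_asymmetry(restricted)
    if not out.defined_rows.any():
        warnings.warn(
            f"{stc.subject_id}: no usable interval in any segment", stacklevel=2
        )
    return out


def group_asymmetry_test(
    matrices: list[AsymmetryMatrix],
    alpha_raw: float = 0.05,
    t_threshold: float | None = None,
) -> GroupAsymmetry:
    """Edge-wise group inference over per-subject asymmetry matrices.

    Each off-diagonal edge is tested with a two-tailed one-sample t-test of
    the subject values against zero; the significance level is Bonferroni
    corrected over the ``K² − K`` edges.  Subjects with an undefined entry
    are dropped pairwise for that edge.  Alternatively ``t_threshold``
    declares an edge significant when ``|t|`` exceeds it (the convention used
    for very large cohorts, where a p-based threshold saturates).
    """
    if not matrices:
        raise StateCourseError("no asymmetry matrices supplied")
    K = matrices[0].K
    stack = np.stack([m.A for m in matrices])  # (n_subj, K, K)
    n_defined = np.sum(~np.isnan(stack), axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_A = np.nanmean(stack, axis=0)
        res = stats.ttest_1samp(stack, 0.0, axis=0, nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)

    offdiag = ~np.eye(K, dtype=bool)
    n_tests = K * K - K
    alpha = alpha_raw / n_tests
    # zero across-subject variance or < 3 defined subjects -> undefined, nonsig
    invalid = ~np.isfinite(t) | (n_defined < 3)
    if (invalid & offdiag).any():
        warnings.warn(
            "edges with undefined t-statistic treated as nonsignificant",
            stacklevel=2,
        )
    if t_threshold is not None:
        sig = np.abs(t) > t_threshold
    else:
        sig = p < alpha
    sig = sig & offdiag & ~invalid
    E = np.where(sig, np.sign(mean_A).astype(int), 0)
    np.fill_diagonal(E, 0)
    np.fill_diagonal(t, 0.0)
    np.fill_diagonal(p, 1.0)
    return GroupAsymmetry(
        mean_A=mean_A,
        t_stats=t,
        p_values=p,
        alpha=alpha,
        E=E,
        n_subjects=len(matrices),
        n_tests=n_tests,
    )
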