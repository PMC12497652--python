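"""Cycle duration and rate via a constrained sequential Poisson decoder.

The cycle is summarized at a coarser level by grouping the K states into
four *metastates* — contiguous quadrant arcs of the circle layout.  A
per-sample feature counts state-visit onsets inside a sliding window of
roughly one mean state lifetime; a four-state hidden Markov chain with
Poisson emissions on that count, transitions restricted to self-loops and
single forward steps (1→2→3→4→1), and a per-sample prior derived from the
circle-space distance of the active state to each metastate centroid is then
decoded by max-product dynamic programming, deliberately without training to
convergence so the decoded path keeps the cycle's definition.  A completed
cycle is the span between successive entries into metastate 1; its inverse
mean is the cycle rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .cycle_analysis import CircleLayout
from .statecourse_io import StateTimeCourse, mean_lifetimes

__all__ = [
    "VisitCountFeature",
    "MetastateModel",
    "visit_count_feature",
    "quadrant_assignment",
    "initialize_state_probs",
    "decode_metastates",
    "cycle_durations",
    "cycle_rate_analysis",
]

N_META = 4
RATE_FLOOR = 1e-3


@dataclass
class VisitCountFeature:
    """Number of state-visit onsets in a centered sliding window.

    The window length ``w`` (odd, in samples) defaults to the grand-mean
    state lifetime; windows are truncated at the sequence edges.
    """

    counts: np.ndarray
    w: int
    fs: float

    @property
    def w_ms(self) -> float:
        return self.w * 1000.0 / self.fs


@dataclass
class MetastateModel:
    """Fitted/decoded state of the sequential four-metastate Poisson model."""

    membership: np.ndarray        # membership[s-1] in 0..3 for state s
    centroids: np.ndarray         # circular mean phase per metastate
    init_probs: np.ndarray        # (T, 4) per-sample prior
    rates: np.ndarray             # Poisson rate per metastate
    transition: np.ndarray        # (4, 4) row-stochastic, sequential pattern
    path: np.ndarray              # decoded metastate index per sample, 0..3
    fs: float
    w: int

    @property
    def n_meta(self) -> int:
        return N_META


def visit_count_feature(stc: StateTimeCourse, w: int | None = None) -> VisitCountFeature:
    """Sliding-window count of visit onsets.

    An onset is any sample whose label differs from its predecessor (sample 0
    counts as an onset).  Even window lengths are rounded up to the next odd
    value so the window is centered.
    """
    if w is None:
        _, grand_ms = mean_lifetimes(stc)
        w = int(round(grand_ms * stc.fs / 1000.0))
    w = max(int(w), 1)
    if w % 2 == 0:
        w += 1
    if w > stc.T:
        raise ValueError(f"window {w} longer than the sequence ({stc.T})")
    onsets = np.empty(stc.T, dtype=float)
    onsets[0] = 1.0
    onsets[1:] = stc.labels[1:] != stc.labels[:-1]
    counts = np.convolve(onsets, np.ones(w), mode="same")
    return VisitCountFeature(counts=np.rint(counts).astype(np.int64), w=w, fs=stc.fs)


def quadrant_assignment(layout: CircleLayout) -> tuple[np.ndarray, np.ndarray]:
    """Metastate membership and centroid phases from contiguous quadrant arcs.

    The K circle positions are split into four contiguous arcs starting at
    phase 0 (nearest-equal sizes when K is not divisible by 4, with a
    warning).  The centroid of an arc is the circular mean of its member
    phases.
    """
    K = layout.K
    if K < N_META:
        raise ValueError(f"quadrant assignment requires K >= {N_META}, got {K}")
    if K % N_META != 0:
        warnings.warn(
            f"K={K} not divisible by {N_META}; using nearest-equal arcs",
            stacklevel=2,
        )
    arcs = np.array_split(np.arange(K), N_META)
    positions = layout.positions
    phases = layout.phases
    membership = np.empty(K, dtype=np.int64)
    centroids = np.empty(N_META)
    for a, arc in enumerate(arcs):
        for pos in arc:
            membership[positions == pos] = a
        arc_phases = 2.0 * np.pi * arc / K
        centroids[a] = np.angle(np.exp(1j * arc_phases).mean()) % (2.0 * np.pi)
    return membership, centroids


def _circular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % (2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


def initialize_state_probs(
    stc: StateTimeCourse, layout: CircleLayout, tau: float = 1.0
) -> np.ndarray:
    """(T, 4) soft metastate probabilities from circle-space distance.

    For each sample the circular distance from the active state's phase to
    each metastate centroid is mapped through ``exp(−d/τ)`` and normalized;
    τ (radians) controls how sharply probability concentrates on the nearest
    metastate (τ→0 gives a one-hot assignment).
    """
    _, centroids = quadrant_assignment(layout)
    phases = layout.phases  # per state
    d = _circular_distance(phases[:, None], centroids[None, :])  # (K, 4)
    logits = -d / tau
    probs_per_state = np.exp(logits - special.logsumexp(logits, axis=1, keepdims=True))
    return probs_per_state[stc.labels - 1]


_SEQ_NEXT = (np.arange(N_META) + 1) % N_META


def _sequential_log_transition(p_stay: float) -> np.ndarray:
    logT = np.full((N_META, N_META), -np.inf)
    logT[np.arange(N_META), np.arange(N_META)] = np.log(p_stay)
    logT[np.arange(N_META), _SEQ_NEXT] = np.log1p(-p_stay)
    return logT


def _viterbi_sequential(loglik: np.ndarray, p_stay: float) -> np.ndarray:
    """Max-product path under the stay/advance-one transition structure."""
    T = loglik.shape[0]
    log_stay = np.log(p_stay)
    log_adv = np.log1p(-p_stay)
    delta = np.full(N_META, np.log(1.0 / N_META)) + loglik[0]
    back = np.empty((T, N_META), dtype=np.int8)
    for t in range(1, T):
        stay = delta + log_stay
        adv = delta[(np.arange(N_META) - 1) % N_META] + log_adv
        take_adv = adv > stay
        delta = np.where(take_adv, adv, stay) + loglik[t]
        back[t] = np.where(take_adv, (np.arange(N_META) - 1) % N_META,
                           np.arange(N_META))
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_metastates(
    feature: VisitCountFeature,
    init_probs: np.ndarray,
    layout: CircleLayout,
    p_stay: float = 0.95,
    n_em: int = 0,
    tiny: float = 1e-12,
) -> MetastateModel:
    """Decode the most-probable sequential metastate path.

    Poisson rates are initialized as the prior-weighted mean count per
    metastate; the emission log-likelihood at each sample is the Poisson
    log-pmf of the visit count plus the log of the circle-distance prior.
    At most ``n_em`` re-estimation sweeps are run (0 by default: the model is
    decoded without training to convergence, so the decoded path cannot
    drift away from the cycle definition it was initialized with).
    """
    if not 0.0 < p_stay < 1.0:
        raise ValueError("p_stay must be in (0, 1)")
    if n_em not in (0, 1):
        raise ValueError("n_em must be 0 or 1")
    counts = feature.counts.astype(float)
    init_probs = np.asarray(init_probs, dtype=float)
    if init_probs.shape != (counts.size, N_META):
        raise ValueError("init_probs must be (T, 4)")

    weights = init_probs / init_probs.sum(axis=0, keepdims=True)
    rates = weights.T @ counts
    if np.any(rates <= 0):
        warnings.warn("zero visit-count rate floored", stacklevel=2)
        rates = np.maximum(rates, RATE_FLOOR)

    membership, centroids = quadrant_assignment(layout)
    log_prior = np.log(init_probs + tiny)

    def run(rts: np.ndarray) -> np.ndarray:
        logpmf = (
            counts[:, None] * np.log(rts)[None, :]
            - rts[None, :]
            - special.gammaln(counts + 1.0)[:, None]
        )
        return _viterbi_sequential(logpmf + log_prior, p_stay)

    path = run(rates)
    for _ in range(n_em):
        new_rates = np.array(
            [counts[path == k].mean() if np.any(path == k) else RATE_FLOOR
             for k in range(N_META)]
        )
        rates = np.maximum(new_rates, RATE_FLOOR)
        path = run(rates)

    return MetastateModel(
        membership=membership,
        centroids=centroids,
        init_probs=init_probs,
        rates=rates,
        transition=np.exp(_sequential_log_transition(p_stay)),
        path=path,
        fs=feature.fs,
        w=feature.w,
    )


def cycle_durations(model: MetastateModel) -> tuple[np.ndarray, float, float]:
    """Completed-cycle durations (ms), their mean, and the cycle rate (Hz).

    A completed cycle is the span between successive entries into metastate 1
    (index 0); the sequential transition structure guarantees metastates
    2, 3 and 4 are traversed in order within it.  Partial head/tail cycles
    are discarded.  With no completed cycle the duration and rate are NaN,
    with a warning.
    """
    path = model.path
    entries = np.flatnonzero((path == 0) & (np.r_[True, path[1:] != path[:-1]]))
    # the first entry may be the start of the recording mid-cycle; diffs only
    if entries.size < 2:
        warnings.warn("no completed cycle in decoded path", stacklevel=2)
        return np.empty(0), float("nan"), float("nan")
    durations_ms = np.diff(entries) * 1000.0 / model.fs
    mean_ms = float(durations_ms.mean())
    return durations_ms, mean_ms, 1000.0 / mean_ms


def cycle_rate_analysis(
    stc: StateTimeCourse,
    layout: CircleLayout,
    w: int | None = None,
    tau: float = 1.0,
    p_stay: float = 0.95,
    n_em: int = 0,
) -> dict:
    """One-call cycle-rate pipeline for a single subject.

    Returns a JSON-ready summary with the window, Poisson rates, mean cycle
    duration (ms) and cycle rate (Hz).
    """
    feature = visit_count_feature(stc, w)
    init = initialize_state_probs(stc, layout, tau=tau)
    model = decode_metastates(feature, init, layout, p_stay=p_stay, n_em=n_em)
    durations, mean_ms, rate_hz = cycle_durations(model)
    return {
        "subject_id": stc.subject_id,
        "w_samples": model.w,
        "w_ms": feature.w_ms,
        "poisson_rates": model.rates.tolist(),
        "p_stay": p_stay,
        "tau": tau,
        "n_completed_cycles": int(durations.size),
        "mean_cycle_duration_ms": mean_ms,
        "cycle_rate_hz": rate_hz,
        "model": model,
    }
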