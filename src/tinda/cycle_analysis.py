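"""Cycle geometry and inference on the asymmetry graph.

The K×K asymmetry matrix is read as a weighted directed graph.  Placing the
states at equally spaced phases ``q`` on the unit circle, each directed edge
projects onto the tangential direction with weight ``sin(q_m − q_n)``; the
normalized tangential sum is the cycle strength

    S = −β · Σ_{m≠n} A[m, n] · sin(q_m − q_n),

where β is one over the theoretical maximum of the raw sum (attained by a
matrix with perfect +1 asymmetry on every clockwise pair and −1 on every
counterclockwise pair), so that S ∈ [−1, 1]: +1 is a perfectly clockwise
cycle, 0 a fully stochastic graph.  The state-to-position assignment is
optimized to maximize S — exhaustively for small K, by multi-restart
simulated annealing otherwise — and significance is assessed with a
label-shuffle permutation test that re-runs the full optimization on each
permuted cohort.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .tinda_core import AsymmetryMatrix, GroupAsymmetry

__all__ = [
    "CircleLayout",
    "CycleStrengthResult",
    "PermutationNull",
    "PhaseComparison",
    "StateMatching",
    "normalization_beta",
    "cycle_strength",
    "optimize_ordering",
    "permutation_test_cycle_strength",
    "phase_difference",
    "match_states",
    "export_circle_graph",
    "circle_graph_document",
    "load_circle_graph",
]

EXHAUSTIVE_K_MAX = 8


@dataclass
class CircleLayout:
    """An assignment of the K states to equally spaced phases on the circle.

    ``ordering[i]`` is the (1-based) state at position ``i``; position ``i``
    carries phase ``2π·i/K``.  Rotation and reflection of the circle are
    gauge freedoms; the canonical form puts state 1 at phase 0.
    """

    ordering: np.ndarray

    def __post_init__(self) -> None:
        self.ordering = np.asarray(self.ordering, dtype=np.int64)
        if sorted(self.ordering.tolist()) != list(range(1, self.K + 1)):
            raise ValueError("ordering must be a permutation of 1..K")

    @property
    def K(self) -> int:
        return int(self.ordering.size)

    @property
    def positions(self) -> np.ndarray:
        """positions[s-1] = circle position of state s."""
        pos = np.empty(self.K, dtype=np.int64)
        pos[self.ordering - 1] = np.arange(self.K)
        return pos

    @property
    def phases(self) -> np.ndarray:
        """phases[s-1] = phase (radians) of state s."""
        return 2.0 * np.pi * self.positions / self.K

    @property
    def beta(self) -> float:
        return normalization_beta(self.K)

    def canonical(self) -> "CircleLayout":
        """Rotate so the lowest-numbered state sits at phase 0."""
        i = int(np.argmin(self.ordering))
        return CircleLayout(np.roll(self.ordering, -i))

    def reflected(self) -> "CircleLayout":
        """Reverse the cycle orientation (negates S)."""
        return CircleLayout(self.ordering[::-1]).canonical()

    @classmethod
    def identity(cls, K: int) -> "CircleLayout":
        return cls(np.arange(1, K + 1))


@dataclass
class CycleStrengthResult:
    """Per-subject and group cycle strength at one layout."""

    S_per_subject: np.ndarray
    layout: CircleLayout

    @property
    def S_group(self) -> float:
        return float(np.nanmean(self.S_per_subject))


@dataclass
class PermutationNull:
    """Observed statistic, permutation null and add-one p-value."""

    observed: float
    null_values: np.ndarray
    seed: int | None
    scheme: str

    @property
    def n_perm(self) -> int:
        return int(self.null_values.size)

    @property
    def p(self) -> float:
        return (1 + int(np.sum(self.null_values >= self.observed))) / (self.n_perm + 1)


@dataclass
class PhaseComparison:
    """Mean absolute circular phase difference between two matched layouts."""

    delta_theta: float
    null_values: np.ndarray
    seed: int | None

    @property
    def p(self) -> float:
        """One-sided: probability of a Δθ this small under random placement."""
        n = self.null_values.size
        return (1 + int(np.sum(self.null_values <= self.delta_theta))) / (n + 1)


@dataclass
class StateMatching:
    """Optimal bijection between two equally sized state sets."""

    assignment: np.ndarray  # assignment[i] = matched 0-based index of row i
    total_cost: float

    def matched_state(self, state: int) -> int:
        """1-based partner of a 1-based state."""
        return int(self.assignment[state - 1]) + 1


# ---------------------------------------------------------------------------
# Cycle strength
# ---------------------------------------------------------------------------

def _tangential_weights(K: int) -> np.ndarray:
    """sin(q_i − q_j) for positions i, j on the K-circle."""
    q = 2.0 * np.pi * np.arange(K) / K
    return np.sin(q[:, None] - q[None, :])


def normalization_beta(K: int) -> float:
    """1 / (theoretical maximum raw cycle sum) for K equally spaced states.

    The maximum is attained by perfect +1 asymmetry on every clockwise pair
    and −1 on every counterclockwise pair, i.e. Σ_{m≠n} |sin(q_m − q_n)|.
    For K = 2 every phase difference is π and the maximum is 0, so the
    normalization is undefined.
    """
    if K < 3:
        raise ValueError(f"cycle strength requires K >= 3 states, got K={K}")
    raw_max = np.abs(_tangential_weights(K)).sum()
    return 1.0 / raw_max


def _coerce_matrix(A: AsymmetryMatrix | np.ndarray) -> np.ndarray:
    M = A.A if isinstance(A, AsymmetryMatrix) else np.asarray(A, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("asymmetry matrix must be square")
    if np.isnan(M).any():
        warnings.warn("undefined asymmetry entries treated as 0", stacklevel=3)
        M = np.nan_to_num(M, nan=0.0)
    return M


def cycle_strength(A: AsymmetryMatrix | np.ndarray, layout: CircleLayout) -> float:
    """Evaluate S for a given matrix and circle layout.

    Positive S means net flow in the direction of increasing phase
    (clockwise in the circle plots).
    """
    M = _coerce_matrix(A)
    K = M.shape[0]
    if layout.K != K:
        raise ValueError(f"layout has K={layout.K} but matrix has K={K}")
    order0 = layout.ordering - 1
    sin_pos = _tangential_weights(K)
    return float(-layout.beta * np.sum(M[np.ix_(order0, order0)] * sin_pos))


# ---------------------------------------------------------------------------
# Ordering optimization
# ---------------------------------------------------------------------------

def _score_orderings(M: np.ndarray, orderings0: np.ndarray, sin_pos: np.ndarray,
                     beta: float) -> np.ndarray:
    """Vectorized S for a batch of 0-based orderings, shape (n, K)."""
    perm = M[orderings0[:, :, None], orderings0[:, None, :]]
    return -beta * np.einsum("nij,ij->n", perm, sin_pos)


def _exhaustive(M: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    sin_pos = _tangential_weights(K)
    beta = normalization_beta(K)
    rest = list(range(1, K))
    best_s = -np.inf
    best = None
    batch: list[tuple[int, ...]] = []
    # state 1 pinned at position 0: rotations of the circle are a gauge freedom
    for perm in itertools.permutations(rest):
        batch.append((0,) + perm)
        if len(batch) == 4096:
            arr = np.array(batch)
            scores = _score_orderings(M, arr, sin_pos, beta)
            i = int(np.argmax(scores))
            if scores[i] > best_s:
                best_s, best = float(scores[i]), arr[i]
            batch = []
    if batch:
        arr = np.array(batch)
        scores = _score_orderings(M, arr, sin_pos, beta)
        i = int(np.argmax(scores))
        if scores[i] > best_s:
            best_s, best = float(scores[i]), arr[i]
    return best, best_s


def _anneal_once(M: np.ndarray, K: int, rng: np.random.Generator,
                 n_iter: int, t_hi: float, t_lo: float) -> tuple[np.ndarray, float]:
    sin_pos = _tangential_weights(K)
    beta = normalization_beta(K)

    def score(order0: np.ndarray) -> float:
        return float(-beta * np.sum(M[np.ix_(order0, order0)] * sin_pos))

    order = rng.permutation(K)
    s = score(order)
    best, best_s = order.copy(), s
    temps = t_hi * (t_lo / t_hi) ** (np.arange(n_iter) / max(n_iter - 1, 1))
    for temp in temps:
        i, j = rng.integers(0, K, size=2)
        cand = order.copy()
        if rng.random() < 0.5:
            cand[i], cand[j] = cand[j], cand[i]
        else:
            lo, hi = (i, j) if i <= j else (j, i)
            cand[lo : hi + 1] = cand[lo : hi + 1][::-1]
        s_cand = score(cand)
        if s_cand >= s or rng.random() < np.exp((s_cand - s) / temp):
            order, s = cand, s_cand
            if s > best_s:
                best, best_s = order.copy(), s
    return best, best_s


def optimize_ordering(
    A: AsymmetryMatrix | np.ndarray,
    method: str = "auto",
    seed: int | np.random.Generator | None = None,
    n_restarts: int = 50,
    n_iter: int | None = None,
    t_hi: float = 0.05,
    t_lo: float = 1e-4,
) -> tuple[CircleLayout, float]:
    """Circle layout maximizing cycle strength, with the attained S.

    Exhaustive over all canonical orderings for ``K <= 8`` (``method='auto'``
    or ``'exhaustive'``); seeded multi-restart simulated annealing with
    position swaps and segment reversals otherwise.  The returned layout is
    canonical (state 1 at phase 0) and its S is never below that of the
    identity ordering.
    """
    M = _coerce_matrix(A)
    K = M.shape[0]
    if K < 3:
        raise ValueError("ordering optimization requires K >= 3")
    if method == "auto":
        method = "exhaustive" if K <= EXHAUSTIVE_K_MAX else "local_search"
    if method == "exhaustive":
        best0, best_s = _exhaustive(M, K)
    elif method == "local_search":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if n_iter is None:
            n_iter = 200 * K
        best0, best_s = None, -np.inf
        for _ in range(n_restarts):
            order0, s = _anneal_once(M, K, rng, n_iter, t_hi, t_lo)
            if s > best_s:
                best0, best_s = order0, s
    else:
        raise ValueError(f"unknown method {method!r}")

    layout = CircleLayout(best0 + 1)
    if best_s < 0:  # reflection is a gauge freedom that negates S
        layout = layout.reflected()
        best_s = -best_s
    layout = layout.canonical()
    identity_s = cycle_strength(M, CircleLayout.identity(K))
    if best_s < identity_s:  # annealing safeguard; cannot happen exhaustively
        layout, best_s = CircleLayout.identity(K), identity_s
    return layout, best_s


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

def permutation_test_cycle_strength(
    cohort: list[AsymmetryMatrix],
    n_perm: int = 1000,
    scheme: str = "reoptimize",
    layout: CircleLayout | None = None,
    seed: int | None = None,
    optimizer: dict | None = None,
) -> PermutationNull:
    """Label-shuffle permutation test of the group-mean cycle strength.

    Each permutation independently relabels the states within every subject
    (conjugating that subject's asymmetry matrix by a random permutation),
    recomputes the group mean, and either re-optimizes the state ordering
    (``scheme='reoptimize'``, as for the headline statistic) or evaluates S
    at a supplied fixed layout (``scheme='fixed_layout'``, as for binned
    analyses).  One-sided add-one p-value: large observed S is significant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(cohort) < 2:
        raise ValueError("permutation test requires at least 2 subjects")
    if scheme not in ("reoptimize", "fixed_layout"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "fixed_layout" and layout is None:
        raise ValueError("scheme='fixed_layout' requires a layout")

    K = cohort[0].K
    stack = np.stack([m.A for m in cohort])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_A = np.nanmean(stack, axis=0)
    opt_kwargs = dict(optimizer or {})
    rng = np.random.default_rng(seed)

    if scheme == "reoptimize":
        _, observed = optimize_ordering(mean_A, seed=rng, **opt_kwargs)
    else:
        observed = cycle_strength(mean_A, layout)

    null = np.empty(n_perm)
    for b in range(n_perm):
        permuted = np.empty_like(stack)
        for s in range(stack.shape[0]):
            pi = rng.permutation(K)
            permuted[s] = stack[s][np.ix_(pi, pi)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_b = np.nanmean(permuted, axis=0)
        mean_b = np.nan_to_num(mean_b, nan=0.0)
        if scheme == "reoptimize":
            _, null[b] = optimize_ordering(mean_b, seed=rng, **opt_kwargs)
        else:
            null[b] = cycle_strength(mean_b, layout)
    return PermutationNull(
        observed=float(observed), null_values=null, seed=seed, scheme=scheme
    )


# ---------------------------------------------------------------------------
# Cross-dataset comparison
# ---------------------------------------------------------------------------

def _circular_abs_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % (2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


def phase_difference(
    layout_a: CircleLayout,
    layout_b: CircleLayout,
    matching: StateMatching | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PhaseComparison:
    """Mean absolute circular phase difference Δθ between matched states.

    The null distribution places layout_b's states at uniformly permuted
    positions; the p-value is the one-sided probability of a Δθ at least
    this small (i.e. of the two cycles agreeing this well by chance).  No
    rotational alignment is applied: both layouts are expected in canonical
    form.
    """
    if layout_a.K != layout_b.K:
        raise ValueError("layouts must share K")
    K = layout_a.K
    qa = layout_a.phases
    qb = layout_b.phases
    if matching is not None:
        qb = qb[matching.assignment]
    observed = float(_circular_abs_diff(qa, qb).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _circular_abs_diff(qa, qb[rng.permutation(K)]).mean()
    return PhaseComparison(delta_theta=observed, null_values=null, seed=seed)


def match_states(cost: np.ndarray) -> StateMatching:
    """Optimal linear-assignment matching between two state sets.

    ``cost[i, j]`` is the dissimilarity between state ``i+1`` of the first
    set and state ``j+1`` of the second (e.g. one minus the correlation of
    their spatiospectral profiles).
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(cost)
    assignment = np.empty(cost.shape[0], dtype=np.int64)
    assignment[rows] = cols
    return StateMatching(assignment=assignment, total_cost=float(cost[rows, cols].sum()))


# ---------------------------------------------------------------------------
# Circle-graph export
# ---------------------------------------------------------------------------

def export_circle_graph(
    layout: CircleLayout,
    E: np.ndarray,
    stats: GroupAsymmetry | None = None,
) -> nx.DiGraph:
    """Directed graph of significant asymmetries on the circle.

    Nodes carry phase and unit-circle coordinates; one directed edge per
    nonzero entry of the signed edge matrix: ``E[j, k] = +1`` draws
    ``j → k`` (state k follows j), ``E[j, k] = −1`` draws ``k → j``.
    """
    E = np.asarray(E)
    K = layout.K
    if E.shape != (K, K):
        raise ValueError("edge matrix shape must match layout K")
    g = nx.DiGraph(K=K, ordering=",".join(map(str, layout.ordering)))
    phases = layout.phases
    for s in range(1, K + 1):
        q = float(phases[s - 1])
        g.add_node(s, phase=q, x=float(np.cos(q)), y=float(np.sin(q)))
    for j in range(K):
        for k in range(K):
            if E[j, k] == 0:
                continue
            src, dst = (j + 1, k + 1) if E[j, k] > 0 else (k + 1, j + 1)
            attrs = {"reference_state": j + 1, "sign": int(E[j, k])}
            if stats is not None:
                attrs["mean_asymmetry"] = float(stats.mean_A[j, k])
                attrs["p_value"] = float(stats.p_values[j, k])
            g.add_edge(src, dst, **attrs)
    return g


def circle_graph_document(
    layout: CircleLayout,
    E: np.ndarray,
    stats: GroupAsymmetry | None = None,
) -> dict:
    """JSON-serializable document of the circle graph (round-trippable)."""
    doc = {
        "K": layout.K,
        "ordering": layout.ordering.tolist(),
        "phases": layout.phases.tolist(),
        "beta": layout.beta,
        "E": np.asarray(E).astype(int).tolist(),
    }
    if stats is not None:
        doc["mean_A"] = stats.mean_A.tolist()
        doc["alpha"] = stats.alpha
    return doc


def load_circle_graph(path: str | Path) -> tuple[CircleLayout, np.ndarray]:
    """Re-import a circle-graph JSON document written by the exporters."""
    with open(path) as fh:
        doc = json.load(fh)
    return CircleLayout(np.array(doc["ordering"])), np.array(doc["E"], dtype=int)
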