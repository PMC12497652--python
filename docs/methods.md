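# Methods

## Model and assumptions

The package operates on discrete state time courses: per-sample assignments
of each timepoint to exactly one of K mutually exclusive network states at a
fixed sampling rate.  It assumes the states are given (typically a hidden
Markov model's most-probable path) and makes no assumption about how they
were inferred; it does assume mutual exclusivity and exhaustiveness — every
sample carries exactly one label.  All sample coordinates are 0-based and
half-open internally; user-facing state labels are 1-based.

The central quantity is the fractional-occupancy (FO) asymmetry.  For a
reference state *m*, an inter-state interval is the span strictly between
two successive visits of *m*.  Samples before the first visit and after the
last visit belong to no interval: intervals are defined only between
reactivations, and how flanking data should be treated is otherwise
undetermined, so they are excluded.  Each interval is split into two
equal-length contiguous halves; the single middle sample of an odd-length
interval is assigned to neither half, keeping the two halves exactly
symmetric.  Intervals shorter than 2 samples cannot be halved and are
excluded.  The asymmetry

    A[m, n] = mean over m's usable intervals of (FO of n in T1 − FO of n in T2)

uses an **unweighted** mean: each interval counts once regardless of its
duration.  Duration weighting is available (`weight_by_duration=True`) but
off by default — the unweighted mean treats each reactivation event as one
observation, which is the natural unit for the downstream subject-level
statistics.  Because states are mutually exclusive and the reference state
cannot occur strictly inside its own intervals, each row of A sums to zero
and the diagonal is exactly zero.  Reference states with no usable interval
produce NaN rows that propagate as missing — never as zero — and subjects
missing an edge are dropped pairwise in group tests.

## Cycle strength and its normalization

A is read as a weighted directed graph.  States sit at equally spaced
phases q on the unit circle; each edge projects tangentially with weight
sin(q_m − q_n), and

    S = −β · Σ_{m≠n} A[m, n] · sin(q_m − q_n)

with β = 1 / Σ_{m≠n} |sin(q_m − q_n)|, the inverse of the raw sum attained
by a matrix with perfect +1 asymmetry on every clockwise pair and −1 on
every counterclockwise pair.  This pins S to [−1, 1] with S = 1 exactly for
the perfect clockwise graph at any K ≥ 3 (for K = 2 all phase differences
are π and the normalization is undefined, so K < 3 is rejected).

Rotation and reflection of the circle are gauge freedoms: rotations leave S
unchanged and reflections negate it.  The canonical form places state 1 at
phase 0 and orients the circle so the optimized S is nonnegative
(maximizing or minimizing S only mirrors the plot).  Ordering optimization
is exhaustive over the (K−1)! orderings with state 1 pinned for K ≤ 8
(5 040 evaluations at K = 8, vectorized in batches); for larger K a seeded
multi-restart simulated annealing is used with position swaps and segment
reversals as the move set, a geometric temperature schedule (0.05 → 1e−4 by
default, 200·K iterations, 50 restarts) and a final safeguard that the
returned S is never below that of the identity ordering.

## Inference

Group edge statistics use a two-tailed one-sample t-test per off-diagonal
edge across subjects with Bonferroni correction over the K² − K edges
(K = 12 gives 132 tests and corrected α ≈ 3.8 × 10⁻⁴ at α_raw = 0.05).  For
very large cohorts an absolute t-value threshold can be used instead, since
p-based thresholds saturate.  Edges with fewer than three defined subject
values or zero across-subject variance are flagged and treated as
nonsignificant.  The signed edge matrix E is +1/−1 where an edge is
significant (sign of the group-mean asymmetry), else 0; E[j,k] = +1 draws
the arrow j → k and E[j,k] = −1 draws k → j in circle graphs.

Cycle-strength significance uses a label-shuffle permutation test: each
permutation independently relabels the states within every subject
(conjugation of that subject's A by a random permutation), recomputes the
group mean and — in the headline `reoptimize` scheme — re-runs the full
ordering optimization before evaluating S.  The per-permutation optimizer
uses the same budget as the observed statistic for K ≤ 8 (both exhaustive);
for larger K the annealing restart count inside permutations is
configurable, trading null fidelity against runtime.  The one-sided p-value
uses the add-one estimator (1 + #{null ≥ observed}) / (n_perm + 1), which
cannot reach zero.  Binned analyses use the `fixed_layout` scheme — S
evaluated at the full-data layout — whose null is centered at zero.

Phase differences between two cycle layouts (Δθ) are the mean absolute
circular difference between matched states' phases, with a null built by
uniformly permuting one layout's positions; the p-value is one-sided for
*smaller*-than-chance Δθ.  No rotational or reflectional alignment is
applied before averaging: both layouts are expected in canonical form, and
whether an explicit alignment step is preferable is an open design question
documented here rather than silently decided.  State matching between
datasets minimizes a user-supplied cost matrix (e.g. one minus the
correlation of spatiospectral profiles) by optimal linear assignment.

## Timescale analysis

Intervals are binned by duration into equal-count percentile bins (five by
default), separately for each subject **and** each reference state so no
bin is biased toward any state; bin edges are computed per subject, not
pooled over the cohort.  Ties are broken by temporal order (stable sort) and
bin counts differ by at most one.  Subject-states with fewer usable
intervals than bins are excluded and logged.  Per bin, the asymmetry is
recomputed from only that bin's intervals through the identical code path,
so the bin-weighted average of per-bin matrices reproduces the full matrix
exactly.  The per-bin cycle strength is evaluated at the fixed full-data
layout; re-optimizing per bin would reintroduce the selection bias that the
permutation null is centered against.

## Cycle rate

The cycle is summarized by four *metastates*: contiguous arcs of K/4
consecutive circle positions starting at phase 0 (nearest-equal sizes, with
a warning, when 4 ∤ K), each with a circular-mean centroid phase.  A
per-sample feature counts state-visit onsets in a centered sliding window;
the window defaults to the grand-mean state lifetime rounded up to an odd
number of samples (≈ 16 samples / 64 ms for the default generator at
250 Hz), since the mean lifetime is the natural scale separating
within-visit from between-visit variation.  A four-state hidden Markov
chain with Poisson emissions on this count and transitions restricted to
self-loops (probability `p_stay`, default 0.95) and single forward steps
(1→2→3→4→1) is decoded by max-product dynamic programming.  Each sample
additionally carries a prior over metastates derived from the circle-space
distance d of the active state's phase to each centroid, mapped through a
softmax exp(−d/τ) with temperature τ (radians, default 1; τ → 0 gives a
one-hot assignment).  The mapping from distance to probability and the way
the count feature and circle prior combine are design choices of this
package — the softmax-times-likelihood composition is one defensible
reading, and both τ and `p_stay` are exposed.  Poisson rates are
initialized as prior-weighted mean counts (floored at 10⁻³ when a metastate
sees no counts) and by default **no** EM sweep is run (`n_em=0`): training
to convergence could relabel the metastates and break the cycle definition;
a single sweep is available.  A completed cycle is the span between
successive entries into metastate 1 — the sequential constraint guarantees
2, 3, 4 are traversed in order — and partial head/tail cycles are
discarded.  The subject summary is the mean completed-cycle duration (ms)
and its inverse, the cycle rate (Hz), the latter being closer to normal
across subjects.

## Synthetic cohorts

`simulate_semi_markov` alternates dwell-length draws with jump draws from a
rotational transition matrix whose off-diagonal entries decay as
exp(−ρ·d_cw) in the clockwise step distance; ρ = 0 is an exact null with
uniform jumps.  Defaults emulate a resting-state cohort: K = 12 states,
55 subjects, 5.5 min at 250 Hz (82 500 samples), lognormal dwells with mean
16 samples (64 ms, a typical network-state lifetime) and σ = 0.75 for a
long right tail, and a weak bias ρ = 0.3.  Per-subject generators are
spawned deterministically from the master seed, so cohorts are reproducible
subject by subject.  Dwell draws are rounded up to at least one sample.

`simulate_dwell_gated_cycle` confines cyclicity to the long dwells: a
latent circle position advances one step whenever a visit lasts at least
`bias_threshold` samples and the next state is the one at the new position,
while shorter visits are followed by a uniformly random state with no
advance.  Short inter-state intervals therefore reflect symmetric flicker
and long intervals span full revolutions, producing cycle strength that is
near zero in the shortest duration bins and strongest in the longest —
whereas a duration-independent bias produces the *opposite* trend at long
durations, because intervals spanning several loop traversals average the
asymmetry away.  A first-order Markov refit of dwell-gated sequences keeps
only the part of the cycle that leaks into the marginal one-step
transition probabilities (about two-thirds of S under the test conditions),
demonstrating end to end that memoryless models understate cyclicity that
is carried by dwell-transition coupling.

What the generators do **not** emulate: continuous MEG signals, spectral
content, observation noise or posterior uncertainty (states are exact),
inter-subject heterogeneity in K or dwell statistics, and non-stationarity
within a recording.  Passing tests on synthetic cohorts therefore validate
the statistics and their calibration, not the neurophysiological
interpretation of any particular dataset.

## Numerical choices and degenerate inputs

* Posterior rows are reduced by argmax with ties broken toward the lowest
  state index, making reads deterministic.
* Segment masks (task epochs) are scanned independently, so no interval
  ever crosses a segment boundary; intervals not fully inside one segment
  are discarded.
* A reference state visited fewer than twice yields an empty interval set,
  not an error; the corresponding asymmetry row is NaN and flagged.
* Missing asymmetry entries entering cycle strength are treated as zero
  with a warning (they contribute no tangential weight).
* All randomized operations take explicit seeds; identical seeds give
  byte-identical JSON outputs through the CLI.

## Test-time problem sizes

The test suite and acceptance checks run the generators at reduced scale —
cohorts of 5–12 subjects with 6 000–30 000 samples per subject and K = 6–12,
1 000 permutations for single analyses and 99 inside replicated recovery
studies — sizes chosen so the full suite completes in a few minutes on one
core while keeping every statistical check well-powered.  Null-calibration
checks use 20–40 seeded replicates.

## Known limitations

* TINDA consumes binarized (hard-assigned) state courses; posterior
  uncertainty is discarded at read time, and extending the asymmetry to
  soft state courses is an open problem.
* The annealing optimizer is heuristic for K > 8; its per-permutation
  budget bounds the fidelity of the reoptimized null for large K.
* The Δθ comparison assumes canonical layouts and applies no rotational
  alignment; cycles that agree up to a rotation are penalized.
* The metastate decoder assumes the four quadrant arcs are contiguous on
  the optimized circle; layouts whose natural grouping is not quadrant-like
  will yield diffuse priors and fewer completed cycles.
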