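# tinda — temporal interval network density analysis

`tinda` quantifies directed, variable-timescale structure in sequences of
discrete brain-network states — for example the most-probable state path of a
hidden Markov model fitted to resting-state MEG.  It is aimed at
electrophysiologists and computational neuroscientists who have per-subject
state time courses (one label in `1..K` per sample at a fixed sampling rate)
and want to know whether the states activate in a consistent global cycle,
at which timescales, and how fast.

## The method

For a reference state *m*, every **inter-state interval** (the samples
strictly between two successive visits of *m*) is split evenly in half
(T₁ first, T₂ second; the middle sample of an odd-length interval is
dropped).  The **fractional-occupancy asymmetry** is

  A[m, n] = ⟨ FO_{T₁}(n) − FO_{T₂}(n) ⟩ over m's intervals,

so A[m, n] > 0 means state *n* tends to *follow* state *m*, over whatever
timescale each interval happens to span.  Rows of A sum to zero and
A[m, m] = 0 by construction.

Reading A as a weighted directed graph with the K states placed at equally
spaced phases q on the unit circle, the **cycle strength** is the normalized
tangential projection of all edges:

  S = −β · Σ_{m≠n} A[m, n] · sin(q_m − q_n),  β = 1 / Σ_{m≠n} |sin(q_m − q_n)|,

so S ∈ [−1, 1]: +1 for a perfectly clockwise cycle, 0 for a fully
stochastic graph.  The assignment of states to circle positions is optimized
to maximize S (exhaustively for K ≤ 8, by seeded simulated annealing
otherwise), and significance is assessed by a label-shuffle permutation test
that re-runs the optimization on each permuted cohort.  Downstream analyses
cover:

* **group edge statistics** — per-edge one-sample t-tests across subjects,
  Bonferroni-corrected over the K² − K edges, summarized in a signed edge
  matrix for circle-graph plots;
* **timescale dependence** — intervals binned into duration percentiles per
  subject and state, with asymmetry, cycle strength and a fixed-layout
  permutation null recomputed per bin;
* **cycle rate** — a four-metastate sequential Poisson decoder (metastates
  are contiguous quadrant arcs of the circle) that converts a visit-count
  feature into completed-cycle durations and their inverse, the cycle rate;
* **cross-dataset comparison** — optimal state matching by linear
  assignment and circular phase-difference tests between two cycle layouts;
* **synthetic cohorts** — semi-Markov generators with controllable
  rotational bias, geometric/lognormal/gamma dwell times and null controls,
  so every stage is verifiable without any neuroimaging data.

## Worked example

```python
import numpy as np
from tinda import (SimulationConfig, simulate_semi_markov, compute_fo_asymmetry,
                   group_asymmetry_test, optimize_ordering,
                   permutation_test_cycle_strength, cycle_rate_analysis)

# a 10-subject cohort with a moderate clockwise bias along states 1..8
cfg = SimulationConfig(seed=1, K=8, n_subjects=10, T=20000, fs=250.0, rho=0.8)
cohort = simulate_semi_markov(cfg)

matrices = [compute_fo_asymmetry(stc) for stc in cohort]
group = group_asymmetry_test(matrices, alpha_raw=0.05)
layout, S = optimize_ordering(group.mean_A)
null = permutation_test_cycle_strength(matrices, n_perm=999, seed=1)

print("cycle order :", layout.ordering)
print("cycle strength S = %.3f (p = %.3f, 999 permutations)" % (S, null.p))
print("significant edges:", int(np.abs(group.E).sum()),
      "of", group.n_tests, "at alpha =", round(group.alpha, 5))

rate = cycle_rate_analysis(cohort.subjects[0], layout)
print("subject sim000: mean cycle %.0f ms -> rate %.2f Hz over %d cycles"
      % (rate["mean_cycle_duration_ms"], rate["cycle_rate_hz"],
         rate["n_completed_cycles"]))
```

prints

```
cycle order : [1 2 3 4 5 6 7 8]
cycle strength S = 0.132 (p = 0.001, 999 permutations)
significant edges: 48 of 56 at alpha = 0.00089
subject sim000: mean cycle 310 ms -> rate 3.23 Hz over 258 cycles
```

The optimizer recovers the generative cycle order 1→2→…→8 (the canonical
form pins state 1 at phase 0), the permutation p-value is at its minimum
(1/1000), most of the 56 directed edges are individually significant after
Bonferroni correction, and the decoded cycles for the first subject take
about 310 ms each — roughly one full revolution of the 8-state cycle.

The same pipeline is available from the shell:

```bash
tinda simulate --out cohort/ --seed 1 --k 8 --n-subjects 10 --n-samples 20000 --rho 0.8
tinda cycle --manifest cohort/manifest.yaml --out results/ --n-perm 999 --seed 1
tinda timescales --manifest cohort/manifest.yaml --out results/ --seed 1
tinda rate --manifest cohort/manifest.yaml --out results/rate --seed 1
```

Input data are plain text: one integer label per row (or a T×K posterior
matrix reduced by row-wise argmax), with a YAML/JSON manifest listing
subject files and the sampling rate.

## Documentation

`docs/methods.md` describes the model assumptions, the tunable parameters
and their defaults, what the synthetic generators do and do not emulate,
and the numerical choices made in degenerate cases.
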