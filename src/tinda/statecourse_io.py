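"""Discrete state time courses: containers, text I/O and interval primitives.

A *state time course* assigns every sample of a recording to exactly one of
``K`` mutually exclusive network states (for example the most-probable path of
a hidden Markov model).  Everything downstream — fractional-occupancy
asymmetry, cycle statistics, the metastate decoder — consumes the types
defined here.

Conventions
-----------
* State labels are 1-based (states ``1..K``), matching the way network states
  are usually numbered in the literature.
* Sample coordinates are 0-based, half-open ``[onset, offset)`` everywhere.
* An *inter-state interval* (ISI) of a reference state ``m`` is the span of
  samples strictly between two successive visits of ``m``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StateCourseError",
    "StateTimeCourse",
    "Visit",
    "IntervalSet",
    "CohortStateData",
    "read_state_time_course",
    "read_cohort_manifest",
    "write_state_time_course",
    "extract_visits",
    "extract_intervals",
    "fractional_occupancy",
    "mean_lifetimes",
    "visits_to_frame",
    "intervals_to_frame",
]


class StateCourseError(ValueError):
    """Raised for malformed state-course files or inconsistent containers."""


class Visit(NamedTuple):
    """One maximal run of a single state: half-open span ``[onset, offset)``."""

    state: int
    onset: int
    offset: int

    @property
    def duration(self) -> int:
        return self.offset - self.onset


@dataclass
class StateTimeCourse:
    """One subject's discrete state labels at a fixed sampling rate.

    Parameters
    ----------
    labels
        Integer labels in ``1..K``, one per sample.
    fs
        Sampling rate in Hz.
    K
        Number of states.  Inferred as ``max(labels)`` when omitted.
    subject_id
        Opaque identifier carried through to outputs.
    segment_mask
        Optional sorted, disjoint list of half-open sample ranges marking
        valid epochs (for example task trials).  Intervals crossing a segment
        boundary are discarded by :func:`extract_intervals`.
    """

    labels: np.ndarray
    fs: float
    K: int = 0
    subject_id: str = ""
    segment_mask: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise StateCourseError("labels must be a nonempty 1-D sequence")
        if self.fs <= 0:
            raise StateCourseError(f"sampling rate must be positive, got {self.fs}")
        if self.K <= 0:
            self.K = int(self.labels.max())
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise StateCourseError(
                f"labels must lie in 1..{self.K}; observed range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        if self.segment_mask is not None:
            prev_stop = 0
            for start, stop in self.segment_mask:
                if not (0 <= start < stop <= self.T):
                    raise StateCourseError(
                        f"segment ({start}, {stop}) outside [0, {self.T})"
                    )
                if start < prev_stop:
                    raise StateCourseError("segments must be sorted and disjoint")
                prev_stop = stop

    @property
    def T(self) -> int:
        """Number of samples."""
        return int(self.labels.size)

    def samples_to_ms(self, n: float | np.ndarray) -> float | np.ndarray:
        return n * 1000.0 / self.fs


@dataclass
class IntervalSet:
    """All inter-occurrence intervals of one reference state.

    ``spans`` holds one half-open ``[start, stop)`` row per interval, the
    samples strictly between two successive visits of ``reference_state``.
    Intervals shorter than 2 samples cannot be halved and are flagged
    unusable.
    """

    reference_state: int
    spans: np.ndarray  # (n, 2) int array
    fs: float

    def __post_init__(self) -> None:
        self.spans = np.asarray(self.spans, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return self.spans.shape[0]

    @property
    def durations(self) -> np.ndarray:
        """Interval durations in samples."""
        if len(self) == 0:
            return np.zeros(0, dtype=np.int64)
        return self.spans[:, 1] - self.spans[:, 0]

    @property
    def durations_ms(self) -> np.ndarray:
        return self.durations * 1000.0 / self.fs

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of intervals long enough (>= 2 samples) to halve."""
        return self.durations >= 2

    def halves(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-partitions ``(T1, T2)`` of the usable intervals.

        Both are ``(n_usable, 2)`` span arrays of equal length per interval;
        the middle sample of an odd-length interval belongs to neither half.
        """
        spans = self.spans[self.usable]
        half = (spans[:, 1] - spans[:, 0]) // 2
        t1 = np.stack([spans[:, 0], spans[:, 0] + half], axis=1)
        t2 = np.stack([spans[:, 1] - half, spans[:, 1]], axis=1)
        return t1, t2

    def select(self, index: np.ndarray) -> "IntervalSet":
        """A new IntervalSet restricted to the given interval indices."""
        return IntervalSet(self.reference_state, self.spans[index], self.fs)


@dataclass
class CohortStateData:
    """A list of state time courses sharing ``K`` and ``fs``."""

    subjects: list[StateTimeCourse]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise StateCourseError("cohort must contain at least one subject")
        ks = {s.K for s in self.subjects}
        fss = {s.fs for s in self.subjects}
        if len(ks) > 1:
            raise StateCourseError(f"subjects disagree on K: {sorted(ks)}")
        if len(fss) > 1:
            raise StateCourseError(f"subjects disagree on fs: {sorted(fss)}")

    @property
    def K(self) -> int:
        return self.subjects[0].K

    @property
    def fs(self) -> float:
        return self.subjects[0].fs

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _tokenize(path: Path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.replace(",", " ").replace("\t", " ").split())
    if not rows:
        raise StateCourseError(f"{path}: file contains no data rows")
    return rows


def read_state_time_course(
    path: str | Path,
    dialect: str = "labels",
    label_base: int = 1,
    fs: float = 1.0,
    K: int | None = None,
    subject_id: str | None = None,
) -> StateTimeCourse:
    """Read one subject's state course from delimited text.

    ``dialect='labels'`` expects one integer label per row; ``'posteriors'``
    expects ``T`` rows of ``K`` nonnegative reals, reduced by per-row argmax
    with ties broken toward the lowest state index.  Labels are stored
    1-based regardless of ``label_base``.
    """
    path = Path(path)
    rows = _tokenize(path)
    if subject_id is None:
        subject_id = path.stem

    if dialect == "labels":
        labels = np.empty(len(rows), dtype=np.int64)
        for i, row in enumerate(rows):
            if len(row) != 1:
                raise StateCourseError(
                    f"{path}: row {i + 1} has {len(row)} fields, expected 1"
                )
            try:
                labels[i] = int(row[0])
            except ValueError:
                raise StateCourseError(
                    f"{path}: row {i + 1}: non-integer label {row[0]!r}"
                ) from None
        if label_base == 0:
            labels += 1
        elif label_base != 1:
            raise StateCourseError(f"label_base must be 0 or 1, got {label_base}")
        k = K if K is not None else int(labels.max())
        if labels.min() < 1 or labels.max() > k:
            bad = int(np.argmax((labels < 1) | (labels > k)))
            raise StateCourseError(
                f"{path}: row {bad + 1}: label {labels[bad]} outside 1..{k}"
            )
    elif dialect == "posteriors":
        width = len(rows[0])
        probs = np.empty((len(rows), width), dtype=float)
        for i, row in enumerate(rows):
            if len(row) != width:
                raise StateCourseError(
                    f"{path}: row {i + 1} has {len(row)} fields, expected {width}"
                )
            try:
                probs[i] = [float(x) for x in row]
            except ValueError:
                raise StateCourseError(
                    f"{path}: row {i + 1}: non-numeric entry"
                ) from None
            if np.any(probs[i] < 0):
                raise StateCourseError(
                    f"{path}: row {i + 1}: negative posterior probability"
                )
        # np.argmax already returns the first (lowest-index) maximum on ties
        labels = np.argmax(probs, axis=1).astype(np.int64) + 1
        k = K if K is not None else width
    else:
        raise StateCourseError(f"unknown dialect {dialect!r}")

    return StateTimeCourse(labels=labels, fs=fs, K=k, subject_id=subject_id)


def write_state_time_course(stc: StateTimeCourse, path: str | Path) -> None:
    """Write labels as one integer per line (the ``labels`` dialect)."""
    np.savetxt(path, stc.labels, fmt="%d")


def read_cohort_manifest(path: str | Path) -> CohortStateData:
    """Load a cohort from a YAML/JSON manifest.

    The manifest lists the shared sampling rate and one entry per subject::

        fs: 250.0
        K: 12            # optional; inferred per subject when absent
        subjects:
          - {subject_id: s01, path: s01.csv, dialect: labels, label_base: 1}

    Subject paths are resolved relative to the manifest file.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = (json.load if path.suffix == ".json" else yaml.safe_load)(fh)
    try:
        fs = float(manifest["fs"])
        entries = manifest["subjects"]
    except (KeyError, TypeError) as exc:
        raise StateCourseError(f"{path}: manifest must define 'fs' and 'subjects'") from exc
    K = manifest.get("K")
    subjects = []
    for entry in entries:
        sub_path = Path(entry["path"])
        if not sub_path.is_absolute():
            sub_path = path.parent / sub_path
        subjects.append(
            read_state_time_course(
                sub_path,
                dialect=entry.get("dialect", "labels"),
                label_base=int(entry.get("label_base", 1)),
                fs=fs,
                K=int(K) if K is not None else None,
                subject_id=str(entry.get("subject_id", sub_path.stem)),
            )
        )
    if K is None:
        # harmonize K across subjects: a state may simply never be visited
        kmax = max(s.K for s in subjects)
        for s in subjects:
            s.K = kmax
    return CohortStateData(subjects)


# ---------------------------------------------------------------------------
# Run-length / interval primitives
# ---------------------------------------------------------------------------

def extract_visits(stc: StateTimeCourse) -> list[Visit]:
    """Run-length encode the labels into maximal single-state visits."""
    labels = stc.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    onsets = np.concatenate([[0], change])
    offsets = np.concatenate([change, [labels.size]])
    return [Visit(int(labels[a]), int(a), int(b)) for a, b in zip(onsets, offsets)]


def _intervals_in_range(labels: np.ndarray, ref: int, start: int, stop: int) -> list[tuple[int, int]]:
    """Spans strictly between successive ``ref`` visits inside ``[start, stop)``."""
    seg = labels[start:stop]
    is_ref = seg == ref
    if not is_ref.any():
        return []
    # offsets of ref runs and onsets of the following ref runs
    d = np.diff(is_ref.astype(np.int8))
    run_ends = np.flatnonzero(d == -1) + 1  # exclusive end of a ref run
    run_starts = np.flatnonzero(d == 1) + 1  # start of a ref run
    nxt = np.searchsorted(run_starts, run_ends, side="left")
    keep = nxt < run_starts.size
    return [
        (start + int(e), start + int(run_starts[i]))
        for e, i in zip(run_ends[keep], nxt[keep])
    ]


def extract_intervals(stc: StateTimeCourse, reference_state: int) -> IntervalSet:
    """All inter-occurrence intervals of ``reference_state``.

    One interval per consecutive pair of reference-state visits, covering the
    samples strictly between them.  Samples before the first visit and after
    the last belong to no interval.  When a segment mask is present, each
    segment is scanned independently, so intervals never cross segment
    boundaries.
    """
    if not 1 <= reference_state <= stc.K:
        raise StateCourseError(
            f"reference state {reference_state} outside 1..{stc.K}"
        )
    ranges = stc.segment_mask if stc.segment_mask is not None else [(0, stc.T)]
    spans: list[tuple[int, int]] = []
    for start, stop in ranges:
        spans.extend(_intervals_in_range(stc.labels, reference_state, start, stop))
    arr = np.array(spans, dtype=np.int64).reshape(-1, 2)
    return IntervalSet(reference_state, arr, stc.fs)


def fractional_occupancy(stc: StateTimeCourse) -> np.ndarray:
    """Per-state proportion of samples; entries sum to 1."""
    counts = np.bincount(stc.labels, minlength=stc.K + 1)[1:]
    return counts / stc.T


def mean_lifetimes(stc: StateTimeCourse) -> tuple[np.ndarray, float]:
    """Per-state mean visit duration and grand mean, both in ms.

    States never visited get ``NaN`` with a warning.
    """
    visits = extract_visits(stc)
    durations = np.array([v.duration for v in visits], dtype=float)
    states = np.array([v.state for v in visits])
    per_state = np.full(stc.K, np.nan)
    for k in range(1, stc.K + 1):
        mask = states == k
        if mask.any():
            per_state[k - 1] = durations[mask].mean()
    if np.isnan(per_state).any():
        missing = np.flatnonzero(np.isnan(per_state)) + 1
        warnings.warn(f"states never visited: {missing.tolist()}", stacklevel=2)
    ms = 1000.0 / stc.fs
    return per_state * ms, float(durations.mean() * ms)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def visits_to_frame(stc: StateTimeCourse) -> pd.DataFrame:
    visits = extract_visits(stc)
    return pd.DataFrame(
        {
            "subject": stc.subject_id,
            "state": [v.state for v in visits],
            "onset": [v.onset for v in visits],
            "offset": [v.offset for v in visits],
            "duration_samples": [v.duration for v in visits],
            "duration_ms": [v.duration * 1000.0 / stc.fs for v in visits],
        }
    )


def intervals_to_frame(stc: StateTimeCourse) -> pd.DataFrame:
    frames = []
    for m in range(1, stc.K + 1):
        ivs = extract_intervals(stc, m)
        frames.append(
            pd.DataFrame(
                {
                    "subject": stc.subject_id,
                    "state": m,
                    "onset": ivs.spans[:, 0],
                    "offset": ivs.spans[:, 1],
                    "duration_samples": ivs.durations,
                    "duration_ms": ivs.durations_ms,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
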