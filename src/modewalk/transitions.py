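"""Mode-transition analytics over per-window mode sequences.

Transition matrix with self-transitions (pooled over tracks), per-mode
window fractions, single-/multi-mode track fractions, consecutive-mode
lifetime records with boundary censoring, and one- vs two-step
cross-transition pathway fractions computed on collapsed run sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np

from .errors import NoDataError

MODES = ("SD", "SP", "FP")


def _labels(seq) -> list[str]:
    """Accept ModeSequence-like objects or plain label sequences."""
    if hasattr(seq, "modes"):
        return list(seq.modes)
    return [str(m) for m in seq]


@dataclass
class TransitionMatrix:
    """Window-to-window transition counts and row-normalized probabilities.

    ``probabilities`` rows with zero outgoing counts are NaN (undefined),
    flagged in ``defined_rows``; defined rows sum to 1 exactly.
    """

    modes: tuple[str, ...]
    counts: np.ndarray
    probabilities: np.ndarray
    defined_rows: np.ndarray
    total: int


def transition_matrix(seqs: Iterable, modes: Sequence[str] = MODES) -> TransitionMatrix:
    """Count every ordered consecutive window pair (self-pairs included)."""
    index = {m: i for i, m in enumerate(modes)}
    counts = np.zeros((len(modes), len(modes)), dtype=int)
    any_seq = False
    for seq in seqs:
        any_seq = True
        labels = _labels(seq)
        for a, b in zip(labels, labels[1:]):
            counts[index[a], index[b]] += 1
    if not any_seq:
        raise NoDataError("empty mode-sequence pool")
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    probs = np.full(counts.shape, np.nan)
    probs[defined] = counts[defined] / row_sums[defined, None]
    return TransitionMatrix(modes=tuple(modes), counts=counts, probabilities=probs,
                            defined_rows=defined, total=int(counts.sum()))


def mode_fractions(seqs: Iterable, modes: Sequence[str] = MODES) -> dict[str, float]:
    """Fraction of windows spent in each mode (sums to 1)."""
    counts = {m: 0 for m in modes}
    total = 0
    for seq in seqs:
        for m in _labels(seq):
            counts[m] += 1
            total += 1
    if total == 0:
        raise NoDataError("empty mode-sequence pool")
    return {m: counts[m] / total for m in modes}


def homogeneity_fraction(seqs: Iterable) -> tuple[float, float]:
    """(single-mode, multi-mode) track fractions; a track is single-mode
    iff all its windows share one mode."""
    single = total = 0
    for seq in seqs:
        labels = _labels(seq)
        if not labels:
            continue
        total += 1
        if len(set(labels)) == 1:
            single += 1
    if total == 0:
        raise NoDataError("empty mode-sequence pool")
    return single / total, (total - single) / total


@dataclass(frozen=True)
class LifetimeRecord:
    """One maximal constant-mode run; length in consecutive windows (hours).

    ``censored`` marks runs touching a track boundary (their true
    lifetime is only bounded below by the observed run length).
    """

    mode: str
    length: int
    censored: bool


def mode_lifetimes(seqs: Iterable) -> tuple[list[LifetimeRecord], dict[str, np.ndarray]]:
    """Extract maximal constant-mode runs and per-mode empirical CDFs.

    Censored (boundary-touching) runs are flagged but included in the
    CDFs; dropping them would bias against long-lived modes on short
    tracks.  Returns (records, {mode: sorted run lengths}).
    """
    records: list[LifetimeRecord] = []
    for seq in seqs:
        labels = _labels(seq)
        runs = [(m, len(list(g))) for m, g in groupby(labels)]
        for i, (m, length) in enumerate(runs):
            censored = i == 0 or i == len(runs) - 1
            records.append(LifetimeRecord(mode=m, length=length, censored=censored))
    lengths: dict[str, np.ndarray] = {}
    for m in {r.mode for r in records}:
        lengths[m] = np.sort([r.length for r in records if r.mode == m])
    return records, lengths


def lifetime_cdf(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF (support, cumulative probability) of run lengths."""
    support, counts = np.unique(np.asarray(lengths), return_counts=True)
    return support, np.cumsum(counts) / counts.sum()


@dataclass
class PathwaySummary:
    """One- vs two-step cross-transition counts per ordered mode pair.

    For each (i, j), i != j: ``one_step[(i, j)]`` counts adjacent i->j
    occurrences in the collapsed (run-mode) sequence; ``two_step[(i, j)]``
    counts i->k->j with k the third mode.  ``fractions`` normalizes the
    two counts within each pair (skipped when both are zero).
    """

    one_step: dict[tuple[str, str], int]
    two_step: dict[tuple[str, str], int]
    fractions: dict[tuple[str, str], tuple[float, float]]


def collapse(labels: Sequence[str]) -> list[str]:
    """Run-mode order of a sequence (self-transitions removed)."""
    return [m for m, _ in groupby(labels)]


def pathway_summary(seqs: Iterable, modes: Sequence[str] = MODES) -> PathwaySummary:
    """Count one-step and two-step cross-transition pathways per mode pair."""
    pairs = [(i, j) for i in modes for j in modes if i != j]
    one = {p: 0 for p in pairs}
    two = {p: 0 for p in pairs}
    for seq in seqs:
        runs = collapse(_labels(seq))
        for a, b in zip(runs, runs[1:]):
            one[(a, b)] += 1
        for a, k, b in zip(runs, runs[1:], runs[2:]):
            if a != b:  # k differs from both by construction of runs
                two[(a, b)] += 1
    fractions = {}
    for p in pairs:
        total = one[p] + two[p]
        if total > 0:
            fractions[p] = (one[p] / total, two[p] / total)
    return PathwaySummary(one_step=one, two_step=two, fractions=fractions)
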