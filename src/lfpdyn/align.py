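"""Trial phase alignment by circular shifting.

A brief stimulus resets the phase of the ongoing oscillation by a different
amount on every trial.  Before trials can be compared or averaged, each one
is circularly shifted to maximize its Pearson correlation with a reference
trial; the shift search is exhaustive over all N circular shifts, evaluated
in O(N log N) via the FFT cross-correlation of the z-scored series.

``circular_align`` also supports an "rms" objective (maximize the raw
circular cross-covariance), which — because a circular shift preserves the
sum of squares — is exactly the shift minimizing the root-mean-square error
against the reference.  Cluster-refinement realignment uses that objective
so the rms against the cluster mean can never increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError
from .trials import TrialSet


@dataclass(frozen=True)
class AlignmentResult:
    """Per-trial shifts and before/after agreement with the reference."""

    shifts: np.ndarray                 # circular shift per trial, in [0, N)
    correlations_before: np.ndarray
    correlations_after: np.ndarray
    rms_before: np.ndarray
    rms_after: np.ndarray
    reference_index: int

    def summary(self) -> dict:
        return {
            "reference_index": int(self.reference_index),
            "corr_before_mean": float(np.mean(self.correlations_before)),
            "corr_before_sd": float(np.std(self.correlations_before, ddof=1)),
            "corr_after_mean": float(np.mean(self.correlations_after)),
            "corr_after_sd": float(np.std(self.correlations_after, ddof=1)),
            "rms_before_mean": float(np.mean(self.rms_before)),
            "rms_before_sd": float(np.std(self.rms_before, ddof=1)),
            "rms_after_mean": float(np.mean(self.rms_after)),
            "rms_after_sd": float(np.std(self.rms_after, ddof=1)),
        }


def rms_error(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference sqrt(mean((a - b)^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise DegenerateSeriesError("constant series has no defined correlation")
    return (x - x.mean()) / sd


def circular_correlations(trial: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of roll(trial, s) with reference, for every s.

    Entry s equals ``corrcoef(np.roll(trial, s), reference)``; computed for
    all N shifts at once via the FFT correlation theorem.
    """
    zt = _zscore(np.asarray(trial, dtype=float))
    zr = _zscore(np.asarray(reference, dtype=float))
    if zt.size != zr.size:
        raise ValueError("series must have equal length")
    c = np.fft.irfft(np.conj(np.fft.rfft(zt)) * np.fft.rfft(zr), zt.size)
    return c / zt.size


def circular_align(trial: np.ndarray, reference: np.ndarray,
                   objective: str = "correlation") -> tuple[int, float]:
    """Best circular shift of ``trial`` against ``reference``.

    Returns ``(shift, correlation)`` where ``shift`` is the argmax over all
    N circular shifts (ties broken by the smallest shift) and
    ``correlation`` the Pearson correlation attained there.  With
    ``objective="rms"`` the shift instead minimizes the rms error (raw
    cross-covariance argmax); the returned second value is then the rms at
    that shift.
    """
    trial = np.asarray(trial, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trial.size != reference.size or trial.size < 2:
        raise ValueError("series must share a length of at least 2")
    if objective == "correlation":
        scores = circular_correlations(trial, reference)
        shift = int(np.argmax(scores))
        return shift, float(scores[shift])
    if objective == "rms":
        # rms^2(s) = (sum t^2 + sum r^2 - 2 * dot(roll(t, s), r)) / N:
        # minimizing rms over shifts == maximizing the raw circular dot.
        dots = np.fft.irfft(np.conj(np.fft.rfft(trial)) * np.fft.rfft(reference),
                            trial.size)
        shift = int(np.argmax(dots))
        return shift, rms_error(np.roll(trial, shift), reference)
    raise ValueError(f"unknown objective {objective!r}")


def choose_reference(tset: TrialSet, policy) -> int:
    """Resolve a reference policy: "first", "best", or an integer index."""
    if isinstance(policy, (int, np.integer)):
        idx = int(policy)
        if not 0 <= idx < len(tset):
            raise ValueError(f"reference index {idx} out of range")
        return idx
    if policy == "first":
        return 0
    if policy == "best":
        # trial with the largest mean absolute zero-shift correlation to all others
        z = np.column_stack([_zscore(t.samples) for t in tset])
        corr = (z.T @ z) / z.shape[0]
        np.fill_diagonal(corr, 0.0)
        return int(np.argmax(np.abs(corr).mean(axis=1)))
    raise ValueError(f"unknown reference policy {policy!r}")


def align_set(tset: TrialSet, reference_policy="first"
              ) -> tuple[TrialSet, AlignmentResult]:
    """Circularly align every trial of a set to a reference trial.

    Every trial is replaced by its optimally shifted copy (the reference
    keeps shift 0 by construction).  Alignment never decreases a trial's
    correlation with the reference because the zero shift is in the search
    set.
    """
    ref_idx = choose_reference(tset, reference_policy)
    ref = tset[ref_idx].samples
    zr = _zscore(ref)

    shifts = np.zeros(len(tset), dtype=int)
    corr_before = np.zeros(len(tset))
    corr_after = np.zeros(len(tset))
    rms_before = np.zeros(len(tset))
    rms_after = np.zeros(len(tset))
    aligned = []
    for i, t in enumerate(tset):
        scores = circular_correlations(t.samples, ref)
        corr_before[i] = scores[0]
        rms_before[i] = rms_error(t.samples, ref)
        s = int(np.argmax(scores))
        shifts[i] = s
        corr_after[i] = scores[s]
        rolled = np.roll(t.samples, s)
        rms_after[i] = rms_error(rolled, ref)
        aligned.append(t.with_samples(rolled))
    result = AlignmentResult(
        shifts=shifts,
        correlations_before=corr_before,
        correlations_after=corr_after,
        rms_before=rms_before,
        rms_after=rms_after,
        reference_index=ref_idx,
    )
    return TrialSet(tuple(aligned)), result
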