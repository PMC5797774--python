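"""Cross-condition attractor comparison.

Two complementary views of how the reconstructed dynamics differ between
conditions:

* the **discrete Frechet distance** between delay-embedded trajectories —
  the minimum over order-preserving couplings of the maximum pointwise
  distance ("shortest dog leash"), computed by the Eiter-Mannila dynamic
  program; trajectories are decimated before the O(nm) table is filled;
* **lognormal fits to per-trial lag-time distributions** — lag times are
  positive and long-tailed, and the ratio of the lognormal centers
  (geometric means) between conditions summarizes the intrinsic time-scale
  change (about threefold in the cocaine condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddedTrajectory

try:  # optional JIT for the DP inner loop; results are identical without it
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


@dataclass(frozen=True)
class FrechetMatrix:
    """All pairwise trajectory distances between two sets of attractors."""

    values: np.ndarray          # (len(row_set), len(col_set))
    row_ids: tuple
    col_ids: tuple
    downsample_step: int


@dataclass(frozen=True)
class LognormalFit:
    """Lognormal parameters of a lag-time sample.

    ``center = exp(mu)`` is the distribution median / geometric mean — the
    "center" used when comparing conditions.
    """

    mu: float
    sigma: float
    n: int

    @property
    def center(self) -> float:
        return float(np.exp(self.mu))


def _frechet_dp_py(D):
    n, m = D.shape
    row = np.empty(m)
    row[0] = D[0, 0]
    for j in range(1, m):
        row[j] = max(row[j - 1], D[0, j])
    for i in range(1, n):
        prev_diag = row[0]
        row[0] = max(row[0], D[i, 0])
        for j in range(1, m):
            best = min(prev_diag, row[j], row[j - 1])
            prev_diag = row[j]
            row[j] = best if best > D[i, j] else D[i, j]
    return row[m - 1]


if _njit is not None:
    _frechet_dp = _njit(cache=False)(_frechet_dp_py)
else:  # pragma: no cover
    _frechet_dp = _frechet_dp_py


def discrete_frechet(P, Q) -> float:
    """Discrete Frechet (coupling) distance between two point sequences.

    ``P`` and ``Q`` are (n, d) arrays or EmbeddedTrajectory objects with a
    common dimensionality.  Symmetric, nonnegative, zero exactly on
    identical sequences, and never less than the Hausdorff distance of the
    two point sets.
    """
    P = _as_points(P)
    Q = _as_points(Q)
    if P.shape[1] != Q.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: {P.shape[1]} vs {Q.shape[1]}"
        )
    D = cdist(P, Q)
    return float(_frechet_dp(D))


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, EmbeddedTrajectory):
        pts = obj.points
    else:
        pts = np.atleast_2d(np.asarray(obj, dtype=float))
    if pts.size == 0:
        raise ValueError("empty trajectory")
    return pts


def frechet_matrix(
    A: Sequence,
    B: Sequence,
    downsample_step: int = 10,
) -> FrechetMatrix:
    """All pairwise discrete Frechet distances between two trajectory lists.

    Every trajectory is decimated by keeping every ``downsample_step``-th
    point before the dynamic program runs (step 1 = no decimation).  Entries
    are computed independently, so the result does not depend on evaluation
    order.
    """
    if downsample_step < 1:
        raise ValueError("downsample_step must be >= 1")
    if not len(A) or not len(B):
        raise ValueError("empty trajectory list")
    pa = [_as_points(t)[::downsample_step] for t in A]
    pb = [_as_points(t)[::downsample_step] for t in B]
    dims = {p.shape[1] for p in pa} | {p.shape[1] for p in pb}
    if len(dims) != 1:
        raise ValueError(f"trajectories span multiple dimensionalities: {dims}")
    values = np.empty((len(pa), len(pb)))
    for i, p in enumerate(pa):
        for j, q in enumerate(pb):
            values[i, j] = float(_frechet_dp(cdist(p, q)))
    row_ids = tuple(getattr(t, "trial_id", i) for i, t in enumerate(A))
    col_ids = tuple(getattr(t, "trial_id", j) for j, t in enumerate(B))
    return FrechetMatrix(values=values, row_ids=row_ids, col_ids=col_ids,
                         downsample_step=downsample_step)


def fit_lognormal(lags) -> LognormalFit:
    """Lognormal fit of a positive lag sample.

    mu is the mean of the log lags (the exact maximum-likelihood location)
    and sigma the sample (n-1 denominator) standard deviation of the logs;
    the center exp(mu) equals the sample geometric mean exactly.
    """
    lags = np.asarray(list(lags), dtype=float)
    if lags.size < 2:
        raise ValueError("need at least two lags")
    if np.any(lags <= 0):
        raise ValueError("lags must all be positive")
    logs = np.log(lags)
    return LognormalFit(
        mu=float(np.mean(logs)),
        sigma=float(np.std(logs, ddof=1)),
        n=int(lags.size),
    )


def lag_ratio(control_lags, treated_lags) -> float:
    """Ratio of lognormal centers, control over treated.

    A value near 3 means the treated dynamics runs about three times
    faster than control.
    """
    return fit_lognormal(control_lags).center / fit_lognormal(treated_lags).center
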