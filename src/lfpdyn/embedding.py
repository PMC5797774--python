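"""Delay-embedding state-space reconstruction.

Implements lag-time selection (autocorrelation first zero, average mutual
information first minimum), delay embedding of a scalar series into d
dimensions, and embedding-dimension estimation by the false-nearest-neighbor
(FNN) criterion with an escape factor f and a Theiler exclusion window.

The FNN rule used: embed at dimension d, find each point's exact nearest
neighbor (Euclidean metric) among points more than ``theiler`` samples away
in time, and declare the pair false when the extra (d+1)-th coordinate
separates them by more than ``f`` times their d-dimensional distance.  The
minimum embedding dimension d_E is the smallest d whose FNN percentage
drops below a threshold (default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import (
    DegenerateSeriesError,
    NoEmbeddingError,
    NoMinimumError,
    NoZeroCrossingError,
)


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: lag tau (samples), dimension d, escape
    factor f, Theiler window (samples), FNN threshold (%), scan ceiling."""

    tau: int = 1
    d: int = 3
    f: float = 10.0
    theiler: int = 500
    fnn_threshold: float = 1.0
    d_max: int = 10

    def __post_init__(self):
        if self.tau < 1 or self.d < 1 or self.theiler < 0:
            raise ValueError("tau >= 1, d >= 1 and theiler >= 0 required")
        if self.f <= 1:
            raise ValueError("escape factor f must exceed 1")


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """A d-dimensional delay-embedded orbit of one trial."""

    points: np.ndarray  # (n_points, d)
    tau: int
    d: int
    trial_id: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.d:
            raise ValueError("points must be (n_points, d)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class FNNCurve:
    """FNN percentage per scanned dimension."""

    dims: tuple[int, ...]
    percentages: tuple[float, ...]
    params: EmbeddingParams

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.dims, self.percentages))


# ---------------------------------------------------------------------------
# Lag-time selection


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased sample autocorrelation r(0..max_lag), computed via FFT."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n // 2
    xc = x - x.mean()
    var = np.dot(xc, xc)
    if var == 0:
        raise DegenerateSeriesError("constant series has no autocorrelation")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    return acov / var


def autocorr_lag(x: np.ndarray, max_lag: int | None = None) -> int:
    """Lag of the autocorrelation's first zero crossing.

    Returns the smallest integer lag at which the biased autocorrelation
    first becomes <= 0 (the integer just past the sign change).  A pure
    sinusoid of period T gives T/4.
    """
    acf = autocorrelation(x, max_lag)
    nonpos = np.nonzero(acf[1:] <= 0)[0]
    if nonpos.size == 0:
        raise NoZeroCrossingError(
            f"no autocorrelation zero crossing within {acf.size - 1} lags"
        )
    return int(nonpos[0]) + 1


def ami(x: np.ndarray, lag: int, bins: int = 16) -> float:
    """Average mutual information I(lag) in bits.

    Uses an equal-width ``bins`` x ``bins`` histogram of (x_t, x_{t+lag})
    over the observed range of x; I(0) equals the binned marginal entropy.
    """
    x = np.asarray(x, dtype=float)
    if lag < 0 or lag >= x.size:
        raise ValueError("lag must satisfy 0 <= lag < len(x)")
    codes = _bin_codes(x, bins)
    return _ami_from_codes(codes, lag, bins)


def _bin_codes(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=np.intp)
    codes = ((x - lo) * (bins / (hi - lo))).astype(np.intp)
    return np.minimum(codes, bins - 1)


def _ami_from_codes(codes: np.ndarray, lag: int, bins: int) -> float:
    a = codes[: codes.size - lag] if lag else codes
    b = codes[lag:] if lag else codes
    joint = np.bincount(a * bins + b, minlength=bins * bins).astype(float)
    total = joint.sum()
    p = joint / total
    px = p.reshape(bins, bins).sum(axis=1)
    py = p.reshape(bins, bins).sum(axis=0)
    outer = np.outer(px, py).ravel()
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def ami_lag(x: np.ndarray, bins: int = 16, max_lag: int | None = None,
            window: int = 1) -> int:
    """Lag of the first strict local minimum of the AMI.

    ``window`` controls robustness: a lag k qualifies only if I(k) is
    strictly below I(j) for every j within ``window`` lags on both sides
    (window=1 is the plain strict-local-minimum rule).  Equal-width binning
    makes the AMI of noise-free periodic signals wiggle on a fine scale as
    samples cross bin boundaries; a wider window skips those micro-dips and
    finds the coarse minimum that lag selection is after.
    """
    x = np.asarray(x, dtype=float)
    if max_lag is None:
        max_lag = x.size // 2
    if window < 1:
        raise ValueError("window must be >= 1")
    codes = _bin_codes(x, bins)
    upper = min(max_lag + window, x.size - 1)
    curve = np.array([_ami_from_codes(codes, l, bins) for l in range(upper + 1)])
    for lag in range(1, max_lag):
        lo = max(0, lag - window)
        hi = min(curve.size - 1, lag + window)
        seg = curve[lo: hi + 1]
        if np.all(curve[lag] < np.delete(seg, lag - lo)):
            return lag
    raise NoMinimumError(f"no AMI local minimum within {max_lag} lags")


# ---------------------------------------------------------------------------
# Embedding and FNN


def delay_embed(x: np.ndarray, tau: int, d: int, trial_id: int = 0
                ) -> EmbeddedTrajectory:
    """Embed ``x`` as points (x_i, x_{i+tau}, ..., x_{i+(d-1) tau})."""
    x = np.asarray(x, dtype=float)
    if tau < 1 or d < 1:
        raise ValueError("tau >= 1 and d >= 1 required")
    m = x.size - (d - 1) * tau
    if m < 1:
        raise ValueError(
            f"series of length {x.size} too short for d={d}, tau={tau}"
        )
    pts = np.column_stack([x[i * tau: i * tau + m] for i in range(d)])
    return EmbeddedTrajectory(pts, tau=tau, d=d, trial_id=trial_id)


def _nearest_neighbors(emb: np.ndarray, theiler: int,
                       chunk: int = 256) -> np.ndarray:
    """Exact nearest neighbor of each row, excluding |i-j| <= theiler.

    Exhaustive search, vectorized in chunks; returns -1 where no valid
    neighbor exists.
    """
    m = emb.shape[0]
    nn = np.full(m, -1, dtype=np.intp)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        dists = cdist(emb[start:stop], emb)
        for r in range(stop - start):
            i = start + r
            lo, hi = max(0, i - theiler), min(m, i + theiler + 1)
            dists[r, lo:hi] = np.inf
        rows_ok = np.isfinite(dists).any(axis=1)
        idx = np.argmin(dists, axis=1)
        nn[start:stop][rows_ok] = idx[rows_ok]
    return nn


def fnn_fraction(x: np.ndarray, tau: int, d: int, f: float = 10.0,
                 theiler: int = 500) -> float:
    """Percentage of false nearest neighbors at embedding dimension d.

    A point's neighbor (its exact nearest neighbor in the d-dimensional
    embedding, outside the Theiler window) is false when the added
    (d+1)-th coordinate moves the pair apart by more than ``f`` times
    their d-dimensional distance.
    """
    x = np.asarray(x, dtype=float)
    m = x.size - d * tau  # points for which the (d+1)-th coordinate exists
    if m < 2:
        raise ValueError("series too short for the d+1 coordinate")
    emb = np.column_stack([x[i * tau: i * tau + m] for i in range(d)])
    extra = x[d * tau: d * tau + m]
    nn = _nearest_neighbors(emb, theiler)
    valid = nn >= 0
    if not valid.any():
        raise DegenerateSeriesError(
            f"Theiler window {theiler} leaves no valid neighbors"
        )
    i_idx = np.nonzero(valid)[0]
    j_idx = nn[valid]
    r_d = np.sqrt(np.sum((emb[i_idx] - emb[j_idx]) ** 2, axis=1))
    jump = np.abs(extra[i_idx] - extra[j_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = jump / r_d
    # coincident d-dim points: false iff they separate in the new coordinate
    false = np.where(r_d > 0, ratio > f, jump > 0)
    return 100.0 * float(np.count_nonzero(false)) / float(i_idx.size)


def embedding_dimension(
    x: np.ndarray,
    tau: int,
    f: float = 10.0,
    threshold: float = 1.0,
    theiler: int = 500,
    d_max: int = 10,
    d_min_scan: int = 1,
) -> tuple[int, FNNCurve]:
    """Smallest d with FNN% below ``threshold``; raises NoEmbeddingError
    (curve attached) if the threshold is never met up to ``d_max``.

    ``d_min_scan`` forces the curve to be evaluated at least up to that
    dimension even if the threshold is met earlier (useful for reporting).
    """
    params = EmbeddingParams(tau=tau, d=1, f=f, theiler=theiler,
                             fnn_threshold=threshold, d_max=d_max)
    dims: list[int] = []
    pcts: list[float] = []
    d_e = None
    for d in range(1, d_max + 1):
        pct = fnn_fraction(x, tau, d, f=f, theiler=theiler)
        dims.append(d)
        pcts.append(pct)
        if d_e is None and pct < threshold:
            d_e = d
        if d_e is not None and d >= d_min_scan:
            break
    curve = FNNCurve(tuple(dims), tuple(pcts), params)
    if d_e is None:
        raise NoEmbeddingError(
            f"FNN never dropped below {threshold}% up to d={d_max}", curve=curve
        )
    return d_e, curve


def cluster_lag_table(lags, assignment) -> pd.DataFrame:
    """Per-cluster arithmetic mean of per-trial lags (samples).

    Parameters
    ----------
    lags : sequence of int
        Per-trial lag times, aligned with ``assignment``.
    assignment : sequence of int
        Cluster label per trial (e.g. ``ClusterResult.labels``).
    """
    lags = np.asarray(list(lags), dtype=float)
    labels = np.asarray(list(assignment))
    if lags.size != labels.size:
        raise ValueError("lags and assignment lengths differ")
    df = pd.DataFrame({"cluster": labels, "lag": lags})
    out = df.groupby("cluster")["lag"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_lag", "count": "n_trials"})
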