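"""Surrogate-data nonlinearity testing.

The null hypothesis is that the series comes from a linear Gaussian process
(possibly observed through a static transform).  Surrogates realize the
null: they share the original's amplitude spectrum — hence all linear
autocorrelations — but have their Fourier phases randomized, destroying any
nonlinear structure.

A discriminating statistic lambda is computed for the original (lambda_0)
and for each of n surrogates (lambda_i).  Three rejection rules are
applied:

* **rank** — lambda_0 is the strict extreme (smallest or largest) of the
  pooled ordered list; at least n >= 1/l surrogates are required for
  significance level l (20 for l = 0.05), and that bound is enforced.
* **average** — gamma = |lambda_bar / lambda_0 - 1| > 1.
* **coefficient of variation** — gamma = |lambda_bar - lambda_0| / sigma_lambda
  exceeds the two-sided standard-normal critical value (1.96 at 95%).

The default statistic is time-reversal asymmetry: the ratio of the third
to the second moment of the delta-lagged increments, which vanishes for
time-reversible (linear Gaussian) processes.  The false-nearest-neighbor
percentage can be used as an alternative statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import embedding as _embedding
from .exceptions import DegenerateSeriesError

CV_CRITICAL_95 = 1.96  # two-sided standard-normal critical value at 95%


def minimum_surrogates(significance: float = 0.05) -> int:
    """Smallest surrogate count n with n >= 1/l (20 for l = 0.05)."""
    if not 0 < significance < 1:
        raise ValueError("significance must be in (0, 1)")
    return math.ceil(1.0 / significance - 1e-12)


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Original statistic lambda_0 plus the surrogate statistics."""

    lambda0: float
    lambdas: tuple[float, ...]
    statistic_name: str = "time_reversal_asymmetry"

    def __post_init__(self):
        if len(self.lambdas) < 1:
            raise ValueError("need at least one surrogate statistic")
        vals = np.asarray(self.lambdas, dtype=float)
        if not (np.isfinite(self.lambda0) and np.all(np.isfinite(vals))):
            raise ValueError("all statistics must be finite")
        object.__setattr__(self, "lambdas", tuple(float(v) for v in vals))

    @property
    def n(self) -> int:
        return len(self.lambdas)

    @property
    def lambda_mean(self) -> float:
        return float(np.mean(self.lambdas))

    @property
    def lambda_sd(self) -> float:
        """Sample (n-1 denominator) standard deviation of the surrogates."""
        if self.n < 2:
            return 0.0
        return float(np.std(self.lambdas, ddof=1))


@dataclass(frozen=True)
class NonlinearityReport:
    """Decisions of the three surrogate rejection rules for one trial."""

    ensemble: SurrogateEnsemble
    gamma_avg: float            # |lambda_bar/lambda_0 - 1|, nan if lambda_0 = 0
    gamma_cv: float             # |lambda_bar - lambda_0| / sigma, nan if sigma = 0
    rank_position: int          # 1..n+1, position of lambda_0 (after ties)
    reject_rank: bool
    reject_avg: bool
    reject_cv: bool
    avg_threshold: float = 1.0
    cv_threshold: float = CV_CRITICAL_95
    degenerate_avg: bool = False   # lambda_0 == 0: average rule undefined
    degenerate_cv: bool = False    # sigma == 0: CV rule undefined

    @property
    def reject_any(self) -> bool:
        return self.reject_rank or self.reject_avg or self.reject_cv


def make_surrogate(x: np.ndarray, seed=None) -> np.ndarray:
    """Fourier-phase-randomized surrogate of ``x``.

    Same length and same amplitude spectrum; phases of all non-DC,
    non-Nyquist bins drawn uniformly on [0, 2pi) with Hermitian symmetry,
    so the output is real and the mean is preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series too short for a surrogate (need length >= 4)")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    nbins = spec.size
    # bins 1..(nbins-2) are free; the last bin is Nyquist only for even n
    last_free = nbins - 1 if n % 2 else nbins - 2
    phases = rng.uniform(0.0, 2.0 * np.pi, size=max(last_free, 0))
    new = spec.copy()
    new[1: last_free + 1] = np.abs(spec[1: last_free + 1]) * np.exp(1j * phases)
    return np.fft.irfft(new, n)


def time_reversal_asymmetry(x: np.ndarray, delta: int = 1) -> float:
    """Time-reversal asymmetry statistic at increment lag ``delta``.

    lambda(delta) = sum (x_t - x_{t-delta})^3 / sum (x_t - x_{t-delta})^2.
    Exactly antisymmetric under time reversal; ~0 for time-symmetric series.
    """
    x = np.asarray(x, dtype=float)
    if delta < 1 or delta >= x.size:
        raise ValueError("delta must satisfy 1 <= delta < len(x)")
    inc = x[delta:] - x[:-delta]
    denom = float(np.sum(inc * inc))
    if denom == 0.0:
        raise DegenerateSeriesError("constant series: statistic undefined")
    return float(np.sum(inc ** 3)) / denom


def fnn_statistic(x: np.ndarray, tau: int, d: int, f: float = 10.0,
                  theiler: int = 500) -> float:
    """FNN percentage as a discriminating statistic (delegates to embedding)."""
    return _embedding.fnn_fraction(x, tau, d, f=f, theiler=theiler)


def test_nonlinearity(
    x: np.ndarray,
    n_surrogates: int = 100,
    statistic: Callable[[np.ndarray], float] | str = "timerev",
    seed=None,
    significance: float = 0.05,
    zscore: bool = True,
    avg_threshold: float = 1.0,
    cv_threshold: float = CV_CRITICAL_95,
    statistic_kwargs: dict | None = None,
) -> NonlinearityReport:
    """Run the three surrogate rejection rules on one series.

    The series is z-scored before the statistic is evaluated (default), so
    statistic values are scale-free and comparable across trials; surrogates
    are generated from the same (z-scored) series.  Ties between lambda_0
    and a surrogate block rejection by the rank rule (conservative).
    """
    if n_surrogates < minimum_surrogates(significance):
        raise ValueError(
            f"n_surrogates={n_surrogates} below the minimum "
            f"{minimum_surrogates(significance)} for significance {significance}"
        )
    x = np.asarray(x, dtype=float)
    if zscore:
        sd = x.std()
        if sd == 0:
            raise DegenerateSeriesError("constant series cannot be z-scored")
        x = (x - x.mean()) / sd

    kwargs = statistic_kwargs or {}
    if statistic == "timerev":
        stat, name = (lambda s: time_reversal_asymmetry(s, **kwargs)), "time_reversal_asymmetry"
    elif statistic == "fnn":
        stat, name = (lambda s: fnn_statistic(s, **kwargs)), "fnn_percentage"
    elif callable(statistic):
        stat, name = (lambda s: statistic(s, **kwargs)), getattr(
            statistic, "__name__", "custom")
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    rng = np.random.default_rng(seed)
    lambda0 = stat(x)
    lambdas = []
    for _ in range(n_surrogates):
        lambdas.append(stat(make_surrogate(x, seed=rng)))
    ens = SurrogateEnsemble(lambda0, tuple(lambdas), statistic_name=name)

    lam = np.asarray(ens.lambdas)
    n_below = int(np.count_nonzero(lam < lambda0))
    n_above = int(np.count_nonzero(lam > lambda0))
    n_tied = ens.n - n_below - n_above
    rank_position = 1 + n_below + n_tied  # lambda_0 placed after any ties
    reject_rank = (n_below == ens.n) or (n_above == ens.n)  # strict extreme

    degenerate_avg = lambda0 == 0.0
    gamma_avg = math.nan if degenerate_avg else abs(ens.lambda_mean / lambda0 - 1.0)
    reject_avg = (not degenerate_avg) and gamma_avg > avg_threshold

    sigma = ens.lambda_sd
    degenerate_cv = sigma == 0.0
    gamma_cv = math.nan if degenerate_cv else abs(ens.lambda_mean - lambda0) / sigma
    reject_cv = (not degenerate_cv) and gamma_cv > cv_threshold

    return NonlinearityReport(
        ensemble=ens,
        gamma_avg=gamma_avg,
        gamma_cv=gamma_cv,
        rank_position=rank_position,
        reject_rank=reject_rank,
        reject_avg=reject_avg,
        reject_cv=reject_cv,
        avg_threshold=avg_threshold,
        cv_threshold=cv_threshold,
        degenerate_avg=degenerate_avg,
        degenerate_cv=degenerate_cv,
    )


def gamma_scores(ensemble: SurrogateEnsemble) -> tuple[float, float]:
    """(gamma_avg, gamma_cv) for a precomputed ensemble; nan when undefined."""
    g_avg = (math.nan if ensemble.lambda0 == 0
             else abs(ensemble.lambda_mean / ensemble.lambda0 - 1.0))
    sd = ensemble.lambda_sd
    g_cv = (math.nan if sd == 0
            else abs(ensemble.lambda_mean - ensemble.lambda0) / sd)
    return g_avg, g_cv
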