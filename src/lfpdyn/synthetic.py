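"""Synthetic LFP generator.

Emulates the statistical structure the downstream analysis assumes in
optogenetically evoked prefrontal LFPs: a dominant slow oscillation with a
phase-locked second harmonic (whose delay embedding is a figure-8 closed
orbit that needs three dimensions to unfold), a small fast gamma component,
stimulus-locked phase resetting that decays within the discarded transient,
trial-to-trial phase/amplitude jitter, and colored (AR(1)) observation
noise.  A "treated" preset runs the same oscillator with its intrinsic time
scale sped up (default 3x), reproducing the shortened delay-time scale that
the analysis is meant to detect.

The model for trial j is::

    x(t) = A (1 + a_j) [ sin(2 pi f0 t + phi_j + r(t))
                         + h sin(4 pi f0 t + 2 phi_j + psi) ]
           + A g sin(2 pi f_gamma t) + eta(t)

with phi_j ~ N(0, phase_jitter_sd), a_j ~ N(0, amp_jitter_sd),
r(t) = rho_j exp(-t / transient_tau) the phase-reset transient with
rho_j ~ N(0, reset_magnitude_sd), and eta an AR(1) process with stationary
standard deviation ``noise_sd * A``.

Randomness is fully reproducible: each trial draws from an independent
substream keyed by (master seed, condition, trial index), so adding trials
or generating conditions in a different order never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import pi

import numpy as np
from scipy.signal import lfilter

from .trials import Trial, TrialSet

_CONDITION_CODE = {"control": 0, "treated": 1}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic LFP oscillator.

    Defaults are calibrated so that the control preset's steady-window
    autocorrelation first zero falls near 0.21-0.25 s (the lag scale of
    ~1 Hz cortical slow oscillations) and the treated preset is three times
    faster.
    """

    f0: float = 1.0                  # fundamental frequency, Hz
    amplitude: float = 10.0          # A, arbitrary units (LFP scale is unitless here)
    harmonic_ratio: float = 0.5      # h, second-harmonic amplitude relative to A
    harmonic_phase: float = pi / 2   # psi, makes the 3-D orbit an "8"
    gamma_freq: float = 40.0         # Hz
    gamma_amp: float = 0.15          # relative to A
    phase_jitter_sd: float = 0.8     # radians, per trial
    amp_jitter_sd: float = 0.1       # relative, per trial
    noise_sd: float = 0.05           # stationary sd of colored noise, relative to A
    ar_coeff: float = 0.9            # AR(1) coefficient of the noise
    transient_tau: float = 0.15      # s, phase-reset decay constant
    reset_magnitude_sd: float = 1.5  # radians, sd of the per-trial reset
    duration: float = 2.0            # s
    dt: float = 1e-4                 # s
    n_trials: int = 100
    seed: int = 0
    condition: str = "control"
    animal_id: int = 1

    def __post_init__(self):
        if self.f0 <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("f0, dt and duration must be positive")
        if min(self.phase_jitter_sd, self.amp_jitter_sd, self.noise_sd,
               self.reset_magnitude_sd) < 0:
            raise ValueError("jitter/noise standard deviations must be >= 0")
        if not abs(self.ar_coeff) < 1:
            raise ValueError("|ar_coeff| must be < 1 for a stationary AR(1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _trial_rng(params: GeneratorParams, trial_index: int) -> np.random.Generator:
    code = _CONDITION_CODE.get(params.condition, 2)
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), code, int(trial_index)])
    )


def generate_trial(params: GeneratorParams, trial_index: int) -> Trial:
    """Generate one trial; deterministic given (params, trial_index)."""
    rng = _trial_rng(params, trial_index)
    n = int(round(params.duration / params.dt))
    t = np.arange(n) * params.dt

    phi = rng.normal(0.0, params.phase_jitter_sd) if params.phase_jitter_sd else 0.0
    amp_j = rng.normal(0.0, params.amp_jitter_sd) if params.amp_jitter_sd else 0.0
    rho = (rng.normal(0.0, params.reset_magnitude_sd)
           if params.reset_magnitude_sd else 0.0)
    reset = rho * np.exp(-t / params.transient_tau)

    a = params.amplitude
    x = a * (1.0 + amp_j) * (
        np.sin(2 * pi * params.f0 * t + phi + reset)
        + params.harmonic_ratio
        * np.sin(4 * pi * params.f0 * t + 2 * phi + params.harmonic_phase)
    )
    if params.gamma_amp:
        x = x + a * params.gamma_amp * np.sin(2 * pi * params.gamma_freq * t)
    if params.noise_sd:
        sigma = params.noise_sd * a
        innov_sd = sigma * np.sqrt(1.0 - params.ar_coeff ** 2)
        e = rng.normal(0.0, innov_sd, size=n)
        noise = lfilter([1.0], [1.0, -params.ar_coeff], e)
        noise[:] += rng.normal(0.0, sigma) * params.ar_coeff ** np.arange(1, n + 1)
        x = x + noise
    return Trial(x, dt=params.dt, trial_id=trial_index, condition=params.condition,
                 animal_id=params.animal_id)


def generate_trialset(params: GeneratorParams) -> TrialSet:
    """Generate ``params.n_trials`` trials from independent substreams."""
    return TrialSet(tuple(generate_trial(params, i) for i in range(params.n_trials)))


def generate_condition_pair(
    control: GeneratorParams | None = None,
    speedup: float = 3.0,
    seed: int | None = None,
) -> tuple[TrialSet, TrialSet]:
    """Generate a (control, treated) pair of trial sets.

    The treated condition is the same oscillator with ``f0`` multiplied by
    ``speedup`` (default 3, matching a roughly threefold intrinsic-time-scale
    acceleration); all other parameters are shared.  Random streams are
    independent between the two conditions.
    """
    if speedup <= 0:
        raise ValueError("speedup must be positive")
    if control is None:
        control = GeneratorParams()
    if seed is not None:
        control = replace(control, seed=seed)
    control = replace(control, condition="control")
    treated = replace(control, f0=control.f0 * speedup, condition="treated")
    return generate_trialset(control), generate_trialset(treated)


def control_preset(seed: int = 0, n_trials: int = 100, **overrides) -> GeneratorParams:
    return GeneratorParams(seed=seed, n_trials=n_trials, condition="control",
                           **overrides)


def cocaine_preset(seed: int = 0, n_trials: int = 100, speedup: float = 3.0,
                   **overrides) -> GeneratorParams:
    """The "treated" preset: intrinsic time scale sped up (default 3x)."""
    base = GeneratorParams(seed=seed, n_trials=n_trials, condition="treated",
                           **overrides)
    return replace(base, f0=base.f0 * speedup)
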