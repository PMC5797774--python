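# Methods

## Scope and data model

The package analyzes multi-trial, uniformly sampled LFP recordings: a
`TrialSet` of equally long sweeps sharing a sampling step `dt`, each
labelled with a condition (`control`/`treated`) and an animal id. The
reference protocol is 2 s sweeps at 10 kHz, 100 trials per condition; the
first 0.5 s of each sweep — the stimulus-locked transient — is discarded
("approximately 0.5 s" is implemented as exactly 0.5 s, configurable), so
analysis operates on 15,000-sample steady windows. Amplitude units are
not enforced; every statistic is either unit-covariant or computed on
z-scored series where cross-trial comparability matters.

## Synthetic LFP generator

No recordings ship with the package, so a generator provides trial sets
with the statistical structure the analysis assumes. Trial j of the
control preset is

    x(t) = A (1 + a_j) [ sin(2π f₀ t + φ_j + r(t))
                         + h sin(4π f₀ t + 2φ_j + ψ) ]
           + A g sin(2π f_γ t) + η(t)

| parameter | default | meaning |
|---|---|---|
| f₀ | 1 Hz | fundamental frequency of the slow rhythm |
| A | 10 (arb.) | amplitude; the data's scale is arbitrary |
| h | 0.5 | second-harmonic amplitude relative to A |
| ψ | π/2 | harmonic phase: makes the orbit a figure-8 |
| f_γ, g | 40 Hz, 0.15 | small gamma-band component |
| φ_j | N(0, 0.8 rad) | per-trial phase jitter |
| a_j | N(0, 0.1) | per-trial relative amplitude jitter |
| r(t) | ρ_j e^{−t/0.15 s}, ρ_j ~ N(0, 1.5 rad) | stimulus-locked phase reset |
| η | AR(1), ar = 0.9, sd 0.05·A | colored observation noise |

The treated ("cocaine") preset is the same oscillator with f₀ tripled —
the intrinsic-time-scale contrast the lag analysis is meant to detect.
Per-trial random substreams are keyed by (master seed, condition, trial
index), so adding trials or reordering conditions never changes earlier
draws.

Why this model: a fundamental plus a phase-locked second harmonic is the
simplest process whose delay embedding is a closed figure-8 — an orbit
that self-intersects in two dimensions and unfolds in three, which is
exactly the geometry the FNN analysis must resolve. The harmonic phase
ψ = π/2 gives x = sin θ + ½cos 2θ, which is mirror-symmetric about its
peaks: the waveform is **time-reversible**, with consequences for the
surrogate tests noted below. The phase-reset transient decays to under 4%
of its initial size by 0.5 s, which is what justifies the steady-window
discard.

What the generator does **not** emulate: real LFP broadband (1/f)
background, non-stationarity across trials, cross-condition waveform
similarity (see "Overlap" below), or any biophysics — it is a statistical
stand-in, not a cortical model. Passing tests demonstrate that the
analysis chain recovers known structure from data of this kind, not that
it would behave identically on recordings.

## Surrogate nonlinearity testing

Surrogates are built by randomizing the Fourier phases of all non-DC,
non-Nyquist bins (Hermitian symmetry preserved), which keeps the
amplitude spectrum — hence all linear autocorrelations and the mean —
while destroying nonlinear structure. At significance l, at least
n = 1/l surrogates are required (20 at l = 0.05); the bound is enforced.

The default discriminating statistic is time-reversal asymmetry
λ(δ) = Σ(x_t − x_{t−δ})³ / Σ(x_t − x_{t−δ})², δ = 1 by default. The
statistic itself is computed on raw values (exactly antisymmetric under
reversal); `test_nonlinearity` z-scores the series first so λ values are
scale-free and comparable across trials. Three rejection rules are
reported per trial:

* **rank**: λ₀ strictly below or strictly above every λᵢ; ties with a
  surrogate block rejection (conservative).
* **average**: γ = |λ̄/λ₀ − 1| > 1. Undefined at λ₀ = 0; reported as
  NaN/flagged, never as a rejection. Note this ratio is unstable for
  small |λ₀| — near-zero statistics can produce large γ without any real
  effect, so the average rule should be read alongside the other two.
* **coefficient of variation**: γ = |λ̄ − λ₀|/σ_λ > 1.96 (95% two-sided
  normal critical value), σ_λ with the n−1 denominator. The acceptance
  suite verifies this rule holds its 5% nominal size on linear Gaussian
  AR(1) draws.

Caveat specific to the generator: because the default waveform is
time-reversible (ψ = π/2 above), the time-reversal statistic carries no
structural signal on synthetic trials — its rejections hover near the
nominal rate, with the average rule firing mainly through its small-λ₀
instability. The nonlinear structure of the figure-8 orbit **is** picked
up by the alternative FNN discriminating statistic (surrogates of a
control trial show severalfold higher FNN% at d = 3 than the original),
which is the statistic the power property test uses. On real, generically
irreversible LFPs the time-reversal statistic is the cheap first choice.

## Phase alignment

Each trial is circularly shifted to maximize its Pearson correlation with
a reference trial (default: the first; alternatives: a chosen index, or
the trial with the highest mean absolute zero-shift correlation to all
others). The argmax is exhaustive over all N shifts, evaluated via the
FFT correlation theorem on z-scored series and tested against the
brute-force argmax; ties break toward the smallest shift. Alignment never
lowers the correlation (shift 0 is in the search set). The rms error
reported is √mean((a−b)²), length-invariant.

Cluster refinement re-aligns each trial to its (fixed) cluster mean with
an rms objective: a circular shift preserves Σx², so minimizing rms
against a fixed target is exactly maximizing the raw circular
cross-covariance; this guarantees the per-trial rms never increases.

A structural caveat: circularly shifting a window that does not hold an
integer number of oscillation periods splices a discontinuity into the
middle of the series (the old endpoints become interior neighbors).
Downstream statistics that embed aligned trials see that splice as a
genuine trajectory defect — on synthetic data it raises FNN percentages
by a few points and can push the estimated d_E up by one. Embedding
unaligned steady windows avoids the artifact; alignment matters for
clustering and averaging, not for per-trial embedding.

## Clustering and the overlap index

Trials enter clustering as whole, aligned, raw-amplitude traces (no
z-scoring: amplitude differences are real cluster structure). Pairwise
Euclidean distances feed agglomerative clustering — single linkage by
default, matching MATLAB's hierarchical-clustering default;
ward/complete/average are available. The tree is
cut at a fixed k (6 and 12 by default for the pooled analysis); the
smallest height whose cut yields ≤ k clusters is reported as the
distance threshold.

For a pooled two-condition set, each cluster's overlap is
min(#before, #after)/#total ∈ [0, 0.5] — 0 for a pure cluster, 0.5 for a
perfectly mixed one — and the summary is the unweighted mean over
clusters, in percent (a size-weighted variant is a one-liner on the
per-cluster table). The index is invariant to swapping the condition
labels.

Limitation: with the threefold time-scale contrast of the default
presets, control and treated traces are linearly separable as whole
vectors, so the synthetic pooled overlap is 0% at any k — the generator
does not reproduce the partial (~20%) mixing seen in real recordings,
which reflects real-data heterogeneity within conditions.

## Lag selection and delay embedding

The lag τ is the autocorrelation first zero: the smallest integer lag at
which the biased (1/N), FFT-computed, mean-subtracted autocorrelation
becomes ≤ 0. For a pure sinusoid this is the quarter period up to the
small (few percent) bias the finite window introduces. The AMI
alternative — first minimum of I(τ) over a 16-bin equal-width joint
histogram, in bits — is implemented with an optional robustness window
because the binned AMI of clean periodic signals wiggles on a fine scale
as samples cross bin boundaries, producing spurious micro-minima; on
multi-component signals its first minimum tracks the fastest component.
Autocorrelation is the default lag estimator throughout.

Embedding is exact: point i of the d-dimensional trajectory is
(x_i, x_{i+τ}, …, x_{i+(d−1)τ}); there are N − (d−1)τ points. Each trial
is embedded at its own lag.

FNN: for every point with a defined (d+1)-th coordinate, the exact
nearest neighbor (Euclidean) is found among points more than `theiler`
samples away in time (default 500 = 0.05 s at 10 kHz); the pair is false
when the new coordinate separates it by more than f (default 10) times
its d-dimensional distance. Coincident d-dimensional points count as
false only if the new coordinate splits them. The neighbor search is an
exhaustive vectorized scan, verified exactly against a plain-loop oracle;
FNN% is monotone non-increasing in f. d_E is the smallest d with FNN%
below 1% (threshold configurable); if the threshold is never met up to
d_max the error carries the full curve. Only the distance-ratio
criterion is implemented; a second "attractor-size" criterion common in
the literature is intentionally omitted because the ratio test is the
defined contract here.

On default control-preset trials the figure-8 geometry yields d_E = 3
(d = 2 shows tens of percent false neighbors). Two caveats, both
diagnosed by ablation: the 40 Hz component plus colored noise make the
true synthetic system a weakly noisy two-torus, so per-trial FNN% at
d = 3 scatters around the 1% threshold and individual trials (or
unlucky seeds) can report d_E = 4 — with gamma and noise switched off the
figure-8 gives exactly 0% at d = 3 for any Theiler window in 100–8000.
The effect is stronger for the treated preset (threefold faster orbit,
so the fixed-frequency gamma and noise weigh more per cycle): its
unfolding typically needs d = 4–5 rather than matching the control's 3.
And a very small Theiler window (~100) admits noise-dominated,
temporally-close neighbor pairs, inflating FNN on noisy data.

## Attractor comparison

The discrete Fréchet distance between two embedded orbits is the
Eiter–Mannila coupling distance, computed by an O(nm) dynamic program
over the pairwise-distance matrix (numba-accelerated when available,
identical results without), and verified against exhaustive enumeration
of all monotone couplings on short sequences. It is symmetric,
nonnegative, zero only on identical sequences, never below the Hausdorff
distance, and scales homogeneously with the coordinates. Orbits are
decimated (default every 10th point in the library, 25th in the analysis
driver) before the DP — full 15,000²-cell tables per pair are
impractical at 100×100 pairs, and the distance between smooth decimated
curves is stable. The decimation step is recorded in the output.

Per-trial lag distributions are long-tailed and positive, so each
condition's lags are fitted with a lognormal: μ = mean(log τ),
σ = sd(log τ, n−1), center = exp(μ) — the distribution median, equal to
the sample geometric mean ("center" is the median by choice; the
alternative, the lognormal mean exp(μ+σ²/2), is a one-liner from the
reported parameters). The condition contrast is the ratio of centers,
control over treated; on default presets it recovers the threefold
speedup within ~5% (2.8–2.9 at 100 trials per condition).

## Pipeline and reproducibility

`run_pipeline(PipelineConfig)` executes the stages in order — simulate or
load, steady windows, surrogate tests, alignment, clustering plus
refinement, per-trial lags and lognormal fits, FNN on a subset,
pooled-condition overlap, and a Fréchet matrix — and writes a JSON report
plus CSV tables. All randomness derives from the master seed; the report
is byte-identical across reruns of the same config. Per-trial
nonlinearity decisions are reported raw (no multiplicity correction)
alongside the Bonferroni per-trial level for
transparency.

Problem sizes in the shipped drivers and acceptance script — 10 trials
for FNN scans, 100 for lag statistics, 10×10 Fréchet blocks at decimation
25, 20-trial surrogate screens — were chosen so each step completes in
seconds to a couple of minutes while keeping the Monte-Carlo error of
every reported quantity well inside its acceptance band.

## Known limitations

* The generator's nonlinearity is invisible to the time-reversal
  statistic (mirror-symmetric waveform); use the FNN statistic on
  synthetic data.
* Aligned (circularly shifted) trials carry a splice discontinuity;
  embed unaligned windows when estimating d_E.
* The synthetic pooled-condition overlap is degenerate (0%): the
  conditions are too separable for the index to show partial mixing.
* d_E on default noisy presets is seed-sensitive around the 1% FNN
  threshold (noisy two-torus); the clean preset is exactly 3-dimensional.
* AMI first-minimum lag selection is unreliable on clean periodic or
  multi-scale signals; autocorrelation is the default for a reason.
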