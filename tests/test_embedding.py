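"""Lag selection, delay embedding and false-nearest-neighbor estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lfpdyn import (
    ami,
    ami_lag,
    autocorr_lag,
    cluster_lag_table,
    delay_embed,
    embedding_dimension,
    fnn_fraction,
)
from lfpdyn.embedding import _bin_codes, _ami_from_codes
from lfpdyn.exceptions import (
    NoEmbeddingError,
    NoMinimumError,
    NoZeroCrossingError,
)


class TestAutocorrLag:
    @pytest.mark.parametrize("period", [40, 100, 10000])
    def test_sinusoid_quarter_period(self, period):
        """The first zero sits at the quarter period, up to the small bias
        the finite-window (biased, mean-subtracted) estimator introduces."""
        n = max(4 * period, 2 * period + 10)
        x = np.sin(2 * np.pi * np.arange(n) / period)
        lag = autocorr_lag(x)
        assert abs(lag - period / 4) <= max(1, 0.05 * period / 4)

    def test_white_noise_decorrelates_immediately(self, rng):
        lags = [autocorr_lag(rng.standard_normal(4096)) for _ in range(20)]
        # brute-force check on one draw: r(1) of white noise is ~0,
        # so the first nonpositive value is found at a tiny lag
        assert np.median(lags) <= 2

    def test_positive_series_without_crossing_errors(self):
        # a slow ramp keeps its acf positive over the first few lags
        x = np.arange(100.0)
        with pytest.raises(NoZeroCrossingError):
            autocorr_lag(x, max_lag=10)


class TestAMI:
    def test_two_level_series_is_one_bit(self):
        # 101 samples -> 100 lag-1 pairs, 50 of each kind: exactly 1 bit
        x = np.array([0.0, 1.0] * 50 + [0.0])
        assert ami(x, lag=1, bins=2) == pytest.approx(1.0)

    def test_hand_computed_histogram_oracle(self):
        """AMI equals the direct sum over an explicitly tabulated 2x2
        histogram for a small asymmetric two-level series."""
        x = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        # lag-1 pairs: (0,0),(0,1),(1,0),(0,1),(1,1),(1,0),(0,0)
        counts = {(0, 0): 2, (0, 1): 2, (1, 0): 2, (1, 1): 1}
        n = 7
        expected = 0.0
        for (i, j), c in counts.items():
            pij = c / n
            pi = sum(v for (a, _), v in counts.items() if a == i) / n
            pj = sum(v for (_, b), v in counts.items() if b == j) / n
            expected += pij * np.log2(pij / (pi * pj))
        assert ami(x, lag=1, bins=2) == pytest.approx(expected)

    def test_lag_zero_equals_marginal_entropy(self, rng):
        x = rng.standard_normal(512)
        codes = _bin_codes(x, 16)
        counts = np.bincount(codes, minlength=16)
        p = counts[counts > 0] / x.size
        assert ami(x, 0, bins=16) == pytest.approx(-np.sum(p * np.log2(p)))

    def test_independent_pairs_have_near_zero_ami(self, rng):
        x = rng.uniform(size=20000)
        assert ami(x, lag=1000, bins=8) < 0.01

    def test_ami_lag_matches_bruteforce_scan(self, rng):
        """ami_lag returns the smallest lag whose AMI is strictly below all
        neighbors within the window — checked against a naive scan."""
        x = np.sin(2 * np.pi * np.arange(600) / 150) + \
            0.3 * rng.standard_normal(600)
        for window in (1, 5):
            bins = 8
            codes = _bin_codes(x, bins)
            curve = np.array([_ami_from_codes(codes, l, bins)
                              for l in range(300 + window + 1)])
            expected = None
            for lag in range(1, 300):
                lo, hi = max(0, lag - window), lag + window
                seg = np.delete(curve[lo: hi + 1], lag - lo)
                if np.all(curve[lag] < seg):
                    expected = lag
                    break
            got = ami_lag(x, bins=bins, max_lag=300, window=window)
            assert got == expected

    def test_monotone_ami_raises(self):
        x = np.arange(64.0)  # AMI decreases monotonically with lag
        with pytest.raises(NoMinimumError):
            ami_lag(x, bins=4, max_lag=10)

    def test_deterministic(self, rng):
        x = rng.standard_normal(256)
        assert ami_lag(x, bins=8) == ami_lag(x, bins=8)


class TestDelayEmbed:
    def test_worked_examples(self):
        traj = delay_embed(np.array([1.0, 2, 3, 4, 5, 6]), tau=2, d=2)
        np.testing.assert_array_equal(
            traj.points, [[1, 3], [2, 4], [3, 5], [4, 6]])
        traj3 = delay_embed(np.arange(1.0, 7.0), tau=1, d=3)
        np.testing.assert_array_equal(
            traj3.points, [[1, 2, 3], [2, 3, 4], [3, 4, 5], [4, 5, 6]])

    def test_d1_is_identity(self, rng):
        x = rng.standard_normal(16)
        np.testing.assert_array_equal(delay_embed(x, 3, 1).points[:, 0], x)

    @given(st.integers(10, 200), st.integers(1, 10), st.integers(1, 5))
    def test_point_count_invariant(self, n, tau, d):
        x = np.arange(float(n))
        if n - (d - 1) * tau < 1:
            with pytest.raises(ValueError):
                delay_embed(x, tau, d)
        else:
            assert len(delay_embed(x, tau, d)) == n - (d - 1) * tau


def brute_force_fnn(x, tau, d, f, theiler):
    """Plain-loop exhaustive FNN oracle."""
    m = len(x) - d * tau
    emb = [[x[i + k * tau] for k in range(d)] for i in range(m)]
    extra = [x[i + d * tau] for i in range(m)]
    n_false = n_valid = 0
    for i in range(m):
        best, best_j = None, None
        for j in range(m):
            if abs(i - j) <= theiler:
                continue
            dist = sum((a - b) ** 2 for a, b in zip(emb[i], emb[j])) ** 0.5
            if best is None or dist < best:
                best, best_j = dist, j
        if best_j is None:
            continue
        n_valid += 1
        jump = abs(extra[i] - extra[best_j])
        if (jump > f * best) if best > 0 else (jump > 0):
            n_false += 1
    return 100.0 * n_false / n_valid


class TestFNN:
    def test_matches_exhaustive_search(self, rng):
        """Vectorized neighbor search equals the plain-loop oracle exactly
        on random walks and noisy sinusoids up to N = 500."""
        for x in (
            np.cumsum(rng.standard_normal(300)),
            np.sin(2 * np.pi * np.arange(500) / 125)
            + 0.1 * rng.standard_normal(500),
        ):
            for d, theiler in ((1, 0), (2, 5), (3, 20)):
                got = fnn_fraction(x, tau=7, d=d, f=5.0, theiler=theiler)
                want = brute_force_fnn(x, 7, d, 5.0, theiler)
                assert got == pytest.approx(want)

    def test_noiseless_sinusoid_zero_at_d2(self):
        # incommensurate period: revisiting cycles come close but never
        # coincide exactly, keeping the distance ratio well defined
        x = np.sin(2 * np.pi * np.arange(2000) / 401.3)
        assert fnn_fraction(x, tau=100, d=2, f=10.0, theiler=10) == 0.0

    def test_white_noise_high_at_low_d(self, rng):
        x = rng.standard_normal(1000)
        assert fnn_fraction(x, tau=1, d=1, f=5.0, theiler=2) > 20.0

    def test_monotone_nonincreasing_in_f(self, rng):
        x = np.cumsum(rng.standard_normal(400))
        pcts = [fnn_fraction(x, tau=3, d=2, f=f, theiler=5)
                for f in (2.0, 5.0, 10.0, 20.0)]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))


class TestEmbeddingDimension:
    def test_sinusoid_embeds_in_two(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 401.3)
        d_e, curve = embedding_dimension(x, tau=100, theiler=10, d_max=4)
        assert d_e == 2
        assert curve.as_dict()[2] < 1.0

    def test_white_noise_never_embeds(self, rng):
        x = rng.standard_normal(800)
        with pytest.raises(NoEmbeddingError) as exc:
            embedding_dimension(x, tau=1, theiler=2, d_max=3)
        assert len(exc.value.curve.dims) == 3

    def test_figure_eight_needs_three_dimensions(self):
        """The harmonic figure-8 orbit self-intersects in the plane and
        unfolds in 3-D; Theiler-window choice does not move d_E."""
        from dataclasses import replace
        from lfpdyn import control_preset, generate_trial, steady_window

        p = control_preset(seed=1, n_trials=1, phase_jitter_sd=0.0,
                           amp_jitter_sd=0.0, noise_sd=0.0,
                           reset_magnitude_sd=0.0, gamma_amp=0.0)
        x = steady_window(generate_trial(p, 0)).samples
        tau = autocorr_lag(x)
        for theiler in (100, 500, 2000, 8000):
            d_e, curve = embedding_dimension(x, tau, theiler=theiler, d_max=4)
            assert d_e == 3
            assert curve.as_dict()[2] > 1.0


class TestClusterLagTable:
    def test_uniform_lags(self):
        table = cluster_lag_table([5, 5, 5, 5], [1, 1, 2, 2])
        assert (table["mean_lag"] == 5).all()

    def test_mean_and_singleton(self):
        table = cluster_lag_table([1724, 1810, 999], [1, 1, 2])
        by = dict(zip(table["cluster"], table["mean_lag"]))
        assert by[1] == pytest.approx(1767.0)
        assert by[2] == pytest.approx(999.0)
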