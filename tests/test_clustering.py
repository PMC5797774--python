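"""Hierarchical trial clustering, refinement and the overlap index."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lfpdyn import (
    Trial,
    TrialSet,
    ClusterResult,
    condition_overlap_analysis,
    hcluster,
    overlap_index,
    refine_alignment,
)


def _tset(arrays, dt=1e-3, condition="control"):
    return TrialSet(tuple(
        Trial(np.asarray(a, dtype=float), dt=dt, trial_id=i + 1,
              condition=condition)
        for i, a in enumerate(arrays)
    ))


def _result_for_labels(labels, n_samples=4):
    """Minimal ClusterResult with the given per-trial labels."""
    labels = np.asarray(labels)
    means = {int(l): np.zeros(n_samples) for l in np.unique(labels)}
    return ClusterResult(labels=labels, k=len(means),
                         merge_heights=np.array([]), cluster_means=means,
                         distance_threshold=0.0)


class TestHCluster:
    def test_identical_trials_single_cluster(self, rng):
        x = rng.standard_normal(32)
        res = hcluster(_tset([x] * 5), k=1)
        assert res.k == 1
        assert res.distance_threshold == 0.0
        np.testing.assert_allclose(res.cluster_means[1], x)

    def test_two_separated_groups_recovered(self, rng):
        """Rolled sinusoids vs pure-noise traces: between-group distance far
        exceeds within-group distance, so k=2 recovers the partition."""
        n = 256
        t = np.arange(n)
        sines = [10 * np.sin(2 * np.pi * (t - r) / 64) for r in (0, 1, 2)]
        noise = [0.1 * rng.standard_normal(n) for _ in range(3)]
        res = hcluster(_tset(sines + noise), k=2)
        labels = res.labels
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equals_n(self, rng):
        tset = _tset(rng.standard_normal((4, 16)))
        res = hcluster(tset, k=4)
        assert sorted(res.labels) == [1, 2, 3, 4]

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            hcluster(_tset(rng.standard_normal((3, 8))), k=4)

    def test_merge_heights_nondecreasing(self, rng):
        tset = _tset(rng.standard_normal((10, 32)))
        res = hcluster(tset, k=3)
        assert np.all(np.diff(res.merge_heights) >= 0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_hierarchical_nesting(self, seed):
        """Cutting at k+1 only splits clusters of the k-cut."""
        rng = np.random.default_rng(seed)
        tset = _tset(rng.standard_normal((12, 16)))
        for k in (2, 3, 4):
            coarse = hcluster(tset, k=k).labels
            fine = hcluster(tset, k=k + 1).labels
            # every fine cluster maps into exactly one coarse cluster
            for lab in set(fine):
                assert len(set(coarse[fine == lab])) == 1


class TestRefineAlignment:
    def test_identical_cluster_rms_zero(self, rng):
        x = rng.standard_normal(64)
        tset = _tset([x] * 4)
        res = hcluster(tset, k=1)
        _, table = refine_alignment(tset, res)
        assert np.allclose(table["rms_after"], 0.0, atol=1e-12)

    def test_rolled_copies_rms_decreases(self, rng):
        x = rng.standard_normal(64)
        tset = _tset([np.roll(x, r) for r in (0, 7, 21)])
        res = hcluster(tset, k=1)
        _, table = refine_alignment(tset, res)
        assert (table["rms_after"] <= table["rms_before"] + 1e-12).all()
        assert table["rms_after"].mean() < table["rms_before"].mean()

    def test_cluster_mean_beats_global_reference(self):
        """On aligned synthetic trials, each trial is closer to its own
        cluster average than to the global reference trial."""
        from lfpdyn import align_set, control_preset, generate_trialset, \
            steady_window_set

        tset = steady_window_set(
            generate_trialset(control_preset(seed=4, n_trials=12)))
        aligned, res_align = align_set(tset)
        res = hcluster(aligned, k=4)
        _, table = refine_alignment(aligned, res)
        assert table["rms_after"].mean() < res_align.rms_after.mean()


class TestOverlapIndex:
    @pytest.mark.parametrize("n_before,n_after,expected", [
        (12, 0, 0.0),     # pure cluster: zero overlap
        (10, 10, 0.5),    # balanced cluster: maximal overlap
        (3, 7, 0.3),
    ])
    def test_worked_examples(self, n_before, n_after, expected):
        labels = [1] * (n_before + n_after)
        conditions = ["before"] * n_before + ["after"] * n_after
        rep = overlap_index(_result_for_labels(labels), conditions)
        assert rep.per_cluster[0][3] == pytest.approx(expected)
        assert rep.mean_overlap_percent == pytest.approx(100 * expected)

    @given(st.lists(st.sampled_from(["before", "after"]), min_size=2,
                    max_size=40),
           st.integers(1, 4))
    def test_bounds_and_label_swap_invariance(self, conditions, k):
        labels = [(i % k) + 1 for i in range(len(conditions))]
        rep = overlap_index(_result_for_labels(labels), conditions)
        for _, _, _, frac in rep.per_cluster:
            assert 0.0 <= frac <= 0.5
        assert 0.0 <= rep.mean_overlap_percent <= 50.0
        swapped = ["after" if c == "before" else "before" for c in conditions]
        rep2 = overlap_index(_result_for_labels(labels), swapped)
        assert rep2.mean_overlap_percent == pytest.approx(
            rep.mean_overlap_percent)


class TestConditionOverlap:
    def test_duplicated_condition_mixes_heavily(self, rng):
        arrays = rng.standard_normal((6, 64))
        before = _tset(arrays, condition="control")
        after = _tset(arrays, condition="treated")
        reports = condition_overlap_analysis(before, after, ks=(2,))
        # every trial has an identical twin in the other condition
        assert reports[0].mean_overlap_percent == pytest.approx(50.0)

    def test_amplitude_separated_conditions_do_not_mix(self, rng):
        # tight cluster of near-copies vs its 100x-amplified version:
        # within-condition distances are tiny, across-condition huge
        template = rng.standard_normal(64)
        arrays = template + 0.05 * rng.standard_normal((5, 64))
        before = _tset(arrays, condition="control")
        after = _tset(arrays * 100.0, condition="treated")
        reports = condition_overlap_analysis(before, after, ks=(2,))
        assert reports[0].mean_overlap_percent == pytest.approx(0.0)

    def test_synthetic_conditions_partially_mix(self):
        from lfpdyn import generate_condition_pair, GeneratorParams, \
            steady_window_set

        ctrl, trt = generate_condition_pair(
            GeneratorParams(seed=6, n_trials=10))
        reports = condition_overlap_analysis(
            steady_window_set(ctrl), steady_window_set(trt), ks=(4,))
        assert 0.0 <= reports[0].mean_overlap_percent < 50.0
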