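"""Hierarchical clustering of aligned trials and condition-overlap analysis.

Trials (whole aligned traces, raw amplitudes) are clustered
agglomeratively on pairwise Euclidean distances and the tree is cut into a
fixed number of groups.  Cluster averages summarize each group; re-aligning
every trial to its own cluster average further reduces the per-trial rms
error.  When control and treated trials are clustered together, the overlap
index

    overlap = min(#control, #treated) / #trials_in_cluster

measures condition mixing per cluster: 0 means the cluster is pure, 0.5
means the two conditions are equally represented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .align import align_set, circular_align, rms_error
from .trials import TrialSet, concat_trialsets

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass(frozen=True)
class ClusterResult:
    """A tree cut: label per trial (1..k), merge heights, cluster means."""

    labels: np.ndarray          # cluster label per trial position, 1..k
    k: int
    merge_heights: np.ndarray   # nondecreasing linkage heights
    cluster_means: dict         # label -> mean trace
    distance_threshold: float   # smallest height whose cut yields <= k clusters
    linkage_method: str = "single"

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]

    def sizes(self) -> dict:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}


@dataclass(frozen=True)
class OverlapReport:
    """Per-cluster condition mixing and its unweighted mean, as a percent."""

    per_cluster: tuple          # (label, n_before, n_after, overlap fraction)
    mean_overlap_percent: float
    k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.per_cluster),
            columns=["cluster", "n_before", "n_after", "overlap"],
        )


def hcluster(tset: TrialSet, k: int, linkage: str = "single") -> ClusterResult:
    """Agglomerative clustering of whole traces, cut to (at most) k groups.

    Euclidean distances between raw aligned amplitude traces; the default
    single linkage matches MATLAB's hierarchical-clustering default.
    Labels are renumbered 1..k in order of
    first appearance.
    """
    n = len(tset)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in 1..{n}")
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    X = tset.to_array().T  # trials x samples
    if n == 1:
        labels = np.array([1])
        heights = np.array([])
        threshold = 0.0
    else:
        Z = scipy_linkage(X, method=linkage, metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")
        # renumber in order of first appearance
        remap: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, lab in enumerate(raw):
            if lab not in remap:
                remap[lab] = len(remap) + 1
            labels[i] = remap[lab]
        heights = Z[:, 2]
        threshold = 0.0 if k >= n else float(heights[n - k - 1])
    means = {
        int(lab): X[labels == lab].mean(axis=0) for lab in np.unique(labels)
    }
    return ClusterResult(
        labels=labels,
        k=int(labels.max()),
        merge_heights=np.asarray(heights, dtype=float),
        cluster_means=means,
        distance_threshold=threshold,
        linkage_method=linkage,
    )


def refine_alignment(tset: TrialSet, result: ClusterResult
                     ) -> tuple[TrialSet, pd.DataFrame]:
    """Re-align each trial to its own cluster average.

    The realignment shift minimizes the rms against the (fixed) cluster
    mean, so the per-trial rms can only decrease or stay equal.  Returns
    the realigned set and a table with rms before/after per trial.
    """
    if result.labels.size != len(tset):
        raise ValueError("cluster result does not match trial set size")
    rows = []
    refined = []
    for i, trial in enumerate(tset):
        mean = result.cluster_means[int(result.labels[i])]
        before = rms_error(trial.samples, mean)
        shift, after = circular_align(trial.samples, mean, objective="rms")
        refined.append(trial.with_samples(np.roll(trial.samples, shift)))
        rows.append((i, int(result.labels[i]), shift, before, after))
    table = pd.DataFrame(
        rows, columns=["trial_index", "cluster", "shift", "rms_before", "rms_after"]
    )
    return TrialSet(tuple(refined)), table


def overlap_index(result: ClusterResult, conditions) -> OverlapReport:
    """Condition-mixing overlap per cluster and its unweighted mean (%).

    ``conditions`` is a label per trial position; exactly two distinct
    labels are expected (e.g. "control"/"treated").  Clusters are averaged
    unweighted; empty clusters cannot occur in a tree cut.
    """
    conditions = np.asarray(list(conditions))
    if conditions.size != result.labels.size:
        raise ValueError("conditions must match the number of clustered trials")
    uniq = sorted(set(conditions.tolist()))
    if len(uniq) > 2:
        raise ValueError(f"expected at most two condition labels, got {uniq}")
    for preferred in ("before", "control"):
        if preferred in uniq:
            before_label = preferred
            break
    else:
        before_label = uniq[0]
    per_cluster = []
    fractions = []
    for lab in sorted(result.cluster_means):
        members = conditions[result.labels == lab]
        n_before = int(np.count_nonzero(members == before_label))
        n_after = int(members.size - n_before)
        frac = min(n_before, n_after) / members.size
        per_cluster.append((lab, n_before, n_after, frac))
        fractions.append(frac)
    return OverlapReport(
        per_cluster=tuple(per_cluster),
        mean_overlap_percent=100.0 * float(np.mean(fractions)),
        k=len(fractions),
    )


def condition_overlap_analysis(
    before: TrialSet,
    after: TrialSet,
    ks=(6, 12),
    linkage: str = "single",
    reference_policy="first",
) -> list[OverlapReport]:
    """Pool two conditions, align, cluster at each k, report overlap.

    Mirrors the combined-dendrogram protocol: concatenate the two trial
    sets into one file, phase-align all trials to a common reference, cut
    the joint dendrogram at each requested k and compute the overlap index.
    """
    combined = concat_trialsets(before, after)
    aligned, _ = align_set(combined, reference_policy=reference_policy)
    conditions = np.array(
        ["before"] * len(before) + ["after"] * len(after)
    )
    reports = []
    for k in ks:
        result = hcluster(aligned, k=k, linkage=linkage)
        reports.append(overlap_index(result, conditions))
    return reports
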