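"""Relief-based hub-probe screening and unsupervised sample clustering.

Within the trait-associated modules, candidate probes are ranked with a
multi-class ReliefF: for every sample, the k nearest same-class neighbors
(hits) and, per other class, the k nearest neighbors of that class (misses)
are found by Euclidean distance on min-max-scaled features; each feature's
weight decreases with its mean hit difference and increases with its
prior-weighted mean miss differences.  The top-k probes (default 25, the
screen's panel size) are then used for average-linkage sample clustering on
correlation distance, scored against the known groups by adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from circscreen.errors import AnalysisError
from circscreen.iolib import ExpressionDataset


@dataclass
class ReliefRanking:
    weights: dict[str, float]  # probe -> ReliefF weight
    k_neighbors: int
    n_iterations: int
    metric: str = "euclidean"

    def ranked_probes(self) -> list[str]:
        return sorted(self.weights, key=lambda p: (-self.weights[p], p))


def relieff_weights(
    data: ExpressionDataset,
    labels: Optional[dict[str, str]] = None,
    k: int = 5,
    pseudocount: float = 1.0,
) -> ReliefRanking:
    """Multi-class ReliefF feature weights on log2(value + pseudocount).

    All samples are used as target instances (no subsampling), making the
    ranking deterministic.  ``k`` is auto-shrunk to (smallest class size - 1)
    when a class is too small; a singleton class is an error.  Neighbor ties
    are broken by sample id so the result is invariant to input order.
    """
    if labels is None:
        labels = dict(data.groups)
    samples = list(data.sample_ids)
    classes = sorted(set(labels[s] for s in samples))
    if len(classes) < 2:
        raise AnalysisError("ReliefF needs >= 2 classes")
    counts = {c: sum(1 for s in samples if labels[s] == c) for c in classes}
    min_count = min(counts.values())
    if min_count < 2:
        raise AnalysisError(
            f"class with a single sample ({counts}); reduce k or merge classes"
        )
    k_eff = min(k, min_count - 1)

    x = np.log2(data.values.to_numpy(dtype=float).T + pseudocount)  # samples x probes
    rng_ = x.max(axis=0) - x.min(axis=0)
    scaled = np.where(rng_ > 0, (x - x.min(axis=0)) / np.where(rng_ > 0, rng_, 1.0), 0.0)

    n = len(samples)
    priors = {c: counts[c] / n for c in classes}
    # pairwise distances with deterministic ordering
    d2 = ((scaled[:, None, :] - scaled[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(d2)
    order_key = np.array(samples)

    w = np.zeros(x.shape[1])
    # iterate instances in sample-id order so the floating-point summation
    # order (hence the result, bit for bit) is invariant to input order
    for i in sorted(range(n), key=lambda j: samples[j]):
        ci = labels[samples[i]]
        for c in classes:
            members = [
                j for j in range(n) if j != i and labels[samples[j]] == c
            ]
            members.sort(key=lambda j: (dist[i, j], order_key[j]))
            nbrs = members[:k_eff]
            diffs = np.abs(scaled[nbrs] - scaled[i]).mean(axis=0)
            if c == ci:
                w -= diffs
            else:
                w += priors[c] / (1.0 - priors[ci]) * diffs
    w /= n
    return ReliefRanking(
        weights=dict(zip(data.probe_ids, w.astype(float))),
        k_neighbors=k_eff,
        n_iterations=n,
    )


def select_hub_probes(ranking: ReliefRanking, k: int = 25) -> list[str]:
    """Top-k probes by ReliefF weight, ties broken lexicographically by id."""
    ranked = ranking.ranked_probes()
    if k > len(ranked):
        raise AnalysisError(f"requested k={k} exceeds {len(ranked)} ranked probes")
    return ranked[:k]


@dataclass
class ClusterScore:
    linkage: np.ndarray
    labels: dict[str, int]
    ari: float


def cluster_and_score(
    data: ExpressionDataset,
    true_groups: Optional[dict[str, str]] = None,
    distance: str = "zeuclidean",
    pseudocount: float = 1.0,
) -> ClusterScore:
    """Average-linkage clustering of samples over the given probes, cut to
    the number of true groups and scored against them by adjusted Rand index.

    ``distance="zeuclidean"`` (default) is heatmap-style column clustering:
    Ward linkage on Euclidean distance between samples after per-probe
    z-scoring of the log2 matrix.  ``distance="correlation"`` uses average
    linkage on 1 - Pearson correlation between sample profiles instead; note
    that correlation distance subtracts each sample's mean over the panel,
    so it is blind to a signature in which every panel probe moves in the
    same direction.
    """
    if true_groups is None:
        true_groups = dict(data.groups)
    samples = data.sample_ids
    n_groups = len(set(true_groups[s] for s in samples))
    if len(samples) < 2 or len(samples) < n_groups:
        raise AnalysisError("need at least as many samples as groups")
    x = np.log2(data.values.to_numpy(dtype=float).T + pseudocount)  # samples x probes
    if distance == "zeuclidean":
        sd = x.std(axis=0)
        xz = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        z = hierarchy.linkage(xz, "ward")
    elif distance == "correlation":
        cor = np.corrcoef(x)
        dissim = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(dissim, 0.0)
        z = hierarchy.linkage(squareform((dissim + dissim.T) / 2, checks=False), "average")
    else:
        raise AnalysisError(f"unknown distance {distance!r}")
    pred = hierarchy.fcluster(z, t=n_groups, criterion="maxclust")
    truth = [true_groups[s] for s in samples]
    ari = float(adjusted_rand_score(truth, pred))
    return ClusterScore(linkage=z, labels=dict(zip(samples, map(int, pred))), ari=ari)
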