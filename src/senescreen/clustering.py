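"""Quality-threshold (QT) clustering of mean density profiles.

QT clustering is the classic greedy procedure for grouping profiles
without fixing the number of clusters in advance: for every remaining
profile a candidate cluster is grown around it — always adding the profile
that least increases the cluster diameter, never letting the diameter
exceed a quality threshold — and the largest candidate is extracted;
the process repeats until no candidate reaches the minimum size.

Distances between profiles are either ``1 - r`` (Pearson correlation
between mean curves, the shape metric used throughout this package;
pairs with undefined r get the maximal distance 2) or the RMS difference
between mean curves (an absolute-fitness metric).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .profile import MDP, pearson_correlation, rms_difference

__all__ = [
    "QTConfig",
    "Clustering",
    "distance_matrix",
    "qt_cluster",
    "cluster_summary",
    "write_cluster_table",
]


@dataclass(frozen=True)
class QTConfig:
    """QT clustering settings.

    ``diameter_threshold`` caps the maximum pairwise distance inside any
    cluster (default 0.3 on the 1-r scale, i.e. members correlate at
    r > 0.7 with each other); clusters smaller than ``min_cluster_size``
    are reported as unclustered singletons.
    """

    diameter_threshold: float = 0.3
    min_cluster_size: int = 2
    distance: str = "one_minus_r"

    def __post_init__(self) -> None:
        if self.diameter_threshold <= 0:
            raise ValueError("diameter_threshold must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.distance not in ("one_minus_r", "rms"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class Clustering:
    """Ordered clusters (largest first) plus the unclustered remainder."""

    clusters: list[list[str]]
    unclustered: set[str]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        """Genotype -> cluster id (1-based; 0 means unclustered)."""
        out = {g: 0 for g in self.unclustered}
        for i, cluster in enumerate(self.clusters, start=1):
            for g in cluster:
                out[g] = i
        return out


def distance_matrix(mdps: Mapping[str, MDP], distance: str = "one_minus_r"):
    """Symmetric pairwise distance matrix over genotypes (sorted order).

    Under ``one_minus_r`` an undefined correlation (constant profile)
    maps to the maximal distance 2.
    """
    genotypes = sorted(mdps)
    n = len(genotypes)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mdps[genotypes[i]], mdps[genotypes[j]]
            if distance == "one_minus_r":
                r = pearson_correlation(a, b)
                d = 2.0 if r is None else 1.0 - r
            else:
                d = rms_difference(a, b)
            D[i, j] = D[j, i] = d
    return genotypes, D


def _grow_candidate(seed: int, D: np.ndarray, available: list[int], threshold: float) -> list[int]:
    """Greedily grow a cluster around one seed: repeatedly add the point
    whose inclusion gives the smallest resulting diameter, stopping when
    any addition would exceed the threshold.  Ties by smallest index
    (genotypes are pre-sorted, so this is alphabetical)."""
    members = [seed]
    diam = 0.0
    # running max distance from each available point to the current members
    reach = {p: D[seed, p] for p in available if p != seed}
    while reach:
        # resulting diameter if p joins; ties by smallest index (alphabetical)
        best = min(reach, key=lambda p: (max(diam, reach[p]), p))
        if reach[best] > threshold:
            break
        diam = max(diam, reach[best])
        members.append(best)
        del reach[best]
        for p in reach:
            reach[p] = max(reach[p], D[best, p])
    return members


def qt_cluster(mdps: Mapping[str, MDP], cfg: QTConfig | None = None) -> Clustering:
    """Classic greedy QT clustering of MDPs.

    Deterministic and independent of input ordering: genotypes are sorted
    internally, candidate ties are resolved in favour of the candidate
    seeded by the alphabetically first genotype.
    """
    cfg = cfg or QTConfig()
    genotypes, D = distance_matrix(mdps, cfg.distance)
    available = list(range(len(genotypes)))
    clusters: list[list[str]] = []
    while available:
        candidates = [
            _grow_candidate(s, D, available, cfg.diameter_threshold) for s in available
        ]
        # largest wins; ties -> earliest (alphabetically first) seed
        best = max(candidates, key=lambda c: (len(c), -c[0]))
        if len(best) < cfg.min_cluster_size:
            break
        clusters.append(sorted(genotypes[i] for i in best))
        taken = set(best)
        available = [i for i in available if i not in taken]
    unclustered = {genotypes[i] for i in available}
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return Clustering(clusters=clusters, unclustered=unclustered)


def cluster_summary(clustering: Clustering, mdps: Mapping[str, MDP], cfg: QTConfig | None = None):
    """Per-cluster statistics: size, medoid (member with the smallest
    summed distance to the rest), mean within-cluster distance and the
    mean profile curve."""
    import pandas as pd

    cfg = cfg or QTConfig()
    rows = []
    for cid, members in enumerate(clustering.clusters, start=1):
        sub = {g: mdps[g] for g in members}
        names, D = distance_matrix(sub, cfg.distance)
        sums = D.sum(axis=1)
        medoid = names[int(np.argmin(sums))]
        k = len(names)
        mean_within = float(D[np.triu_indices(k, 1)].mean()) if k > 1 else 0.0
        mean_curve = np.mean([mdps[g].mean for g in members], axis=0)
        rows.append(
            {
                "cluster_id": cid,
                "size": k,
                "medoid": medoid,
                "mean_within_distance": mean_within,
                "mean_curve": mean_curve,
            }
        )
    return pd.DataFrame(rows)


def write_cluster_table(clustering: Clustering, mdps: Mapping[str, MDP], path,
                        cfg: QTConfig | None = None) -> None:
    """Cluster assignment file: genotype, cluster_id (0 = unclustered),
    medoid_flag."""
    cfg = cfg or QTConfig()
    summary = cluster_summary(clustering, mdps, cfg)
    medoids = set(summary["medoid"]) if len(summary) else set()
    labels = clustering.labels()
    with open(path, "w") as fh:
        fh.write("genotype\tcluster_id\tmedoid_flag\n")
        for g in sorted(labels):
            fh.write(f"{g}\t{labels[g]}\t{int(g in medoids)}\n")
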