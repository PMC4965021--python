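"""Consensus clustering, cluster stability and size-dependence curves.

The robustness of both feature clusters (meta-measures) and body types is
judged by rerunning the entire map-training + cluster-detection procedure
on many random sub-cohorts and counting, for every pair of items, how
often the pair lands in the same cluster among the runs where both were
sampled.  The resulting consensus matrix supports:

* intra-cluster consensus m(k): the mean consensus over item pairs of a
  reference cluster k (computed on the full cohort), and its unweighted
  mean over clusters <m(k)>,
* inter-cluster consensus between reference clusters, used as a
  similarity for a single-linkage dendrogram of clusters,
* stability curves: cluster count (mean +/- SD over runs) and <m(k)> as
  a function of sub-cohort size.

Subsampling is without replacement (Monti-style consensus clustering);
drawing with replacement is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .features import UNASSIGNED

__all__ = [
    "ConsensusMatrix",
    "ConsensusStats",
    "StabilityCurve",
    "subsampled_consensus",
    "consensus_stats",
    "consensus_dendrogram",
    "stability_vs_size",
]


class ConsensusError(ValueError):
    pass


#: signature of a clustering procedure: (data_subset, seed) -> int labels,
#: UNASSIGNED (-1) allowed for items the procedure could not place
ClusteringProcedure = Callable[[np.ndarray, int], np.ndarray]


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering counts from repeated subsampled runs."""

    co_cluster_counts: np.ndarray   # runs where the pair shared a cluster
    co_sample_counts: np.ndarray    # runs where both items were sampled
    run_cluster_counts: list        # clusters found in each run
    n_items: int

    @property
    def consensus(self) -> np.ndarray:
        """Element-wise ratio; never-co-sampled pairs are NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            c = self.co_cluster_counts / self.co_sample_counts
        c[self.co_sample_counts == 0] = np.nan
        return c

    def validate(self) -> None:
        cc, cs = self.co_cluster_counts, self.co_sample_counts
        if not np.array_equal(cc, cc.T) or not np.array_equal(cs, cs.T):
            raise ConsensusError("consensus count matrices must be symmetric")
        if np.any(cc > cs):
            raise ConsensusError("co_cluster_counts cannot exceed co_sample_counts")
        if np.any(cc < 0) or np.any(cs < 0):
            raise ConsensusError("counts must be non-negative")


def subsampled_consensus(
    data: np.ndarray,
    subsample_size: int,
    clustering_procedure: ClusteringProcedure,
    n_iter: int = 100,
    seed: int = 0,
    with_replacement: bool = False,
) -> ConsensusMatrix:
    """Build the consensus matrix over ``n_iter`` subsampled runs.

    Every iteration draws ``subsample_size`` items (without replacement by
    default), reruns the full clustering procedure with a derived seed
    (``seed + iteration``), and updates the pair counts.  Items a run
    leaves unassigned count as sampled but co-clustered with nobody; their
    diagonal entry still counts as sampled (consensus diag = 1 wherever
    sampled at least once).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n_iter < 2:
        raise ConsensusError("n_iter must be >= 2")
    if not (1 <= subsample_size <= n):
        raise ConsensusError("subsample_size must lie in [1, n_items]")
    co_cluster = np.zeros((n, n), dtype=np.int32)
    co_sample = np.zeros((n, n), dtype=np.int32)
    run_counts = []
    rng = np.random.default_rng(seed)
    for it in range(n_iter):
        idx = rng.choice(n, size=subsample_size, replace=with_replacement)
        idx = np.unique(idx)  # with replacement, duplicates collapse
        labels = np.asarray(clustering_procedure(data[idx], int((seed + it) % 2**31)))
        if labels.shape[0] != len(idx):
            raise ConsensusError("clustering_procedure returned wrong label count")
        co_sample[np.ix_(idx, idx)] += 1
        ks = np.unique(labels[labels != UNASSIGNED])
        for k in ks:
            m = idx[labels == k]
            co_cluster[np.ix_(m, m)] += 1
        run_counts.append(int(len(ks)))
    # unassigned items still agree with themselves: diagonal = times sampled
    np.fill_diagonal(co_cluster, np.diag(co_sample))
    return ConsensusMatrix(
        co_cluster_counts=co_cluster,
        co_sample_counts=co_sample,
        run_cluster_counts=run_counts,
        n_items=n,
    )


@dataclass
class ConsensusStats:
    """Intra- and inter-cluster consensus of a reference partition."""

    cluster_ids: list               # reference cluster ids, ordered
    intra: np.ndarray               # m(k) per cluster (NaN if < 2 members)
    inter: np.ndarray               # K x K mean cross-consensus, diag = m(k)

    @property
    def mean_intra(self) -> float:
        """<m(k)>: unweighted mean of m(k) over clusters with defined values."""
        return float(np.nanmean(self.intra))


def consensus_stats(
    cmat: ConsensusMatrix, reference_labels: np.ndarray
) -> ConsensusStats:
    """Average the consensus matrix within and between reference clusters.

    m(k) averages consensus over distinct within-cluster pairs (observed
    pairs only — never-co-sampled pairs drop out of the denominator);
    clusters with fewer than two members get NaN.  inter(k, l) averages
    over all cross pairs.
    """
    labels = np.asarray(reference_labels)
    if labels.shape[0] != cmat.n_items:
        raise ConsensusError("reference labels must cover the consensus items")
    consensus = cmat.consensus
    ids = sorted(int(k) for k in np.unique(labels[labels != UNASSIGNED]))
    K = len(ids)
    intra = np.full(K, np.nan)
    inter = np.full((K, K), np.nan)
    for a, k in enumerate(ids):
        mk = np.flatnonzero(labels == k)
        if len(mk) >= 2:
            block = consensus[np.ix_(mk, mk)]
            off = block[np.triu_indices(len(mk), k=1)]
            if np.any(~np.isnan(off)):
                intra[a] = float(np.nanmean(off))
        inter[a, a] = intra[a]
        for b in range(a + 1, K):
            ml = np.flatnonzero(labels == ids[b])
            block = consensus[np.ix_(mk, ml)]
            if np.any(~np.isnan(block)):
                inter[a, b] = inter[b, a] = float(np.nanmean(block))
    return ConsensusStats(cluster_ids=ids, intra=intra, inter=inter)


def consensus_dendrogram(stats: ConsensusStats) -> np.ndarray:
    """Single-linkage dendrogram of clusters on 1 - inter-consensus.

    Returns the scipy linkage matrix (merge list with heights in [0, 1]);
    leaves follow ``stats.cluster_ids`` order.
    """
    K = len(stats.cluster_ids)
    if K < 2:
        raise ConsensusError("dendrogram needs at least 2 clusters")
    dissim = 1.0 - stats.inter
    np.fill_diagonal(dissim, 0.0)
    if np.any(np.isnan(dissim)):
        dissim = np.where(np.isnan(dissim), 1.0, dissim)  # unobserved = maximally distant
    return linkage(squareform(dissim, checks=False), method="single")


@dataclass
class StabilityCurve:
    """Cluster count and consensus stability versus sub-cohort size."""

    sizes: list
    mean_cluster_count: list
    sd_cluster_count: list
    mean_intra: list
    size_consensus_correlation: list  # Pearson r(reference cluster size, m(k)) per size
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "mean_cluster_count": self.mean_cluster_count,
                "sd_cluster_count": self.sd_cluster_count,
                "mean_intra_consensus": self.mean_intra,
                "size_consensus_r": self.size_consensus_correlation,
            }
        )


def stability_vs_size(
    data: np.ndarray,
    sizes: Sequence[int],
    clustering_procedure: ClusteringProcedure,
    n_iter: int = 100,
    seed: int = 0,
    reference_labels: np.ndarray | None = None,
) -> StabilityCurve:
    """Consensus statistics across a ladder of sub-cohort sizes.

    The reference partition defaults to one full-data run of the
    procedure.  Per size the function reports the mean and SD of the
    per-run cluster counts, <m(k)> against the reference, and the Pearson
    correlation between reference cluster sizes and their m(k) (NaN when
    fewer than 3 clusters have defined consensus).
    """
    data = np.asarray(data, dtype=float)
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ConsensusError("sizes must be increasing")
    if any(s > data.shape[0] for s in sizes):
        raise ConsensusError("sizes must not exceed the number of items")
    if reference_labels is None:
        reference_labels = np.asarray(clustering_procedure(data, seed))
    ref_sizes = {
        int(k): int((reference_labels == k).sum())
        for k in np.unique(reference_labels[reference_labels != UNASSIGNED])
    }
    means, sds, intras, corrs = [], [], [], []
    for j, s in enumerate(sizes):
        cmat = subsampled_consensus(
            data, s, clustering_procedure, n_iter=n_iter,
            seed=int((seed + 10_007 * (j + 1)) % 2**31),
        )
        counts = np.asarray(cmat.run_cluster_counts, dtype=float)
        means.append(float(counts.mean()))
        sds.append(float(counts.std(ddof=1)))
        stats = consensus_stats(cmat, reference_labels)
        intras.append(stats.mean_intra)
        ok = ~np.isnan(stats.intra)
        if ok.sum() >= 3:
            x = np.array([ref_sizes[k] for k, o in zip(stats.cluster_ids, ok) if o], float)
            y = stats.intra[ok]
            r = pearsonr(x, y).statistic if np.std(x) > 0 and np.std(y) > 0 else np.nan
        else:
            r = np.nan
        corrs.append(float(r) if r == r else float("nan"))
    return StabilityCurve(
        sizes=sizes,
        mean_cluster_count=means,
        sd_cluster_count=sds,
        mean_intra=intras,
        size_consensus_correlation=corrs,
        n_iterations=n_iter,
    )
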