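"""Population-level clustering and sample-level PCA.

Population profiles are per-probe medians of M across a population's
samples (even counts use the mean of the two middle values).  Hierarchical
clustering of profiles (euclidean / average linkage by default) is exported
as a newick string; PCA of individual samples runs on probe-wise
mean-centered, unscaled M-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "median_profiles",
    "cluster_populations",
    "sample_pca",
    "within_between_distances",
]


def median_profiles(m, sheet) -> pd.DataFrame:
    """Per-probe median M within each population (probes x populations)."""
    out = {}
    for pop in sheet.population_set:
        cols = [list(m.sample_ids).index(s) for s in sheet.samples_of(pop)]
        out[pop] = np.median(m.values[:, cols], axis=1)
    return pd.DataFrame(out, index=pd.Index(m.probe_ids, name="probe_id"))


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_populations(profiles: pd.DataFrame, distance: str = "euclidean", linkage: str = "average") -> str:
    """Agglomerative clustering of population profiles; returns newick.

    Deterministic given fixed tie-breaking: profiles are taken in sorted
    label order before linkage.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 population profiles to cluster")
    labels = sorted(profiles.columns)
    x = profiles[labels].to_numpy().T
    d = pdist(x, metric=distance)
    z = hierarchy.linkage(d, method=linkage)
    tree = hierarchy.to_tree(z)
    return _tree_to_newick(tree, labels) + ";"


def sample_pca(m, n_components: int = 10, scale: bool = False):
    """PCA of samples on probe-wise centered M-values.

    Returns (scores DataFrame samples x PCs, explained-variance fractions).
    A constant matrix yields zero scores and zero variance fractions.
    """
    x = m.values.T.astype(float)  # samples x probes
    n_samples = x.shape[0]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    k = min(n_components, n_samples - 1, x.shape[1])
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    if total == 0:
        scores = np.zeros((n_samples, k))
        evr = np.zeros(k)
    else:
        # sign convention: largest-magnitude loading positive, for determinism
        signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
        u = u * signs
        scores = (u * s)[:, :k]
        evr = (s**2 / total)[:k]
    score_df = pd.DataFrame(
        scores, index=list(m.sample_ids), columns=[f"PC{i+1}" for i in range(k)]
    )
    return score_df, evr


def within_between_distances(m, sheet) -> tuple:
    """Mean pairwise euclidean distance within populations (across donors)
    versus within donors (across populations).

    The paper-style contrast "lineage beats individual" holds when the first
    mean is smaller than the second.
    """
    x = m.values.T
    sids = list(m.sample_ids)
    pop = {s: p for s, p in zip(sheet.sample_ids, sheet.populations)}
    donor = {s: d for s, d in zip(sheet.sample_ids, sheet.donor_ids)}
    within_pop, within_donor = [], []
    for i in range(len(sids)):
        for j in range(i + 1, len(sids)):
            d = float(np.linalg.norm(x[i] - x[j]))
            si, sj = sids[i], sids[j]
            if pop[si] == pop[sj] and donor[si] != donor[sj]:
                within_pop.append(d)
            elif donor[si] == donor[sj] and pop[si] != pop[sj]:
                within_donor.append(d)
    return float(np.mean(within_pop)), float(np.mean(within_donor))
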