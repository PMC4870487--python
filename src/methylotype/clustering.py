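"""Hierarchical clustering of samples with multiscale-bootstrap support.

Samples are clustered by Ward's criterion applied to Manhattan
dissimilarities (the ``ward.D2`` convention: the Lance-Williams recurrence
runs on squared dissimilarities and merge heights are reported on the
original scale). Cluster confidence comes from multiscale bootstrap
resampling of the probes: at each scale ratio ``r`` the probe set is
resampled with replacement to size ``n' = round(r * n)``, the whole
distance-plus-linkage computation is redone, and the bootstrap probability
``BP_r`` of a cluster is the fraction of replicates whose tree contains
exactly the same leaf set. Writing ``sigma = sqrt(n / n')``, the normal
quantiles ``z_r = Phi^{-1}(1 - BP_r)`` are fitted by weighted least
squares to the two-parameter curve

    z(sigma) = v * sigma + c / sigma

and the approximately unbiased support is ``AU = 100 * (1 - Phi(v - c))``,
which corrects the plain bootstrap proportion for the curvature of the
cluster's boundary in data space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import ValidationError

DEFAULT_SCALES = tuple(float(r) for r in np.round(np.arange(0.5, 1.41, 0.1), 10))


def manhattan_distance_matrix(matrix: pd.DataFrame,
                              axis: str = "samples") -> pd.DataFrame:
    """Pairwise Manhattan (city-block) distances between samples (columns)
    or probes (rows)."""
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("distance computation requires complete data")
    if axis == "samples":
        labels, pts = matrix.columns, X.T
    elif axis == "probes":
        labels, pts = matrix.index, X
    else:
        raise ValueError("axis must be 'samples' or 'probes'")
    D = squareform(pdist(pts, metric="cityblock"))
    return pd.DataFrame(D, index=labels, columns=labels)


def ward2_linkage(distance_matrix: pd.DataFrame) -> np.ndarray:
    """Ward.D2 agglomeration of a precomputed dissimilarity matrix.

    Returns a scipy linkage matrix; heights are on the unsquared
    dissimilarity scale. Requires at least two items.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    condensed = squareform(D, checks=False)
    return hierarchy.linkage(condensed, method="ward")


def node_leaf_sets(Z: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Leaf-index set of every internal node, in linkage-row order."""
    sets: list[frozenset] = []
    for a, b in Z[:, :2].astype(int):
        sa = frozenset([a]) if a < n_leaves else sets[a - n_leaves]
        sb = frozenset([b]) if b < n_leaves else sets[b - n_leaves]
        sets.append(sa | sb)
    return sets


@dataclass
class Dendrogram:
    """Sample tree with optional per-node bootstrap support.

    ``au``/``bp`` are percentages aligned with linkage rows; ``v``/``c``
    the fitted curve coefficients; ``degenerate`` flags nodes where the
    weighted fit was impossible and the support was clamped.
    """

    linkage: np.ndarray
    leaf_ids: list
    au: np.ndarray | None = None
    bp: np.ndarray | None = None
    v: np.ndarray | None = None
    c: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    scales: tuple = ()
    n_boot: int = 0
    seed: int | None = None
    bp_by_scale: np.ndarray | None = None  # nodes x scales raw proportions

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_sets(self) -> list[frozenset]:
        return node_leaf_sets(self.linkage, self.n_leaves)

    def to_newick(self) -> str:
        """Newick string with AU percentages as internal-node labels."""
        tree = hierarchy.to_tree(self.linkage)
        au = self.au

        def rec(node):
            if node.is_leaf():
                return str(self.leaf_ids[node.id])
            label = ""
            if au is not None:
                label = f"{au[node.id - self.n_leaves]:.1f}"
            return (f"({rec(node.left)},{rec(node.right)}){label}"
                    f":{node.dist:.6g}")

        return rec(tree) + ";"

    def to_dict(self) -> dict:
        d = {
            "leaf_ids": list(map(str, self.leaf_ids)),
            "merges": self.linkage[:, :2].astype(int).tolist(),
            "heights": self.linkage[:, 2].tolist(),
            "scales": list(self.scales),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        for name in ("au", "bp", "v", "c"):
            arr = getattr(self, name)
            d[name] = None if arr is None else np.asarray(arr, float).tolist()
        if self.degenerate is not None:
            d["degenerate"] = self.degenerate.astype(bool).tolist()
        return d


def _fit_au(bp: np.ndarray, sigmas: np.ndarray,
            B: int) -> tuple[float, float, float, bool]:
    """Fit the two-parameter curve to one node's bootstrap proportions.

    Returns ``(au_percent, v, c, degenerate)``. The weighted fit needs at
    least three scales with BP strictly inside (0, 1); otherwise the node
    is clamped to 0 or 100 according to the side its proportions sit on.
    """
    usable = (bp > 0.0) & (bp < 1.0)
    if usable.sum() < 3:
        return (100.0 if bp.mean() >= 0.5 else 0.0), np.nan, np.nan, True
    bpz = bp[usable]
    s = sigmas[usable]
    z = stats.norm.ppf(1.0 - bpz)
    # delta-method weights: Var(z) = BP(1-BP) / (B * phi(z)^2)
    w = B * stats.norm.pdf(z) ** 2 / (bpz * (1.0 - bpz))
    X = np.column_stack([s, 1.0 / s])
    WX = X * w[:, None]
    coef, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = 100.0 * (1.0 - stats.norm.cdf(v - c))
    return au, v, c, False


def multiscale_bootstrap_au(feature_matrix: pd.DataFrame,
                            scales=DEFAULT_SCALES, B: int = 1000,
                            seed: int = 0) -> Dendrogram:
    """Cluster samples and attach AU/BP support to every internal node.

    Parameters
    ----------
    feature_matrix
        probes x samples values (beta scale by default in this pipeline);
        **rows (probes) are the resampling units**.
    scales
        grid of resample-size ratios ``r``; ``B`` replicates are drawn per
        scale with ``n' = round(r * n_probes)`` probes sampled with
        replacement.
    """
    X = feature_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("bootstrap clustering requires complete data")
    n_probes, n_samples = X.shape
    if n_samples < 3:
        raise ValidationError("need >= 3 samples for meaningful clusters")
    if B < 1:
        raise ValidationError("B must be >= 1")
    scales = tuple(float(r) for r in scales)
    rng = np.random.default_rng(seed)

    # observed tree
    obs_Z = hierarchy.linkage(pdist(X.T, metric="cityblock"), method="ward")
    obs_sets = node_leaf_sets(obs_Z, n_samples)
    node_index = {s: i for i, s in enumerate(obs_sets)}
    n_nodes = len(obs_sets)

    # Manhattan distance is additive over probes: precompute each probe's
    # contribution to every sample pair, so a replicate's distance vector
    # is a single matrix product with its multinomial resampling counts.
    iu = np.triu_indices(n_samples, k=1)
    P = np.abs(X[:, iu[0]] - X[:, iu[1]])  # n_probes x n_pairs

    hits = np.zeros((n_nodes, len(scales)), dtype=np.int64)
    pvals = np.full(n_probes, 1.0 / n_probes)
    for si, r in enumerate(scales):
        n_sub = max(2, int(round(r * n_probes)))
        counts = rng.multinomial(n_sub, pvals, size=B).astype(float)
        D = counts @ P  # B x n_pairs condensed distance vectors
        for b in range(B):
            Zb = hierarchy.linkage(D[b], method="ward")
            for s in node_leaf_sets(Zb, n_samples):
                i = node_index.get(s)
                if i is not None:
                    hits[i, si] += 1

    bp_by_scale = hits / float(B)
    sigmas = np.sqrt(n_probes / np.array(
        [max(2, int(round(r * n_probes))) for r in scales], dtype=float))
    au = np.empty(n_nodes)
    v = np.empty(n_nodes)
    c = np.empty(n_nodes)
    degen = np.zeros(n_nodes, dtype=bool)
    for i in range(n_nodes):
        au[i], v[i], c[i], degen[i] = _fit_au(bp_by_scale[i], sigmas, B)
    # raw bootstrap proportion reported at the scale closest to sigma = 1
    near1 = int(np.argmin(np.abs(np.array(scales) - 1.0)))
    bp = 100.0 * bp_by_scale[:, near1]

    return Dendrogram(linkage=obs_Z, leaf_ids=list(feature_matrix.columns),
                      au=au, bp=bp, v=v, c=c, degenerate=degen,
                      scales=scales, n_boot=B, seed=seed,
                      bp_by_scale=bp_by_scale)


@dataclass
class ClusterPartition:
    """Assignment of samples to significant clusters (or 'unassigned')."""

    assignments: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)  # dicts: label, samples, au, size

    @property
    def labels(self) -> list:
        return [c["label"] for c in self.clusters]

    def members(self, label: str) -> list:
        for c in self.clusters:
            if c["label"] == label:
                return list(c["samples"])
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {"assignments": dict(self.assignments),
                "clusters": [dict(c) for c in self.clusters]}


def select_significant_clusters(dendro: Dendrogram, au_threshold: float = 95.0,
                                min_size: int = 5,
                                feature_matrix: pd.DataFrame | None = None,
                                ) -> ClusterPartition:
    """Extract the maximal clusters with AU above threshold.

    Among internal nodes (the root excluded — it contains every sample in
    every replicate) with ``AU > au_threshold`` and at least ``min_size``
    leaves, only nodes not nested inside another qualifying node are
    reported. When exactly two maximal clusters partition all samples and
    ``feature_matrix`` is given, they are labelled CI/CII with CII the
    cluster of higher mean methylation over the clustering probes (the
    methylator orientation); otherwise labels are C1, C2, ...
    """
    if dendro.au is None:
        raise ValidationError("dendrogram carries no AU values")
    sets = dendro.leaf_sets()
    n = dendro.n_leaves
    qual = [i for i in range(len(sets) - 1)  # last row = root
            if dendro.au[i] > au_threshold and len(sets[i]) >= min_size]
    maximal = [i for i in qual
               if not any(j != i and sets[i] < sets[j] for j in qual)]
    maximal.sort(key=lambda i: -len(sets[i]))

    leaf_ids = list(dendro.leaf_ids)
    groups = [sorted(leaf_ids[k] for k in sets[i]) for i in maximal]
    covers_all = (len(groups) == 2
                  and len(sets[maximal[0]] | sets[maximal[1]]) == n
                  and sets[maximal[0]].isdisjoint(sets[maximal[1]]))
    if covers_all and feature_matrix is not None:
        means = [float(feature_matrix[g].to_numpy().mean()) for g in groups]
        order = np.argsort(means)  # CI = lower methylation
        labels = [None, None]
        labels[order[0]], labels[order[1]] = "CI", "CII"
    else:
        labels = [f"C{k + 1}" for k in range(len(groups))]

    assignments = {s: "unassigned" for s in leaf_ids}
    clusters = []
    for lab, g, i in sorted(zip(labels, groups, maximal)):
        for s in g:
            assignments[s] = lab
        clusters.append({"label": lab, "samples": g,
                         "au": float(dendro.au[i]), "size": len(g)})
    return ClusterPartition(assignments=assignments, clusters=clusters)
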