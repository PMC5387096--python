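"""Optimal-matching dissimilarities, Ward clustering and cluster validation.

Optimal matching compares two state sequences by the minimal total cost of
insertions, deletions (indel cost) and substitutions needed to transform one
into the other (a weighted Levenshtein distance, computed by dynamic
programming).  Substitution costs are derived from transition rates: states
that frequently follow each other are cheap to substitute (cost
2 - p(i|j) - p(j|i), zero on the diagonal, at most 2).  The pairwise distance
matrix feeds Ward's error-sum-of-squares hierarchical clustering
(Lance-Williams recurrence on squared dissimilarities), and the number of
clusters is chosen by the mean silhouette width, with merge-height scree
values and classical MDS coordinates as supporting diagnostics.  A mean
silhouette above 0.51 is flagged as indicating a reasonable structure; the
flag is advisory only and no solution is auto-rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .markov import MarkovModel
from .seqdata import Dataset, StateSequence

SILHOUETTE_STRUCTURE_THRESHOLD = 0.51


@dataclass
class CostMatrix:
    """Symmetric substitution costs with zero diagonal, plus an indel cost."""

    sub: np.ndarray
    indel: float = 1.0

    def __post_init__(self) -> None:
        self.sub = np.asarray(self.sub, dtype=float)
        if self.sub.ndim != 2 or self.sub.shape[0] != self.sub.shape[1]:
            raise ValueError("sub must be square")
        if not np.allclose(self.sub, self.sub.T):
            raise ValueError("sub must be symmetric")
        if not np.allclose(np.diag(self.sub), 0.0):
            raise ValueError("sub must have zero diagonal")
        if (self.sub < 0).any() or self.indel <= 0:
            raise ValueError("costs must be nonnegative, indel positive")


def trate_costs(model: MarkovModel | np.ndarray, indel: float = 1.0) -> CostMatrix:
    """Transition-rate substitution costs: sub[i, j] = 2 - p(j|i) - p(i|j).

    Substituting two states is cheap when they commonly follow one another;
    the cost is 0 when each always follows the other and 2 when they never
    occur consecutively.
    """
    p = model.transition if isinstance(model, MarkovModel) else np.asarray(model, float)
    sub = 2.0 - p - p.T
    np.fill_diagonal(sub, 0.0)
    return CostMatrix(sub=sub, indel=indel)


def om_distance(s1, s2, costs: CostMatrix) -> float:
    """Minimal edit cost between two state sequences (dynamic programming)."""
    a = s1.states if isinstance(s1, StateSequence) else np.asarray(s1, dtype=int)
    b = s2.states if isinstance(s2, StateSequence) else np.asarray(s2, dtype=int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequences must be non-empty")
    indel = costs.indel
    sub = costs.sub
    prev = indel * np.arange(len(b) + 1, dtype=float)
    for i in range(1, len(a) + 1):
        cur = np.empty(len(b) + 1)
        cur[0] = i * indel
        sub_row = sub[a[i - 1], b]
        for j in range(1, len(b) + 1):
            cur[j] = min(
                prev[j] + indel,  # delete from a
                cur[j - 1] + indel,  # insert into a
                prev[j - 1] + sub_row[j - 1],  # substitute
            )
        prev = cur
    return float(prev[-1])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise OM distances with the dyad-id index."""

    values: np.ndarray
    dyad_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.dyad_ids) != n:
            raise ValueError("values must be n x n matching dyad_ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(dataset: Dataset, costs: CostMatrix | None = None) -> DistanceMatrix:
    """All pairwise OM distances between the dyads' expanded state sequences.

    When no cost matrix is supplied, transition-rate costs are derived from a
    basic Markov model fitted on the same dataset (with unit indel cost).
    """
    seqs = dataset.state_sequences()
    if costs is None:
        from .markov import fit_markov

        model = fit_markov(seqs)
        transition = np.nan_to_num(model.transition, nan=0.0)
        costs = trate_costs(transition)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = om_distance(seqs[i], seqs[j], costs)
    return DistanceMatrix(values=d, dyad_ids=[s.dyad_id for s in seqs])


# ---------------------------------------------------------------------------
# Ward clustering


def ward_cluster(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Agglomerative Ward clustering from a precomputed dissimilarity matrix.

    Uses the Lance-Williams recurrence on squared dissimilarities; merge
    heights are reported on the squared scale and are non-decreasing.  Ties
    are broken deterministically by the lowest index pair.  The returned
    (n-1) x 4 merge table follows the usual linkage layout: the two merged
    cluster ids (original observations are 0..n-1, new clusters n, n+1, ...),
    the merge height and the new cluster's size.
    """
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    cur = dm.astype(float) ** 2
    np.fill_diagonal(cur, np.inf)
    sizes = {i: 1 for i in range(n)}
    ids = list(range(n))  # cluster id per active row
    active = cur.copy()
    merge = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        # lowest-index tie-break: argmin over the upper triangle scans row-major
        flat = np.argmin(active)
        i, j = divmod(flat, active.shape[0])
        if i > j:
            i, j = j, i
        h = active[i, j]
        ni, nj = sizes[ids[i]], sizes[ids[j]]
        merge[step] = (min(ids[i], ids[j]), max(ids[i], ids[j]), h, ni + nj)
        # Lance-Williams update of row i as the merged cluster
        for k in range(active.shape[0]):
            if k in (i, j):
                continue
            nk = sizes[ids[k]]
            dk = (
                (ni + nk) * active[i, k] + (nj + nk) * active[j, k] - nk * h
            ) / (ni + nj + nk)
            active[i, k] = active[k, i] = dk
        sizes[next_id] = ni + nj
        ids[i] = next_id
        next_id += 1
        # deactivate row j
        active = np.delete(np.delete(active, j, axis=0), j, axis=1)
        del ids[j]
    return merge


def cut_tree(merge: np.ndarray, k: int) -> np.ndarray:
    """Labels (0..k-1) from the merge table at k clusters.

    Label numbering follows the order in which cluster representatives first
    appear, so it is deterministic for a given tree.
    """
    n = merge.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError("k must be in 1..n")
    parent = {}
    for step in range(n - 1 - (k - 1)):
        a, b = int(merge[step, 0]), int(merge[step, 1])
        parent[a] = n + step
        parent[b] = n + step

    def root(x):
        while x in parent:
            x = parent[x]
        return x

    roots = [root(i) for i in range(n)]
    seen: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = seen.setdefault(r, len(seen))
    return labels


def silhouette_widths(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-object silhouette widths s(i) = (b - a) / max(a, b) from distances.

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to any other cluster; singletons get s(i) = 0.
    """
    labels = np.asarray(labels)
    n = len(labels)
    widths = np.zeros(n)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    masks = {c: labels == c for c in clusters}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0  # singleton convention
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, masks[c]].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.maximum(vals[order], 0.0)
    return vecs[:, order] * np.sqrt(vals)


@dataclass
class ClusterSolution:
    """Ward merge tree with per-k labels, silhouettes and diagnostics."""

    merge_tree: np.ndarray
    labels_k: dict[int, np.ndarray]
    silhouette_mean: dict[int, float]
    silhouette_widths: dict[int, np.ndarray]
    chosen_k: int
    reasonable_structure: bool
    scree_heights: np.ndarray  # last merge heights, largest first
    mds_coords: np.ndarray
    dyad_ids: list[str] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return self.labels_k[self.chosen_k]


def silhouette_select(
    d: DistanceMatrix | np.ndarray,
    merge_tree: np.ndarray | None = None,
    k_range=None,
) -> ClusterSolution:
    """Cut the Ward tree over a range of k and choose k by mean silhouette.

    Reports per-k mean silhouettes, per-dyad widths at every k, merge-height
    scree values and 2-D classical MDS coordinates.  The "reasonable
    structure" flag is set when the best mean silhouette exceeds 0.51; the
    choice is never auto-rejected on its basis.
    """
    ids = d.dyad_ids if isinstance(d, DistanceMatrix) else [str(i) for i in range(len(d))]
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if merge_tree is None:
        merge_tree = ward_cluster(dm)
    if k_range is None:
        k_range = range(2, min(8, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k < n]
    if not k_range:
        raise ValueError("no valid k in range")
    labels_k, sil_mean, sil_widths = {}, {}, {}
    for k in k_range:
        labels = cut_tree(merge_tree, k)
        if len(np.unique(labels)) < k:
            continue  # empty cluster at this cut
        widths = silhouette_widths(dm, labels)
        labels_k[k] = labels
        sil_widths[k] = widths
        sil_mean[k] = float(widths.mean())
    chosen_k = max(sil_mean, key=lambda k: (sil_mean[k], -k))
    best = sil_mean[chosen_k]
    return ClusterSolution(
        merge_tree=merge_tree,
        labels_k=labels_k,
        silhouette_mean=sil_mean,
        silhouette_widths=sil_widths,
        chosen_k=chosen_k,
        reasonable_structure=best > SILHOUETTE_STRUCTURE_THRESHOLD,
        scree_heights=np.sort(merge_tree[:, 2])[::-1],
        mds_coords=classical_mds(dm),
        dyad_ids=list(ids),
    )


# ---------------------------------------------------------------------------
# Cluster validation


def agreement(labels1, labels2) -> float:
    """Maximal percentage of identically assigned objects over label matchings.

    All one-to-one matchings between the two labelings' groups are tried
    (brute force, up to 6 groups per side).
    """
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if len(l1) != len(l2):
        raise ValueError("labelings must cover the same dyads")
    g1 = np.unique(l1)
    g2 = np.unique(l2)
    if len(g1) > 6 or len(g2) > 6:
        raise ValueError("brute-force matching supports at most 6 groups")
    # match the smaller side into the larger
    if len(g1) > len(g2):
        l1, l2, g1, g2 = l2, l1, g2, g1
    best = 0
    for perm in itertools.permutations(g2, len(g1)):
        mapping = dict(zip(g1, perm))
        best = max(best, int(sum(mapping[a] == b for a, b in zip(l1, l2))))
    return 100.0 * best / len(l1)


def covariate_association(labels, covariate) -> tuple[float, float]:
    """Point-biserial correlation between 2-group membership and a covariate.

    Group membership is coded as a 0/1 dummy (the group listed first in the
    label array is coded 0); the two-tailed p comes from the t distribution
    with n - 2 degrees of freedom.
    """
    from scipy import stats

    labels = np.asarray(labels)
    covariate = np.asarray(covariate, dtype=float)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly 2 groups required")
    if len(labels) < 3:
        raise ValueError("need at least 3 dyads")
    dummy = (labels == groups[1]).astype(float)
    if np.ptp(covariate) == 0 or np.ptp(dummy) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(dummy, covariate)
    return float(r), float(p)
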