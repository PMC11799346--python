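"""Relatedness-based clustering with multiscale-bootstrap support.

Dyadic relatedness is turned into a dissimilarity (1 - r_xy), clustered by
average linkage (UPGMA), and each internal node receives an approximately
unbiased (AU) p-value from multiscale bootstrap resampling: bootstrap
probabilities are collected at several resample sizes, a signed distance d
and curvature c are fitted to the normal-quantile transform of the BP
curve, and AU = 1 - Phi(d - c).  Significantly supported clusters (AU above
a threshold, 0.95 by default) are extracted as maximal nodes; diet-by-
cluster association is assessed with an exact r x c Fisher test; and a
leave-one-out mode reruns the whole chain without one individual to probe
the influence of single bridging samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import norm


class ClusteringError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity with zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("matrix shape must match number of ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < -1e-12):
            raise ValueError("distances must be non-negative")
        self.matrix = np.clip((d + d.T) / 2.0, 0.0, None)


@dataclass
class Dendrogram:
    """Ultrametric UPGMA tree: leaf ids plus a scipy linkage matrix.

    Internal node k (0-based) merges at height ``linkage[k, 2]``; its leaf
    set is recoverable from the linkage encoding.  Leaves are stored in
    lexicographic id order so the topology is independent of input order.
    """

    ids: list[str]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def node_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def is_ultrametric(self) -> bool:
        h = self.linkage[:, 2]
        return bool(np.all(np.diff(h) >= -1e-9))

    def cluster_leafsets(self) -> list[frozenset[str]]:
        """Leaf-id set of each internal node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset[str]] = []
        store: dict[int, frozenset[str]] = {i: frozenset([self.ids[i]]) for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.linkage):
            merged = store[int(a)] | store[int(b)]
            store[n + k] = merged
            sets.append(merged)
        return sets

    def node_depths(self) -> np.ndarray:
        """Edges between each internal node and the root (root depth 0)."""
        n = self.n_leaves
        parent = {}
        for k, (a, b, _, _) in enumerate(self.linkage):
            parent[int(a)] = n + k
            parent[int(b)] = n + k
        depths = np.zeros(len(self.linkage), dtype=int)
        for k in range(len(self.linkage) - 2, -1, -1):
            depths[k] = depths[parent[n + k] - n] + 1
        return depths

    def cut(self, node: int) -> frozenset[str]:
        return self.cluster_leafsets()[node]

    def to_newick(self, support: dict[int, float] | None = None) -> str:
        """Newick string; internal-node labels carry AU support if given."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for k, row in enumerate(self.linkage):
            heights[n + k] = row[2]

        def render(node: int) -> str:
            if node < n:
                return self.ids[node]
            k = node - n
            a, b = int(self.linkage[k, 0]), int(self.linkage[k, 1])
            la = heights[node] - heights[a]
            lb = heights[node] - heights[b]
            label = ""
            if support is not None and k in support:
                label = f"{support[k]:.3f}"
            return f"({render(a)}:{la:.6g},{render(b)}:{lb:.6g}){label}"

        return render(2 * n - 2) + ";"


@dataclass
class ClusterSupport:
    """Per-node multiscale-bootstrap support.

    ``table`` has one row per internal node with the BP fraction at every
    scale, the fitted signed distance d and curvature c, the AU value and
    its standard error, and degenerate-fit flags.
    """

    table: pd.DataFrame
    scales: list[float]
    nboot: int

    def au(self) -> dict[int, float]:
        return dict(zip(self.table["node"], self.table["au"]))


# ---------------------------------------------------------------------------
# distance construction and UPGMA
# ---------------------------------------------------------------------------

def build_distance_matrix(pairs: pd.DataFrame) -> DistanceMatrix:
    """D_ij = 1 - clamp(r_xy, 0, 1) from an all-dyads relatedness table."""
    ids = sorted(set(pairs["id_x"]) | set(pairs["id_y"]))
    index = {name: i for i, name in enumerate(ids)}
    n = len(ids)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for _, row in pairs.iterrows():
        i, j = index[row["id_x"]], index[row["id_y"]]
        val = 1.0 - min(max(float(row["r_xy"]), 0.0), 1.0)
        d[i, j] = d[j, i] = val
    missing = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(d[i, j])
    ]
    if missing:
        raise ClusteringError(f"missing dyads: {missing[:10]}")
    return DistanceMatrix(ids=ids, matrix=d)


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with order-independent output.

    Leaves are sorted lexicographically before clustering so exchangeable
    inputs give identical topologies regardless of input order.
    """
    if len(dist.ids) < 2:
        raise ClusteringError("need at least two individuals to cluster")
    order = np.argsort(dist.ids)
    ids = [dist.ids[i] for i in order]
    d = dist.matrix[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    z = z.copy()
    z[:, 2] /= 2.0  # ultrametric height: leaf-to-leaf path equals the distance
    return Dendrogram(ids=ids, linkage=z)


def _upgma_on_profiles(profiles: np.ndarray, ids: list[str], metric: str) -> Dendrogram:
    d = squareform(pdist(profiles.T, metric=metric))
    return upgma(DistanceMatrix(ids=ids, matrix=d))


# ---------------------------------------------------------------------------
# multiscale bootstrap AU p-values
# ---------------------------------------------------------------------------

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


def multiscale_bootstrap_au(
    profiles: np.ndarray,
    ids: list[str],
    nboot: int = 1000,
    scales: tuple[float, ...] | None = None,
    seed: int = 0,
    metric: str = "euclidean",
    base_tree: Dendrogram | None = None,
) -> tuple[Dendrogram, ClusterSupport]:
    """AU p-values for hierarchical clusters by multiscale bootstrap.

    ``profiles`` is a feature-by-individual matrix: columns are the
    individuals to cluster, rows are the units resampled with replacement.
    For each scale rho^2, ``nboot`` resamples of round(rho^2 * n_rows) rows
    are drawn, the columns are reclustered, and the bootstrap probability
    BP of each original cluster (exact leaf-set identity) recorded.  The
    model Phi^-1(1 - BP_rho) = d * rho + c / rho is fitted by weighted
    least squares with binomial weights, and AU = 1 - Phi(d - c).

    With a single scale the curvature is not identifiable; AU falls back to
    the plain BP with a warning and a degenerate-fit flag.
    """
    if nboot < 100:
        raise ClusteringError("nboot must be at least 100")
    profiles = np.asarray(profiles, dtype=float)
    if scales is None:
        scales = DEFAULT_SCALES
    scales = tuple(float(s) for s in scales)
    n_rows = profiles.shape[0]
    rng = np.random.default_rng(seed)

    if base_tree is None:
        base_tree = _upgma_on_profiles(profiles, ids, metric)
    ref_sets = base_tree.cluster_leafsets()
    # the root contains everything and is trivially recovered; keep it anyway
    counts = np.zeros((len(ref_sets), len(scales)))

    for si, scale in enumerate(scales):
        size = max(2, int(round(scale * n_rows)))
        for _ in range(nboot):
            rows = rng.integers(n_rows, size=size)
            boot = _upgma_on_profiles(profiles[rows], ids, metric)
            found = set(boot.cluster_leafsets())
            for ci, cs in enumerate(ref_sets):
                if cs in found:
                    counts[ci, si] += 1

    bp = counts / nboot
    rho = np.sqrt(scales)
    records = []
    for ci, cs in enumerate(ref_sets):
        rec = {"node": ci, "size": len(cs), **{f"bp_{s:g}": bp[ci, si] for si, s in enumerate(scales)}}
        never_seen = counts[ci].sum() == 0
        # boundary scales (BP exactly 0 or 1) carry no curvature information
        # and, clipped, would drag the fit toward AU = 1/2; fit on the
        # informative scales only
        informative = (counts[ci] > 0) & (counts[ci] < nboot)
        if len(scales) < 2:
            warnings.warn("single bootstrap scale: AU falls back to BP")
            rec.update(
                d=np.nan, c=np.nan, au=float(bp[ci, 0]), se=np.nan, degenerate=True
            )
        elif never_seen:
            rec.update(d=np.nan, c=np.nan, au=0.0, se=np.nan, degenerate=True)
        elif informative.sum() < 2:
            # pinned to the boundary at (almost) every scale
            side = 1.0 - 0.5 / nboot if bp[ci].mean() > 0.5 else 0.5 / nboot
            rec.update(d=np.nan, c=np.nan, au=float(side), se=np.nan, degenerate=False)
        else:
            bpc = np.clip(bp[ci, informative], 0.5 / nboot, 1.0 - 0.5 / nboot)
            z = norm.ppf(1.0 - bpc)
            w = nboot * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
            x = np.column_stack([rho[informative], 1.0 / rho[informative]])
            xtwx = x.T @ (w[:, None] * x)
            xtwz = x.T @ (w * z)
            try:
                beta = np.linalg.solve(xtwx, xtwz)
                cov = np.linalg.inv(xtwx)
            except np.linalg.LinAlgError:
                rec.update(d=np.nan, c=np.nan, au=float(bp[ci, -1]), se=np.nan, degenerate=True)
                records.append(rec)
                continue
            d_hat, c_hat = beta
            au = float(1.0 - norm.cdf(d_hat - c_hat))
            grad = norm.pdf(d_hat - c_hat)
            var = grad**2 * (cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
            rec.update(
                d=float(d_hat),
                c=float(c_hat),
                au=au,
                se=float(np.sqrt(max(var, 0.0))),
                degenerate=False,
            )
        records.append(rec)
    table = pd.DataFrame(records)
    table["depth"] = base_tree.node_depths()
    return base_tree, ClusterSupport(table=table, scales=list(scales), nboot=nboot)


def relatedness_dendrogram(
    pairs: pd.DataFrame,
    nboot: int = 1000,
    scales: tuple[float, ...] | None = None,
    seed: int = 0,
    mode: str = "direct",
) -> tuple[Dendrogram, ClusterSupport]:
    """Cluster a relatedness table and attach AU support.

    ``mode='direct'`` clusters on 1 - r_xy itself; bootstrap perturbation
    resamples the rows of the dissimilarity matrix (individuals as
    features).  ``mode='profile-euclidean'`` clusters on Euclidean
    distances between the columns of the dissimilarity matrix, matching
    tools that recompute a column-profile distance internally.
    """
    dist = build_distance_matrix(pairs)
    order = np.argsort(dist.ids)
    ids = [dist.ids[i] for i in order]
    d = dist.matrix[np.ix_(order, order)]
    if mode == "direct":
        base = upgma(dist)
    elif mode == "profile-euclidean":
        base = _upgma_on_profiles(d, ids, "euclidean")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return multiscale_bootstrap_au(
        d, ids, nboot=nboot, scales=scales, seed=seed, metric="euclidean", base_tree=base
    )


def significant_clusters(
    tree: Dendrogram, support: ClusterSupport, threshold: float = 0.95
) -> tuple[list[dict], list[str]]:
    """Maximal internal nodes with AU above the threshold.

    Returns (clusters, unassigned): each cluster carries its node index,
    leaf set, AU value and node depth; individuals contained in no
    significant cluster are listed separately.  The root is not a
    hypothesis (every resample recovers the full leaf set by construction)
    and is excluded from extraction.
    """
    leafsets = tree.cluster_leafsets()
    au = support.au()
    sig = [k for k in range(len(leafsets) - 1) if au.get(k, 0.0) > threshold]
    maximal = [
        k for k in sig
        if not any(other != k and leafsets[k] < leafsets[other] for other in sig)
    ]
    depths = tree.node_depths()
    clusters = [
        {
            "node": k,
            "members": sorted(leafsets[k]),
            "au": au[k],
            "depth": int(depths[k]),
        }
        for k in sorted(maximal, key=lambda k: -len(leafsets[k]))
    ]
    assigned = set().union(*(leafsets[k] for k in maximal)) if maximal else set()
    unassigned = sorted(set(tree.ids) - assigned)
    return clusters, unassigned


# ---------------------------------------------------------------------------
# exact r x c Fisher test
# ---------------------------------------------------------------------------

def _table_logprob(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability given both margins."""
    t = np.asarray(table)
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact_rxc(
    table: np.ndarray | list[list[int]],
    mc: bool = False,
    n_mc: int = 100000,
    seed: int = 0,
) -> float:
    """Two-sided exact test of independence for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of those no more probable
    than the observed table (relative tolerance 1e-7); reduces to the
    standard two-sided Fisher test for 2 x 2 tables.  Tables larger than
    5 x 10 must use the Monte-Carlo mode (``mc=True``), which samples
    tables from the null by permutation.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() < 1:
        raise ValueError("table must contain at least one observation")
    # drop empty rows/columns: they carry no information
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    r, c = t.shape
    if (min(r, c) > 5 or max(r, c) > 10) and not mc:
        raise ValueError(
            f"{r}x{c} table exceeds the enumeration bound (5x10); use mc=True"
        )
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    obs_lp = _table_logprob(t)

    if mc:
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(c), col_sums)
        row_of = np.repeat(np.arange(r), row_sums)
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(labels)
            perm = np.zeros((r, c), dtype=int)
            np.add.at(perm, (row_of, labels), 1)
            if _table_logprob(perm) <= obs_lp + 1e-7:
                hits += 1
        return (hits + 1) / (n_mc + 1)

    total_p = 0.0

    def fill_row(i: int, remaining_cols: np.ndarray, partial: list[np.ndarray]) -> None:
        nonlocal total_p
        if i == r - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            cand = np.array(partial + [last])
            lp = _table_logprob(cand)
            if lp <= obs_lp + 1e-7 * abs(obs_lp) + 1e-12:
                total_p += math.exp(lp)
            return
        target = row_sums[i]

        def fill_cell(j: int, left: int, row: list[int]) -> None:
            if j == c - 1:
                if 0 <= left <= remaining_cols[c - 1]:
                    fill_row(
                        i + 1,
                        remaining_cols - np.array(row + [left]),
                        partial + [np.array(row + [left])],
                    )
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill_cell(j + 1, left - v, row + [v])

        fill_cell(0, int(target), [])

    fill_row(0, col_sums.copy(), [])
    return min(total_p, 1.0)


def diet_cluster_table(
    diet: dict[str, str], clusters: list[dict], unknown: str = "unknown"
) -> pd.DataFrame:
    """Diet-by-cluster contingency table over significantly clustered individuals."""
    rows = sorted({v for v in diet.values() if v != unknown})
    cols = [f"cluster{c['node']}" for c in clusters]
    tab = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for c, name in zip(clusters, cols):
        for member in c["members"]:
            label = diet.get(member, unknown)
            if label != unknown:
                tab.loc[label, name] += 1
    return tab


def leave_one_out_recluster(
    pairs: pd.DataFrame,
    drop_id: str,
    diet: dict[str, str] | None = None,
    nboot: int = 1000,
    threshold: float = 0.95,
    seed: int = 0,
    mode: str = "direct",
) -> dict:
    """Rerun clustering and diet-association without one individual.

    Reports the reduced tree, its support, significant clusters, the diet
    contingency table and Fisher p (when diet labels are given), and the
    change in significant-cluster count relative to the full run.
    """
    ids = set(pairs["id_x"]) | set(pairs["id_y"])
    if drop_id not in ids:
        raise ClusteringError(f"unknown individual {drop_id!r}")
    if len(ids) - 1 < 2:
        raise ClusteringError("cannot recluster fewer than two individuals")
    full_tree, full_support = relatedness_dendrogram(
        pairs, nboot=nboot, seed=seed, mode=mode
    )
    full_clusters, _ = significant_clusters(full_tree, full_support, threshold)
    reduced = pairs[(pairs["id_x"] != drop_id) & (pairs["id_y"] != drop_id)]
    tree, support = relatedness_dendrogram(reduced, nboot=nboot, seed=seed, mode=mode)
    clusters, unassigned = significant_clusters(tree, support, threshold)
    out = {
        "tree": tree,
        "support": support,
        "clusters": clusters,
        "unassigned": unassigned,
        "n_clusters_full": len(full_clusters),
        "n_clusters_reduced": len(clusters),
    }
    if diet is not None and clusters:
        tab = diet_cluster_table(diet, clusters)
        if tab.to_numpy().sum() > 0 and tab.shape[0] >= 2 and tab.shape[1] >= 2:
            out["diet_table"] = tab
            out["diet_p"] = fisher_exact_rxc(tab.to_numpy())
        else:
            out["diet_table"] = tab
            out["diet_p"] = float("nan")
    return out
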