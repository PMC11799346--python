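"""Mitochondrial pipeline: haplogroups, median-joining network, AMOVA phi_ST.

Variable alignment columns are tallied; columns whose minor base occurs in
exactly one sequence are treated as putative sequencing errors (singletons)
and masked, so individuals are grouped into haplogroups — equivalence
classes over the remaining diagnostic sites — rather than raw haplotypes.
A median-joining network connects the haplogroups, and population
differentiation is quantified by AMOVA phi_ST with a permutation test and
Bonferroni-corrected pairwise comparisons, treating the mitogenome as a
single locus.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from demekin.genio import AlignmentSet

_MISSING = {"N", "-"}


@dataclass
class VariantTable:
    """Variable alignment columns and per-sequence genotypes at them."""

    ids: list[str]
    positions: np.ndarray  # alignment coordinates (0-based) of variable sites
    base_counts: list[dict[str, int]]  # per variable site
    singleton: np.ndarray  # per variable site
    genotypes: np.ndarray  # (n_sequences, n_variable) characters incl. N/-

    @property
    def n_variable(self) -> int:
        return len(self.positions)


@dataclass
class HaplogroupSet:
    """Singleton-masked haplogroup assignments.

    Two individuals share a haplogroup iff their bases agree at every
    diagnostic (variable, non-singleton) site.
    """

    labels: list[str]
    assignment: dict[str, str]
    defining: dict[str, str]  # haplogroup -> base vector over diagnostic sites
    diagnostic_positions: np.ndarray
    ambiguous: list[str] = field(default_factory=list)

    def counts(self) -> pd.Series:
        return pd.Series(list(self.assignment.values())).value_counts()

    def composition(self, groups: dict[str, str]) -> pd.DataFrame:
        rows = [
            {"id": i, "haplogroup": h, "group": groups.get(i, "?")}
            for i, h in self.assignment.items()
        ]
        return (
            pd.DataFrame(rows)
            .groupby(["haplogroup", "group"])
            .size()
            .unstack(fill_value=0)
        )


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes: haplogroup labels (+ inferred medians), edges weighted
    observed: dict[str, int]  # haplogroup -> count
    spanning_length: float = 0.0  # MST length over the final node set

    def total_length(self) -> float:
        """Summed edge weight including alternative (tied) links."""
        return sum(w for _, _, w in self.graph.edges.data("weight"))


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# variant calling and haplogroups
# ---------------------------------------------------------------------------

def call_variant_sites(aln: AlignmentSet) -> VariantTable:
    """Tally unambiguous bases per column; flag variable and singleton sites.

    Gaps and N are missing and excluded from tallies; a column is variable
    when at least two distinct unambiguous bases are observed.  Bases
    carried by exactly one sequence are treated as putative sequencing
    errors: they are masked to N in the genotype matrix, and a variable
    column where masking leaves fewer than two distinct bases is flagged
    singleton (so one private mutation can never split a haplogroup).
    """
    if not aln.ids:
        raise ValueError("empty alignment")
    arr = aln.as_array()
    positions, counts, singleton = [], [], []
    masked = arr.copy()
    for col in range(arr.shape[1]):
        column = arr[:, col]
        ok = ~np.isin(column, list(_MISSING))
        vals, n = np.unique(column[ok], return_counts=True)
        if len(vals) >= 2:
            positions.append(col)
            counts.append(dict(zip(vals.tolist(), n.tolist())))
            private = vals[n == 1]
            if private.size:
                masked[np.isin(column, private), col] = "N"
            singleton.append(len(vals[n > 1]) < 2)
    positions = np.array(positions, dtype=int)
    genotypes = (
        masked[:, positions] if len(positions) else np.empty((len(aln.ids), 0), dtype="U1")
    )
    return VariantTable(
        ids=list(aln.ids),
        positions=positions,
        base_counts=counts,
        singleton=np.array(singleton, dtype=bool),
        genotypes=genotypes,
    )


def assign_haplogroups(vt: VariantTable) -> HaplogroupSet:
    """Group sequences by identity at the diagnostic (non-singleton) sites.

    Sequences with missing diagnostic bases are assigned to the unique
    compatible haplogroup when one exists, otherwise flagged ambiguous.
    With no diagnostic sites everything collapses into one haplogroup.
    """
    diag = ~vt.singleton if vt.n_variable else np.zeros(0, dtype=bool)
    diag_pos = vt.positions[diag]
    vectors = vt.genotypes[:, diag] if diag.any() else np.empty((len(vt.ids), 0), dtype="U1")

    complete: dict[str, list[int]] = {}
    incomplete: list[int] = []
    for i in range(len(vt.ids)):
        vec = vectors[i]
        if any(b in _MISSING for b in vec):
            incomplete.append(i)
        else:
            complete.setdefault("".join(vec), []).append(i)

    labels = {key: f"H{j + 1}" for j, key in enumerate(sorted(complete))}
    assignment: dict[str, str] = {}
    for key, members in complete.items():
        for i in members:
            assignment[vt.ids[i]] = labels[key]
    ambiguous: list[str] = []
    for i in incomplete:
        vec = vectors[i]
        compatible = [
            key
            for key in complete
            if all(b in _MISSING or b == k for b, k in zip(vec, key))
        ]
        if len(compatible) == 1:
            assignment[vt.ids[i]] = labels[compatible[0]]
        else:
            ambiguous.append(vt.ids[i])
            assignment[vt.ids[i]] = "ambiguous"
    if not complete:  # every sequence incomplete or no diagnostic sites
        for i in vt.ids:
            assignment[i] = "H1"
        labels = {"": "H1"}
        ambiguous = []
    return HaplogroupSet(
        labels=sorted(set(assignment.values()) - {"ambiguous"}),
        assignment=assignment,
        defining={labels[k]: k for k in labels},
        diagnostic_positions=diag_pos,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msts_union(vectors: dict[str, str], epsilon: int = 0) -> nx.Graph:
    """Union of all minimum spanning trees (Kruskal with tied weights).

    An edge of weight w is kept iff its endpoints are not already connected
    by edges of weight < w - ``epsilon``; with epsilon = 0 this is exactly
    the set of edges belonging to some MST, and larger epsilon admits the
    slightly longer alternative links of the median-joining relaxation.
    """
    names = sorted(vectors)
    g = nx.Graph()
    g.add_nodes_from(names)
    edges = sorted(
        (_hamming(vectors[a], vectors[b]), a, b)
        for a, b in itertools.combinations(names, 2)
    )
    for w, a, b in edges:
        uf = nx.utils.UnionFind(names)
        for w2, a2, b2 in edges:
            if w2 < w - epsilon:
                uf.union(a2, b2)
        if uf[a] != uf[b]:
            g.add_edge(a, b, weight=w)
    # ensure connectivity (epsilon pruning cannot disconnect, but guard anyway)
    if names and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        while len(comps) > 1:
            best = min(
                (_hamming(vectors[a], vectors[b]), a, b)
                for a in comps[0]
                for comp in comps[1:]
                for b in comp
            )
            g.add_edge(best[1], best[2], weight=best[0])
            comps = [sorted(c) for c in nx.connected_components(g)]
    return g


def _mst_total(vectors: dict[str, str]) -> float:
    names = sorted(vectors)
    if len(names) < 2:
        return 0.0
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        g.add_edge(a, b, weight=_hamming(vectors[a], vectors[b]))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(g).edges(data=True))


def median_joining_network(
    hgs: HaplogroupSet, epsilon: int = 0, max_medians: int = 50
) -> HaplotypeNetwork:
    """Median-joining network over the haplogroup base vectors.

    Starts from the union of minimum spanning trees within tolerance
    ``epsilon`` on Hamming distances, iteratively adds median (sitewise
    consensus) vectors of connected triplets when they shorten the total
    spanning length, and prunes inferred medians that no longer help.
    """
    observed = dict(hgs.counts())
    observed.pop("ambiguous", None)
    vectors = {h: hgs.defining[h] for h in observed}
    if not vectors:
        raise ValueError("no haplogroups")
    median_count = 0

    def medians_of(g: nx.Graph) -> list[str]:
        cands = []
        for u in g.nodes:
            nbrs = sorted(g.neighbors(u))
            for v, w in itertools.combinations(nbrs, 2):
                vec = "".join(
                    max(triple, key=lambda b: (triple.count(b), b))
                    for triple in zip(vectors[u], vectors[v], vectors[w])
                )
                if vec not in vectors.values():
                    cands.append(vec)
        return cands

    current_len = _mst_total(vectors)
    improved = True
    while improved and median_count < max_medians:
        improved = False
        net = _msts_union(vectors, epsilon)
        for vec in medians_of(net):
            trial = dict(vectors)
            name = f"median{median_count + 1}"
            trial[name] = vec
            new_len = _mst_total(trial)
            if new_len < current_len - 1e-9:
                vectors = trial
                current_len = new_len
                median_count += 1
                improved = True
                break

    # prune medians whose removal does not lengthen the spanning structure
    for name in [n for n in sorted(vectors) if n.startswith("median")]:
        trial = {k: v for k, v in vectors.items() if k != name}
        if _mst_total(trial) <= current_len + 1e-9:
            vectors = trial
            current_len = _mst_total(trial)

    graph = _msts_union(vectors, epsilon)
    for node in graph.nodes:
        graph.nodes[node]["count"] = observed.get(node, 0)
        graph.nodes[node]["inferred"] = node.startswith("median")
        graph.nodes[node]["vector"] = vectors[node]
    return HaplotypeNetwork(
        graph=graph, observed=observed, spanning_length=_mst_total(vectors)
    )


# ---------------------------------------------------------------------------
# AMOVA phi_ST
# ---------------------------------------------------------------------------

def _pairwise_differences(vectors: np.ndarray) -> np.ndarray:
    """Counts of differing sites for every sequence pair, missing excluded."""
    n = vectors.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vectors[i], vectors[j]
            ok = ~np.isin(a, list(_MISSING)) & ~np.isin(b, list(_MISSING))
            d[i, j] = d[j, i] = int(np.sum(a[ok] != b[ok]))
    return d


def _amova_components(d2: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float]:
    """Variance components from squared distances (Excoffier AMOVA).

    ``d2`` holds the squared inter-individual distances; for nucleotide
    data the number of differing sites plays that role directly.
    """
    n_total = sum(len(g) for g in group_idx)
    n_groups = len(group_idx)
    ss_total = d2.sum() / (2.0 * n_total)
    ss_within = sum(
        d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in group_idx
    )
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n_total - n_groups
    ms_among = ss_among / df_among if df_among else 0.0
    ms_within = ss_within / df_within if df_within else 0.0
    n0 = (n_total - sum(len(g) ** 2 for g in group_idx) / n_total) / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0 if n0 > 0 else 0.0
    return sigma_among, sigma_within


def _phi(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    sa, sw = _amova_components(d2, group_idx)
    tot = sa + sw
    return sa / tot if tot > 0 else 0.0


def amova_phist(
    hgs: HaplogroupSet,
    groups: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    distance: str = "diff",
    pairwise_tests: bool = True,
    alpha: float = 0.05,
    max_missing: float = 0.1,
) -> AmovaResult:
    """AMOVA-based phi_ST with a permutation test and pairwise comparisons.

    The mitogenome is one locus; inter-individual distance is the number of
    differing diagnostic sites (``distance='diff'``) or 0/1 haplogroup
    identity (``distance='identity'``).  Variance components come from the
    standard AMOVA mean squares; significance from permuting individuals
    among groups, p = (1 + #{phi* >= phi}) / (n_perm + 1).  Pairwise
    phi_ST is tested for every group pair with a Bonferroni-adjusted alpha.
    """
    ids = [i for i in hgs.assignment if hgs.assignment[i] != "ambiguous"]
    diag = hgs.diagnostic_positions
    # sequence vectors over diagnostic sites, via the haplogroup definitions
    vecs = []
    kept_ids = []
    for i in ids:
        key = hgs.defining[hgs.assignment[i]]
        arr = np.array(list(key), dtype="U1") if key else np.array([], dtype="U1")
        if key and np.isin(arr, list(_MISSING)).mean() > max_missing:
            warnings.warn(f"{i}: > {max_missing:.0%} diagnostic sites missing; dropped")
            continue
        vecs.append(arr)
        kept_ids.append(i)
    ids = kept_ids
    labels = [groups[i] for i in ids]
    uniq = sorted(set(labels))
    sizes = {g: labels.count(g) for g in uniq}
    keep_groups = [g for g in uniq if sizes[g] >= 2]
    for g in uniq:
        if sizes[g] < 2:
            warnings.warn(f"group {g!r} has fewer than two members; excluded")
    if len(keep_groups) < 2:
        raise ValueError("need at least two groups with two or more members")
    mask = [lab in keep_groups for lab in labels]
    ids = [i for i, m in zip(ids, mask) if m]
    labels = [lab for lab, m in zip(labels, mask) if m]
    vec_arr = np.array([vecs[k] for k, m in enumerate(mask) if m])

    if distance == "diff":
        d2 = _pairwise_differences(vec_arr)
    elif distance == "identity":
        hap = [hgs.assignment[i] for i in ids]
        d2 = np.array([[0.0 if a == b else 1.0 for b in hap] for a in hap])
    else:
        raise ValueError(f"unknown distance {distance!r}")

    group_idx = [
        np.array([k for k, lab in enumerate(labels) if lab == g]) for g in keep_groups
    ]
    degenerate = not d2.any()
    sigma_a, sigma_w = _amova_components(d2, group_idx)
    phi = _phi(d2, group_idx)

    rng = np.random.default_rng(seed)
    perm_labels = np.array(labels)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        pg = [np.flatnonzero(perm_labels == g) for g in keep_groups]
        if _phi(d2, pg) >= phi - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)

    pw = None
    if pairwise_tests and len(keep_groups) >= 2:
        n_tests = len(keep_groups) * (len(keep_groups) - 1) // 2
        adj_alpha = alpha / n_tests
        rows = []
        for ga, gb in itertools.combinations(keep_groups, 2):
            sel = [k for k, lab in enumerate(labels) if lab in (ga, gb)]
            sub_d2 = d2[np.ix_(sel, sel)]
            sub_labels = np.array([labels[k] for k in sel])
            gi = [np.flatnonzero(sub_labels == g) for g in (ga, gb)]
            sub_phi = _phi(sub_d2, gi)
            sub_hits = 0
            pl = sub_labels.copy()
            for _ in range(n_perm):
                rng.shuffle(pl)
                pgi = [np.flatnonzero(pl == g) for g in (ga, gb)]
                if _phi(sub_d2, pgi) >= sub_phi - 1e-12:
                    sub_hits += 1
            sub_p = (1 + sub_hits) / (n_perm + 1)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "phi_st": sub_phi,
                    "p": sub_p,
                    "significant_raw": sub_p < alpha,
                    "significant_bonferroni": sub_p < adj_alpha,
                    "adjusted_alpha": adj_alpha,
                }
            )
        pw = pd.DataFrame(rows)

    return AmovaResult(
        sigma_among=sigma_a,
        sigma_within=sigma_w,
        phi_st=phi,
        p_value=p,
        n_permutations=n_perm,
        pairwise=pw,
        degenerate=degenerate,
    )
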