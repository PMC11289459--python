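"""Co-expression network: Spearman matrix, permutation-FDR edge filtering,
planar maximally filtered graph (PMFG), multiscale module detection, module
eigengene / trait association, and Fisher overlap enrichment.

The PMFG is the densest planar subgraph reachable by greedy insertion of
edges in decreasing |rho| order; planarity caps it at 3(n-2) edges, which a
complete candidate set always attains. Modules are found by recursive
silhouette-selected k-medoids on shortest-path distances over the PMFG, a
defined multiscale procedure in the spirit of MEGENA-style clustering:
leaves form a non-overlapping partition of the clustered nodes, and each
leaf's relevance to a binary trait is the correlation between its first
principal component (module eigengene) and the trait indicator, with
Benjamini-Hochberg control across the module x trait family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import dijkstra
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "CorrelationNetwork",
    "PMFG",
    "ModuleTree",
    "ModuleTraitResult",
    "OverlapResult",
    "spearman_matrix",
    "permutation_edge_filter",
    "build_pmfg",
    "multiscale_cluster",
    "principal_components",
    "module_trait_association",
    "fisher_overlap",
]


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: i, j, rho, p, q (i < j as node indices)


@dataclass
class PMFG:
    nodes: list[str]
    edges: pd.DataFrame  # columns: i, j, weight (|rho|), rho

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        for row in self.edges.itertuples(index=False):
            g.add_edge(int(row.i), int(row.j), weight=float(row.weight),
                       rho=float(row.rho))
        return g

    def to_graphml(self, path) -> None:
        """Export with gene ids as node labels."""
        g = nx.relabel_nodes(self.to_networkx(),
                             dict(enumerate(self.nodes)), copy=True)
        nx.write_graphml(g, path)


@dataclass
class ModuleNode:
    module_id: str
    members: list[int]
    parent: str | None
    children: list[str] = field(default_factory=list)
    quality: float | None = None  # silhouette of the split that made it


@dataclass
class ModuleTree:
    nodes: dict[str, ModuleNode]
    root_ids: list[str]

    def leaves(self) -> list[ModuleNode]:
        return [n for n in self.nodes.values() if not n.children]

    def assert_partition(self, universe: set[int]) -> None:
        seen: set[int] = set()
        for leaf in self.leaves():
            overlap = seen & set(leaf.members)
            if overlap:
                raise AssertionError(f"leaf modules overlap at nodes {overlap}")
            seen |= set(leaf.members)
        if seen != universe:
            raise AssertionError("leaf modules do not cover the clustered nodes")


@dataclass
class ModuleTraitResult:
    module_id: str
    trait: str
    n_genes: int
    pc1_variance_fraction: float
    correlation: float
    p: float
    q: float | None = None
    significant: bool = False


@dataclass
class OverlapResult:
    size_a: int
    size_b: int
    universe: int
    overlap: int
    odds_ratio: float
    p: float
    haldane_corrected: bool


def spearman_matrix(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Gene-gene Spearman rho matrix (average ranks for ties); genes with
    zero variance across samples are excluded and reported by id."""
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples for rank correlations")
    values = expr.values
    keep = values.std(axis=1) > 0
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    ranks = np.apply_along_axis(stats.rankdata, 1, values[keep])
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    return rho, kept_ids


def permutation_edge_filter(
    expr: ExpressionMatrix,
    B: int = 100,
    q_threshold: float = 0.05,
    seed: int | None = None,
    pool_null: bool = True,
) -> CorrelationNetwork:
    """Permutation-test edge filter with BH FDR control.

    The null distribution of |rho| comes from B whole-matrix permutations
    (each gene's samples shuffled independently, destroying all gene-gene
    dependence while preserving margins). With ``pool_null`` (default) the
    null draws are pooled across pairs, buying empirical-p resolution of
    ~1/(B * n_pairs); with ``pool_null=False`` each pair is ranked against
    its own B draws only (resolution 1/(B+1)). Edges with BH q below
    ``q_threshold`` are retained.
    """
    if B < 100:
        raise ValueError("B < 100 gives too coarse empirical p resolution")
    rng = np.random.default_rng(seed)
    rho, kept_ids = spearman_matrix(expr)
    m = len(kept_ids)
    iu = np.triu_indices(m, k=1)
    obs = np.abs(rho[iu])

    values = expr.values[[expr.gene_ids.index(g) for g in kept_ids]]
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    null_pool = []
    for _ in range(B):
        perm_ranks = np.array([r[rng.permutation(len(r))] for r in ranks])
        null_rho = np.corrcoef(perm_ranks)
        null_pool.append(np.abs(null_rho[iu]))

    if pool_null:
        null = np.sort(np.concatenate(null_pool))
        n_null = len(null)
        geq = n_null - np.searchsorted(null, obs, side="left")
        p = (1.0 + geq) / (n_null + 1.0)
    else:
        null_per_pair = np.stack(null_pool)  # B x n_pairs
        geq = (null_per_pair >= obs[None, :]).sum(axis=0)
        p = (1.0 + geq) / (B + 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")[:4]

    keep = q < q_threshold
    edges = pd.DataFrame(
        {
            "i": iu[0][keep],
            "j": iu[1][keep],
            "rho": rho[iu][keep],
            "p": p[keep],
            "q": q[keep],
        }
    )
    return CorrelationNetwork(nodes=kept_ids, edges=edges)


def build_pmfg(network: CorrelationNetwork) -> PMFG:
    """Greedy planar filtering: candidate edges sorted by |rho| descending
    (ties broken by the lexicographic node pair), inserted iff the graph
    stays planar, stopping at the planar bound 3(n-2)."""
    n = len(network.nodes)
    if n < 3:
        raise ValueError("PMFG needs >= 3 nodes")
    edges = network.edges.copy()
    edges["absrho"] = edges["rho"].abs()
    edges = edges.sort_values(
        by=["absrho", "i", "j"], ascending=[False, True, True], kind="mergesort"
    )
    limit = 3 * (n - 2)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    kept = []

    # union-find over connected components lets two classes of edges skip
    # the O(n) planarity check: a bridge between components never breaks
    # planarity, and an intra-component edge beyond the 3c-6 bound never
    # keeps it.
    parent = list(range(n))
    comp_members: dict[int, set[int]] = {i: {i} for i in range(n)}
    comp_edges = [0] * n

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row in edges.itertuples(index=False):
        if len(kept) >= limit:
            break
        i, j = int(row.i), int(row.j)
        ri, rj = find(i), find(j)
        if ri != rj:
            if len(comp_members[ri]) < len(comp_members[rj]):
                ri, rj = rj, ri
            parent[rj] = ri
            comp_members[ri] |= comp_members.pop(rj)
            comp_edges[ri] += comp_edges[rj] + 1
            g.add_edge(i, j)
            kept.append((i, j, abs(row.rho), row.rho))
            continue
        c = len(comp_members[ri])
        if c >= 3 and comp_edges[ri] + 1 > 3 * c - 6:
            continue
        g.add_edge(i, j)
        # planarity is a per-component property: test only the touched one
        planar, _ = nx.check_planarity(
            g.subgraph(comp_members[ri]), counterexample=False
        )
        if planar:
            comp_edges[ri] += 1
            kept.append((i, j, abs(row.rho), row.rho))
        else:
            g.remove_edge(i, j)
    out = pd.DataFrame(kept, columns=["i", "j", "weight", "rho"])
    return PMFG(nodes=list(network.nodes), edges=out)


def _pam_kmedoids(
    dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 30
) -> np.ndarray:
    """Seeded PAM (build + swap) k-medoids on a precomputed distance matrix;
    returns cluster labels."""
    n = dist.shape[0]
    # build: greedy min-cost medoid additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        improved = False
        for ci in range(k):
            members = np.flatnonzero(labels == ci)
            if members.size == 0:
                continue
            costs = dist[np.ix_(members, members)].sum(axis=0)
            best = members[np.argmin(costs)]
            if best != medoids[ci]:
                medoids[ci] = best
                improved = True
        if not improved:
            break
    return np.argmin(dist[:, medoids], axis=1)


def multiscale_cluster(
    pmfg: PMFG,
    min_size: int = 10,
    k_max: int = 8,
    silhouette_threshold: float = 0.3,
    seed: int | None = None,
    epsilon: float = 1e-6,
) -> ModuleTree:
    """Recursive multiscale module detection on the PMFG.

    Shortest-path distances are computed with edge length 1 - |rho| + eps.
    Each module of size >= 2*min_size is split by k-medoids for
    k = 2..k_max, the k with the best mean silhouette wins, and the split
    is accepted (and recursed into) only when that silhouette reaches the
    threshold. Connected components are handled independently; leaves are
    the reported non-overlapping module set.
    """
    g = pmfg.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    n = g.number_of_nodes()
    adj = np.full((n, n), np.inf)
    for i, j, data in g.edges(data=True):
        length = 1.0 - abs(data.get("rho", data.get("weight", 0.0))) + epsilon
        adj[i, j] = adj[j, i] = min(adj[i, j], length)
    np.fill_diagonal(adj, 0.0)
    adj[np.isinf(adj)] = 0.0
    dist_full = dijkstra(adj, directed=False, unweighted=False)

    nodes: dict[str, ModuleNode] = {}
    root_ids: list[str] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"M{counter[0]}"

    def split(members: list[int], parent_id: str | None) -> str:
        mid = new_id()
        node = ModuleNode(module_id=mid, members=list(members), parent=parent_id)
        nodes[mid] = node
        if len(members) >= 2 * min_size:
            sub = dist_full[np.ix_(members, members)]
            finite_max = sub[np.isfinite(sub)].max() if np.isfinite(sub).any() else 1.0
            sub = np.where(np.isfinite(sub), sub, 10 * finite_max + 1)
            best_labels, best_sil = None, -np.inf
            for k in range(2, min(k_max, len(members) - 1) + 1):
                labels = _pam_kmedoids(sub, k, rng)
                if len(np.unique(labels)) < 2:
                    continue
                sil = silhouette_score(sub, labels, metric="precomputed")
                if sil > best_sil:
                    best_sil, best_labels = sil, labels
            if best_labels is not None and best_sil >= silhouette_threshold:
                node.quality = float(best_sil)
                for lab in np.unique(best_labels):
                    child_members = [members[i] for i in
                                     np.flatnonzero(best_labels == lab)]
                    child_id = split(child_members, mid)
                    node.children.append(child_id)
        return mid

    for comp in nx.connected_components(g):
        root_ids.append(split(sorted(comp), None))

    tree = ModuleTree(nodes=nodes, root_ids=root_ids)
    tree.assert_partition(set(range(n)))
    return tree


def principal_components(
    matrix: np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of an observations x variables matrix.

    Columns are standardised first (constant columns rejected); returns
    (scores, variance fractions). PC1's sign is fixed so its correlation
    with the row-wise mean profile is non-negative.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if k > min(X.shape):
        raise ValueError("k exceeds matrix rank bound")
    sd = X.std(axis=0)
    if (sd == 0).all():
        raise ValueError("constant matrix has no principal components")
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    var_frac = (s**2 / (s**2).sum())[:k]
    mean_profile = X.mean(axis=1)
    if mean_profile.std() > 0 and scores.shape[1] >= 1:
        r = np.corrcoef(scores[:, 0], mean_profile)[0, 1]
        if np.isfinite(r) and r < 0:
            scores[:, 0] *= -1
    return scores, var_frac


def module_trait_association(
    tree: ModuleTree,
    expr: ExpressionMatrix,
    traits: dict[str, np.ndarray],
    node_gene_ids: list[str] | None = None,
    method: str = "spearman",
    q_threshold: float = 0.05,
) -> list[ModuleTraitResult]:
    """Module eigengene vs trait association for every leaf module.

    PC1 of each leaf's gene x sample submatrix (samples as observations)
    is correlated with each binary trait indicator; BH adjustment runs
    across the full module x trait family. Modules with < 2 genes are
    skipped.
    """
    gene_ids = node_gene_ids if node_gene_ids is not None else expr.gene_ids
    gene_row = {g: i for i, g in enumerate(expr.gene_ids)}
    results: list[ModuleTraitResult] = []
    for leaf in tree.leaves():
        members = [gene_ids[i] for i in leaf.members]
        rows = [gene_row[g] for g in members if g in gene_row]
        if len(rows) < 2:
            continue
        sub = expr.values[rows].T  # samples x genes
        try:
            scores, var_frac = principal_components(sub, k=1)
        except ValueError:
            continue
        pc1 = scores[:, 0]
        for trait_name, indicator in traits.items():
            indicator = np.asarray(indicator, dtype=float)
            if method == "spearman":
                corr, p = stats.spearmanr(pc1, indicator)
            elif method == "pearson":
                corr, p = stats.pearsonr(pc1, indicator)
            else:
                raise ValueError(f"unknown method {method!r}")
            results.append(
                ModuleTraitResult(
                    module_id=leaf.module_id,
                    trait=trait_name,
                    n_genes=len(rows),
                    pc1_variance_fraction=float(var_frac[0]),
                    correlation=float(corr),
                    p=float(p) if np.isfinite(p) else 1.0,
                )
            )
    if results:
        pvals = [r.p for r in results]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")[:4]
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.significant = bool(q < q_threshold)
    return results


def fisher_overlap(set_a, set_b, universe) -> OverlapResult:
    """Two-sided Fisher exact test of the overlap of two gene sets within
    a universe; odds ratio from the 2x2 table with Haldane 0.5 correction
    iff any cell is zero (flagged)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    haldane = (table == 0).any()
    if haldane:
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        universe=len(universe),
        overlap=n11,
        odds_ratio=float(odds),
        p=float(p),
        haldane_corrected=bool(haldane),
    )
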