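"""Spearman network, permutation FDR, PMFG, modules, eigengenes, overlap."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from trilayer.containers import ExpressionMatrix
from trilayer.network import (
    CorrelationNetwork,
    build_pmfg,
    fisher_overlap,
    module_trait_association,
    multiscale_cluster,
    permutation_edge_filter,
    principal_components,
    spearman_matrix,
)


def _expr(values, prefix="g"):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
    )


class TestSpearman:
    def test_unit_diagonal(self):
        rng = np.random.default_rng(0)
        rho, _ = spearman_matrix(_expr(rng.normal(size=(5, 20))))
        assert np.allclose(np.diag(rho), 1.0)

    def test_monotone_invariance(self):
        x = np.linspace(0.1, 3, 25)
        rho, _ = spearman_matrix(_expr(np.vstack([x, np.exp(x)])))
        assert rho[0, 1] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(2, 10))
        rho, _ = spearman_matrix(_expr(vals))
        r1, r2 = stats.rankdata(vals[0]), stats.rankdata(vals[1])
        assert rho[0, 1] == pytest.approx(np.corrcoef(r1, r2)[0, 1])

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(3, 10))
        vals[1] = 5.0
        rho, kept = spearman_matrix(_expr(vals))
        assert kept == ["g0", "g2"]
        assert rho.shape == (2, 2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            spearman_matrix(_expr(np.zeros((4, 2))))


class TestPermutationFilter:
    def test_null_data_controls_fdr(self):
        kept_frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = _expr(rng.normal(size=(50, 100)))
            net = permutation_edge_filter(expr, B=100, seed=seed + 500)
            kept_frac.append(len(net.edges) / comb(50, 2))
        assert np.mean(kept_frac) <= 2 * 0.05

    def test_planted_strong_pairs_recovered(self):
        rng = np.random.default_rng(3)
        n = 50
        base = rng.normal(size=(10, n))
        noise = rng.normal(size=(10, n))
        planted = np.sqrt(0.9) * base + np.sqrt(0.1) * noise  # rho ~ 0.95
        expr = _expr(np.vstack([base, planted, rng.normal(size=(30, n))]))
        net = permutation_edge_filter(expr, B=200, seed=42)
        found = {(int(r.i), int(r.j)) for r in net.edges.itertuples(index=False)}
        hits = sum((i, i + 10) in found or (i + 10, i) in found
                   for i in range(10))
        assert hits >= 9  # >= 90% of the 10 planted pairs

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B"):
            permutation_edge_filter(_expr(np.zeros((3, 5))), B=10)

    def test_per_pair_null_recovers_strong_edges(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=30)
        expr = _expr(np.vstack([base, base + 0.1 * rng.normal(size=30),
                                rng.normal(size=(8, 30))]))
        # per-pair resolution is 1/(B+1): B must exceed n_pairs/q for the
        # top-ranked edge to clear its BH threshold
        net = permutation_edge_filter(expr, B=2000, seed=11, pool_null=False)
        found = {(int(r.i), int(r.j)) for r in net.edges.itertuples(index=False)}
        assert (0, 1) in found


def _complete_network(n, seed=0):
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n), 2))
    rho = rng.uniform(-1, 1, len(pairs))
    edges = pd.DataFrame(
        {"i": [p[0] for p in pairs], "j": [p[1] for p in pairs],
         "rho": rho, "p": 0.001, "q": 0.001}
    )
    return CorrelationNetwork(nodes=[f"g{i}" for i in range(n)], edges=edges)


def _naive_pmfg_edges(network):
    """Brute-force oracle: plain greedy insertion with a whole-graph
    planarity check at every step and no shortcuts."""
    n = len(network.nodes)
    edges = network.edges.copy()
    edges["absrho"] = edges["rho"].abs()
    edges = edges.sort_values(by=["absrho", "i", "j"],
                              ascending=[False, True, True], kind="mergesort")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    kept = []
    for row in edges.itertuples(index=False):
        if len(kept) >= 3 * (n - 2):
            break
        g.add_edge(int(row.i), int(row.j))
        if nx.check_planarity(g, counterexample=False)[0]:
            kept.append((int(row.i), int(row.j)))
        else:
            g.remove_edge(int(row.i), int(row.j))
    return kept


class TestPMFG:
    def test_k4_keeps_all_six_edges(self):
        pmfg = build_pmfg(_complete_network(4))
        assert len(pmfg.edges) == 6

    def test_k5_keeps_exactly_nine_planar_edges(self):
        pmfg = build_pmfg(_complete_network(5))
        assert len(pmfg.edges) == 9
        assert nx.check_planarity(pmfg.to_networkx())[0]

    def test_triangle(self):
        pmfg = build_pmfg(_complete_network(3))
        assert len(pmfg.edges) == 3

    @pytest.mark.parametrize("n,seed", [(8, 1), (12, 2), (20, 3)])
    def test_matches_naive_greedy_oracle(self, n, seed):
        net = _complete_network(n, seed)
        pmfg = build_pmfg(net)
        naive = _naive_pmfg_edges(net)
        assert [(int(r.i), int(r.j)) for r in
                pmfg.edges.itertuples(index=False)] == naive

    def test_planar_and_bounded_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            n = int(rng.integers(4, 51))
            pmfg = build_pmfg(_complete_network(n, seed=100 + trial))
            g = pmfg.to_networkx()
            assert nx.check_planarity(g)[0]
            assert len(pmfg.edges) == 3 * (n - 2)  # complete candidate set

    def test_invariant_to_candidate_row_order(self):
        net = _complete_network(10, seed=5)
        shuffled = CorrelationNetwork(
            nodes=net.nodes,
            edges=net.edges.sample(frac=1, random_state=0).reset_index(drop=True),
        )
        a = build_pmfg(net).edges
        b = build_pmfg(shuffled).edges
        assert a[["i", "j"]].values.tolist() == b[["i", "j"]].values.tolist()


def _two_cliques_network(size=15, seed=0):
    rng = np.random.default_rng(seed)
    pairs, rows = [], []
    for offset in (0, size):
        for i, j in itertools.combinations(range(offset, offset + size), 2):
            rows.append((i, j, 0.9 + 0.05 * rng.random()))
    edges = pd.DataFrame(rows, columns=["i", "j", "rho"])
    edges["p"] = 0.001
    edges["q"] = 0.001
    return CorrelationNetwork(nodes=[f"g{i}" for i in range(2 * size)],
                              edges=edges)


class TestMultiscale:
    def test_disconnected_cliques_form_two_modules(self):
        pmfg = build_pmfg(_two_cliques_network())
        tree = multiscale_cluster(pmfg, min_size=10, seed=0)
        leaves = tree.leaves()
        assert len(leaves) == 2
        got = {frozenset(l.members) for l in leaves}
        assert got == {frozenset(range(15)), frozenset(range(15, 30))}

    def test_leaves_partition_nodes(self, module_network_config):
        from trilayer.synthetic import simulate_study

        study = simulate_study(module_network_config(seed=77))
        net = permutation_edge_filter(study.expression, B=100, seed=78)
        pmfg = build_pmfg(net)
        tree = multiscale_cluster(pmfg, seed=79)
        seen = sorted(m for leaf in tree.leaves() for m in leaf.members)
        assert seen == list(range(len(pmfg.nodes)))

    def test_planted_four_modules_recovered(self, module_network_config):
        from trilayer.synthetic import simulate_study

        study = simulate_study(module_network_config(seed=80))
        net = permutation_edge_filter(study.expression, B=100, seed=81)
        pmfg = build_pmfg(net)
        tree = multiscale_cluster(pmfg, seed=82)
        truth_of = {g: name for name, info in study.truth.modules.items()
                    for g in info["genes"]}
        pred, truth = [], []
        for leaf in tree.leaves():
            for gi in leaf.members:
                pred.append(leaf.module_id)
                truth.append(truth_of[pmfg.nodes[gi]])
        assert adjusted_rand_score(truth, pred) >= 0.8

    def test_empty_graph_rejected(self):
        from trilayer.network import PMFG

        empty = PMFG(nodes=[], edges=pd.DataFrame(columns=["i", "j",
                                                           "weight", "rho"]))
        with pytest.raises(ValueError, match="empty"):
            multiscale_cluster(empty)


class TestPrincipalComponents:
    def test_rank_one_matrix_has_full_pc1(self):
        u = np.arange(1, 9, dtype=float)
        v = np.array([1.0, -2.0, 0.5])
        scores, var_frac = principal_components(np.outer(u, v), k=1)
        assert var_frac[0] == pytest.approx(1.0)

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        _, var_frac = principal_components(X, k=3)
        Z = (X - X.mean(0)) / X.std(0)
        eig = np.sort(np.linalg.eigvalsh(Z.T @ Z))[::-1]
        assert np.allclose(var_frac, eig / eig.sum())

    def test_pc1_sign_convention(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(20, 6))
            X += np.linspace(0, 3, 20)[:, None]  # shared mean trend
            scores, _ = principal_components(X, k=1)
            r = np.corrcoef(scores[:, 0], X.mean(axis=1))[0, 1]
            assert r >= 0
        del rng

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            principal_components(np.ones((5, 3)), k=1)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k"):
            principal_components(np.eye(3), k=4)


class TestModuleTrait:
    @staticmethod
    def _study_and_modules(seed, module_network_config):
        from trilayer.synthetic import simulate_study

        study = simulate_study(module_network_config(seed=seed))
        net = permutation_edge_filter(study.expression, B=100, seed=seed + 1)
        pmfg = build_pmfg(net)
        tree = multiscale_cluster(pmfg, seed=seed + 2)
        return study, pmfg, tree

    def test_trait_coupled_modules_flagged(self, module_network_config):
        study, pmfg, tree = self._study_and_modules(90, module_network_config)
        traits = {"PPMS": study.phenotypes.indicator("PPMS")}
        results = module_trait_association(tree, study.expression, traits,
                                           node_gene_ids=pmfg.nodes)
        flagged = {r.module_id for r in results if r.significant}
        coupled_genes = [set(info["genes"])
                         for info in study.truth.modules.values()
                         if info["trait"] is not None]
        hits = 0
        for gset in coupled_genes:
            for leaf in tree.leaves():
                members = {pmfg.nodes[g] for g in leaf.members}
                if (len(gset & members) / max(len(members), 1) > 0.5
                        and leaf.module_id in flagged):
                    hits += 1
                    break
        assert hits == len(coupled_genes)

    def test_trait_flip_negates_correlation_keeps_q(self, module_network_config):
        study, pmfg, tree = self._study_and_modules(91, module_network_config)
        ind = study.phenotypes.indicator("PPMS")
        res_a = module_trait_association(tree, study.expression,
                                         {"t": ind}, node_gene_ids=pmfg.nodes)
        res_b = module_trait_association(tree, study.expression,
                                         {"t": 1 - ind}, node_gene_ids=pmfg.nodes)
        for a, b in zip(res_a, res_b):
            assert b.correlation == pytest.approx(-a.correlation)
            assert b.q == pytest.approx(a.q)

    def test_uncoupled_module_correlation_small(self):
        rng = np.random.default_rng(8)
        expr = _expr(rng.normal(size=(20, 100)))
        from trilayer.network import ModuleNode, ModuleTree

        tree = ModuleTree(
            nodes={"M1": ModuleNode("M1", list(range(20)), None)},
            root_ids=["M1"],
        )
        hits = 0
        n_rep = 200  # theoretical pass rate ~95%; 200 draws stabilises it
        for seed in range(n_rep):
            trait = np.random.default_rng(seed).integers(0, 2, 100).astype(float)
            res = module_trait_association(tree, expr, {"t": trait})
            hits += abs(res[0].correlation) < 0.2
        assert hits >= 0.9 * n_rep


class TestFisherOverlap:
    def test_full_overlap_reference_p(self):
        universe = range(20)
        res = fisher_overlap(range(5), range(5), universe)
        assert res.p == pytest.approx(1 / comb(20, 5), rel=1e-6)
        assert res.overlap == 5

    def test_independent_expectation_gives_or_near_one(self):
        # overlap exactly |A||B|/N
        universe = range(100)
        a = set(range(50))
        b = set(range(25, 75))  # |A&B| = 25 = 50*50/100
        res = fisher_overlap(a, b, universe)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 31))
            ka = int(rng.integers(1, n + 1))
            kb = int(rng.integers(1, n + 1))
            a = set(rng.choice(n, ka, replace=False).tolist())
            b = set(rng.choice(n, kb, replace=False).tolist())
            res = fisher_overlap(a, b, range(n))
            # oracle: sum hypergeometric point probabilities <= observed
            k_obs = len(a & b)
            lo = max(0, ka + kb - n)
            hi = min(ka, kb)
            pmf = {k: stats.hypergeom.pmf(k, n, ka, kb)
                   for k in range(lo, hi + 1)}
            expected = sum(p for p in pmf.values()
                           if p <= pmf[k_obs] * (1 + 1e-9))
            assert res.p == pytest.approx(expected, rel=1e-6)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap(set(), set(), set())

    def test_zero_cell_uses_haldane(self):
        res = fisher_overlap(set(range(5)), set(range(5)), range(10))
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)
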