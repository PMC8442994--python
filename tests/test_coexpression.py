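"""Correlation sets, pseudoset, clustering cross-check and their oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikemads import (
    SetRuleParams,
    assign_sets,
    compare_groupings,
    detect_pseudoset,
    hierarchical_cluster,
    pearson_matrix,
)
from spikemads.coexpression import heatmap_table
from spikemads.qpcr import ExpressionMatrix
from spikemads.stages import DEFAULT_GRID


def expr_from(profiles, conditions=None, grid=None):
    mean = pd.DataFrame(profiles).T.astype(float)
    if conditions is not None:
        mean.columns = conditions
    sd = pd.DataFrame(0.0, index=mean.index, columns=mean.columns)
    return ExpressionMatrix(mean, sd, "stage", grid)


def corr_from(matrix, genes):
    return pd.DataFrame(np.asarray(matrix, dtype=float), index=genes,
                        columns=genes)


class TestPearson:
    def test_self_correlation_is_one(self):
        expr = expr_from({"a": [1, 2, 3], "b": [4, 1, 7]})
        corr = pearson_matrix(expr)
        assert corr.at["a", "a"] == 1.0

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = expr_from({"x": x, "y": -x + 10})
        corr = pearson_matrix(expr)
        assert corr.at["x", "y"] == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        expr = expr_from({"x": x, "y": y})
        r = pearson_matrix(expr).at["x", "y"]
        expected = np.sum((x - x.mean()) * (y - y.mean())) / (
            len(x) * x.std() * y.std()
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_has_missing_r(self):
        expr = expr_from({"a": [1, 2, 3], "flat": [2, 2, 2]})
        corr = pearson_matrix(expr)
        assert np.isnan(corr.at["a", "flat"])
        assert not np.isnan(corr.at["flat", "flat"])
        # a missing r never qualifies as an edge
        params = SetRuleParams()
        assignment = assign_sets(corr, params, expr)
        assert assignment.members.get("set_1") is None

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(expr_from({"a": [1, 2], "b": [2, 1]}))


def mcore_oracle(adj, m):
    """Max subset with induced degree >= m, by exhaustive subset enumeration."""
    nodes = list(adj.nodes)
    best = set()
    for k in range(len(nodes), 0, -1):
        for sub in itertools.combinations(nodes, k):
            s = set(sub)
            if all(sum(1 for v in adj[u] if v in s) >= m for u in s):
                return s
    return best


class TestAssignSets:
    def params(self, **kw):
        return SetRuleParams(**kw)

    def test_mutual_triple_forms_one_set(self):
        genes = ["a", "b", "c", "d"]
        r = np.full((4, 4), 0.2)
        np.fill_diagonal(r, 1.0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            r[i, j] = r[j, i] = 0.95
        expr = expr_from({g: np.random.default_rng(i).uniform(0, 1, 5)
                          for i, g in enumerate(genes)})
        out = assign_sets(corr_from(r, genes), self.params(), expr)
        assert out.members["set_1"] == ["a", "b", "c"]
        assert out.label_of["d"] in ("ungrouped",)

    def test_chain_collapses_in_two_core(self):
        # a-b and b-c edges only: b has 2 partners but a and c do not;
        # iterated deletion removes everyone
        genes = ["a", "b", "c"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.95
        r[1, 2] = r[2, 1] = 0.95
        r[0, 2] = r[2, 0] = 0.5
        expr = expr_from({g: [1, 2, 3, 1, 5] for g in genes})
        out = assign_sets(corr_from(r, genes), self.params(), expr)
        assert out.n_sets == 0
        assert set(out.label_of.values()) <= {"pseudoset", "ungrouped"}

    def test_threshold_is_strict(self):
        genes = ["a", "b", "c"]
        r = np.full((3, 3), 0.9)  # exactly tau, not over it
        np.fill_diagonal(r, 1.0)
        expr = expr_from({g: [1, 2, 3] for g in genes})
        out = assign_sets(corr_from(r, genes), self.params(tau2=0.5), expr)
        assert out.n_sets == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mcore_matches_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        genes = [f"g{i}" for i in range(n)]
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r[i, j] = r[j, i] = rng.uniform(0.5, 1.0)
        corr = corr_from(r, genes)
        params = self.params(tau2=0.75)
        expr = expr_from({g: rng.uniform(0, 1, 5) for g in genes})
        out = assign_sets(corr, params, expr)
        got_core = {g for g, lab in out.label_of.items()
                    if lab.startswith("set_")}
        g = nx.Graph()
        g.add_nodes_from(genes)
        for i in range(n):
            for j in range(i + 1, n):
                if r[i, j] > params.tau:
                    g.add_edge(genes[i], genes[j])
        oracle = mcore_oracle(g, params.m)
        # components >= min_set_size of the oracle core
        expected = set()
        for comp in nx.connected_components(g.subgraph(oracle)):
            if len(comp) >= params.min_set_size:
                expected |= comp
        assert got_core == expected

    def test_mcore_independent_of_input_order(self):
        rng = np.random.default_rng(5)
        n = 12
        genes = [f"g{i}" for i in range(n)]
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r[i, j] = r[j, i] = rng.uniform(0.6, 1.0)
        profiles = {g: rng.uniform(0, 1, 6) for g in genes}
        base = assign_sets(corr_from(r, genes), self.params(), expr_from(profiles))
        for perm_seed in range(5):
            order = list(rng.permutation(genes))
            corr = corr_from(r, genes).loc[order, order]
            expr = expr_from({g: profiles[g] for g in order})
            out = assign_sets(corr, self.params(), expr)
            assert {g: base.label_of[g] for g in genes} == \
                {g: out.label_of[g] for g in genes}

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        n = 15
        genes = [f"g{i}" for i in range(n)]
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r[i, j] = r[j, i] = rng.uniform(-0.5, 1.0)
        out = assign_sets(corr_from(r, genes), self.params(),
                          expr_from({g: rng.uniform(0, 1, 6) for g in genes}))
        assert sorted(out.label_of) == sorted(genes)
        all_members = [g for mem in out.members.values() for g in mem]
        assert len(all_members) == len(set(all_members))

    def test_every_member_has_m_partners_within_set(self):
        rng = np.random.default_rng(3)
        n = 14
        genes = [f"g{i}" for i in range(n)]
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r[i, j] = r[j, i] = rng.uniform(0.7, 1.0)
        params = self.params()
        corr = corr_from(r, genes)
        out = assign_sets(corr, params,
                          expr_from({g: rng.uniform(0, 1, 6) for g in genes}))
        for name, members in out.members.items():
            if not name.startswith("set_"):
                continue
            for gene in members:
                partners = sum(
                    1 for other in members
                    if other != gene and corr.at[gene, other] > params.tau
                )
                assert partners >= params.m


class TestPseudoset:
    def test_no_pairs_above_tau2_all_ungrouped(self):
        genes = ["a", "b", "c"]
        r = np.full((3, 3), 0.3)
        np.fill_diagonal(r, 1.0)
        pseudo, ungrouped = detect_pseudoset(corr_from(r, genes), genes,
                                             SetRuleParams())
        assert pseudo == []
        assert sorted(ungrouped) == genes

    def test_moderate_block_becomes_pseudoset(self):
        genes = list("abcde")
        r = np.full((5, 5), 0.8)
        np.fill_diagonal(r, 1.0)
        pseudo, ungrouped = detect_pseudoset(corr_from(r, genes), genes,
                                             SetRuleParams())
        assert sorted(pseudo) == genes
        assert ungrouped == []

    def test_largest_component_wins(self):
        genes = list("abcdefg")
        r = np.full((7, 7), 0.1)
        np.fill_diagonal(r, 1.0)
        for i, j in [(0, 1), (1, 2), (0, 2)]:           # 3-component
            r[i, j] = r[j, i] = 0.8
        for i, j in itertools.combinations(range(3, 7), 2):  # 4-component
            r[i, j] = r[j, i] = 0.8
        pseudo, ungrouped = detect_pseudoset(corr_from(r, genes), genes,
                                             SetRuleParams())
        assert sorted(pseudo) == ["d", "e", "f", "g"]
        assert sorted(ungrouped) == ["a", "b", "c"]


def naive_complete_linkage(x, k):
    """O(n^3) agglomeration; ties broken by smallest pair indices."""
    clusters = [[i] for i in range(len(x))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(np.linalg.norm(x[i] - x[j])
                        for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(x), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


class TestHierarchical:
    def test_identical_genes_merge_first(self):
        expr = expr_from({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4],
                          "c": [9, 1, 2, 2], "d": [3, 8, 1, 0]})
        labels = hierarchical_cluster(expr, 3)
        assert labels["a"] == labels["b"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        profiles = {f"g{i}": rng.uniform(0.0, 5.0, 6) for i in range(n)}
        expr = expr_from(profiles)
        k = int(rng.integers(2, n))
        got = hierarchical_cluster(expr, k)
        x = expr.mean.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        expected = naive_complete_linkage(z, k)
        assert compare_groupings(
            got, {f"g{i}": int(expected[i]) for i in range(n)}
        ) == pytest.approx(1.0)

    def test_zero_variance_gene_excluded_with_warning(self, caplog):
        expr = expr_from({"a": [1, 2, 3], "b": [3, 1, 2], "flat": [1, 1, 1]})
        with caplog.at_level("WARNING"):
            labels = hierarchical_cluster(expr, 2)
        assert "flat" not in labels
        assert any("flat" in rec.message for rec in caplog.records)


class TestCompareGroupings:
    def test_identical_partitions_score_one(self):
        a = {"a": 1, "b": 1, "c": 2}
        assert compare_groupings(a, dict(a)) == 1.0

    def test_degenerate_partitions_score_zero(self):
        genes = [f"g{i}" for i in range(10)]
        singletons = {g: i for i, g in enumerate(genes)}
        lump = {g: 0 for g in genes}
        assert compare_groupings(singletons, lump) == pytest.approx(0.0)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_groupings({"a": 1}, {"b": 1})

    def test_random_permutations_center_on_zero(self):
        # closed-form contingency ARI, recomputed by hand, vs implementation;
        # over many label permutations the mean ARI is ~0
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        base = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3]

        def ari_contingency(la, lb):
            from math import comb
            cats_a, cats_b = sorted(set(la)), sorted(set(lb))
            nij = np.zeros((len(cats_a), len(cats_b)), dtype=int)
            for x, y in zip(la, lb):
                nij[cats_a.index(x), cats_b.index(y)] += 1
            a = nij.sum(1); b = nij.sum(0); n = nij.sum()
            sij = sum(comb(int(v), 2) for v in nij.ravel())
            sa = sum(comb(int(v), 2) for v in a)
            sb = sum(comb(int(v), 2) for v in b)
            exp = sa * sb / comb(n, 2)
            return (sij - exp) / ((sa + sb) / 2 - exp)

        vals = []
        for _ in range(10_000):
            perm = list(rng.permutation(base))
            got = compare_groupings(dict(zip(genes, base)),
                                    dict(zip(genes, perm)))
            assert got == pytest.approx(
                ari_contingency(base, perm), abs=1e-12)
            vals.append(got)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3


class TestHeatmapTable:
    def test_log_scale_and_cap(self):
        expr = expr_from({"a": [1.0, 10.0, 100.0, 1000.0]})
        table = heatmap_table(expr, eps=0.0, cap_quantile=0.5)
        assert table.to_numpy().max() <= np.log10(1000.0)
        assert table.iloc[0, 0] == pytest.approx(0.0)
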