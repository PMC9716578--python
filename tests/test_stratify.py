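"""Correlation network, weighted-KS enrichment, permutation NES/p, BH
adjustment and Welch specificity tests, each against an independent oracle."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from fusiontarget.cohorts import GeneSet
from fusiontarget.errors import ValidationError
from fusiontarget.stratify import (
    bh_adjust,
    build_network,
    component_stats,
    correlation_matrix,
    enrichment_score,
    nes_permutation,
    rank_sample,
    read_graphml,
    specificity_heatmap,
    stratify_cohort,
    welch_t,
    write_graphml,
)
from fusiontarget.synthgen import EWS_LABEL

from conftest import make_expr


# ---------------------------------------------------------------------------
# correlation


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / (sd_x * sd_y) on raw sums."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    cov = (x * y).sum() - sx * sy / n
    vx = (x * x).sum() - sx * sx / n
    vy = (y * y).sum() - sy * sy / n
    return cov / math.sqrt(vx * vy)


class TestCorrelationMatrix:
    def test_duplicated_sample_has_r_one(self):
        vals = np.array([[1.0, 1.0, 4.0], [2.0, 2.0, 0.5], [8.0, 8.0, 1.0]])
        cm = correlation_matrix(make_expr(vals), GeneSet.from_iterable(["g0", "g1", "g2"]))
        assert cm.r.loc["s0", "s1"] == pytest.approx(1.0)

    def test_log_space_negation_gives_minus_one(self):
        v1 = np.array([1.0, 2.0, 3.0, 4.0])
        v2 = 2 * v1.mean() - v1  # negation around the mean, in log2(FPKM+1) space
        fpkm = np.power(2.0, np.column_stack([v1, v2])) - 1.0
        cm = correlation_matrix(
            make_expr(fpkm), GeneSet.from_iterable([f"g{i}" for i in range(4)])
        )
        assert cm.r.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_matches_closed_form_oracle_within_1e10(self):
        rng = np.random.default_rng(20)
        fpkm = rng.uniform(0, 50, size=(5, 4))
        genes = [f"g{i}" for i in range(5)]
        cm = correlation_matrix(make_expr(fpkm), GeneSet.from_iterable(genes))
        logv = np.log2(fpkm + 1.0)
        for i in range(4):
            for j in range(4):
                expected = pearson_oracle(logv[:, i], logv[:, j])
                assert abs(cm.r.iloc[i, j] - expected) < 1e-10

    def test_constant_sample_flagged_and_zeroed(self):
        vals = np.array([[1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        cm = correlation_matrix(make_expr(vals), GeneSet.from_iterable(["g0", "g1", "g2"]))
        assert cm.constant_samples == ("s1",)
        assert (cm.r.loc["s1"] == 0.0).all()
        assert cm.r.loc["s0", "s0"] == 1.0

    def test_too_few_genes_errors(self):
        expr = make_expr([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            correlation_matrix(expr, GeneSet.from_iterable(["g0"]))


class TestNetwork:
    def _cm(self, n=5, seed=21):
        rng = np.random.default_rng(seed)
        fpkm = rng.uniform(0, 30, size=(10, n))
        return correlation_matrix(
            make_expr(fpkm), GeneSet.from_iterable([f"g{i}" for i in range(10)])
        ), make_expr(fpkm)

    def test_impossible_threshold_gives_edgeless_graph(self):
        cm, expr = self._cm()
        g = build_network(cm, expr.labels, r_min=1.01)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_minus_one_threshold_gives_complete_graph(self):
        cm, expr = self._cm()
        g = build_network(cm, expr.labels, r_min=-1.0)
        assert g.number_of_edges() == 5 * 4 // 2

    def test_planted_ews_clique_with_no_cross_edges(self, dataset):
        met = dataset.cohorts["met"]
        sig = GeneSet.from_iterable(dataset.truth.planted_target_genes)
        cm = correlation_matrix(met, sig)
        g = build_network(cm, met.labels, r_min=0.5)
        stats = component_stats(g, EWS_LABEL)
        assert stats["n_target_nodes"] == 11
        assert stats["target_clique_fraction"] == 1.0
        assert stats["largest_target_component"] == 11
        assert stats["cross_label_edges"] == 0

    def test_graphml_round_trip_exact(self, tmp_path):
        cm, expr = self._cm()
        g = build_network(cm, expr.labels, r_min=-1.0)
        write_graphml(g, tmp_path / "n.graphml")
        back = read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        for n in g.nodes:
            assert back.nodes[n]["type_label"] == g.nodes[n]["type_label"]
        for u, v in g.edges:
            assert back.edges[u, v]["weight"] == g.edges[u, v]["weight"]


class TestComponentStats:
    def test_edgeless_graph(self):
        g = nx.Graph()
        for i in range(4):
            g.add_node(f"n{i}", type_label="T")
        stats = component_stats(g, "T")
        assert stats["largest_target_component"] == 1
        assert stats["cross_label_edges"] == 0

    def test_complete_graph_on_targets(self):
        g = nx.complete_graph(11)
        nx.set_node_attributes(g, "T", "type_label")
        assert component_stats(g, "T")["largest_target_component"] == 11

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            n = 12
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            labels = {i: ("T" if rng.random() < 0.5 else "O") for i in g.nodes}
            nx.set_node_attributes(g, labels, "type_label")
            # union-find oracle
            parent = list(range(n))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for u, v in g.edges:
                parent[find(u)] = find(v)
            comp_targets: dict[int, int] = {}
            for i in g.nodes:
                if labels[i] == "T":
                    root = find(i)
                    comp_targets[root] = comp_targets.get(root, 0) + 1
            expected = max(comp_targets.values(), default=1 if "T" in labels.values() else 0)
            assert component_stats(g, "T")["largest_target_component"] == expected


# ---------------------------------------------------------------------------
# ranking


class TestRankSample:
    def test_private_gene_ranks_first(self):
        vals = np.zeros((5, 4))
        vals[3, 0] = 50.0
        ranked = rank_sample(make_expr(vals), "s0")
        assert ranked.index[0] == "g3"

    def test_constant_gene_gets_zero(self):
        vals = np.vstack([np.full(4, 7.0), np.arange(4.0)])
        ranked = rank_sample(make_expr(vals), "s0")
        assert ranked.loc["g0"] == 0.0

    def test_matches_hand_computed_zscores(self):
        rng = np.random.default_rng(23)
        fpkm = rng.uniform(0, 20, size=(10, 5))
        expr = make_expr(fpkm)
        ranked = rank_sample(expr, "s2")
        logv = np.log2(fpkm + 1.0)
        z = (logv[:, 2] - logv.mean(axis=1)) / logv.std(axis=1, ddof=1)
        expected = sorted(
            zip(z, [f"g{i}" for i in range(10)]), key=lambda t: (-t[0], t[1])
        )
        assert list(ranked.index) == [g for _, g in expected]
        assert np.allclose(ranked.to_numpy(), [v for v, _ in expected])

    def test_ties_break_lexicographically(self):
        vals = np.tile(np.array([[3.0, 1.0, 2.0]]), (4, 1))
        ranked = rank_sample(make_expr(vals), "s0")
        assert list(ranked.index) == ["g0", "g1", "g2", "g3"]

    def test_unknown_sample_errors(self):
        with pytest.raises(ValidationError):
            rank_sample(make_expr(np.ones((2, 3))), "zzz")


# ---------------------------------------------------------------------------
# enrichment score


def running_sum_oracle(metric, hit, p=1.0):
    """Exhaustive position-by-position running sum, straight from the
    weighted-KS definition."""
    n = len(metric)
    n_set = sum(hit)
    denom = sum(abs(m) ** p for m, h in zip(metric, hit) if h)
    total, out = 0.0, []
    for m, h in zip(metric, hit):
        if h:
            total += abs(m) ** p / denom
        else:
            total -= 1.0 / (n - n_set)
        out.append(total)
    return out


class TestEnrichmentScore:
    def test_top_block_gives_es_one(self):
        metric = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(10)])
        es, _ = enrichment_score(ranked, ["g0", "g1", "g2"])
        assert es == pytest.approx(1.0)

    def test_bottom_block_gives_negative_es(self):
        metric = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(10)])
        es, _ = enrichment_score(ranked, ["g7", "g8", "g9"])
        assert es < 0

    def test_matches_exhaustive_running_sum_oracle(self):
        """N=10 list, set at ranks {1,4,7}: compare every position."""
        metric = [5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.25, 0.1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(10)])
        members = ["g0", "g3", "g6"]
        hit = [g in members for g in ranked.index]
        expected_run = running_sum_oracle(metric, hit)
        es, run = enrichment_score(ranked, members)
        assert np.allclose(run, expected_run)
        peak = max(expected_run, key=abs)
        assert es == pytest.approx(peak)

    def test_empty_intersection_errors(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValidationError):
            enrichment_score(ranked, ["zzz"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st_h.integers(0, 2**31 - 1))
    def test_es_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        metric = np.sort(rng.normal(size=n))[::-1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(n)])
        k = int(rng.integers(1, n))
        members = list(rng.choice(ranked.index, size=k, replace=False))
        es, _ = enrichment_score(ranked, members)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# permutation NES


class TestNesPermutation:
    def _ranked(self, seed=24, n=200):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(metric, index=[f"g{i}" for i in range(n)])

    def test_same_seed_reproducible(self):
        ranked = self._ranked()
        a = nes_permutation(ranked, [f"g{i}" for i in range(10)], n_perm=200, seed=5)
        b = nes_permutation(ranked, [f"g{i}" for i in range(10)], n_perm=200, seed=5)
        assert (a.es, a.nes, a.p_perm) == (b.es, b.nes, b.p_perm)

    def test_nes_sign_follows_es(self):
        ranked = self._ranked()
        top = nes_permutation(ranked, [f"g{i}" for i in range(10)], n_perm=200, seed=1)
        bottom = nes_permutation(
            ranked, [f"g{i}" for i in range(190, 200)], n_perm=200, seed=1
        )
        assert top.es > 0 and top.nes > 0
        assert bottom.es < 0 and bottom.nes < 0

    def test_p_floor_respected(self):
        ranked = self._ranked()
        res = nes_permutation(ranked, [f"g{i}" for i in range(15)], n_perm=300, seed=2)
        assert res.p_perm >= 1.0 / 301

    def test_all_zero_metric_rejected(self):
        ranked = pd.Series(np.zeros(50), index=[f"g{i}" for i in range(50)])
        with pytest.raises(ValidationError):
            nes_permutation(ranked, ["g0", "g1"], n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValidationError):
            nes_permutation(self._ranked(), ["g0"], n_perm=50, seed=0)

    def test_nes_monotone_in_es_at_fixed_null(self):
        """Stronger leading-edge sets get larger NES against the same null."""
        ranked = self._ranked()
        sizes_nes = []
        for top_k in (40, 20, 10):
            res = nes_permutation(ranked, [f"g{i}" for i in range(top_k)], n_perm=500, seed=3)
            sizes_nes.append(res.es)
        assert sizes_nes == sorted(sizes_nes)


def test_bh_adjust_hand_cases():
    assert bh_adjust([0.02]) == pytest.approx([0.02])
    # classic 4-element staircase: all q collapse to 0.04
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
    # hand computation with distinct q: p*(m/rank) then running min from the top
    got = bh_adjust([0.001, 0.02, 0.9])
    assert got == pytest.approx([0.003, 0.03, 0.9])


def test_bh_adjust_rejects_out_of_range():
    for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
        with pytest.raises(ValidationError):
            bh_adjust(bad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st_h.lists(st_h.floats(1e-6, 1.0), min_size=1, max_size=30))
def test_bh_adjust_dominates_p_and_stays_in_unit_interval(pvals):
    q = bh_adjust(pvals)
    assert (q >= np.asarray(pvals) - 1e-15).all()
    assert (q <= 1.0 + 1e-15).all()


# ---------------------------------------------------------------------------
# cohort stratification


class TestStratifyCohort:
    def test_recovers_planted_ews_and_is_deterministic(self, dataset):
        met = dataset.cohorts["met"]
        sig = GeneSet.from_iterable(dataset.truth.planted_target_genes)
        calls = stratify_cohort(met, sig, n_perm=300, seed=40)
        ews = calls[calls["type_label"] == EWS_LABEL]
        non = calls[calls["type_label"] != EWS_LABEL]
        assert ews["call"].all()
        assert (1.0 - non["call"].mean()) >= 0.95
        again = stratify_cohort(met, sig, n_perm=300, seed=40)
        pd.testing.assert_frame_equal(calls, again)

    def test_q_dominates_p(self, dataset):
        met = dataset.cohorts["met"]
        sig = GeneSet.from_iterable(dataset.truth.planted_target_genes)
        calls = stratify_cohort(met, sig, n_perm=200, seed=41)
        assert (calls["q"] >= calls["p_perm"] - 1e-15).all()

    def test_absent_signature_errors(self, dataset):
        met = dataset.cohorts["met"]
        with pytest.raises(ValidationError):
            stratify_cohort(met, GeneSet.from_iterable(["nope1", "nope2"]), n_perm=100)

    def test_small_cohort_rejected(self):
        expr = make_expr(np.ones((5, 4)))
        with pytest.raises(ValidationError):
            stratify_cohort(expr, GeneSet.from_iterable(["g0", "g1"]), n_perm=100)


# ---------------------------------------------------------------------------
# specificity heatmap


def welch_oracle(a, b):
    """Closed-form Welch statistic and Welch-Satterthwaite df -> p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


class TestSpecificityHeatmap:
    def test_welch_matches_closed_form(self):
        a = [2.0, 3.5, 4.1]
        b = [1.0, 0.5, 2.2]
        t, p = welch_t(np.array(a), np.array(b))
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0)
        assert p == pytest.approx(p0)

    def test_identical_groups_give_zero_cell(self):
        vals = np.array([[2.0, 2.0, 2.0, 2.0]])
        expr = make_expr(vals, types=["T", "T", "O", "O"])
        res = specificity_heatmap(expr, "T", GeneSet.from_iterable(["g0"]))
        assert res.t.loc["g0", "O"] == 0.0
        assert res.p.loc["g0", "O"] == 1.0
        assert res.neglog10p.loc["g0", "O"] == 0.0

    def test_small_group_flagged_missing(self):
        vals = np.random.default_rng(0).uniform(1, 5, size=(2, 5))
        expr = make_expr(vals, types=["T", "T", "O", "O", "Solo"])
        res = specificity_heatmap(expr, "T", GeneSet.from_iterable(["g0", "g1"]))
        assert res.p["Solo"].isna().all()
        assert res.p["O"].notna().all()

    def test_planted_gene_strongly_specific(self, dataset):
        met = dataset.cohorts["met"]
        sig = GeneSet.from_iterable(dataset.truth.planted_target_genes[:5])
        res = specificity_heatmap(met, EWS_LABEL, sig)
        assert (res.neglog10p > 2.0).all().all()  # p < 0.01 everywhere
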