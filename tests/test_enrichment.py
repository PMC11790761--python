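import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteodpe import enrichment as enr
from proteodpe.containers import GeneSetCollection


def brute_force_es(stats_ranked, hit_set_positions, weight_exp=1.0):
    """Independent running-sum oracle: walk the list step by step."""
    N = len(stats_ranked)
    hits = set(hit_set_positions)
    w = {i: abs(stats_ranked[i]) ** weight_exp for i in hits}
    total = sum(w.values()) or float(len(hits))
    running, best = 0.0, 0.0
    for i in range(N):
        if i in hits:
            running += (w[i] if sum(w.values()) else 1.0) / total
        else:
            running -= 1.0 / (N - len(hits))
        if abs(running) > abs(best):
            best = running
    return best


def _ranked(stats, genes=None):
    genes = genes or [f"G{i}" for i in range(len(stats))]
    return pd.DataFrame({"gene_symbol": genes, "accession": genes,
                         "stat": np.asarray(stats, dtype=float)})


class TestRankStatistic:
    def _dpe(self, accs, symbols, t, logfc=None, p=None):
        return pd.DataFrame(
            {
                "accession": accs,
                "gene_symbol": symbols,
                "contrast": "c",
                "logFC": logfc if logfc is not None else t,
                "t": t,
                "p_value": p if p is not None else [0.05] * len(accs),
                "adj_p_value": 0.1,
            }
        )

    def test_descending_signed_order(self):
        dpe = self._dpe(["P1", "P2"], ["A", "B"], [3.0, -3.0])
        ranked = enr.rank_statistic(dpe)
        assert list(ranked["gene_symbol"]) == ["A", "B"]

    def test_tie_broken_by_accession_stably(self):
        dpe = self._dpe(["P9", "P1", "P5"], ["A", "B", "C"], [1.0, 1.0, 1.0])
        r1 = enr.rank_statistic(dpe)
        r2 = enr.rank_statistic(dpe.sample(frac=1, random_state=0))
        assert list(r1["accession"]) == ["P1", "P5", "P9"]
        assert list(r1["accession"]) == list(r2["accession"])

    def test_duplicate_symbols_collapse_to_max_abs(self):
        dpe = self._dpe(["P1", "P2", "P3"], ["A", "A", "B"], [1.0, -4.0, 2.0])
        ranked = enr.rank_statistic(dpe)
        assert len(ranked) == 2
        assert ranked.set_index("gene_symbol").loc["A", "stat"] == -4.0

    def test_mode_switch_reorders_only_where_orders_differ(self):
        # same sign ordering, different p ordering for two mid-list genes
        dpe = self._dpe(
            ["P1", "P2", "P3"], ["A", "B", "C"], [3.0, 2.0, 1.0],
            p=[0.001, 0.5, 0.01],
        )
        by_t = list(enr.rank_statistic(dpe, mode="t_stat")["gene_symbol"])
        by_p = list(enr.rank_statistic(dpe, mode="signed_logp")["gene_symbol"])
        assert by_t == ["A", "B", "C"]
        assert by_p == ["A", "C", "B"]


class TestEnrichmentScore:
    def test_top_gene_singleton_set_scores_one(self):
        """Five ranked genes, set = {top gene}, weight 1: the running sum
        peaks at 1 right after position 1."""
        es, _ = enr.enrichment_score(
            np.array([3.0, 2.0, 1.0, -1.0, -2.0]), np.array([0])
        )
        assert es == pytest.approx(1.0)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        stats = np.sort(rng.normal(size=30))[::-1]
        for _ in range(25):
            k = rng.integers(2, 10)
            pos = rng.choice(30, size=k, replace=False)
            es, _ = enr.enrichment_score(stats, pos)
            assert es == pytest.approx(brute_force_es(stats, pos), abs=1e-12)

    def test_reversing_ranked_list_negates_es(self):
        rng = np.random.default_rng(1)
        stats = np.sort(rng.normal(size=20))[::-1]
        pos = np.array([1, 4, 9])
        es_fwd, _ = enr.enrichment_score(stats, pos)
        es_rev, _ = enr.enrichment_score(stats[::-1], 19 - pos)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_es_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 40))
        stats = np.sort(rng.normal(size=N))[::-1]
        k = int(rng.integers(1, N))
        pos = rng.choice(N, size=k, replace=False)
        es, _ = enr.enrichment_score(stats, pos)
        assert abs(es) <= 1.0 + 1e-12


class TestGseaPreranked:
    def test_permutation_p_agrees_with_exhaustive_enumeration(self):
        """8-gene universe, 3-gene set: all C(8,3)=56 memberships are
        enumerable. The permutation p and the null ES distribution must
        match enumeration within total variation 0.02."""
        rng = np.random.default_rng(2)
        stats = np.sort(rng.normal(size=8))[::-1]
        ranked = _ranked(stats)
        target = ["G0", "G2", "G5"]
        sets = GeneSetCollection({"T": target})
        res = enr.gsea_preranked(ranked, sets, n_perm=60000, seed=0,
                                 min_size=2, max_size=8)
        es_obs = res["ES"].iloc[0]
        # exact null over all memberships (independent brute-force ES)
        null = [
            brute_force_es(stats, combo)
            for combo in itertools.combinations(range(8), 3)
        ]
        p_exact = (1 + sum(abs(e) >= abs(es_obs) - 1e-12 for e in null)) / (
            1 + len(null)
        )
        assert res["p_value"].iloc[0] == pytest.approx(p_exact, abs=0.02)
        # total variation between the enumerated null and the permuted null
        perms = enr._perm_es(stats, 3, 60000, np.random.default_rng(1), 1.0)
        vals = sorted(set(round(v, 9) for v in null))
        tv = 0.5 * sum(
            abs(
                np.mean(np.isclose(null, v, atol=1e-9))
                - np.mean(np.isclose(perms, v, atol=1e-9))
            )
            for v in vals
        )
        assert tv < 0.02

    def test_null_pvalues_uniform(self):
        """Random sets against a null ranking: p-values pass a KS
        uniformity check at the 1% level over 200 sets."""
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        N = 300
        genes = [f"G{i}" for i in range(N)]
        ranked = _ranked(np.sort(rng.normal(size=N))[::-1], genes)
        sets = GeneSetCollection(
            {
                f"S{j}": list(rng.choice(genes, size=20, replace=False))
                for j in range(200)
            }
        )
        res = enr.gsea_preranked(ranked, sets, n_perm=2000, seed=4,
                                 min_size=5)
        ks = sps.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_min_attainable_p_has_add_one_correction(self, monkeypatch):
        monkeypatch.setattr(enr, "PERMUTATION_CAP", 500)
        rng = np.random.default_rng(5)
        N = 60
        stats = np.sort(rng.normal(size=N))[::-1]
        stats[:8] += 10.0  # extreme head so the top set is unbeatable
        ranked = _ranked(stats)
        sets = GeneSetCollection({"TOP": [f"G{i}" for i in range(8)]})
        res = enr.gsea_preranked(ranked, sets, n_perm=500, seed=0, min_size=3)
        assert res["p_value"].iloc[0] == pytest.approx(1.0 / 501.0)

    def test_whole_universe_set_skipped(self):
        ranked = _ranked([2.0, 1.0, -1.0])
        sets = GeneSetCollection({"ALL": ["G0", "G1", "G2"]})
        res = enr.gsea_preranked(ranked, sets, n_perm=200, min_size=1,
                                 max_size=500)
        assert res.empty

    def test_small_n_perm_rejected(self):
        ranked = _ranked([1.0, -1.0])
        with pytest.raises(ValueError, match="n_perm"):
            enr.gsea_preranked(ranked, GeneSetCollection({"S": ["G0"]}),
                               n_perm=50)

    def test_leading_edge_members_precede_extremum(self):
        rng = np.random.default_rng(6)
        N = 100
        stats = np.sort(rng.normal(size=N))[::-1]
        stats[:10] += 3.0
        ranked = _ranked(stats)
        members = [f"G{i}" for i in range(0, 30, 3)]
        res = enr.gsea_preranked(
            ranked, GeneSetCollection({"S": members}), n_perm=200, min_size=3
        )
        lead = res["leading_edge"].iloc[0].split(";")
        assert set(lead) <= set(members)
        assert res["ES"].iloc[0] > 0
        positions = [int(g[1:]) for g in lead]
        non_lead = set(members) - set(lead)
        assert all(int(g[1:]) > max(positions) for g in non_lead)


class TestLeadingEdgeFrequency:
    def _table(self, edges, adj):
        return pd.DataFrame(
            {
                "set_name": [f"S{i}" for i in range(len(edges))],
                "leading_edge": edges,
                "adj_p_value": adj,
            }
        )

    def test_counts_over_significant_sets_only(self):
        edges = ["A;B", "A;C", "A", "A;D", "B", "A;B"]
        adj = [0.01, 0.01, 0.01, 0.01, 0.5, 0.5]  # 4 significant
        freq = enr.leading_edge_frequency(self._table(edges, adj), alpha=0.05)
        assert freq["A"] == 4
        assert freq["B"] == 1

    def test_min_count_filters(self):
        edges = ["A;B", "A", "A"]
        freq = enr.leading_edge_frequency(
            self._table(edges, [0.01] * 3), alpha=0.05, min_count=2
        )
        assert list(freq.index) == ["A"]

    def test_alpha_zero_gives_empty(self):
        freq = enr.leading_edge_frequency(
            self._table(["A"], [0.001]), alpha=0.0
        )
        assert freq.empty


class TestOraHypergeometric:
    def test_exact_tail_on_ten_gene_toy(self):
        """Fully contained 4-gene set among 4 hits on a 10-gene background:
        the upper-tail probability is computed independently by enumerating
        the hypergeometric pmf with binomial coefficients."""
        background = [f"G{i}" for i in range(10)]
        gene_set = background[:4]
        hits = background[:4]
        sets = GeneSetCollection({"S": gene_set})
        res = enr.ora_hypergeometric(hits, background, sets)
        N, K, n = 10, 4, 4
        p_exact = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(4, min(K, n) + 1)
        )
        assert res["p_value"].iloc[0] == pytest.approx(p_exact, rel=1e-12)

    def test_no_overlap_p_near_one(self):
        background = [f"G{i}" for i in range(100)]
        sets = GeneSetCollection({"S": background[90:93]})
        res = enr.ora_hypergeometric(background[:5], background, sets)
        assert res["p_value"].iloc[0] > 0.8

    def test_saturated_set_p_is_one(self):
        background = [f"G{i}" for i in range(20)]
        sets = GeneSetCollection({"S": background})
        res = enr.ora_hypergeometric(background[:7], background, sets)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_stray_hit_rejected(self):
        with pytest.raises(ValueError, match="XX"):
            enr.ora_hypergeometric(["XX"], ["G1"], GeneSetCollection({"S": ["G1"]}))


class TestKappa:
    def test_agrees_with_sklearn_cohen_kappa(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random(50) < 0.3
            b = rng.random(50) < 0.4
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert enr.cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_identical_sets_merge(self):
        uni = [f"G{i}" for i in range(50)]
        sets = GeneSetCollection({"A": uni[:10], "B": uni[:10], "C": uni[30:45]})
        out = enr.kappa_simplify(sets, uni, kappa_max=0.4)
        assert ["A", "B"] in out.clusters
        assert len(out.clusters) == 2

    def test_disjoint_sets_never_merge(self):
        """Two disjoint 10-gene sets over 1000 genes: the agreement table
        gives kappa <= 0, so no merge even at threshold 0."""
        uni = [f"G{i}" for i in range(1000)]
        a, b = uni[:10], uni[10:20]
        assert enr.cohens_kappa(
            np.isin(uni, a), np.isin(uni, b)
        ) <= 0
        out = enr.kappa_simplify(
            GeneSetCollection({"A": a, "B": b}), uni, kappa_max=0.0
        )
        assert len(out.clusters) == 2

    def test_unattainable_threshold_keeps_singletons(self):
        uni = [f"G{i}" for i in range(30)]
        sets = GeneSetCollection({"A": uni[:10], "B": uni[5:15], "C": uni[20:25]})
        out = enr.kappa_simplify(sets, uni, kappa_max=1.0)
        assert all(len(c) == 1 for c in out.clusters)

    def test_terminates_on_redundant_200_set_fixture(self):
        rng = np.random.default_rng(2)
        uni = [f"G{i}" for i in range(500)]
        sets = {}
        for j in range(100):
            base = list(rng.choice(uni, size=30, replace=False))
            sets[f"A{j:03d}"] = base
            noisy = base.copy()
            for _ in range(3):
                noisy[int(rng.integers(0, 30))] = uni[int(rng.integers(0, 500))]
            sets[f"B{j:03d}"] = noisy
        out = enr.kappa_simplify(GeneSetCollection(sets), uni, kappa_max=0.4)
        assert out.max_residual_kappa <= 0.4
        assert len(out.clusters) < 200
        # representatives pairwise satisfy the threshold
        M = {
            rep: np.isin(uni, sorted(GeneSetCollection(sets)[rep]))
            for rep in out.representatives
        }
        reps = out.representatives
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert enr.cohens_kappa(M[reps[i]], M[reps[j]]) <= 0.4 + 1e-12

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enr.kappa_simplify(
                GeneSetCollection({"A": ["G1"], "B": ["G2"]}), [], 0.4
            )
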