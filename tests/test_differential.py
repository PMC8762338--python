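"""DEG calling, over-representation, consistency, and feature screens."""
import math

import numpy as np
import pandas as pd
import pytest

from immsub import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    composition_test,
    consistent_pathways,
    differential_genes,
    one_vs_rest_features,
    ora_pathways,
    pathway_immune_correlation,
)
from immsub.containers import EnrichmentMatrix
from oracles import hypergeom_resampling_oracle
from test_genomic_scores import assignment_for


def planted_deg_matrix(seed=4, n_null=48, n_per_group=20, fc=3.0):
    rng = np.random.default_rng(seed)
    genes = [f"DEG{i}" for i in range(2)] + [f"NULL{i}" for i in range(n_null)]
    a_cols = [f"a{i}" for i in range(n_per_group)]
    b_cols = [f"b{i}" for i in range(n_per_group)]
    base = rng.normal(100, 3, size=(len(genes), 2 * n_per_group)).clip(1)
    data = pd.DataFrame(base, index=genes, columns=a_cols + b_cols)
    data.loc[["DEG0", "DEG1"], a_cols] *= fc
    return ExpressionMatrix(data, scale="linear"), a_cols, b_cols


class TestDifferentialGenes:
    def test_planted_genes_recovered_exactly(self):
        m, a, b = planted_deg_matrix()
        res = differential_genes(m, a, b)
        assert set(res.significant_genes) == {"DEG0", "DEG1"}
        assert set(res.upregulated_in("a")) == {"DEG0", "DEG1"}

    def test_identical_groups_give_empty_result(self):
        rng = np.random.default_rng(1)
        block = rng.normal(50, 5, size=(30, 10)).clip(1)
        data = np.hstack([block, block])
        cols = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        m = ExpressionMatrix(pd.DataFrame(
            data, index=[f"G{i}" for i in range(30)], columns=cols))
        res = differential_genes(m, cols[:10], cols[10:])
        assert res.significant_genes == []

    def test_fold_change_boundary_is_strict(self):
        # FC exactly 1.5 with essentially no noise: significant FDR but
        # excluded by the strict fold-change inequality
        a_cols = [f"a{i}" for i in range(10)]
        b_cols = [f"b{i}" for i in range(10)]
        wiggle = np.tile([0.125, -0.125], 5)  # exact binary fraction: means exact
        row_a = np.full(10, 3.0) + wiggle
        row_b = np.full(10, 2.0) + wiggle
        data = pd.DataFrame([np.concatenate([row_a, row_b])], index=["G"],
                            columns=a_cols + b_cols)
        m = ExpressionMatrix(data, scale="linear")
        res = differential_genes(m, a_cols, b_cols, fc_threshold=1.5)
        assert res.table.loc["G", "fold_change"] == pytest.approx(1.5)
        assert not res.table.loc["G", "significant"]

    def test_swapping_groups_flips_directions(self):
        m, a, b = planted_deg_matrix()
        r1 = differential_genes(m, a, b)
        r2 = differential_genes(m, b, a)
        assert np.allclose(r1.table["p"], r2.table["p"])
        flipped = r2.table["direction"].map(
            {"up_in_a": "up_in_b", "up_in_b": "up_in_a"})
        assert (r1.table["direction"] == flipped).all()

    def test_overlapping_groups_rejected(self):
        m, a, b = planted_deg_matrix()
        with pytest.raises(ValueError, match="disjoint"):
            differential_genes(m, a, a[:5] + b[:5])


class TestOraPathways:
    def test_exact_minimum_p_when_degs_equal_pathway(self):
        background = [f"G{i}" for i in range(100)]
        pathway = GeneSetCollection.from_sets(
            [GeneSet.from_genes("P", background[:10])])
        out = ora_pathways(background[:10], background, pathway)
        assert out.loc["P", "p"] == pytest.approx(1 / math.comb(100, 10))

    def test_disjoint_degs_give_p_one(self):
        background = [f"G{i}" for i in range(50)]
        pathway = GeneSetCollection.from_sets(
            [GeneSet.from_genes("P", background[:10])])
        out = ora_pathways(background[40:], background, pathway)
        assert out.loc["P", "p"] == pytest.approx(1.0)

    def test_matches_resampling_oracle(self):
        background = [f"G{i}" for i in range(60)]
        pathway = GeneSetCollection.from_sets(
            [GeneSet.from_genes("P", background[:12])])
        degs = background[:5] + background[30:40]  # overlap 5, size 15
        out = ora_pathways(degs, background, pathway)
        mc = hypergeom_resampling_oracle(overlap=5, background=60, set_size=12,
                                         deg_size=15, draws=100_000, seed=0)
        se = math.sqrt(mc * (1 - mc) / 100_000)
        assert abs(out.loc["P", "p"] - mc) <= 3 * se + 1e-6

    def test_background_order_invariance(self):
        rng = np.random.default_rng(6)
        background = [f"G{i}" for i in range(40)]
        pathway = GeneSetCollection.from_sets(
            [GeneSet.from_genes("P", background[5:15])])
        degs = background[::4]
        p1 = ora_pathways(degs, background, pathway).loc["P", "p"]
        p2 = ora_pathways(degs, rng.permutation(background), pathway).loc["P", "p"]
        assert p1 == p2

    def test_deg_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora_pathways(["X"], ["A", "B"],
                         GeneSetCollection.from_sets(
                             [GeneSet.from_genes("P", ["A", "B"])]))


class TestConsistentPathways:
    @staticmethod
    def table(names, significant):
        df = pd.DataFrame({"significant": [n in significant for n in names]},
                          index=pd.Index(names, name="pathway"))
        return df

    def test_identical_tables_intersect_to_themselves(self):
        t = self.table(["A"], {"A"})
        assert consistent_pathways([t, t.copy()]) == ["A"]

    def test_empty_table_absorbs(self):
        full = self.table(["A", "B"], {"A", "B"})
        empty = pd.DataFrame(columns=["significant"])
        assert consistent_pathways([full, full, empty, full, full]) == []

    def test_hand_intersection(self):
        t1 = self.table(["A", "B", "C"], {"A", "B", "C"})
        t2 = self.table(["B", "C"], {"B", "C"})
        t3 = self.table(["B", "D"], {"B", "D"})
        assert consistent_pathways([t1, t2, t3]) == ["B"]


class TestPathwayImmuneCorrelation:
    @staticmethod
    def enrichment_from_rows(rows, samples):
        return EnrichmentMatrix(scores=pd.DataFrame(
            rows, index=[f"P{i}" for i in range(len(rows))], columns=samples))

    def test_self_correlation_is_one(self):
        samples = [f"s{i}" for i in range(8)]
        imm = pd.Series(np.arange(8.0), index=samples)
        em = self.enrichment_from_rows([np.arange(8.0)], samples)
        out = pathway_immune_correlation(em, imm)
        assert out.loc["P0", "rho"] == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        samples = [f"s{i}" for i in range(8)]
        imm = pd.Series(np.arange(8.0), index=samples)
        em = self.enrichment_from_rows([-np.arange(8.0)], samples)
        assert pathway_immune_correlation(em, imm).loc["P0", "rho"] == \
            pytest.approx(-1.0)

    def test_planted_monotone_pathways_all_positive(self):
        rng = np.random.default_rng(9)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        imm = pd.Series(rng.normal(size=n), index=samples)
        rows = []
        for _ in range(6):  # monotone transforms of the immune score, SNR ~3
            rows.append(np.exp(imm.to_numpy() / 2) +
                        rng.normal(0, np.exp(imm.to_numpy() / 2).std() / 3, n))
        em = self.enrichment_from_rows(rows, samples)
        out = pathway_immune_correlation(em, imm)
        assert (out["rho"] > 0).all()
        assert (out["fdr"] < 0.05).all()

    def test_too_few_shared_samples_rejected(self):
        samples = ["s0", "s1"]
        em = self.enrichment_from_rows([[1.0, 2.0]], samples)
        with pytest.raises(ValueError, match=">=3"):
            pathway_immune_correlation(em, pd.Series([1.0, 2.0], index=samples))


class TestOneVsRestFeatures:
    @staticmethod
    def features_for(groups, rows):
        cols = sum(groups.values(), [])
        return pd.DataFrame(rows, columns=cols)

    def test_dominant_feature_assigned(self):
        rng = np.random.default_rng(1)
        groups = {"ImH": [f"h{i}" for i in range(10)],
                  "ImM": [f"m{i}" for i in range(10)],
                  "ImL": [f"l{i}" for i in range(10)]}
        a = assignment_for(groups)
        row = np.concatenate([np.full(10, 10.0), np.full(10, 1.0),
                              np.full(10, 1.0)]) + rng.normal(0, 0.01, 30)
        feats = self.features_for(groups, [row])
        assigned = one_vs_rest_features(feats, a)
        assert assigned["ImH"] == [0]

    def test_tie_between_two_subtypes_assigns_nothing(self):
        rng = np.random.default_rng(2)
        groups = {"ImH": [f"h{i}" for i in range(10)],
                  "ImM": [f"m{i}" for i in range(10)],
                  "ImL": [f"l{i}" for i in range(10)]}
        a = assignment_for(groups)
        row = np.concatenate([np.full(10, 5.0), np.full(10, 5.0),
                              np.full(10, 1.0)]) + rng.normal(0, 0.01, 30)
        assigned = one_vs_rest_features(self.features_for(groups, [row]), a)
        assert all(v == [] for v in assigned.values())

    def test_planted_mid_dominant_features_recovered(self):
        rng = np.random.default_rng(6)
        n = 30
        groups = {"ImH": [f"h{i}" for i in range(n)],
                  "ImM": [f"m{i}" for i in range(n)],
                  "ImL": [f"l{i}" for i in range(n)]}
        a = assignment_for(groups)
        rows = []
        names = []
        for i in range(8):  # mid-dominant planted features
            rows.append(np.concatenate([
                rng.normal(1, 0.3, n), rng.normal(3, 0.3, n),
                rng.normal(1, 0.3, n)]))
            names.append(f"MID{i}")
        for i in range(50):
            rows.append(rng.normal(2, 0.3, 3 * n))
            names.append(f"NULL{i}")
        feats = pd.DataFrame(rows, index=names, columns=sum(groups.values(), []))
        assigned = one_vs_rest_features(feats, a)
        assert set(assigned["ImM"]) == {f"MID{i}" for i in range(8)}
        assert assigned["ImH"] == [] and assigned["ImL"] == []

    def test_no_feature_assigned_twice(self):
        rng = np.random.default_rng(8)
        groups = {"ImH": [f"h{i}" for i in range(8)],
                  "ImM": [f"m{i}" for i in range(8)],
                  "ImL": [f"l{i}" for i in range(8)]}
        a = assignment_for(groups)
        feats = pd.DataFrame(rng.normal(size=(40, 24)),
                             columns=sum(groups.values(), []))
        assigned = one_vs_rest_features(feats, a)
        all_assigned = sum(assigned.values(), [])
        assert len(all_assigned) == len(set(all_assigned))


class TestCompositionTest:
    def test_category_equal_to_subtype_is_extreme(self):
        groups = {"ImH": [f"h{i}" for i in range(30)],
                  "ImM": [f"m{i}" for i in range(30)],
                  "ImL": [f"l{i}" for i in range(30)]}
        a = assignment_for(groups)
        cat = a.labels.copy()
        props, res = composition_test(a, cat, seed=0)
        assert res.p_value < 1e-3
        assert props.loc["ImH", "ImH"] == 1.0

    def test_random_category_usually_insignificant(self):
        significant = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(13 + rep)
            groups = {"ImH": [f"h{i}" for i in range(100)],
                      "ImM": [f"m{i}" for i in range(100)],
                      "ImL": [f"l{i}" for i in range(100)]}
            a = assignment_for(groups)
            cat = pd.Series(rng.choice(["x", "y"], size=300),
                            index=a.sample_ids)
            _, res = composition_test(a, cat, seed=rep)
            if res.p_value < 0.05:
                significant += 1
        assert significant <= max(2, int(0.1 * n_rep))

    def test_planted_receptor_like_composition_recovered(self):
        rng = np.random.default_rng(8)
        n = 200
        groups = {"ImH": [f"h{i}" for i in range(n)],
                  "ImM": [f"m{i}" for i in range(n)],
                  "ImL": [f"l{i}" for i in range(n)]}
        a = assignment_for(groups)
        rates = {"ImH": 0.40, "ImM": 0.14, "ImL": 0.05}
        values = {}
        for lab, members in groups.items():
            for s in members:
                values[s] = "tnbc" if rng.random() < rates[lab] else "other"
        _, res = composition_test(a, pd.Series(values), seed=1)
        props, _ = composition_test(a, pd.Series(values), seed=1)
        assert res.p_value < 1e-3
        for lab, r in rates.items():
            assert abs(props.loc[lab, "tnbc"] - r) <= 0.07

    def test_single_category_rejected(self):
        groups = {"ImH": ["h1", "h2"], "ImM": ["m1", "m2"], "ImL": ["l1", "l2"]}
        a = assignment_for(groups)
        cat = pd.Series("only", index=a.sample_ids)
        with pytest.raises(ValueError, match="two categories"):
            composition_test(a, cat)
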