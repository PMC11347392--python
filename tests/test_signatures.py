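import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sttme.cluster import ClusterAssignment, NormalizedMatrix
from sttme.errors import InvalidArgumentError, SttmeError
from sttme.signatures import (Signature, SurvivalCohort, enrich_hypergeometric,
                              km_logrank, read_gmt, read_regulons,
                              regulon_activity, score_bulk_signature,
                              top_signature, tumor_specific_genes,
                              wilcoxon_deg)
from sttme.synth import simulate_bulk_cohort


def nm_from(values, gene_ids=None):
    values = np.asarray(values, float)
    gene_ids = gene_ids or [f"G{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values=values,
                            barcodes=np.array([f"B{i}" for i in range(values.shape[0])], object),
                            gene_ids=np.array(gene_ids, object), method="log_cpm")


class TestWilcoxonDEG:
    def make_planted(self, seed=0, n_a=50, n_b=150, fold=4.0):
        rng = np.random.default_rng(seed)
        values = np.log1p(rng.poisson(5, size=(n_a + n_b, 40)))
        values[:n_a, 0] = np.log1p(rng.poisson(5 * fold, size=n_a))
        labels = np.repeat([0, 1], [n_a, n_b])
        return nm_from(values), ClusterAssignment(labels=labels, method="graph")

    def test_planted_marker_recovered(self):
        nm, ca = self.make_planted()
        deg = wilcoxon_deg(nm, ca)
        row = deg[(deg["cluster"] == 0) & (deg["gene"] == "G0")]
        assert len(row) == 1
        assert row["avg_log2FC"].iloc[0] > 0.25
        assert row["p_adj_bonferroni"].iloc[0] < 0.05

    def test_low_detection_gene_filtered(self):
        rng = np.random.default_rng(1)
        values = np.log1p(rng.poisson(3, size=(60, 5)))
        values[:, 2] = 0.0
        values[rng.choice(60, 3, replace=False), 2] = 1.0  # 5% detection
        ca = ClusterAssignment(labels=np.repeat([0, 1], 30), method="graph")
        deg = wilcoxon_deg(nm_from(values), ca, min_pct=0.1)
        assert "G2" not in set(deg["gene"])

    def test_swapping_groups_negates_log_fold_change(self):
        nm, ca = self.make_planted(seed=2)
        deg = wilcoxon_deg(nm, ca, min_pct=0.0, logfc_threshold=0.0)
        a = deg[deg["cluster"] == 0].set_index("gene")
        b = deg[deg["cluster"] == 1].set_index("gene")
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(a.loc[common, "avg_log2FC"],
                                   -b.loc[common, "avg_log2FC"], atol=1e-12)
        np.testing.assert_allclose(a.loc[common, "p_value"],
                                   b.loc[common, "p_value"], atol=1e-12)

    def test_bonferroni_not_below_raw(self):
        nm, ca = self.make_planted(seed=3)
        deg = wilcoxon_deg(nm, ca, min_pct=0.0, logfc_threshold=0.0)
        assert (deg["p_adj_bonferroni"] >= deg["p_value"] - 1e-15).all()

    def test_shuffled_labels_calibrated(self):
        """Under a label-shuffled null the raw p-values are uniform."""
        rng = np.random.default_rng(4)
        values = np.log1p(rng.poisson(8, size=(200, 600)))
        labels = rng.permutation(np.arange(200) % 2)
        ca = ClusterAssignment(labels=labels, method="graph")
        deg = wilcoxon_deg(nm_from(values), ca, min_pct=0.0, logfc_threshold=0.0)
        frac = (deg[deg["cluster"] == 0]["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02


class TestTopSignature:
    def deg_table(self):
        return pd.DataFrame({
            "gene": ["A", "B", "C", "D", "E"],
            "cluster": 0,
            "avg_log2FC": [2.0, -1.0, 0.5, 1.5, 3.0],
            "pct_in": 0.5, "pct_out": 0.1,
            "p_value": [1e-5, 1e-5, 0.2, 1e-4, 1e-6],
            "p_adj_bonferroni": [1e-4, 1e-4, 0.9, 1e-3, 1e-5],
        })

    def test_fewer_qualifying_genes_than_k(self):
        sig = top_signature(self.deg_table(), 0, k=50)
        assert sig.genes == ["E", "A", "D"]  # descending avg_log2FC, p_adj<.05, positive

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        deg = pd.DataFrame({
            "gene": [f"G{i}" for i in range(n)], "cluster": 0,
            "avg_log2FC": rng.normal(1, 1, n), "pct_in": 0.5, "pct_out": 0.1,
            "p_value": rng.uniform(0, 0.1, n),
        })
        deg["p_adj_bonferroni"] = deg["p_value"] * 2
        sig = top_signature(deg, 0, k=10)
        qual = deg[(deg["p_adj_bonferroni"] < 0.05) & (deg["avg_log2FC"] > 0)]
        expected = list(qual.sort_values("avg_log2FC", ascending=False)["gene"][:10])
        assert sig.genes == expected

    def test_k_zero_returns_empty(self):
        assert top_signature(self.deg_table(), 0, k=0).genes == []


class TestTumorSpecific:
    def table(self, genes, lfc, p):
        return pd.DataFrame({"gene": genes, "cluster": 0, "avg_log2FC": lfc,
                             "pct_in": 0.5, "pct_out": 0.1, "p_value": p,
                             "p_adj_bonferroni": p})

    def test_intersection_logic(self):
        t1 = self.table(["G", "H"], [1.0, 1.0], [0.01, 0.01])
        t2 = self.table(["G", "H"], [1.0, 0.1], [0.01, 0.01])  # H fails lfc
        t3 = self.table(["G", "H"], [1.0, 1.0], [0.01, 0.01])
        assert tumor_specific_genes([t1, t2, t3]) == {"G"}

    def test_thresholds_are_strict(self):
        t = self.table(["X", "Y"], [0.25, 0.26], [0.05, 0.04])
        # X sits exactly at both thresholds -> excluded
        assert tumor_specific_genes([t, t, t]) == {"Y"}

    def test_matches_brute_force_triple_filter(self):
        rng = np.random.default_rng(6)
        tables = [self.table([f"G{i}" for i in range(50)],
                             rng.normal(0.3, 0.2, 50), rng.uniform(0, 0.1, 50))
                  for _ in range(3)]
        expected = None
        for t in tables:
            s = {g for g, l, p in zip(t["gene"], t["avg_log2FC"], t["p_value"])
                 if l > 0.25 and p < 0.05}
            expected = s if expected is None else expected & s
        assert tumor_specific_genes(tables) == expected


class TestEnrichment:
    def test_full_overlap_closed_form(self):
        universe = {f"G{i}" for i in range(10)}
        hits = {f"G{i}" for i in range(5)}
        res = enrich_hypergeometric(hits, {"S": sorted(hits)}, universe)
        assert abs(res["p"].iloc[0] - 1 / 252) < 1e-12

    def test_zero_overlap_p_one(self):
        universe = {f"G{i}" for i in range(10)}
        res = enrich_hypergeometric({"G0"}, {"S": ["G5", "G6"]}, universe)
        assert res[res["set"] == "S"]["p"].iloc[0] <= 1.0
        res2 = enrich_hypergeometric(set(), {"S": ["G5"]}, universe)
        assert res2["p"].iloc[0] == 1.0

    def test_matches_enumeration_oracle(self):
        from itertools import combinations
        universe = set("ABCDEFGH")
        gene_set = {"A", "B", "C"}
        hits = {"A", "B", "D"}
        res = enrich_hypergeometric(hits, {"S": sorted(gene_set)}, universe)
        overlap = len(gene_set & hits)
        count = sum(1 for combo in combinations(sorted(universe), len(hits))
                    if len(set(combo) & gene_set) >= overlap)
        from math import comb
        assert abs(res["p"].iloc[0] - count / comb(8, 3)) < 1e-12

    def test_bh_monotone_in_raw_p(self):
        universe = {f"G{i}" for i in range(30)}
        sets = {f"S{k}": [f"G{i}" for i in range(k, k + 5)] for k in range(10)}
        res = enrich_hypergeometric({f"G{i}" for i in range(8)}, sets, universe)
        res = res.sort_values("p")
        # BH-adjusted values, after cummin, are non-decreasing with raw p
        assert (np.diff(res["p_adj_bh"]) >= -1e-12).all()

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(InvalidArgumentError):
            enrich_hypergeometric({"X"}, {}, {"A"})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tA\tB\tC\nS2\tdesc\tD\n")
        sets = read_gmt(path)
        assert sets == {"S1": ["A", "B", "C"], "S2": ["D"]}


class TestRegulonActivity:
    def regulons(self, n_targets=6, mode=1):
        return pd.DataFrame({"tf": "TF1", "target": [f"G{j}" for j in range(n_targets)],
                             "mode": mode, "confidence": "A"})

    def test_activity_of_uniform_z(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(20, 6))
        # spot 0 at z=+1 for every gene
        mu, sd = values.mean(axis=0), values.std(axis=0)
        values[0] = mu + sd
        mu2, sd2 = values.mean(axis=0), values.std(axis=0)
        nm = nm_from(values)
        act = regulon_activity(nm, self.regulons(), min_targets=5)
        expected = ((values[0] - mu2) / sd2).mean()
        assert abs(act["TF1"].iloc[0] - expected) < 1e-12

    def test_mode_flip_negates_activity(self):
        values = np.random.default_rng(8).normal(size=(15, 6))
        nm = nm_from(values)
        a = regulon_activity(nm, self.regulons(mode=1), min_targets=5)
        b = regulon_activity(nm, self.regulons(mode=-1), min_targets=5)
        np.testing.assert_allclose(a["TF1"], -b["TF1"], atol=1e-12)

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(10, 8))
        reg = pd.DataFrame({"tf": "T", "target": [f"G{j}" for j in range(8)],
                            "mode": rng.choice([-1, 1], 8), "confidence": "B"})
        act = regulon_activity(nm_from(values), reg, min_targets=5)
        Z = (values - values.mean(axis=0)) / values.std(axis=0)
        expected = (Z * reg["mode"].to_numpy()).mean(axis=1)
        np.testing.assert_allclose(act["T"], expected, atol=1e-12)

    def test_small_regulons_skipped(self):
        values = np.random.default_rng(10).normal(size=(10, 6))
        with pytest.raises(SttmeError):
            regulon_activity(nm_from(values), self.regulons(n_targets=3))

    def test_confidence_filter(self, tmp_path):
        df = pd.DataFrame({"tf": "T", "target": [f"G{j}" for j in range(6)],
                           "mode": 1, "confidence": ["A", "B", "C", "D", "E", "D"]})
        path = tmp_path / "reg.tsv"
        df.to_csv(path, sep="\t", index=False)
        reg = read_regulons(path)
        values = np.random.default_rng(11).normal(size=(10, 6))
        with pytest.raises(SttmeError):  # only 3 targets at confidence <= C
            regulon_activity(nm_from(values), reg, confidence_max="C")


class TestSurvival:
    def cohort(self, n=20, seed=0, hr=0.0):
        return SurvivalCohort.from_bulk(
            simulate_bulk_cohort(n, ["A", "B"], hr, censor_rate=0.2, seed=seed))

    def test_duplicated_groups_give_null_logrank(self):
        rng = np.random.default_rng(12)
        time = np.tile(rng.exponential(100, 10), 2)
        event = np.tile(rng.integers(0, 2, 10) | 1, 2)
        expr = pd.DataFrame({f"P{i}": [0.0] for i in range(20)}, index=["A"])
        cohort = SurvivalCohort(expression=expr, time=time, event=event)
        score = np.r_[np.zeros(10), np.ones(10)]  # split exactly along copies
        km = km_logrank(cohort, score)
        assert abs(km.statistic) < 1e-10
        assert km.p_value > 0.99

    def test_no_events_raises(self):
        c = self.cohort()
        c.event[:] = 0
        with pytest.raises(SttmeError):
            km_logrank(c, np.arange(20.0))

    def test_constant_score_raises(self):
        with pytest.raises(SttmeError):
            km_logrank(self.cohort(), np.zeros(20))

    def test_km_matches_product_limit_by_hand(self):
        # 5 subjects, deaths at 2 and 4, censored at 3; S(4)=0.8*(1-1/3)
        time = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 0, 0])
        expr = pd.DataFrame({f"P{i}": [0.0] for i in range(5)}, index=["A"])
        cohort = SurvivalCohort(expression=expr, time=time, event=event)
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(time, event)
        s4 = km.survival_function_at_times(4.0).iloc[0]
        assert abs(s4 - 0.8 * (2 / 3)) < 1e-12

    def test_signature_score_equals_z_for_single_gene(self):
        c = self.cohort(seed=3)
        score = score_bulk_signature(c, Signature("s", ["A"]))
        x = c.expression.loc["A"].to_numpy(float)
        np.testing.assert_allclose(score, (x - x.mean()) / x.std(), atol=1e-12)

    def test_constant_expression_scores_zero(self):
        expr = pd.DataFrame(np.ones((2, 12)), index=["A", "B"],
                            columns=[f"P{i}" for i in range(12)])
        cohort = SurvivalCohort(expression=expr, time=np.ones(12),
                                event=np.ones(12, int))
        np.testing.assert_allclose(
            score_bulk_signature(cohort, Signature("s", ["A", "B"])), 0.0)

    def test_mean_of_z_matches_oracle(self):
        c = self.cohort(seed=4)
        score = score_bulk_signature(c, Signature("s", ["A", "B"]))
        X = c.expression.loc[["A", "B"]].to_numpy(float)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        np.testing.assert_allclose(score, Z.mean(axis=0), atol=1e-12)

    def test_csv_round_trip(self, tmp_path):
        bulk = simulate_bulk_cohort(15, ["A", "B"], 0.5, 0.2, seed=5,
                                    n_noise_genes=2)
        bulk.to_csv(tmp_path / "cohort.csv")
        c = SurvivalCohort.read_csv(tmp_path / "cohort.csv")
        np.testing.assert_allclose(c.time, bulk.time)
        np.testing.assert_array_equal(c.event, bulk.event)
        np.testing.assert_allclose(c.expression.loc["A"].to_numpy(float),
                                   bulk.expression.loc["A"].to_numpy())
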