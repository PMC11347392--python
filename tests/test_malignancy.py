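import numpy as np
import pytest
import scipy.stats

from conftest import make_spot_matrix
from sttme.cluster import ClusterAssignment, NormalizedMatrix
from sttme.errors import InvalidArgumentError, SttmeError
from sttme.experiments import naive_window_smooth
from sttme.genome import make_genome
from sttme.malignancy import (MarkerPanel, call_malignant, cnv_score,
                              compare_scores_across_clusters, infer_cnv,
                              panel_score, select_reference_cluster,
                              two_phase_identify)


def nm_from(values, gene_ids=None):
    values = np.asarray(values, float)
    gene_ids = gene_ids or [f"G{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values=values,
                            barcodes=np.array([f"B{i}" for i in range(values.shape[0])], object),
                            gene_ids=np.array(gene_ids, object), method="log_cpm")


class TestPanelScore:
    def test_mean_of_constant_panel(self):
        nm = nm_from(np.full((3, 4), 2.0), gene_ids=["A", "B", "C", "D"])
        panel = MarkerPanel("p", ["A", "B", "C", "D"])
        np.testing.assert_allclose(panel_score(nm, panel), 2.0)

    def test_zero_spot_scores_zero(self):
        nm = nm_from([[0.0, 0.0], [1.0, 3.0]], gene_ids=["A", "B"])
        scores = panel_score(nm, MarkerPanel("p", ["A", "B"]))
        assert scores[0] == 0.0

    def test_missing_genes_skipped(self):
        nm = nm_from([[1.0, 3.0]], gene_ids=["A", "B"])
        scores = panel_score(nm, MarkerPanel("p", ["A", "B", "ABSENT"]))
        np.testing.assert_allclose(scores, [2.0])

    def test_all_genes_missing_raises(self):
        nm = nm_from([[1.0]], gene_ids=["A"])
        with pytest.raises(SttmeError):
            panel_score(nm, MarkerPanel("p", ["X", "Y"]))

    def test_matches_per_spot_mean_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 8))
        genes = [f"G{j}" for j in range(8)]
        nm = nm_from(values, genes)
        panel = MarkerPanel("p", ["G1", "G4", "G6"])
        scores = panel_score(nm, panel)
        for i in range(5):
            expected = (values[i, 1] + values[i, 4] + values[i, 6]) / 3
            assert abs(scores[i] - expected) < 1e-12


class TestKruskalWallis:
    def test_three_rank_blocks_give_h_7_2(self):
        scores = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9.0])
        ca = ClusterAssignment(labels=np.repeat([0, 1, 2], 3), method="graph")
        h, p, med = compare_scores_across_clusters(scores, ca)
        assert abs(h - 7.2) < 1e-10
        assert med == {0: 2.0, 1: 5.0, 2: 8.0}

    def test_identical_groups_give_zero(self):
        scores = np.tile([1.0, 2.0, 3.0], 3)
        ca = ClusterAssignment(labels=np.repeat([0, 1, 2], 3), method="graph")
        h, p, _ = compare_scores_across_clusters(scores, ca)
        assert h == 0.0 or p > 0.99

    def test_tied_data_matches_rank_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 5, size=30).astype(float)  # many ties
        labels = rng.integers(0, 3, size=30)
        labels[:3] = [0, 1, 2]
        ca = ClusterAssignment(labels=labels, method="graph")
        h, _, _ = compare_scores_across_clusters(scores, ca)
        # brute-force H with tie correction
        ranks = scipy.stats.rankdata(scores)
        n = len(scores)
        ssq = sum(len(ranks[labels == g]) * (ranks[labels == g].mean() - (n + 1) / 2) ** 2
                  for g in range(3))
        h_raw = 12.0 / (n * (n + 1)) * ssq
        _, counts = np.unique(scores, return_counts=True)
        tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
        assert abs(h - h_raw / tie) < 1e-10

    def test_single_cluster_raises(self):
        ca = ClusterAssignment(labels=np.zeros(5, int), method="graph")
        with pytest.raises(SttmeError):
            compare_scores_across_clusters(np.arange(5.0), ca)


class TestReferenceSelection:
    def test_argmax_of_cluster_means(self):
        scores = np.array([0.1, 0.1, 0.9, 0.9, 0.2, 0.2])
        ca = ClusterAssignment(labels=np.repeat([0, 1, 2], 2), method="graph")
        assert select_reference_cluster(scores, ca) == 1

    def test_exact_tie_prefers_lowest_id(self):
        scores = np.array([0.5, 0.5, 0.1, 0.1, 0.5, 0.5])
        ca = ClusterAssignment(labels=np.repeat([0, 1, 2], 2), method="graph")
        assert select_reference_cluster(scores, ca) == 0


@pytest.fixture(scope="module")
def flat_genome():
    return make_genome(n_genes=300, n_chroms=2, seed=0)


class TestInferCNV:
    def test_reference_spots_cancel(self, flat_genome):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, size=(30, 300))
        counts[:, 0] += 1
        m = make_spot_matrix(counts, gene_ids=list(flat_genome.gene_ids))
        ref = np.zeros(30, bool)
        ref[:15] = True
        cr = infer_cnv(m, flat_genome, ref, window=11)
        # reference re-baseline: smoothed reference mean is 0 gene-wise
        assert np.abs(cr.cnv[ref].mean(axis=0)).max() < 1e-10

    def test_window_one_is_identity_smoothing(self, flat_genome):
        rng = np.random.default_rng(3)
        counts = rng.poisson(20, size=(10, 300))
        counts[:, 0] += 1
        m = make_spot_matrix(counts, gene_ids=list(flat_genome.gene_ids))
        ref = np.arange(10) < 5
        cr = infer_cnv(m, flat_genome, ref, window=1)
        ordered, _ = flat_genome.genome_order(m.gene_ids)
        col = {g: i for i, g in enumerate(m.gene_ids)}
        X = np.array([[counts[i, col[g]] for g in ordered] for i in range(10)], float)
        E = np.log2(X / X.sum(axis=1, keepdims=True) * 1e4 + 1)
        E -= E[ref].mean(axis=0)
        E = np.clip(E, -3, 3)
        E -= np.median(E, axis=1, keepdims=True)
        E -= E[ref].mean(axis=0)
        np.testing.assert_allclose(cr.cnv, E, atol=1e-10)

    def test_smoothing_matches_naive_loop_oracle(self):
        from sttme.malignancy import _truncated_moving_average
        rng = np.random.default_rng(4)
        for _ in range(20):
            E = rng.normal(size=(20, 500))
            chroms = np.repeat(["chr1", "chr2", "chr3"], [200, 200, 100])
            fast = np.empty_like(E)
            for c in ("chr1", "chr2", "chr3"):
                sel = chroms == c
                fast[:, sel] = _truncated_moving_average(E[:, sel], 101)
            slow = naive_window_smooth(E, chroms, 101)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_planted_gain_detected_in_malignant_spots(self, small_section):
        m, genome, truth = small_section
        ref = truth.region == "immune_infiltrate"
        cr = infer_cnv(m, genome, ref)
        # locate the planted segment: first 200 genes of the largest chrom
        from sttme.synth import default_cnv
        fold = default_cnv(genome).fold_vector(genome)
        seg = (fold.to_numpy() == 2.0)
        ordered_pos = {g: i for i, g in enumerate(cr.gene_ids)}
        seg_cols = [ordered_pos[g] for g in fold.index[seg]]
        out_cols = [ordered_pos[g] for g in fold.index[~seg]]
        mal = truth.malignant
        inside = cr.cnv[np.ix_(mal, seg_cols)].mean()
        flank_vals = cr.cnv[np.ix_(mal, out_cols)]
        assert inside > 0
        assert inside - flank_vals.mean() > 3 * flank_vals.mean(axis=1).std()

    def test_empty_reference_rejected(self, flat_genome):
        m = make_spot_matrix(np.ones((5, 300), int),
                             gene_ids=list(flat_genome.gene_ids))
        with pytest.raises(InvalidArgumentError):
            infer_cnv(m, flat_genome, np.zeros(5, bool))

    def test_even_window_rejected(self, flat_genome):
        m = make_spot_matrix(np.ones((5, 300), int),
                             gene_ids=list(flat_genome.gene_ids))
        with pytest.raises(InvalidArgumentError):
            infer_cnv(m, flat_genome, np.array([True, False, False, False, False]),
                      window=10)

    def test_window_variance_shrinks_on_white_noise(self, flat_genome):
        rng = np.random.default_rng(5)
        counts = rng.poisson(50, size=(40, 300))
        counts[:, 0] += 1
        m = make_spot_matrix(counts, gene_ids=list(flat_genome.gene_ids))
        ref = np.arange(40) < 20
        v_small = infer_cnv(m, flat_genome, ref, window=5).cnv.var()
        v_large = infer_cnv(m, flat_genome, ref, window=51).cnv.var()
        assert v_large < v_small


class TestCNVScore:
    def test_zero_matrix_scores_zero(self):
        from sttme.malignancy import CNVResult
        cr = CNVResult(cnv=np.zeros((4, 10)), gene_ids=np.arange(10),
                       barcodes=np.arange(4), reference_spots=np.zeros(4, bool))
        np.testing.assert_array_equal(cnv_score(cr), 0.0)

    def test_mean_of_squares(self):
        from sttme.malignancy import CNVResult
        cr = CNVResult(cnv=np.array([[0.1, -0.1]]), gene_ids=np.arange(2),
                       barcodes=np.arange(1), reference_spots=np.zeros(1, bool))
        np.testing.assert_allclose(cnv_score(cr), [0.01])

    def test_malignant_scores_exceed_reference(self, small_section):
        m, genome, truth = small_section
        cr = infer_cnv(m, genome, truth.region == "immune_infiltrate")
        scores = cnv_score(cr)
        _, p = scipy.stats.mannwhitneyu(scores[truth.malignant],
                                        scores[cr.reference_spots],
                                        alternative="greater")
        assert p < 0.001


class TestCallMalignant:
    def test_single_cluster_with_huge_gain_called(self, small_section):
        m, genome, truth = small_section
        # reference = everything except the malignant spots; k=1
        cr = infer_cnv(m, genome, ~truth.malignant)
        cnv_score(cr)
        cr = call_malignant(cr, k=1, min_effect=3.0)
        assert set(cr.call[truth.malignant]) == {"malignant"}

    def test_reference_never_called_malignant(self, small_section):
        m, genome, truth = small_section
        cr = infer_cnv(m, genome, truth.region == "immune_infiltrate")
        cnv_score(cr)
        cr = call_malignant(cr, k=4, min_effect=3.0)
        assert set(cr.call[cr.reference_spots]) == {"reference"}


class TestTwoPhase:
    def test_end_to_end_recovery(self, small_section):
        m, genome, truth = small_section
        res = two_phase_identify(m, genome, seed=7, min_effect=3.0)
        pred = res.cnv_result.call == "malignant"
        tp = (pred & truth.malignant).sum()
        assert tp / max(pred.sum(), 1) >= 0.9
        assert tp / truth.malignant.sum() >= 0.9

    def test_epithelial_score_highest_in_malignant_group(self, small_section):
        m, genome, _ = small_section
        res = two_phase_identify(m, genome, seed=7, min_effect=3.0)
        by_call = res.epithelial_by_call
        assert by_call["malignant"] > by_call.get("other", -np.inf)
        assert by_call["malignant"] > by_call["reference"]

    def test_deterministic_given_seed(self, tiny_section):
        m, genome, _ = tiny_section
        a = two_phase_identify(m, genome, seed=3, k_phase2=4, window=51)
        b = two_phase_identify(m, genome, seed=3, k_phase2=4, window=51)
        np.testing.assert_array_equal(a.cnv_result.call, b.cnv_result.call)
        np.testing.assert_array_equal(a.phase1.labels, b.phase1.labels)
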