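import numpy as np
import pytest

from grnforge import GRN, auc, benchmark, eda, zscore_baseline
from grnforge.evaluate import BenchmarkError


def random_truth(n: int, rng, density: float = 0.3, self_loops: bool = False) -> GRN:
    w = (rng.random((n, n)) < density).astype(float)
    if not self_loops:
        np.fill_diagonal(w, 0)
    if w.sum() == 0:
        w[1, 0] = 1.0
    return GRN(genes=[f"g{i}" for i in range(n)], weights=w)


def brute_force_areas(scores: np.ndarray, truth: GRN, include_self=True):
    """Naive confusion-matrix sweep: recount TP/FP at every distinct cut.

    Complete predictions only.  ROC/PR points are computed by explicit
    loops over thresholds, trapezoid areas by pairwise summation.
    """
    mask = np.ones(scores.shape, dtype=bool)
    if not include_self:
        np.fill_diagonal(mask, False)
    s = np.abs(scores[mask])
    label = (truth.weights != 0)[mask]
    P = label.sum()
    N = label.size - P
    pts_roc = [(0.0, 0.0)]
    pts_pr = []
    for theta in sorted(set(s), reverse=True):
        pred = s >= theta
        tp = int((pred & label).sum())
        fp = int((pred & ~label).sum())
        pts_roc.append((fp / N, tp / P))
        pts_pr.append((tp / P, tp / (tp + fp)))
    pts_pr = [(0.0, pts_pr[0][1])] + pts_pr
    trap = lambda pts: sum(
        (x1 - x0) * (y0 + y1) / 2 for (x0, y0), (x1, y1) in zip(pts, pts[1:])
    )
    return trap(pts_roc), trap(pts_pr)


class TestAuc:
    def test_diagonal_half(self):
        assert auc([(0, 0), (1, 1)]) == pytest.approx(0.5)

    def test_flat_top_one(self):
        assert auc([(0, 1), (1, 1)]) == pytest.approx(1.0)

    def test_matches_pairwise_trapezoid_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = np.sort(rng.random(30))
            y = np.sort(rng.random(30))
            expected = sum(
                (x[i + 1] - x[i]) * (y[i] + y[i + 1]) / 2 for i in range(29)
            )
            assert abs(auc(np.column_stack([x, y])) - expected) < 1e-12

    def test_degenerate_curve_rejected(self):
        with pytest.raises(BenchmarkError):
            auc([(0.5, 0.5)])

    def test_decreasing_x_rejected(self):
        with pytest.raises(BenchmarkError):
            auc([(0, 0), (1, 1), (0.5, 1)])


class TestBenchmark:
    def test_perfect_ranking_auroc_one(self):
        rng = np.random.default_rng(1)
        truth = random_truth(5, rng)
        scores = np.where(truth.weights != 0, 2.0, 1.0) + rng.random((5, 5)) * 0.5
        scores = np.where(truth.weights != 0, scores + 10, scores)
        res = benchmark(scores, truth)
        assert res.auroc == pytest.approx(1.0)
        assert res.aupr == pytest.approx(1.0)

    def test_reversed_ranking_auroc_zero(self):
        rng = np.random.default_rng(2)
        truth = random_truth(5, rng)
        scores = np.where(truth.weights != 0, 0.1, 1.0) + rng.random((5, 5)) * 0.05
        res = benchmark(scores, truth)
        assert res.auroc == pytest.approx(0.0, abs=1e-9)

    def test_empty_prediction_extension_exact(self):
        rng = np.random.default_rng(3)
        truth = random_truth(5, rng)
        res = benchmark(np.full((5, 5), np.nan), truth)
        assert res.extended
        assert res.auroc == pytest.approx(0.5, abs=0)
        prevalence = res.n_positives / res.n_candidates
        assert res.aupr == pytest.approx(prevalence)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_sweep(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        truth = random_truth(n, rng)
        scores = rng.random((n, n))
        if seed % 2:  # exercise tie handling
            scores = np.round(scores, 1)
        res = benchmark(scores, truth)
        roc_bf, pr_bf = brute_force_areas(scores, truth)
        assert res.auroc == pytest.approx(roc_bf, abs=1e-12)
        assert res.aupr == pytest.approx(pr_bf, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_auroc_matches_sklearn_rank_statistic(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(100 + seed)
        n = 8
        truth = random_truth(n, rng)
        scores = np.round(rng.random((n, n)), 1)
        res = benchmark(scores, truth)
        expected = roc_auc_score(
            (truth.weights != 0).ravel().astype(int), np.abs(scores).ravel()
        )
        assert res.auroc == pytest.approx(expected, abs=1e-12)

    def test_random_ranking_mean_half(self):
        rng = np.random.default_rng(5)
        truth = random_truth(5, rng)
        aurocs = [
            benchmark(np.random.default_rng(t).random((5, 5)), truth).auroc
            for t in range(200)
        ]
        assert abs(np.mean(aurocs) - 0.5) < 0.02

    def test_partial_prediction_curves_complete(self):
        rng = np.random.default_rng(6)
        truth = random_truth(6, rng)
        scores = rng.random((6, 6))
        scores[rng.random((6, 6)) < 0.5] = np.nan  # half the candidates unscored
        res = benchmark(scores, truth)
        assert res.extended
        np.testing.assert_allclose(res.roc[0], [0, 0])
        np.testing.assert_allclose(res.roc[-1], [1, 1])
        assert np.all(np.diff(res.roc[:, 0]) >= -1e-12)
        assert np.all(np.diff(res.roc[:, 1]) >= -1e-12)
        assert res.pr[-1, 0] == pytest.approx(1.0)
        assert np.all(np.diff(res.pr[:, 0]) >= -1e-12)

    def test_self_loop_exclusion_candidate_count(self):
        rng = np.random.default_rng(7)
        truth = random_truth(6, rng)
        scores = rng.random((6, 6))
        with_loops = benchmark(scores, truth, include_self_loops=True)
        without = benchmark(scores, truth, include_self_loops=False)
        assert with_loops.n_candidates - without.n_candidates == 6

    def test_signed_mode_penalizes_wrong_sign(self):
        w = np.zeros((3, 3))
        w[1, 0] = 1.0
        truth = GRN(genes=["A", "B", "C"], weights=w)
        scores = np.full((3, 3), 0.1)
        scores[1, 0] = -5.0  # right edge, wrong sign
        unsigned = benchmark(scores, truth, signed=False)
        signed = benchmark(scores, truth, signed=True)
        assert unsigned.auroc == pytest.approx(1.0)
        assert signed.auroc < 1.0

    def test_edge_list_prediction(self):
        w = np.zeros((3, 3))
        w[1, 0] = 1.0
        truth = GRN(genes=["A", "B", "C"], weights=w)
        res = benchmark([("A", "B", 5.0), ("B", "C", 1.0)], truth)
        assert res.extended
        assert res.extra["n_scored"] == 2

    def test_unknown_gene_rejected(self):
        truth = random_truth(3, np.random.default_rng(8))
        with pytest.raises(BenchmarkError, match="unknown gene"):
            benchmark([("gX", "g1", 1.0)], truth)

    def test_empty_truth_rejected(self):
        truth = GRN(genes=["A", "B"], weights=np.zeros((2, 2)))
        truth.weights[0, 0] = 0.0
        with pytest.raises(BenchmarkError):
            benchmark(np.ones((2, 2)), truth)


class TestEda:
    def test_perfect_knockdown_rank(self):
        design = -0.8 * np.eye(3)
        fc = np.full((3, 3), -0.1)
        np.fill_diagonal(fc, -3.0)  # target always most reduced
        report = eda(fc, design)
        assert report.perturbation_rank == pytest.approx(1 / 3)

    def test_identical_replicates_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 5))
        fc = np.vstack([base, base])
        design = np.vstack([-0.8 * np.eye(5)[:3]] * 2)
        report = eda(fc, design)
        assert report.median_replicate_corr == pytest.approx(1.0)

    def test_constant_matrix_degenerate(self):
        fc = np.zeros((4, 5))
        design = -0.8 * np.eye(5)[:4]
        report = eda(fc, design)
        assert report.fraction_unique == pytest.approx(1 / 20)
        assert report.log10_condition_number is None

    def test_no_single_knockdowns_rank_undefined(self):
        fc = np.random.default_rng(1).normal(size=(2, 4))
        design = np.full((2, 4), -0.1)
        assert eda(fc, design).perturbation_rank is None

    def test_singular_values_sorted_nonnegative(self):
        rng = np.random.default_rng(2)
        fc = rng.normal(size=(6, 4))
        report = eda(fc, -0.8 * np.eye(4)[[0, 1, 2, 3, 0, 1]])
        sv = report.singular_values
        assert np.all(sv >= 0)
        assert np.all(np.diff(sv) <= 0)


class TestZscoreBaseline:
    def test_constructed_edge_ranked_first(self):
        # knocking down g0 halves g2 and nothing else responds
        rng = np.random.default_rng(3)
        n = 4
        design = -0.8 * np.eye(n)
        fc = rng.normal(0, 0.01, size=(n, n))
        fc[0, 2] = -1.0
        scores = zscore_baseline(fc, design)
        flat_order = np.argsort(-np.abs(scores), axis=None)
        assert flat_order[0] == np.ravel_multi_index((2, 0), (n, n))

    def test_constant_matrix_zero_scores(self):
        design = -0.8 * np.eye(3)
        scores = zscore_baseline(np.ones((3, 3)), design)
        np.testing.assert_allclose(scores, 0.0)

    def test_invariant_to_per_gene_affine_rescale(self):
        rng = np.random.default_rng(4)
        n = 5
        design = -0.8 * np.eye(n)
        fc = rng.normal(size=(n, n))
        a = zscore_baseline(fc, design)
        scale = rng.uniform(0.5, 2.0, n)
        shift = rng.normal(size=n)
        b = zscore_baseline(fc * scale + shift, design)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_unperturbed_regulator_column_unscored(self):
        design = np.zeros((2, 3))
        design[0, 0] = -0.8
        design[1, 1] = -0.8
        scores = zscore_baseline(np.random.default_rng(5).normal(size=(2, 3)), design)
        assert np.all(np.isnan(scores[:, 2]))
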