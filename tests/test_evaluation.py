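"""Network scoring: precision/recall, ROC, averaging, random baseline."""
import itertools

import numpy as np
import pytest

from ssmgrn import (ConnectivityMatrix, GeneNetwork, ROCResult, average_roc,
                    random_baseline_precision, roc_curve, score_network)


def _net(genes, pairs):
    return GeneNetwork(genes=tuple(genes), edges={p: 1.0 for p in pairs})


class TestScoreNetwork:
    def test_perfect_inference(self, toy_truth):
        r = score_network(toy_truth, toy_truth)
        assert (r.precision, r.recall) == (1.0, 1.0)

    def test_total_miss(self, toy_truth):
        inferred = _net(toy_truth.genes, [("g2", "g1"), ("g3", "g2")])
        assert score_network(inferred, toy_truth).precision == 0.0

    def test_hand_counted_toy(self):
        """5 inferred edges, 2 of them among the 10 true edges of a 5-gene
        truth: precision 0.4, recall 0.2."""
        genes = ("a", "b", "c", "d", "e")
        all_pairs = [(x, y) for x, y in itertools.permutations(genes, 2)]
        truth = _net(genes, all_pairs[:10])
        inferred = _net(genes, all_pairs[8:13])  # overlap = pairs 8, 9
        r = score_network(inferred, truth)
        assert (r.tp, r.fp, r.fn) == (2, 3, 8)
        assert r.precision == pytest.approx(0.4)
        assert r.recall == pytest.approx(0.2)

    def test_direction_must_match(self):
        truth = _net(("a", "b"), [("a", "b")])
        inferred = _net(("a", "b"), [("b", "a")])
        assert score_network(inferred, truth).tp == 0

    def test_gene_mismatch_reported(self, toy_truth):
        inferred = _net(("g1", "zzz"), [("g1", "zzz")])
        with pytest.raises(ValueError, match="zzz"):
            score_network(inferred, toy_truth)


class TestRocCurve:
    def test_perfect_separation_gives_auroc_one(self):
        C = np.array([[0.0, 0.9, 0.1], [0.05, 0.0, 0.8], [0.12, 0.02, 0.0]])
        truth = _net(("a", "b", "c"), [("b", "a"), ("c", "b")])
        roc = roc_curve(ConnectivityMatrix(C, ("a", "b", "c")), truth)
        assert roc.auroc == pytest.approx(1.0)

    def test_matches_exhaustive_threshold_enumeration(self):
        """Every (FPR, TPR) point from sweeping each distinct |C| as a
        threshold must appear, computed here by brute-force enumeration."""
        rng = np.random.default_rng(4)
        C = rng.standard_normal((3, 3))
        genes = ("a", "b", "c")
        truth = _net(genes, [("b", "a"), ("a", "c"), ("c", "b")])
        roc = roc_curve(ConnectivityMatrix(C, genes), truth)

        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        labels = {(i, j): (genes[j], genes[i]) in truth.edge_pairs
                  for i, j in pairs}
        P = sum(labels.values())
        N = len(pairs) - P
        expected = {(0.0, 0.0)}
        for th in {abs(C[i, j]) for i, j in pairs}:
            called = [(i, j) for i, j in pairs if abs(C[i, j]) >= th]
            tp = sum(labels[p] for p in called)
            fp = len(called) - tp
            expected.add((fp / N, tp / P))
        expected.add((1.0, 1.0))
        got = {(round(f, 12), round(t, 12)) for f, t in roc.points}
        assert got == {(round(f, 12), round(t, 12)) for f, t in expected}

    def test_null_scores_give_half_auroc(self):
        """Random truth vs random scores over 200 seeds: mean AUROC ~ 0.5."""
        aurocs = []
        genes = tuple(f"g{i}" for i in range(10))
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pairs = [(a, b) for a, b in itertools.permutations(genes, 2)]
            idx = rng.choice(len(pairs), size=20, replace=False)
            truth = _net(genes, [pairs[i] for i in idx])
            cm = ConnectivityMatrix(rng.standard_normal((10, 10)), genes)
            aurocs.append(roc_curve(cm, truth).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_endpoints_and_monotonicity(self, rng):
        genes = tuple("abcd")
        truth = _net(genes, [("a", "b"), ("c", "d"), ("d", "a")])
        roc = roc_curve(ConnectivityMatrix(rng.standard_normal((4, 4)), genes),
                        truth)
        pts = np.asarray(roc.points)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_auroc_invariant_under_monotone_transform(self, rng):
        genes = tuple("abcde")
        truth = _net(genes, [("a", "b"), ("b", "c"), ("d", "e"), ("e", "a")])
        C = rng.standard_normal((5, 5))
        r1 = roc_curve(ConnectivityMatrix(C, genes), truth)
        r2 = roc_curve(ConnectivityMatrix(C ** 3, genes), truth)  # |.|-monotone
        assert r1.auroc == pytest.approx(r2.auroc, abs=1e-12)

    def test_single_class_truth_rejected(self, rng):
        genes = ("a", "b")
        empty = GeneNetwork(genes=genes, edges={})
        with pytest.raises(ValueError, match="both"):
            roc_curve(ConnectivityMatrix(rng.standard_normal((2, 2)), genes),
                      empty)


class TestAverageRoc:
    def test_single_curve_identity_on_grid(self):
        curve = ROCResult(points=((0.0, 0.0), (0.5, 0.8), (1.0, 1.0)), auroc=0.65)
        grid = [0.0, 0.5, 1.0]
        avg = average_roc([curve], grid)
        assert avg.points == ((0.0, 0.0), (0.5, 0.8), (1.0, 1.0))

    def test_idempotent_on_identical_curves(self):
        curve = ROCResult(points=((0.0, 0.0), (0.3, 0.6), (1.0, 1.0)), auroc=0.65)
        one = average_roc([curve])
        two = average_roc([curve, curve])
        assert one.points == two.points
        assert one.auroc == pytest.approx(two.auroc)

    def test_linearity_diagonal_plus_perfect(self):
        diag = ROCResult(points=((0.0, 0.0), (1.0, 1.0)), auroc=0.5)
        perfect = ROCResult(points=((0.0, 0.0), (0.0, 1.0), (1.0, 1.0)), auroc=1.0)
        avg = average_roc([diag, perfect], np.linspace(0, 1, 1001))
        assert avg.auroc == pytest.approx(0.75, abs=0.01)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_roc([])


class TestRandomBaseline:
    def test_saturated_truth(self):
        genes = ("a", "b", "c")
        truth = _net(genes, list(itertools.permutations(genes, 2)))
        assert random_baseline_precision(truth, 3) == 1.0

    def test_empty_truth(self):
        truth = GeneNetwork(genes=("a", "b"), edges={})
        assert random_baseline_precision(truth, 2) == 0.0

    def test_fifty_gene_benchmark_density(self):
        """169 true edges among 50 genes: baseline 169/2450 ~ 6.9%."""
        genes = tuple(f"g{i}" for i in range(50))
        pairs = list(itertools.permutations(genes, 2))[:169]
        truth = _net(genes, pairs)
        assert random_baseline_precision(truth, 50) == pytest.approx(169 / 2450)
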