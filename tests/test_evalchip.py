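"""Tests of peak assignment, ranking evaluation and Fisher overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tissuegrn as tg

from conftest import make_edge_list


def annotation(rows):
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                     "strand"]).set_index("gene")
    return tg.GeneAnnotation(df)


def peaks(rows):
    return tg.PeakSet(pd.DataFrame(rows, columns=["chrom", "summit"]))


class TestAssignPeakTargets:
    ANN = [("gA", "chr1", 50_001, 52_000, "+"),
           ("gB", "chr1", 200_001, 202_000, "-"),
           ("gC", "chr2", 50_001, 52_000, "+")]

    def test_summit_5kb_upstream_included(self):
        # gene span starts at 0-based 50_000; summit 5_000 bp upstream
        got = tg.assign_peak_targets(peaks([("chr1", 45_000)]),
                                     annotation(self.ANN))
        assert got == {"gA"}

    def test_summit_just_outside_window_excluded(self):
        # nearest span coordinate is 0-based 50_000; 10_001 bp away
        got = tg.assign_peak_targets(peaks([("chr1", 39_999)]),
                                     annotation(self.ANN))
        assert got == set()

    def test_summit_exactly_at_window_included(self):
        got = tg.assign_peak_targets(peaks([("chr1", 40_000)]),
                                     annotation(self.ANN))
        assert got == {"gA"}

    def test_summit_inside_gene_body_included(self):
        got = tg.assign_peak_targets(peaks([("chr1", 51_000)]),
                                     annotation(self.ANN))
        assert got == {"gA"}

    def test_chromosomes_kept_separate(self):
        got = tg.assign_peak_targets(peaks([("chr2", 51_000)]),
                                     annotation(self.ANN))
        assert got == {"gC"}

    def test_gff3_bed_roundtrip(self, tmp_path):
        ann = annotation(self.ANN)
        ann.to_gff3(tmp_path / "g.gff3")
        back = tg.GeneAnnotation.from_gff3(tmp_path / "g.gff3")
        pd.testing.assert_frame_equal(back.table, ann.table)
        pk = peaks([("chr1", 45_000), ("chr2", 51_000)])
        pk.to_bed(tmp_path / "p.bed")
        back_pk = tg.PeakSet.from_bed(tmp_path / "p.bed")
        assert list(back_pk.table["summit"]) == [45_000, 51_000]


class TestPredictedTargets:
    def test_absent_tf_yields_empty_set(self, toy_grn):
        assert tg.predicted_targets(toy_grn, "TF9", 100) == set()

    def test_full_network_yields_all_targets(self, toy_grn):
        assert tg.predicted_targets(toy_grn, "TF1", len(toy_grn)) == \
            {"G1", "G2", "G3", "G4", "TF2"}

    def test_nested_sizes_give_nested_sets(self, toy_grn):
        sizes = [2, 5, 8, 10]
        sets = [tg.predicted_targets(toy_grn, "TF1", k) for k in sizes]
        for a, b in zip(sets, sets[1:]):
            assert a <= b


def brute_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_aupr(scores, labels):
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    p_total = sum(labels)
    area = prev_recall = 0.0
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]]
            fp += not labels[order[j]]
            j += 1
        recall = tp / p_total
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestEvaluateRanking:
    @staticmethod
    def _truth(tf, positives, universe):
        return tg.PositiveTargetSet(tf, set(positives), set(universe))

    def test_perfect_separation(self):
        grn = make_edge_list([("T", "a", 0.9), ("T", "b", 0.8)])
        truth = self._truth("T", {"a", "b"}, {"a", "b", "c", "d"})
        rep = tg.evaluate_ranking(grn, truth)
        assert rep.auroc == 1.0
        assert rep.aupr == 1.0

    def test_inverted_separation(self):
        grn = make_edge_list([("T", "c", 0.9), ("T", "d", 0.8)])
        truth = self._truth("T", {"a", "b"}, {"a", "b", "c", "d"})
        assert tg.evaluate_ranking(grn, truth).auroc == 0.0

    def test_six_gene_hand_case(self):
        scores = [0.9, 0.8, 0.4, 0.3, 0.2, 0.1]
        genes = list("abcdef")
        grn = make_edge_list([("T", g, s) for g, s in zip(genes, scores)])
        truth = self._truth("T", {"a", "c", "e"}, set(genes))
        rep = tg.evaluate_ranking(grn, truth)
        labels = [g in truth.positives for g in genes]
        assert rep.auroc == pytest.approx(brute_auroc(scores, labels))
        assert rep.aupr == pytest.approx(brute_aupr(scores, labels))
        assert rep.auroc == pytest.approx(6 / 9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = rng.choice(np.round(rng.uniform(0, 1, 8), 3), size=n)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[-1] = False
        assert tg.auroc_score(scores, labels) == \
            pytest.approx(brute_auroc(scores, labels))
        assert tg.aupr_score(scores, labels) == \
            pytest.approx(brute_aupr(scores, labels))

    def test_auroc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 50)
        labels = rng.random(50) < 0.3
        labels[0] = True
        labels[1] = False
        a = tg.auroc_score(scores, labels)
        assert tg.auroc_score(np.exp(3 * scores), labels) == pytest.approx(a)

    def test_genes_without_edges_form_tied_block(self):
        grn = make_edge_list([("T", "a", 0.9)])
        truth = self._truth("T", {"a", "b"}, {"a", "b", "c", "d", "e"})
        rep = tg.evaluate_ranking(grn, truth)
        # positive a above everything (3 concordant); positive b tied with
        # c, d, e at score 0 -> 1.5 of 3; AUROC = 4.5/6
        assert rep.auroc == pytest.approx(4.5 / 6)


class TestPermutationBaseline:
    def test_mean_auroc_centers_on_half(self, toy_grn):
        universe = {"G1", "G2", "G3", "G4", "G5", "G6", "TF2"}
        truth = tg.PositiveTargetSet("TF1", {"G1", "G3", "G5"}, universe)
        m_auroc, _ = tg.permutation_baseline(toy_grn, truth, n_perm=4000,
                                             seed=0)
        p, n = 3, 4
        sd_single = np.sqrt((p + n + 1) / (12 * p * n))
        assert abs(m_auroc - 0.5) < 3 * sd_single / np.sqrt(4000)

    def test_tiny_instance_matches_exact_enumeration(self, toy_grn):
        # average both areas over every possible positive set of size 3
        universe = {"G1", "G2", "G3", "G4", "G5", "G6", "TF2"}
        truth = tg.PositiveTargetSet("TF1", {"G1", "G3", "G5"}, universe)
        m_auroc, m_aupr = tg.permutation_baseline(toy_grn, truth,
                                                  n_perm=4000, seed=0)
        genes = sorted(universe - {"TF1"})
        scores = toy_grn.weight_of("TF1", genes).to_numpy()
        exp_auroc, exp_aupr = [], []
        for pos in itertools.combinations(range(len(genes)), 3):
            labels = np.zeros(len(genes), dtype=bool)
            labels[list(pos)] = True
            exp_auroc.append(tg.auroc_score(scores, labels))
            exp_aupr.append(tg.aupr_score(scores, labels))
        assert m_auroc == pytest.approx(np.mean(exp_auroc), abs=0.01)
        assert m_aupr == pytest.approx(np.mean(exp_aupr), abs=0.01)

    def test_mean_aupr_matches_prevalence_on_large_instance(self):
        # the analytic expectation |positives| / |universe| holds for a
        # random ranking once the universe is large and scores distinct
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(1000)]
        rows = [("T", g, float(w)) for g, w in
                zip(genes, rng.uniform(0.01, 1.0, size=1000))]
        grn = make_edge_list(rows)
        truth = tg.PositiveTargetSet("T", set(genes[:100]), set(genes))
        _, m_aupr = tg.permutation_baseline(grn, truth, n_perm=1000, seed=0)
        assert abs(m_aupr - 100 / 1000) < 0.015

    def test_single_permutation_reproducible(self, toy_grn):
        universe = {"G1", "G2", "G3", "G4"}
        truth = tg.PositiveTargetSet("TF1", {"G1"}, universe)
        a = tg.permutation_baseline(toy_grn, truth, n_perm=1, seed=42)
        b = tg.permutation_baseline(toy_grn, truth, n_perm=1, seed=42)
        assert a == b


def exhaustive_fisher_tail(n_universe, n_chip, n_pred, observed):
    """Upper-tail hypergeometric probability by direct enumeration."""
    from math import comb
    total = 0
    for k in range(observed, min(n_chip, n_pred) + 1):
        total += comb(n_chip, k) * comb(n_universe - n_chip, n_pred - k)
    return total / comb(n_universe, n_pred)


class TestFisherOverlap:
    def test_complete_overlap_probability(self):
        universe = set(range(20))
        pred = chip = set(range(10))
        _, odds, p = tg.fisher_overlap(pred, chip, universe)
        from math import comb
        assert p == pytest.approx(1 / comb(20, 10))
        assert odds == float("inf")

    def test_zero_overlap_is_depleted_not_enriched(self):
        universe = set(range(20))
        _, _, p = tg.fisher_overlap(set(range(10)), set(range(10, 20)),
                                    universe)
        assert p >= 0.99

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_u = int(rng.integers(10, 50))
        universe = set(range(n_u))
        pred = set(rng.choice(n_u, size=int(rng.integers(1, n_u)),
                              replace=False))
        chip = set(rng.choice(n_u, size=int(rng.integers(1, n_u)),
                              replace=False))
        table, _, p = tg.fisher_overlap(pred, chip, universe)
        assert p == pytest.approx(
            exhaustive_fisher_tail(n_u, len(chip), len(pred), table[0, 0]))

    def test_null_calibration(self):
        # independent random sets: small p-values occur at roughly their
        # nominal rate (discreteness makes the test conservative)
        rng = np.random.default_rng(12)
        universe = set(range(60))
        hits = 0
        for _ in range(1000):
            pred = set(rng.choice(60, size=20, replace=False))
            chip = set(rng.choice(60, size=20, replace=False))
            _, _, p = tg.fisher_overlap(pred, chip, universe)
            hits += p < 0.05
        assert hits <= 70


class TestSizeSweep:
    def test_universal_positives_give_full_overlap(self, toy_grn):
        universe = {"G1", "G2", "G3", "G4", "TF2"}
        truth = tg.PositiveTargetSet("TF1", set(universe), set(universe))
        out = tg.size_sweep(toy_grn, truth, sizes=[2, 5, 10])
        assert all(v == 100.0 for v in out.values())

    def test_absent_tf_flagged_undefined(self, toy_grn):
        truth = tg.PositiveTargetSet("TF9", {"G1"}, {"G1", "G2"})
        with pytest.warns(UserWarning):
            out = tg.size_sweep(toy_grn, truth, sizes=[5])
        assert out[5] is None

    def test_precision_declines_with_size_on_simulated_truth(self,
                                                             small_dataset):
        base, nets, _ = small_dataset
        # score true edges of tissue 1 high with noise, others low
        rng = np.random.default_rng(0)
        net = nets[0]
        rows = []
        true_set = net.edge_set()
        for tf in sorted(base.tf_ids):
            for g in sorted(base.gene_ids):
                if g == tf:
                    continue
                s = rng.uniform(0.5, 1.0) if (tf, g) in true_set \
                    else rng.uniform(0.0, 0.6)
                rows.append((tf, g, s))
        grn = make_edge_list(rows, tf_ids=base.tf_ids)
        tf = max(base.tf_ids, key=lambda t: len(net.targets_of(t)))
        truth = tg.PositiveTargetSet(tf, net.targets_of(tf),
                                     set(base.gene_ids) - {tf})
        out = tg.size_sweep(grn, truth, sizes=[50, 200, len(grn)])
        vals = [v for v in out.values() if v is not None]
        assert vals == sorted(vals, reverse=True)
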