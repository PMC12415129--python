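"""Confidence-thresholded classification, Venn regions, hypergeometric test."""

import itertools
import math

import numpy as np
import pytest

import gcgrader as g
from gcgrader.errors import DomainError, QuantificationError
from gcgrader.quantify import (
    classify_with_threshold,
    hypergeom_overlap_test,
    overlap_report,
    venn_regions,
)


def probs(pairs):
    return np.asarray(pairs, dtype=float)


class TestThreshold:
    def test_above_threshold_is_fs(self):
        r = classify_with_threshold(probs([[0.04, 0.96]]), 0.95)
        assert list(r.labels) == ["FS"]

    def test_below_threshold_is_ambiguous(self):
        r = classify_with_threshold(probs([[0.06, 0.94]]), 0.95)
        assert list(r.labels) == ["ambiguous"]

    def test_published_monotocous_percentage_arithmetic(self):
        """160 confident FS and 1,413 confident NFS -> 10.17% FS among the
        1,573 confident cells, with 15 ambiguous cells excluded."""
        P = [[0.01, 0.99]] * 160 + [[0.99, 0.01]] * 1413 + [[0.5, 0.5]] * 15
        r = classify_with_threshold(probs(P), 0.95)
        assert (r.n_fs, r.n_nfs, r.n_ambiguous) == (160, 1413, 15)
        assert round(r.fs_percentage, 2) == 10.17

    def test_counts_partition_all_cells(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0, 1, size=500)
        r = classify_with_threshold(probs(np.c_[1 - p1, p1]), 0.95)
        assert r.n_fs + r.n_nfs + r.n_ambiguous == 500

    def test_raising_threshold_never_reduces_ambiguity(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0, 1, size=400)
        P = probs(np.c_[1 - p1, p1])
        prev = -1
        for thr in (0.55, 0.7, 0.85, 0.95, 0.99):
            n_amb = classify_with_threshold(P, thr).n_ambiguous
            assert n_amb >= prev
            prev = n_amb

    def test_fs_percentage_invariant_to_cell_order(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0, 1, size=300)
        P = probs(np.c_[1 - p1, p1])
        r1 = classify_with_threshold(P, 0.95)
        r2 = classify_with_threshold(P[rng.permutation(300)], 0.95)
        assert r1.fs_percentage == pytest.approx(r2.fs_percentage)

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(DomainError):
            classify_with_threshold(probs([[0.9, 0.9]]), 0.95)

    def test_threshold_domain(self):
        with pytest.raises(DomainError):
            classify_with_threshold(probs([[0.5, 0.5]]), 0.4)

    def test_per_sample_summary(self):
        P = probs([[0.01, 0.99], [0.99, 0.01], [0.5, 0.5], [0.02, 0.98]])
        r = classify_with_threshold(
            P, 0.95, cell_ids=list("abcd"), sample=["s1", "s1", "s2", "s2"]
        )
        s = r.summary.set_index("sample")
        assert s.loc["s1", "n_fs"] == 1 and s.loc["s1", "n_nfs"] == 1
        assert s.loc["s2", "n_ambiguous"] == 1
        assert s.loc["s2", "fs_pct_confident"] == 100.0


class TestWithinSampleDGE:
    def test_all_ambiguous_is_error(self, small_sim):
        _, samples, _ = small_sim
        pm = g.per_million_normalize(samples["monotocous"])
        P = probs([[0.5, 0.5]] * pm.n_obs)
        r = classify_with_threshold(P, 0.95, cell_ids=list(pm.obs_names))
        with pytest.raises(QuantificationError):
            g.within_sample_dge(pm, r)

    def test_label_shuffled_null_yields_no_degs(self, small_sim):
        """Random confident labels over one homogeneous sample: essentially
        nothing passes both the FDR and fold-change gates."""
        cfg, samples, _ = small_sim
        cfg0 = g.SimulationConfig(
            n_cells_per_sample=(400, 400), n_genes=200, n_deg=0,
            fs_fraction=(0.0, 0.0), seed=33,
        )
        s0, _ = g.generate_two_sample_dataset(cfg0)
        pm = g.per_million_normalize(s0["monotocous"])
        rng = np.random.default_rng(5)
        fs = rng.random(pm.n_obs) < 0.5
        P = probs(np.c_[np.where(fs, 0.01, 0.99), np.where(fs, 0.99, 0.01)])
        r = classify_with_threshold(P, 0.95, cell_ids=list(pm.obs_names))
        table = g.within_sample_dge(pm, r)
        assert int(table["significant"].sum()) <= 2


class TestVenn:
    def test_hand_enumeration(self):
        regions = venn_regions({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert regions == {
            "a_only": 1, "b_only": 1, "c_only": 0,
            "ab_only": 1, "ac_only": 0, "bc_only": 0, "abc": 1,
        }

    def test_identical_sets(self):
        s = set(range(12))
        regions = venn_regions(s, s, s)
        assert regions["abc"] == 12
        assert sum(v for k, v in regions.items() if k != "abc") == 0

    def test_disjoint_sets(self):
        regions = venn_regions({1}, {2}, {3})
        assert regions["a_only"] == regions["b_only"] == regions["c_only"] == 1
        assert regions["ab_only"] == regions["ac_only"] == regions["bc_only"] == 0
        assert regions["abc"] == 0

    def test_counts_sum_to_union_and_relabeling_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            A, B, C = (set(rng.integers(0, 30, size=rng.integers(0, 15))) for _ in range(3))
            regions = venn_regions(A, B, C)
            assert sum(regions.values()) == len(A | B | C)
            swapped = venn_regions(B, A, C)
            assert swapped["a_only"] == regions["b_only"]
            assert swapped["ac_only"] == regions["bc_only"]
            assert swapped["abc"] == regions["abc"]


class TestHypergeom:
    def test_zero_overlap_is_one(self):
        assert hypergeom_overlap_test(0, 5, 4, 10) == pytest.approx(1.0)

    def test_single_tail_term(self):
        # C(5,4) * C(5,0) / C(10,4) = 5/210
        p = hypergeom_overlap_test(4, 5, 4, 10)
        assert p == pytest.approx(5 / 210)

    def test_matches_enumeration_small_universes(self):
        """Upper tail equals direct enumeration over all draws, N <= 15."""
        for N in (6, 10, 15):
            for K in (0, 2, 5, N):
                for n in (0, 3, min(7, N)):
                    for k in range(0, min(K, n) + 1):
                        expected = sum(
                            math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                            for j in range(k, min(K, n) + 1)
                        )
                        assert hypergeom_overlap_test(k, K, n, N) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_impossible_counts_rejected(self):
        with pytest.raises(DomainError):
            hypergeom_overlap_test(5, 4, 4, 10)
        with pytest.raises(DomainError):
            hypergeom_overlap_test(1, 11, 4, 10)


class TestOverlapReport:
    def test_pairwise_tests_against_training_set(self):
        result = overlap_report(
            ["g1", "g2", "g3"], ["g2", "g3", "g4", "g5"], ["g3"], universe=50
        )
        assert result.regions["abc"] == 1
        pairs = dict(zip(result.pairwise["pair"], result.pairwise["overlap"]))
        assert pairs == {"model_training|polytocous": 2, "model_training|monotocous": 1}
        assert (result.pairwise["pvalue"] <= 1).all()
        expected = hypergeom_overlap_test(2, 3, 4, 50)
        got = result.pairwise.set_index("pair").loc[
            "model_training|polytocous", "pvalue"
        ]
        assert got == pytest.approx(expected)
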