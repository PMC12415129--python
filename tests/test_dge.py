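"""Welch t-test, BH adjustment, and gene ranking against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

import gcgrader as g
from gcgrader.dge import rank_genes, significant_genes, welch_t, bh_adjust, DEGThresholds
from gcgrader.errors import DomainError, InsufficientDataError, SchemaError
from gcgrader.simulate import NORM_STATE_KEY


def hand_welch(a, b):
    """Textbook Welch formula, written independently of the implementation."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def step_up_bh(pvals):
    """Brute-force BH step-up: q_i = min over j>=rank(i) of m*p_(j)/j, capped."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


class TestWelch:
    def test_identical_groups_null(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_example(self):
        t, df, p = welch_t([1, 2, 3, 4], [5, 6, 7, 8])
        ht, hdf, hp = hand_welch([1, 2, 3, 4], [5, 6, 7, 8])
        assert t == pytest.approx(ht, abs=1e-12)
        assert df == pytest.approx(hdf, abs=1e-12)
        assert p == pytest.approx(hp, abs=1e-12)

    def test_zero_variance_equal_means(self):
        t, df, p = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_matches_hand_formula_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nb)
            t, df, p = welch_t(a, b)
            ht, hdf, hp = hand_welch(a, b)
            assert abs(t - ht) < 1e-10 and abs(df - hdf) < 1e-10 and abs(p - hp) < 1e-10
            # scipy as a second, fully independent implementation
            st, sp_ = stats.ttest_ind(a, b, equal_var=False)
            assert abs(t - st) < 1e-10 and abs(p - sp_) < 1e-10

    def test_group_too_small(self):
        with pytest.raises(InsufficientDataError):
            welch_t([1.0], [2.0, 3.0])


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_subsets_of_eight_match_enumeration(self):
        rng = np.random.default_rng(1)
        pool = rng.uniform(0, 1, size=8)
        for r in range(1, 9):
            for subset in itertools.combinations(range(8), r):
                p = [pool[i] for i in subset]
                assert bh_adjust(p) == pytest.approx(step_up_bh(p), abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


def _pm_adata(X, prefix):
    X = np.asarray(X, dtype=float)
    ad = AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=[f"{prefix}{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]),
    )
    ad.uns[NORM_STATE_KEY] = "raw"
    return g.per_million_normalize(ad)


class TestRankGenes:
    def _pair(self, seed=0, n=60, m=25, shift_gene=None, shift=4.0):
        rng = np.random.default_rng(seed)
        A = rng.poisson(8.0, size=(n, m)).astype(float) + 1
        B = rng.poisson(8.0, size=(n, m)).astype(float) + 1
        if shift_gene is not None:
            A[:, shift_gene] *= shift
        return _pm_adata(A, "a"), _pm_adata(B, "b")

    def test_significance_requires_both_gates(self, study_run):
        _, results, _ = study_run
        t = results.deg_table
        flagged = t["significant"]
        recomputed = t["tested"] & (t["qval"] <= 0.01) & (t["log2fc"].abs() >= 1.5)
        assert (flagged == recomputed).all()
        # a gene clearing the fold-change gate but not the FDR gate stays out
        assert not t.loc[(t.qval > 0.01) & (t.log2fc.abs() >= 1.5), "significant"].any()

    def test_group_swap_antisymmetry(self):
        a, b = self._pair(seed=3, shift_gene=2)
        t_ab = rank_genes(a, b).set_index("gene")
        t_ba = rank_genes(b, a).set_index("gene")
        genes = t_ab.index
        assert np.allclose(t_ab["log2fc"], -t_ba.loc[genes, "log2fc"], atol=1e-9)
        assert np.allclose(t_ab["t"], -t_ba.loc[genes, "t"], atol=1e-9)
        assert np.allclose(t_ab["pval"], t_ba.loc[genes, "pval"], atol=1e-12)
        assert np.allclose(t_ab["qval"], t_ba.loc[genes, "qval"], atol=1e-12)

    def test_cell_order_invariance(self):
        a, b = self._pair(seed=4, shift_gene=1)
        t1 = rank_genes(a, b)
        perm = np.random.default_rng(0).permutation(a.n_obs)
        a2 = a[perm].copy()
        a2.uns[NORM_STATE_KEY] = "per_million"
        t2 = rank_genes(a2, b)
        pd.testing.assert_frame_equal(t1.reset_index(drop=True), t2.reset_index(drop=True))

    def test_gene_set_mismatch(self):
        a, b = self._pair()
        b2 = b[:, list(b.var_names[:-1])].copy()
        b2.uns[NORM_STATE_KEY] = "per_million"
        with pytest.raises(SchemaError):
            rank_genes(a, b2)

    def test_planted_recovery_on_simulator(self):
        """500 cells per state, 40 planted DEGs at |log2FC| = 2, dropout 0:
        within-state contrast flags nearly all planted genes and nearly no
        background."""
        cfg = g.SimulationConfig(
            n_cells_per_sample=(500, 500), n_genes=200, n_deg=40,
            planted_log2fc=2.0, dropout_rate=0.0, fs_fraction=(0.0, 1.0), seed=8,
        )
        samples, truth = g.generate_two_sample_dataset(cfg)
        # sample 2 is pure FS, sample 1 pure NFS: a clean two-group contrast
        a = g.per_million_normalize(samples["polytocous"])
        b = g.per_million_normalize(samples["monotocous"])
        table = rank_genes(a, b)
        found = set(significant_genes(table))
        planted = set(truth.deg_genes)
        assert len(found & planted) >= 36
        assert len(found - planted) <= 2

    def test_round_trip_table(self, tmp_path):
        a, b = self._pair(seed=5, shift_gene=0)
        t = rank_genes(a, b)
        path = tmp_path / "deg.tsv"
        g.dge.write_deg_table(t, path)
        back = g.dge.read_deg_table(path)
        assert list(back["gene"]) == list(t["gene"])
        assert np.allclose(back["log2fc"], t["log2fc"])
        assert (back["significant"] == t["significant"]).all()


def test_null_calibration_type_one_error():
    """Random splits of one homogeneous population: the raw p <= 0.05
    fraction over 20 replicates x 200 genes stays at the nominal rate."""
    cfg = g.SimulationConfig(
        n_cells_per_sample=(400, 400), n_genes=200, n_deg=0,
        fs_fraction=(0.0, 0.0), seed=21,
    )
    samples, _ = g.generate_two_sample_dataset(cfg)
    pm = g.per_million_normalize(samples["monotocous"])
    rng = np.random.default_rng(77)
    hits, total = 0, 0
    for _ in range(20):
        perm = rng.permutation(pm.n_obs)
        a = pm[perm[:200]].copy()
        b = pm[perm[200:]].copy()
        a.uns[NORM_STATE_KEY] = b.uns[NORM_STATE_KEY] = "per_million"
        table = rank_genes(a, b)
        pv = table.loc[table["tested"], "pval"]
        hits += int((pv <= 0.05).sum())
        total += len(pv)
    frac = hits / total
    assert abs(frac - 0.05) <= 0.015
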