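"""Count normalization, NB differential expression and the RNA-active rule."""

import numpy as np
import pandas as pd
import pytest

import phagoscreen as ps
from phagoscreen import rna
from phagoscreen.errors import InputError


class TestSizeFactors:
    def test_doubled_well(self):
        m = np.array([[10, 20], [5, 10], [8, 16]])
        f = rna.size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_identical_wells_unity(self):
        m = np.tile([[10], [20], [30]], (1, 4))
        assert rna.size_factors(m) == pytest.approx(np.ones(4))

    def test_worked_median_of_ratios(self):
        m = np.array([[10, 20], [20, 40], [30, 60]])
        assert rna.size_factors(m) == pytest.approx([0.70710678, 1.41421356])

    def test_gene_order_invariant(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(20, size=(50, 6)) + 1
        f1 = rna.size_factors(m)
        f2 = rna.size_factors(m[rng.permutation(50)])
        assert f1 == pytest.approx(f2)

    def test_scaling_one_well_scales_factor_ratio(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(20, size=(100, 4)) + 1
        f1 = rna.size_factors(m)
        m2 = m.copy()
        m2[:, 2] *= 3
        f2 = rna.size_factors(m2)
        assert f2[2] / f2[0] == pytest.approx(3 * f1[2] / f1[0], rel=1e-9)

    def test_fallback_warns_without_all_nonzero_gene(self):
        m = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        with pytest.warns(UserWarning, match="size factors"):
            f = rna.size_factors(m)
        assert np.all(f > 0)


class TestBHAdjust:
    def test_step_up_hand_arithmetic(self):
        assert rna.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert rna.bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert rna.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        assert (rna.bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            rna.bh_adjust([0.5, 1.5])


class TestNBTest:
    def test_group_overlap_rejected(self):
        m = np.ones((5, 6))
        with pytest.raises(InputError):
            rna.nb_test(m, [0, 1, 2], [2, 3, 4])

    def test_all_zero_gene(self):
        rng = np.random.default_rng(3)
        m = rng.poisson(10, size=(20, 8))
        m[5] = 0
        de = rna.nb_test(m, [0, 1, 2, 3], [4, 5, 6, 7])
        assert de.loc[5, "p_value"] == 1.0
        assert de.loc[5, "log2_fold_change"] == 0.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        m = rng.poisson(30, size=(100, 8))
        a, b = [0, 1, 2, 3], [4, 5, 6, 7]
        d1 = rna.nb_test(m, a, b)
        d2 = rna.nb_test(m, b, a)
        assert np.allclose(d1["log2_fold_change"], -d2["log2_fold_change"], atol=1e-10)
        assert np.allclose(d1["p_value"], d2["p_value"], atol=1e-10)

    def test_null_false_positive_rate_near_nominal(self):
        """Two identically drawn groups: ~5% of genes at p < 0.05."""
        cfg = ps.CountsSimConfig(n_genes=4000, n_dmso_wells=8, compounds=0,
                                 mean_log_mu=4.0, mean_log_sigma=1.0, seed=7)
        counts, meta, _ = ps.simulate_counts(cfg)
        dm = meta.loc[meta["role"] == "dmso", "well"].tolist()
        de = rna.nb_test(counts, dm[:4], dm[4:])
        assert (de["p_value"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_planted_fold_change_recovered(self):
        """A 4-fold gene at mean 100, dispersion 0.1, n = 4 vs 4 estimates
        log2FC within +-0.5 of 2."""
        rng = np.random.default_rng(11)
        r = 1 / 0.1
        base = rng.negative_binomial(r, r / (r + 100.0), size=(50, 8)).astype(float)
        up = base.copy()
        up[:, :4] = rng.negative_binomial(r, r / (r + 400.0), size=(50, 4))
        de = rna.nb_test(up, [0, 1, 2, 3], [4, 5, 6, 7], factors=np.ones(8))
        assert de["log2_fold_change"].median() == pytest.approx(2.0, abs=0.5)
        assert (de["p_value"] < 0.05).mean() > 0.9

    def test_matches_deseq2_direction_on_small_fixture(self):
        """Independent cross-check: log2FC estimates agree with pyDESeq2's
        on a small planted-DE matrix (rank correlation, strong-gene sign)."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = ps.CountsSimConfig(n_genes=300, n_dmso_wells=4, compounds=1, active=1,
                                 n_de_genes=60, de_log2fc=2.0, mean_log_mu=4.0,
                                 mean_log_sigma=1.0, seed=21)
        counts, meta, truth = ps.simulate_counts(cfg)
        cw = meta.loc[meta["role"] == "compound", "well"].tolist()
        dw = meta.loc[meta["role"] == "dmso", "well"].tolist()
        mine = rna.nb_test(counts, cw, dw).set_index("gene")

        adata_counts = counts[dw + cw].T
        clinical = pd.DataFrame(
            {"condition": ["dmso"] * len(dw) + ["compound"] * len(cw)},
            index=adata_counts.index,
        )
        dds = DeseqDataSet(counts=adata_counts, metadata=clinical,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "compound", "dmso"], quiet=True)
        ds.summary()
        theirs = ds.results_df["log2FoldChange"]

        both = mine["log2_fold_change"].to_frame("mine").join(theirs.rename("deseq2")).dropna()
        rho = both["mine"].corr(both["deseq2"], method="spearman")
        assert rho > 0.9
        strong = both[both["deseq2"].abs() > 1.5]
        assert (np.sign(strong["mine"]) == np.sign(strong["deseq2"])).all()


class TestCountDeg:
    def test_empty(self):
        assert rna.count_deg(pd.DataFrame()) == 0

    def test_strict_boundaries(self):
        de = pd.DataFrame({"adjusted_p": [0.1, 0.09, 0.09], "log2_fold_change": [2.0, 1.0, 1.01]})
        assert rna.count_deg(de) == 1  # padj==0.1 and |lfc|==1 both excluded

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        de = pd.DataFrame({"adjusted_p": rng.uniform(size=500),
                           "log2_fold_change": rng.normal(scale=2, size=500)})
        assert rna.count_deg(de, 0.05, 1.5) <= rna.count_deg(de, 0.1, 1.0)
        assert rna.count_deg(de, 0.1, 2.0) <= rna.count_deg(de, 0.1, 1.0)

    def test_planted_de_genes_counted(self):
        cfg = ps.CountsSimConfig(n_genes=2000, n_dmso_wells=4, compounds=1, active=1,
                                 n_de_genes=300, de_log2fc=2.0, dispersion=0.1,
                                 mean_log_mu=4.0, mean_log_sigma=1.0, seed=3)
        counts, meta, _ = ps.simulate_counts(cfg)
        de = rna.nb_test(counts, meta.loc[meta["role"] == "compound", "well"].tolist(),
                         meta.loc[meta["role"] == "dmso", "well"].tolist())
        assert 250 <= rna.count_deg(de) <= 310


class TestDmsoNull:
    def test_nearest_rank_percentile(self):
        assert rna.nearest_rank_percentile([0, 0, 1, 1, 2, 2, 3, 3, 4, 20], 95) == 20

    def test_degenerate_null_threshold_zero(self):
        assert rna.nearest_rank_percentile([0] * 10, 95) == 0
        call = rna.call_rna_active("c", 1, np.zeros(10), 0.0)
        assert call.active

    def test_deterministic_given_seed(self):
        cfg = ps.CountsSimConfig(n_genes=400, n_dmso_wells=10, compounds=0,
                                 n_de_genes=0, seed=1)
        counts, meta, _ = ps.simulate_counts(cfg)
        dm = meta["well"].tolist()
        n1, t1 = rna.dmso_null(counts, dm, 4, n_draws=10, seed=42)
        n2, t2 = rna.dmso_null(counts, dm, 4, n_draws=10, seed=42)
        assert np.array_equal(n1, n2) and t1 == t2

    def test_insufficient_wells_rejected(self):
        cfg = ps.CountsSimConfig(n_genes=100, n_dmso_wells=6, compounds=0,
                                 n_de_genes=0, seed=1)
        counts, meta, _ = ps.simulate_counts(cfg)
        with pytest.raises(InputError):
            rna.dmso_null(counts, meta["well"].tolist(), 4, n_draws=5)


class TestCallRnaActive:
    def test_above_threshold_active(self):
        assert rna.call_rna_active("c", 30, np.arange(20), 18).active

    def test_equal_to_threshold_not_active(self):
        assert not rna.call_rna_active("c", 18, np.arange(20), 18).active


class TestOraEnrichment:
    def test_exact_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        p, k = rna.ora_enrichment(universe[:5], universe[:5], universe)
        assert k == 5
        from math import comb

        assert p == pytest.approx(1 / comb(20, 5))

    def test_no_overlap_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        p, k = rna.ora_enrichment(universe[:3], universe[50:53], universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_degs_equal_universe(self):
        universe = [f"g{i}" for i in range(10)]
        p, k = rna.ora_enrichment(universe, universe[:4], universe)
        assert k == 4 and p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            rna.ora_enrichment([], [], [])

    def test_non_subset_rejected(self):
        with pytest.raises(InputError):
            rna.ora_enrichment(["x"], ["a"], ["a", "b"])
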