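"""Morphotype classification, feature correlations and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import phagoscreen as ps
from phagoscreen import morphology, screen, simulate
from phagoscreen.errors import InputError, UndefinedSeparationError

unit = st.floats(0.0, 1.0)


class TestClassifyMorphotype:
    @pytest.mark.parametrize(
        "sol,ecc,expect",
        [
            (0.95, 0.20, "ameboid"),
            (0.50, 0.95, "ramified"),
            (0.95, 0.95, "ambiguous"),  # discordant corner
            (0.30, 0.30, "ambiguous"),
            (0.75, 0.70, "rod"),
        ],
    )
    def test_default_rule(self, sol, ecc, expect):
        assert morphology.classify_morphotype(sol, ecc) == expect

    @given(sol=unit, ecc=unit)
    def test_partition_of_feature_space(self, sol, ecc):
        """Every cell lands in exactly one of the four classes."""
        assert morphology.classify_morphotype(sol, ecc) in morphology.MORPHOTYPES

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            morphology.classify_morphotype(1.5, 0.5)

    def test_tertile_thresholds_from_dmso(self):
        rng = np.random.default_rng(3)
        cells = pd.DataFrame(
            {"solidity": rng.uniform(0.4, 1.0, 300), "eccentricity": rng.uniform(0.2, 0.95, 300)}
        )
        thr = morphology.dmso_tertile_thresholds(cells)
        assert thr.derivation == "dmso_tertiles"
        assert thr.solidity_low == pytest.approx(np.quantile(cells["solidity"], 1 / 3))
        labels = morphology.classify_morphotype(
            cells["solidity"].to_numpy(), cells["eccentricity"].to_numpy(), thr
        )
        assert set(labels) <= set(morphology.MORPHOTYPES)


class TestCompoundPhenotypes:
    def test_all_ramified_fractions(self, default_screen):
        _, fields, _ = default_screen
        sub = fields[fields["role"] == "compound"].head(24)
        cells = pd.DataFrame(
            {"compound": sub["compound"].iloc[0], "solidity": [0.4] * 5, "eccentricity": [0.9] * 5}
        )
        pheno = morphology.compound_phenotypes(sub, cells)
        row = pheno.set_index("compound").loc[cells["compound"].iloc[0]]
        assert row["frac_ramified"] == pytest.approx(1.0)
        assert row["frac_ameboid"] == pytest.approx(0.0)
        assert row["fractions_defined"]

    def test_missing_cells_flagged_undefined(self, default_screen):
        _, fields, _ = default_screen
        pheno = morphology.compound_phenotypes(fields[fields["role"] == "compound"].head(48))
        assert not pheno["fractions_defined"].any()
        assert pheno["frac_ramified"].isna().all()

    def test_identical_compounds_identical_phenotypes(self):
        f = pd.DataFrame(
            [
                dict(plate="P1", well="A01", role="compound", compound=c, field_index=i,
                     cell_count=10, synaptosome_area=50, mean_solidity=0.7,
                     mean_eccentricity=0.6, mean_iba1=1.0)
                for c in ("C1", "C2") for i in range(3)
            ]
        )
        pheno = morphology.compound_phenotypes(f).drop(columns="compound")
        assert (pheno.iloc[0].fillna(-1) == pheno.iloc[1].fillna(-1)).all()

    def test_eccentricity_shift_override_ranks_first(self):
        """A compound given a strong eccentricity shift (ramifying, IBA1-
        lowering treatment) tops the mean-eccentricity ranking."""
        cfg = ps.ScreenSimConfig(
            n_compounds=40, toxic_fraction=0.0, inhibitor_fraction=0.0,
            morph_overrides={"C0010": (-0.10, 0.20, -0.30)}, seed=13,
        )
        fields, _ = ps.simulate_screen(cfg)
        pheno = morphology.compound_phenotypes(fields)
        top = pheno.sort_values("mean_eccentricity").iloc[-1]
        assert top["compound"] == "C0010"
        assert pheno.set_index("compound").loc["C0010", "mean_iba1"] == pytest.approx(0.7, abs=0.1)


class TestFeatureCorrelation:
    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"x": [0.1, 0.2, 0.3, 0.4], "y": [0.9, 0.8, 0.7, 0.6]})
        r, p = morphology.feature_correlation(df, "x", "y")
        assert r == pytest.approx(-1.0)

    def test_printed_triple(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 5.0]})
        r, _ = morphology.feature_correlation(df, "x", "y")
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        r_xy, p_xy = morphology.feature_correlation(df, "x", "y")
        r_yx, p_yx = morphology.feature_correlation(df, "y", "x")
        assert r_xy == pytest.approx(r_yx) and p_xy == pytest.approx(p_yx)
        df["x2"] = 5.0 * df["x"] + 3.0
        r2, _ = morphology.feature_correlation(df, "x2", "y")
        assert r2 == pytest.approx(r_xy)
        df["x3"] = -2.0 * df["x"]
        r3, _ = morphology.feature_correlation(df, "x3", "y")
        assert r3 == pytest.approx(-r_xy)

    def test_p_values_uniform_under_independence(self):
        """Analytic t-distribution p agrees with the permutation behaviour:
        under independence p is uniform (KS)."""
        rng = np.random.default_rng(7)
        ps_ = []
        for _ in range(1000):
            df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
            _, p = morphology.feature_correlation(df, "x", "y")
            ps_.append(p)
        assert stats.kstest(ps_, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [0.1, 0.2, 0.3]})
        with pytest.raises(UndefinedSeparationError):
            morphology.feature_correlation(df, "x", "y")

    def test_planted_anticorrelation_recovered(self):
        df = simulate.simulate_compound_phenotypes(100, -0.9, seed=5)
        r, p = morphology.feature_correlation(df, "mean_solidity", "mean_eccentricity")
        assert r == pytest.approx(-0.9, abs=0.05)
        assert p < 1e-10


class TestPhenotypePCA:
    @staticmethod
    def _pheno(n=30, seed=0, k=4):
        rng = np.random.default_rng(seed)
        cols = dict(zip(morphology.PCA_FEATURES, rng.normal(size=(k, n))))
        df = pd.DataFrame(cols)
        df.insert(0, "compound", [f"C{i}" for i in range(n)])
        return df

    def test_reconstruction_identity(self):
        df = self._pheno()
        scores, loadings, varfrac = morphology.phenotype_pca(df)
        X = df.loc[:, list(morphology.PCA_FEATURES)].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        recon = scores.iloc[:, 1:].to_numpy() @ loadings.to_numpy()
        assert np.allclose(recon, Z, atol=1e-10)
        assert varfrac.sum() == pytest.approx(1.0)
        assert (np.diff(varfrac) <= 1e-12).all()

    def test_loadings_orthonormal(self):
        _, loadings, _ = morphology.phenotype_pca(self._pheno(seed=3))
        L = loadings.to_numpy()
        assert np.allclose(L @ L.T, np.eye(L.shape[0]), atol=1e-10)

    def test_sign_convention(self):
        _, loadings, _ = morphology.phenotype_pca(self._pheno(seed=5))
        for _, row in loadings.iterrows():
            assert row.iloc[np.argmax(np.abs(row.to_numpy()))] > 0

    def test_two_correlated_features_single_component(self):
        df = self._pheno(k=4)
        df["mean_eccentricity"] = 2.0 * df["phagocytic_index"] + 1.0
        scores, loadings, varfrac = morphology.phenotype_pca(
            df, features=("phagocytic_index", "mean_eccentricity")
        )
        assert varfrac[0] == pytest.approx(1.0)

    def test_anticorrelated_features_antiparallel_loadings(self):
        """When solidity = 1 - eccentricity, their feature vectors point in
        opposite directions in PC space."""
        df = self._pheno(k=4, seed=9)
        df["mean_solidity"] = 1.0 - df["mean_eccentricity"]
        _, loadings, varfrac = morphology.phenotype_pca(df)
        # restrict to informative components (the exact dependency leaves a
        # null direction whose loadings are arbitrary)
        keep = varfrac > 1e-10
        a = loadings["mean_solidity"].to_numpy()[keep]
        b = loadings["mean_eccentricity"].to_numpy()[keep]
        cos = a @ b / np.linalg.norm(a) / np.linalg.norm(b)
        assert cos <= -0.99

    def test_constant_feature_named_in_error(self):
        df = self._pheno()
        df["mean_iba1"] = 1.0
        with pytest.raises(UndefinedSeparationError, match="mean_iba1"):
            morphology.phenotype_pca(df)


def test_screen_phenotypes_recover_planted_feature_couplings(default_screen):
    """Compound-level correlations in a simulated screen reflect the
    generator's planted shape/intensity covariance: solidity against
    eccentricity strongly negative, IBA1 following solidity."""
    cfg, fields, truth = default_screen
    keep = truth.loc[truth["effect_class"] == "inhibitor", "compound"]
    sub = fields[fields["compound"].isin(keep)]
    pheno = morphology.compound_phenotypes(sub)
    r_se, _ = morphology.feature_correlation(pheno, "mean_solidity", "mean_eccentricity")
    r_ei, p_ei = morphology.feature_correlation(pheno, "mean_eccentricity", "mean_iba1")
    r_si, p_si = morphology.feature_correlation(pheno, "mean_solidity", "mean_iba1")
    assert r_se < -0.7
    assert r_ei < -0.3 and p_ei < 0.05
    assert r_si > 0.3 and p_si < 0.05
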