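"""Morphotype classification and morphology/function statistics.

Microglia-like cells are binned into ramified (low solidity, high
eccentricity), ameboid (high solidity, low eccentricity) and rod/bipolar
(mid/mid) morphotypes; discordant corners (e.g. high solidity with high
eccentricity) are ``ambiguous``.  Cutoffs default to tertiles of the DMSO
cell population, with a fixed-value override.  Compound-level phenotypes are
field means then compound means; feature relationships are summarised with
Pearson correlation and PCA on standardized compound-level features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import InputError, UndefinedSeparationError

__all__ = [
    "MorphotypeThresholds",
    "dmso_tertile_thresholds",
    "classify_morphotype",
    "compound_phenotypes",
    "feature_correlation",
    "phenotype_pca",
]

MORPHOTYPES = ("ramified", "rod", "ameboid", "ambiguous")

PCA_FEATURES = ("phagocytic_index", "mean_solidity", "mean_eccentricity", "mean_iba1")


@dataclass
class MorphotypeThresholds:
    """Solidity/eccentricity cutoffs separating the morphotype bins."""

    solidity_low: float = 0.70
    solidity_high: float = 0.85
    eccentricity_low: float = 0.60
    eccentricity_high: float = 0.80
    derivation: str = "fixed"

    def validate(self) -> None:
        for lo, hi, name in (
            (self.solidity_low, self.solidity_high, "solidity"),
            (self.eccentricity_low, self.eccentricity_high, "eccentricity"),
        ):
            if not 0.0 <= lo < hi <= 1.0:
                raise InputError(f"{name} thresholds must satisfy 0 <= low < high <= 1")


def dmso_tertile_thresholds(dmso_cells: pd.DataFrame) -> MorphotypeThresholds:
    """Derive cutoffs from the DMSO cell population: tertiles of solidity
    and eccentricity (columns ``solidity`` / ``eccentricity`` or the
    field-mean variants)."""
    sol_col = "solidity" if "solidity" in dmso_cells.columns else "mean_solidity"
    ecc_col = "eccentricity" if "eccentricity" in dmso_cells.columns else "mean_eccentricity"
    sol = dmso_cells[sol_col].dropna().to_numpy()
    ecc = dmso_cells[ecc_col].dropna().to_numpy()
    if sol.size < 3 or ecc.size < 3:
        raise InputError("need at least 3 DMSO cells to derive tertiles")
    s_lo, s_hi = np.quantile(sol, [1 / 3, 2 / 3])
    e_lo, e_hi = np.quantile(ecc, [1 / 3, 2 / 3])
    thr = MorphotypeThresholds(float(s_lo), float(s_hi), float(e_lo), float(e_hi),
                               derivation="dmso_tertiles")
    thr.validate()
    return thr


def classify_morphotype(
    solidity, eccentricity, thresholds: MorphotypeThresholds | None = None
):
    """Assign each (solidity, eccentricity) pair to a morphotype.

    Ramified: solidity <= low and eccentricity >= high.  Ameboid:
    solidity >= high and eccentricity <= low.  Rod: both features mid.
    Everything else (discordant corners) is ambiguous.  Scalar in, scalar
    out; array in, object array out.
    """
    thr = thresholds or MorphotypeThresholds()
    thr.validate()
    s = np.asarray(solidity, dtype=float)
    e = np.asarray(eccentricity, dtype=float)
    if np.any((s < 0) | (s > 1)) or np.any((e < 0) | (e > 1)):
        raise InputError("solidity and eccentricity must lie in [0, 1]")
    out = np.full(np.broadcast(s, e).shape, "ambiguous", dtype=object)
    ram = (s <= thr.solidity_low) & (e >= thr.eccentricity_high)
    amoe = (s >= thr.solidity_high) & (e <= thr.eccentricity_low)
    rod = (
        (s > thr.solidity_low) & (s < thr.solidity_high)
        & (e > thr.eccentricity_low) & (e < thr.eccentricity_high)
    )
    out[ram], out[amoe], out[rod] = "ramified", "ameboid", "rod"
    if out.ndim == 0:
        return out.item()
    return out


def compound_phenotypes(
    fields: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    thresholds: MorphotypeThresholds | None = None,
) -> pd.DataFrame:
    """Per-compound phenotype table from field measurements.

    Feature means are field means then compound means; the phagocytic index
    is total area over total cells per compound.  Morphotype fractions come
    from per-cell classification when a ``cells`` table (columns compound,
    solidity, eccentricity) is supplied; otherwise they are NaN and
    ``fractions_defined`` is False.
    """
    f = fields.loc[fields["role"] == "compound"]
    if f.empty:
        raise InputError("no compound fields")
    rows = []
    for compound, grp in f.groupby("compound"):
        total_cells = grp["cell_count"].sum()
        rows.append(
            dict(
                compound=compound,
                phagocytic_index=(grp["synaptosome_area"].sum() / total_cells
                                  if total_cells > 0 else np.nan),
                mean_solidity=grp["mean_solidity"].mean(),
                mean_eccentricity=grp["mean_eccentricity"].mean(),
                mean_iba1=grp["mean_iba1"].mean(),
                n_fields=len(grp),
            )
        )
    out = pd.DataFrame(rows)
    for m in MORPHOTYPES:
        out[f"frac_{m}"] = np.nan
    out["fractions_defined"] = False
    if cells is not None and not cells.empty:
        labels = classify_morphotype(
            cells["solidity"].to_numpy(), cells["eccentricity"].to_numpy(), thresholds
        )
        lab = pd.DataFrame({"compound": cells["compound"].to_numpy(), "morphotype": labels})
        frac = (
            lab.groupby("compound")["morphotype"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        for m in MORPHOTYPES:
            if m not in frac.columns:
                frac[m] = 0.0
        for i, compound in enumerate(out["compound"]):
            if compound in frac.index:
                for m in MORPHOTYPES:
                    out.loc[i, f"frac_{m}"] = frac.loc[compound, m]
                out.loc[i, "fractions_defined"] = True
    return out


def feature_correlation(
    phenotypes: pd.DataFrame, feature_x: str, feature_y: str
) -> tuple[float, float]:
    """Pearson r and two-sided p (t reference, n-2 df) between two
    compound-level features."""
    x = phenotypes[feature_x].to_numpy(dtype=float)
    y = phenotypes[feature_y].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InputError("need at least 3 compounds")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedSeparationError("zero feature variance; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def phenotype_pca(
    phenotypes: pd.DataFrame, features: tuple[str, ...] = PCA_FEATURES
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of standardized compound-level features.

    Returns ``(scores, loadings, variance_fractions)``.  Loadings are
    orthonormal rows (components x features); the sign of each component is
    fixed so its largest-magnitude loading is positive.  A constant feature
    raises, naming the offender.
    """
    X = phenotypes.loc[:, list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("phenotype features contain non-finite values")
    if X.shape[0] < 3:
        raise InputError("need at least 3 compounds for PCA")
    sd = X.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise UndefinedSeparationError(f"feature '{features[j]}' is constant")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=len(features), svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    pc_names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    scores_df = pd.DataFrame(scores, columns=pc_names)
    scores_df.insert(0, "compound", phenotypes["compound"].to_numpy())
    loadings_df = pd.DataFrame(loadings, index=pc_names, columns=list(features))
    return scores_df, loadings_df, pca.explained_variance_ratio_
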