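"""Morphotype analysis of the confirmed inhibitors.

Computes compound-level phenotypes (phagocytic index, solidity,
eccentricity, IBA1 intensity) from the secondary-screen fields, the
pairwise feature correlations, and a PCA of the standardized features.
The generator plants a strong solidity-eccentricity anticorrelation with
IBA1 tracking solidity, which the analysis recovers.
"""

from pathlib import Path

import pandas as pd

import phagoscreen as ps
from phagoscreen import hits, io, morphology, screen, simulate

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def _secondary_fields():
    path = ROOT / "scratch" / "secondary_fields.csv"
    if path.exists():
        return io.read_table(path)
    cfg = ps.ScreenSimConfig(seed=SEED)
    fields, truth = ps.simulate_screen(cfg)
    wells = screen.toxicity_filter(screen.summarize_wells(screen.overseg_filter(fields)))
    res = hits.compound_results(wells)
    return simulate.simulate_secondary(
        cfg, truth, res.loc[res["primary_hit"], "compound"].tolist(),
        fields_per_well=15, seed=SEED + 200,
    )


def main() -> None:
    sec_fields = _secondary_fields()
    sec = hits.classify_secondary(sec_fields)
    confirmed = sec.loc[sec["classification"] == "confirmed_inhibitor", "compound"]
    keep = sec_fields["compound"].isin(confirmed)
    pheno = morphology.compound_phenotypes(sec_fields[keep])
    io.write_table(pheno, ROOT / "results" / "phenotypes.csv")
    print(f"{len(pheno)} confirmed inhibitors phenotyped -> results/phenotypes.csv")

    rows = []
    for fx, fy in (
        ("mean_eccentricity", "mean_iba1"),
        ("mean_solidity", "mean_iba1"),
        ("mean_solidity", "mean_eccentricity"),
        ("phagocytic_index", "mean_eccentricity"),
    ):
        r, p = morphology.feature_correlation(pheno, fx, fy)
        rows.append(dict(feature_x=fx, feature_y=fy, r=r, p=p))
        print(f"  {fx} vs {fy}: r = {r:.3f}, p = {p:.4f}")
    io.write_table(pd.DataFrame(rows), ROOT / "results" / "correlations.csv")

    scores, loadings, varfrac = morphology.phenotype_pca(pheno)
    io.write_table(scores, ROOT / "results" / "pca_scores.csv")
    io.write_table(loadings.reset_index(names="component"), ROOT / "results" / "pca_loadings.csv")
    print("PCA variance fractions:", ", ".join(f"{v:.2f}" for v in varfrac))
    # biplot geometry: feature vectors in the PC1/PC2 plane
    a = loadings.loc[["PC1", "PC2"], "mean_solidity"]
    b = loadings.loc[["PC1", "PC2"], "mean_eccentricity"]
    cos = a @ b / (a @ a) ** 0.5 / (b @ b) ** 0.5
    print(f"solidity/eccentricity biplot cosine: {cos:.2f} (antiparallel when near -1)")


if __name__ == "__main__":
    main()
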