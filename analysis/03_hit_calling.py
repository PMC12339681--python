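"""Primary hit calling and secondary confirmation.

Applies the exclusion filters (over-segmentation, toxicity), z-scores each
compound's mean phagocytic index against the DMSO controls, calls primary
hits at z <= -2, then re-screens the hits at 15 fields/well and confirms
inhibitors at a compound/DMSO PI ratio of 0.5 or less.
"""

from pathlib import Path

import phagoscreen as ps
from phagoscreen import hits, io, screen, simulate

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = ps.ScreenSimConfig(seed=SEED)
    fields_path = ROOT / "scratch" / "primary_fields.csv"
    if fields_path.exists():
        fields = io.read_table(fields_path)
        truth = io.read_table(ROOT / "results" / "ground_truth.csv")
    else:
        fields, truth = ps.simulate_screen(cfg)
    wells = screen.toxicity_filter(screen.summarize_wells(screen.overseg_filter(fields)))
    res = hits.compound_results(wells)
    io.write_table(res, ROOT / "results" / "compound_results.csv")

    n_toxic = int(res["toxic_primary"].sum())
    hit_names = res.loc[res["primary_hit"], "compound"].tolist()
    planted = set(truth.loc[truth["effect_class"] == "inhibitor", "compound"])
    print(f"{len(res)} compounds screened; {n_toxic} excluded for toxicity; "
          f"{len(hit_names)} primary hits (z <= -2), "
          f"{len(set(hit_names) & planted)} of {len(planted)} planted inhibitors recovered; "
          f"{int(res['activator'].sum())} activators")

    sec_fields = simulate.simulate_secondary(cfg, truth, hit_names,
                                             fields_per_well=15, seed=SEED + 200)
    sec_wells = screen.toxicity_filter(screen.summarize_wells(sec_fields))
    sec = hits.classify_secondary(sec_fields, toxic=hits.compound_toxicity(sec_wells))
    io.write_table(sec, ROOT / "results" / "secondary_results.csv")
    io.write_table(sec_fields, ROOT / "scratch" / "secondary_fields.csv")
    counts = sec["classification"].value_counts()
    print("secondary screen:", ", ".join(f"{v} {k}" for k, v in counts.items()))

    merged = res.merge(sec, on="compound")
    r, p = hits.primary_secondary_concordance(merged["z_score"], merged["secondary_ratio"])
    print(f"primary z vs secondary ratio concordance: r = {r:.2f}, p = {p:.2g}")


if __name__ == "__main__":
    main()
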