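"""Simulate the primary phagocytosis screen.

Generates the full 489-compound, 3-replicate, 12-fields-per-well primary
screen with planted inhibitors (47), toxic compounds (35) and null
compounds, and writes the per-field measurement table (large, to scratch/)
plus the per-compound ground truth (to results/).
"""

from pathlib import Path

import phagoscreen as ps
from phagoscreen import io

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = ps.ScreenSimConfig(seed=SEED)
    fields, truth = ps.simulate_screen(cfg)
    (ROOT / "scratch").mkdir(exist_ok=True)
    io.write_table(fields, ROOT / "scratch" / "primary_fields.csv")
    io.write_table(truth, ROOT / "results" / "ground_truth.csv")
    print(f"simulated {cfg.n_compounds} compounds, {len(fields)} fields")
    print(truth["effect_class"].value_counts().to_string())
    print(f"fields -> scratch/primary_fields.csv; truth -> results/ground_truth.csv")


if __name__ == "__main__":
    main()
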