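"""Assay quality control.

Simulates the control-separation validation plate (24 DMSO vs 24
cytochalasin-D wells) and computes per-plate Z'-factor and SSMD for the
primary screen.  A Z' >= 0.5 marks an excellent screening window and an
SSMD > 5 a robust assay; the simulated assay sits in that regime.
"""

from pathlib import Path

import phagoscreen as ps
from phagoscreen import io, screen

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    vcfg = ps.ScreenSimConfig(
        n_compounds=48, n_replicates_per_compound=1,
        dmso_wells_per_plate=24, cytod_wells_per_plate=24,
        inhibitor_fraction=0.0, toxic_fraction=0.0, seed=SEED + 100,
    )
    vfields, _ = ps.simulate_screen(vcfg)
    vwells = screen.summarize_wells(vfields)
    neg = vwells.loc[vwells["role"] == "dmso", "phagocytic_index"]
    pos = vwells.loc[vwells["role"] == "cytod", "phagocytic_index"]
    print(f"validation plate: Z' = {screen.z_factor(neg, pos):.3f}, "
          f"SSMD = {screen.ssmd(neg, pos):.2f} (24 wells per control)")

    fields_path = ROOT / "scratch" / "primary_fields.csv"
    if not fields_path.exists():
        fields, _ = ps.simulate_screen(ps.ScreenSimConfig(seed=SEED))
    else:
        fields = io.read_table(fields_path)
    wells = screen.summarize_wells(screen.overseg_filter(fields))
    qc = screen.plate_qc(wells)
    io.write_table(qc, ROOT / "results" / "plate_qc.csv")
    print(f"screen plates: Z' in [{qc['z_factor'].min():.2f}, {qc['z_factor'].max():.2f}], "
          f"SSMD in [{qc['ssmd'].min():.1f}, {qc['ssmd'].max():.1f}] "
          f"over {len(qc)} plates -> results/plate_qc.csv")


if __name__ == "__main__":
    main()
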