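"""Well aggregation, assay quality metrics and exclusion filters.

The phagocytic index (PI) of a well is the sum of synaptosome signal area
over its image fields divided by the sum of cell counts.  Plate quality is
summarised with the Z'-factor (>= 0.5 marks an excellent screening window)
and the strictly standardized mean difference (SSMD, > 5 marks a robust
assay), both computed from DMSO negative- and cytochalasin-D positive-
control wells.

Filter order is fixed: over-segmentation (field level, robust MAD rule
against same-plate DMSO fields) -> toxicity (well level, < 10 % of the DMSO
mean cell count) -> PI computation over the surviving fields.  Applying a
filter twice changes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedIndexError, UndefinedSeparationError

__all__ = [
    "phagocytic_index",
    "z_factor",
    "ssmd",
    "overseg_filter",
    "toxicity_filter",
    "summarize_wells",
    "plate_qc",
    "PlateQC",
]

TOXICITY_FRACTION = 0.10
OVERSEG_MAD_K = 5.0
MIN_FIELDS_FOR_OVERSEG = 8


def phagocytic_index(synaptosome_area, cell_count) -> float:
    """Sum of synaptosome area divided by sum of cell count over fields.

    Raises :class:`UndefinedIndexError` when the total cell count is zero.
    """
    area = np.asarray(synaptosome_area, dtype=float)
    count = np.asarray(cell_count, dtype=float)
    if area.size == 0:
        raise InputError("phagocytic_index needs at least one field")
    total_cells = count.sum()
    if total_cells <= 0:
        raise UndefinedIndexError("total cell count is zero; PI undefined")
    return float(area.sum() / total_cells)


def _two_group_stats(neg, pos, min_n: int = 2):
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size < min_n or pos.size < min_n:
        raise InputError(f"need at least {min_n} wells per control group")
    return neg.mean(), neg.std(ddof=1), pos.mean(), pos.std(ddof=1)


def z_factor(neg, pos) -> float:
    """Screening-window coefficient Z' = 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|.

    Sample (n-1) standard deviations.  Raises
    :class:`UndefinedSeparationError` when the group means coincide.
    """
    mu_n, sd_n, mu_p, sd_p = _two_group_stats(neg, pos)
    if mu_p == mu_n:
        raise UndefinedSeparationError("control means are equal; Z' undefined")
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


def ssmd(neg, pos) -> float:
    """Strictly standardized mean difference (mu_neg - mu_pos)/sqrt(sd_neg^2 + sd_pos^2).

    Signed: positive when the negative-control mean exceeds the positive-
    control mean.  Raises :class:`UndefinedSeparationError` when both
    variances are zero.
    """
    mu_n, sd_n, mu_p, sd_p = _two_group_stats(neg, pos)
    denom = np.sqrt(sd_n**2 + sd_p**2)
    if denom == 0:
        if mu_n == mu_p:
            return 0.0
        raise UndefinedSeparationError("both control variances are zero")
    return float((mu_n - mu_p) / denom)


@dataclass
class PlateQC:
    """Control statistics and quality metrics for one plate."""

    plate: str
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    z_factor: float
    ssmd: float
    n_neg: int
    n_pos: int


def overseg_filter(
    fields: pd.DataFrame, k: float = OVERSEG_MAD_K, min_fields: int = MIN_FIELDS_FOR_OVERSEG
) -> pd.DataFrame:
    """Flag over-segmented fields per plate.

    A field is flagged when its cell count exceeds ``median + k * MAD`` of
    the same plate's DMSO fields.  Plates with fewer than ``min_fields``
    DMSO fields are skipped with a warning (too few for robust statistics).
    Returns a copy with a boolean ``over_segmented`` column; idempotent.
    """
    out = fields.copy()
    out["over_segmented"] = False
    for plate, grp in out.groupby("plate"):
        ref = grp.loc[grp["role"] == "dmso", "cell_count"].to_numpy(dtype=float)
        if ref.size < min_fields:
            warnings.warn(
                f"plate {plate}: only {ref.size} DMSO fields; over-segmentation "
                "filter skipped",
                stacklevel=2,
            )
            continue
        med = np.median(ref)
        mad = np.median(np.abs(ref - med))
        cutoff = med + k * mad
        out.loc[grp.index[grp["cell_count"] > cutoff], "over_segmented"] = True
    return out


def summarize_wells(fields: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a field table to one row per well.

    Fields flagged ``over_segmented`` (if the column is present) are left
    out of the PI sums and morphology means but still counted in
    ``n_fields_total``.  Wells whose usable fields have zero total cells
    get ``phagocytic_index`` NaN.
    """
    f = fields.copy()
    if "over_segmented" not in f.columns:
        f["over_segmented"] = False
    keys = ["plate", "well"]
    meta_cols = [c for c in ("role", "compound", "dose_um") if c in f.columns]
    rows = []
    for (plate, well), grp in f.groupby(keys, sort=True):
        use = grp.loc[~grp["over_segmented"]]
        total_cells = int(use["cell_count"].sum())
        total_area = float(use["synaptosome_area"].sum())
        pi = total_area / total_cells if total_cells > 0 else np.nan
        row = dict(plate=plate, well=well, total_cell_count=total_cells,
                   phagocytic_index=pi, n_fields_used=len(use),
                   n_fields_total=len(grp))
        for c in meta_cols:
            row[c] = grp[c].iloc[0]
        for c in ("mean_solidity", "mean_eccentricity", "mean_iba1"):
            if c in grp.columns:
                row[c] = float(use[c].mean()) if len(use) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["excluded"] = False
    out["exclusion_reason"] = "none"
    return out


def toxicity_filter(
    wells: pd.DataFrame,
    fraction: float = TOXICITY_FRACTION,
    scope: str = "plate",
) -> pd.DataFrame:
    """Flag wells with treatment-induced toxicity.

    A well is excluded when its total cell count is strictly below
    ``fraction`` (default 10 %) of the mean DMSO total cell count.  The
    reference is the same-plate DMSO mean (``scope='plate'``, default, which
    absorbs plate effects) or the screen-wide DMSO mean (``scope='screen'``).
    Idempotent; raises :class:`InputError` if no DMSO wells exist in scope.
    """
    if scope not in ("plate", "screen"):
        raise InputError("scope must be 'plate' or 'screen'")
    out = wells.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = "none"
    dmso = out.loc[out["role"] == "dmso"]
    if dmso.empty:
        raise InputError("no DMSO wells; toxicity reference undefined")
    if scope == "screen":
        ref = {p: dmso["total_cell_count"].mean() for p in out["plate"].unique()}
    else:
        per_plate = dmso.groupby("plate")["total_cell_count"].mean()
        missing = set(out["plate"].unique()) - set(per_plate.index)
        if missing:
            raise InputError(f"plates without DMSO wells: {sorted(missing)}")
        ref = per_plate.to_dict()
    cutoff = out["plate"].map(ref) * fraction
    toxic = (out["total_cell_count"] < cutoff) & (out["role"] != "dmso")
    out.loc[toxic, "excluded"] = True
    out.loc[toxic, "exclusion_reason"] = "toxicity"
    return out


def plate_qc(wells: pd.DataFrame) -> pd.DataFrame:
    """Z'-factor and SSMD per plate from DMSO (negative) and cytochalasin-D
    (positive) control well PIs.  Plates lacking either control group are
    omitted."""
    rows = []
    for plate, grp in wells.groupby("plate"):
        neg = grp.loc[grp["role"] == "dmso", "phagocytic_index"].dropna().to_numpy()
        pos = grp.loc[grp["role"] == "cytod", "phagocytic_index"].dropna().to_numpy()
        if neg.size < 2 or pos.size < 2:
            continue
        rows.append(
            PlateQC(
                plate=str(plate),
                mu_neg=float(neg.mean()), sd_neg=float(neg.std(ddof=1)),
                mu_pos=float(pos.mean()), sd_pos=float(pos.std(ddof=1)),
                z_factor=z_factor(neg, pos), ssmd=ssmd(neg, pos),
                n_neg=int(neg.size), n_pos=int(pos.size),
            ).__dict__
        )
    return pd.DataFrame(rows)
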