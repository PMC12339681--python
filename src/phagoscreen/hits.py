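"""Primary hit calling and secondary-screen confirmation.

Primary hits are non-toxic compounds whose mean phagocytic index across
replicate wells sits at least two reference standard deviations below the
DMSO mean (z <= -2, inclusive).  Two z-score references are supported:
``vs_dmso`` (mean/SD of DMSO control well PIs, the default) and
``vs_library`` (mean/SD of the per-compound means across the library).
Secondary confirmation compares mean per-field PI of a compound to the DMSO
mean; a ratio of 0.5 or less confirms an inhibitor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedSeparationError

__all__ = [
    "compound_toxicity",
    "compound_z_scores",
    "call_primary_hits",
    "secondary_ratio",
    "classify_compound",
    "classify_secondary",
    "primary_secondary_concordance",
]

Z_HIT_THRESHOLD = -2.0
CONFIRM_RATIO = 0.5
NO_EFFECT_DELTA = 0.05


def compound_toxicity(
    wells: pd.DataFrame, fraction: float = 0.10, mode: str = "per_compound"
) -> pd.Series:
    """Per-compound toxicity flags from a well summary table.

    ``per_compound`` (default): a compound is toxic when the mean total cell
    count of its replicate wells is strictly below ``fraction`` of the
    screen-wide DMSO mean.  ``per_well``: toxic when *any* replicate well
    was individually excluded for toxicity (requires toxicity_filter run
    first).
    """
    comp = wells.loc[wells["role"] == "compound"]
    if mode == "per_well":
        if "exclusion_reason" not in wells.columns:
            raise InputError("per_well mode needs toxicity_filter output")
        return comp.groupby("compound").apply(
            lambda g: bool((g["exclusion_reason"] == "toxicity").any()),
            include_groups=False,
        )
    if mode != "per_compound":
        raise InputError("mode must be 'per_compound' or 'per_well'")
    dmso = wells.loc[wells["role"] == "dmso", "total_cell_count"]
    if dmso.empty:
        raise InputError("no DMSO wells; toxicity reference undefined")
    cutoff = fraction * dmso.mean()
    return comp.groupby("compound")["total_cell_count"].mean() < cutoff


def compound_z_scores(wells: pd.DataFrame, mode: str = "vs_dmso") -> pd.DataFrame:
    """Per-compound mean PI and z-score.

    Replicate wells are aggregated by their mean (excluded wells dropped).
    ``vs_dmso`` references the DMSO well PI distribution; ``vs_library``
    references the distribution of per-compound means.
    """
    if mode not in ("vs_dmso", "vs_library"):
        raise InputError("mode must be 'vs_dmso' or 'vs_library'")
    usable = wells.loc[~wells.get("excluded", False) & wells["phagocytic_index"].notna()]
    means = (
        usable.loc[usable["role"] == "compound"]
        .groupby("compound")["phagocytic_index"]
        .mean()
    )
    if mode == "vs_dmso":
        ref = usable.loc[usable["role"] == "dmso", "phagocytic_index"].to_numpy()
        if ref.size < 2:
            raise InputError("vs_dmso mode needs at least 2 DMSO wells")
        mu, sd = ref.mean(), ref.std(ddof=1)
    else:
        if means.size < 10:
            raise InputError("vs_library mode needs at least 10 compounds")
        mu, sd = means.mean(), means.std(ddof=1)
    if sd == 0:
        raise UndefinedSeparationError("reference SD is zero; z-scores undefined")
    out = means.rename("mean_pi").to_frame()
    out["z_score"] = (out["mean_pi"] - mu) / sd
    out["z_mode"] = mode
    return out.reset_index()


def call_primary_hits(
    results: pd.DataFrame,
    z_threshold: float = Z_HIT_THRESHOLD,
    toxic: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag primary hits (z <= threshold, inclusive) among non-toxic
    compounds; activators (z >= -threshold) are reported separately but are
    never hits.  Toxicity takes precedence over any z-score."""
    out = results.copy()
    if toxic is not None:
        out["toxic_primary"] = out["compound"].map(toxic).fillna(False).astype(bool)
    elif "toxic_primary" not in out.columns:
        out["toxic_primary"] = False
    out["primary_hit"] = (~out["toxic_primary"]) & (out["z_score"] <= z_threshold)
    out["activator"] = (~out["toxic_primary"]) & (out["z_score"] >= -z_threshold)
    return out


def compound_results(
    wells: pd.DataFrame,
    mode: str = "vs_dmso",
    z_threshold: float = Z_HIT_THRESHOLD,
    toxicity_fraction: float = 0.10,
) -> pd.DataFrame:
    """One row per compound: toxicity flag, mean PI and z-score (NaN for
    compounds whose wells were all excluded), primary-hit call."""
    toxic = compound_toxicity(wells, fraction=toxicity_fraction)
    z = compound_z_scores(wells, mode=mode)
    out = toxic.rename("toxic_primary").to_frame().reset_index().merge(
        z, on="compound", how="left"
    )
    out["z_mode"] = mode
    return call_primary_hits(out, z_threshold=z_threshold)


def secondary_ratio(compound_field_pis, dmso_field_pis) -> tuple[float, float]:
    """Ratio of mean per-field PI of a compound to the DMSO mean, with its
    standard error (compound-group SEM divided by the DMSO mean)."""
    c = np.asarray(compound_field_pis, dtype=float)
    d = np.asarray(dmso_field_pis, dtype=float)
    if c.size < 2 or d.size < 2:
        raise InputError("need at least 2 fields per group")
    d_mean = d.mean()
    if d_mean == 0:
        raise UndefinedSeparationError("DMSO mean PI is zero; ratio undefined")
    sem = c.std(ddof=1) / np.sqrt(c.size) / d_mean
    return float(c.mean() / d_mean), float(sem)


def classify_compound(
    ratio: float | None,
    toxic_secondary: bool = False,
    delta: float = NO_EFFECT_DELTA,
    confirm_ratio: float = CONFIRM_RATIO,
) -> str:
    """Secondary-screen classification of one compound.

    Toxicity dominates; otherwise a ratio of ``confirm_ratio`` or less
    (inclusive) is a confirmed inhibitor, a ratio within ``delta`` of 1 is
    no effect, above ``1 + delta`` an activator, and anything between a
    weak inhibitor.  ``None`` ratio means the compound was not tested.
    """
    if toxic_secondary:
        return "toxic"
    if ratio is None or (isinstance(ratio, float) and np.isnan(ratio)):
        return "not_tested"
    if ratio <= confirm_ratio:
        return "confirmed_inhibitor"
    if ratio < 1.0 - delta:
        return "weak_inhibitor"
    if ratio > 1.0 + delta:
        return "activator"
    return "no_effect"


def classify_secondary(
    fields: pd.DataFrame,
    toxic: pd.Series | None = None,
    delta: float = NO_EFFECT_DELTA,
    confirm_ratio: float = CONFIRM_RATIO,
) -> pd.DataFrame:
    """Secondary screen over a field table: per-field PIs, compound/DMSO
    ratio with SEM, and classification per compound."""
    f = fields.copy()
    f = f.loc[f["cell_count"] > 0]
    f["field_pi"] = f["synaptosome_area"] / f["cell_count"]
    dmso = f.loc[f["role"] == "dmso", "field_pi"].to_numpy()
    rows = []
    for compound, grp in f.loc[f["role"] == "compound"].groupby("compound"):
        ratio, sem = secondary_ratio(grp["field_pi"].to_numpy(), dmso)
        is_toxic = bool(toxic.get(compound, False)) if toxic is not None else False
        rows.append(
            dict(compound=compound, secondary_ratio=ratio, secondary_sem=sem,
                 toxic_secondary=is_toxic,
                 classification=classify_compound(ratio, is_toxic, delta, confirm_ratio))
        )
    return pd.DataFrame(rows)


def primary_secondary_concordance(primary, secondary) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired primary and
    secondary per-compound outcomes."""
    x = np.asarray(primary, dtype=float)
    y = np.asarray(secondary, dtype=float)
    if x.size != y.size:
        raise InputError("paired vectors must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 paired compounds")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedSeparationError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
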