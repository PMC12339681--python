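"""Synthetic data generators for the phagocytosis-screen pipeline.

Three generators with known ground truth stand in for the study's raw data:

* :func:`simulate_screen` — per-field measurement tables for 96-well
  phagocytosis screens (DMSO negative controls, cytochalasin-D positive
  controls, compounds with planted inhibition/activation/toxicity effects).
* :func:`render_field` — small 3-channel microscopy fields (nuclei, IBA1,
  pHrodo) with exact ground-truth label masks, for testing the imaging stage.
* :func:`simulate_counts` — DRUG-seq-like negative-binomial gene x well count
  matrices with replicate DMSO wells and planted differentially expressed
  genes, for testing the RNA-activity stage.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .errors import ConfigError, RenderOverlapError

__all__ = [
    "ScreenSimConfig",
    "CellSpec",
    "FieldRenderSpec",
    "CountsSimConfig",
    "simulate_screen",
    "simulate_secondary",
    "render_field",
    "simulate_counts",
    "simulate_compound_phenotypes",
    "expected_z",
    "predicted_well_sd",
    "predicted_z_factor",
    "predicted_ssmd",
    "FIELD_COLUMNS",
]

#: Column order of the per-field measurement table produced by
#: :func:`simulate_screen` and consumed by the screen/hit/morphology stages.
FIELD_COLUMNS = [
    "plate",
    "well",
    "role",
    "compound",
    "dose_um",
    "field_index",
    "cell_count",
    "synaptosome_area",
    "mean_solidity",
    "mean_eccentricity",
    "mean_iba1",
]

_ROWS = "ABCDEFGH"
_DEFAULT_MORPH_SHIFTS: Mapping[str, tuple[float, float, float]] = {
    "null": (0.0, 0.0, 0.0),
    "inhibitor": (0.04, -0.06, 0.08),
    "activator": (-0.04, 0.06, -0.08),
    "toxic": (0.0, 0.0, 0.0),
}


@dataclass
class ScreenSimConfig:
    """Design constants and effect model for a simulated compound screen.

    Defaults mirror the study design: 489 compounds at 10 uM, three
    replicate wells per compound split across plates, 12 image fields per
    well, DMSO negative and 2 uM cytochalasin D positive controls on every
    plate.  ``inhibitor_effect`` / ``activator_effect`` are multiplicative
    factors on the phagocytic index (PI); either a scalar or a ``(low,
    high)`` range from which per-compound multipliers are drawn uniformly.
    ``toxic_cell_fraction`` is the surviving-cell fraction for toxic
    compounds (the toxicity filter excludes wells below 10 % of DMSO).
    """

    n_compounds: int = 489
    n_replicates_per_compound: int = 3
    fields_per_well: int = 12
    dmso_wells_per_plate: int = 8
    cytod_wells_per_plate: int = 4
    cells_per_field_mean: float = 100.0
    baseline_pi_mean: float = 1.0
    baseline_pi_cv: float = 0.30
    cytod_effect: float = 0.12
    inhibitor_fraction: float = 47 / 489
    inhibitor_effect: float | tuple[float, float] = (0.20, 0.70)
    activator_fraction: float = 0.0
    activator_effect: float | tuple[float, float] = 1.5
    toxic_fraction: float = 35 / 489
    toxic_cell_fraction: float = 0.05
    morph_shift_model: Mapping[str, tuple[float, float, float]] = dc_field(
        default_factory=lambda: dict(_DEFAULT_MORPH_SHIFTS)
    )
    morph_overrides: Mapping[str, tuple[float, float, float]] = dc_field(
        default_factory=dict
    )
    morph_jitter_sd: tuple[float, float, float] = (0.02, 0.03, 0.06)
    # per-compound jitter correlation over (solidity, eccentricity, IBA1):
    # branched cells are elongated and dimmer, so solidity and eccentricity
    # anticorrelate strongly and IBA1 follows solidity
    morph_jitter_corr: tuple = (
        (1.0, -0.9, 0.624),
        (-0.9, 1.0, -0.565),
        (0.624, -0.565, 1.0),
    )
    morph_baseline: tuple[float, float, float] = (0.72, 0.70, 1.0)
    morph_field_sd: tuple[float, float, float] = (0.02, 0.02, 0.05)
    dose_um: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "inhibitor_fraction": self.inhibitor_fraction,
            "activator_fraction": self.activator_fraction,
            "toxic_fraction": self.toxic_fraction,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name}={f} outside [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ConfigError("effect-class fractions sum to more than 1")
        for name in (
            "n_compounds",
            "n_replicates_per_compound",
            "fields_per_well",
            "dmso_wells_per_plate",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cytod_wells_per_plate < 0:
            raise ConfigError("cytod_wells_per_plate must be >= 0")
        if self.baseline_pi_cv <= 0:
            raise ConfigError("baseline_pi_cv must be > 0")
        if self.baseline_pi_mean <= 0:
            raise ConfigError("baseline_pi_mean must be > 0")
        if not 0.0 <= self.toxic_cell_fraction < 0.1:
            raise ConfigError("toxic_cell_fraction must lie in [0, 0.1)")
        lo, hi = _effect_range(self.inhibitor_effect)
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("inhibitor_effect must lie in [0, 1)")
        lo, _ = _effect_range(self.activator_effect)
        if lo <= 1.0:
            raise ConfigError("activator_effect must be > 1")
        n_ctrl = self.dmso_wells_per_plate + self.cytod_wells_per_plate
        if n_ctrl >= 96:
            raise ConfigError("controls occupy the whole plate")


def _effect_range(effect: float | tuple[float, float]) -> tuple[float, float]:
    if isinstance(effect, (tuple, list)):
        lo, hi = float(effect[0]), float(effect[1])
    else:
        lo = hi = float(effect)
    return lo, hi


def _draw_effects(
    rng: np.random.Generator, effect: float | tuple[float, float], n: int
) -> np.ndarray:
    lo, hi = _effect_range(effect)
    if lo == hi:
        return np.full(n, lo)
    return rng.uniform(lo, hi, size=n)


def _plate_well_names() -> list[str]:
    # column-major so controls fill whole columns first
    return [f"{r}{c:02d}" for c in range(1, 13) for r in _ROWS]


def _lognormal(
    rng: np.random.Generator, mean: np.ndarray, cv: float, size=None
) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def expected_z(config: ScreenSimConfig, multiplier: float) -> float:
    """Expected primary-screen Z-score of a compound with the given true
    PI multiplier, under the configured field CV and fields/well."""
    return (multiplier - 1.0) * math.sqrt(config.fields_per_well) / config.baseline_pi_cv


def predicted_well_sd(config: ScreenSimConfig, multiplier: float = 1.0) -> float:
    """Closed-form well-level PI standard deviation: field-level log-normal
    noise averaged over ``fields_per_well`` fields."""
    mean = config.baseline_pi_mean * multiplier
    return mean * config.baseline_pi_cv / math.sqrt(config.fields_per_well)


def predicted_z_factor(config: ScreenSimConfig) -> float:
    mu_n = config.baseline_pi_mean
    mu_p = config.baseline_pi_mean * config.cytod_effect
    s_n = predicted_well_sd(config, 1.0)
    s_p = predicted_well_sd(config, config.cytod_effect)
    return 1.0 - 3.0 * (s_n + s_p) / abs(mu_n - mu_p)


def predicted_ssmd(config: ScreenSimConfig) -> float:
    mu_n = config.baseline_pi_mean
    mu_p = config.baseline_pi_mean * config.cytod_effect
    s_n = predicted_well_sd(config, 1.0)
    s_p = predicted_well_sd(config, config.cytod_effect)
    return (mu_n - mu_p) / math.sqrt(s_n**2 + s_p**2)


def _assign_classes(rng: np.random.Generator, config: ScreenSimConfig) -> pd.DataFrame:
    n = config.n_compounds
    n_inh = int(round(config.inhibitor_fraction * n))
    n_act = int(round(config.activator_fraction * n))
    n_tox = int(round(config.toxic_fraction * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_inh]] = "inhibitor"
    classes[order[n_inh : n_inh + n_act]] = "activator"
    classes[order[n_inh + n_act : n_inh + n_act + n_tox]] = "toxic"

    mult = np.ones(n)
    mult[classes == "inhibitor"] = _draw_effects(rng, config.inhibitor_effect, n_inh)
    mult[classes == "activator"] = _draw_effects(rng, config.activator_effect, n_act)
    viability = np.ones(n)
    viability[classes == "toxic"] = config.toxic_cell_fraction

    names = [f"C{i + 1:04d}" for i in range(n)]
    sd = np.asarray(config.morph_jitter_sd, dtype=float)
    corr = np.asarray(config.morph_jitter_corr, dtype=float)
    cov = np.outer(sd, sd) * corr
    jitter = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    shifts = np.array(
        [config.morph_shift_model.get(cls, (0.0, 0.0, 0.0)) for cls in classes]
    )
    sol0, ecc0, iba0 = (shifts + jitter).T.copy()
    for name, (ds, de, di) in config.morph_overrides.items():
        if name in names:
            i = names.index(name)
            sol0[i], ecc0[i], iba0[i] = ds, de, di
    return pd.DataFrame(
        {
            "compound": names,
            "effect_class": classes,
            "pi_multiplier": mult,
            "cell_viability": viability,
            "d_solidity": sol0,
            "d_eccentricity": ecc0,
            "d_iba1": iba0,
        }
    )


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full primary screen and return ``(fields, ground_truth)``.

    ``fields`` has one row per microscope field (:data:`FIELD_COLUMNS`);
    ``ground_truth`` has one row per compound with its effect class, true
    PI multiplier, surviving-cell fraction and morphology deltas.

    Replicate wells of a compound are placed on different plates (one plate
    set per replicate); DMSO and cytochalasin-D control wells occupy fixed
    columns on every plate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _assign_classes(rng, config)

    capacity = 96 - config.dmso_wells_per_plate - config.cytod_wells_per_plate
    n_plates = math.ceil(config.n_compounds / capacity)
    wells96 = _plate_well_names()
    dmso_wells = wells96[: config.dmso_wells_per_plate]
    cytod_wells = (
        wells96[-config.cytod_wells_per_plate :] if config.cytod_wells_per_plate else []
    )
    compound_slots = [w for w in wells96 if w not in dmso_wells and w not in cytod_wells]

    rows: list[dict] = []
    for rep in range(config.n_replicates_per_compound):
        for p in range(n_plates):
            plate = f"R{rep + 1}P{p + 1:02d}"
            start = p * capacity
            block = truth.iloc[start : start + capacity]
            for w in dmso_wells:
                rows.append(
                    dict(plate=plate, well=w, role="dmso", compound="DMSO",
                         dose_um=0.0, pi_multiplier=1.0, cell_viability=1.0,
                         d_solidity=0.0, d_eccentricity=0.0, d_iba1=0.0)
                )
            for w in cytod_wells:
                rows.append(
                    dict(plate=plate, well=w, role="cytod", compound="CytoD",
                         dose_um=2.0, pi_multiplier=config.cytod_effect,
                         cell_viability=1.0, d_solidity=0.0, d_eccentricity=0.0,
                         d_iba1=0.0)
                )
            for w, (_, t) in zip(compound_slots, block.iterrows()):
                rows.append(
                    dict(plate=plate, well=w, role="compound",
                         compound=t["compound"], dose_um=config.dose_um,
                         pi_multiplier=t["pi_multiplier"],
                         cell_viability=t["cell_viability"],
                         d_solidity=t["d_solidity"],
                         d_eccentricity=t["d_eccentricity"],
                         d_iba1=t["d_iba1"])
                )
    wells = pd.DataFrame(rows)
    fields = _fields_from_wells(wells, config, rng, config.fields_per_well)
    return fields, truth


def _fields_from_wells(
    wells: pd.DataFrame,
    config: ScreenSimConfig,
    rng: np.random.Generator,
    fields_per_well: int,
) -> pd.DataFrame:
    """Expand a well design table (with true multipliers/deltas) to fields."""
    F = fields_per_well
    n_wells = len(wells)
    n_fields = n_wells * F
    mult = np.repeat(wells["pi_multiplier"].to_numpy(), F)
    viability = np.repeat(wells["cell_viability"].to_numpy(), F)

    pi = _lognormal(rng, config.baseline_pi_mean * mult, config.baseline_pi_cv)
    cells = rng.poisson(config.cells_per_field_mean, size=n_fields)
    tox = viability < 1.0
    cells[tox] = rng.binomial(cells[tox], viability[tox])
    area = np.rint(pi * cells).astype(np.int64)

    sol0, ecc0, iba0 = config.morph_baseline
    sd_s, sd_e, sd_i = config.morph_field_sd
    sol = sol0 + np.repeat(wells["d_solidity"].to_numpy(), F) + rng.normal(0, sd_s, n_fields)
    ecc = ecc0 + np.repeat(wells["d_eccentricity"].to_numpy(), F) + rng.normal(0, sd_e, n_fields)
    iba = iba0 * (1.0 + np.repeat(wells["d_iba1"].to_numpy(), F)) + rng.normal(0, sd_i, n_fields)

    fields = pd.DataFrame(
        {
            "plate": np.repeat(wells["plate"].to_numpy(), F),
            "well": np.repeat(wells["well"].to_numpy(), F),
            "role": np.repeat(wells["role"].to_numpy(), F),
            "compound": np.repeat(wells["compound"].to_numpy(), F),
            "dose_um": np.repeat(wells["dose_um"].to_numpy(), F),
            "field_index": np.tile(np.arange(F), n_wells),
            "cell_count": cells,
            "synaptosome_area": area,
            "mean_solidity": np.clip(sol, 0.05, 1.0),
            "mean_eccentricity": np.clip(ecc, 0.0, 0.99),
            "mean_iba1": np.clip(iba, 0.0, None),
        }
    )[FIELD_COLUMNS]
    return fields


def simulate_secondary(
    config: ScreenSimConfig,
    truth: pd.DataFrame,
    compounds: Sequence[str],
    fields_per_well: int = 15,
    n_replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a secondary (confirmation) screen of selected compounds.

    Re-tests ``compounds`` at their primary-screen ground truth (same true
    PI multipliers and morphology deltas from ``truth``) with
    ``fields_per_well`` image fields per well, alongside DMSO control
    wells.  Returns a field table in the same layout as
    :func:`simulate_screen`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = truth.set_index("compound")
    missing = [c for c in compounds if c not in t.index]
    if missing:
        raise ConfigError(f"compounds missing from ground truth: {missing}")
    rows = []
    wells96 = _plate_well_names()
    capacity = 96 - config.dmso_wells_per_plate
    n_plates = math.ceil(len(compounds) / capacity)
    slots = wells96[config.dmso_wells_per_plate :]
    for rep in range(n_replicates):
        for p in range(n_plates):
            plate = f"S{rep + 1}P{p + 1:02d}"
            block = list(compounds)[p * capacity : (p + 1) * capacity]
            for w in wells96[: config.dmso_wells_per_plate]:
                rows.append(
                    dict(plate=plate, well=w, role="dmso", compound="DMSO",
                         dose_um=0.0, pi_multiplier=1.0, cell_viability=1.0,
                         d_solidity=0.0, d_eccentricity=0.0, d_iba1=0.0)
                )
            for w, name in zip(slots, block):
                tr = t.loc[name]
                rows.append(
                    dict(plate=plate, well=w, role="compound", compound=name,
                         dose_um=config.dose_um,
                         pi_multiplier=tr["pi_multiplier"],
                         cell_viability=tr["cell_viability"],
                         d_solidity=tr["d_solidity"],
                         d_eccentricity=tr["d_eccentricity"],
                         d_iba1=tr["d_iba1"])
                )
    return _fields_from_wells(pd.DataFrame(rows), config, rng, fields_per_well)


# ---------------------------------------------------------------------------
# field rendering


@dataclass
class CellSpec:
    """One cell to paint: centre (row, col), ellipse semi-axes in pixels,
    orientation in radians, morphotype and IBA1 intensity in [0, 1]."""

    row: float
    col: float
    semi_major: float
    semi_minor: float
    orientation: float = 0.0
    morphotype: str = "ameboid"  # ameboid | rod -> ellipse; ramified -> star
    iba1_intensity: float = 0.6


@dataclass
class FieldRenderSpec:
    """Scene description for :func:`render_field`."""

    shape: tuple[int, int] = (512, 512)
    cells: Sequence[CellSpec] = dc_field(default_factory=list)
    puncta_count: int = 0
    puncta_radius: int = 4
    puncta_placement: str = "inside"  # inside | outside
    nucleus_radius: int = 6
    background: float = 0.05
    noise_sd: float = 0.01
    overlap_cap: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        for c in self.cells:
            if not (0 <= c.row < h and 0 <= c.col < w):
                raise ConfigError("cell centre outside image bounds")
            if c.semi_major <= 0 or c.semi_minor <= 0:
                raise ConfigError("cell semi-axes must be positive")
            if not 0.0 <= c.iba1_intensity <= 1.0:
                raise ConfigError("iba1_intensity must lie in [0, 1]")
        if self.puncta_placement not in ("inside", "outside"):
            raise ConfigError("puncta_placement must be 'inside' or 'outside'")
        if self.puncta_radius <= 0:
            raise ConfigError("puncta_radius must be positive")


def _paint_cell(spec: FieldRenderSpec, cell: CellSpec) -> np.ndarray:
    """Boolean mask of one cell.  Ellipse for ameboid/rod; a small core with
    four narrow arms (low solidity, branched silhouette) for ramified."""
    h, w = spec.shape
    mask = np.zeros((h, w), dtype=bool)
    if cell.morphotype == "ramified":
        rr, cc = skdraw.ellipse(
            cell.row, cell.col, 0.35 * cell.semi_major, 0.35 * cell.semi_major,
            shape=(h, w),
        )
        mask[rr, cc] = True
        for k, ang in enumerate(
            (cell.orientation, cell.orientation + np.pi / 2,
             cell.orientation + np.pi / 4, cell.orientation - np.pi / 4)
        ):
            arm_len = cell.semi_major if k < 2 else 0.7 * cell.semi_major
            rr, cc = skdraw.ellipse(
                cell.row, cell.col, max(1.5, 0.15 * cell.semi_minor),
                arm_len, rotation=-ang, shape=(h, w),
            )
            mask[rr, cc] = True
    else:
        rr, cc = skdraw.ellipse(
            cell.row, cell.col, cell.semi_minor, cell.semi_major,
            rotation=-cell.orientation, shape=(h, w),
        )
        mask[rr, cc] = True
    return mask


def render_field(
    spec: FieldRenderSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a 3-channel field and its ground truth.

    Returns ``(image, cell_labels, puncta_mask)`` where ``image`` is a
    float32 array of shape ``(3, H, W)`` with channels nuclei, IBA1 and
    pHrodo (all in [0, 1]), ``cell_labels`` is the exact painted label mask
    (label ``i + 1`` for ``spec.cells[i]``), and ``puncta_mask`` marks the
    painted synaptosome puncta pixels.

    Raises :class:`RenderOverlapError` if any cell overlaps already painted
    cells by more than ``spec.overlap_cap`` of its own area.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    labels = np.zeros((h, w), dtype=np.int32)
    iba1 = np.zeros((h, w), dtype=np.float32)
    nuclei = np.zeros((h, w), dtype=np.float32)

    for i, cell in enumerate(spec.cells):
        mask = _paint_cell(spec, cell)
        n_pix = int(mask.sum())
        if n_pix == 0:
            continue
        overlap = int((mask & (labels > 0)).sum())
        if overlap > spec.overlap_cap * n_pix:
            raise RenderOverlapError(
                f"cell {i} overlaps existing cells on {overlap}/{n_pix} pixels"
            )
        paint = mask & (labels == 0)
        labels[paint] = i + 1
        iba1[paint] = cell.iba1_intensity
        rr, cc = skdraw.disk((cell.row, cell.col), spec.nucleus_radius, shape=(h, w))
        nuclei[rr, cc] = 0.9

    puncta = np.zeros((h, w), dtype=bool)
    if spec.puncta_count > 0:
        if spec.puncta_placement == "inside":
            cand = np.flatnonzero(labels.ravel() > 0)
            if cand.size == 0:
                raise ConfigError("no cell pixels to place 'inside' puncta on")
        else:
            dist = ndimage.distance_transform_edt(labels == 0)
            cand = np.flatnonzero((dist > spec.puncta_radius + 1).ravel())
        centers = rng.choice(cand, size=spec.puncta_count, replace=True)
        for flat in centers:
            r, c = divmod(int(flat), w)
            rr, cc = skdraw.disk((r, c), spec.puncta_radius, shape=(h, w))
            puncta[rr, cc] = True

    phrodo = np.where(puncta, 0.9, 0.0).astype(np.float32)
    image = np.stack([nuclei, iba1, phrodo])
    image += spec.background
    image += rng.normal(0.0, spec.noise_sd, size=image.shape).astype(np.float32)
    np.clip(image, 0.0, 1.0, out=image)
    return image.astype(np.float32), labels, puncta


def random_field_spec(
    n_cells: int,
    shape: tuple[int, int] = (512, 512),
    morphotype: str = "ameboid",
    puncta_count: int = 0,
    seed: int = 0,
    min_gap: float = 12.0,
    axis_range: tuple[float, float] = (15.0, 40.0),
    **kwargs,
) -> FieldRenderSpec:
    """Convenience builder: place ``n_cells`` non-overlapping cells of one
    morphotype at random positions (dart throwing with a minimum
    centre-to-centre gap)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    cells: list[CellSpec] = []
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(cells) < n_cells and attempts < 200 * max(n_cells, 1):
        attempts += 1
        a = rng.uniform(*axis_range)
        ratio = {"ameboid": 1.15, "rod": 3.0, "ramified": 1.0}.get(morphotype, 1.5)
        b = a / ratio
        margin = a + 5
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if any((r - r0) ** 2 + (c - c0) ** 2 < (2 * a + min_gap) ** 2 for r0, c0 in centers):
            continue
        cells.append(
            CellSpec(row=r, col=c, semi_major=a, semi_minor=b,
                     orientation=rng.uniform(0, np.pi), morphotype=morphotype,
                     iba1_intensity=rng.uniform(0.5, 0.8))
        )
        centers.append((r, c))
    if len(cells) < n_cells:
        raise ConfigError(f"could not place {n_cells} non-overlapping cells")
    return FieldRenderSpec(
        shape=shape, cells=cells, puncta_count=puncta_count, seed=seed, **kwargs
    )


# ---------------------------------------------------------------------------
# DRUG-seq-like counts


@dataclass
class CountsSimConfig:
    """Negative-binomial count-matrix simulation for a DRUG-seq-like plate.

    Baseline per-gene means are log-normal; counts are NB with a common
    (or gamma-distributed) dispersion; each well gets a log-normal library
    size factor.  Active compounds have ``n_de_genes`` genes shifted by
    ``de_log2fc`` (half up, half down).
    """

    n_genes: int = 2000
    n_dmso_wells: int = 12
    n_wells_per_compound: int = 4
    compounds: Sequence[str] | int = 8
    active: Sequence[str] | int = 0
    n_de_genes: int = 300
    de_log2fc: float = 2.0
    de_min_mean: float = 10.0  # plant DE only on detectably expressed genes
    mean_log_mu: float = 2.0
    mean_log_sigma: float = 1.5
    dispersion: float | tuple[float, float] = 0.1  # scalar, or gamma (shape, scale)
    libsize_cv: float = 0.2
    batch: str = "B1"
    seed: int = 0

    def compound_names(self) -> list[str]:
        if isinstance(self.compounds, int):
            return [f"C{i + 1:04d}" for i in range(self.compounds)]
        return list(self.compounds)

    def active_names(self) -> list[str]:
        names = self.compound_names()
        if isinstance(self.active, int):
            return names[: self.active]
        return list(self.active)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_dmso_wells <= 0 or self.n_wells_per_compound <= 0:
            raise ConfigError("counts, wells and genes must be positive")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes exceeds n_genes")
        if self.n_de_genes < 0:
            raise ConfigError("n_de_genes must be >= 0")
        disp = self.dispersion
        if isinstance(disp, (tuple, list)):
            if disp[0] <= 0 or disp[1] <= 0:
                raise ConfigError("gamma dispersion parameters must be > 0")
        elif disp <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.mean_log_sigma <= 0:
            raise ConfigError("mean_log_sigma must be > 0")
        if isinstance(self.active, int):
            n_comp = len(self.compound_names())
            if not 0 <= self.active <= n_comp:
                raise ConfigError(f"active={self.active} outside [0, {n_comp}]")
        unknown = set(self.active_names()) - set(self.compound_names())
        if unknown:
            raise ConfigError(f"active compounds not in compound list: {unknown}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws parameterised by mean and dispersion alpha (var = m + a m^2)."""
    r = 1.0 / np.maximum(alpha, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, mean.shape), np.broadcast_to(p, mean.shape))


def simulate_counts(
    config: CountsSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x well count matrix.

    Returns ``(counts, meta, truth)``: an integer DataFrame (genes as rows,
    wells as columns), a well metadata table (well, compound, role, batch),
    and a per-compound ground-truth table (active flag, planted DE genes).
    Wells of inactive compounds are exchangeable with DMSO wells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    names = config.compound_names()
    active = set(config.active_names())

    mu = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, size=config.n_genes)
    disp = config.dispersion
    if isinstance(disp, (tuple, list)):
        alpha = rng.gamma(disp[0], disp[1], size=config.n_genes)
    else:
        alpha = np.full(config.n_genes, float(disp))

    wells: list[str] = []
    meta_rows: list[dict] = []
    cols: list[np.ndarray] = []
    truth_rows: list[dict] = []

    def add_well(name: str, compound: str, role: str, fc: np.ndarray) -> None:
        s = _lognormal(rng, np.array(1.0), config.libsize_cv) if config.libsize_cv > 0 else 1.0
        m = mu * fc * float(s)
        cols.append(_nb_draw(rng, m, alpha))
        wells.append(name)
        meta_rows.append(dict(well=name, compound=compound, role=role, batch=config.batch))

    ones = np.ones(config.n_genes)
    for j in range(config.n_dmso_wells):
        add_well(f"DMSO_{j + 1:02d}", "DMSO", "dmso", ones)

    for name in names:
        fc = np.ones(config.n_genes)
        de_idx: np.ndarray = np.array([], dtype=int)
        if name in active and config.n_de_genes > 0:
            eligible = np.flatnonzero(mu >= config.de_min_mean)
            if eligible.size < config.n_de_genes:
                eligible = np.argsort(mu)[-config.n_de_genes :]
            de_idx = rng.choice(eligible, size=config.n_de_genes, replace=False)
            signs = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
            fc[de_idx] = 2.0 ** (config.de_log2fc * signs)
        for j in range(config.n_wells_per_compound):
            add_well(f"{name}_{j + 1:02d}", name, "compound", fc)
        truth_rows.append(
            dict(compound=name, rna_active=name in active,
                 n_de_genes=int(de_idx.size),
                 de_genes=";".join(genes[i] for i in sorted(de_idx)))
        )

    counts = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=genes, columns=wells
    )
    counts.index.name = "gene"
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return counts, meta, truth


def simulate_compound_phenotypes(
    n_compounds: int = 100,
    r_solidity_eccentricity: float = -0.9,
    seed: int = 0,
    solidity_mean: float = 0.72,
    eccentricity_mean: float = 0.70,
    sd: float = 0.08,
) -> pd.DataFrame:
    """Compound-level phenotype table with a planted solidity-eccentricity
    correlation, for validating the morphology statistics."""
    rng = np.random.default_rng(seed)
    r = float(r_solidity_eccentricity)
    cov = sd * sd * np.array([[1.0, r], [r, 1.0]])
    xy = rng.multivariate_normal([solidity_mean, eccentricity_mean], cov, size=n_compounds)
    return pd.DataFrame(
        {
            "compound": [f"C{i + 1:04d}" for i in range(n_compounds)],
            "mean_solidity": np.clip(xy[:, 0], 0.05, 1.0),
            "mean_eccentricity": np.clip(xy[:, 1], 0.0, 0.99),
        }
    )
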