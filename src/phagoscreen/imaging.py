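"""Per-field image measurements: segmentation, shape features, uptake area.

Replaces the high-content pipeline stage at desk scale.  Cells are
segmented from the IBA1 channel (background-subtracted, smoothed, Otsu
foreground) and split with a nuclei-seeded watershed; shape features use
the standard region-properties definitions — solidity is area over
convex-hull area, eccentricity is that of the ellipse with identical second
central moments (0 = circle).  Synaptosome uptake is the count of
above-threshold pHrodo pixels inside segmented cells (pH-sensitive dye:
signal outside cells is treated as background by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology as skmorph, segmentation

from .errors import InputError

__all__ = [
    "SegmentationParams",
    "CellShape",
    "FieldMeasurement",
    "segment_cells",
    "shape_features",
    "synaptosome_area",
    "measure_field",
]


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation recipe (a documented stand-in for
    the original high-content pipeline, whose parameters are not public)."""

    smoothing_sigma: float = 2.0
    background_radius: int = 50  # median-filter background subtraction; 0 = off
    min_cell_area: int = 50  # px, suppresses debris
    nuclei_smoothing_sigma: float = 2.0
    nuclei_threshold: float | None = None  # None -> Otsu
    iba1_threshold: float | None = None  # None -> Otsu
    phrodo_threshold: float = 0.5
    # Otsu on a signal-free field splits the noise floor; any automatic
    # threshold below this intensity is treated as "no foreground"
    min_intensity_floor: float = 0.15
    empty_field_max_cells: int = 0
    overseg_max_cells: int | None = None  # plate-level rule usually applies


@dataclass
class CellShape:
    """Shape and intensity summary of one segmented cell."""

    label: int
    area: int
    convex_area: int
    solidity: float
    eccentricity: float
    mean_iba1_intensity: float
    centroid: tuple[float, float]


@dataclass
class FieldMeasurement:
    """Measurements for one microscope field."""

    plate: str
    well: str
    field_index: int
    cell_count: int
    synaptosome_area: int
    cells: list[CellShape] = dc_field(default_factory=list)
    qc_flags: set = dc_field(default_factory=set)

    def to_row(self) -> dict:
        sols = [c.solidity for c in self.cells]
        eccs = [c.eccentricity for c in self.cells]
        ibas = [c.mean_iba1_intensity for c in self.cells]
        return dict(
            plate=self.plate,
            well=self.well,
            field_index=self.field_index,
            cell_count=self.cell_count,
            synaptosome_area=self.synaptosome_area,
            mean_solidity=float(np.mean(sols)) if sols else np.nan,
            mean_eccentricity=float(np.mean(eccs)) if eccs else np.nan,
            mean_iba1=float(np.mean(ibas)) if ibas else np.nan,
            qc_flags=";".join(sorted(self.qc_flags)),
        )


def _check_channels(*channels: np.ndarray) -> None:
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise InputError(f"channel shapes differ: {sorted(shapes)}")
    for c in channels:
        if c.ndim != 2:
            raise InputError("channels must be 2-D")
        if np.any(c < 0):
            raise InputError("channel intensities must be nonnegative")


def _subtract_background(img: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return img
    bg = ndimage.median_filter(img, size=2 * radius + 1)
    return np.clip(img - bg, 0.0, None)


def _foreground(
    img: np.ndarray, sigma: float, threshold: float | None, floor: float = 0.0
) -> np.ndarray:
    sm = ndimage.gaussian_filter(img.astype(float), sigma)
    if threshold is None:
        if sm.max() - sm.min() < 1e-9:  # blank channel: no foreground
            return np.zeros_like(sm, dtype=bool)
        threshold = max(filters.threshold_otsu(sm), floor)
    return sm > threshold


def segment_cells(
    nuclei: np.ndarray, iba1: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Label individual cells: IBA1 foreground defines cell extent, nuclei
    act as watershed seeds so touching cells with separate nuclei split.

    Foreground components without any nucleus seed are discarded; objects
    below ``min_cell_area`` are removed.  Returns an int32 label image.
    """
    params = params or SegmentationParams()
    nuclei = np.asarray(nuclei, dtype=float)
    iba1 = np.asarray(iba1, dtype=float)
    _check_channels(nuclei, iba1)

    iba1c = _subtract_background(iba1, params.background_radius)
    fg = _foreground(
        iba1c, params.smoothing_sigma, params.iba1_threshold,
        params.min_intensity_floor,
    )
    fg = skmorph.remove_small_objects(fg, max_size=params.min_cell_area - 1)
    if not fg.any():
        return np.zeros(iba1.shape, dtype=np.int32)

    seeds = _foreground(
        nuclei, params.nuclei_smoothing_sigma, params.nuclei_threshold,
        params.min_intensity_floor,
    )
    markers, n_mark = ndimage.label(seeds & fg)
    if n_mark == 0:
        return np.zeros(iba1.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(fg)
    labels = segmentation.watershed(-dist, markers, mask=fg, connectivity=1)
    labels = skmorph.remove_small_objects(labels, max_size=params.min_cell_area - 1)
    # compact labels so they are consecutive
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


def shape_features(labels: np.ndarray, iba1: np.ndarray) -> list[CellShape]:
    """One :class:`CellShape` per label (solidity = area / convex area;
    moments-ellipse eccentricity).  Empty mask -> empty list."""
    labels = np.asarray(labels)
    iba1 = np.asarray(iba1, dtype=float)
    _check_channels(labels, iba1)
    out: list[CellShape] = []
    for rp in measure.regionprops(labels, intensity_image=iba1):
        out.append(
            CellShape(
                label=int(rp.label),
                area=int(rp.area),
                convex_area=int(rp.area_convex),
                solidity=float(rp.solidity),
                eccentricity=float(rp.eccentricity),
                mean_iba1_intensity=float(rp.intensity_mean),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return out


def synaptosome_area(
    phrodo: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = 0.5,
) -> int:
    """Pixel count of pHrodo signal above ``threshold`` inside segmented
    cells.  ``threshold=None`` uses Otsu (0 on a blank channel)."""
    phrodo = np.asarray(phrodo, dtype=float)
    labels = np.asarray(labels)
    _check_channels(phrodo, labels)
    if threshold is None:
        if phrodo.max() - phrodo.min() < 1e-9:
            return 0
        threshold = filters.threshold_otsu(phrodo)
    return int(np.count_nonzero((phrodo > threshold) & (labels > 0)))


def measure_field(
    image: np.ndarray,
    plate: str = "",
    well: str = "",
    field_index: int = 0,
    params: SegmentationParams | None = None,
) -> FieldMeasurement:
    """Measure one 3-channel field (channel order nuclei, IBA1, pHrodo).

    Composes :func:`segment_cells`, :func:`shape_features` and
    :func:`synaptosome_area` and sets the per-field QC flags (``empty``;
    ``over_segmented`` when a per-field cap is configured — the robust
    plate-level rule lives in the screen-core stage).
    """
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 3:
        raise InputError("expected a (3, H, W) image: nuclei, IBA1, pHrodo")
    nuclei, iba1, phrodo = image
    labels = segment_cells(nuclei, iba1, params)
    cells = shape_features(labels, iba1)
    area = synaptosome_area(phrodo, labels, params.phrodo_threshold)
    flags: set = set()
    if len(cells) <= params.empty_field_max_cells:
        flags.add("empty")
    if params.overseg_max_cells is not None and len(cells) > params.overseg_max_cells:
        flags.add("over_segmented")
    return FieldMeasurement(
        plate=plate,
        well=well,
        field_index=field_index,
        cell_count=len(cells),
        synaptosome_area=area,
        cells=cells,
        qc_flags=flags,
    )
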