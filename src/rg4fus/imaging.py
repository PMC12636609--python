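"""Condensate image quantification.

Droplet assays: threshold-segment fluorescent droplets, measure per-droplet
size/area/intensity, and score FUS enrichment as mean intensity inside a
droplet divided by mean background intensity. Cell assays: enhance speckle-
scale foci with a white top-hat, mask out (shrunken) nuclei to isolate
cytoplasmic foci, and quantify colocalization of two channels with Pearson
correlation over the union of their foci masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = ["DropletRecord", "segment_droplets", "enrichment_scores",
           "phase_diagram", "enhance_speckles", "cytoplasmic_foci_mask",
           "pearson_colocalization", "count_assemblies"]


@dataclass(frozen=True)
class DropletRecord:
    """Per-droplet measurements from a segmented image."""

    label: int
    area_px: float
    size_px: float            # equivalent diameter
    mean_intensity: float
    area_um2: float | None = None
    enrichment: float | None = None


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or min(grid.shape) < 16:
        raise ValueError("intensity grid must be 2-D and at least 16x16")
    if not np.all(np.isfinite(grid)):
        raise ValueError("intensity grid must be finite")
    return grid


def _disk(diameter: int) -> np.ndarray:
    # feature sizes are specified as diameters in the assay conventions
    return morphology.disk(max(1, diameter // 2))


def segment_droplets(grid: np.ndarray, threshold: float | str = "otsu",
                     min_area: int = 4, pixel_size: float | None = None
                     ) -> tuple[np.ndarray, list[DropletRecord]]:
    """Threshold-segment droplets and measure them.

    The mask is ``grid >= threshold`` (Otsu-derived when requested);
    8-connected components smaller than ``min_area`` px are discarded.
    Returns the label map and one record per droplet. An image that is all
    background (or all foreground collapsing into nothing above threshold)
    yields zero droplets, not an error.
    """
    grid = _validate_grid(grid)
    if threshold == "otsu":
        if np.ptp(grid) == 0:
            return np.zeros(grid.shape, dtype=int), []
        threshold = threshold_otsu(grid)
    mask = grid >= float(threshold)
    labels = measure.label(mask, connectivity=2)
    records: list[DropletRecord] = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_id = 0
    for prop in measure.regionprops(labels, intensity_image=grid):
        if prop.area < min_area:
            continue
        next_id += 1
        keep[prop.label] = next_id
        records.append(DropletRecord(
            label=next_id,
            area_px=float(prop.area),
            size_px=float(prop.equivalent_diameter_area),
            mean_intensity=float(prop.intensity_mean),
            area_um2=(float(prop.area) * pixel_size ** 2
                      if pixel_size is not None else None),
        ))
    return keep[labels], records


def enrichment_scores(grid: np.ndarray, label_map: np.ndarray,
                      halo_px: int = 2) -> list[float]:
    """Per-droplet enrichment: mean intensity inside / mean background.

    Background pixels are those outside every labelled droplet dilated by
    ``halo_px``, so partition estimates are not diluted by droplet rims.
    """
    grid = _validate_grid(grid)
    if label_map.shape != grid.shape:
        raise ValueError("label map and grid shapes differ")
    foreground = label_map > 0
    excluded = (morphology.dilation(foreground, morphology.disk(halo_px))
                if halo_px > 0 else foreground)
    background = ~excluded
    if not background.any():
        raise ValueError("no background pixels remain after halo exclusion")
    bg_mean = float(grid[background].mean())
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    scores = []
    for lab in range(1, int(label_map.max()) + 1):
        inside = label_map == lab
        if inside.any():
            scores.append(float(grid[inside].mean()) / bg_mean)
    return scores


def phase_diagram(per_image: pd.DataFrame) -> pd.DataFrame:
    """Summarise droplet measurements into phase-diagram cells.

    ``per_image`` has one row per (condition, time, image) with columns
    ``condition``, ``time``, ``image``, ``count`` and (optionally, one row
    per droplet) ``enrichment``. Returns per (condition, time): mean droplet
    count per image and mean enrichment pooled over droplets (NA when a cell
    has no droplets).
    """
    required = {"condition", "time", "image", "count"}
    if not required <= set(per_image.columns):
        raise ValueError(f"per_image must have columns {sorted(required)}")
    rows = []
    for (cond, time), grp in per_image.groupby(["condition", "time"],
                                               sort=True):
        mean_count = grp.drop_duplicates("image")["count"].mean()
        if "enrichment" in grp.columns:
            enr = grp["enrichment"].dropna()
            mean_enr = float(enr.mean()) if len(enr) else np.nan
        else:
            mean_enr = np.nan
        rows.append({"condition": cond, "time": time,
                     "mean_count": float(mean_count),
                     "mean_enrichment": mean_enr})
    return pd.DataFrame(rows)


def enhance_speckles(grid: np.ndarray, feature_size: int = 20) -> np.ndarray:
    """White top-hat speckle enhancement.

    Subtracts the morphological opening with a disk of diameter
    ``feature_size``, keeping bright features smaller than the disk and
    suppressing broad background (nuclei, gradients).
    """
    grid = _validate_grid(grid)
    if feature_size < 2:
        raise ValueError("feature_size must be >= 2")
    return morphology.white_tophat(grid, footprint=_disk(feature_size))


def cytoplasmic_foci_mask(foci_grid: np.ndarray, nuclei_grid: np.ndarray,
                          shrink_px: int = 5,
                          threshold: float | str = "otsu",
                          feature_size: int = 20) -> np.ndarray:
    """Binary mask of cytoplasmic foci.

    Foci are thresholded from the speckle-enhanced channel; the nuclei mask
    is eroded by ``shrink_px`` (so peri-nuclear foci are not swallowed) and
    inverted before intersection with the foci mask.
    """
    foci_grid = _validate_grid(foci_grid)
    nuclei_grid = _validate_grid(nuclei_grid)
    if foci_grid.shape != nuclei_grid.shape:
        raise ValueError("channel shapes differ")
    enhanced = enhance_speckles(foci_grid, feature_size)
    if threshold == "otsu":
        if np.ptp(enhanced) == 0:
            foci = np.zeros(enhanced.shape, dtype=bool)
        else:
            foci = enhanced >= threshold_otsu(enhanced)
    else:
        foci = enhanced >= float(threshold)
    if np.ptp(nuclei_grid) == 0:
        nuclei = np.zeros(nuclei_grid.shape, dtype=bool)
    else:
        nuclei = nuclei_grid >= threshold_otsu(nuclei_grid)
    if shrink_px > 0:
        nuclei = morphology.erosion(nuclei, morphology.disk(shrink_px))
    return foci & ~nuclei


def pearson_colocalization(grid_a: np.ndarray, grid_b: np.ndarray,
                           mask: np.ndarray) -> float:
    """Pearson correlation of two channels' raw intensities within a mask.

    The mask is conventionally the union of both channels' cytoplasmic foci
    masks. Requires at least 10 mask pixels and nonzero variance in both
    channels within the mask.
    """
    grid_a = _validate_grid(grid_a)
    grid_b = _validate_grid(grid_b)
    if grid_a.shape != grid_b.shape or mask.shape != grid_a.shape:
        raise ValueError("channel/mask shapes differ")
    mask = mask.astype(bool)
    if mask.sum() < 10:
        raise ValueError("mask must contain at least 10 pixels")
    a, b = grid_a[mask], grid_b[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within mask")
    return float(np.corrcoef(a, b)[0, 1])


def count_assemblies(label_maps: Sequence[np.ndarray]) -> float:
    """Mean number of segmented assemblies per image."""
    if not label_maps:
        raise ValueError("at least one image is required")
    return float(np.mean([int(lm.max()) for lm in label_maps]))
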