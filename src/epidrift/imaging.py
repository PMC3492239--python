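"""Nuclear segmentation and per-nucleus morphometry/intensity features.

The DAPI channel is segmented with a block-wise adaptive Otsu threshold and
a size filter; for every retained nucleus 25 features are extracted: 11
shape descriptors and 14 intensity descriptors of the immunomarker channel.
Feature definitions follow the CellProfiler conventions:

shape (11)
    area, compactness = P^2/(4*pi*A), eccentricity, euler_number, extent,
    form_factor = 4*pi*A/P^2, major_axis_length, minor_axis_length,
    orientation (radians in (-pi/2, pi/2]), perimeter, solidity

intensity (14)
    {integrated, mean, std, min, max} over the full segmentation and over
    its edge (mask minus its erosion), plus mass_displacement (distance in
    px between the binary and the intensity-weighted centroid),
    lower_quartile, median and upper_quartile over the full segmentation.

Coordinates are (row, col), 0-based pixel centers; objects are 8-connected.
Border-touching nuclei are discarded: their truncated features would bias
the population statistics.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops, label as sk_label
from skimage.transform import resize

__all__ = [
    "segment_nuclei",
    "shape_features",
    "intensity_features",
    "extract_nuclei",
    "build_feature_table",
    "read_feature_table",
    "write_feature_table",
    "SHAPE_FEATURES",
    "INTENSITY_FEATURES",
    "FEATURE_COLUMNS",
]

SHAPE_FEATURES = (
    "area", "compactness", "eccentricity", "euler_number", "extent",
    "form_factor", "major_axis_length", "minor_axis_length", "orientation",
    "perimeter", "solidity",
)
INTENSITY_FEATURES = (
    "integrated_intensity", "mean_intensity", "std_intensity",
    "min_intensity", "max_intensity",
    "integrated_intensity_edge", "mean_intensity_edge", "std_intensity_edge",
    "min_intensity_edge", "max_intensity_edge",
    "mass_displacement", "lower_quartile_intensity", "median_intensity",
    "upper_quartile_intensity",
)
FEATURE_COLUMNS = SHAPE_FEATURES + INTENSITY_FEATURES

_EIGHT = np.ones((3, 3), dtype=bool)


def _adaptive_otsu_surface(image: np.ndarray, block_size: int) -> np.ndarray:
    """Per-block Otsu thresholds, bilinearly interpolated to full size.

    Blocks without bimodal content (flat background) fall back to the global
    Otsu threshold so empty regions do not produce spurious foreground.
    """
    img = np.asarray(image, dtype=float)
    try:
        global_t = float(threshold_otsu(img))
    except ValueError:  # constant image
        return np.full(img.shape, np.inf)

    nr = max(1, int(np.ceil(img.shape[0] / block_size)))
    nc = max(1, int(np.ceil(img.shape[1] / block_size)))
    grid = np.empty((nr, nc))
    for i in range(nr):
        for j in range(nc):
            blk = img[i * block_size:(i + 1) * block_size,
                      j * block_size:(j + 1) * block_size]
            # flat or foreground-free block: use the global threshold
            if np.ptp(blk) < 1e-12 or blk.max() < global_t:
                grid[i, j] = global_t
            else:
                t = float(threshold_otsu(blk))
                # clamp implausible local thresholds toward the global one
                grid[i, j] = t if t >= 0.5 * global_t else global_t
    if nr == 1 and nc == 1:
        return np.full(img.shape, grid[0, 0])
    return resize(grid, img.shape, order=1, mode="edge", anti_aliasing=False)


def segment_nuclei(
    dapi: np.ndarray,
    min_area: float = 80.0,
    max_area: float = 5000.0,
    block_size: int = 128,
    discard_border: bool = True,
) -> np.ndarray:
    """Segment nuclei from the DAPI channel.

    Adaptive Otsu thresholding (block-wise threshold surface, bilinear
    interpolation) followed by 8-connected labelling, removal of objects
    with area outside ``[min_area, max_area]`` and of border-touching
    objects.  Labels are relabelled contiguously from 1.  A blank image
    yields an empty mask with a warning.
    """
    if dapi.ndim != 2:
        raise ValueError("expected a single-channel image")
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")

    surface = _adaptive_otsu_surface(dapi, block_size)
    binary = np.asarray(dapi, dtype=float) > surface
    if not binary.any():
        warnings.warn("no foreground found; returning an empty mask")
        return np.zeros(dapi.shape, dtype=np.int32)

    labels = sk_label(binary, connectivity=2)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    areas = np.bincount(labels.ravel())
    keep[1:] = (areas[1:] >= min_area) & (areas[1:] <= max_area)
    if discard_border:
        border = np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
        ])
        keep[np.unique(border[border > 0])] = False

    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[np.flatnonzero(keep)] = np.arange(1, int(keep.sum()) + 1)
    out = remap[labels]
    if out.max() == 0:
        warnings.warn("no objects retained after size/border filtering")
    return out


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """The 11 shape descriptors of a single-nucleus binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = sk_label(mask, connectivity=2)
    if lab.max() != 1:
        raise ValueError("mask must contain exactly one connected component")
    rp = regionprops(lab)[0]
    area = float(rp.area)
    perim = float(rp.perimeter)
    form_factor = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
    return {
        "area": area,
        "compactness": 1.0 / form_factor,
        "eccentricity": float(rp.eccentricity),
        "euler_number": float(rp.euler_number),
        "extent": float(rp.extent),
        "form_factor": form_factor,
        "major_axis_length": float(rp.axis_major_length),
        "minor_axis_length": float(rp.axis_minor_length),
        "orientation": float(rp.orientation),
        "perimeter": perim,
        "solidity": float(rp.solidity),
    }


def _edge_mask(mask: np.ndarray) -> np.ndarray:
    """Perimeter pixels: mask minus its 8-connected erosion."""
    return mask & ~ndimage.binary_erosion(mask, structure=_EIGHT)


def intensity_features(mask: np.ndarray, marker: np.ndarray) -> dict[str, float]:
    """The 14 intensity descriptors of one nucleus over the marker channel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.shape != marker.shape:
        raise ValueError("mask and image shapes differ")
    vals = np.asarray(marker, dtype=float)[mask]
    edge = _edge_mask(mask)
    evals = np.asarray(marker, dtype=float)[edge]

    rows, cols = np.nonzero(mask)
    binary_c = np.array([rows.mean(), cols.mean()])
    total = vals.sum()
    if total > 0:
        weighted_c = np.array([
            (rows * vals).sum() / total, (cols * vals).sum() / total
        ])
        mass_disp = float(np.hypot(*(weighted_c - binary_c)))
    else:
        mass_disp = 0.0  # zero total intensity: displacement defined as 0

    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "integrated_intensity": float(vals.sum()),
        "mean_intensity": float(vals.mean()),
        "std_intensity": float(vals.std()),
        "min_intensity": float(vals.min()),
        "max_intensity": float(vals.max()),
        "integrated_intensity_edge": float(evals.sum()),
        "mean_intensity_edge": float(evals.mean()),
        "std_intensity_edge": float(evals.std()),
        "min_intensity_edge": float(evals.min()),
        "max_intensity_edge": float(evals.max()),
        "mass_displacement": mass_disp,
        "lower_quartile_intensity": float(q1),
        "median_intensity": float(q2),
        "upper_quartile_intensity": float(q3),
    }


def extract_nuclei(
    dapi: np.ndarray,
    marker: np.ndarray,
    group_id: int,
    source_image: str = "field",
    **segment_kw,
) -> pd.DataFrame:
    """Segment one field and return its per-nucleus feature rows."""
    if dapi.shape != marker.shape:
        raise ValueError(
            f"channel size mismatch: DAPI {dapi.shape} vs marker {marker.shape}"
        )
    labels = segment_nuclei(dapi, **segment_kw)
    rows = []
    for rp in regionprops(labels):
        sl = rp.slice
        m = labels[sl] == rp.label
        feats = shape_features(m)
        feats.update(intensity_features(m, np.asarray(marker, dtype=float)[sl]))
        row = {
            "label": rp.label,
            "centroid_row": rp.centroid[0] + sl[0].start,
            "centroid_col": rp.centroid[1] + sl[1].start,
            "group_id": group_id,
            "source_image": source_image,
        }
        row.update(feats)
        rows.append(row)
    cols = ["label", "centroid_row", "centroid_col", "group_id",
            "source_image", *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


def build_feature_table(fields) -> pd.DataFrame:
    """Merge per-field extractions into one table, one row per nucleus.

    ``fields`` is a sequence of (dapi, marker, group_id) or
    (dapi, marker, group_id, source_image) tuples.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("at least one field is required")
    tables = []
    for i, f in enumerate(fields):
        if len(f) == 3:
            dapi, marker, gid = f
            name = f"field{i}"
        else:
            dapi, marker, gid, name = f
        tables.append(extract_nuclei(dapi, marker, gid, source_image=name))
    return pd.concat(tables, ignore_index=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
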