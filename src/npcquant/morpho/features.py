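"""Per-cell metrics, per-image feature matrices and area analysis.

The effective cell diameter is the geometric mean of the fitted-ellipse
axes — for an ellipse this equals the diameter of the circle with the
same area, making it robust to orientation.  The aspect ratio
(oblongness) is major/minor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from npcquant.morpho.classify import AnnulusSpec, background_level, classify_cell
from npcquant.morpho.enhance import (
    enhance_marker,
    enhance_nuclear,
    normalize_channel,
)
from npcquant.morpho.segment import NucleusRecord, segment_nuclei

CLASSES = ("red_positive", "green_positive", "double", "negative")


def cell_metrics(
    nucleus: NucleusRecord, convention: str = "geometric"
) -> tuple[float, float]:
    """(effective_diameter, aspect_ratio) from the fitted ellipse."""
    major, minor = nucleus.major_axis, nucleus.minor_axis
    if major <= 0 or minor <= 0:
        raise ValueError("degenerate ellipse: axes must be positive")
    if convention == "geometric":
        diameter = float(np.sqrt(major * minor))
    elif convention == "arithmetic":
        diameter = float((major + minor) / 2.0)
    else:
        raise ValueError(f"unknown diameter convention {convention!r}")
    return diameter, float(major / minor)


@dataclass
class MorphoConfig:
    """Tunable parameters of the image pipeline (pixel units)."""

    nucleus_radius: float = 10.0
    accept: dict = field(
        default_factory=lambda: {"min_area": 40.0, "max_area": 5000.0,
                                 "min_circularity": 0.5}
    )
    annulus: AnnulusSpec = field(default_factory=AnnulusSpec)
    presence_threshold: float = 3.0
    marker_highpass_sigma: float = 20.0
    diameter_convention: str = "geometric"


def measure_image(
    nuclear: np.ndarray,
    red: np.ndarray | None = None,
    green: np.ndarray | None = None,
    config: MorphoConfig | None = None,
) -> pd.DataFrame:
    """Run enhancement, segmentation, classification and metrics on one field.

    Returns one row per retained nucleus with centroid, ellipse axes,
    effective diameter, aspect ratio and marker classification.
    """
    config = config or MorphoConfig()
    nuc_enh = enhance_nuclear(
        normalize_channel(nuclear), nucleus_radius=config.nucleus_radius
    )
    red_enh = (
        enhance_marker(normalize_channel(red), config.marker_highpass_sigma)
        if red is not None
        else None
    )
    green_enh = (
        enhance_marker(normalize_channel(green), config.marker_highpass_sigma)
        if green is not None
        else None
    )
    # image-level background statistics computed once, reused per cell
    red_level = (
        background_level(red_enh, config.presence_threshold)
        if red_enh is not None else None
    )
    green_level = (
        background_level(green_enh, config.presence_threshold)
        if green_enh is not None else None
    )
    rows = []
    for nucleus in segment_nuclei(nuc_enh, config.accept):
        diameter, aspect = cell_metrics(nucleus, config.diameter_convention)
        cls = classify_cell(
            nucleus, red_enh, green_enh, config.annulus,
            config.presence_threshold, red_level, green_level,
        )
        rows.append(
            {
                "cx": nucleus.centroid[0],
                "cy": nucleus.centroid[1],
                "area": nucleus.area,
                "major": nucleus.major_axis,
                "minor": nucleus.minor_axis,
                "diameter": diameter,
                "aspect": aspect,
                "classification": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cx", "cy", "area", "major", "minor", "diameter", "aspect",
                 "classification"],
    )


def feature_matrix(per_image_cells: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per image x cell class: count, diameter mean/sd, aspect mean/sd.

    ``per_image_cells`` maps image id to a :func:`measure_image` frame.
    Standard deviations are absent (NaN) when fewer than 2 cells.
    """
    rows = []
    for image_id, cells in per_image_cells.items():
        for cls in CLASSES:
            sub = cells[cells["classification"] == cls] if len(cells) else cells
            n = len(sub)
            rows.append(
                {
                    "image": image_id,
                    "classification": cls,
                    "count": n,
                    "diameter_mean": sub["diameter"].mean() if n else np.nan,
                    "diameter_sd": sub["diameter"].std(ddof=1) if n > 1 else np.nan,
                    "aspect_mean": sub["aspect"].mean() if n else np.nan,
                    "aspect_sd": sub["aspect"].std(ddof=1) if n > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def group_fold_change(
    per_image_cells: dict[str, pd.DataFrame],
    groups: dict[str, str],
    classes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Cell-level group comparison: fold change of mean diameter and aspect.

    ``groups`` maps image id to one of exactly two group labels; folds
    are second group over first (labels sorted).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    pooled = []
    for image_id, cells in per_image_cells.items():
        if len(cells) == 0:
            continue
        sub = cells.copy()
        sub["group"] = groups[image_id]
        pooled.append(sub)
    allcells = pd.concat(pooled, ignore_index=True)
    if classes is not None:
        allcells = allcells[allcells["classification"].isin(classes)]
    rows = []
    for metric in ("diameter", "aspect"):
        means = allcells.groupby("group")[metric].mean()
        counts = allcells.groupby("group")[metric].size()
        rows.append(
            {
                "metric": metric,
                f"mean_{labels[0]}": means[labels[0]],
                f"mean_{labels[1]}": means[labels[1]],
                f"n_{labels[0]}": int(counts[labels[0]]),
                f"n_{labels[1]}": int(counts[labels[1]]),
                "fold": means[labels[1]] / means[labels[0]],
            }
        )
    return pd.DataFrame(rows)


def actin_area(
    actin_raster: np.ndarray,
    nuclear_raster: np.ndarray,
    threshold_method: str = "otsu",
    config: MorphoConfig | None = None,
) -> dict:
    """Total thresholded F-actin area, nuclear cell count and area per cell.

    Returns keys ``total_area`` (px), ``cell_count`` and
    ``mean_area_per_cell`` (None when the field has no nuclei).
    """
    if actin_raster.shape != nuclear_raster.shape:
        raise ValueError("actin and nuclear channels must share a shape")
    config = config or MorphoConfig()
    actin = normalize_channel(actin_raster)
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if np.ptp(actin) < 1e-12:
        total = 0
    else:
        total = int((actin > threshold_otsu(actin)).sum())
    nuc_enh = enhance_nuclear(
        normalize_channel(nuclear_raster), nucleus_radius=config.nucleus_radius
    )
    count = len(segment_nuclei(nuc_enh, config.accept))
    return {
        "total_area": total,
        "cell_count": count,
        "mean_area_per_cell": (total / count) if count else None,
    }


def density_match(
    image_counts: dict[str, int],
    groups: dict[str, str],
    bin_width: int = 10,
) -> dict[str, list[str]]:
    """Retain only images in nuclear-count bins populated by both groups.

    Returns the retained image ids per group, deterministically ordered.
    An empty result (no overlapping bins) is accompanied by a warning.
    """
    import warnings

    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins: dict[str, dict[int, list[str]]] = {lab: {} for lab in labels}
    for image_id in sorted(image_counts):
        b = image_counts[image_id] // bin_width
        bins[groups[image_id]].setdefault(b, []).append(image_id)
    shared = sorted(set(bins[labels[0]]) & set(bins[labels[1]]))
    if not shared:
        warnings.warn("no density bins shared between groups; empty match",
                      stacklevel=2)
    return {
        lab: [img for b in shared for img in bins[lab][b]] for lab in labels
    }
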