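"""Nucleus segmentation and sieving.

Otsu threshold on the enhanced nuclear channel, connected components,
contour extraction and a sieve on area and circularity.  Each retained
contour gets a moment-based ellipse fit (centroid, major/minor axes,
orientation).  Touching nuclei are not split; generators used for
benchmarking enforce a minimum center spacing instead.

Coordinates are pixel-centered with origin at the top-left corner,
x rightward (columns) and y downward (rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops


@dataclass
class NucleusRecord:
    """One segmented nucleus: contour, centroid, area, fitted ellipse."""

    label: int
    centroid: tuple[float, float]  # (x, y)
    area: float
    major_axis: float
    minor_axis: float
    orientation: float
    circularity: float
    contour: np.ndarray = field(repr=False)  # (N, 2) array of (x, y)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def equivalent_radius(self) -> float:
        return float(np.sqrt(self.area / np.pi))


DEFAULT_ACCEPT = {"min_area": 40.0, "max_area": 5000.0, "min_circularity": 0.5}


def segment_nuclei(
    enhanced: np.ndarray,
    accept: dict | None = None,
) -> list[NucleusRecord]:
    """Segment and sieve nuclei from an enhanced nuclear channel.

    ``accept`` may override ``min_area``, ``max_area`` and
    ``min_circularity`` (circularity = 4*pi*area/perimeter^2).  A blank
    field yields an empty list.
    """
    params = dict(DEFAULT_ACCEPT)
    if accept:
        params.update(accept)
    enhanced = np.asarray(enhanced, dtype=float)
    if enhanced.max() <= 0 or np.ptp(enhanced) < 1e-12:
        return []
    thresh = threshold_otsu(enhanced)
    mask = enhanced > thresh
    if not mask.any():
        return []
    labeled = label(mask)
    records: list[NucleusRecord] = []
    for region in regionprops(labeled):
        area = float(region.area)
        if area < params["min_area"] or area > params["max_area"]:
            continue
        perimeter = float(region.perimeter)
        circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
        circularity = min(circularity, 1.0)
        if circularity < params["min_circularity"]:
            continue
        if region.axis_minor_length <= 0:
            continue
        # contour in global coordinates, (x, y) order
        minr, minc, maxr, maxc = region.bbox
        padded = np.pad(region.image, 1)
        contours = find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        longest = max(contours, key=len)
        contour_xy = np.column_stack(
            [longest[:, 1] - 1 + minc, longest[:, 0] - 1 + minr]
        )
        cy, cx = region.centroid
        records.append(
            NucleusRecord(
                label=int(region.label),
                centroid=(float(cx), float(cy)),
                area=area,
                major_axis=float(region.axis_major_length),
                minor_axis=float(region.axis_minor_length),
                orientation=float(region.orientation),
                circularity=circularity,
                contour=contour_xy,
                bbox=(minr, minc, maxr, maxc),
            )
        )
    records.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return records
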