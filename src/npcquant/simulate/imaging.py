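"""Synthetic fluorescence-microscopy fields with per-cell ground truth.

Fields emulate a nuclear stain (filled, blurred ellipses over a smooth
background gradient plus noise) and one or two cytoplasmic markers
rendered as annular soma rings around the nuclei a marker is assigned
to.  One focal plane, one grayscale raster per channel.  Every rendered
cell carries a truth record (centroid, ellipse axes, marker class), so
segmentation and classification accuracy can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse


@dataclass(frozen=True)
class ImageSimSpec:
    """Design of a simulated multi-channel field."""

    width: int = 512
    height: int = 512
    n_cells: int = 50
    diameter_mean: float = 20.0
    diameter_sd: float = 3.0
    aspect_mean: float = 1.3
    aspect_sd: float = 0.2
    p_marker_red: float = 0.6
    p_marker_green: float = 0.3
    soma_annulus_width: float = 6.0
    background_gradient_amp: float = 0.1
    noise_sd: float = 0.02
    min_center_spacing: float = 36.0
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.diameter_mean <= 0 or self.diameter_sd < 0:
            raise ValueError("diameters must be positive")
        if self.aspect_mean < 1:
            raise ValueError("aspect ratio must be >= 1")
        for name in ("p_marker_red", "p_marker_green"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class MultiChannelImage:
    """Aligned grayscale channels of one field (float, arbitrary units)."""

    nuclear: np.ndarray
    red: np.ndarray | None = None
    green: np.ndarray | None = None
    actin: np.ndarray | None = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        for name in ("red", "green", "actin"):
            ch = getattr(self, name)
            if ch is not None and ch.shape != self.nuclear.shape:
                raise ValueError(f"channel {name!r} shape differs from nuclear")

    def channels(self) -> dict[str, np.ndarray]:
        out = {"nuclear": self.nuclear}
        for name in ("red", "green", "actin"):
            ch = getattr(self, name)
            if ch is not None:
                out[name] = ch
        return out

    def to_tiff(self, directory, prefix: str = "field") -> list[str]:
        import tifffile

        paths = []
        for name, ch in self.channels().items():
            path = f"{directory}/{prefix}_{name}.tif"
            tifffile.imwrite(path, ch.astype(np.float32))
            paths.append(path)
        return paths

    @classmethod
    def from_tiff(cls, nuclear, red=None, green=None, actin=None) -> "MultiChannelImage":
        import tifffile

        def load(p):
            return None if p is None else tifffile.imread(p).astype(float)

        return cls(load(nuclear), load(red), load(green), load(actin))


@dataclass
class ImageTruth:
    """Per-cell ground truth for a simulated field."""

    cells: pd.DataFrame = field(repr=False)

    def to_json(self) -> str:
        return json.dumps(self.cells.to_dict(orient="records"))

    @classmethod
    def from_json(cls, text: str) -> "ImageTruth":
        return cls(pd.DataFrame(json.loads(text)))


_TRUTH_COLUMNS = [
    "cell_id", "cx", "cy", "major", "minor", "orientation",
    "diameter", "aspect", "red", "green", "classification",
]


def _place_centers(rng, spec: ImageSimSpec) -> np.ndarray:
    """Rejection-sample cell centers honoring the minimum spacing."""
    margin = spec.diameter_mean * 1.2
    centers: list[tuple[float, float]] = []
    max_tries = 300 * max(spec.n_cells, 1)
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {spec.n_cells} cells at spacing "
                f"{spec.min_center_spacing} within {spec.width}x{spec.height} "
                f"after {max_tries} tries"
            )
        tries += 1
        x = rng.uniform(margin, spec.width - margin)
        y = rng.uniform(margin, spec.height - margin)
        if all(
            (x - cx) ** 2 + (y - cy) ** 2 >= spec.min_center_spacing**2
            for cx, cy in centers
        ):
            centers.append((x, y))
    return np.asarray(centers).reshape(-1, 2)


def _classification(red: bool, green: bool) -> str:
    if red and green:
        return "double"
    if red:
        return "red_positive"
    if green:
        return "green_positive"
    return "negative"


def gen_image(spec: ImageSimSpec) -> tuple[MultiChannelImage, ImageTruth]:
    """Render a nuclear + red + green field with known per-cell truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    nuclear = np.zeros(shape)
    red = np.zeros(shape)
    green = np.zeros(shape)

    centers = _place_centers(rng, spec)
    records = []
    for i in range(spec.n_cells):
        x, y = centers[i]
        d = max(rng.normal(spec.diameter_mean, spec.diameter_sd), 4.0)
        aspect = max(rng.normal(spec.aspect_mean, spec.aspect_sd), 1.0)
        major = d * np.sqrt(aspect)
        minor = d / np.sqrt(aspect)
        theta = rng.uniform(0.0, np.pi)
        rr, cc = draw_ellipse(y, x, major / 2, minor / 2, shape=shape, rotation=theta)
        nuclear[rr, cc] = 1.0

        has_red = rng.random() < spec.p_marker_red
        has_green = rng.random() < spec.p_marker_green
        if has_red or has_green:
            r_in = major / 2 + 1.0
            r_out = r_in + spec.soma_annulus_width
            rr_o, cc_o = draw_ellipse(y, x, r_out, r_out * minor / major, shape=shape,
                                      rotation=theta)
            ring = np.zeros(shape, dtype=bool)
            ring[rr_o, cc_o] = True
            rr_i, cc_i = draw_ellipse(y, x, r_in, r_in * minor / major, shape=shape,
                                      rotation=theta)
            ring[rr_i, cc_i] = False
            if has_red:
                red[ring] = 1.0
            if has_green:
                green[ring] = 1.0
        records.append(
            (f"cell{i + 1}", x, y, major, minor, theta, d, aspect,
             has_red, has_green, _classification(has_red, has_green))
        )

    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    gradient = spec.background_gradient_amp * (
        0.5 * xx / max(spec.width - 1, 1) + 0.5 * yy / max(spec.height - 1, 1)
    )

    nuclear = gaussian_filter(nuclear, 1.5) + gradient
    red = gaussian_filter(red, 1.0) + 0.5 * gradient
    green = gaussian_filter(green, 1.0) + 0.5 * gradient
    if spec.noise_sd > 0:
        nuclear = nuclear + rng.normal(0, spec.noise_sd, shape)
        red = red + rng.normal(0, spec.noise_sd, shape)
        green = green + rng.normal(0, spec.noise_sd, shape)

    image = MultiChannelImage(
        nuclear=np.clip(nuclear, 0, None),
        red=np.clip(red, 0, None),
        green=np.clip(green, 0, None),
    )
    truth = ImageTruth(pd.DataFrame(records, columns=_TRUTH_COLUMNS))
    return image, truth


def gen_actin_field(
    width: int = 512,
    height: int = 512,
    n_cells: int = 30,
    nucleus_radius: float = 8.0,
    cell_radius: float = 18.0,
    noise_sd: float = 0.02,
    min_center_spacing: float = 40.0,
    seed: int = 0,
) -> tuple[MultiChannelImage, dict]:
    """Field with disk-shaped F-actin footprints of known total area.

    Returns the image (nuclear + actin channels) and a truth dict with
    the exact painted pixel area and the cell count.
    """
    spec = ImageSimSpec(
        width=width, height=height, n_cells=n_cells,
        diameter_mean=2 * nucleus_radius, diameter_sd=0.0,
        aspect_mean=1.0, aspect_sd=0.0,
        min_center_spacing=min_center_spacing, seed=seed,
    )
    rng = np.random.default_rng(seed)
    shape = (height, width)
    centers = _place_centers(rng, spec)
    nuclear = np.zeros(shape)
    actin_mask = np.zeros(shape, dtype=bool)
    for x, y in centers:
        rr, cc = draw_ellipse(y, x, nucleus_radius, nucleus_radius, shape=shape)
        nuclear[rr, cc] = 1.0
        rr, cc = draw_ellipse(y, x, cell_radius, cell_radius, shape=shape)
        actin_mask[rr, cc] = True
    painted_area = int(actin_mask.sum())
    nuclear = gaussian_filter(nuclear, 1.0)
    actin = gaussian_filter(actin_mask.astype(float), 1.0)
    if noise_sd > 0:
        nuclear = nuclear + rng.normal(0, noise_sd, shape)
        actin = actin + rng.normal(0, noise_sd, shape)
    image = MultiChannelImage(
        nuclear=np.clip(nuclear, 0, None), actin=np.clip(actin, 0, None)
    )
    return image, {"painted_area": painted_area, "n_cells": n_cells}
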