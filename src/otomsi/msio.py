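"""Image I/O, grayscale/jet conversion, and region/line intensity analyses.

Intensities live on [0, 1] in memory regardless of the bit depth on disk.
The region-histogram and line-profile tools quantify why one illumination
channel separates the tympanic membrane from the meatal wall better than
another: well-separated inside/outside histograms and a sharp intensity step
where a scan line crosses the membrane rim both make the boundary easy for a
region-based contour to find.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .geometry import Ellipse

__all__ = [
    "ChannelImage",
    "RegionHistogram",
    "LineProfile",
    "read_image",
    "read_channel_image",
    "write_image",
    "to_grayscale",
    "apply_jet_colormap",
    "region_histogram",
    "histogram_overlap",
    "line_profile",
]

CHANNEL_LABELS = ("white", "red", "green", "blue", "gray")

#: ITU-R BT.601 luminance weights (sum to 1); applied by :func:`to_grayscale`.
GRAYSCALE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class ChannelImage:
    """A single-channel raster with intensities in [0, 1]."""

    pixels: np.ndarray
    channel_label: str = "gray"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ChannelImage requires a 2-D raster of size >= 1x1")
        if not np.isfinite(self.pixels).all():
            raise ValueError("ChannelImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RegionHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    region_label: str
    mean: float
    sd: float

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:],
             "count": self.counts}
        ).to_csv(path, index=False)


@dataclass
class LineProfile:
    coords: np.ndarray          # (N, 2) pixel (x, y) samples, ordered along the line
    intensity: np.ndarray       # intensity at each sample
    boundary_marks: np.ndarray  # (M, 2) pixel (x, y) line-ellipse crossings, M in {0, 1, 2}
    orientation: str = "horizontal"
    missed_ellipse: bool = False

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"index": np.arange(len(self.intensity)), "intensity": self.intensity}
        ).to_csv(path, index=False)


def _normalize(raw: np.ndarray) -> np.ndarray:
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / float(np.iinfo(raw.dtype).max)
    return raw.astype(float)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF raster, normalized to [0, 1] floats.

    Returns shape (H, W) for grayscale files and (H, W, 3) for RGB(A)
    (the alpha plane, if present, is dropped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    raw = iio.imread(path)
    arr = _normalize(np.asarray(raw))
    if arr.ndim == 3 and arr.shape[2] >= 3:
        return arr[..., :3]
    if arr.ndim == 2:
        return arr
    raise ValueError(f"unsupported image layout {arr.shape} in {path}")


def read_channel_image(path, channel_label: str = "gray") -> ChannelImage:
    arr = read_image(path)
    if arr.ndim == 3:
        return to_grayscale(arr)
    return ChannelImage(arr, channel_label)


def write_image(raster, path, bit_depth: int = 8) -> None:
    """Write a [0, 1] raster (2-D grayscale or HxWx3 RGB) as PNG/TIFF."""
    if isinstance(raster, ChannelImage):
        raster = raster.pixels
    arr = np.clip(np.asarray(raster, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        out = np.round(arr * 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(arr * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, out)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return read_image(path) > 0.5


def to_grayscale(rgb_raster: np.ndarray) -> ChannelImage:
    """Weighted-luminance grayscale conversion (BT.601 weights)."""
    rgb = np.asarray(rgb_raster, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 raster, got shape {rgb.shape}")
    w = np.asarray(GRAYSCALE_WEIGHTS)
    return ChannelImage(rgb @ w, "gray")


def apply_jet_colormap(img: ChannelImage) -> np.ndarray:
    """Map scalar intensities through the classic jet ramp (display only).

    0 maps to dark blue (0, 0, 0.5) and 1 to dark red (0.5, 0, 0); equal
    intensities map to equal colors.
    """
    cmap = colormaps["jet"]
    return np.asarray(cmap(np.clip(img.pixels, 0.0, 1.0)))[..., :3]


def region_histogram(
    img: ChannelImage,
    region: np.ndarray,
    n_bins: int = 256,
    region_label: str = "region",
    value_range: tuple[float, float] = (0.0, 1.0),
) -> RegionHistogram:
    """Intensity histogram restricted to the masked pixels."""
    region = np.asarray(region, dtype=bool)
    if region.shape != img.shape:
        raise ValueError(f"mask shape {region.shape} does not match image {img.shape}")
    values = img.pixels[region]
    if values.size == 0:
        raise ValueError("region mask selects no pixels")
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    return RegionHistogram(edges, counts, region_label,
                           float(values.mean()), float(values.std()))


def histogram_overlap(h1: RegionHistogram, h2: RegionHistogram) -> float:
    """Overlap coefficient Σᵢ min(pᵢ, qᵢ) of two normalized histograms on
    identical bins; 1 for identical distributions, 0 for disjoint support."""
    if h1.bin_edges.shape != h2.bin_edges.shape or not np.allclose(h1.bin_edges, h2.bin_edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.minimum(h1.normalized(), h2.normalized()).sum())


def line_profile(
    img: ChannelImage,
    orientation: str,
    position: int,
    reference_ellipse: Ellipse | None = None,
) -> LineProfile:
    """Intensity profile along a full pixel row (``horizontal``) or column
    (``vertical``), with the analytic line-ellipse crossings marked.

    A line that misses the reference ellipse yields zero marks and sets
    ``missed_ellipse`` instead of raising.
    """
    rows, cols = img.shape
    if orientation == "horizontal":
        if not 0 <= position < rows:
            raise ValueError(f"row {position} outside image of {rows} rows")
        xs = np.arange(cols)
        coords = np.stack([xs, np.full(cols, position)], axis=1)
        intensity = img.pixels[position, :]
    elif orientation == "vertical":
        if not 0 <= position < cols:
            raise ValueError(f"column {position} outside image of {cols} columns")
        ys = np.arange(rows)
        coords = np.stack([np.full(rows, position), ys], axis=1)
        intensity = img.pixels[:, position]
    else:
        raise ValueError(f"orientation must be 'horizontal' or 'vertical', got {orientation!r}")

    marks: Sequence[tuple[float, float]] = []
    missed = False
    if reference_ellipse is not None:
        marks = reference_ellipse.line_intersections(orientation, position)
        marks = [(round(x), round(y)) for x, y in marks]
        missed = len(marks) == 0
    return LineProfile(coords=coords, intensity=np.asarray(intensity, dtype=float),
                       boundary_marks=np.asarray(marks, dtype=int).reshape(-1, 2),
                       orientation=orientation, missed_ellipse=missed)
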