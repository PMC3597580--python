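"""Corneal endothelial cell centroid extraction from specular microscopy images.

Specular microscopy (SM) shows the endothelial mosaic as bright cell
interiors separated by dark borders, usually on top of a strong illumination
gradient. Registration needs only the cell centroids, so the pipeline here
is deliberately simple and fully parameterized:

1. flatten the large-scale illumination trend (Gaussian divide),
2. smooth,
3. find one marker per cell via h-maxima (shallow-peak suppression),
4. marker-controlled watershed on the inverted image,
5. discard regions by area bounds and frame-border contact,
6. report the unweighted centroid of each surviving region.

All steps are deterministic: the same image and parameters always yield the
same centroid set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.filters import gaussian

from .errors import InvalidInputError, InvalidParameterError
from .pointset import CentroidSet


@dataclass
class GrayImage:
    """A 2-D grayscale raster with a declared bit depth (8 or 16).

    ``mask`` (optional) marks valid pixels; warping fills pixels that map
    outside the source with a sentinel and records them here as False.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError(f"image must be 2-D and non-empty, got {px.shape}")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit_depth must be 8 or 16")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class SegmentationParams:
    """Tunables of the watershed centroid extractor.

    Defaults were fixed once against the synthetic mosaic renderer at its
    default scale (~250 cells in a 480x480 frame) and live here, not inside
    the operations.
    """

    background_sigma: float = 50.0  # px, illumination-flattening scale
    smoothing_sigma: float = 2.0  # px
    h_depth: float = 10.0  # intensity units, shallow-maxima suppression
    min_cell_area: float = 40.0  # px^2
    max_cell_area: float = 2000.0  # px^2
    border_margin: float = 2.0  # px

    def __post_init__(self) -> None:
        vals = (
            self.background_sigma,
            self.smoothing_sigma,
            self.h_depth,
            self.min_cell_area,
            self.max_cell_area,
            self.border_margin,
        )
        if any(v <= 0 for v in vals):
            raise InvalidParameterError("all segmentation parameters must be > 0")
        if self.min_cell_area >= self.max_cell_area:
            raise InvalidParameterError("min_cell_area must be < max_cell_area")


def read_image(path: str | Path) -> GrayImage:
    """Load a PNG/TIFF image; RGB inputs are converted by luminance with a warning."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        warnings.warn(
            f"{path}: color input converted to grayscale by luminance", stacklevel=2
        )
        arr = (
            0.2126 * arr[..., 0] + 0.7152 * arr[..., 1] + 0.0722 * arr[..., 2]
        ).astype(arr.dtype)
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(arr, bit_depth=bit_depth)


def write_image(img: GrayImage, path: str | Path) -> None:
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), np.clip(img.pixels, 0, img.max_value).astype(dtype))


def flatten_illumination(img: GrayImage, background_sigma: float | None = None) -> GrayImage:
    """Divide out the large-scale illumination trend.

    The trend is a Gaussian blur at scale ``background_sigma``; the image is
    divided by it and scaled back by the global mean intensity, so overall
    brightness and local contrast are preserved while the large-scale trend
    is removed (clipped to the bit-depth range). A constant image passes
    through unchanged.
    """
    if background_sigma is None:
        background_sigma = SegmentationParams().background_sigma
    if background_sigma < 1:
        raise InvalidParameterError("background_sigma must be >= 1 px")
    px = img.pixels.astype(float)
    trend = gaussian(px, sigma=background_sigma, preserve_range=True)
    trend = np.maximum(trend, 1e-9)
    out = np.clip(px / trend * np.mean(px), 0, img.max_value)
    return GrayImage(np.round(out).astype(img.pixels.dtype), bit_depth=img.bit_depth)


def extract_centroids(
    img: GrayImage,
    params: SegmentationParams | None = None,
    source_id: str = "",
    flatten: bool = True,
) -> CentroidSet:
    """Marker-controlled watershed centroid extraction.

    Returns centroids of all segmented cells whose area lies within the
    configured bounds and whose bounding box stays clear of the frame border
    by ``border_margin`` px (border cells have biased centroids and are
    dropped deliberately). A blank image yields an empty set, not an error.
    """
    if params is None:
        params = SegmentationParams()
    if img.height < 64 or img.width < 64:
        raise InvalidInputError("image must be at least 64x64 px")

    flat = flatten_illumination(img, params.background_sigma) if flatten else img
    smooth = gaussian(flat.pixels.astype(float), sigma=params.smoothing_sigma,
                      preserve_range=True)

    if smooth.max() - smooth.min() <= params.h_depth:
        return CentroidSet(np.empty((0, 2)), img.width, img.height, source_id)

    # markers: bright (Otsu) connected components that contain at least one
    # regional maximum surviving h-suppression. The h-maxima provide the
    # shallow-peak rejection; merging them within a bright component keeps
    # one marker per cell interior even when a flat-topped cell carries
    # several pixel-level maxima.
    from skimage.filters import threshold_otsu

    eight = np.ones((3, 3), dtype=int)
    peaks = morphology.h_maxima(smooth, params.h_depth)
    bright, _ = ndi.label(smooth >= threshold_otsu(smooth), structure=eight)
    peaked = np.unique(bright[(peaks > 0) & (bright > 0)])
    markers = np.where(np.isin(bright, peaked), bright, 0)
    n_markers = len(peaked)
    if n_markers == 0:
        return CentroidSet(np.empty((0, 2)), img.width, img.height, source_id)

    # dark background / border network as its own catchment, so isolated
    # cells do not flood the whole frame
    bg_label = int(bright.max()) + 1
    markers[(smooth < threshold_otsu(smooth)) & (markers == 0)] = bg_label

    labels = segmentation.watershed(-smooth, markers)

    pts: list[tuple[float, float]] = []
    m = params.border_margin
    for region in measure.regionprops(labels):
        if region.label == bg_label:
            continue
        if not (params.min_cell_area <= region.area <= params.max_cell_area):
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 < m or c0 < m or r1 > img.height - m or c1 > img.width - m:
            continue
        cy, cx = region.centroid  # unweighted mass centre, (row, col)
        pts.append((cx, cy))

    cs = CentroidSet(np.array(pts) if pts else np.empty((0, 2)),
                     img.width, img.height, source_id)
    cs = _enforce_min_separation(cs, 2.0)
    return cs.sorted_by_yx()


def _enforce_min_separation(cs: CentroidSet, min_sep: float) -> CentroidSet:
    """Greedily drop the later of any pair closer than ``min_sep`` px."""
    if len(cs) < 2:
        return cs
    from scipy.spatial import cKDTree

    tree = cKDTree(cs.points)
    close = tree.query_pairs(min_sep)
    drop = {max(i, j) for i, j in close}
    if not drop:
        return cs
    keep = np.array([i for i in range(len(cs)) if i not in drop])
    return CentroidSet(cs.points[keep], cs.frame_width, cs.frame_height, cs.source_id)


def count_guard(cs: CentroidSet, minimum: int = 100) -> bool:
    """Low-count warning flag.

    A successful alignment only certifies cell-by-cell identity when enough
    centroids anchor it; with too few cells an affine fit can contort a small
    set onto a subset of an unrelated larger one. The flag is raised iff the
    count is strictly below ``minimum`` (default 100; the boundary count
    itself passes).
    """
    if minimum < 0:
        raise InvalidParameterError("minimum must be >= 0")
    return len(cs) < minimum
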