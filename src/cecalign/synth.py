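"""Synthetic endothelial mosaics and registered image pairs with ground truth.

The corneal endothelium is a near-hexagonal tessellation of cells whose
sizes vary slightly (polymegathism) — exactly the variation that makes
centroid-based registration work. The generator models this as a hexagonal
lattice of seed sites perturbed by uniform jitter, tessellated by Voronoi
regions clipped to the frame. A rendered image adds dark borders, bright
interiors, Gaussian noise and an optional radial vignette, emulating the
look of a specular micrograph.

Registered pairs are built backwards from a known ground-truth transform:
the fixed set is the mosaic's centroids; the moving set is the inverse
transform applied to them, cropped to the (equal-size) moving frame to hit a
target overlap fraction, then degraded by centroid jitter, dropout and
spurious points — the imperfections a real centroid extractor produces.
Everything is deterministic given the seeds carried by MosaicSpec and
PairSpec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .centroids import GrayImage
from .errors import (
    InvalidParameterError,
    InvalidTransformError,
    OverlapUnreachableError,
)
from .pointset import CentroidSet
from .transform import AffineTransform


@dataclass(frozen=True)
class MosaicSpec:
    frame: tuple[int, int] = (480, 480)  # (width, height) px
    n_cells: int = 250
    jitter_fraction: float = 0.3  # lattice perturbation, fraction of pitch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if not (0 <= self.jitter_fraction <= 1):
            raise InvalidParameterError("jitter_fraction must be in [0, 1]")
        w, h = self.frame
        if w < 1 or h < 1:
            raise InvalidParameterError("frame dimensions must be >= 1")


@dataclass
class Mosaic:
    seeds: np.ndarray  # (N, 2) site coordinates
    cells: list[Polygon]  # Voronoi regions clipped to the frame
    centroids: CentroidSet

    @property
    def frame(self) -> tuple[int, int]:
        return (self.centroids.frame_width, self.centroids.frame_height)


@dataclass(frozen=True)
class PairSpec:
    true_transform: AffineTransform
    overlap_fraction: float = 0.6
    centroid_jitter: float = 0.0  # px, Gaussian
    dropout_rate: float = 0.0
    spurious_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.overlap_fraction <= 1):
            raise InvalidParameterError("overlap_fraction must be in (0, 1]")
        for name in ("dropout_rate", "spurious_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise InvalidParameterError(f"{name} must be in [0, 1)")
        if self.centroid_jitter < 0:
            raise InvalidParameterError("centroid_jitter must be >= 0")


@dataclass
class SyntheticPair:
    moving: CentroidSet
    fixed: CentroidSet
    truth: AffineTransform  # maps moving coordinates onto fixed coordinates
    realized_overlap: float
    images: tuple[GrayImage, GrayImage] | None = None  # (moving, fixed)


# ---------------------------------------------------------------------------
# mosaic generation
# ---------------------------------------------------------------------------

def _hex_lattice(width: float, height: float, n_cells: int) -> tuple[np.ndarray, float]:
    """Hexagonal lattice covering the frame; returns sites and the pitch."""
    area = width * height
    pitch = np.sqrt(area / n_cells / (np.sqrt(3) / 2))
    row_h = pitch * np.sqrt(3) / 2
    sites = []
    r = 0
    y = row_h / 2
    while y < height + row_h:
        x0 = pitch / 2 if r % 2 == 0 else pitch
        x = x0
        while x < width + pitch:
            sites.append((x, y))
            x += pitch
        y += row_h
        r += 1
    return np.array(sites), pitch


def generate_mosaic(spec: MosaicSpec) -> Mosaic:
    """Perturbed-hexagonal Voronoi mosaic, deterministic in the seed.

    The lattice is laid down with a seed-dependent global orientation and
    phase (real endothelial mosaics have no preferred axis, and two eyes
    never share one), the n_cells sites nearest the frame centre are kept
    and jittered uniformly by up to jitter_fraction x pitch in each
    coordinate, and the Voronoi tessellation of the sites (bounded by mirror
    images across the frame edges) is clipped to the frame, so the cells
    tile it exactly.
    """
    w, h = spec.frame
    sites, pitch = _hex_lattice(max(w, h) * 1.6, max(w, h) * 1.6,
                                int(spec.n_cells * 1.6**2 * max(w, h)**2 / (w * h)))
    if pitch < 4:
        raise InvalidParameterError(
            f"infeasible density: pitch {pitch:.2f} px < 4 px for {spec.n_cells} cells"
        )
    rng = np.random.default_rng(spec.seed)
    center = np.array([w / 2, h / 2])

    # seed-dependent lattice orientation (hex symmetry: 60 deg) and phase
    theta = rng.uniform(0, np.pi / 3)
    phase = rng.uniform(0, pitch, size=2)
    c, s = np.cos(theta), np.sin(theta)
    lat_center = np.array([max(w, h) * 0.8, max(w, h) * 0.8])
    sites = (sites - lat_center) @ np.array([[c, -s], [s, c]]).T + center + phase
    d2 = np.sum((sites - center) ** 2, axis=1)
    order = np.lexsort((sites[:, 0], sites[:, 1], d2))
    sites = sites[order[: spec.n_cells]]

    jitter = rng.uniform(-1, 1, size=sites.shape) * spec.jitter_fraction * pitch
    sites = sites + jitter
    margin = 1.0
    sites[:, 0] = np.clip(sites[:, 0], margin, w - margin)
    sites[:, 1] = np.clip(sites[:, 1], margin, h - margin)

    frame_box = box(0, 0, w, h)
    if len(sites) == 1:
        cells = [frame_box]
    else:
        # mirror sites across each edge so every original region is finite
        mirrors = [
            sites * [-1, 1],
            sites * [1, -1],
            np.column_stack([2 * w - sites[:, 0], sites[:, 1]]),
            np.column_stack([sites[:, 0], 2 * h - sites[:, 1]]),
        ]
        vor = Voronoi(np.vstack([sites] + mirrors))
        cells = []
        for i in range(len(sites)):
            region = vor.regions[vor.point_region[i]]
            poly = Polygon(vor.vertices[region]).intersection(frame_box)
            cells.append(poly)

    cents = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    centroids = CentroidSet(cents, w, h, source_id=f"mosaic-seed{spec.seed}")
    return Mosaic(seeds=sites, cells=cells, centroids=centroids)


def render_image(
    m: Mosaic,
    border_width: int = 2,
    noise_sigma: float = 6.0,
    vignette_strength: float = 0.0,
    seed: int = 0,
    interior_level: int = 190,
    border_level: int = 60,
) -> GrayImage:
    """Render a mosaic as an 8-bit SM-like image.

    Cell interiors are bright, borders dark; additive Gaussian noise and an
    optional multiplicative radial vignette (corner intensity reduced by
    ``vignette_strength``) complete the illusion. Deterministic in the seed.
    """
    if border_width < 1:
        raise InvalidParameterError("border_width must be >= 1")
    w, h = m.frame
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)

    if len(m.seeds) == 1:
        labels = np.zeros((h, w), dtype=int)
    else:
        from scipy.spatial import cKDTree

        _, lab = cKDTree(m.seeds).query(pix)
        labels = lab.reshape(h, w)

    from skimage.segmentation import find_boundaries
    from skimage.morphology import binary_dilation, disk

    border = find_boundaries(labels, mode="thick")
    if border_width > 2:
        border = binary_dilation(border, disk((border_width - 1) // 2))

    img = np.where(border, float(border_level), float(interior_level))

    if vignette_strength > 0:
        cx, cy = w / 2, h / 2
        r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (cx**2 + cy**2)
        img = img * (1.0 - vignette_strength * r2)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sigma, size=img.shape)

    return GrayImage(np.clip(img, 0, 255).astype(np.uint8), bit_depth=8)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def make_pair(m: Mosaic, p: PairSpec) -> SyntheticPair:
    """Build a (moving, fixed) centroid pair related by a known transform.

    fixed = the mosaic centroids. moving = inverse(true_transform) applied
    to them, cropped to the moving frame (same size as the fixed frame); if
    the crop retains more than overlap_fraction x |fixed| points, a
    deterministic band crop (smallest x first) trims to the target. Centroid
    jitter, dropout and spurious points are then applied in that order.
    """
    try:
        t_inv = p.true_transform.invert()
    except InvalidTransformError:
        raise
    w, h = m.frame
    fixed = m.centroids
    rng = np.random.default_rng(p.seed)

    pts = t_inv.apply(fixed.points)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    )
    pts = pts[inside]
    n_target = int(round(p.overlap_fraction * len(fixed)))
    if len(pts) < n_target - 0.05 * len(fixed):
        raise OverlapUnreachableError(
            f"frame crop keeps {len(pts)}/{len(fixed)} points; "
            f"overlap {p.overlap_fraction} unreachable for this transform"
        )
    if len(pts) > n_target:
        order = np.lexsort((pts[:, 1], pts[:, 0]))  # by x, then y
        pts = pts[order[:n_target]]
    realized = len(pts) / len(fixed)

    if p.centroid_jitter > 0:
        pts = pts + rng.normal(0, p.centroid_jitter, size=pts.shape)
    if p.dropout_rate > 0:
        keep = rng.random(len(pts)) >= p.dropout_rate
        pts = pts[keep]
    if p.spurious_rate > 0:
        n_spur = int(round(p.spurious_rate * len(pts)))
        if n_spur:
            spur = rng.uniform([0, 0], [w, h], size=(n_spur, 2))
            pts = np.vstack([pts, spur])

    moving = CentroidSet(pts, w, h, source_id=f"{fixed.source_id}-moving")
    return SyntheticPair(
        moving=moving, fixed=fixed, truth=p.true_transform, realized_overlap=realized
    )


def make_unrelated_pair(
    spec_a: MosaicSpec, spec_b: MosaicSpec
) -> tuple[CentroidSet, CentroidSet]:
    """Two independent mosaics' centroid sets — the specificity test substrate."""
    if spec_a.seed == spec_b.seed:
        raise InvalidParameterError("unrelated mosaics need distinct seeds")
    return generate_mosaic(spec_a).centroids, generate_mosaic(spec_b).centroids
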