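"""Per-nucleus morphometric features and the tessellation cellularity index.

Each segmented nucleus is summarized by shape (area, perimeter,
eccentricity, solidity), chromatin intensity (mean and SD of the
hematoxylin concentration) and a cellularity index: the plane is
tessellated into one Voronoi region per nucleus centroid, regions are
clipped to the tile rectangle, and cellularity is the inverse of the
clipped region area — dense neighborhoods give small regions and high
cellularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from skimage import measure

from .segmentation import LabelMask

__all__ = [
    "NucleusRecord",
    "TessellationMap",
    "extract_features",
    "compute_cellularity",
    "records_to_frame",
    "FEATURE_COLUMNS",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "tissue_id",
    "nucleus_id",
    "x",
    "y",
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "mean_h",
    "sd_h",
    "cellularity",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus. Centroid is 0-based (x = column, y = row);
    intensities are in hematoxylin OD-concentration units; cellularity in
    1/px^2."""

    nucleus_id: int
    tissue_id: str
    centroid_xy: tuple[float, float]
    area: float
    perimeter: float
    eccentricity: float
    solidity: float
    mean_h_intensity: float
    sd_h_intensity: float
    cellularity: float = np.nan


@dataclass
class TessellationMap:
    """Clipped Voronoi region area per nucleus, aligned with input order."""

    areas: np.ndarray
    bounds: tuple[float, float]  # (width, height) of the clipping rectangle
    cellularity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas <= 0).any():
            raise ValueError("tessellated region areas must be positive")
        self.cellularity = 1.0 / self.areas


def compute_cellularity(
    centroids: np.ndarray, bounds: tuple[float, float]
) -> TessellationMap:
    """Voronoi-tessellate nucleus centroids and invert clipped region areas.

    Parameters
    ----------
    centroids : (N, 2) array of (x, y) positions inside the tile.
    bounds : (width, height) of the tile; regions are clipped to the pixel
        rectangle [-0.5, width-0.5] x [-0.5, height-0.5] whose area is
        exactly width*height, so clipped region areas sum to the tile area.

    Duplicate centroids are perturbed by +0.5 px in x (logged) so the
    tessellation is defined.

    Notes
    -----
    Unbounded outer regions are made finite by tessellating the input
    points together with their mirror images across the four rectangle
    edges; each original point's region is then exactly its true Voronoi
    region intersected with the rectangle.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2).copy()
    if len(pts) == 0:
        raise ValueError("need at least one centroid")
    w, h = float(bounds[0]), float(bounds[1])
    xlo, ylo, xhi, yhi = -0.5, -0.5, w - 0.5, h - 0.5
    if (
        (pts[:, 0] < xlo).any()
        or (pts[:, 0] > xhi).any()
        or (pts[:, 1] < ylo).any()
        or (pts[:, 1] > yhi).any()
    ):
        raise ValueError("centroids must lie inside the tile bounds")

    # resolve exact duplicates deterministically
    seen: dict[tuple[float, float], int] = {}
    for i, (x, y) in enumerate(pts):
        key = (float(x), float(y))
        while key in seen:
            log.warning("duplicate centroid %s perturbed by +0.5 px in x", key)
            pts[i, 0] = min(pts[i, 0] + 0.5, xhi)
            key = (float(pts[i, 0]), float(pts[i, 1]))
        seen[key] = i

    clip = box(xlo, ylo, xhi, yhi)
    if len(pts) == 1:
        return TessellationMap(areas=np.array([w * h]), bounds=(w, h))

    mirrors = [
        np.column_stack([2 * xlo - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xhi - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ylo - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * yhi - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack([pts] + mirrors))
    areas = np.empty(len(pts))
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(clip)
        areas[i] = poly.area
    return TessellationMap(areas=areas, bounds=(w, h))


def extract_features(
    mask: LabelMask, hematoxylin: np.ndarray, tissue_id: str
) -> list[NucleusRecord]:
    """One NucleusRecord per label, including the cellularity index.

    Centroids are unweighted pixel means. sd is the population standard
    deviation of the hematoxylin values over the region. Cellularity is
    computed from the centroids of all nuclei in this mask, clipped to the
    mask rectangle.
    """
    labels = mask.labels
    hema = np.asarray(hematoxylin, dtype=float)
    if labels.shape != hema.shape:
        raise ValueError("mask and channel shapes differ")
    props = measure.regionprops(labels, intensity_image=hema)
    if not props:
        return []
    records = []
    centroids = []
    for p in props:
        cy, cx = p.centroid
        vals = hema[tuple(p.coords.T)]
        records.append(
            NucleusRecord(
                nucleus_id=int(p.label),
                tissue_id=tissue_id,
                centroid_xy=(float(cx), float(cy)),
                area=float(p.area),
                perimeter=float(p.perimeter),
                eccentricity=float(p.eccentricity),
                solidity=float(p.solidity),
                mean_h_intensity=float(vals.mean()),
                sd_h_intensity=float(vals.std()),
            )
        )
        centroids.append((cx, cy))
    h, w = labels.shape
    tess = compute_cellularity(np.asarray(centroids), bounds=(w, h))
    for rec, cell in zip(records, tess.cellularity):
        rec.cellularity = float(cell)
    return records


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Flatten records into the fixed-header CSV table."""
    rows = [
        {
            "tissue_id": r.tissue_id,
            "nucleus_id": r.nucleus_id,
            "x": r.centroid_xy[0],
            "y": r.centroid_xy[1],
            "area": r.area,
            "perimeter": r.perimeter,
            "eccentricity": r.eccentricity,
            "solidity": r.solidity,
            "mean_h": r.mean_h_intensity,
            "sd_h": r.sd_h_intensity,
            "cellularity": r.cellularity,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
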