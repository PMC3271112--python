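"""Nuclear segmentation from the hematoxylin concentration channel.

The channel is thresholded by minimizing intra-class variance over its
256-bin histogram (Otsu). Thresholded blobs are then refined two ways:

* intensity refinement — each blob's intensity distribution is fit with a
  mixture of up to three Gaussians by EM; if the BIC-selected mixture has
  well-separated components, the blob is split by maximum-responsibility
  assignment (two adjacent nuclei with very different chromatin content
  merge under a single threshold but separate in intensity);
* geometric refinement — blobs whose solidity (area / convex-hull area)
  falls below a threshold are cut along chords joining boundary concavity
  points, recursively, splitting touching nuclei whose shared boundary is
  only perceptual.

Components are 4-connected throughout and a min/max area filter is applied
before and after refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure
from skimage.draw import line as draw_line
from sklearn.mixture import GaussianMixture

from .stain import RGBTile, StainBasis, deconvolve, normalize_stain, rgb_to_od

__all__ = [
    "LabelMask",
    "SegmentationConfig",
    "DegenerateHistogramError",
    "otsu_threshold",
    "segment_blobs",
    "refine_gmm",
    "refine_convexity",
    "segment_tile",
    "segment_channel",
    "hematoxylin_channel",
]

log = logging.getLogger(__name__)

_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class DegenerateHistogramError(ValueError):
    """All histogram mass in a single bin; no threshold separates two classes."""


@dataclass
class LabelMask:
    """Integer label image: 0 = background, 1..n = nuclei (4-connected)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class SegmentationConfig:
    """Thresholds for the intensity and geometric refinement constraints.

    min_area / max_area bracket plausible nuclear areas at a 20x objective;
    gmm_separation is the minimal gap between adjacent mixture means in
    multiples of the pooled within-component standard deviation; blobs below
    gmm_min_pixels are too small for a stable mixture fit and are left
    unsplit; solidity_threshold / concavity_depth_min govern convexity
    splitting.
    """

    min_area: int = 40
    max_area: int = 5000
    gmm_max_components: int = 3
    gmm_min_pixels: int = 100
    gmm_separation: float = 2.0
    solidity_threshold: float = 0.96
    concavity_depth_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if self.gmm_max_components not in (1, 2, 3):
            raise ValueError("gmm_max_components must be 1, 2 or 3")
        if not (0 < self.solidity_threshold <= 1):
            raise ValueError("solidity_threshold must be in (0, 1]")


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold of a 256-bin histogram minimizing intra-class variance.

    Returns the cut ``t`` (bins <= t are background, bins > t foreground)
    maximizing between-class variance over all 255 possible cuts;
    equivalently minimizing the within-class variance. Ties break to the
    smallest t.
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if h.min() < 0:
        raise ValueError("histogram counts must be nonnegative")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("histogram mass concentrated in one bin")

    if np.allclose(h, np.rint(h)):
        # exact integer path: ties (which genuinely occur, e.g. for
        # symmetric histograms) must break to the smallest t, and floating
        # point cannot order exact ties reliably
        counts = [int(c) for c in np.rint(h)]
        w_tot = sum(counts)
        m_tot = sum(i * c for i, c in enumerate(counts))
        best_t = None
        best_num, best_den = -1, 1
        w0 = m0 = 0
        for t in range(255):
            w0 += counts[t]
            m0 += t * counts[t]
            w1 = w_tot - w0
            if w0 == 0 or w1 == 0:
                continue
            m1 = m_tot - m0
            num = (m0 * w1 - m1 * w0) ** 2  # between-class variance, scaled
            den = w0 * w1
            if num * best_den > best_num * den:  # strict: keeps smallest t
                best_num, best_den, best_t = num, den, t
        return int(best_t)

    bins = np.arange(256, dtype=float)
    w0 = np.cumsum(h)[:-1]                 # mass of class {0..t}, t = 0..254
    w1 = h.sum() - w0
    m0 = np.cumsum(h * bins)[:-1]
    m1 = (h * bins).sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = m1 / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf  # empty class -> invalid cut
    return int(np.argmax(between))  # argmax takes the first (smallest t) on ties


def _quantize256(channel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantize a real channel to bin indices 0..255 plus its histogram."""
    lo, hi = float(channel.min()), float(channel.max())
    scaled = (channel - lo) / (hi - lo)
    q = np.minimum((scaled * 256).astype(int), 255)
    hist = np.bincount(q.ravel(), minlength=256).astype(float)
    return q, hist


def _size_filter(labels: np.ndarray, min_area: int, max_area: int) -> np.ndarray:
    """Zero out components outside [min_area, max_area]; relabel 1..n."""
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    bad = (counts < min_area) | (counts > max_area)
    bad[0] = False
    out = labels.copy()
    out[bad[labels]] = 0
    return _relabel(out)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map the surviving label set onto contiguous 1..n preserving order."""
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1)
    return lut[labels]


def segment_blobs(hematoxylin: np.ndarray, config: SegmentationConfig) -> LabelMask:
    """Threshold the hematoxylin channel and size-filter connected blobs.

    A constant (degenerate) channel yields an empty mask rather than an
    error: a blank block simply contains no nuclei.
    """
    chan = np.asarray(hematoxylin, dtype=float)
    if chan.size == 0:
        raise ValueError("channel is empty")
    if chan.min() == chan.max():
        return LabelMask(labels=np.zeros(chan.shape, dtype=np.int32))
    q, hist = _quantize256(chan)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return LabelMask(labels=np.zeros(chan.shape, dtype=np.int32))
    fg = q > t
    labels, _ = ndimage.label(fg, structure=_STRUCT4)
    labels = _size_filter(labels.astype(np.int32), config.min_area, config.max_area)
    return LabelMask(labels=labels)


# ---------------------------------------------------------------------------
# intensity refinement


def refine_gmm(
    blob_pixels: np.ndarray, config: SegmentationConfig
) -> np.ndarray | None:
    """Fit 1..gmm_max_components Gaussians to a blob's intensities by EM.

    Component count is selected by BIC. A split is reported only when the
    selected count exceeds one AND every pair of adjacent (sorted) component
    means is separated by more than ``gmm_separation`` pooled standard
    deviations; insufficiently separated adjacent components are merged
    before this test. Returns an integer component index per pixel, or
    ``None`` when the blob stays unsplit (including the < gmm_min_pixels
    guard and EM failure).
    """
    x = np.asarray(blob_pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("blob has no pixels")
    if x.size < config.gmm_min_pixels or np.ptp(x) == 0:
        return None

    X = x.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, config.gmm_max_components + 1):
        if x.size < 2 * k:
            break
        # fully deterministic init: quantile means, uniform weights,
        # shared precision from the overall variance
        qs = np.quantile(x, (np.arange(k) + 1) / (k + 1))
        var = max(x.var(), 1e-12)
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            means_init=qs.reshape(-1, 1),
            weights_init=np.full(k, 1.0 / k),
            precisions_init=np.full((k, 1, 1), 1.0 / var),
            max_iter=200,
            n_init=1,
            random_state=config.seed,
            reg_covar=1e-6,
        )
        try:
            gm.fit(X)
        except Exception:  # non-convergence/degeneracy -> fewer components
            continue
        bic = gm.bic(X)
        if bic < best_bic:
            best_bic = bic
            best = gm
    if best is None or best.n_components == 1:
        return None

    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    variances = best.covariances_.reshape(-1)[order]
    weights = best.weights_.ravel()[order]
    pooled_sd = float(np.sqrt(np.sum(weights * variances)))

    # merge adjacent components whose means are not separated enough
    groups = [0]
    for i in range(1, len(means)):
        if means[i] - means[i - 1] > config.gmm_separation * max(pooled_sd, 1e-12):
            groups.append(groups[-1] + 1)
        else:
            groups.append(groups[-1])
    if groups[-1] == 0:
        return None

    comp = best.predict(X)  # component index per pixel
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    merged = np.asarray(groups)[rank[comp]]
    return merged


# ---------------------------------------------------------------------------
# geometric (convexity) refinement


def _blob_contour(mask: np.ndarray) -> np.ndarray | None:
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    return contour - 1.0  # undo padding offset; (row, col) float coords


def _concavity_points(
    contour: np.ndarray, min_depth: float
) -> list[tuple[float, np.ndarray]]:
    """Deepest point of each boundary run lying >= min_depth inside the hull."""
    hull = Polygon(contour).convex_hull
    if hull.area <= 0:
        return []
    boundary = hull.exterior
    depths = np.array([boundary.distance(Point(p)) for p in contour])
    deep = depths >= min_depth
    if not deep.any():
        return []
    # rotate so the scan does not start mid-run (contour is circular)
    start = int(np.argmin(deep))
    deep_r = np.roll(deep, -start)
    depths_r = np.roll(depths, -start)
    idx_r = np.roll(np.arange(len(contour)), -start)
    points: list[tuple[float, np.ndarray]] = []
    i = 0
    n = len(contour)
    while i < n:
        if not deep_r[i]:
            i += 1
            continue
        j = i
        while j < n and deep_r[j]:
            j += 1
        run = slice(i, j)
        k = i + int(np.argmax(depths_r[run]))
        points.append((float(depths_r[k]), contour[idx_r[k]]))
        i = j
    return points


def _chord_pixels(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = int(round(p[0])), int(round(p[1]))
    r1, c1 = int(round(q[0])), int(round(q[1]))
    return draw_line(r0, c0, r1, c1)


def _valid_chord(mask: np.ndarray, p: np.ndarray, q: np.ndarray) -> bool:
    rr, cc = _chord_pixels(p, q)
    inside = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    if not inside.all():
        return False
    # the cut must run through the blob (endpoints sit on the boundary)
    return bool(mask[rr[1:-1], cc[1:-1]].all()) if len(rr) > 2 else True


def _single_concavity_chord(
    mask: np.ndarray, contour: np.ndarray, candidates: list[tuple[float, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Chord from the deepest concavity to the nearest far-side boundary point."""
    depth, p = max(candidates, key=lambda c: c[0])
    n = len(contour)
    idx_p = int(np.argmin(np.hypot(contour[:, 0] - p[0], contour[:, 1] - p[1])))
    dists = np.hypot(contour[:, 0] - p[0], contour[:, 1] - p[1])
    order = np.argsort(dists)
    for j in order:
        sep = min(abs(j - idx_p), n - abs(j - idx_p))
        if sep < n // 4:  # skip neighbors along the boundary
            continue
        q = contour[j]
        if _valid_chord(mask, p, q):
            return p, q
    return None


def _solidity(mask: np.ndarray) -> float:
    contour = _blob_contour(mask)
    if contour is None or len(contour) < 3:
        return 1.0
    hull_area = Polygon(contour).convex_hull.area
    if hull_area <= 0:
        return 1.0
    return float(mask.sum() / hull_area)


def refine_convexity(
    blob_mask: np.ndarray, config: SegmentationConfig
) -> list[np.ndarray]:
    """Partition a non-convex blob along chords between boundary concavities.

    If the blob's solidity meets ``solidity_threshold`` it is returned
    unchanged. Otherwise concavity points (local maxima of depth below the
    convex hull, depth >= ``concavity_depth_min``) are paired by minimal
    Euclidean distance subject to the chord lying inside the blob, the blob
    is cut along the chord, and each part is refined recursively until every
    part passes the solidity test or no valid pair remains.
    """
    blob_mask = np.asarray(blob_mask).astype(bool)
    out: list[np.ndarray] = []
    stack = [blob_mask]
    while stack:
        m = stack.pop()
        if _solidity(m) >= config.solidity_threshold:
            out.append(m)
            continue
        contour = _blob_contour(m)
        if contour is None:
            out.append(m)
            continue
        candidates = _concavity_points(contour, config.concavity_depth_min)
        pair = None
        best_dist = np.inf
        for a in range(len(candidates)):
            for b in range(a + 1, len(candidates)):
                pa, pb = candidates[a][1], candidates[b][1]
                d = float(np.hypot(*(pa - pb)))
                if d < best_dist and _valid_chord(m, pa, pb):
                    best_dist = d
                    pair = (pa, pb)
        if pair is None and candidates:
            # single visible concavity (the other side of the neck is too
            # shallow): cut to the nearest boundary point on the far side
            pair = _single_concavity_chord(m, contour, candidates)
        if pair is None:
            out.append(m)
            continue
        cut = m.copy()
        rr, cc = _chord_pixels(*pair)
        cut[rr, cc] = False
        parts, n = ndimage.label(cut, structure=_STRUCT4)
        if n < 2:
            out.append(m)
            continue
        # reclaim the cut line for the nearest part so area loss is one
        # pixel-wide at most; keep parts as separate masks
        for lab in range(1, n + 1):
            out_or_stack = parts == lab
            stack.append(out_or_stack)
    return out


# ---------------------------------------------------------------------------
# full tile segmentation


def hematoxylin_channel(
    tile: RGBTile, reference: RGBTile, basis: StainBasis | None = None
) -> np.ndarray:
    """Stain-normalize, convert to OD and deconvolve; return the
    hematoxylin concentration map."""
    basis = basis or StainBasis.default_he()
    normalized = normalize_stain(tile, reference)
    od = rgb_to_od(normalized)
    return deconvolve(od, basis).hematoxylin


def segment_tile(
    tile: RGBTile,
    reference: RGBTile,
    basis: StainBasis | None = None,
    config: SegmentationConfig | None = None,
) -> LabelMask:
    """Delineate nuclei in an RGB tile.

    Composition: stain normalization against the reference, Beer-Lambert OD
    conversion, color deconvolution, Otsu thresholding of the hematoxylin
    channel, per-blob Gaussian-mixture then convexity refinement, final size
    filter and contiguous relabeling.
    """
    hema = hematoxylin_channel(tile, reference, basis)
    return segment_channel(hema, config)


def segment_channel(
    hema: np.ndarray, config: SegmentationConfig | None = None
) -> LabelMask:
    """Threshold + refine an already-deconvolved hematoxylin channel."""
    config = config or SegmentationConfig()
    mask = segment_blobs(hema, config)
    labels = mask.labels
    if labels.max() == 0:
        return mask

    out = np.zeros_like(labels)
    next_label = 1
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        local = labels[sl] == lab
        pieces = _refine_blob(local, hema[sl], config)
        for piece in pieces:
            target = out[sl]
            target[piece] = next_label
            next_label += 1

    out = _size_filter(out, config.min_area, config.max_area)
    return LabelMask(labels=out)


def _refine_blob(
    local_mask: np.ndarray, local_hema: np.ndarray, config: SegmentationConfig
) -> list[np.ndarray]:
    """GMM split (spatialized by max responsibility) then convexity split."""
    pixels = local_hema[local_mask]
    assignment = refine_gmm(pixels, config)
    if assignment is None:
        gmm_parts = [local_mask]
    else:
        comp_img = np.full(local_mask.shape, -1, dtype=int)
        comp_img[local_mask] = assignment
        gmm_parts = []
        for comp in np.unique(assignment):
            part, n = ndimage.label(comp_img == comp, structure=_STRUCT4)
            for lab in range(1, n + 1):
                gmm_parts.append(part == lab)
    final: list[np.ndarray] = []
    for part in gmm_parts:
        if part.sum() < config.min_area:
            continue  # slivers from the intensity split
        final.extend(refine_convexity(part, config))
    return final
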