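"""Stain color normalization and color deconvolution for H&E tiles.

Bright-field H&E images mix two dyes: hematoxylin (nuclei, blue-purple) and
eosin (cytoplasm/stroma, pink). In optical-density (OD) space the dyes mix
linearly (Beer-Lambert), so a 3x3 basis of unit OD vectors — hematoxylin,
eosin and a residual completing the frame — can be inverted to recover a
per-stain concentration image from RGB. Before deconvolution, tiles are
color-normalized against a single reference ("gold standard") tile by
per-channel monotone histogram matching, which removes batch-to-batch
staining heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBTile",
    "ODImage",
    "StainBasis",
    "StainChannels",
    "DegenerateReferenceError",
    "normalize_stain",
    "rgb_to_od",
    "deconvolve",
]


class DegenerateReferenceError(ValueError):
    """Reference tile has a constant channel; its quantile map is undefined."""


@dataclass
class RGBTile:
    """An 8-bit RGB bright-field tile.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        Channel intensities in [0, 255].
    pixel_size : float, optional
        Microns per pixel (metadata only; ~0.5 at a 20x objective).
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("tile must be at least 1x1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ODImage:
    """Per-channel optical density of a tile: OD = log10(I0 / I) >= 0."""

    od: np.ndarray
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[2] != 3:
            raise ValueError("OD image must be HxWx3")
        if self.od.min() < 0:
            raise ValueError("optical density must be nonnegative")


# Canonical published H&E OD vectors (RGB order) for linear stain separation;
# the residual column completes a right-handed frame via the cross product.
_DEFAULT_H = np.array([0.650, 0.704, 0.286])
_DEFAULT_E = np.array([0.072, 0.990, 0.105])


@dataclass
class StainBasis:
    """A 3x3 OD basis; columns are unit vectors for hematoxylin, eosin, residual."""

    vectors: np.ndarray = field(
        default_factory=lambda: StainBasis.default_he().vectors
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("stain basis must be 3x3")
        norms = np.linalg.norm(v, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"basis columns must be unit length, got norms {norms}")
        if abs(np.linalg.det(v)) < 1e-12:
            raise ValueError("stain basis is singular")
        self.vectors = v

    @classmethod
    def default_he(cls) -> "StainBasis":
        h = _DEFAULT_H / np.linalg.norm(_DEFAULT_H)
        e = _DEFAULT_E / np.linalg.norm(_DEFAULT_E)
        r = np.cross(h, e)
        r /= np.linalg.norm(r)
        return cls(vectors=np.column_stack([h, e, r]))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)

    def to_list(self) -> list[list[float]]:
        return self.vectors.tolist()

    @classmethod
    def from_list(cls, rows: list[list[float]]) -> "StainBasis":
        return cls(vectors=np.asarray(rows, dtype=float))


@dataclass
class StainChannels:
    """Per-stain concentration maps; negatives clipped to 0 in the named
    channels, raw (unclipped) values kept for the reconstruction invariant."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    residual: np.ndarray
    raw: np.ndarray  # (H, W, 3) unclipped concentrations

    def reconstruct_od(self, basis: StainBasis) -> np.ndarray:
        """basis @ raw concentrations, pixelwise; inverse of deconvolution."""
        return np.einsum("ij,hwj->hwi", basis.vectors, self.raw)


def normalize_stain(tile: RGBTile, reference: RGBTile) -> RGBTile:
    """Match each RGB channel's empirical distribution to the reference's.

    Monotone per-channel quantile mapping (histogram specification): a
    gray level g with left-continuous empirical CDF p = P(X < g) in the
    tile maps to the reference channel's type-1 p-quantile. The
    left-continuous convention sends a point-mass tile to the reference's
    minimum-quantile value and makes a tile its own fixed point; the map
    is idempotent up to one gray level.

    Raises
    ------
    DegenerateReferenceError
        If any reference channel is constant.
    """
    ref = reference.pixels
    for c in range(3):
        if ref[..., c].min() == ref[..., c].max():
            raise DegenerateReferenceError(
                f"reference channel {c} is constant; cannot match histograms"
            )
    out = np.empty_like(tile.pixels)
    for c in range(3):
        src = tile.pixels[..., c]
        counts = np.bincount(src.ravel(), minlength=256).astype(np.int64)
        below = np.cumsum(counts) - counts  # count of pixels < g
        ref_counts = np.bincount(ref[..., c].ravel(), minlength=256).astype(np.int64)
        ref_cum = np.cumsum(ref_counts)
        n_ref = int(ref[..., c].size)
        # type-1 inverse CDF: smallest gray level r with
        # F_ref(r) > P(X < g), compared in exact integer arithmetic as
        # ref_cum[r] * n_src > below[g] * n_ref
        lut = np.searchsorted(ref_cum * int(src.size), below * n_ref, side="right")
        out[..., c] = np.clip(lut, 0, 255).astype(np.uint8)[src]
    return RGBTile(pixels=out, pixel_size=tile.pixel_size)


def rgb_to_od(tile: RGBTile, background_intensity: float = 255.0) -> ODImage:
    """Convert intensities to optical density: OD = log10(I0 / max(I, 1)).

    The max(I, 1) floor bounds the OD of fully absorbed (zero) pixels at
    log10(I0); saturated pixels brighter than I0 clip to OD 0.
    """
    if background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    i = np.maximum(tile.pixels.astype(float), 1.0)
    od = np.log10(background_intensity / i)
    od = np.clip(od, 0.0, None)
    return ODImage(od=od, background_intensity=background_intensity)


def deconvolve(od: ODImage, basis: StainBasis) -> StainChannels:
    """Invert the stain basis to recover per-stain concentration maps.

    Solves basis @ c = od pixelwise. Small negative concentrations (noise,
    basis mismatch) are clipped to zero in the returned channels since
    concentrations are physical; raw values are retained on ``raw``.
    """
    inv = basis.inverse  # raises upstream if singular
    raw = np.einsum("ij,hwj->hwi", inv, od.od)
    clipped = np.clip(raw, 0.0, None)
    return StainChannels(
        hematoxylin=clipped[..., 0],
        eosin=clipped[..., 1],
        residual=clipped[..., 2],
        raw=raw,
    )
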