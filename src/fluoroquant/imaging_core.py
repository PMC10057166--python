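"""Per-pixel Fv/Fm image analysis.

Workflow: threshold-segment the plant from the bright (Fm) frame, compute
(Fm - Fo) / Fm per foreground pixel with divide safety, summarize the map as
a histogram whose peak bin gives the plant-level Fv/Fm, classify health
against a threshold (default 0.79), and render a fixed-scale pseudocolor map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from matplotlib import colormaps as _mpl_colormaps
from skimage.filters import threshold_otsu

from .errors import (
    ConfigurationError,
    DegenerateImageError,
    EmptyPlantError,
    ParameterizationError,
)

__all__ = [
    "RawImage",
    "ImagePair",
    "BinaryMask",
    "FvFmMap",
    "FvFmSummary",
    "segment_plant",
    "compute_fvfm_map",
    "summarize_fvfm",
    "render_pseudocolor",
]

DEFAULT_HEALTH_THRESHOLD = 0.79
DEFAULT_BIN_WIDTH = 0.01
DEFAULT_EPS = 1.0


@dataclass(frozen=True)
class RawImage:
    """A single monochrome fluorescence frame."""

    pixels: np.ndarray
    bit_depth: int = 16
    channel: Optional[str] = None  # "Fo" | "Fm"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterizationError(f"image must be 2-D, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ParameterizationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ParameterizationError(f"pixels must be integer-typed, got {px.dtype}")
        if px.min() < 0 or px.max() > self.max_value:
            raise ParameterizationError(
                f"intensities outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImagePair:
    """One plant's Fo and Fm frames plus identity metadata."""

    fo: RawImage
    fm: RawImage
    plant_id: Optional[str] = None
    group: Optional[str] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fo.shape != self.fm.shape:
            raise ParameterizationError(
                f"Fo shape {self.fo.shape} != Fm shape {self.fm.shape}"
            )
        if self.fo.bit_depth != self.fm.bit_depth:
            raise ParameterizationError("Fo and Fm bit depths differ")


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask with the threshold that produced it."""

    pixels: np.ndarray
    threshold: Optional[float] = None
    method: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterizationError("mask must be 2-D")
        if px.dtype != bool:
            uniq = np.unique(px)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ParameterizationError("mask must be binary")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class FvFmMap:
    """Per-pixel Fv/Fm with a validity mask.

    ``values`` are defined (finite, in [0, 1]) wherever ``valid`` is True;
    invalid pixels hold 0. ``clipped_fraction`` is the share of valid pixels
    whose raw ratio fell outside [0, 1] before clipping (noise can push
    Fo above Fm).
    """

    values: np.ndarray
    valid: np.ndarray
    clipped_fraction: float = 0.0
    plant_id: Optional[str] = None
    group: Optional[str] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if vals.shape != valid.shape:
            raise ParameterizationError("values and valid must share a shape")
        inside = vals[valid]
        if inside.size and (not np.all(np.isfinite(inside)) or inside.min() < 0 or inside.max() > 1):
            raise ParameterizationError("valid Fv/Fm values must be finite and in [0, 1]")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "valid", valid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class FvFmSummary:
    """Plant-level scalar summary of an Fv/Fm map."""

    mode: float
    mean: float
    n_valid: int
    bin_edges: np.ndarray
    counts: np.ndarray
    health: str  # "healthy" | "stressed"
    mode_tied: bool
    bin_width: float
    health_threshold: float
    clipped_fraction: float


def segment_plant(
    image: RawImage,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> BinaryMask:
    """Threshold segmentation: foreground = pixels strictly above the threshold.

    ``method="otsu"`` picks the threshold maximizing between-class variance;
    ``method="fixed"`` uses the supplied value.
    """
    px = image.pixels
    if method == "fixed":
        if threshold is None:
            raise ConfigurationError("fixed segmentation requires a threshold value")
        if not 0 <= threshold <= image.max_value:
            raise ParameterizationError(
                f"threshold {threshold} outside [0, {image.max_value}]"
            )
        thr = float(threshold)
    elif method == "otsu":
        if px.min() == px.max():
            raise DegenerateImageError("cannot compute Otsu threshold on a blank image")
        thr = float(threshold_otsu(px))
    else:
        raise ConfigurationError(f"unknown segmentation method {method!r}")
    return BinaryMask(pixels=px > thr, threshold=thr, method=method)


def compute_fvfm_map(
    pair: ImagePair, mask: BinaryMask, eps: float = DEFAULT_EPS
) -> FvFmMap:
    """Per-pixel (Fm - Fo) / Fm over the foreground, clipped to [0, 1].

    Pixels that are background or have Fm <= eps are marked invalid; the
    fraction of valid pixels whose raw ratio needed clipping is reported.
    """
    if mask.pixels.shape != pair.fm.shape:
        raise ParameterizationError("mask shape does not match image shape")
    fm = pair.fm.pixels.astype(np.float64)
    fo = pair.fo.pixels.astype(np.float64)
    valid = mask.pixels & (fm > eps)
    raw = np.zeros_like(fm)
    np.divide(fm - fo, fm, out=raw, where=valid)
    n_valid = int(valid.sum())
    clipped = int(np.count_nonzero(valid & ((raw < 0.0) | (raw > 1.0))))
    values = np.clip(raw, 0.0, 1.0)
    values[~valid] = 0.0
    return FvFmMap(
        values=values,
        valid=valid,
        clipped_fraction=clipped / n_valid if n_valid else 0.0,
        plant_id=pair.plant_id,
        group=pair.group,
        day=pair.day,
    )


def summarize_fvfm(
    fvfm_map: FvFmMap,
    bin_width: float = DEFAULT_BIN_WIDTH,
    health_threshold: float = DEFAULT_HEALTH_THRESHOLD,
) -> FvFmSummary:
    """Histogram the valid pixels over [0, 1]; the peak bin's center is the
    plant-level Fv/Fm. Ties pick the lowest qualifying bin. Health is
    "healthy" iff mode >= health_threshold.
    """
    if not 0.0 < bin_width <= 0.1:
        raise ConfigurationError(f"bin_width must be in (0, 0.1], got {bin_width}")
    vals = fvfm_map.values[fvfm_map.valid]
    if vals.size == 0:
        raise EmptyPlantError("no valid pixels to summarize")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(vals, bins=edges)
    peak = int(np.argmax(counts))  # first maximum = lowest bin
    mode = float((edges[peak] + edges[peak + 1]) / 2.0)
    tied = int(np.count_nonzero(counts == counts[peak])) > 1
    return FvFmSummary(
        mode=mode,
        mean=float(vals.mean()),
        n_valid=int(vals.size),
        bin_edges=edges,
        counts=counts,
        health="healthy" if mode >= health_threshold else "stressed",
        mode_tied=tied,
        bin_width=bin_width,
        health_threshold=health_threshold,
        clipped_fraction=fvfm_map.clipped_fraction,
    )


def render_pseudocolor(
    fvfm_map: FvFmMap,
    colormap_name: str = "jet",
    background: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Render an Fv/Fm map as an RGB uint8 image on a fixed [0, 1] scale.

    The scale is never rescaled per image, so renderings are comparable
    across days and groups. Invalid pixels get the reserved background color.
    """
    try:
        cmap = _mpl_colormaps[colormap_name]
    except KeyError as exc:
        raise ConfigurationError(f"unknown colormap {colormap_name!r}") from exc
    rgba = cmap(np.clip(fvfm_map.values, 0.0, 1.0))
    rgb = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    rgb[~fvfm_map.valid] = np.asarray(background, dtype=np.uint8)
    return rgb
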