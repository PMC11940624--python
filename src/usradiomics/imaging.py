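"""Image and ROI handling for ultrasound radiomics.

Grayscale B-mode frames are represented as :class:`GrayImage` (a 2-D
non-negative raster with an isotropic pixel spacing in mm).  Regions of
interest are pixel-aligned binary rasters (:class:`ROIMask`) with one of
three roles: the tumor core, the tumor plus a peritumoral ring of tissue,
or an exclusion region (skin band, pectoral muscle) subtracted from the
analysed area.

Intensities are normalised and quantised per ROI before texture analysis:
the default ``mu3sigma`` scheme clamps in-mask intensities to
[mu - 3*sigma, mu + 3*sigma] and bins them linearly into ``Ng`` gray levels,
which makes every downstream texture feature exactly invariant to positive
affine rescalings of the raw intensities.

Coordinate convention: row-major, 0-based pixel indices; masks are
pixel-aligned (no sub-pixel contours).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

Role = Literal["tumor", "tumor_plus_peritumoral", "exclusion"]

__all__ = [
    "GrayImage",
    "ROIMask",
    "NormConfig",
    "PreprocessConfig",
    "QuantizedROI",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "preprocess",
    "build_peritumoral",
    "normalize_quantize",
]


@dataclass
class GrayImage:
    """A 2-D grayscale raster with isotropic pixel spacing.

    Parameters
    ----------
    data : ndarray of shape (h, w)
        Non-negative intensities (any numeric dtype).
    pixel_spacing_mm : float
        Isotropic spacing in mm per pixel.  Anisotropic inputs must be
        resampled upstream; they are not accepted here.
    bit_depth : int
        Nominal bit depth of the source (8 or 16 for file-backed images).
    """

    data: np.ndarray
    pixel_spacing_mm: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(
                f"expected a 2-D grayscale raster, got shape {self.data.shape}"
            )
        if not np.isfinite(self.pixel_spacing_mm) or self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be a positive finite scalar")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """A binary raster aligned to a :class:`GrayImage`."""

    data: np.ndarray
    role: Role

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.data.sum())


@dataclass
class NormConfig:
    """Intensity normalisation / quantisation settings.

    mode:
        ``mu3sigma`` (clamp to mu +/- 3 sigma over in-mask pixels, then bin),
        ``minmax`` (bin between in-mask min and max) or ``none`` (input is
        already integer levels in [0, Ng-1]).
    n_gray_levels:
        Number of quantisation levels Ng (power of two, >= 4).
    per_roi:
        Statistics are computed over the ROI being quantised (the only
        implemented scope; global normalisation would couple ROIs).
    """

    mode: Literal["mu3sigma", "minmax", "none"] = "mu3sigma"
    n_gray_levels: int = 64
    per_roi: bool = True

    def __post_init__(self) -> None:
        ng = self.n_gray_levels
        if ng < 4 or (ng & (ng - 1)) != 0:
            raise ValueError("n_gray_levels must be a power of two >= 4")
        if self.mode not in ("mu3sigma", "minmax", "none"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")


@dataclass
class PreprocessConfig:
    """Stand-in denoising step: a median filter of configurable radius.

    Disabled by default so that texture fidelity experiments see the raw
    speckle; enable for workflows that expect a smoothed input.
    """

    enabled: bool = False
    median_radius_px: int = 1


@dataclass
class QuantizedROI:
    """In-mask pixels quantised to integer gray levels.

    ``levels`` is a full-frame int array with -1 outside the mask, which
    keeps the 2-D geometry needed by co-occurrence / run-length / wavelet
    analysis while the mask records membership.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_gray_levels: int
    role: Role
    constant: bool = False  # sigma == 0 warning flag
    raw_values: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("quantized ROI must be non-empty")
        inm = self.levels[self.mask]
        if inm.min() < 0 or inm.max() >= self.n_gray_levels:
            raise ValueError("levels out of range [0, Ng-1] inside mask")

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


# ---------------------------------------------------------------------------
# I/O


def load_image(path, pixel_spacing_mm: float) -> GrayImage:
    """Read an 8/16-bit grayscale PNG or TIFF.

    Color images are rejected: the analysis operates on grayscale B-mode
    frames only.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: color image (shape {arr.shape}); only grayscale input is supported"
        )
    depth = 16 if arr.dtype.itemsize >= 2 else 8
    return GrayImage(arr, pixel_spacing_mm=pixel_spacing_mm, bit_depth=depth)


def save_image(path, img: GrayImage) -> None:
    """Write a GrayImage losslessly (PNG/TIFF chosen by extension)."""
    data = img.data
    if np.issubdtype(data.dtype, np.floating):
        # float rasters are scaled to the 8-bit range for export
        lo, hi = float(data.min()), float(data.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        data = np.clip((data - lo) * scale, 0, 255).astype(np.uint8)
    iio.imwrite(path, data)


def load_mask(path, image: GrayImage, role: Role = "tumor") -> ROIMask:
    """Read a mask PNG and binarise at half-range (255 -> True for uint8)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(f"{path}: mask must be single-channel")
    if arr.shape != image.shape:
        raise ValueError(
            f"{path}: mask shape {arr.shape} does not match image {image.shape}"
        )
    half = (np.iinfo(arr.dtype).max + 1) // 2 if arr.dtype.kind in "ui" else 0.5
    return ROIMask(arr >= half, role=role)


def save_mask(path, mask: ROIMask) -> None:
    iio.imwrite(path, np.where(mask.data, 255, 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# Preprocessing and ROI construction


def preprocess(img: GrayImage, cfg: PreprocessConfig | None = None) -> GrayImage:
    """Apply the documented denoising stand-in (median filter), or identity."""
    if cfg is None or not cfg.enabled:
        return img
    size = 2 * int(cfg.median_radius_px) + 1
    out = ndimage.median_filter(img.data, size=size, mode="reflect")
    return GrayImage(out, pixel_spacing_mm=img.pixel_spacing_mm, bit_depth=img.bit_depth)


def build_peritumoral(
    tumor: ROIMask,
    pixel_spacing_mm: float,
    margin_mm: float = 7.5,
    exclusion: ROIMask | None = None,
) -> ROIMask:
    """Grow the tumor mask by a peritumoral ring of ``margin_mm`` of tissue.

    The result is the exact Euclidean dilation of the tumor by a disk of
    radius ``round(margin_mm / pixel_spacing_mm)`` pixels (computed via a
    distance transform), minus the exclusion mask, clipped to the frame.
    The margin must lie in the 5-10 mm peritumoral band.
    """
    if tumor.role != "tumor":
        raise ValueError("build_peritumoral expects a tumor-role mask")
    if not (5.0 <= margin_mm <= 10.0):
        raise ValueError(
            f"margin_mm={margin_mm} outside the peritumoral definition of "
            "0.5-1 cm of surrounding tissue; pass a value in [5, 10] mm"
        )
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    radius = int(round(margin_mm / pixel_spacing_mm))
    if radius < 1:
        raise ValueError(
            f"margin {margin_mm} mm rounds to a dilation radius of {radius} px "
            f"at {pixel_spacing_mm} mm/px: spacing too coarse for a peritumoral ring"
        )
    if not tumor.data.any():
        raise ValueError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(~tumor.data)
    grown = dist <= radius
    if exclusion is not None:
        if exclusion.shape != tumor.shape:
            raise ValueError("exclusion mask shape mismatch")
        grown &= ~exclusion.data
    return ROIMask(grown, role="tumor_plus_peritumoral")


def normalize_quantize(
    img: GrayImage, mask: ROIMask, cfg: NormConfig | None = None
) -> QuantizedROI:
    """Normalise and quantise in-mask intensities to Ng integer gray levels.

    ``mu3sigma``: clamp to [mu-3s, mu+3s] (statistics over in-mask pixels),
    then linearly bin into Ng levels; the upper clamp bound maps to Ng-1.
    A constant ROI (sigma == 0) yields all-zero levels and sets the
    ``constant`` warning flag.
    """
    cfg = cfg or NormConfig()
    m = mask.data
    if img.shape != mask.shape:
        raise ValueError("mask and image shapes differ")
    if not m.any():
        raise ValueError("cannot quantise an empty mask")
    vals = img.data[m].astype(np.float64)
    ng = cfg.n_gray_levels

    if cfg.mode == "none":
        lv = np.rint(img.data).astype(np.int64)
        if lv[m].min() < 0 or lv[m].max() >= ng:
            raise ValueError("mode='none' requires integer levels in [0, Ng-1]")
        levels = np.where(m, lv, -1)
        const = bool(np.ptp(lv[m]) == 0)
        return QuantizedROI(levels, m, ng, mask.role, constant=const, raw_values=vals)

    if cfg.mode == "mu3sigma":
        mu = vals.mean()
        sigma = vals.std()
        lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    else:  # minmax
        lo, hi = vals.min(), vals.max()

    if hi <= lo:  # constant ROI
        levels = np.where(m, 0, -1)
        return QuantizedROI(levels, m, ng, mask.role, constant=True, raw_values=vals)

    clamped = np.clip(img.data.astype(np.float64), lo, hi)
    lv = np.floor((clamped - lo) / (hi - lo) * ng).astype(np.int64)
    lv = np.clip(lv, 0, ng - 1)
    levels = np.where(m, lv, -1)
    return QuantizedROI(levels, m, ng, mask.role, constant=False, raw_values=vals)
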