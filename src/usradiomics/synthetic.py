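"""Synthetic ultrasound-like lesion cohorts and tabular feature sets.

Patient images behind published breast-ultrasound radiomic signatures are
rarely shareable, so this module generates stand-ins with the statistical
structure the downstream analysis assumes:

* :func:`simulate_lesion_image` draws a speckle-textured hypoechoic lesion
  (a perturbed ellipse on a brighter background) with a single texture
  knob — the correlation length of the multiplicative Rayleigh speckle —
  plus an echogenicity contrast, optional margin irregularity and an
  optional posterior shadow band.  A top band of the frame acts as the
  skin exclusion region.
* :func:`simulate_cohort` assembles a two-class cohort (pathogenic-variant
  positive vs negative) whose class effect enters only through the texture
  parameters, never through mask geometry, together with class-dependent
  binary Ki67 categories and a two-machine batch structure that is
  independent of class by construction.
* :func:`simulate_feature_table` produces purely tabular feature matrices
  with planted mean shifts and correlated blocks, for exercising the
  selection cascade at known ground truth.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import GrayImage, ROIMask

__all__ = [
    "LesionParams",
    "CohortConfig",
    "FeatTabConfig",
    "SyntheticCohort",
    "simulate_lesion_image",
    "simulate_cohort",
    "simulate_feature_table",
    "null_cohort_config",
    "write_cohort",
]


@dataclass
class LesionParams:
    """Geometry and texture of one synthetic lesion.

    texture_correlation_length_px is the Gaussian smoothing length applied
    to the speckle field — the class-dependent texture knob.  An
    echogenicity_contrast below 1 makes the lesion hypoechoic (darker than
    background), the typical malignant appearance.
    """

    image_size_px: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.2
    lesion_center_px: tuple[float, float] = (64.0, 64.0)
    lesion_radii_px: tuple[float, float] = (22.0, 17.0)  # (semi-axis y, x)
    margin_irregularity: float = 0.3
    echogenicity_contrast: float = 0.5
    speckle_scale: float = 0.25
    texture_correlation_length_px: float = 1.5
    posterior_shadow: bool = False
    background_level: float = 0.6
    skin_band_px: int = 8

    def validate(self) -> None:
        h, w = self.image_size_px
        ry, rx = self.lesion_radii_px
        cy, cx = self.lesion_center_px
        if ry <= 0 or rx <= 0:
            raise ValueError("lesion radii must be positive")
        if not (0.0 <= self.margin_irregularity < 1.0):
            raise ValueError("margin_irregularity must lie in [0, 1)")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be non-negative")
        if self.echogenicity_contrast <= 0:
            raise ValueError("echogenicity_contrast must be positive")
        # the perturbed radius never exceeds r*(1+irregularity)
        grow = 1.0 + self.margin_irregularity
        if (
            cy - ry * grow < 0
            or cy + ry * grow > h - 1
            or cx - rx * grow < 0
            or cx + rx * grow > w - 1
        ):
            raise ValueError(
                "lesion (including margin perturbation) does not fit inside the "
                f"{h}x{w} frame: center {self.lesion_center_px}, radii "
                f"{self.lesion_radii_px}, irregularity {self.margin_irregularity}"
            )


@dataclass
class CohortConfig:
    """Composition and effect model of a synthetic two-class cohort.

    Defaults mirror the published study conditions this pipeline is built
    around: 50 pathogenic-variant-positive and 38 negative lesions, Ki67
    high (>=20%) rates of 46/50 and 26/38 per class, and a roughly even
    two-machine split that is independent of class.  The class effect on
    images enters only through the texture correlation length and the
    echogenicity contrast.
    """

    n_positive: int = 50
    n_negative: int = 38
    corr_len_pos: tuple[float, float] = (2.4, 0.25)  # (mean, sd) px
    corr_len_neg: tuple[float, float] = (1.3, 0.25)
    contrast_pos: float = 0.45
    contrast_neg: float = 0.55
    ki67_high_rate_pos: float = 46 / 50
    ki67_high_rate_neg: float = 26 / 38
    machine_fraction: float = 0.5
    image_size_px: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.2
    radii_range_px: tuple[float, float] = (14.0, 22.0)
    margin_irregularity: float = 0.3
    speckle_scale: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("each class needs at least one lesion")
        for r in (self.ki67_high_rate_pos, self.ki67_high_rate_neg, self.machine_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def null_cohort_config(seed: int = 0, **kw) -> CohortConfig:
    """A no-effect cohort: identical texture distributions and Ki67 rates
    in both classes (class labels carry no signal)."""
    return CohortConfig(
        corr_len_pos=(1.8, 0.25),
        corr_len_neg=(1.8, 0.25),
        contrast_pos=0.5,
        contrast_neg=0.5,
        ki67_high_rate_pos=0.8,
        ki67_high_rate_neg=0.8,
        seed=seed,
        **kw,
    )


@dataclass
class FeatTabConfig:
    """Tabular feature-matrix generator settings.

    The first ``planted_feature_count`` features carry a standardized mean
    shift ``effect_size`` between classes; ``correlated_blocks`` lists
    block sizes drawn with within-block Spearman correlation
    ``block_spearman`` (members of a block are noise features placed after
    the planted ones); everything else is exchangeable N(0,1) noise.
    """

    n_per_class: int = 44
    n_features: int = 300
    planted_feature_count: int = 5
    effect_size: float = 1.5
    correlated_blocks: tuple[int, ...] = ()
    block_spearman: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.planted_feature_count > self.n_features:
            raise ValueError("more planted features than features")
        if not (-1.0 < self.block_spearman <= 1.0):
            raise ValueError("|block correlation| must be < 1 (or exactly 1 for duplicates)")
        if self.planted_feature_count + sum(self.correlated_blocks) > self.n_features:
            raise ValueError("planted features + blocks exceed n_features")


@dataclass
class SyntheticCohort:
    """Images, masks and per-lesion metadata of one simulated cohort."""

    images: list[GrayImage]
    tumor_masks: list[ROIMask]
    exclusion_masks: list[ROIMask]
    meta: pd.DataFrame = field(repr=False)  # id, label, ki67_high, machine, spacing_mm

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------


def _margin_profile(rng: np.random.Generator, n_harmonics: int = 5) -> callable:
    """Smooth periodic radial perturbation g(phi) with max |g| == 1."""
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.normal(size=n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)

    def g(phi: np.ndarray) -> np.ndarray:
        val = np.zeros_like(phi)
        for k, a, p in zip(ks, amps, phases):
            val += a * np.cos(k * phi + p)
        peak = np.max(np.abs(val))
        return val / peak if peak > 0 else val

    return g


def simulate_lesion_image(
    params: LesionParams, seed: int
) -> tuple[GrayImage, ROIMask, ROIMask]:
    """Draw one speckle-textured lesion frame.

    Returns the image, the tumor mask (the perturbed-ellipse interior) and
    an exclusion mask (a top skin band).  Deterministic for a fixed seed.
    The intensity model is a piecewise-constant echogenicity map (lesion =
    background * contrast) times a mean-one multiplicative Rayleigh
    speckle perturbation, Gaussian-smoothed at the texture correlation
    length; the speckle_scale -> 0 limit is noise-free.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    h, w = params.image_size_px
    cy, cx = params.lesion_center_px
    ry, rx = params.lesion_radii_px

    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) / ry
    dx = (xx - cx) / rx
    rho = np.hypot(dy, dx)
    if params.margin_irregularity > 0:
        phi = np.arctan2(dy, dx)
        g = _margin_profile(rng)
        boundary = 1.0 + params.margin_irregularity * g(phi)
    else:
        boundary = 1.0
    tumor = rho <= boundary

    emap = np.where(
        tumor,
        params.background_level * params.echogenicity_contrast,
        params.background_level,
    )
    if params.posterior_shadow:
        below = (yy > cy + ry) & (np.abs(xx - cx) < rx)
        emap = np.where(below, emap * 0.5, emap)

    if params.speckle_scale > 0:
        s = params.speckle_scale
        rayleigh = rng.rayleigh(scale=s, size=(h, w))
        noise = rayleigh - s * np.sqrt(np.pi / 2.0)  # mean-one multiplier
        img = emap * (1.0 + noise)
    else:
        img = emap.astype(np.float64)
    if params.texture_correlation_length_px > 0:
        img = ndimage.gaussian_filter(img, sigma=params.texture_correlation_length_px)
    img = np.clip(img, 0.0, None)

    excl = np.zeros((h, w), dtype=bool)
    excl[: params.skin_band_px, :] = True
    return (
        GrayImage(img, pixel_spacing_mm=params.pixel_spacing_mm),
        ROIMask(tumor, role="tumor"),
        ROIMask(excl, role="exclusion"),
    )


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a full two-class lesion cohort with Ki67 and machine labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_positive + config.n_negative
    labels = np.array([1] * config.n_positive + [0] * config.n_negative)

    images, tmasks, emasks = [], [], []
    ki67, machine = [], []
    h, w = config.image_size_px
    rlo, rhi = config.radii_range_px
    for i in range(n):
        pos = labels[i] == 1
        mean, sd = config.corr_len_pos if pos else config.corr_len_neg
        corr = max(0.3, rng.normal(mean, sd))
        contrast = config.contrast_pos if pos else config.contrast_neg
        radii = (rng.uniform(rlo, rhi), rng.uniform(rlo, rhi))
        grow = 1.0 + config.margin_irregularity
        jitter = 4.0
        center = (
            float(np.clip(h / 2 + rng.uniform(-jitter, jitter), radii[0] * grow + 1, h - 2 - radii[0] * grow)),
            float(np.clip(w / 2 + rng.uniform(-jitter, jitter), radii[1] * grow + 1, w - 2 - radii[1] * grow)),
        )
        params = LesionParams(
            image_size_px=config.image_size_px,
            pixel_spacing_mm=config.pixel_spacing_mm,
            lesion_center_px=center,
            lesion_radii_px=radii,
            margin_irregularity=config.margin_irregularity,
            echogenicity_contrast=contrast,
            speckle_scale=config.speckle_scale,
            texture_correlation_length_px=corr,
        )
        img, tm, em = simulate_lesion_image(params, seed=int(rng.integers(2**31 - 1)))
        images.append(img)
        tmasks.append(tm)
        emasks.append(em)
        rate = config.ki67_high_rate_pos if pos else config.ki67_high_rate_neg
        ki67.append(int(rng.random() < rate))
        machine.append("A" if rng.random() < config.machine_fraction else "B")

    meta = pd.DataFrame(
        {
            "id": [f"lesion_{i:03d}" for i in range(n)],
            "label": labels,
            "ki67_high": ki67,
            "machine": machine,
            "spacing_mm": config.pixel_spacing_mm,
        }
    )
    return SyntheticCohort(images, tmasks, emasks, meta)


def simulate_feature_table(config: FeatTabConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Tabular feature matrix with planted shifts and correlated blocks.

    Returns (features DataFrame, binary labels).  Planted features are
    ``f000..``; block members are named ``blk<b>_<j>``.  The requested
    within-block Spearman correlation is achieved in expectation by the
    Gaussian copula mapping rho_pearson = 2*sin(pi*rho_s/6).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_class
    y = np.array([1] * config.n_per_class + [0] * config.n_per_class)
    p = config.n_features
    X = rng.standard_normal((n, p))
    k = config.planted_feature_count
    X[y == 1, :k] += config.effect_size

    names = [f"f{j:03d}" for j in range(p)]
    col = k
    for b, size in enumerate(config.correlated_blocks):
        rho_s = config.block_spearman
        rho = 1.0 if rho_s >= 1.0 else 2.0 * np.sin(np.pi * rho_s / 6.0)
        z = rng.standard_normal(n)
        for j in range(size):
            if rho >= 1.0:
                X[:, col] = z
            else:
                X[:, col] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.standard_normal(n)
            names[col] = f"blk{b}_{j}"
            col += 1
    return pd.DataFrame(X, columns=names), y


# ---------------------------------------------------------------------------
# Export


def write_cohort(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write images/masks as 8-bit PNGs plus a metadata CSV; returns a manifest."""
    from .imaging import save_image, save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, tm, em) in enumerate(
        zip(cohort.images, cohort.tumor_masks, cohort.exclusion_masks)
    ):
        lid = cohort.meta["id"].iloc[i]
        ip, tp, ep = out / f"{lid}.png", out / f"{lid}_tumor.png", out / f"{lid}_excl.png"
        save_image(ip, img)
        save_mask(tp, tm)
        save_mask(ep, em)
        rows.append(
            {
                "id": lid,
                "image_path": str(ip),
                "tumor_mask_path": str(tp),
                "exclusion_mask_path": str(ep),
                "spacing_mm": img.pixel_spacing_mm,
            }
        )
    cohort.meta.to_csv(out / "cohort.csv", index=False)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
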