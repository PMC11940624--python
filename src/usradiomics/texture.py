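"""Mazda-convention texture features for quantised ultrasound ROIs.

Implements the five feature families used to characterise lesion texture:

* first-order histogram statistics (mean, variance, skewness, kurtosis and
  nearest-rank percentiles) of the quantised gray levels;
* gray-level co-occurrence (GLCM) statistics in the classical Haralick
  form, for offsets (0,d), (d,0), (d,d), (d,-d) with d = 1..5;
* gray-level run-length (GLRLM) statistics along 0, 45, 90 and 135 degrees;
* a first-order causal autoregressive model (Teta1..Teta4, Sigma) with the
  W / NW / N / NE neighbourhood;
* orthonormal Haar wavelet sub-band energies WavEn{LL,LH,HL,HH}_s{1..6}.

Feature names follow the convention used in published breast-ultrasound
radiomic signatures: ``S(0,1)Contrast`` for GLCM, ``Horzl_RLNonUni`` /
``135dr_GLevNonU`` for run lengths, ``Teta1..4``/``Sigma`` for the AR
model, ``WavEnLL_s6`` for wavelets and ``Perc.01.`` for percentiles.
Export-mangled spellings such as ``X.S.0.1.Contrast`` or ``ZWavEnLL_s6``
map onto these via :func:`canonical_name`.

Undefined values (e.g. a wavelet scale larger than the ROI bounding box,
or a GLCM offset with no in-mask pair) are reported as NaN, never as a
silent zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .imaging import GrayImage, NormConfig, QuantizedROI, ROIMask, normalize_quantize

__all__ = [
    "GLCMatrix",
    "RunLengthMatrix",
    "feature_registry",
    "canonical_name",
    "nearest_rank_percentile",
    "histogram_features",
    "glcm",
    "glcm_features",
    "run_length_matrix",
    "glrlm_features",
    "ar_model",
    "wavelet_energies",
    "extract_all",
    "GLCM_OFFSETS",
    "GLCM_STAT_NAMES",
    "GLRLM_ANGLES",
    "GLRLM_STAT_NAMES",
    "HISTOGRAM_NAMES",
    "AR_NAMES",
    "WAVELET_BANDS",
    "MAX_WAVELET_SCALE",
]

# Registry layout -----------------------------------------------------------

HISTOGRAM_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc.01.",
    "Perc.10.",
    "Perc.50.",
    "Perc.90.",
    "Perc.99.",
)

GLCM_STAT_NAMES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)

# offsets are (dy, dx): horizontal, vertical and the two diagonals, d=1..5
GLCM_OFFSETS = tuple(
    off for d in range(1, 6) for off in ((0, d), (d, 0), (d, d), (d, -d))
)

GLRLM_ANGLES: Mapping[int, str] = {0: "Horzl", 45: "45dgr", 90: "Vertl", 135: "135dr"}
GLRLM_STAT_NAMES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")

AR_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")

WAVELET_BANDS = ("LL", "LH", "HL", "HH")
MAX_WAVELET_SCALE = 6


def feature_registry(max_wavelet_scale: int = MAX_WAVELET_SCALE) -> list[str]:
    """Ordered canonical names of the full feature vector (278 by default)."""
    names = list(HISTOGRAM_NAMES)
    for dy, dx in GLCM_OFFSETS:
        names.extend(f"S({dy},{dx}){s}" for s in GLCM_STAT_NAMES)
    for ang in (0, 45, 90, 135):
        names.extend(f"{GLRLM_ANGLES[ang]}_{s}" for s in GLRLM_STAT_NAMES)
    names.extend(AR_NAMES)
    for k in range(1, max_wavelet_scale + 1):
        names.extend(f"WavEn{b}_s{k}" for b in WAVELET_BANDS)
    return names


_MANGLED_GLCM = re.compile(r"^X\.S\.(\d+)\.(\d+)\.(\w+)$")
_MANGLED_WAV = re.compile(r"^Z?WavEn(LL|LH|HL|HH)_s\.?(\d)$")


def canonical_name(name: str) -> str:
    """Map export-mangled feature spellings onto canonical registry names.

    ``X.S.0.1.Contrast`` -> ``S(0,1)Contrast``; ``ZWavEnLL_s6`` and
    ``WavEnHL_s.3`` -> ``WavEnLL_s6`` / ``WavEnHL_s3``; ``X135dr_GLevNonU``
    -> ``135dr_GLevNonU``.  Already-canonical names pass through.
    """
    m = _MANGLED_GLCM.match(name)
    if m:
        return f"S({m.group(1)},{m.group(2)}){m.group(3)}"
    m = _MANGLED_WAV.match(name)
    if m:
        return f"WavEn{m.group(1)}_s{m.group(2)}"
    if name.startswith("X") and re.match(r"^X(45dgr|135dr|Horzl|Vertl)_", name):
        return name[1:]
    return name


# ---------------------------------------------------------------------------
# First-order histogram


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th order statistic (1-based)."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(p * n))
    k = min(max(k, 1), n)
    return float(v[k - 1])


def histogram_features(roi: QuantizedROI) -> dict[str, float]:
    """First-order statistics of the quantised in-mask gray levels.

    Skewness and kurtosis are undefined (NaN) for a constant ROI.
    """
    x = roi.in_mask_levels.astype(np.float64)
    mean = x.mean()
    var = x.var()
    out = {"Mean": float(mean), "Variance": float(var)}
    if var == 0.0:
        out["Skewness"] = np.nan
        out["Kurtosis"] = np.nan
    else:
        z = (x - mean) / np.sqrt(var)
        out["Skewness"] = float(np.mean(z**3))
        out["Kurtosis"] = float(np.mean(z**4) - 3.0)
    for p, nm in ((0.01, "Perc.01."), (0.10, "Perc.10."), (0.50, "Perc.50."),
                  (0.90, "Perc.90."), (0.99, "Perc.99.")):
        out[nm] = nearest_rank_percentile(x, p)
    return out


# ---------------------------------------------------------------------------
# GLCM


@dataclass
class GLCMatrix:
    """Normalised symmetric co-occurrence matrix for one pixel offset."""

    p: np.ndarray  # Ng x Ng, sums to 1
    offset: tuple[int, int]  # (dy, dx)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(self.p < 0):
            raise ValueError("negative co-occurrence entries")
        s = self.p.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"co-occurrence entries must sum to 1, got {s}")


def glcm(roi: QuantizedROI, offset: tuple[int, int]) -> GLCMatrix | None:
    """Symmetric co-occurrence matrix for offset (dy, dx).

    Both pixels of a pair must lie inside the mask; pairs are accumulated
    in both directions.  Returns None when the mask admits no valid pair.
    """
    dy, dx = offset
    if (dy, dx) == (0, 0):
        raise ValueError("offset (0,0) is not a valid co-occurrence offset")
    lv, m, ng = roi.levels, roi.mask, roi.n_gray_levels
    h, w = lv.shape

    y0s, y0e = max(0, -dy), min(h, h - dy)
    x0s, x0e = max(0, -dx), min(w, w - dx)
    if y0s >= y0e or x0s >= x0e:
        return None
    src_m = m[y0s:y0e, x0s:x0e]
    dst_m = m[y0s + dy : y0e + dy, x0s + dx : x0e + dx]
    valid = src_m & dst_m
    if not valid.any():
        return None
    a = lv[y0s:y0e, x0s:x0e][valid]
    b = lv[y0s + dy : y0e + dy, x0s + dx : x0e + dx][valid]
    counts = np.bincount(a * ng + b, minlength=ng * ng).astype(np.float64)
    counts += np.bincount(b * ng + a, minlength=ng * ng)
    p = counts.reshape(ng, ng)
    return GLCMatrix(p / p.sum(), offset=(dy, dx))


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p*ln(p) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_features(m: GLCMatrix | None) -> dict[str, float]:
    """Classical Haralick statistics of one co-occurrence matrix.

    Gray levels are indexed 1..Ng; entropies use the natural logarithm.
    A degenerate (single-entry) matrix yields AngScMom 1, Contrast 0 and
    zero entropies; its Correlat is reported as 0 by convention.
    """
    if m is None:
        return {s: np.nan for s in GLCM_STAT_NAMES}
    p = m.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=1)  # == py for a symmetric matrix
    mu = float(i @ px)
    var = float(((i - mu) ** 2) @ px)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    feats: dict[str, float] = {}
    feats["AngScMom"] = float((p**2).sum())
    feats["Contrast"] = float((diff**2 * p).sum())
    if var > 0:
        feats["Correlat"] = float(((ii * jj * p).sum() - mu * mu) / var)
    else:
        feats["Correlat"] = 0.0
    feats["SumOfSqs"] = float((((ii - mu) ** 2) * p).sum())
    feats["InvDfMom"] = float((p / (1.0 + diff**2)).sum())

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    flat = p.ravel()
    sum_idx = (ii + jj).astype(int).ravel() - 2
    pxy_sum = np.bincount(sum_idx, weights=flat, minlength=2 * ng - 1)
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    sum_avg = float(ks @ pxy_sum)
    feats["SumAverg"] = sum_avg
    feats["SumVarnc"] = float(((ks - sum_avg) ** 2) @ pxy_sum)
    feats["SumEntrp"] = float(-_xlogx(pxy_sum).sum())
    feats["Entropy"] = float(-_xlogx(flat).sum())

    diff_idx = np.abs(ii - jj).astype(int).ravel()
    pxy_diff = np.bincount(diff_idx, weights=flat, minlength=ng)
    kd = np.arange(ng, dtype=np.float64)
    mu_d = float(kd @ pxy_diff)
    feats["DifVarnc"] = float(((kd - mu_d) ** 2) @ pxy_diff)
    feats["DifEntrp"] = float(-_xlogx(pxy_diff).sum())
    return feats


# ---------------------------------------------------------------------------
# GLRLM


@dataclass
class RunLengthMatrix:
    """R(g, l): number of maximal runs of level g and length l along one angle."""

    matrix: np.ndarray  # Ng x Lmax, integer counts; column j = run length j+1
    angle_deg: int
    n_pixels: int  # in-mask pixels traversed

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


def _scanlines(lv: np.ndarray, m: np.ndarray, angle_deg: int) -> Iterable[tuple[np.ndarray, np.ndarray]]:
    """Yield (levels, mask) along each scanline of the given direction.

    0 deg: rows; 90 deg: columns; 135 deg: main diagonals (row - col
    constant); 45 deg: anti-diagonals (row + col constant).
    """
    h, w = lv.shape
    if angle_deg == 0:
        for r in range(h):
            yield lv[r], m[r]
    elif angle_deg == 90:
        for c in range(w):
            yield lv[:, c], m[:, c]
    elif angle_deg == 135:
        for off in range(-(h - 1), w):
            yield lv.diagonal(off), m.diagonal(off)
    elif angle_deg == 45:
        fl, fm = lv[:, ::-1], m[:, ::-1]
        for off in range(-(h - 1), w):
            yield fl.diagonal(off), fm.diagonal(off)
    else:
        raise ValueError("angle must be one of 0, 45, 90, 135 degrees")


def run_length_matrix(roi: QuantizedROI, angle_deg: int) -> RunLengthMatrix:
    """Enumerate maximal constant-level runs along mask-interior scanlines.

    A run breaks at mask boundaries and at level changes.
    """
    lv, m = roi.levels, roi.mask
    ng = roi.n_gray_levels
    run_levels: list[np.ndarray] = []
    run_lengths: list[np.ndarray] = []
    n_px = 0
    for line, lm in _scanlines(lv, m, angle_deg):
        if not lm.any():
            continue
        n_px += int(lm.sum())
        # break runs where mask is off or level changes
        tagged = np.where(lm, line, -1)
        change = np.flatnonzero(tagged[1:] != tagged[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [tagged.size]))
        keep = tagged[starts] >= 0
        run_levels.append(tagged[starts[keep]])
        run_lengths.append((ends - starts)[keep])
    levels = np.concatenate(run_levels) if run_levels else np.zeros(0, int)
    lengths = np.concatenate(run_lengths) if run_lengths else np.zeros(0, int)
    lmax = int(lengths.max()) if lengths.size else 1
    mat = np.zeros((ng, lmax), dtype=np.int64)
    np.add.at(mat, (levels, lengths - 1), 1)
    return RunLengthMatrix(mat, angle_deg=angle_deg, n_pixels=n_px)


def glrlm_features(roi: QuantizedROI, angle_deg: int) -> dict[str, float]:
    """Classical run-length statistics for one direction.

    ShrtREmp = sum R/l^2 / N;  LngREmph = sum R*l^2 / N;
    GLevNonU = sum_g (sum_l R)^2 / N;  RLNonUni = sum_l (sum_g R)^2 / N;
    Fraction = N / (number of traversed in-mask pixels).
    """
    rlm = run_length_matrix(roi, angle_deg)
    r = rlm.matrix.astype(np.float64)
    n = r.sum()
    if n == 0:
        return {s: np.nan for s in GLRLM_STAT_NAMES}
    l = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    per_len = r.sum(axis=0)
    per_lvl = r.sum(axis=1)
    return {
        "ShrtREmp": float((per_len / l**2).sum() / n),
        "LngREmph": float((per_len * l**2).sum() / n),
        "GLevNonU": float((per_lvl**2).sum() / n),
        "RLNonUni": float((per_len**2).sum() / n),
        "Fraction": float(n / rlm.n_pixels),
    }


# ---------------------------------------------------------------------------
# Causal autoregressive model


def ar_model(roi: QuantizedROI, min_valid: int = 32) -> dict[str, float]:
    """First-order causal AR texture model on mean-centred gray levels.

    s(x,y) ~ Teta1*s(x-1,y) + Teta2*s(x-1,y-1) + Teta3*s(x,y-1) + Teta4*s(x+1,y-1)
    fitted by least squares over pixels whose four causal neighbours
    (W, NW, N, NE) are all in-mask; Sigma is the residual standard
    deviation.  A rank-deficient design (constant ROI) yields zeros.
    """
    lv, m = roi.levels, roi.mask
    s = np.where(m, lv.astype(np.float64) - lv[m].mean(), 0.0)
    h, w = s.shape
    if h < 3 or w < 3:
        raise ValueError("ROI raster too small for the causal AR neighbourhood")

    c = np.s_[1 : h - 0, 1 : w - 1]  # rows 1.., cols 1..w-2
    cm = m[1:, 1:-1]
    west = m[1:, :-2]
    nw = m[:-1, :-2]
    north = m[:-1, 1:-1]
    ne = m[:-1, 2:]
    valid = cm & west & nw & north & ne
    n_valid = int(valid.sum())
    if n_valid < min_valid:
        raise ValueError(
            f"only {n_valid} pixels have all four causal neighbours in-mask "
            f"(need >= {min_valid})"
        )
    y = s[1:, 1:-1][valid]
    X = np.column_stack(
        [s[1:, :-2][valid], s[:-1, :-2][valid], s[:-1, 1:-1][valid], s[:-1, 2:][valid]]
    )
    if not np.any(X):  # constant ROI after centring
        return {"Teta1": 0.0, "Teta2": 0.0, "Teta3": 0.0, "Teta4": 0.0, "Sigma": 0.0}
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    sigma = float(np.sqrt(np.mean(resid**2)))
    return dict(zip(AR_NAMES, [*map(float, theta), sigma]))


# ---------------------------------------------------------------------------
# Haar wavelet sub-band energies


def wavelet_energies(
    roi: QuantizedROI, max_scale: int = MAX_WAVELET_SCALE
) -> dict[str, float]:
    """Mean squared orthonormal Haar coefficients per sub-band and scale.

    The mask's bounding-box patch (out-of-mask pixels filled with the
    in-mask mean) is decomposed by non-overlapping 2x2 block transforms:
    LL=(a+b+c+d)/2, HL=(a-b+c-d)/2 (horizontal frequency), LH=(a+b-c-d)/2
    (vertical frequency), HH=(a-b-c+d)/2; odd trailing rows/columns are
    truncated.  Energies average over coefficient positions whose support
    intersects the mask.  Scales whose dyadic support exceeds the bounding
    box are reported as NaN.
    """
    lv, m = roi.levels, roi.mask
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    patch_m = m[r0:r1, c0:c1]
    fill = lv[m].astype(np.float64).mean()
    patch = np.where(patch_m, lv[r0:r1, c0:c1].astype(np.float64), fill)
    bh, bw = patch.shape

    out: dict[str, float] = {}
    cur, cur_m = patch, patch_m
    for k in range(1, max_scale + 1):
        names = {b: f"WavEn{b}_s{k}" for b in WAVELET_BANDS}
        if bh < 2**k or bw < 2**k or cur.shape[0] < 2 or cur.shape[1] < 2:
            for b in WAVELET_BANDS:
                out[names[b]] = np.nan
            continue
        h2, w2 = cur.shape[0] - cur.shape[0] % 2, cur.shape[1] - cur.shape[1] % 2
        a = cur[0:h2:2, 0:w2:2]
        b_ = cur[0:h2:2, 1:w2:2]
        c_ = cur[1:h2:2, 0:w2:2]
        d = cur[1:h2:2, 1:w2:2]
        ll = (a + b_ + c_ + d) / 2.0
        hl = (a - b_ + c_ - d) / 2.0
        lh = (a + b_ - c_ - d) / 2.0
        hh = (a - b_ - c_ + d) / 2.0
        ms = cur_m[0:h2:2, 0:w2:2] | cur_m[0:h2:2, 1:w2:2] | cur_m[1:h2:2, 0:w2:2] | cur_m[1:h2:2, 1:w2:2]
        if not ms.any():
            for bn in WAVELET_BANDS:
                out[names[bn]] = np.nan
            continue
        for bn, band in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
            out[names[bn]] = float(np.mean(band[ms] ** 2))
        cur, cur_m = ll, ms
    return out


# ---------------------------------------------------------------------------
# Full-vector extraction


def extract_features(roi: QuantizedROI, max_wavelet_scale: int = MAX_WAVELET_SCALE) -> dict[str, float]:
    """All feature families for one quantised ROI, in registry order."""
    feats = dict(histogram_features(roi))
    for off in GLCM_OFFSETS:
        stats = glcm_features(glcm(roi, off))
        feats.update({f"S({off[0]},{off[1]}){k}": v for k, v in stats.items()})
    for ang, prefix in GLRLM_ANGLES.items():
        stats = glrlm_features(roi, ang)
        feats.update({f"{prefix}_{k}": v for k, v in stats.items()})
    try:
        feats.update(ar_model(roi))
    except ValueError:
        feats.update({nm: np.nan for nm in AR_NAMES})
    feats.update(wavelet_energies(roi, max_wavelet_scale))
    order = feature_registry(max_wavelet_scale)
    return {nm: feats[nm] for nm in order}


def extract_all(
    img: GrayImage,
    tumor: ROIMask,
    tumor_plus_peri: ROIMask,
    cfg: NormConfig | None = None,
    max_wavelet_scale: int = MAX_WAVELET_SCALE,
) -> dict[str, dict[str, float]]:
    """Feature vectors for both ROI scopes of one lesion.

    Returns ``{"tumor": {...}, "tumor_plus_peritumoral": {...}}``, each an
    ordered canonical-name -> value map of the full registry.  Intensities
    are normalised per ROI (default mu-3-sigma, Ng=64).
    """
    cfg = cfg or NormConfig()
    if not np.all(tumor_plus_peri.data[tumor.data]):
        raise ValueError("tumor mask must be contained in the tumor+peritumoral mask")
    out = {}
    for mask in (tumor, tumor_plus_peri):
        q = normalize_quantize(img, mask, cfg)
        out[mask.role] = extract_features(q, max_wavelet_scale)
    return out
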