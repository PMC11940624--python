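"""Texture-feature families against brute-force oracles and closed forms."""

import numpy as np
import pytest

from usradiomics.imaging import GrayImage, NormConfig, ROIMask, normalize_quantize
from usradiomics.texture import (
    GLCM_OFFSETS,
    GLRLM_ANGLES,
    ar_model,
    canonical_name,
    extract_all,
    extract_features,
    feature_registry,
    glcm,
    glcm_features,
    glrlm_features,
    histogram_features,
    nearest_rank_percentile,
    run_length_matrix,
    wavelet_energies,
)

from conftest import make_roi, random_roi
from oracles import (
    brute_glcm,
    brute_glcm_features,
    brute_glrlm_features,
    brute_nearest_rank,
    brute_runs,
)


# ---------------------------------------------------------------------- hist


def test_nearest_rank_percentile_order_statistics():
    vals = np.arange(1, 101)
    assert nearest_rank_percentile(vals, 0.01) == 1  # ceil(0.01*100) = 1st
    assert nearest_rank_percentile(vals, 0.50) == 50
    assert nearest_rank_percentile(vals, 0.99) == 99
    rng = np.random.default_rng(0)
    x = rng.normal(size=37)
    for p in (0.01, 0.1, 0.5, 0.9, 0.99):
        assert nearest_rank_percentile(x, p) == brute_nearest_rank(x, p)


def test_histogram_constant_roi_degenerate():
    roi = make_roi(np.full((4, 4), 0), ng=8)
    h = histogram_features(roi)
    assert h["Variance"] == 0.0
    assert h["Perc.01."] == 0.0 and h["Perc.99."] == 0.0
    assert np.isnan(h["Skewness"]) and np.isnan(h["Kurtosis"])


def test_histogram_shift_invariance_via_normalization():
    """Features computed downstream of mu-3-sigma quantisation do not move
    when the raw intensities are shifted."""
    rng = np.random.default_rng(3)
    raw = rng.integers(10, 200, size=(8, 8)).astype(np.float64)
    mask = ROIMask(np.ones((8, 8), bool), role="tumor")
    q1 = normalize_quantize(GrayImage(raw, 0.1), mask, NormConfig())
    q2 = normalize_quantize(GrayImage(raw + 37.0, 0.1), mask, NormConfig())
    assert histogram_features(q1) == histogram_features(q2)


# ---------------------------------------------------------------------- GLCM


def test_glcm_constant_roi_single_entry():
    roi = make_roi(np.full((4, 4), 2), ng=4)
    m = glcm(roi, (0, 1))
    assert m.p[2, 2] == 1.0 and m.p.sum() == 1.0


def test_glcm_checkerboard_exact_matrix():
    levels = np.indices((4, 4)).sum(axis=0) % 2
    roi = make_roi(levels, ng=4)
    m = glcm(roi, (0, 1))
    expect = np.zeros((4, 4))
    expect[0, 1] = expect[1, 0] = 0.5
    assert np.allclose(m.p, expect)
    f = glcm_features(m)
    assert f["Contrast"] == pytest.approx(1.0)
    assert f["AngScMom"] == pytest.approx(0.5)


def test_glcm_zero_offset_rejected():
    roi = make_roi(np.zeros((3, 3), int))
    with pytest.raises(ValueError):
        glcm(roi, (0, 0))


def test_glcm_no_valid_pair_gives_undefined():
    mask = np.zeros((3, 3), bool)
    mask[0, 0] = mask[2, 2] = True  # no (0,1)-neighbouring pair
    roi = make_roi(np.zeros((3, 3), int), mask)
    assert glcm(roi, (0, 1)) is None
    assert all(np.isnan(v) for v in glcm_features(None).values())


def test_glcm_features_degenerate_matrix():
    roi = make_roi(np.full((3, 3), 1), ng=4)
    f = glcm_features(glcm(roi, (1, 0)))
    assert f["AngScMom"] == 1.0
    assert f["Contrast"] == 0.0
    assert f["SumEntrp"] == 0.0 and f["Entropy"] == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_glcm_oracle_equivalence_random(seed):
    rng = np.random.default_rng(seed)
    roi = random_roi(rng)
    for off in ((0, 1), (1, 0), (1, 1), (1, -1), (0, 2), (2, -2)):
        ours = glcm(roi, off)
        ref = brute_glcm(roi.levels, roi.mask, off, roi.n_gray_levels)
        if ours is None:
            assert ref is None
            continue
        assert np.allclose(ours.p, ref, atol=1e-15)
        got = glcm_features(ours)
        want = brute_glcm_features(ref)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k


# --------------------------------------------------------------------- GLRLM


def test_glrlm_single_run_closed_form():
    roi = make_roi(np.full((1, 8), 3), ng=4)
    f = glrlm_features(roi, 0)
    assert f["GLevNonU"] == 1.0
    assert f["RLNonUni"] == 1.0
    assert f["LngREmph"] == 64.0
    assert f["Fraction"] == pytest.approx(1 / 8)


def test_glrlm_alternating_all_short_runs():
    roi = make_roi(np.arange(8).reshape(1, 8) % 2, ng=4)
    f = glrlm_features(roi, 0)
    assert f["ShrtREmp"] == 1.0  # 8 runs of length 1
    assert f["Fraction"] == 1.0


@pytest.mark.parametrize("angle", [0, 45, 90, 135])
def test_glrlm_pixel_conservation(angle, rng):
    for _ in range(10):
        roi = random_roi(rng)
        rlm = run_length_matrix(roi, angle)
        l = np.arange(1, rlm.matrix.shape[1] + 1)
        assert (rlm.matrix @ l).sum() == roi.mask.sum() == rlm.n_pixels


@pytest.mark.parametrize("seed", range(20))
def test_glrlm_oracle_equivalence_random(seed):
    rng = np.random.default_rng(100 + seed)
    roi = random_roi(rng)
    for angle in (0, 45, 90, 135):
        got = glrlm_features(roi, angle)
        want = brute_glrlm_features(roi.levels, roi.mask, angle)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-12), (angle, k)


def test_run_break_at_mask_boundary():
    levels = np.zeros((1, 5), int)
    mask = np.array([[1, 1, 0, 1, 1]], bool)
    runs = brute_runs(levels, mask, 0)
    assert runs == [(0, 2), (0, 2)]
    rlm = run_length_matrix(make_roi(levels, mask), 0)
    assert rlm.n_runs == 2 and rlm.matrix[0, 1] == 2


# ------------------------------------------------------------------------ AR


def test_ar_constant_roi_degenerate():
    roi = make_roi(np.full((10, 10), 5), ng=8)
    f = ar_model(roi)
    assert f == {"Teta1": 0.0, "Teta2": 0.0, "Teta3": 0.0, "Teta4": 0.0, "Sigma": 0.0}


def test_ar_too_few_valid_pixels():
    mask = np.zeros((10, 10), bool)
    mask[:2, :2] = True
    roi = make_roi(np.zeros((10, 10), int), mask)
    with pytest.raises(ValueError, match="causal neighbours"):
        ar_model(roi)


def _causal_field(theta, shape, rng):
    h, w = shape
    s = np.zeros(shape)
    eps = rng.standard_normal(shape)
    for y in range(1, h):
        for x in range(1, w - 1):
            s[y, x] = (
                theta[0] * s[y, x - 1]
                + theta[1] * s[y - 1, x - 1]
                + theta[2] * s[y - 1, x]
                + theta[3] * s[y - 1, x + 1]
                + eps[y, x]
            )
    return s


def test_ar_parameter_recovery():
    rng = np.random.default_rng(7)
    s = _causal_field((0.4, 0.0, 0.3, 0.0), (128, 128), rng)
    img = GrayImage(s - s.min(), 0.1)
    q = normalize_quantize(img, ROIMask(np.ones(s.shape, bool), role="tumor"))
    f = ar_model(q)
    assert f["Teta1"] == pytest.approx(0.4, abs=0.05)
    assert f["Teta2"] == pytest.approx(0.0, abs=0.05)
    assert f["Teta3"] == pytest.approx(0.3, abs=0.05)
    assert f["Teta4"] == pytest.approx(0.0, abs=0.05)


def test_ar_white_noise_null():
    rng = np.random.default_rng(8)
    s = rng.standard_normal((100, 100))
    img = GrayImage(s - s.min(), 0.1)
    q = normalize_quantize(img, ROIMask(np.ones(s.shape, bool), role="tumor"))
    f = ar_model(q)
    for k in ("Teta1", "Teta2", "Teta3", "Teta4"):
        assert abs(f[k]) < 0.1


# -------------------------------------------------------------------- wavelet


def test_wavelet_constant_roi_no_detail():
    roi = make_roi(np.full((64, 64), 3), ng=8)
    f = wavelet_energies(roi, max_scale=6)
    for k in range(1, 7):
        for band in ("LH", "HL", "HH"):
            assert f[f"WavEn{band}_s{k}"] == 0.0


def test_wavelet_vertical_step_edge():
    levels = np.zeros((8, 8), int)
    levels[:, 3:] = 5  # edge inside a 2x2 block column pair
    f = wavelet_energies(make_roi(levels, ng=8), max_scale=1)
    assert f["WavEnHL_s1"] > 0.0
    assert f["WavEnLH_s1"] == 0.0


def test_wavelet_parseval_scale1(rng):
    levels = rng.integers(0, 16, size=(16, 16))
    roi = make_roi(levels, ng=16)
    f = wavelet_energies(roi, max_scale=1)
    n_coef = 8 * 8
    band_energy = n_coef * sum(f[f"WavEn{b}_s1"] for b in ("LL", "LH", "HL", "HH"))
    assert band_energy == pytest.approx(np.sum(levels.astype(float) ** 2))


def test_wavelet_small_roi_undefined_scales():
    roi = make_roi(np.zeros((8, 8), int), ng=4)
    f = wavelet_energies(roi, max_scale=6)
    assert np.isfinite(f["WavEnLL_s3"])
    for band in ("LL", "LH", "HL", "HH"):
        assert np.isnan(f[f"WavEn{band}_s4"])


# ----------------------------------------------------------------- registry


def test_registry_complete_and_deterministic(rng):
    names = feature_registry()
    assert len(names) == 278
    assert len(set(names)) == 278
    roi = make_roi(rng.integers(0, 8, size=(20, 20)), ng=8)
    f1 = extract_features(roi)
    f2 = extract_features(roi)
    assert list(f1) == names
    assert f1 == f2


def test_extract_all_requires_nesting(rng):
    img = GrayImage(rng.integers(0, 255, size=(32, 32)).astype(float), 0.2)
    t = ROIMask(np.zeros((32, 32), bool), role="tumor")
    t.data[10:20, 10:20] = True
    p = ROIMask(np.zeros((32, 32), bool), role="tumor_plus_peritumoral")
    p.data[12:18, 12:18] = True  # does not contain the tumor
    with pytest.raises(ValueError, match="contained"):
        extract_all(img, t, p)


def test_rotation_permutes_directional_features(rng):
    """A 90-degree rotation swaps horizontal/vertical and the two diagonal
    directions exactly (full-frame mask, no boundary loss)."""
    levels = rng.integers(0, 8, size=(16, 16))
    roi = make_roi(levels, ng=8)
    rot = make_roi(np.rot90(levels).copy(), ng=8)

    for d in (1, 2):
        f_h = glcm_features(glcm(roi, (0, d)))
        f_v = glcm_features(glcm(rot, (d, 0)))
        assert f_h == pytest.approx(f_v)
        f_d1 = glcm_features(glcm(roi, (d, d)))
        f_d2 = glcm_features(glcm(rot, (d, -d)))
        assert f_d1 == pytest.approx(f_d2)

    assert glrlm_features(roi, 0) == pytest.approx(glrlm_features(rot, 90))
    assert glrlm_features(roi, 90) == pytest.approx(glrlm_features(rot, 0))
    assert glrlm_features(roi, 45) == pytest.approx(glrlm_features(rot, 135))
    assert glrlm_features(roi, 135) == pytest.approx(glrlm_features(rot, 45))


def test_canonical_name_mapping():
    assert canonical_name("X.S.0.1.Contrast") == "S(0,1)Contrast"
    assert canonical_name("X.S.2.2.AngScMom") == "S(2,2)AngScMom"
    assert canonical_name("X135dr_GLevNonU") == "135dr_GLevNonU"
    assert canonical_name("ZWavEnLL_s6") == "WavEnLL_s6"
    assert canonical_name("WavEnHL_s.3") == "WavEnHL_s3"
    assert canonical_name("Perc.01.") == "Perc.01."
    assert canonical_name("Teta2") == "Teta2"


def test_affine_invariance_end_to_end():
    """All 278 features are identical for I and a*I + b under mu-3-sigma
    quantisation (exact, by the scale-free binning)."""
    rng = np.random.default_rng(11)
    raw = rng.integers(0, 256, size=(32, 32)).astype(np.float64)
    mask = ROIMask(np.ones((32, 32), bool), role="tumor")
    q1 = normalize_quantize(GrayImage(raw, 0.1), mask)
    q2 = normalize_quantize(GrayImage(2.0 * raw + 16.0, 0.1), mask)
    assert np.array_equal(q1.levels, q2.levels)
    f1, f2 = extract_features(q1), extract_features(q2)
    assert f1 == f2
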