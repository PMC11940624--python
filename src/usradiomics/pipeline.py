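"""End-to-end convenience pipeline: cohort images -> feature tables ->
selection cascade -> Rad-Score -> classifier report.

This glues the modules together the way the full analysis runs: texture
features are extracted for both ROI scopes of every lesion, the selection
cascade is fitted (full-cohort scope by default), per-lesion Rad-Scores
are computed, and a classifier is trained on {Rad-Score, Ki67-high} with
a stratified 75/25 split and evaluated on the held-out quarter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import NormConfig, build_peritumoral
from .radscore import (
    ClassifierCfg,
    ClassifierKind,
    ClassifierReport,
    RadiomicsSignature,
    split_cohort,
    train_and_evaluate,
)
from .selection import CascadeConfig
from .synthetic import SyntheticCohort
from .texture import extract_all

__all__ = ["extract_cohort_features", "evaluate_cohort", "PipelineResult"]


def extract_cohort_features(
    cohort: SyntheticCohort,
    margin_mm: float = 7.5,
    norm: NormConfig | None = None,
    max_wavelet_scale: int = 6,
) -> dict[str, pd.DataFrame]:
    """Feature tables for both ROI scopes, rows aligned with cohort.meta."""
    rows_t, rows_p = [], []
    for img, tm, em in zip(cohort.images, cohort.tumor_masks, cohort.exclusion_masks):
        peri = build_peritumoral(tm, img.pixel_spacing_mm, margin_mm, exclusion=em)
        feats = extract_all(img, tm, peri, cfg=norm, max_wavelet_scale=max_wavelet_scale)
        rows_t.append(feats["tumor"])
        rows_p.append(feats["tumor_plus_peritumoral"])
    index = cohort.meta["id"]
    return {
        "tumor": pd.DataFrame(rows_t, index=index),
        "tumor_plus_peritumoral": pd.DataFrame(rows_p, index=index),
    }


@dataclass
class PipelineResult:
    report: ClassifierReport
    rad_scores: np.ndarray
    signature: RadiomicsSignature
    split: tuple[np.ndarray, np.ndarray]


def evaluate_cohort(
    features: pd.DataFrame,
    labels,
    ki67_high,
    classifier: ClassifierKind = "knn",
    seed: int = 0,
    cascade: CascadeConfig | None = None,
    clf_cfg: ClassifierCfg | None = None,
    scope: str = "radscore1",
    importance_permutations: int = 0,
) -> PipelineResult:
    """Cascade + Rad-Score + one classifier on {Rad-Score, Ki67-high}."""
    labels = np.asarray(labels)
    cascade = cascade or CascadeConfig(seed=seed)
    sig = RadiomicsSignature(cascade=cascade, scope=scope).fit(features, labels)
    scores = sig.decision_function(features)
    predictors = pd.DataFrame(
        {"rad_score": scores, "ki67_high": np.asarray(ki67_high, dtype=float)}
    )
    split = split_cohort(labels, ratio=0.75, seed=seed)
    report = train_and_evaluate(
        classifier, predictors, labels, split, cfg=clf_cfg, seed=seed,
        importance_permutations=importance_permutations or 1,
    )
    if not importance_permutations:
        report.importances = {}
    return PipelineResult(report=report, rad_scores=scores, signature=sig, split=split)
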