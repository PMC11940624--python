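"""Cohort-level group comparisons and machine batch-effect checks.

Categorical clinical variables (histology, grade, Ki67 category, receptor
status) are compared between pathogenic-variant-positive and -negative
groups with Pearson's chi-squared test *without* continuity correction —
the convention that reproduces the published group-comparison p-values
from their printed counts (a Yates-corrected test does not).  Age is
compared by medians plus a two-sided Mann-Whitney test.  Per-feature Welch
t-tests screen for acquisition-machine batch effects; the cohort is
flagged batch-effect-free when every feature's p exceeds 0.050.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selection import mann_whitney

__all__ = [
    "ContingencyTable",
    "CATEGORICAL_VOCABULARY",
    "pearson_chi2",
    "compare_ages",
    "batch_effect_test",
    "table2_report",
]

# Closed category vocabularies, in reporting order.
CATEGORICAL_VOCABULARY: dict[str, list[str]] = {
    "histology": ["IDC-NST", "ILC", "DCIS", "Other"],
    "grade": ["0", "1", "2", "3"],
    "ki67": ["<20", ">20"],
    "ER": ["+", "-"],
    "PR": ["+", "-"],
    "HER2": ["+", "-"],
}


@dataclass
class ContingencyTable:
    """Labeled r x c counts (variable category x group)."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (chi2, df, p).  A zero row or column marginal is an error.
    """
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total; drop empty rows/columns first")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def compare_ages(a, b) -> tuple[float, float, float]:
    """Group medians and two-sided Mann-Whitney p for age."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    _, p = mann_whitney(a, b)
    return float(np.median(a)), float(np.median(b)), p


def batch_effect_test(tab: pd.DataFrame, machines) -> pd.DataFrame:
    """Per-feature Welch t-test between the two acquisition machines.

    Returns a DataFrame (feature, t, p) with NaN markers for features that
    are constant within both machines; the attribute
    ``df.attrs['no_batch_effect']`` is True iff every defined p > 0.050.
    """
    machines = np.asarray(machines)
    groups = np.unique(machines)
    if groups.size != 2:
        raise ValueError("exactly two machines required")
    a = tab.loc[machines == groups[0]]
    b = tab.loc[machines == groups[1]]
    ts, ps = [], []
    for col in tab.columns:
        x, y = a[col].to_numpy(np.float64), b[col].to_numpy(np.float64)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            ts.append(np.nan)
            ps.append(np.nan)
            continue
        with np.errstate(all="ignore"):
            t, p = stats.ttest_ind(x, y, equal_var=False)
        ts.append(float(t))
        ps.append(float(p))
    out = pd.DataFrame({"feature": tab.columns, "t": ts, "p": ps})
    defined = out["p"].dropna()
    out.attrs["no_batch_effect"] = bool((defined > 0.050).all()) if len(defined) else True
    return out


def table2_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison table: age medians + MW p, categorical counts +
    Pearson chi-squared p (3-decimal formatting in ``p_fmt``).

    ``cohort`` needs columns ``group`` (``pathogenic``/``non-pathogenic``),
    ``age`` and any of the closed-vocabulary categorical columns.  Empty
    category levels are retained with zero counts but excluded from the
    test (a zero marginal is untestable).
    """
    groups = cohort["group"].unique()
    if set(groups) != {"pathogenic", "non-pathogenic"} and len(groups) < 2:
        raise ValueError("both groups must be present")
    gpos = cohort[cohort["group"] == "pathogenic"]
    gneg = cohort[cohort["group"] == "non-pathogenic"]
    if len(gpos) == 0 or len(gneg) == 0:
        raise ValueError("both groups must be present")

    rows: list[dict] = []
    if "age" in cohort.columns:
        med_p, med_n, p = compare_ages(gpos["age"], gneg["age"])
        rows.append(
            {"variable": "age", "category": "(median)", "pathogenic": med_p,
             "non_pathogenic": med_n, "p": p, "p_fmt": f"{p:.3f}"}
        )

    for var, vocab in CATEGORICAL_VOCABULARY.items():
        if var not in cohort.columns:
            continue
        counts = np.array(
            [
                [int((gpos[var].astype(str) == lvl).sum()),
                 int((gneg[var].astype(str) == lvl).sum())]
                for lvl in vocab
            ]
        )
        nonzero = counts.sum(axis=1) > 0
        testable = counts[nonzero]
        if testable.shape[0] >= 2:
            _, _, p = pearson_chi2(testable)
        else:
            p = np.nan
        for lvl, (cp, cn) in zip(vocab, counts):
            rows.append(
                {"variable": var, "category": lvl, "pathogenic": cp,
                 "non_pathogenic": cn, "p": p,
                 "p_fmt": f"{p:.3f}" if np.isfinite(p) else ""}
            )
    return pd.DataFrame(rows)
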