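"""Three-step radiomic feature-selection cascade.

Step 1 — univariate screen: two-sided Mann-Whitney U per feature with
Benjamini-Hochberg false-discovery-rate adjustment; keep adjusted p < alpha
(default 0.050).

Step 2 — redundancy pruning: while any retained pair has |Spearman rho|
above the threshold (default 0.9), take the pair with the largest |rho|
and drop its member with the larger mean absolute correlation against all
currently retained features (ties resolved by registry order, keeping the
earlier feature).

Step 3 — LASSO-penalised logistic regression: features are standardized,
a log-spaced lambda grid is anchored at lambda_max (the smallest penalty
with an all-zero solution), mean binomial deviance is estimated by
stratified k-fold cross-validation, and the minimising lambda (or the
1-SE alternative) defines the surviving non-zero coefficients.

Following the source analysis convention, the cascade runs on the full
cohort by default; a leakage-free variant restricted to training indices
is available via ``CascadeConfig.selection_scope``.

Each step is an sklearn-compatible selector (``fit``/``transform``/
``get_support``); :func:`run_cascade` chains them and returns an audit
trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "MannWhitneyFilter",
    "SpearmanPruner",
    "LassoLogisticSelector",
    "CascadeConfig",
    "SelectionResult",
    "univariate_filter",
    "correlation_prune",
    "lasso_logistic_cv",
    "run_cascade",
]

_ENUM_LIMIT = 20_000  # max #assignments for full permutation enumeration


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    U uses midranks.  Small samples (when the number of group assignments
    C(n+m, min(n,m)) is at most 20,000) are handled by full enumeration of
    the permutation distribution, which is exact under ties; tie-free
    samples with min(n, m) <= 8 use the exact distribution; everything
    else uses the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if np.ptp(pooled) == 0:  # everything tied across both groups
        return u_obs, 1.0

    small = min(n, m)
    if comb(n + m, small) <= _ENUM_LIMIT:
        # enumerate assignments of the pooled midranks to the smaller group
        total = n + m
        centre = n * m / 2.0
        dev_obs = abs(u_obs - centre)
        count = 0
        n_assign = 0
        offs = small * (small + 1) / 2.0
        for idx in combinations(range(total), small):
            u = ranks[list(idx)].sum() - offs
            if small != n:  # enumerate over b's positions -> convert to a's U
                u = n * m - u
            if abs(u - centre) >= dev_obs - 1e-12:
                count += 1
            n_assign += 1
        return u_obs, count / n_assign

    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (small <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return u_obs, float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    idempotent, bounded by 1)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Step 1


class MannWhitneyFilter(SelectorMixin, BaseEstimator):
    """Keep features whose BH-adjusted two-sided Mann-Whitney p < alpha.

    Features containing NaN ("undefined" markers from extraction) are
    dropped with an explicit reason rather than tested.

    Attributes (after fit): ``u_statistic_``, ``pvalues_``,
    ``adjusted_pvalues_``, ``support_``, ``drop_reason_``.
    """

    def __init__(self, alpha: float = 0.050):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("binary labels required")
        if min((y == c).sum() for c in classes) < 2:
            raise ValueError("need at least 2 samples per class")
        n_feat = X.shape[1]
        u = np.full(n_feat, np.nan)
        p = np.full(n_feat, np.nan)
        defined = ~np.isnan(X).any(axis=0)
        a_idx, b_idx = y == classes[1], y == classes[0]
        for j in np.flatnonzero(defined):
            u[j], p[j] = mann_whitney(X[a_idx, j], X[b_idx, j])
        adj = np.full(n_feat, np.nan)
        if defined.any():
            adj[defined] = bh_adjust(p[defined])
        support = defined & (adj < self.alpha)
        reasons = np.where(
            ~defined, "undefined", np.where(support, "", "adjusted_p>=alpha")
        )
        self.u_statistic_ = u
        self.pvalues_ = p
        self.adjusted_pvalues_ = adj
        self.support_ = support
        self.drop_reason_ = reasons
        self.n_features_in_ = n_feat
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Step 2


class SpearmanPruner(SelectorMixin, BaseEstimator):
    """Greedy Spearman-redundancy pruning to max pairwise |rho| <= threshold.

    Constant features (undefined rho) are dropped first.  The surviving
    set always satisfies the pairwise bound, which ``mean_abs_corr_`` and
    ``drop_reason_`` make auditable.
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, n_feat = X.shape
        if n < 3:
            raise ValueError("need at least 3 samples for rank correlations")
        support = np.ones(n_feat, dtype=bool)
        reasons = np.array([""] * n_feat, dtype=object)

        constant = np.array([np.ptp(X[:, j]) == 0 or np.isnan(X[:, j]).any()
                             for j in range(n_feat)])
        support[constant] = False
        reasons[constant] = "constant_or_undefined"

        idx = np.flatnonzero(support)
        mean_abs = np.full(n_feat, np.nan)
        if idx.size >= 2:
            rho = self._spearman(X[:, idx])
            np.fill_diagonal(rho, 0.0)
            local = np.arange(idx.size)
            alive = np.ones(idx.size, dtype=bool)
            while True:
                sub = np.abs(rho[np.ix_(alive, alive)])
                if sub.size == 0 or sub.max() <= self.threshold:
                    break
                ai = local[alive]
                r, c = np.unravel_index(np.argmax(sub), sub.shape)
                fi, fj = ai[r], ai[c]
                mi = np.abs(rho[fi, ai]).mean()
                mj = np.abs(rho[fj, ai]).mean()
                # drop the larger mean-|rho| member; tie -> keep earlier feature
                drop = fj if (mj > mi or np.isclose(mi, mj)) else fi
                alive[drop] = False
                support[idx[drop]] = False
                reasons[idx[drop]] = "high_correlation"
            for li in local:
                mean_abs[idx[li]] = np.abs(rho[li, local[alive]]).mean() if alive.any() else 0.0

        self.support_ = support
        self.drop_reason_ = reasons
        self.mean_abs_corr_ = mean_abs
        self.n_features_in_ = n_feat
        return self

    @staticmethod
    def _spearman(X: np.ndarray) -> np.ndarray:
        if X.shape[1] == 1:
            return np.ones((1, 1))
        rho = stats.spearmanr(X).statistic
        return np.atleast_2d(rho)

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Step 3


class LassoLogisticSelector(SelectorMixin, BaseEstimator):
    """L1-penalised logistic regression with cross-validated penalty.

    Features are standardized (zero mean, unit variance, global statistics).
    The lambda grid is log-spaced from lambda_max = max|X'(y-ybar)|/n down
    to ``lambda_min_ratio * lambda_max``; per-lambda mean binomial deviance
    over stratified k folds picks lambda (``rule='min'`` or ``'1se'``).
    Coefficients are reported on the standardized scale; survivors are the
    non-zero entries.

    Attributes: ``lambda_``, ``lambda_max_``, ``coef_``, ``intercept_``,
    ``deviance_path_`` (DataFrame: lambda, mean_deviance, se_deviance,
    n_nonzero), ``support_``.
    """

    def __init__(
        self,
        k: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        rule: Literal["min", "1se"] = "min",
        random_state: int = 0,
    ):
        self.k = k
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule
        self.random_state = random_state

    @staticmethod
    def _fit_at(Xs, y, lam):
        n = Xs.shape[0]
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", tol=1e-8,
            max_iter=2000, random_state=0,
        )
        clf.fit(Xs, y)
        return clf

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("binary labels required")
        yb = (y == classes[1]).astype(np.float64)
        n, n_feat = X.shape
        if n < self.k:
            raise ValueError("fewer samples than folds")
        if min(int(yb.sum()), int(n - yb.sum())) < self.k / 2:
            raise ValueError("a class is too small for stratified folds")

        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd_safe

        lam_max = float(np.abs(Xs.T @ (yb - yb.mean())).max() / n)
        if lam_max <= 0:
            lam_max = 1e-4
        grid = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

        skf = StratifiedKFold(n_splits=self.k, shuffle=True,
                              random_state=self.random_state)
        folds = list(skf.split(Xs, yb))
        dev = np.zeros((self.n_lambdas, self.k))
        nnz_path = np.zeros(self.n_lambdas, dtype=int)
        eps = 1e-12
        for li, lam in enumerate(grid):
            for fi, (tr, va) in enumerate(folds):
                clf = self._fit_at(Xs[tr], yb[tr], lam)
                pr = np.clip(clf.predict_proba(Xs[va])[:, 1], eps, 1 - eps)
                dev[li, fi] = -2.0 * np.mean(
                    yb[va] * np.log(pr) + (1 - yb[va]) * np.log(1 - pr)
                )
        mean_dev = dev.mean(axis=1)
        se_dev = dev.std(axis=1, ddof=1) / np.sqrt(self.k)

        best = int(np.argmin(mean_dev))
        if self.rule == "1se":
            bound = mean_dev[best] + se_dev[best]
            ok = np.flatnonzero(mean_dev <= bound)
            best = int(ok[0])  # largest lambda within 1 SE (grid is decreasing)
        lam_star = float(grid[best])

        final = self._fit_at(Xs, yb, lam_star)
        coef = final.coef_.ravel().copy()
        coef[np.abs(coef) <= 1e-8] = 0.0
        for li, lam in enumerate(grid):
            c = self._fit_at(Xs, yb, lam).coef_.ravel()
            nnz_path[li] = int((np.abs(c) > 1e-8).sum())

        self.lambda_ = lam_star
        self.lambda_max_ = lam_max
        self.coef_ = coef
        self.intercept_ = float(final.intercept_[0])
        self.feature_means_ = mu
        self.feature_sds_ = sd_safe
        self.deviance_path_ = pd.DataFrame(
            {"lambda": grid, "mean_deviance": mean_dev, "se_deviance": se_dev,
             "n_nonzero": nnz_path}
        )
        self.support_ = coef != 0.0
        self.n_features_in_ = n_feat
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class CascadeConfig:
    alpha: float = 0.050
    corr_threshold: float = 0.9
    cv_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_rule: Literal["min", "1se"] = "min"
    selection_scope: Literal["full_cohort", "train_only"] = "full_cohort"
    seed: int = 0


@dataclass
class SelectionResult:
    """Audit trail of the three-step cascade.

    ``audit`` has one row per input feature: U, raw and adjusted p, step-1
    decision and reason, step-2 mean absolute correlation and reason,
    step-3 coefficient.  ``survivors_per_step`` records the cascade
    counts; ``final_features`` maps surviving names to standardized-scale
    LASSO coefficients.
    """

    audit: pd.DataFrame
    survivors_per_step: tuple[int, int, int]
    final_features: dict[str, float]
    lambda_: float | None = None
    lambda_max_: float | None = None
    deviance_path: pd.DataFrame | None = None
    halted_after: int | None = None
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)


def univariate_filter(
    tab: pd.DataFrame, labels, alpha: float = 0.050
) -> tuple[pd.DataFrame, MannWhitneyFilter]:
    """Step 1 on a named feature table; returns (kept table, fitted filter)."""
    f = MannWhitneyFilter(alpha=alpha).fit(tab.to_numpy(), np.asarray(labels))
    return tab.loc[:, f.support_], f


def correlation_prune(
    tab: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, SpearmanPruner]:
    """Step 2 on a named feature table; returns (kept table, fitted pruner)."""
    p = SpearmanPruner(threshold=threshold).fit(tab.to_numpy())
    return tab.loc[:, p.support_], p


def lasso_logistic_cv(
    tab: pd.DataFrame, labels, k: int = 10, seed: int = 0, **kw
) -> tuple[pd.DataFrame, LassoLogisticSelector]:
    """Step 3 on a named feature table; returns (kept table, fitted selector)."""
    sel = LassoLogisticSelector(k=k, random_state=seed, **kw).fit(
        tab.to_numpy(), np.asarray(labels)
    )
    return tab.loc[:, sel.support_], sel


def run_cascade(
    tab: pd.DataFrame, labels, cfg: CascadeConfig | None = None
) -> SelectionResult:
    """Apply the three selection steps in order and collect the audit trail.

    An empty intermediate survivor set halts the cascade with an
    informative (empty) result rather than raising.
    """
    cfg = cfg or CascadeConfig()
    labels = np.asarray(labels)
    names = list(tab.columns)
    audit = pd.DataFrame(index=names)

    if cfg.selection_scope == "train_only":
        raise ValueError(
            "train_only scope needs explicit train indices; call the steps "
            "directly on the training subset"
        )

    t1, f1 = univariate_filter(tab, labels, alpha=cfg.alpha)
    audit["U"] = f1.u_statistic_
    audit["p_raw"] = f1.pvalues_
    audit["p_adjusted"] = f1.adjusted_pvalues_
    audit["kept_step1"] = f1.support_
    audit["reason_step1"] = f1.drop_reason_
    n1 = t1.shape[1]
    audit["kept_step2"] = False
    audit["mean_abs_corr"] = np.nan
    audit["reason_step2"] = ""
    audit["beta"] = 0.0
    audit["kept_step3"] = False
    if n1 == 0:
        return SelectionResult(audit, (0, 0, 0), {}, halted_after=1)

    t2, f2 = correlation_prune(t1, threshold=cfg.corr_threshold)
    audit.loc[t1.columns, "kept_step2"] = f2.support_
    audit.loc[t1.columns, "mean_abs_corr"] = f2.mean_abs_corr_
    audit.loc[t1.columns, "reason_step2"] = f2.drop_reason_
    n2 = t2.shape[1]
    if n2 == 0:
        return SelectionResult(audit, (n1, 0, 0), {}, halted_after=2)

    _, f3 = lasso_logistic_cv(
        t2,
        labels,
        k=cfg.cv_folds,
        seed=cfg.seed,
        n_lambdas=cfg.n_lambdas,
        lambda_min_ratio=cfg.lambda_min_ratio,
        rule=cfg.lambda_rule,
    )
    audit.loc[t2.columns, "beta"] = f3.coef_
    audit.loc[t2.columns, "kept_step3"] = f3.support_
    final = {
        nm: float(c) for nm, c in zip(t2.columns, f3.coef_) if c != 0.0
    }
    means = dict(zip(t2.columns, f3.feature_means_))
    sds = dict(zip(t2.columns, f3.feature_sds_))
    return SelectionResult(
        audit,
        (n1, n2, len(final)),
        final,
        lambda_=f3.lambda_,
        lambda_max_=f3.lambda_max_,
        deviance_path=f3.deviance_path_,
        feature_means=means,
        feature_sds=sds,
    )
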