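"""Selection cascade: Mann-Whitney, BH, Spearman pruning, LASSO CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usradiomics.selection import (
    CascadeConfig,
    LassoLogisticSelector,
    MannWhitneyFilter,
    SpearmanPruner,
    bh_adjust,
    correlation_prune,
    lasso_logistic_cv,
    mann_whitney,
    run_cascade,
    univariate_filter,
)
from usradiomics.synthetic import FeatTabConfig, simulate_feature_table

from oracles import brute_mw_enumeration


# ------------------------------------------------------------- Mann-Whitney


def test_mw_identical_tied_triples():
    u, p = mann_whitney([1, 2, 3], [1, 2, 3])
    assert u == 4.5
    assert p == 1.0


def test_mw_complete_separation_exact():
    u, p = mann_whitney([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3)


def test_mw_single_equal_observations():
    assert mann_whitney([5.0], [5.0])[1] == 1.0


def test_mw_all_tied_across_groups():
    assert mann_whitney([2, 2, 2, 2], [2, 2])[1] == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_mw_small_samples_match_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 6, size=int(rng.integers(2, 7))).astype(float)
    b = rng.integers(0, 6, size=int(rng.integers(2, 7))).astype(float)
    u, p = mann_whitney(a, b)
    u_ref, p_ref = brute_mw_enumeration(a, b)
    assert u == pytest.approx(u_ref)
    assert p == pytest.approx(p_ref)


def test_mw_large_samples_use_corrected_normal_approximation(rng):
    from scipy import stats

    a = rng.normal(size=60)
    b = rng.normal(0.5, size=55)
    u, p = mann_whitney(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    assert u == ref.statistic
    assert p == pytest.approx(ref.pvalue)


# --------------------------------------------------------------------- BH


def test_bh_single_p_unchanged():
    assert bh_adjust([0.037])[0] == pytest.approx(0.037)


def test_bh_stepup_hand_example():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_inflation_monotone_bounded(ps):
    adj = bh_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
    # order-preserving on the sorted sequence
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_matches_stepup_formula(rng):
    """Adjusted p equals min over j >= i of min(1, m*p_(j)/j)."""
    p = rng.random(17)
    order = np.argsort(p)
    m = p.size
    ref_sorted = np.minimum.accumulate(
        np.minimum(1.0, m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    ref = np.empty(m)
    ref[order] = ref_sorted
    assert np.allclose(bh_adjust(p), ref)


# ------------------------------------------------------------------ step 1


def test_univariate_filter_alpha_zero_empty():
    tab, y = simulate_feature_table(FeatTabConfig(n_per_class=10, n_features=20, seed=1))
    kept, _ = univariate_filter(tab, y, alpha=0.0)
    assert kept.shape[1] == 0


def test_univariate_filter_drops_undefined_with_reason():
    tab, y = simulate_feature_table(FeatTabConfig(n_per_class=10, n_features=5, seed=2))
    tab.iloc[3, 0] = np.nan
    _, f = univariate_filter(tab, y)
    assert f.drop_reason_[0] == "undefined"
    assert not f.support_[0]


def test_univariate_filter_planted_feature_power():
    hits = 0
    for seed in range(20):
        cfg = FeatTabConfig(n_per_class=44, n_features=50, planted_feature_count=1,
                            effect_size=2.0, seed=seed)
        tab, y = simulate_feature_table(cfg)
        kept, _ = univariate_filter(tab, y)
        hits += "f000" in kept.columns
    assert hits >= 19


# ------------------------------------------------------------------ step 2


def test_prune_duplicate_column_keeps_one():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    tab = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
    kept, p = correlation_prune(tab)
    assert kept.shape[1] == 2
    assert "c" in kept.columns
    assert sum(n in kept.columns for n in ("a", "b")) == 1


def test_prune_greedy_rule_hand_trace():
    """A == B (rho 1); C weakly correlated: one of A/B is dropped, C kept."""
    rng = np.random.default_rng(4)
    a = rng.normal(size=50)
    c = rng.normal(size=50)
    tab = pd.DataFrame({"A": a, "B": a.copy(), "C": c})
    kept, _ = correlation_prune(tab, threshold=0.9)
    assert "C" in kept.columns
    assert kept.shape[1] == 2


def test_prune_constant_feature_dropped_first():
    rng = np.random.default_rng(5)
    tab = pd.DataFrame({"const": np.ones(20), "x": rng.normal(size=20)})
    kept, p = correlation_prune(tab)
    assert list(kept.columns) == ["x"]
    assert p.drop_reason_[0] == "constant_or_undefined"


@pytest.mark.parametrize("seed", range(5))
def test_prune_postcondition_max_abs_rho(seed):
    from scipy import stats

    rng = np.random.default_rng(seed)
    base = rng.normal(size=(40, 4))
    X = np.hstack([base + 0.1 * rng.normal(size=(40, 4)) for _ in range(4)])
    tab = pd.DataFrame(X, columns=[f"v{i}" for i in range(16)])
    kept, _ = correlation_prune(tab, threshold=0.9)
    if kept.shape[1] >= 2:
        rho = np.atleast_2d(stats.spearmanr(kept.to_numpy()).statistic)
        np.fill_diagonal(rho, 0.0)
        assert np.nanmax(np.abs(rho)) <= 0.9


# ------------------------------------------------------------------ step 3


@pytest.fixture(scope="module")
def planted_table():
    cfg = FeatTabConfig(n_per_class=50, n_features=20, planted_feature_count=1,
                        effect_size=3.0, seed=10)
    return simulate_feature_table(cfg)


def test_lasso_all_zero_at_lambda_max(planted_table):
    tab, y = planted_table
    sel = LassoLogisticSelector(random_state=0).fit(tab.to_numpy(), y)
    coef_at_max = sel._fit_at(
        (tab.to_numpy() - sel.feature_means_) / sel.feature_sds_, (y == 1).astype(float),
        sel.lambda_max_,
    ).coef_.ravel()
    assert np.all(np.abs(coef_at_max) <= 1e-6)


def test_lasso_path_support_grows_as_lambda_shrinks(planted_table):
    tab, y = planted_table
    sel = LassoLogisticSelector(random_state=0).fit(tab.to_numpy(), y)
    nnz = sel.deviance_path_["n_nonzero"].to_numpy()
    assert nnz[0] == 0
    assert nnz[-1] >= nnz[0]
    # overall trend: cumulative max equals the path except small wiggles
    assert nnz[-1] == nnz.max() or nnz.max() - nnz[-1] <= 2


def test_lasso_recovers_planted_feature_sign():
    ok = 0
    for seed in range(10):
        cfg = FeatTabConfig(n_per_class=50, n_features=100, planted_feature_count=1,
                            effect_size=3.0, seed=seed)
        tab, y = simulate_feature_table(cfg)
        kept, sel = lasso_logistic_cv(tab, y, seed=seed)
        if "f000" in kept.columns:
            beta = sel.coef_[list(tab.columns).index("f000")]
            ok += beta > 0
    assert ok >= 9


def test_lasso_deterministic_under_seed(planted_table):
    tab, y = planted_table
    s1 = LassoLogisticSelector(random_state=42).fit(tab.to_numpy(), y)
    s2 = LassoLogisticSelector(random_state=42).fit(tab.to_numpy(), y)
    assert s1.lambda_ == s2.lambda_
    assert np.array_equal(s1.coef_, s2.coef_)


def test_lasso_rejects_tiny_class():
    X = np.random.default_rng(0).normal(size=(20, 3))
    y = np.array([1] * 3 + [0] * 17)
    with pytest.raises(ValueError, match="class"):
        LassoLogisticSelector(k=10).fit(X, y)


# ----------------------------------------------------------------- cascade


def test_cascade_halts_on_alpha_zero():
    tab, y = simulate_feature_table(FeatTabConfig(n_per_class=10, n_features=10, seed=0))
    res = run_cascade(tab, y, CascadeConfig(alpha=0.0))
    assert res.halted_after == 1
    assert res.survivors_per_step == (0, 0, 0)
    assert res.final_features == {}


def test_cascade_nesting_invariant():
    cfg = FeatTabConfig(n_per_class=44, n_features=60, planted_feature_count=5,
                        effect_size=1.5, correlated_blocks=(3, 3, 3),
                        block_spearman=1.0, seed=6)
    tab, y = simulate_feature_table(cfg)
    res = run_cascade(tab, y, CascadeConfig(seed=6))
    a = res.audit
    assert set(a.index[a["kept_step3"]]) <= set(a.index[a["kept_step2"]])
    assert set(a.index[a["kept_step2"]]) <= set(a.index[a["kept_step1"]])
    assert (a.loc[a["kept_step1"], "p_adjusted"] < 0.050).all()
    n1, n2, n3 = res.survivors_per_step
    assert n1 >= n2 >= n3


def test_cascade_fixture_trace_duplicate_blocks():
    """Duplicate blocks (rho = 1) collapse to one member each at step 2."""
    cfg = FeatTabConfig(n_per_class=44, n_features=40, planted_feature_count=0,
                        effect_size=0.0, correlated_blocks=(4, 4),
                        block_spearman=1.0, seed=7)
    tab, y = simulate_feature_table(cfg)
    kept, _ = correlation_prune(tab)
    for b in (0, 1):
        members = [c for c in kept.columns if c.startswith(f"blk{b}_")]
        assert len(members) == 1
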