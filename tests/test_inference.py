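"""Estimation machinery: imputation, robust fits, pooling, power."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dormantlink.inference import (
    ImputationConfig,
    SeparationError,
    fit_mean_difference,
    fit_odds_ratio,
    impute_chained,
    mdes,
    pool_rubin,
    power_table,
    run_sensitivity_matrix,
)


def toy_frame(n=200, seed=0, p_event=(0.2, 0.3)):
    rng = np.random.default_rng(seed)
    half = n // 2
    df = pd.DataFrame(
        {
            "arm_modified": [1] * half + [0] * (n - half),
            "sex": rng.integers(0, 2, n),
            "birth_weight": rng.normal(3400, 400, n),
            "gestational_age": rng.normal(39.5, 1.2, n),
            "maternal_smoking": rng.integers(0, 2, n).astype(float),
            "maternal_degree": rng.integers(0, 2, n).astype(float),
            "centre": rng.choice(["NT", "L"], n),
            "death": 0,
        }
    )
    df["y"] = rng.normal(size=n)
    df["event"] = np.where(
        df["arm_modified"] == 1,
        rng.random(n) < p_event[0],
        rng.random(n) < p_event[1],
    ).astype(float)
    return df


# -- Rubin pooling -----------------------------------------------------------

def test_rubin_hand_oracle():
    pooled, T, W, B = pool_rubin([0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
    assert pooled == pytest.approx(0.2)
    assert B == pytest.approx(0.01)
    assert T == pytest.approx(0.01 + (4 / 3) * 0.01)
    assert np.sqrt(T) == pytest.approx(0.1528, abs=2e-4)


def test_rubin_degenerate_cases():
    pooled, T, W, B = pool_rubin([0.4], [0.09])
    assert (pooled, T, W, B) == (0.4, 0.09, 0.09, 0.0)
    pooled, T, W, B = pool_rubin([0.2, 0.2, 0.2], [0.04, 0.04, 0.04])
    assert B == 0.0 and T == W
    with pytest.raises(ValueError):
        pool_rubin([], [])


def test_rubin_total_never_below_within():
    rng = np.random.default_rng(4)
    for _ in range(20):
        q = rng.normal(size=7)
        v = rng.uniform(0.01, 0.1, 7)
        _, T, W, _ = pool_rubin(q, v)
        assert T >= W


# -- sandwich variance -------------------------------------------------------

def test_sandwich_matches_explicit_formula():
    """HC1 variance equals (X'X)^-1 X'diag(e^2)X (X'X)^-1 * n/(n-k)."""
    df = toy_frame(n=120, seed=5)
    est, var, n = fit_mean_difference(df, "y", adjusted=False)
    X = np.column_stack([np.ones(n), df["arm_modified"].to_numpy(float)])
    y = df["y"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    e = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e**2)[:, None])
    V = bread @ meat @ bread * n / (n - X.shape[1])
    assert est == pytest.approx(beta[1])
    assert var == pytest.approx(V[1, 1], rel=1e-10)


def test_sandwich_close_to_classical_when_homoscedastic():
    """Under homoscedastic errors the robust/classical SE ratio is ~1."""
    import statsmodels.api as sm

    rng = np.random.default_rng(6)
    ratios = []
    for _ in range(50):
        n = 300
        X = sm.add_constant(rng.normal(size=(n, 3)))
        y = X @ np.array([0.5, 0.2, -0.1, 0.3]) + rng.normal(size=n)
        robust = sm.OLS(y, X).fit(cov_type="HC1").bse[1]
        classical = sm.OLS(y, X).fit().bse[1]
        ratios.append(robust / classical)
    assert 0.9 < np.mean(ratios) < 1.1


def test_unadjusted_estimate_is_difference_in_means():
    df = toy_frame(n=201, seed=7)
    est, _, _ = fit_mean_difference(df, "y", adjusted=False)
    diff = df.loc[df.arm_modified == 1, "y"].mean() - df.loc[df.arm_modified == 0, "y"].mean()
    assert est == pytest.approx(diff, rel=1e-12)


def test_perfect_fit_has_zero_residual_variance():
    df = toy_frame(n=100, seed=8)
    df["y2"] = df["arm_modified"].astype(float)
    est, var, _ = fit_mean_difference(df, "y2", adjusted=False)
    assert est == pytest.approx(1.0)
    assert var == pytest.approx(0.0, abs=1e-20)


def test_single_centre_design_drops_collinear_dummy():
    df = toy_frame(n=150, seed=9)
    df["centre"] = "C"
    est, var, n = fit_mean_difference(df, "y", adjusted=True)
    assert np.isfinite(est) and var > 0


# -- logistic / odds ratios --------------------------------------------------

def test_odds_ratio_matches_cross_product():
    df = pd.DataFrame(
        {
            "arm_modified": [1] * 100 + [0] * 100,
            "event": [1] * 20 + [0] * 80 + [1] * 30 + [0] * 70,
            "centre": "C", "sex": 0, "birth_weight": 3400.0,
            "gestational_age": 39.0, "maternal_smoking": 0.0, "maternal_degree": 0.0,
        }
    )
    lo, var, n = fit_odds_ratio(df, "event", adjusted=False)
    assert np.exp(lo) == pytest.approx(20 * 70 / (80 * 30), rel=1e-6)
    assert n == 200


def test_odds_ratio_no_events_raises():
    df = toy_frame(n=100, seed=10)
    df["event"] = 0.0
    with pytest.raises(SeparationError):
        fit_odds_ratio(df, "event", adjusted=False)


def test_odds_ratio_separation_raises():
    df = toy_frame(n=80, seed=11)
    df["event"] = df["arm_modified"].astype(float)  # perfectly separated
    with pytest.raises(SeparationError):
        fit_odds_ratio(df, "event", adjusted=False)


def test_null_odds_ratio_ci_coverage():
    """Generative OR=1: the 95% CI covers 1 in ~95% of replicates."""
    rng = np.random.default_rng(12)
    cover = 0
    reps = 200
    for i in range(reps):
        df = toy_frame(n=240, seed=1000 + i, p_event=(0.3, 0.3))
        lo, var, _ = fit_odds_ratio(df, "event", adjusted=False)
        se = np.sqrt(var)
        cover += lo - 1.96 * se <= 0.0 <= lo + 1.96 * se
    assert 0.90 <= cover / reps <= 0.99


# -- chained imputation ------------------------------------------------------

def test_impute_zero_missingness_returns_identical_copies():
    df = toy_frame(n=150, seed=13)
    out = impute_chained(df, ImputationConfig(m=4, seed=1))
    assert len(out) == 4
    for o in out:
        pd.testing.assert_frame_equal(o, df)


def test_impute_rejects_deceased_rows():
    df = toy_frame(n=50, seed=14)
    df.loc[0, "death"] = 1
    with pytest.raises(ValueError, match="deceased"):
        impute_chained(df, ImputationConfig(m=2, seed=1))


def test_impute_completes_missing_and_is_deterministic():
    df = toy_frame(n=200, seed=15)
    df = df.rename(columns={"y": "sd_maths16"})
    miss = np.random.default_rng(16).random(len(df)) < 0.25
    df.loc[miss, "sd_maths16"] = np.nan
    df.loc[:4, "maternal_smoking"] = np.nan
    cfg = ImputationConfig(m=3, seed=42)
    out1 = impute_chained(df, cfg)
    out2 = impute_chained(df, cfg)
    for a, b in zip(out1, out2):
        pd.testing.assert_frame_equal(a, b)
    for o in out1:
        assert o["sd_maths16"].notna().all()
        assert o["maternal_smoking"].notna().all()
        assert set(o.loc[:4, "maternal_smoking"]) <= {0.0, 1.0}
    # observed values never change
    obs = ~miss
    assert (out1[0].loc[obs, "sd_maths16"] == df.loc[obs, "sd_maths16"]).all()


def test_impute_explicit_all_missing_variable_raises():
    df = toy_frame(n=60, seed=17)
    df["sd_maths16"] = np.nan
    with pytest.raises(ValueError, match="100% missing"):
        impute_chained(df, ImputationConfig(m=2, seed=1), variables=("sd_maths16",))


def test_mcar_imputation_unbiased_under_null():
    """20% MCAR-missing outcome: pooled MI estimate is unbiased over 200 reps."""
    ests = []
    for i in range(200):
        rng = np.random.default_rng(3000 + i)
        df = toy_frame(n=200, seed=3000 + i)
        df = df.rename(columns={"y": "sd_maths16"})
        df.loc[rng.random(len(df)) < 0.2, "sd_maths16"] = np.nan
        imp = impute_chained(df, ImputationConfig(m=5, seed=i), variables=("sd_maths16",))
        fits = [fit_mean_difference(d, "sd_maths16", adjusted=False) for d in imp]
        pooled, *_ = pool_rubin([f[0] for f in fits], [f[1] for f in fits])
        ests.append(pooled)
    ests = np.asarray(ests)
    mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean()) < 3 * mc_se


# -- MDES --------------------------------------------------------------------

def test_mdes_closed_form_values():
    assert mdes(149, 150) == pytest.approx(0.32, abs=0.005)
    assert mdes(82, 89) == pytest.approx(0.43, abs=0.005)


def test_mdes_monotone_decreasing_to_zero():
    values = [mdes(n, n) for n in (10, 50, 100, 1000, 100_000)]
    assert all(b < a for a, b in zip(values, values[1:]))
    assert values[-1] < 0.02
    with pytest.raises(ValueError):
        mdes(1, 50)


def test_power_table_covers_all_trials():
    tab = power_table()
    assert len(tab) == 7
    assert tab["mdes"].between(0.2, 0.6).all()


# -- sensitivity matrix ------------------------------------------------------

def test_sensitivity_matrix_zero_missingness_mi_equals_cc():
    df = toy_frame(n=160, seed=18)
    df = df.rename(columns={"y": "sd_maths16", "event": "five_plus_gcse_c"})
    df["trial_id"] = "TOY"
    df["ext_maths16"] = df["sd_maths16"] * 1.7 + 0.2
    cells = run_sensitivity_matrix(
        df, ImputationConfig(m=3, seed=5),
        outcomes=("sd_maths16",), binary_outcomes=("five_plus_gcse_c",),
    )
    cells = cells.set_index(["outcome", "analysis_label"])
    for outcome in ("sd_maths16", "five_plus_gcse_c"):
        mi = cells.loc[(outcome, "MI_adjusted")]
        cc = cells.loc[(outcome, "CC_adjusted")]
        assert abs(mi["estimate"] - cc["estimate"]) < 1e-10
        assert abs(mi["se"] - cc["se"]) < 1e-10
    labels = set(cells.reset_index()["analysis_label"])
    assert {"MI_adjusted", "MI_unadjusted", "CC_adjusted", "CC_unadjusted"} <= labels
    assert (cells.reset_index().query("outcome=='sd_maths16'")["analysis_label"] == "external_standardised").sum() == 1


def test_adjusted_and_unadjusted_agree_on_balanced_data():
    """Randomisation balance: adjustment shifts the estimate only within MC error."""
    df = toy_frame(n=4000, seed=19)
    est_u, _, _ = fit_mean_difference(df, "y", adjusted=False)
    est_a, _, _ = fit_mean_difference(df, "y", adjusted=True)
    assert abs(est_a - est_u) < 0.05
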