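"""Mixed model: REML oracle equivalence, OLS limits, Satterthwaite inference,
random-effect adjustment, and invariance properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from variomics.mixed_model import (
    adjust_for_random_effects,
    contrast_pvalues,
    fit_mixed_model,
    fit_summary,
)


def _sim(rng, genos, truth, n_batches, reps, su, se):
    rows = []
    for b in range(n_batches):
        u = rng.normal(0, su) if su > 0 else 0.0
        for g in genos:
            for r in range(reps):
                rows.append((g, f"b{b}", r, truth[g] + u + rng.normal(0, se)))
    return pd.DataFrame(rows, columns=["genotype", "batch", "replicate", "value"])


def _brute_force_reml(df):
    """Independent dense REML: build V explicitly, grid + refine over the
    variance ratio, never touching the package's sufficient-statistic path."""
    genos = sorted(df["genotype"].unique())
    batches = sorted(df["batch"].unique())
    y = df["value"].to_numpy(float)
    X = np.column_stack([(df["genotype"] == g).to_numpy(float) for g in genos])
    Z = np.column_stack([(df["batch"] == b).to_numpy(float) for b in batches])
    n, p = X.shape
    ZZt = Z @ Z.T

    def neg2loglik(lam):
        W = np.eye(n) + lam * ZZt
        Wi = np.linalg.inv(W)
        XtWX = X.T @ Wi @ X
        beta = np.linalg.solve(XtWX, X.T @ Wi @ y)
        r = y - X @ beta
        s2e = float(r @ Wi @ r) / (n - p)
        return (
            (n - p) * np.log(s2e)
            + np.linalg.slogdet(W)[1]
            + np.linalg.slogdet(XtWX)[1]
            + (n - p),
            beta,
            s2e,
        )

    lams = np.concatenate(([0.0], np.logspace(-6, 6, 200)))
    devs = [neg2loglik(l)[0] for l in lams]
    k = int(np.argmin(devs))
    lam = lams[k]
    if 0 < k < len(lams) - 1:
        res = optimize.minimize_scalar(
            lambda l: neg2loglik(l)[0],
            bounds=(lams[k - 1], lams[k + 1]),
            method="bounded",
            options={"xatol": 1e-13},
        )
        if res.fun < devs[k]:
            lam = float(res.x)
    _, beta, s2e = neg2loglik(lam)
    return beta, np.sqrt(lam * s2e), np.sqrt(s2e)


def test_single_batch_noise_free_is_exact_ols():
    df = pd.DataFrame(
        {
            "genotype": ["WT"] * 3 + ["EV"] * 3 + ["V"] * 3,
            "batch": ["b0"] * 9,
            "value": [1.0] * 3 + [0.0] * 3 + [0.5] * 3,
        }
    )
    fit = fit_mixed_model(df)
    assert fit.beta_hat["WT"] == 1.0
    assert fit.beta_hat["EV"] == 0.0
    assert fit.beta_hat["V"] == 0.5
    assert fit.sigma_u == 0.0 and fit.sigma_e == 0.0


def test_reml_matches_brute_force_oracle():
    """Balanced two-batch toy sets (<=24 rows): estimates agree with a dense
    grid/refine REML maximization to 1e-6."""
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        truth = {"WT": 1.0, "EV": 0.0, "A": 0.6, "B": 0.2}
        df = _sim(rng, list(truth), truth, n_batches=2, reps=3, su=0.15, se=0.1)
        assert len(df) == 24
        fit = fit_mixed_model(df)
        beta_o, su_o, se_o = _brute_force_reml(df)
        assert np.allclose(fit.beta_hat.to_numpy(), beta_o, atol=1e-6)
        assert fit.sigma_u == pytest.approx(su_o, abs=1e-6)
        assert fit.sigma_e == pytest.approx(se_o, abs=1e-6)


def test_reml_matches_statsmodels_mixedlm():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.5}
    df = _sim(rng, list(truth), truth, n_batches=5, reps=4, su=0.1, se=0.12)
    fit = fit_mixed_model(df)
    md = sm.MixedLM.from_formula(
        "value ~ 0 + C(genotype)", groups="batch", data=df
    ).fit(reml=True)
    assert np.allclose(sorted(fit.beta_hat), sorted(md.fe_params), atol=1e-6)
    assert fit.sigma_u == pytest.approx(np.sqrt(md.cov_re.iloc[0, 0]), abs=1e-4)
    assert fit.sigma_e == pytest.approx(np.sqrt(md.scale), abs=1e-4)


def test_boundary_fit_reduces_to_classical_ols_ttest():
    """When the batch variance hits zero, Satterthwaite p-values equal the
    classical pooled t test from the OLS fit to 1e-10."""
    rng = np.random.default_rng(3)
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.8}
    df = _sim(rng, list(truth), truth, n_batches=3, reps=4, su=0.0, se=0.1)
    # force exactly equal batch means so the variance ratio lands on zero
    df["value"] -= df.groupby("batch")["value"].transform("mean")
    fit = fit_mixed_model(df)
    assert fit.sigma_u == 0.0
    res = contrast_pvalues(fit, "WT")
    n, p = len(df), df["genotype"].nunique()
    means = df.groupby("genotype")["value"].mean()
    counts = df.groupby("genotype").size()
    rss = float(((df["value"] - df["genotype"].map(means)) ** 2).sum())
    s2 = rss / (n - p)
    for _, row in res.iterrows():
        est = means[row["genotype"]] - means["WT"]
        se = np.sqrt(s2 * (1 / counts[row["genotype"]] + 1 / counts["WT"]))
        p_ols = 2 * stats.t.sf(abs(est) / se, n - p)
        assert row["p_value"] == pytest.approx(p_ols, abs=1e-10)
        assert row["df_satterthwaite"] == n - p


def test_variance_component_recovery():
    """Median REML estimates land within 50% of the generating variances."""
    su, se = 0.05, 0.1
    est_u, est_e = [], []
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.5, "B": 0.2}
    for seed in range(200):
        rng = np.random.default_rng(1000 + seed)
        df = _sim(rng, list(truth), truth, n_batches=8, reps=8, su=su, se=se)
        fit = fit_mixed_model(df)
        est_u.append(fit.sigma_u)
        est_e.append(fit.sigma_e)
    assert abs(np.median(est_u) - su) < 0.5 * su
    assert abs(np.median(est_e) - se) < 0.5 * se


def test_estimates_invariant_to_row_and_label_order():
    rng = np.random.default_rng(9)
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.5}
    df = _sim(rng, list(truth), truth, n_batches=4, reps=3, su=0.1, se=0.1)
    fit1 = fit_mixed_model(df)
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    fit2 = fit_mixed_model(shuffled)
    pd.testing.assert_series_equal(fit1.beta_hat, fit2.beta_hat, atol=1e-12, rtol=0)
    assert fit1.sigma_u == pytest.approx(fit2.sigma_u, abs=1e-6)


def test_reml_objective_is_locally_optimal():
    rng = np.random.default_rng(12)
    truth = {"WT": 1.0, "EV": 0.0}
    df = _sim(rng, list(truth), truth, n_batches=4, reps=4, su=0.1, se=0.1)
    fit = fit_mixed_model(df)
    ss = fit._ss
    dev_hat = ss.deviance_theta(fit.sigma_u**2, fit.sigma_e**2)
    for _ in range(50):
        s2u = fit.sigma_u**2 * np.exp(rng.normal(0, 0.3))
        s2e = fit.sigma_e**2 * np.exp(rng.normal(0, 0.3))
        assert ss.deviance_theta(s2u, s2e) >= dev_hat - 1e-8


def test_adjusted_values_remove_batch_shift():
    rng = np.random.default_rng(21)
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.5}
    df = _sim(rng, list(truth), truth, n_batches=4, reps=4, su=0.1, se=0.08)
    fit = fit_mixed_model(df)
    shifted = df.copy()
    shifted.loc[shifted["batch"] == "b1", "value"] += 0.3
    fit_s = fit_mixed_model(shifted)
    # the shift splits into a constant (absorbed uniformly by the fixed
    # effects, later cancelled by control anchoring) and a batch deviation
    # (absorbed by the BLUP): genotype contrasts of adjusted values are
    # invariant, and the uniform remainder is exactly shift / n_batches
    base = pd.Series(adjust_for_random_effects(fit)).groupby(df["genotype"]).mean()
    moved = pd.Series(adjust_for_random_effects(fit_s)).groupby(shifted["genotype"]).mean()
    delta = (moved - base).to_numpy()
    assert np.allclose(delta, 0.3 / 4, atol=1e-8)
    assert np.allclose(moved.to_numpy() - moved["WT"], base.to_numpy() - base["WT"], atol=1e-8)
    # group means of adjusted values equal the fixed-effect estimates
    assert np.allclose(base[fit.genotypes], fit.beta_hat.to_numpy(), atol=1e-10)


def test_single_batch_adjusted_equals_observed():
    df = pd.DataFrame(
        {
            "genotype": ["WT", "WT", "EV", "EV", "V", "V"],
            "batch": ["b0"] * 6,
            "value": [1.0, 1.1, 0.0, 0.1, 0.5, 0.6],
        }
    )
    fit = fit_mixed_model(df)
    assert np.allclose(adjust_for_random_effects(fit), df["value"].to_numpy())


def test_confounded_genotype_is_flagged():
    df = pd.DataFrame(
        {
            "genotype": ["WT", "WT", "EV", "EV", "X", "X"],
            "batch": ["b0", "b1", "b0", "b1", "b9", "b9"],
            "value": [1.0, 1.1, 0.0, 0.1, 0.5, 0.6],
        }
    )
    with pytest.warns(UserWarning, match="X"):
        fit = fit_mixed_model(df)
    assert fit.flagged == ["X"]


def test_contrast_group_must_exist():
    df = pd.DataFrame(
        {
            "genotype": ["WT", "WT", "EV", "EV"],
            "batch": ["b0", "b0", "b0", "b0"],
            "value": [1.0, 1.1, 0.0, 0.1],
        }
    )
    fit = fit_mixed_model(df)
    with pytest.raises(ValueError, match="nope"):
        contrast_pvalues(fit, "nope")


def test_identical_genotypes_give_null_contrast():
    df = pd.DataFrame(
        {
            "genotype": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "batch": (["b0"] * 2 + ["b1"] * 2) * 3,
            "value": [0.4, 0.6, 0.5, 0.7] * 2 + [1.0, 1.2, 1.1, 1.3],
        }
    )
    fit = fit_mixed_model(df)
    res = contrast_pvalues(fit, "A").set_index("genotype")
    assert res.loc["B", "estimate"] == pytest.approx(0.0, abs=1e-12)
    assert res.loc["B", "p_value"] == pytest.approx(1.0, abs=1e-9)


def test_satterthwaite_df_bounded_by_residual_df():
    rng = np.random.default_rng(33)
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.5}
    df = _sim(rng, list(truth), truth, n_batches=3, reps=5, su=0.2, se=0.1)
    fit = fit_mixed_model(df)
    res = contrast_pvalues(fit, "WT")
    assert ((res["df_satterthwaite"] > 0) & (res["df_satterthwaite"] <= fit.n - fit.p)).all()


def test_wald_interval_coverage():
    """Nominal 95% t intervals on a genotype contrast cover the true effect
    at close to nominal rate with 8 batches."""
    truth = {"WT": 1.0, "A": 0.5}
    cover = 0
    n_sim = 400
    for seed in range(n_sim):
        rng = np.random.default_rng(5000 + seed)
        df = _sim(rng, list(truth), truth, n_batches=8, reps=3, su=0.08, se=0.1)
        fit = fit_mixed_model(df)
        row = contrast_pvalues(fit, "WT").iloc[0]
        half = stats.t.ppf(0.975, row["df_satterthwaite"]) * row["se"]
        cover += abs(row["estimate"] - (-0.5)) <= half
    assert cover / n_sim == pytest.approx(0.95, abs=0.025)


def test_fit_summary_layout():
    rng = np.random.default_rng(2)
    truth = {"WT": 1.0, "EV": 0.0, "A": 0.5}
    df = _sim(rng, list(truth), truth, n_batches=3, reps=3, su=0.05, se=0.1)
    summary = fit_summary(fit_mixed_model(df), "WT", "EV")
    assert list(summary.columns) == ["genotype", "beta", "se", "n", "p_vs_wt", "p_vs_null"]
    assert summary.set_index("genotype").loc["A", "n"] == 9
    assert np.isnan(summary.set_index("genotype").loc["WT", "p_vs_wt"])
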