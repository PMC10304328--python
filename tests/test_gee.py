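"""GEE estimation: equivalence oracles, covariance assembly, marginalization."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from snfrisk import SynthConfig, simulate
from snfrisk.gee import (
    GEEError,
    GEEFit,
    build_design,
    fit_gee,
    joint_wald_equal_risk,
    marginal_risk,
    marginal_risk_ci,
    odds_table,
    risk_table,
)

from conftest import slim_outcomes, true_group_series, true_score_frame


def small_claims(seed=0, n_patients=600, re_sd_person=0.5, re_sd_state=0.0,
                 slopes=(0.4, -0.3), offsets=(0.0, 0.3, -0.2), visit_rate=0.8,
                 n_states=5, interactions=None, n_groups=3):
    cfg = SynthConfig(
        n_patients=n_patients, n_snfs=60, n_states=n_states, n_patient_vars=4,
        k_patient=2, n_snf_vars=4, k_snf=1, n_groups=n_groups,
        visit_rate=visit_rate,
        group_weights=np.full(n_groups, 1 / n_groups),
        outcome_coefs=slim_outcomes(2, n_groups, intercept=-0.5, slopes=slopes,
                                    offsets=offsets, interactions=interactions),
        re_sd_state=re_sd_state, re_sd_person=re_sd_person,
        exclusion_rate=0.05, seed=seed,
    )
    claims, _, truth = simulate(cfg)
    scores = true_score_frame(claims, truth)
    groups = true_group_series(truth, cfg.n_snfs)
    return claims, scores, groups, truth


@pytest.fixture(scope="module")
def fitted():
    claims, scores, groups, truth = small_claims()
    design = build_design(claims, scores, groups, "rehosp60")
    fit = fit_gee(design, cov_type="person")
    return claims, design, fit


# ---------------------------------------------------------------------------
# Design assembly


def test_design_column_count_without_controls():
    claims, scores, groups, _ = small_claims()
    d = build_design(claims, scores, groups, "rehosp60", controls_on=False)
    k, K = 2, 3
    assert d.X.shape[1] == 1 + k + (K - 1) + k * (K - 1)
    assert d.adjusted is False


def test_design_drops_excluded_rows():
    claims, scores, groups, _ = small_claims()
    d = build_design(claims, scores, groups, "rehosp60")
    assert d.X.shape[0] == int((claims["excluded"] == 0).sum())


def test_control_columns_are_centered_and_interactions_multiply():
    claims, scores, groups, _ = small_claims()
    d = build_design(claims, scores, groups, "rehosp60", controls_on=True)
    for idx in d.control_cols:
        assert abs(d.X[:, idx].mean()) < 1e-10
    for (j, g), col in d.inter_cols.items():
        parent_f = d.X[:, d.factor_cols[j - 1]]
        parent_g = d.X[:, d.group_cols[g - 2]]
        assert np.allclose(d.X[:, col], parent_f * parent_g)


def test_centered_age_on_three_row_fixture():
    claims = pd.DataFrame({
        "claim_id": [0, 1, 2], "patient_id": [0, 1, 2], "state_id": [0, 0, 0],
        "snf_id": [0, 1, 0], "age": [60.0, 70.0, 80.0], "female": [0, 1, 0],
        "race": ["White", "White", "Black"], "complication": [0, 1, 0],
        "los": [3.0, 4.0, 5.0], "rehosp60": [0, 1, 0], "death60": [0, 0, 1],
    })
    scores = pd.DataFrame({"f1": [0.1, -0.2, 0.3]}, index=claims.index)
    groups = pd.Series([1, 2], index=[0, 1])
    d = build_design(claims, scores, groups, "rehosp60", controls_on=True)
    age = d.X[:, d.columns.index("age")]
    assert np.allclose(age, [-10.0, 0.0, 10.0])


def test_reference_only_claims_zero_group_columns():
    claims, scores, groups, _ = small_claims()
    groups_all_ref = pd.Series(1, index=groups.index)
    # Keep K=3 bookkeeping by reusing the fitted groups' max label.
    d = build_design(claims, scores, groups_all_ref, "rehosp60")
    assert d.n_groups == 1 and d.group_cols.size == 0


def test_missing_group_raises():
    claims, scores, groups, _ = small_claims()
    with pytest.raises(GEEError, match="without a group"):
        build_design(claims, scores, groups.iloc[:5], "rehosp60")


# ---------------------------------------------------------------------------
# Estimation oracles


def test_singleton_clusters_match_logistic_mle():
    """One visit per patient, one patient per state: GEE == independent MLE."""
    cfg = SynthConfig(
        n_patients=800, n_snfs=40, n_states=800, n_patient_vars=4, k_patient=2,
        n_snf_vars=4, k_snf=1, n_groups=2, visit_rate=0.0,
        outcome_coefs=slim_outcomes(2, 2, intercept=-0.4, slopes=[0.5, -0.2],
                                    offsets=[0.0, 0.3]),
        re_sd_state=0.0, re_sd_person=0.0, exclusion_rate=0.0, seed=3,
    )
    claims, _, truth = simulate(cfg)
    claims["state_id"] = np.arange(len(claims))  # force singleton states
    scores = true_score_frame(claims, truth)
    groups = true_group_series(truth, cfg.n_snfs)
    d = build_design(claims, scores, groups, "rehosp60")
    fit = fit_gee(d, cov_type="nested")
    mle = sm.Logit(d.y, d.X).fit(disp=0)
    assert np.abs(fit.beta - mle.params).max() < 1e-4


def test_independence_cov_matches_logistic_mle(fitted):
    _, design, _ = fitted
    fit = fit_gee(design, cov_type="independence")
    mle = sm.Logit(design.y, design.X).fit(disp=0)
    assert np.abs(fit.beta - mle.params).max() < 1e-4
    assert fit.rho_person == 0.0 and fit.rho_state == 0.0


def test_person_cov_agrees_with_statsmodels_exchangeable():
    """Cross-check against an independent GEE implementation."""
    claims, scores, groups, _ = small_claims(seed=5)
    d = build_design(claims, scores, groups, "rehosp60")
    fit = fit_gee(d, cov_type="person")
    ref = sm.GEE(d.y, d.X, groups=d.patient,
                 family=sm.families.Binomial(),
                 cov_struct=sm.cov_struct.Exchangeable()).fit()
    assert np.abs(fit.beta - ref.params).max() < 5e-3
    assert abs(fit.rho_person - ref.cov_struct.dep_params) < 0.02


def test_null_random_intercepts_give_null_correlations():
    claims, scores, groups, _ = small_claims(
        seed=6, n_patients=3000, re_sd_person=0.0, re_sd_state=0.0)
    d = build_design(claims, scores, groups, "rehosp60")
    fit = fit_gee(d, cov_type="nested")
    assert abs(fit.rho_person) < 0.05
    assert abs(fit.rho_state) < 0.05


def test_estimating_equation_residual_is_small_at_solution(fitted):
    _, design, fit = fitted
    assert fit.converged
    assert fit.score_norm < 1e-5 * design.X.shape[0]


def test_sandwich_matches_dense_assembly_on_three_cluster_fixture():
    """Robust covariance equals B^{-1} M B^{-1} built from dense per-cluster
    matrices."""
    claims, scores, groups, _ = small_claims(seed=7, n_patients=90, n_states=3,
                                             re_sd_state=0.2)
    d = build_design(claims, scores, groups, "rehosp60")
    fit = fit_gee(d, cov_type="nested")

    mu = expit(d.X @ fit.beta)
    a = mu * (1 - mu)
    r = d.y - mu
    B = np.zeros((d.X.shape[1],) * 2)
    M = np.zeros_like(B)
    for s in np.unique(d.state):
        idx = np.where(d.state == s)[0]
        u = np.sqrt(a[idx])
        person = d.patient[idx]
        R = np.where(person[:, None] == person[None, :],
                     fit.rho_state + fit.rho_person, fit.rho_state)
        np.fill_diagonal(R, 1.0)
        V = u[:, None] * R * u[None, :]  # phi omitted; cancels in the sandwich
        D = a[idx, None] * d.X[idx]
        Vinv_D = np.linalg.solve(V, D)
        B += D.T @ Vinv_D
        g = D.T @ np.linalg.solve(V, r[idx])
        M += np.outer(g, g)
    Binv = np.linalg.inv(B)
    expected = Binv @ M @ Binv
    assert np.abs(expected - fit.robust_cov).max() < 1e-10


def test_robust_cov_is_symmetric_psd(fitted):
    _, _, fit = fitted
    assert np.allclose(fit.robust_cov, fit.robust_cov.T, atol=1e-12)
    assert np.linalg.eigvalsh(fit.robust_cov).min() > -1e-12


def test_degenerate_outcomes_and_rank_deficiency_raise():
    claims, scores, groups, _ = small_claims(seed=8, n_patients=100)
    d = build_design(claims, scores, groups, "rehosp60")
    d_bad = d
    d_bad.y = np.ones_like(d.y)
    with pytest.raises(GEEError, match="event"):
        fit_gee(d_bad)
    claims2, scores2, groups2, _ = small_claims(seed=9, n_patients=100)
    d2 = build_design(claims2, scores2, groups2, "rehosp60")
    d2.X = np.column_stack([d2.X, d2.X[:, 1]])
    d2.columns = d2.columns + ["dup"]
    with pytest.raises(GEEError, match="rank"):
        fit_gee(d2)


def test_separation_is_detected():
    n = 200
    rng = np.random.default_rng(10)
    x = rng.standard_normal(n)
    claims = pd.DataFrame({
        "claim_id": np.arange(n), "patient_id": np.arange(n),
        "state_id": np.arange(n), "snf_id": 0,
        "rehosp60": (x > 0).astype(int), "death60": 0,
    })
    scores = pd.DataFrame({"f1": x}, index=claims.index)
    groups = pd.Series([1], index=[0])
    d = build_design(claims, scores, groups, "rehosp60")
    with pytest.raises(GEEError, match="separation"):
        fit_gee(d)


# ---------------------------------------------------------------------------
# Marginal risks


def test_intercept_only_marginal_risk_is_expit_beta0(fitted):
    _, design, fit = fitted
    null = GEEFit(
        params=pd.Series(np.zeros(len(fit.beta)), index=fit.params.index),
        rho_state=0.0, rho_person=0.0, phi=1.0,
        robust_cov=np.zeros_like(fit.robust_cov),
        model_cov=np.zeros_like(fit.model_cov),
        n_iter=1, converged=True, score_norm=0.0, cov_type="person",
        n_obs=fit.n_obs, n_clusters=fit.n_clusters)
    assert marginal_risk(null, design, 1, 2) == pytest.approx(0.5)
    null.params.iloc[0] = -1.2
    for g in (1, 2, 3):
        assert marginal_risk(null, design, 1, g) == pytest.approx(expit(-1.2))


def test_zero_group_coefficients_make_risks_group_invariant(fitted):
    _, design, fit = fitted
    beta = fit.params.copy()
    beta.iloc[list(design.group_cols) + list(design.inter_cols.values())] = 0.0
    flat = GEEFit(params=beta, rho_state=0, rho_person=0, phi=1,
                  robust_cov=fit.robust_cov, model_cov=fit.model_cov,
                  n_iter=1, converged=True, score_norm=0.0,
                  cov_type="person", n_obs=fit.n_obs, n_clusters=fit.n_clusters)
    risks = [marginal_risk(flat, design, 2, g) for g in (1, 2, 3)]
    assert max(risks) - min(risks) < 1e-15


def test_marginal_risk_matches_row_by_row_enumeration(fitted):
    """Exhaustive per-visit counterfactual oracle on a 50-row slice."""
    _, design, fit = fitted
    sub = design
    s = sub.scores[:, 0]
    thr = s.mean() + s.std(ddof=1)
    rows = np.where(s > thr)[0][:50]
    beta = dict(zip(sub.columns, fit.beta))
    for g in (1, 2, 3):
        probs = []
        for i in rows:
            eta = beta["intercept"]
            eta += beta["f1"] * sub.scores[i, 0] + beta["f2"] * sub.scores[i, 1]
            if g > 1:
                eta += beta[f"group{g}"]
                eta += beta[f"f1:group{g}"] * sub.scores[i, 0]
                eta += beta[f"f2:group{g}"] * sub.scores[i, 1]
            probs.append(expit(eta))
        # Compare against the module on exactly those rows.
        sel = np.zeros(len(s), dtype=bool)
        sel[rows] = True
        from snfrisk.gee import _counterfactual_X
        module_probs = expit(_counterfactual_X(sub, sel, g) @ fit.beta)
        assert np.abs(np.asarray(probs) - module_probs).max() < 1e-12


def test_marginal_risk_lies_within_counterfactual_probability_range(fitted):
    _, design, fit = fitted
    from snfrisk.gee import _counterfactual_X, _qualifying_rows
    for j in (1, 2):
        sel = _qualifying_rows(design, j)
        for g in (1, 2, 3):
            probs = expit(_counterfactual_X(design, sel, g) @ fit.beta)
            r = marginal_risk(fit, design, j, g)
            assert probs.min() - 1e-12 <= r <= probs.max() + 1e-12


def test_ci_degenerates_to_point_estimate_with_zero_covariance(fitted):
    _, design, fit = fitted
    frozen = GEEFit(params=fit.params, rho_state=0, rho_person=0, phi=1,
                    robust_cov=np.zeros_like(fit.robust_cov),
                    model_cov=fit.model_cov, n_iter=1, converged=True,
                    score_norm=0.0, cov_type="person", n_obs=fit.n_obs,
                    n_clusters=fit.n_clusters)
    r, lo, hi = marginal_risk_ci(frozen, design, 1, 2)
    assert lo == pytest.approx(r) and hi == pytest.approx(r)


def test_ci_gradient_matches_finite_differences(fitted):
    _, design, fit = fitted
    from snfrisk.gee import _qualifying_rows, _risk_and_gradient
    sel = _qualifying_rows(design, 1)
    risk, grad = _risk_and_gradient(fit, design, sel, 2)
    h = 1e-6
    from snfrisk.gee import _counterfactual_X
    Xc = _counterfactual_X(design, sel, 2)
    for idx in range(0, len(fit.beta), 3):
        bp, bm = fit.beta.copy(), fit.beta.copy()
        bp[idx] += h
        bm[idx] -= h
        fd = (expit(Xc @ bp).mean() - expit(Xc @ bm).mean()) / (2 * h)
        assert grad[idx] == pytest.approx(fd, abs=1e-8)


def test_ci_brackets_point_estimate_inside_unit_interval(fitted):
    _, design, fit = fitted
    for j in (1, 2):
        for g in (1, 2, 3):
            r, lo, hi = marginal_risk_ci(fit, design, j, g)
            assert 0.0 <= lo <= r <= hi <= 1.0


def test_marginal_risks_invariant_to_control_recentering():
    """Shifting a control column only moves the intercept, not the risks."""
    claims, scores, groups, _ = small_claims(seed=11)
    d1 = build_design(claims, scores, groups, "rehosp60", controls_on=True)
    d2 = build_design(claims, scores, groups, "rehosp60", controls_on=True)
    d2.X = d2.X.copy()
    d2.X[:, d2.control_cols[0]] += 17.0  # un-center age
    f1 = fit_gee(d1, cov_type="person")
    f2 = fit_gee(d2, cov_type="person")
    for g in (1, 2, 3):
        assert marginal_risk(f1, d1, 1, g) == pytest.approx(
            marginal_risk(f2, d2, 1, g), abs=1e-8)


# ---------------------------------------------------------------------------
# Wald tests and odds


def test_wald_is_degenerate_null_when_no_effects_and_no_variance(fitted):
    _, design, fit = fitted
    beta = fit.params.copy()
    beta[:] = 0.0
    null = GEEFit(params=beta, rho_state=0, rho_person=0, phi=1,
                  robust_cov=np.zeros_like(fit.robust_cov),
                  model_cov=fit.model_cov, n_iter=1, converged=True,
                  score_norm=0.0, cov_type="person", n_obs=fit.n_obs,
                  n_clusters=fit.n_clusters)
    stat, df, p = joint_wald_equal_risk(null, design, 1)
    assert stat == 0.0 and df == 2 and p == 1.0


def test_wald_detects_planted_interaction():
    inter = np.zeros((2, 3))
    inter[0, 1] = 0.8
    claims, scores, groups, _ = small_claims(
        seed=12, n_patients=2500, offsets=(0.0, 0.0, 0.0), interactions=inter)
    d = build_design(claims, scores, groups, "rehosp60")
    fit = fit_gee(d, cov_type="person")
    stat, df, p = joint_wald_equal_risk(fit, d, 1)
    assert p < 0.01


def test_odds_table_arithmetic(fitted):
    _, _, fit = fitted
    tab = odds_table(fit)
    se = fit.robust_se()
    z = 1.959963984540054
    assert np.allclose(tab["odds_ratio"], np.exp(fit.beta), atol=1e-10)
    assert np.allclose(tab["lower"], np.exp(fit.beta - z * se), atol=1e-10)
    assert np.allclose(tab["upper"], np.exp(fit.beta + z * se), atol=1e-10)


def test_risk_table_shape_and_contents(fitted):
    _, design, fit = fitted
    rt = risk_table(fit, design)
    assert len(rt.frame) == design.k * design.n_groups
    assert set(rt.wald["factor"]) == {1, 2}
    assert ((rt.frame["lower"] <= rt.frame["risk"])
            & (rt.frame["risk"] <= rt.frame["upper"])).all()
    assert rt.wald["p"].between(0, 1).all()
    wide = rt.pivot()
    assert wide.shape == (2, design.n_groups + 1)


def test_coefficient_scale_wald_option(fitted):
    _, design, fit = fitted
    stat, df, p = joint_wald_equal_risk(fit, design, 1, scale="coefficient")
    assert df == 2 * (design.n_groups - 1)
    assert 0.0 <= p <= 1.0
    with pytest.raises(GEEError):
        joint_wald_equal_risk(fit, design, 1, scale="odds")


def test_bootstrap_ci_brackets_the_point_estimate(fitted):
    _, design, fit = fitted
    r, lo, hi = marginal_risk_ci(fit, design, 1, 2, method="bootstrap",
                                 n_boot=40, seed=0)
    assert 0.0 <= lo < hi <= 1.0
    assert lo <= r <= hi
    # Wider than nothing, comparable order to the delta interval.
    _, dlo, dhi = marginal_risk_ci(fit, design, 1, 2)
    assert (hi - lo) < 4 * (dhi - dlo) + 0.05


def test_discharge_date_as_extra_control():
    cfg = SynthConfig(
        n_patients=400, n_snfs=40, n_states=3, n_patient_vars=6, k_patient=2,
        n_snf_vars=4, k_snf=1, n_groups=2, with_discharge_date=True, seed=17,
    )
    claims, _, truth = simulate(cfg)
    assert "discharge_date" in claims.columns
    scores = true_score_frame(claims, truth)
    groups = true_group_series(truth, cfg.n_snfs)
    d = build_design(claims, scores, groups, "rehosp60", controls_on=True,
                     extra_controls=["discharge_date"])
    idx = d.columns.index("discharge_date")
    assert abs(d.X[:, idx].mean()) < 1e-10
    fit = fit_gee(d, cov_type="person")
    assert fit.converged
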