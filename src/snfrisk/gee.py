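"""GEE logistic models of 60-day rehospitalization and mortality.

Fits marginal logistic regressions of a binary outcome on patient
factor scores, facility group, and their interactions, using
generalized estimating equations with a working covariance that is the
sum of two compound-symmetry components: a common correlation between
visits from the same state and an additional correlation between visits
from the same person.  States are the top-level independent clusters;
persons are nested within states.  Robust (sandwich) covariances,
marginally standardized risks for +1 SD factor subpopulations,
delta-method confidence intervals, and joint Wald tests of equal risk
across groups are provided.

The working correlation matrix for one state is

    R = (1 - rho_s - rho_p) I + rho_p Z Z' + rho_s 1 1'

with Z the person-indicator matrix, so R can be inverted in O(n) by two
nested Sherman-Morrison steps; no dense per-cluster matrices are formed.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2, norm

__all__ = [
    "DesignMatrix",
    "GEEFit",
    "GEEError",
    "RiskTable",
    "build_design",
    "fit_gee",
    "marginal_risk",
    "marginal_risk_ci",
    "joint_wald_equal_risk",
    "odds_table",
    "risk_table",
]


class GEEError(RuntimeError):
    """Raised on degenerate designs or estimation failure."""


@dataclass
class DesignMatrix:
    """Model matrix plus the bookkeeping needed for marginalization.

    Columns are, in order: intercept; k factor-score columns; K-1 group
    indicators (reference = Group 1, the largest); k*(K-1) factor-by-
    group interactions; then any mean-centered control columns.
    """

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    state: np.ndarray
    patient: np.ndarray
    scores: np.ndarray  # (n, k) factor scores per included claim
    k: int
    n_groups: int
    factor_cols: np.ndarray  # column indices of the k factor scores
    group_cols: np.ndarray  # column indices for groups 2..K
    inter_cols: dict[tuple[int, int], int]  # (factor j, group g) -> column
    control_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    outcome: str = ""
    adjusted: bool = False


def build_design(
    claims: pd.DataFrame,
    scores: pd.DataFrame,
    groups: pd.Series,
    outcome: str,
    controls_on: bool = False,
    extra_controls: list[str] | None = None,
    min_category_count: int = 20,
    min_category_events: int = 5,
) -> DesignMatrix:
    """Assemble the regression design from included claims.

    ``scores`` must be row-aligned with ``claims`` (same index);
    ``groups`` maps snf_id to a group label in 1..K.  Rows flagged
    ``excluded`` are dropped.  Controls (age, female, race dummies with
    the largest category as reference, complication, length of stay, and
    any ``extra_controls`` columns) are mean-centered over included
    claims and added only when ``controls_on``.

    Race categories with fewer than ``min_category_count`` included
    claims, or fewer than ``min_category_events`` events or non-events
    for the modeled outcome, are merged into the reference: a dummy
    whose cell lacks one outcome level is quasi-separated and
    destabilizes the fit.
    """
    if "excluded" in claims.columns:
        keep = claims["excluded"].to_numpy() == 0
    else:
        keep = np.ones(len(claims), dtype=bool)
    claims = claims.loc[keep]
    if claims.empty:
        raise GEEError("no included claims")
    missing_scores = claims.index.difference(scores.index)
    if len(missing_scores):
        raise GEEError(f"claims without factor scores: {list(missing_scores[:5])}")
    S = scores.loc[claims.index].to_numpy(dtype=float)
    k = S.shape[1]

    grp = claims["snf_id"].map(groups)
    if grp.isna().any():
        bad = claims.loc[grp.isna(), "snf_id"].unique()
        raise GEEError(f"claims reference SNFs without a group: {list(bad[:5])}")
    grp = grp.to_numpy(dtype=int)
    K = int(groups.max())

    n = len(claims)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    factor_cols = np.arange(1, 1 + k)
    for j in range(k):
        cols.append(S[:, j])
        names.append(f"f{j+1}")
    group_cols = np.arange(1 + k, 1 + k + (K - 1))
    for g in range(2, K + 1):
        cols.append((grp == g).astype(float))
        names.append(f"group{g}")
    inter_cols: dict[tuple[int, int], int] = {}
    for j in range(1, k + 1):
        for g in range(2, K + 1):
            inter_cols[(j, g)] = len(cols)
            cols.append(S[:, j - 1] * (grp == g))
            names.append(f"f{j}:group{g}")

    control_idx: list[int] = []
    if controls_on:
        def add_centered(name, values):
            v = np.asarray(values, dtype=float)
            control_idx.append(len(cols))
            cols.append(v - v.mean())
            names.append(name)

        add_centered("age", claims["age"])
        add_centered("female", claims["female"])
        race = claims["race"].astype(str)
        counts = race.value_counts()
        ref = counts.idxmax()
        y_out = claims[outcome].to_numpy(dtype=float)
        merge = set()
        for level, cnt in counts.items():
            if level == ref:
                continue
            events = y_out[(race == level).to_numpy()].sum()
            if (cnt < min_category_count
                    or events < min_category_events
                    or cnt - events < min_category_events):
                merge.add(level)
        if merge:
            race = race.where(~race.isin(merge), ref)
        for level in sorted(race.unique()):
            if level == ref:
                continue
            add_centered(f"race_{level}", (race == level).astype(float))
        add_centered("complication", claims["complication"])
        add_centered("los", claims["los"])
        for name in extra_controls or []:
            add_centered(name, claims[name])

    X = np.column_stack(cols)
    y = claims[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise GEEError(f"outcome {outcome!r} is not binary")
    return DesignMatrix(
        X=X, columns=names, y=y,
        state=claims["state_id"].to_numpy(),
        patient=claims["patient_id"].to_numpy(),
        scores=S, k=k, n_groups=K,
        factor_cols=factor_cols, group_cols=group_cols,
        inter_cols=inter_cols, control_cols=np.asarray(control_idx, dtype=int),
        outcome=outcome, adjusted=controls_on,
    )


# ---------------------------------------------------------------------------
# Working-covariance solver


def _nested_solve(a, rho_p, rho_s, person_codes, state_codes, M):
    """Solve ``(A^{1/2} R A^{1/2}) x = m`` for each column m of M.

    ``R`` is the two-level exchangeable correlation matrix (block
    diagonal over states).  Uses Sherman-Morrison at the person level
    and again at the state level; O(n) per column.
    """
    a = np.asarray(a, dtype=float)
    u = np.sqrt(a)
    c = 1.0 - rho_s - rho_p
    single = M.ndim == 1
    M2 = M[:, None] if single else M
    n_person = person_codes.max() + 1
    np_counts = np.bincount(person_codes, minlength=n_person).astype(float)
    denom_p = c + rho_p * np_counts  # per person

    if rho_s != 0.0:
        n_state = state_codes.max() + 1
        Binv_u = (1.0 / u) / denom_p[person_codes]
        s_uBu = np.bincount(state_codes, weights=u * Binv_u, minlength=n_state)
        state_denom = 1.0 + rho_s * s_uBu

    out = np.empty_like(M2, dtype=float)
    for jcol in range(M2.shape[1]):
        x = M2[:, jcol]
        t_p = np.bincount(person_codes, weights=x / u, minlength=n_person)
        Binv_x = x / (c * a) - (rho_p / c) * (t_p / denom_p)[person_codes] / u
        if rho_s != 0.0:
            s_x = np.bincount(state_codes, weights=u * Binv_x, minlength=n_state)
            Binv_x = Binv_x - rho_s * (s_x / state_denom)[state_codes] * Binv_u
        out[:, jcol] = Binv_x
    return out[:, 0] if single else out


def _pair_moments(e, codes, n_codes):
    """Sum and count of e_i e_j over unordered within-group pairs."""
    S = np.bincount(codes, weights=e, minlength=n_codes)
    Q = np.bincount(codes, weights=e**2, minlength=n_codes)
    counts = np.bincount(codes, minlength=n_codes).astype(float)
    pair_sum = float(((S**2 - Q) / 2.0).sum())
    pair_count = float((counts * (counts - 1) / 2.0).sum())
    return pair_sum, pair_count


def _clip_rhos(rho_s, rho_p, np_counts, eps=1e-3):
    """Keep the implied working correlation positive definite for every
    realized cluster size."""
    rho_s = float(np.clip(rho_s, -0.95, 0.95))
    rho_p = float(np.clip(rho_p, -0.95, 0.95))
    # Diagonal dominance of the base term.
    if rho_s + rho_p > 1.0 - eps:
        scale = (1.0 - eps) / (rho_s + rho_p)
        rho_s *= scale
        rho_p *= scale
    c = 1.0 - rho_s - rho_p
    n_max = np_counts.max() if len(np_counts) else 1.0
    if rho_p < 0 and c + rho_p * n_max < eps:
        rho_p = (eps - c) / n_max
    # Negative state correlation: keep the state-level Sherman-Morrison
    # denominator positive (bounded by the largest state size).
    c = 1.0 - rho_s - rho_p
    if rho_s < 0:
        t_max = float((np_counts / (c + rho_p * np_counts)).sum())
        if 1.0 + rho_s * t_max < eps:
            rho_s = (eps - 1.0) / t_max
    return rho_s, rho_p


@dataclass
class GEEFit:
    """A converged GEE fit for one outcome model."""

    params: pd.Series  # coefficients on the log-odds scale
    rho_state: float
    rho_person: float
    phi: float
    robust_cov: np.ndarray
    model_cov: np.ndarray
    n_iter: int
    converged: bool
    score_norm: float  # sup-norm of the estimating equation at the solution
    cov_type: str
    n_obs: int
    n_clusters: int

    @property
    def beta(self) -> np.ndarray:
        return self.params.to_numpy()

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov)), index=self.params.index)

    def to_json(self, path) -> None:
        payload = {
            "params": {k: float(v) for k, v in self.params.items()},
            "rho_state": self.rho_state,
            "rho_person": self.rho_person,
            "phi": self.phi,
            "robust_cov": self.robust_cov.tolist(),
            "model_cov": self.model_cov.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "score_norm": self.score_norm,
            "cov_type": self.cov_type,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def fit_gee(
    design: DesignMatrix,
    cov_type: str = "nested",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GEEFit:
    """Solve the GEE score equation with logit link.

    ``cov_type='nested'`` uses state as the top-level cluster with the
    person correlation nested inside (two working parameters);
    ``'person'`` drops the state level and clusters on person (suitable
    when there are too few states for a stable sandwich);
    ``'independence'`` fixes both correlations at zero.

    The correlation parameters and scale are re-estimated at every
    iteration from moment equations on the Pearson residuals: the mean
    cross-product over same-person pairs estimates rho_s + rho_p, and
    over same-state different-person pairs estimates rho_s.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if y.sum() == 0 or y.sum() == n:
        raise GEEError("need at least one event and one non-event")
    if np.linalg.matrix_rank(X) < p:
        raise GEEError("design matrix is rank deficient")
    if cov_type not in ("nested", "person", "independence"):
        raise GEEError(f"unknown cov_type {cov_type!r}")

    _, person_codes = np.unique(design.patient, return_inverse=True)
    if cov_type == "nested":
        _, top_codes = np.unique(design.state, return_inverse=True)
    else:
        top_codes = person_codes
    n_person = person_codes.max() + 1
    n_top = top_codes.max() + 1
    np_counts = np.bincount(person_codes, minlength=n_person).astype(float)

    # Initialize from a few independence IRLS steps.
    beta = np.zeros(p)
    beta[0] = logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    for _ in range(5):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = X @ beta + (y - mu) / w
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)

    rho_s = rho_p = 0.0
    phi = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(X @ beta)
        a = np.clip(mu * (1 - mu), 1e-10, None)
        r = y - mu
        e = r / np.sqrt(a)
        phi = float(e @ e) / max(n - p, 1)

        if cov_type != "independence":
            pp_sum, pp_cnt = _pair_moments(e, person_codes, n_person)
            rho_same_person = pp_sum / max(pp_cnt - p, 1.0) / phi
            if cov_type == "nested":
                st_sum, st_cnt = _pair_moments(e, top_codes, n_top)
                ss_sum = st_sum - pp_sum
                ss_cnt = st_cnt - pp_cnt
                rho_s_new = ss_sum / max(ss_cnt - p, 1.0) / phi
                rho_p_new = rho_same_person - rho_s_new
            else:
                rho_s_new = 0.0
                rho_p_new = rho_same_person
            rho_s, rho_p = _clip_rhos(rho_s_new, rho_p_new, np_counts)

        AX = a[:, None] * X
        S_AX = _nested_solve(a, rho_p, rho_s, person_codes, top_codes, AX)
        B = AX.T @ S_AX  # scaled by 1/phi in V; cancels in the Newton step
        U = S_AX.T @ r
        try:
            delta = np.linalg.solve(B, U)
        except np.linalg.LinAlgError as err:
            raise GEEError("singular working information matrix") from err
        beta = beta + delta
        if np.abs(beta).max() > 50:
            raise GEEError("divergent coefficients; possible separation")
        if np.abs(delta).max() < tol:
            converged = True
            break

    # Final quantities at the returned beta.
    mu = expit(X @ beta)
    a = np.clip(mu * (1 - mu), 1e-10, None)
    r = y - mu
    e = r / np.sqrt(a)
    phi = float(e @ e) / max(n - p, 1)
    AX = a[:, None] * X
    S_AX = _nested_solve(a, rho_p, rho_s, person_codes, top_codes, AX)
    S_r = _nested_solve(a, rho_p, rho_s, person_codes, top_codes, r)
    B = AX.T @ S_AX
    U = S_AX.T @ r
    score_norm = float(np.abs(U).max()) / phi

    # Cluster-level score contributions for the sandwich meat.
    G = np.empty((n_top, p))
    for j in range(p):
        G[:, j] = np.bincount(top_codes, weights=AX[:, j] * S_r, minlength=n_top)
    M = G.T @ G
    Binv = np.linalg.inv(B)
    robust_cov = Binv @ M @ Binv  # phi cancels between B^{-1} and M
    model_cov = phi * Binv

    if not converged:
        raise GEEError(
            f"GEE did not converge in {max_iter} iterations "
            f"(last step {np.abs(delta).max():.3g}, score norm {score_norm:.3g})")

    return GEEFit(
        params=pd.Series(beta, index=design.columns),
        rho_state=rho_s if cov_type == "nested" else 0.0,
        rho_person=rho_p,
        phi=phi,
        robust_cov=robust_cov,
        model_cov=model_cov,
        n_iter=n_iter,
        converged=converged,
        score_norm=score_norm,
        cov_type=cov_type,
        n_obs=n,
        n_clusters=int(n_top),
    )


# ---------------------------------------------------------------------------
# Marginal standardization


def _qualifying_rows(design: DesignMatrix, factor_j: int) -> np.ndarray:
    s = design.scores[:, factor_j - 1]
    thr = s.mean() + s.std(ddof=1)
    sel = s > thr
    if not sel.any():
        raise GEEError(f"no visits exceed +1 SD on factor {factor_j}")
    return sel


def _counterfactual_X(design: DesignMatrix, sel: np.ndarray, group_g: int) -> np.ndarray:
    """Copy of the selected rows with group columns set to group_g."""
    Xc = design.X[sel].copy()
    Xc[:, design.group_cols] = 0.0
    for col in design.inter_cols.values():
        Xc[:, col] = 0.0
    if group_g > 1:
        g_col = design.group_cols[group_g - 2]
        Xc[:, g_col] = 1.0
        for j in range(1, design.k + 1):
            Xc[:, design.inter_cols[(j, group_g)]] = design.scores[sel, j - 1]
    return Xc


def _check_jg(design, factor_j, group_g):
    if not (1 <= factor_j <= design.k):
        raise GEEError(f"factor_j must lie in 1..{design.k}")
    if not (1 <= group_g <= design.n_groups):
        raise GEEError(f"group_g must lie in 1..{design.n_groups}")


def marginal_risk(fit: GEEFit, design: DesignMatrix, factor_j: int, group_g: int) -> float:
    """Marginally standardized risk for the +1 SD subpopulation of factor j.

    Selects visits whose factor-j score exceeds its mean + 1 SD (moments
    over all included visits), counterfactually assigns every selected
    visit to ``group_g`` (keeping all other covariates), and averages
    the model-predicted probabilities.
    """
    _check_jg(design, factor_j, group_g)
    sel = _qualifying_rows(design, factor_j)
    Xc = _counterfactual_X(design, sel, group_g)
    return float(expit(Xc @ fit.beta).mean())


def _risk_and_gradient(fit, design, sel, group_g):
    Xc = _counterfactual_X(design, sel, group_g)
    p_hat = expit(Xc @ fit.beta)
    grad = (p_hat * (1 - p_hat)) @ Xc / len(p_hat)
    return float(p_hat.mean()), grad


def _bootstrap_design(design: DesignMatrix, cluster_ids, rng) -> DesignMatrix:
    """Resample top-level clusters with replacement; copies get fresh ids."""
    uniq = np.unique(cluster_ids)
    pick = rng.choice(uniq, size=len(uniq), replace=True)
    rows, new_state, new_patient = [], [], []
    for rep_i, c in enumerate(pick):
        idx = np.where(cluster_ids == c)[0]
        rows.append(idx)
        new_state.append(np.full(len(idx), rep_i))
        # Persons must stay distinct between copies of the same cluster.
        new_patient.append(design.patient[idx].astype(np.int64)
                           + rep_i * (design.patient.max() + 1))
    rows = np.concatenate(rows)
    boot = DesignMatrix(
        X=design.X[rows], columns=design.columns, y=design.y[rows],
        state=np.concatenate(new_state), patient=np.concatenate(new_patient),
        scores=design.scores[rows], k=design.k, n_groups=design.n_groups,
        factor_cols=design.factor_cols, group_cols=design.group_cols,
        inter_cols=design.inter_cols, control_cols=design.control_cols,
        outcome=design.outcome, adjusted=design.adjusted)
    return boot


def marginal_risk_ci(
    fit: GEEFit,
    design: DesignMatrix,
    factor_j: int,
    group_g: int,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float, float]:
    """CI for the marginal risk, truncated to (0, 1).

    ``method="delta"`` (default) propagates the robust covariance of the
    coefficients through the gradient of the averaged inverse-logit.
    ``method="bootstrap"`` resamples top-level clusters with
    replacement, refits the GEE on each resample, and reports the
    percentile interval of the recomputed risk.
    """
    _check_jg(design, factor_j, group_g)
    sel = _qualifying_rows(design, factor_j)
    risk, grad = _risk_and_gradient(fit, design, sel, group_g)
    if method == "delta":
        var = float(grad @ fit.robust_cov @ grad)
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        return risk, max(risk - half, 0.0), min(risk + half, 1.0)
    if method != "bootstrap":
        raise GEEError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    cluster_ids = design.state if fit.cov_type == "nested" else design.patient
    draws = []
    for _ in range(n_boot):
        boot = _bootstrap_design(design, cluster_ids, rng)
        try:
            bfit = fit_gee(boot, cov_type=fit.cov_type, max_iter=50)
        except GEEError:
            continue  # degenerate resample
        draws.append(marginal_risk(bfit, boot, factor_j, group_g))
    if len(draws) < max(20, n_boot // 4):
        raise GEEError("too few successful bootstrap refits")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return risk, float(lo), float(hi)


def joint_wald_equal_risk(
    fit: GEEFit, design: DesignMatrix, factor_j: int, scale: str = "risk"
) -> tuple[float, int, float]:
    """Joint Wald test that the marginal risk is equal across all groups.

    ``scale="risk"`` (default) contrasts the K marginally standardized
    risks; ``scale="coefficient"`` instead tests that all group offsets
    and all factor-j interaction coefficients are zero (2(K-1) df),
    i.e. equality of the linear predictor across groups at any score.

    Forms the K-vector of marginal risks for factor j, the K-1 adjacent
    differences, and the delta-method covariance of the risk vector;
    returns ``(statistic, df, p)`` with a chi-square reference on K-1
    degrees of freedom.

    With very few top-level clusters the robust covariance has rank at
    most ``n_clusters - 1``, so the contrast covariance can be rank
    deficient; the test then uses its pseudo-inverse with the rank as
    the effective degrees of freedom (and emits a warning).
    """
    K = design.n_groups
    if K < 2:
        raise GEEError("need at least two groups")
    if scale == "coefficient":
        idx = list(design.group_cols) + [design.inter_cols[(factor_j, g)]
                                         for g in range(2, K + 1)]
        b = fit.beta[idx]
        V = fit.robust_cov[np.ix_(idx, idx)]
        if np.linalg.cond(V) > 1e12:
            raise GEEError("singular coefficient covariance in joint Wald test")
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return stat, df, float(chi2.sf(stat, df))
    if scale != "risk":
        raise GEEError(f"unknown Wald scale {scale!r}")
    sel = _qualifying_rows(design, factor_j)
    risks = np.empty(K)
    grads = np.empty((K, len(fit.beta)))
    for g in range(1, K + 1):
        risks[g - 1], grads[g - 1] = _risk_and_gradient(fit, design, sel, g)
    C = np.eye(K - 1, K) - np.eye(K - 1, K, k=1)
    diff = C @ risks
    df = K - 1
    V = C @ grads @ fit.robust_cov @ grads.T @ C.T
    if np.abs(V).max() < 1e-300:
        if np.abs(diff).max() < 1e-12:
            # Degenerate but consistent: no contrast and no uncertainty.
            return 0.0, df, 1.0
        raise GEEError("singular contrast covariance in joint Wald test")
    w, Q = np.linalg.eigh(V)
    rank = int((w > w.max() * 1e-10).sum())
    if rank == 0:
        raise GEEError("singular contrast covariance in joint Wald test")
    if rank < df:
        warnings.warn(
            f"contrast covariance has rank {rank} < {df} (few top-level "
            "clusters); using a rank-adjusted Wald test", stacklevel=2)
        keep = w > w.max() * 1e-10
        proj = Q[:, keep].T @ diff
        stat = float(proj @ (proj / w[keep]))
        return stat, rank, float(chi2.sf(stat, rank))
    stat = float(diff @ np.linalg.solve(V, diff))
    return stat, df, float(chi2.sf(stat, df))


def odds_table(fit: GEEFit, level: float = 0.95) -> pd.DataFrame:
    """Exponentiated coefficients with robust Wald confidence intervals."""
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.robust_se().to_numpy()
    beta = fit.beta
    return pd.DataFrame(
        {
            "odds_ratio": np.exp(beta),
            "lower": np.exp(beta - z * se),
            "upper": np.exp(beta + z * se),
        },
        index=fit.params.index,
    )


@dataclass
class RiskTable:
    """Marginal risks with CIs per (patient factor, group) and Wald tests."""

    frame: pd.DataFrame  # columns: factor, group, risk, lower, upper, n
    wald: pd.DataFrame  # columns: factor, statistic, df, p
    outcome: str
    adjusted: bool

    def pivot(self) -> pd.DataFrame:
        """Wide layout: one row per factor, risk (CI) per group, p-value."""
        wide = self.frame.pivot(index="factor", columns="group", values="risk")
        wide.columns = [f"group{g}" for g in wide.columns]
        return wide.join(self.wald.set_index("factor")["p"])

    def to_json(self, path) -> None:
        payload = {
            "outcome": self.outcome,
            "adjusted": self.adjusted,
            "risks": self.frame.to_dict(orient="records"),
            "wald": self.wald.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def risk_table(fit: GEEFit, design: DesignMatrix, level: float = 0.95) -> RiskTable:
    """Marginal risk, CI, and qualifying-visit count for every cell."""
    rows = []
    wald_rows = []
    for j in range(1, design.k + 1):
        sel = _qualifying_rows(design, j)
        for g in range(1, design.n_groups + 1):
            risk, lo, hi = marginal_risk_ci(fit, design, j, g, level=level)
            rows.append({"factor": j, "group": g, "risk": risk,
                         "lower": lo, "upper": hi, "n": int(sel.sum())})
        stat, df, pval = joint_wald_equal_risk(fit, design, j)
        wald_rows.append({"factor": j, "statistic": stat, "df": df, "p": pval})
    return RiskTable(
        frame=pd.DataFrame(rows),
        wald=pd.DataFrame(wald_rows),
        outcome=design.outcome,
        adjusted=design.adjusted,
    )
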