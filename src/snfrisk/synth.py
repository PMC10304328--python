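"""Synthetic SNF claims generator with known latent structure.

Every downstream stage of the pipeline (factor reduction, facility
grouping, GEE risk estimation) can be tested for parameter recovery
against the :class:`GroundTruth` object emitted here.

Correlated binary outcomes are generated through latent Gaussian random
intercepts (state + person) on the logit scale.  Because GEE estimates a
*marginal* model, the implied marginal quantities (risks, coefficients)
are computed by Gauss-Hermite integration over the random intercepts and
serve as the recovery targets.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.special import expit, logit
from scipy.stats import norm

from .config import (
    CONTROL_NAMES,
    ConfigError,
    OutcomeCoefs,
    RACE_LEVELS,
    RACE_PROBS,
    SynthConfig,
)

__all__ = [
    "GroundTruth",
    "PatientData",
    "FacilityData",
    "simulate_patients",
    "simulate_facilities",
    "simulate_claims",
    "simulate",
    "gh_logistic_mean",
    "gh_marginal_coefs",
    "indicator_columns",
    "facility_columns",
]

# Generating moments of the control covariates (age in years, hospital
# length of stay in days); values typical of Medicare SNF admissions.
AGE_MEAN, AGE_SD = 78.5, 9.9
FEMALE_RATE = 0.626
COMPLICATION_RATE = 0.64
LOS_MEAN, LOS_SD = 6.2, 5.0

IND_PREFIX = "ind_"
FAC_PREFIX = "fac_"


def indicator_columns(n_vars: int) -> list[str]:
    width = max(4, len(str(n_vars)))
    return [f"{IND_PREFIX}{i:0{width}d}" for i in range(1, n_vars + 1)]


def facility_columns(n_vars: int) -> list[str]:
    width = max(3, len(str(n_vars)))
    return [f"{FAC_PREFIX}{i:0{width}d}" for i in range(1, n_vars + 1)]


# ---------------------------------------------------------------------------
# Gauss-Hermite helpers


def gh_logistic_mean(eta, sd_state: float, sd_person: float, n_nodes: int = 21):
    """E[expit(eta + u_s + u_p)] with u_s ~ N(0, sd_state^2), u_p ~ N(0, sd_person^2).

    Computed by a tensor-product Gauss-Hermite rule over the two random
    intercepts; degenerate (zero-SD) components collapse automatically.
    """
    eta = np.asarray(eta, dtype=float)
    sd = float(np.hypot(sd_state, sd_person))
    if sd == 0.0:
        return expit(eta)
    # The two independent intercepts enter additively, so their sum is a
    # single N(0, sd_state^2 + sd_person^2) variable and one quadrature
    # dimension is exact.
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    weights = weights / np.sqrt(np.pi)
    out = np.zeros_like(eta)
    shift = np.sqrt(2.0) * sd * nodes
    for s, w in zip(shift, weights):
        out += w * expit(eta + s)
    return out


def gh_marginal_coefs(
    coefs: OutcomeCoefs,
    sd_state: float,
    sd_person: float,
    k: int,
    n_nodes: int = 30,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Population marginal logistic coefficients implied by a conditional model.

    For a model with linear predictor ``intercept + factor_slopes . f``
    (no group or control terms) over covariates ``f ~ N(0, I_k)``, the
    marginal visit-level success probability is ``p(f) = E_u expit(eta + u)``.
    This solves the population logistic score equation

        E_f[ x(f) (expit(x(f)' b) - p(f)) ] = 0,   x(f) = (1, f),

    by Newton iteration over a tensor-product Gauss-Hermite grid for f.
    The result is the probability limit of a marginal (GEE) logistic fit.
    """
    if np.any(coefs.group_offsets != 0) or np.any(coefs.interactions != 0):
        raise ConfigError("gh_marginal_coefs requires zero group/interaction terms")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    f1 = np.sqrt(2.0) * nodes
    w1 = weights / np.sqrt(np.pi)
    grids = np.meshgrid(*([f1] * k), indexing="ij")
    F = np.column_stack([g.ravel() for g in grids])  # (n_nodes^k, k)
    wgrids = np.meshgrid(*([w1] * k), indexing="ij")
    W = np.prod(np.column_stack([g.ravel() for g in wgrids]), axis=1)
    eta = coefs.intercept + F @ coefs.factor_slopes[:k]
    p_true = gh_logistic_mean(eta, sd_state, sd_person)
    X = np.column_stack([np.ones(len(F)), F])
    b = np.zeros(k + 1)
    b[0] = coefs.intercept
    b[1:] = coefs.factor_slopes[:k]
    for _ in range(max_iter):
        mu = expit(X @ b)
        score = X.T @ (W * (p_true - mu))
        H = (X * (W * mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(H, score)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    return b


# ---------------------------------------------------------------------------
# Simulation stages


@dataclass
class PatientData:
    """Patient factor scores and per-visit indicator draws."""

    scores: np.ndarray  # (n_patients, k_patient)
    visits: pd.DataFrame  # patient_id + binary indicator columns, one row/visit


@dataclass
class FacilityData:
    """Facility table with its generating factor structure."""

    table: pd.DataFrame  # snf_id + facility variable columns
    groups: np.ndarray  # true group label per SNF, 0-based
    scores: np.ndarray  # (n_snfs, k_snf) true factor scores
    loadings: np.ndarray  # (n_snf_vars, k_snf)
    centroids: np.ndarray  # (n_groups, k_snf)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_patient_scores: np.ndarray
    true_loadings: np.ndarray  # patient variables x k_patient
    true_snf_scores: np.ndarray
    true_snf_loadings: np.ndarray
    true_snf_groups: np.ndarray  # 0-based group per SNF
    centroids: np.ndarray
    outcome_coefs: Mapping[str, OutcomeCoefs]
    re_sd_state: float
    re_sd_person: float
    #: outcome -> (k_patient, n_groups) marginal risk for a +1 SD
    #: subpopulation on each factor, assigned to each group.
    true_marginal_risks: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_patient_scores": self.true_patient_scores.tolist(),
            "true_loadings": self.true_loadings.tolist(),
            "true_snf_scores": self.true_snf_scores.tolist(),
            "true_snf_loadings": self.true_snf_loadings.tolist(),
            "true_snf_groups": self.true_snf_groups.tolist(),
            "centroids": self.centroids.tolist(),
            "re_sd_state": self.re_sd_state,
            "re_sd_person": self.re_sd_person,
            "outcome_coefs": {
                name: {
                    "intercept": c.intercept,
                    "factor_slopes": c.factor_slopes.tolist(),
                    "group_offsets": c.group_offsets.tolist(),
                    "interactions": c.interactions.tolist(),
                    "control_slopes": dict(c.control_slopes),
                }
                for name, c in self.outcome_coefs.items()
            },
            "true_marginal_risks": {
                name: risks.tolist() for name, risks in self.true_marginal_risks.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _loading_matrix(primary: np.ndarray, mags: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((len(primary), k))
    L[np.arange(len(primary)), primary] = mags
    return L


def simulate_patients(config: SynthConfig, rng: np.random.Generator | None = None) -> PatientData:
    """Draw patient factor scores and per-visit binary indicators.

    Scores are iid standard normal per factor.  For variable v with
    primary factor j and loading magnitude lambda_v, each visit's
    indicator is Bernoulli(expit(alpha_v + lambda_v * score_j)) with
    alpha_v = logit(base_rate_v), so the configured base rate is the
    exact prevalence when lambda_v = 0.  A patient's visits reuse the
    same factor scores but redraw the indicators.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n_patients, config.k_patient
    scores = rng.standard_normal((n, k))
    n_visits = 1 + rng.poisson(config.visit_rate, size=n)
    patient_of_visit = np.repeat(np.arange(n), n_visits)

    primary, mags = config.loading_spec
    alpha = logit(config.base_rates)
    eta = alpha[None, :] + scores[patient_of_visit][:, primary] * mags[None, :]
    indicators = (rng.random(eta.shape) < expit(eta)).astype(np.int8)

    visits = pd.DataFrame(indicators, columns=indicator_columns(config.n_patient_vars))
    visits.insert(0, "patient_id", patient_of_visit)
    return PatientData(scores=scores, visits=visits)


def simulate_facilities(config: SynthConfig, rng: np.random.Generator | None = None) -> FacilityData:
    """Draw the facility table with cluster structure in factor space.

    Group centroids are placed in k_snf-dimensional factor space with a
    minimum pairwise separation of ``group_sep``; facility
    scores are centroid + isotropic Gaussian noise; observed variables
    are loadings x scores + unique noise, with the leading count-like
    block rescaled, floored at zero, and rounded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G, k = config.n_groups, config.k_snf
    if k >= G - 1:
        # Regular simplex: every pair of centroids exactly group_sep apart,
        # randomly oriented.  This is the canonical "G separated groups"
        # geometry; a random layout would leave some pairs far more
        # separated than others.
        V = np.eye(G) - 1.0 / G
        Q, _ = np.linalg.qr(V.T)
        P = (V @ Q[:, :G - 1]) * (config.group_sep / np.sqrt(2.0))
        centroids = np.zeros((G, k))
        centroids[:, :G - 1] = P
        A = rng.standard_normal((k, k))
        Qr, _ = np.linalg.qr(A)
        centroids = centroids @ Qr.T
    else:
        # Too few dimensions for an equidistant layout: random directions
        # scaled so the closest pair is group_sep apart.
        raw = rng.standard_normal((G, k))
        dmin = pdist(raw).min()
        if dmin <= 0:  # pragma: no cover - essentially impossible
            raise ConfigError("degenerate centroid draw")
        centroids = raw * (config.group_sep / dmin)

    # Every group is guaranteed at least one facility.
    base = np.arange(G)
    rest = rng.choice(G, size=config.n_snfs - G, p=config.group_weights)
    groups = rng.permutation(np.concatenate([base, rest]))

    scores = centroids[groups] + config.group_sd * rng.standard_normal((config.n_snfs, k))

    primary, mags = config.snf_loading_spec
    L = _loading_matrix(primary, mags, k)
    unique_sd = np.sqrt(np.clip(1.0 - mags**2, 0.0, None))
    X = scores @ L.T + rng.standard_normal((config.n_snfs, config.n_snf_vars)) * unique_sd

    n_count = int(round(config.count_like_frac * config.n_snf_vars))
    if n_count:
        v = np.arange(n_count)
        m = 10.0 + 90.0 * ((v * 37) % 97) / 97.0  # deterministic spread of scales
        s = 0.3 * m
        X[:, :n_count] = np.round(np.clip(m + s * X[:, :n_count], 0.0, None))

    table = pd.DataFrame(X, columns=facility_columns(config.n_snf_vars))
    table.insert(0, "snf_id", np.arange(config.n_snfs))
    return FacilityData(table=table, groups=groups, scores=scores, loadings=L,
                        centroids=centroids)


def _draw_controls(config, rng, patient_of_visit, scores):
    n_pat = config.n_patients
    age_p = AGE_MEAN + AGE_SD * rng.standard_normal(n_pat)
    female_p = (rng.random(n_pat) < FEMALE_RATE).astype(np.int8)
    race_p = rng.choice(
        len(RACE_LEVELS), size=n_pat, p=np.asarray(RACE_PROBS) / np.sum(RACE_PROBS))
    if config.confound_controls:
        age_p = age_p + 4.0 * scores[:, 0]
    nv = len(patient_of_visit)
    compl_logit = logit(COMPLICATION_RATE)
    if config.confound_controls:
        compl_p = expit(compl_logit + 0.5 * scores[patient_of_visit, 0])
    else:
        compl_p = np.full(nv, COMPLICATION_RATE)
    complication = (rng.random(nv) < compl_p).astype(np.int8)
    # Gamma length-of-stay matching the target mean/SD, floored at one day.
    shape = (LOS_MEAN / LOS_SD) ** 2
    los = np.maximum(1.0, np.round(rng.gamma(shape, LOS_MEAN / shape, size=nv), 1))
    return {
        "age": np.round(age_p[patient_of_visit], 1),
        "female": female_p[patient_of_visit],
        "race": np.asarray(RACE_LEVELS)[race_p[patient_of_visit]],
        "complication": complication,
        "los": los,
    }


def _control_eta(controls: Mapping[str, np.ndarray], slopes: Mapping[str, float]) -> np.ndarray:
    """Contribution of mean-centered controls to the linear predictor."""
    centers = {"age": AGE_MEAN, "female": FEMALE_RATE,
               "complication": COMPLICATION_RATE, "los": LOS_MEAN}
    eta = np.zeros(len(next(iter(controls.values()))))
    for name, slope in slopes.items():
        eta = eta + slope * (np.asarray(controls[name], dtype=float) - centers[name])
    return eta


def _true_marginal_risks(config: SynthConfig, rng: np.random.Generator,
                         n_draws: int = 20000) -> dict[str, np.ndarray]:
    """Marginal risk per (factor, group) for the +1 SD subpopulation.

    Averages the Gauss-Hermite-integrated visit-level probability over the
    generating distribution of the other factors and controls, with the
    index factor drawn from its N(0,1) distribution truncated above +1.
    """
    k, G = config.k_patient, config.n_groups
    out: dict[str, np.ndarray] = {}
    # Control draws (shared across outcomes/cells; centered contribution only)
    controls = {
        "age": AGE_MEAN + AGE_SD * rng.standard_normal(n_draws),
        "female": (rng.random(n_draws) < FEMALE_RATE).astype(float),
        "complication": (rng.random(n_draws) < COMPLICATION_RATE).astype(float),
        "los": np.maximum(1.0, rng.gamma((LOS_MEAN / LOS_SD) ** 2,
                                         LOS_SD**2 / LOS_MEAN, size=n_draws)),
    }
    f_all = rng.standard_normal((n_draws, k))
    # Truncated-normal draws for the index factor: f_j | f_j > 1.
    u = rng.random(n_draws)
    f_trunc = norm.ppf(norm.cdf(1.0) + u * (1.0 - norm.cdf(1.0)))
    for name, coefs in config.outcome_coefs.items():
        risks = np.empty((k, G))
        ctrl = _control_eta(controls, coefs.control_slopes)
        for j in range(k):
            f = f_all.copy()
            f[:, j] = f_trunc
            eta_base = coefs.intercept + f @ coefs.factor_slopes + ctrl
            for g in range(G):
                eta = eta_base + coefs.group_offsets[g] + f @ coefs.interactions[:, g]
                risks[j, g] = gh_logistic_mean(
                    eta, config.re_sd_state, config.re_sd_person).mean()
        if not ((risks > 0) & (risks < 1)).all():  # pragma: no cover
            raise ConfigError("true marginal risks fell outside (0, 1)")
        out[name] = risks
    return out


def simulate_claims(
    patients: PatientData,
    facilities: FacilityData,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Assemble the claim table and its ground truth.

    Each patient is assigned one state and each visit one SNF; outcomes
    are Bernoulli(expit(eta + u_state + u_person)) with independent
    Gaussian random intercepts per outcome, which induces correlation
    between claims from the same person and, more weakly, the same state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients
    visits = patients.visits
    patient_of_visit = visits["patient_id"].to_numpy()
    nv = len(visits)

    patient_state = rng.integers(0, config.n_states, size=n_pat)

    if config.group_pref_strength > 0:
        pref = rng.integers(0, config.n_groups, size=n_pat)
        w = np.ones((nv, config.n_snfs))
        same = facilities.groups[None, :] == pref[patient_of_visit][:, None]
        w = w + config.group_pref_strength * same
        w = w / w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        snf_of_visit = (cum < rng.random((nv, 1))).sum(axis=1)
    else:
        snf_of_visit = rng.integers(0, config.n_snfs, size=nv)
    group_of_visit = facilities.groups[snf_of_visit]

    controls = _draw_controls(config, rng, patient_of_visit, patients.scores)

    f = patients.scores[patient_of_visit]
    claims = visits.copy()
    claims.insert(0, "claim_id", np.arange(nv))
    claims.insert(2, "state_id", patient_state[patient_of_visit])
    claims.insert(3, "snf_id", snf_of_visit)
    for name in ("age", "female", "race", "complication", "los"):
        claims[name] = controls[name]
    if config.with_discharge_date:
        # Days since study start over an 8-year window; no time trend.
        claims["discharge_date"] = rng.integers(0, 8 * 365, size=nv)

    for name, coefs in config.outcome_coefs.items():
        eta = (coefs.intercept
               + f @ coefs.factor_slopes
               + coefs.group_offsets[group_of_visit]
               + np.einsum("ij,ij->i", f, coefs.interactions[:, group_of_visit].T)
               + _control_eta(controls, coefs.control_slopes))
        u_state = rng.normal(0.0, config.re_sd_state, size=config.n_states)
        u_person = rng.normal(0.0, config.re_sd_person, size=n_pat)
        eta = eta + u_state[patient_state[patient_of_visit]] + u_person[patient_of_visit]
        claims[name] = (rng.random(nv) < expit(eta)).astype(np.int8)

    claims["excluded"] = (rng.random(nv) < config.exclusion_rate).astype(np.int8)

    truth = GroundTruth(
        true_patient_scores=patients.scores,
        true_loadings=_loading_matrix(*config.loading_spec, config.k_patient),
        true_snf_scores=facilities.scores,
        true_snf_loadings=facilities.loadings,
        true_snf_groups=facilities.groups,
        centroids=facilities.centroids,
        outcome_coefs=config.outcome_coefs,
        re_sd_state=config.re_sd_state,
        re_sd_person=config.re_sd_person,
        true_marginal_risks=_true_marginal_risks(
            config, np.random.default_rng(rng.integers(2**31))),
    )
    return claims, truth


def simulate(config: SynthConfig, seed: int | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Run all three simulation stages with deterministic sub-streams.

    Returns (claims table, facility table, ground truth).
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_pat, s_fac, s_claims = root.spawn(3)
    patients = simulate_patients(config, np.random.default_rng(s_pat))
    facilities = simulate_facilities(config, np.random.default_rng(s_fac))
    claims, truth = simulate_claims(patients, facilities, config,
                                    np.random.default_rng(s_claims))
    return claims, facilities.table, truth
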