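"""Configuration objects for the synthetic claims generator.

The generator emulates the structure of skilled-nursing-facility (SNF)
claims: many binary patient indicators (comorbidities, diagnosis codes)
driven by a low-dimensional latent factor model, facility variables driven
by a small factor model with cluster structure, multiple claims per
patient, state- and person-level outcome correlation, and logistic
outcomes with factor-by-facility-group interaction effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ConfigError",
    "OutcomeCoefs",
    "SynthConfig",
    "RACE_LEVELS",
    "RACE_PROBS",
    "default_outcome_coefs",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


#: Race/ethnicity categories carried on each claim, with a population mix
#: resembling Midwestern Medicare fee-for-service claims.
RACE_LEVELS = (
    "White",
    "Black",
    "Hispanic",
    "AsianPacific",
    "NativeAmerican",
    "Other",
    "Unknown",
)
RACE_PROBS = (0.889, 0.084, 0.008, 0.005, 0.003, 0.007, 0.004)

#: Names of scalar control covariates whose slopes may enter the outcome model.
CONTROL_NAMES = ("age", "female", "complication", "los")


@dataclass
class OutcomeCoefs:
    """Generating coefficients for one binary outcome, on the log-odds scale.

    The linear predictor for a visit by patient p assigned to an SNF in
    (true) group g is

        eta = intercept + sum_j factor_slopes[j] * f_pj
              + group_offsets[g] + sum_j interactions[j, g] * f_pj
              + sum_c control_slopes[c] * (x_c - mean_c)

    with the control covariates centered at their generating means.
    """

    intercept: float
    factor_slopes: np.ndarray
    group_offsets: np.ndarray
    interactions: np.ndarray  # shape (k_patient, n_groups)
    control_slopes: Mapping[str, float] = field(default_factory=dict)

    def validate(self, k: int, n_groups: int) -> None:
        self.factor_slopes = np.asarray(self.factor_slopes, dtype=float)
        self.group_offsets = np.asarray(self.group_offsets, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        if self.factor_slopes.shape != (k,):
            raise ConfigError(f"factor_slopes must have shape ({k},)")
        if self.group_offsets.shape != (n_groups,):
            raise ConfigError(f"group_offsets must have shape ({n_groups},)")
        if self.interactions.shape != (k, n_groups):
            raise ConfigError(f"interactions must have shape ({k}, {n_groups})")
        for name in self.control_slopes:
            if name not in CONTROL_NAMES:
                raise ConfigError(f"unknown control slope {name!r}")


def default_outcome_coefs(k: int, n_groups: int) -> dict[str, OutcomeCoefs]:
    """Default generating coefficients for the two 60-day outcomes.

    Intercepts correspond to marginal event rates of roughly 30%
    (rehospitalization) and 13% (mortality), in line with published
    fee-for-service SNF cohorts.  Factor slopes alternate in sign with
    moderate magnitude; group offsets are small; interactions default to
    zero so that group effects are homogeneous unless explicitly planted.
    """
    j = np.arange(k)
    rehosp = OutcomeCoefs(
        intercept=-0.84,
        factor_slopes=np.where(j % 2 == 0, 0.25, -0.15),
        group_offsets=np.resize([0.0, 0.15, -0.10, 0.05], n_groups),
        interactions=np.zeros((k, n_groups)),
        control_slopes={"age": 0.02, "female": -0.10, "complication": 0.30, "los": 0.03},
    )
    death = OutcomeCoefs(
        intercept=-1.89,
        factor_slopes=np.where(j % 2 == 0, 0.20, -0.10),
        group_offsets=np.resize([0.0, -0.12, 0.08, 0.0], n_groups),
        interactions=np.zeros((k, n_groups)),
        control_slopes={"age": 0.04, "female": -0.15, "complication": 0.25, "los": 0.02},
    )
    rehosp.group_offsets[0] = 0.0
    death.group_offsets[0] = 0.0
    return {"rehosp60": rehosp, "death60": death}


def _default_base_rates(n_vars: int) -> np.ndarray:
    """Marginal prevalences spread on the logit scale between 0.05 and 0.5.

    Claims indicator panels mix common comorbidities (hypertension ~70%)
    with rare diagnosis codes (<1%); a 5-50% spread keeps every indicator
    informative at desk scale while preserving heterogeneity.
    """
    lo, hi = np.log(0.05 / 0.95), np.log(0.5 / 0.5)
    logits = np.linspace(lo, hi, max(n_vars, 2))[:n_vars]
    return 1.0 / (1.0 + np.exp(-logits))


def _default_loading_spec(n_vars: int, k: int, magnitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Round-robin primary-factor assignment with a common loading magnitude."""
    primary = np.arange(n_vars) % k
    mags = np.full(n_vars, float(magnitude))
    return primary, mags


@dataclass
class SynthConfig:
    """Study conditions for one synthetic claims draw.

    Variable counts default to the scale of a real claims panel (416
    patient indicators, 154 facility variables, 12 patient factors, 3
    facility factors, 4 facility groups) with patient/facility counts
    reduced to desk scale.
    """

    n_patients: int = 4000
    n_snfs: int = 400
    n_states: int = 3
    n_patient_vars: int = 416
    n_snf_vars: int = 154
    k_patient: int = 12
    k_snf: int = 3
    n_groups: int = 4
    #: (primary factor index, loading magnitude) per patient variable.
    loading_spec: tuple[np.ndarray, np.ndarray] | None = None
    #: Marginal prevalence per patient indicator, strictly inside (0, 1).
    base_rates: np.ndarray | None = None
    #: (primary factor index, loading magnitude) per facility variable.
    snf_loading_spec: tuple[np.ndarray, np.ndarray] | None = None
    #: Claims per patient are 1 + Poisson(visit_rate); the default 0.6
    #: gives ~1.6 visits/patient, similar to observed discharge/patient
    #: ratios in fee-for-service claims.
    visit_rate: float = 0.6
    outcome_coefs: dict[str, OutcomeCoefs] | None = None
    re_sd_state: float = 0.1
    re_sd_person: float = 0.5
    exclusion_rate: float = 0.055
    #: Mixing weights of the facility groups (uneven by default, largest first).
    group_weights: np.ndarray | None = None
    #: Pairwise centroid distance: exact for every pair when the factor
    #: space admits an equidistant (regular simplex) layout, i.e. when
    #: k_snf >= n_groups - 1, otherwise the minimum pairwise distance of
    #: a random layout.  The default is six within-group SDs.
    group_sep: float = 6.0
    #: Within-group SD of facility factor scores.
    group_sd: float = 1.0
    #: 0 = visits assigned to SNFs uniformly; > 0 biases each patient's
    #: visits toward one preferred group (a free parameter of the design,
    #: not an inference target).
    group_pref_strength: float = 0.0
    #: When True, age and complication depend on patient factor 1 so that
    #: adjusted and unadjusted risk estimates diverge.
    confound_controls: bool = False
    #: Leading fraction of facility variables treated as counts (floored
    #: at zero and rounded, like bed or staff counts).
    count_like_frac: float = 0.6
    #: When True, each claim carries a discharge_date column (days since
    #: the study start) usable as an extra control.
    with_discharge_date: bool = False
    loading_magnitude: float = 0.7
    snf_loading_magnitude: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_snfs", "n_states", "n_patient_vars",
                     "n_snf_vars", "k_patient", "k_snf", "n_groups"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.k_patient >= self.n_patient_vars:
            raise ConfigError("k_patient must be < n_patient_vars")
        if self.k_snf >= self.n_snf_vars:
            raise ConfigError("k_snf must be < n_snf_vars")
        if self.n_groups < 2:
            raise ConfigError("n_groups must be >= 2")
        if self.n_snfs < self.n_groups:
            raise ConfigError("n_snfs must be >= n_groups")
        if not (0.0 <= self.exclusion_rate < 1.0):
            raise ConfigError("exclusion_rate must lie in [0, 1)")
        if self.re_sd_state < 0 or self.re_sd_person < 0:
            raise ConfigError("random-intercept SDs must be >= 0")
        if self.visit_rate < 0:
            raise ConfigError("visit_rate must be >= 0")

        if self.loading_spec is None:
            self.loading_spec = _default_loading_spec(
                self.n_patient_vars, self.k_patient, self.loading_magnitude)
        primary, mags = self.loading_spec
        primary = np.asarray(primary, dtype=int)
        mags = np.asarray(mags, dtype=float)
        if primary.shape != (self.n_patient_vars,) or mags.shape != (self.n_patient_vars,):
            raise ConfigError("loading_spec arrays must have length n_patient_vars")
        if primary.min() < 0 or primary.max() >= self.k_patient:
            raise ConfigError("loading_spec primary factors out of range")
        if (mags < 0).any() or (mags > 1).any():
            raise ConfigError("loading magnitudes must lie in [0, 1]")
        self.loading_spec = (primary, mags)

        if self.base_rates is None:
            self.base_rates = _default_base_rates(self.n_patient_vars)
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        if self.base_rates.shape != (self.n_patient_vars,):
            raise ConfigError("base_rates must have length n_patient_vars")
        if (self.base_rates <= 0).any() or (self.base_rates >= 1).any():
            raise ConfigError("base_rates must lie strictly inside (0, 1)")

        if self.snf_loading_spec is None:
            self.snf_loading_spec = _default_loading_spec(
                self.n_snf_vars, self.k_snf, self.snf_loading_magnitude)
        sp, sm = self.snf_loading_spec
        sp = np.asarray(sp, dtype=int)
        sm = np.asarray(sm, dtype=float)
        if sp.shape != (self.n_snf_vars,) or sm.shape != (self.n_snf_vars,):
            raise ConfigError("snf_loading_spec arrays must have length n_snf_vars")
        if sp.min() < 0 or sp.max() >= self.k_snf:
            raise ConfigError("snf_loading_spec primary factors out of range")
        if (sm < 0).any() or (sm > 1).any():
            raise ConfigError("snf loading magnitudes must lie in [0, 1]")
        self.snf_loading_spec = (sp, sm)

        if self.group_weights is None:
            if self.n_groups == 4:
                self.group_weights = np.array([0.514, 0.208, 0.158, 0.120])
            else:
                self.group_weights = np.full(self.n_groups, 1.0 / self.n_groups)
        self.group_weights = np.asarray(self.group_weights, dtype=float)
        if self.group_weights.shape != (self.n_groups,):
            raise ConfigError("group_weights must have length n_groups")
        if (self.group_weights <= 0).any():
            raise ConfigError("group_weights must be positive")
        self.group_weights = self.group_weights / self.group_weights.sum()

        if self.outcome_coefs is None:
            self.outcome_coefs = default_outcome_coefs(self.k_patient, self.n_groups)
        for coefs in self.outcome_coefs.values():
            coefs.validate(self.k_patient, self.n_groups)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.outcome_coefs)
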