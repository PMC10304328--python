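"""Named benchmark designs used by the recovery tests and acceptance script.

Each function returns a :class:`~snfrisk.config.SynthConfig` describing
one fixed study condition.  The designs are deliberately frozen here so
that every consumer (tests, acceptance script, documentation examples)
measures the same thing.
"""
from __future__ import annotations

import numpy as np

from .config import OutcomeCoefs, SynthConfig

__all__ = [
    "factor_recovery_config",
    "cluster_recovery_config",
    "gee_marginal_config",
    "wald_null_config",
    "planted_interaction_config",
]


def factor_recovery_config(seed: int, n_patients: int = 5000) -> SynthConfig:
    """Factor-recovery benchmark: 100 indicators, 6 factors, loading 0.8.

    Base rates are held at 0.5 (maximally informative balanced
    indicators) so the benchmark isolates structural recovery from
    prevalence effects.
    """
    n_vars, k = 100, 6
    return SynthConfig(
        n_patients=n_patients,
        n_snfs=20,
        n_patient_vars=n_vars,
        k_patient=k,
        n_snf_vars=8,
        k_snf=2,
        n_groups=2,
        loading_spec=(np.arange(n_vars) % k, np.full(n_vars, 0.8)),
        base_rates=np.full(n_vars, 0.5),
        seed=seed,
    )


def cluster_recovery_config(seed: int, n_snfs: int = 300) -> SynthConfig:
    """Facility-grouping benchmark: 4 groups, centroid separation 6x noise SD."""
    return SynthConfig(
        n_patients=50,
        n_snfs=n_snfs,
        n_patient_vars=6,
        k_patient=2,
        n_snf_vars=24,
        k_snf=3,
        n_groups=4,
        group_sep=6.0,
        group_sd=1.0,
        seed=seed,
    )


def _slim_outcome(k: int, n_groups: int, intercept: float, slopes,
                  offsets=None, interactions=None) -> dict[str, OutcomeCoefs]:
    return {
        "rehosp60": OutcomeCoefs(
            intercept=intercept,
            factor_slopes=np.asarray(slopes, dtype=float),
            group_offsets=np.zeros(n_groups) if offsets is None else np.asarray(offsets),
            interactions=np.zeros((k, n_groups)) if interactions is None
            else np.asarray(interactions),
            control_slopes={},
        )
    }


def gee_marginal_config(seed: int, n_patients: int = 2000) -> SynthConfig:
    """Marginal-coefficient benchmark for CI coverage.

    Two factors with conditional slopes (0.4, -0.3), intercept -1, a
    person-level random intercept of SD 0.8 and no state, group, or
    control effects, so the implied marginal logistic coefficients are
    exactly computable by Gauss-Hermite projection.
    """
    k, G = 2, 2
    return SynthConfig(
        n_patients=n_patients,
        n_snfs=20,
        n_states=10,
        n_patient_vars=4,
        k_patient=k,
        n_snf_vars=4,
        k_snf=1,
        n_groups=G,
        outcome_coefs=_slim_outcome(k, G, -1.0, [0.4, -0.3]),
        re_sd_state=0.0,
        re_sd_person=0.8,
        exclusion_rate=0.0,
        seed=seed,
    )


def wald_null_config(seed: int, n_patients: int = 1000) -> SynthConfig:
    """No-group-effect generator for the joint Wald type-I benchmark."""
    k, G = 2, 4
    return SynthConfig(
        n_patients=n_patients,
        n_snfs=120,
        n_states=10,
        n_patient_vars=4,
        k_patient=k,
        n_snf_vars=4,
        k_snf=1,
        n_groups=G,
        group_weights=np.full(G, 0.25),
        outcome_coefs=_slim_outcome(k, G, -0.8, [0.3, -0.3]),
        re_sd_state=0.0,
        re_sd_person=0.5,
        exclusion_rate=0.0,
        seed=seed,
    )


def planted_interaction_config(seed: int, delta: float = 0.5,
                               n_patients: int = 1200) -> SynthConfig:
    """End-to-end benchmark with a planted (factor 1, group 2) interaction.

    The generator's true group 2 (0-based index 1) carries a positive
    interaction ``delta`` with patient factor 1, so visits scoring high
    on factor 1 have elevated risk in that group and the final risk
    table should rank it highest for the matched fitted factor.
    """
    k, G = 3, 4
    interactions = np.zeros((k, G))
    interactions[0, 1] = delta
    return SynthConfig(
        n_patients=n_patients,
        n_snfs=160,
        n_states=6,
        n_patient_vars=45,
        k_patient=k,
        n_snf_vars=18,
        k_snf=3,
        n_groups=G,
        group_weights=np.full(G, 0.25),
        loading_spec=(np.arange(45) % k, np.full(45, 0.8)),
        base_rates=np.full(45, 0.4),
        outcome_coefs=_slim_outcome(k, G, -0.8, [0.25, -0.2, 0.15],
                                    interactions=interactions),
        re_sd_state=0.05,
        re_sd_person=0.5,
        seed=seed,
    )
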