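import numpy as np
import pandas as pd
import pytest

from snfrisk import SynthConfig, simulate
from snfrisk.config import OutcomeCoefs


def slim_outcomes(k, n_groups, intercept=-0.8, slopes=None, offsets=None,
                  interactions=None, controls=None):
    """One-outcome coefficient set with everything defaulting to zero."""
    return {
        "rehosp60": OutcomeCoefs(
            intercept=intercept,
            factor_slopes=np.zeros(k) if slopes is None else np.asarray(slopes, float),
            group_offsets=np.zeros(n_groups) if offsets is None else np.asarray(offsets, float),
            interactions=np.zeros((k, n_groups)) if interactions is None
            else np.asarray(interactions, float),
            control_slopes=controls or {},
        )
    }


@pytest.fixture(scope="session")
def tiny_config():
    return SynthConfig(
        n_patients=400, n_snfs=60, n_states=3, n_patient_vars=24, k_patient=3,
        n_snf_vars=12, k_snf=2, n_groups=3, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate(tiny_config)


def true_score_frame(claims: pd.DataFrame, truth, k=None) -> pd.DataFrame:
    """True patient factor scores aligned row-wise with the claim table."""
    S = truth.true_patient_scores[claims["patient_id"].to_numpy()]
    if k is not None:
        S = S[:, :k]
    cols = [f"f{j+1}" for j in range(S.shape[1])]
    return pd.DataFrame(S, index=claims.index, columns=cols)


def true_group_series(truth, n_snfs) -> pd.Series:
    """True SNF groups as 1-based labels indexed by snf_id."""
    return pd.Series(truth.true_snf_groups + 1, index=np.arange(n_snfs), name="group")
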