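import numpy as np
import pandas as pd
import pytest

from aprs.syndata import CohortConfig, generate_cohort


def make_outcomes(times, events, types=None):
    """Outcome table from plain arrays (helper for hand-built fixtures)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if types is None:
        types = np.where(events == 1, "kidney", "none")
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(len(times))],
            "time_years": times,
            "event": events,
            "event_type": types,
        }
    )


def simulate_survival(rng, X, beta, censor_scale=2.0, admin=None):
    """Exponential PH survival draw for a covariate matrix (test oracle aid)."""
    lp = np.asarray(X) @ np.asarray(beta)
    T = rng.exponential(np.exp(-lp))
    C = rng.exponential(censor_scale, len(lp))
    if admin is not None:
        C = np.minimum(C, admin)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    return t, e


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with three planted proteins (per-SD log HRs 0.8/0.5/-0.5)."""
    cfg = CohortConfig(
        n_subjects=400,
        n_proteins=30,
        n_signal=3,
        true_betas=(3.2, 2.0, -2.0),  # per log2 unit; x0.25 spread = per-SD effects
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal anywhere (clinical effects off as well)."""
    cfg = CohortConfig(
        n_subjects=300,
        n_proteins=40,
        n_signal=0,
        true_betas=(),
        clinical_effects={},
        seed=7,
    )
    return generate_cohort(cfg)
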