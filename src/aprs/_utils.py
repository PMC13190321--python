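"""Shared helpers: outcome-table validation, fold construction, sorting."""

from __future__ import annotations

import numpy as np
import pandas as pd

OUTCOME_COLUMNS = ("subject_id", "time_years", "event", "event_type")
EVENT_TYPES = ("kidney", "death", "none")


def check_outcomes(outcomes: pd.DataFrame, require_events: int = 0) -> pd.DataFrame:
    """Validate an outcome table (subject_id, time_years, event[, event_type])."""
    if not isinstance(outcomes, pd.DataFrame):
        raise TypeError("outcomes must be a DataFrame")
    missing = {"subject_id", "time_years", "event"} - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    out = outcomes.copy()
    if "event_type" not in out.columns:
        out["event_type"] = np.where(out["event"].astype(int) == 1, "kidney", "none")
    t = out["time_years"].to_numpy(dtype=float)
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("follow-up times must be finite and non-negative")
    e = out["event"].to_numpy()
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    bad = (out["event"].astype(int) == 0) & (out["event_type"] != "none")
    if bad.any():
        raise ValueError("event=0 rows must have event_type 'none'")
    if int(out["event"].sum()) < require_events:
        raise ValueError(
            f"need at least {require_events} events, got {int(out['event'].sum())}"
        )
    return out


def align_outcomes(X: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Return outcomes row-aligned to X's index (subject ids)."""
    out = check_outcomes(outcomes)
    out = out.set_index("subject_id")
    if X.index.isin(out.index).all():
        out = out.loc[X.index]
    elif len(out) == len(X):
        # ids do not match but row counts do: assume positional alignment
        pass
    else:
        raise ValueError("outcome table does not cover all subjects in X")
    out.index.name = "subject_id"
    return out.reset_index()


def time_event_arrays(outcomes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = outcomes["time_years"].to_numpy(dtype=float)
    e = outcomes["event"].to_numpy(dtype=float)
    return t, e


def stratified_folds(event: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Event-stratified fold labels 0..k-1, deterministic under seed."""
    n = len(event)
    if int(event.sum()) < k:
        raise ValueError(f"{k}-fold CV needs at least {k} events")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.int64)
    for val in (1, 0):
        idx = np.flatnonzero(event == val)
        idx = idx[rng.permutation(len(idx))]
        labels[idx] = np.arange(len(idx)) % k
    return labels


def spawn_seed(seed: int, *salt: int) -> int:
    """Derive a child seed below 2**31 from a parent seed and salts."""
    ss = np.random.SeedSequence([int(seed)] + [int(s) for s in salt])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
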