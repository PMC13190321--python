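"""Turn raw subject-level tables into analysis-ready inputs.

Covers the missingness filter (columns with more than 15% missing are
excluded), chained-equation imputation run separately within training and
test folds, the 2021 race-free CKD-EPI creatinine equation, derivation of
the composite kidney/death outcome with administrative censoring, stratified
train/test splitting, and cross-platform (e.g. Olink-to-SomaScan) imputation
of absent protein targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge, Ridge
from sklearn.model_selection import StratifiedShuffleSplit

from ._utils import check_outcomes, spawn_seed

__all__ = [
    "filter_missing",
    "impute_chained",
    "ImputationResult",
    "ckd_epi_egfr_2021",
    "creatinine_from_egfr",
    "derive_outcome",
    "stratified_split",
    "cross_platform_impute",
]


def filter_missing(matrix: pd.DataFrame, max_missing: float = 0.15):
    """Drop columns with missing fraction strictly greater than ``max_missing``.

    Returns (filtered matrix, report dict with kept/dropped column ids and
    per-column missing fractions).  A column at exactly the threshold is
    retained (the rule is "more than").
    """
    frac = matrix.isna().mean(axis=0)
    keep = frac.index[frac <= max_missing].tolist()
    dropped = frac.index[frac > max_missing].tolist()
    if not keep:
        raise ValueError("all columns exceed the missingness threshold")
    report = {
        "max_missing": max_missing,
        "n_in": matrix.shape[1],
        "n_kept": len(keep),
        "dropped": list(map(str, dropped)),
        "missing_fraction": {str(c): float(f) for c, f in frac.items()},
    }
    return matrix[keep], report


@dataclass
class ImputationResult:
    """Completed datasets from chained-equation imputation."""

    completed: list[pd.DataFrame]
    n_sweeps: int
    columns_imputed: list[str] = field(default_factory=list)

    @property
    def first(self) -> pd.DataFrame:
        return self.completed[0]

    def stacked(self) -> pd.DataFrame:
        """Cell-wise average of the completed datasets."""
        return sum(self.completed) / len(self.completed)


def _mice_pmm(df: pd.DataFrame, rng: np.random.Generator, n_sweeps: int, n_donors: int) -> pd.DataFrame:
    """One chained-equation pass with predictive-mean-matching draws."""
    data = df.to_numpy(dtype=float).copy()
    mask = np.isnan(data)
    cols = np.flatnonzero(mask.any(axis=0))
    # initialize with column means
    col_mean = np.nanmean(data, axis=0)
    for j in cols:
        data[mask[:, j], j] = col_mean[j]
    for _ in range(n_sweeps):
        for j in cols:
            miss = mask[:, j]
            obs = ~miss
            others = [k for k in range(data.shape[1]) if k != j]
            model = BayesianRidge()
            model.fit(data[obs][:, others], data[obs, j])
            pred_obs = model.predict(data[obs][:, others])
            pred_mis = model.predict(data[miss][:, others])
            obs_vals = data[obs, j]
            k = min(n_donors, len(obs_vals))
            for row, pm in zip(np.flatnonzero(miss), pred_mis):
                # donors: observed rows whose predicted mean is closest
                d = np.abs(pred_obs - pm)
                donors = np.argpartition(d, k - 1)[:k]
                data[row, j] = obs_vals[donors[rng.integers(k)]]
    out = df.copy()
    out.iloc[:, :] = data
    return out


def impute_chained(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    n_imputations: int = 5,
    seed: int = 0,
    n_sweeps: int = 5,
    n_donors: int = 5,
):
    """Multiple imputation by chained equations with predictive mean matching.

    Each column with missing values is regressed on all others (Bayesian
    ridge); missing entries are replaced by draws from the ``n_donors``
    observed values whose predicted means are closest.  Training and test
    tables are imputed independently — the test model never sees training
    rows and vice versa — so no information leaks across the split.
    Observed values are never modified.

    Returns an :class:`ImputationResult`, or a pair of them when ``test``
    is given.
    """
    for name, df in (("train", train), ("test", test)):
        if df is None:
            continue
        fully_missing = df.columns[df.isna().all(axis=0)].tolist()
        if fully_missing:
            raise ValueError(f"columns fully missing in {name} fold: {fully_missing}")

    def _run(df: pd.DataFrame, salt: int) -> ImputationResult:
        imputed_cols = df.columns[df.isna().any(axis=0)].tolist()
        if not imputed_cols:
            return ImputationResult([df.copy() for _ in range(n_imputations)], 0, [])
        completed = [
            _mice_pmm(df, np.random.default_rng(spawn_seed(seed, salt, m)), n_sweeps, n_donors)
            for m in range(n_imputations)
        ]
        return ImputationResult(completed, n_sweeps, list(map(str, imputed_cols)))

    train_res = _run(train, 0)
    if test is None:
        return train_res
    return train_res, _run(test, 1)


def ckd_epi_egfr_2021(creatinine, age, sex):
    """2021 race-free CKD-EPI creatinine eGFR (ml/min/1.73 m^2).

    eGFR = 142 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.200
               * 0.9938^age * (1.012 if female)
    with kappa = 0.7 (female) / 0.9 (male), alpha = -0.241 / -0.302.
    """
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    female = _is_female(sex, scr.shape)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be positive")
    if np.any(age < 18):
        raise ValueError("equation applies to adults (age >= 18)")
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr / kappa
    egfr = (
        142.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938**age
        * np.where(female, 1.012, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_from_egfr(egfr, age, sex):
    """Invert the 2021 CKD-EPI equation: creatinine consistent with eGFR."""
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    female = _is_female(sex, egfr.shape)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    base = 142.0 * 0.9938**age * np.where(female, 1.012, 1.0)
    # ratio <= 1 branch: egfr = base * ratio^alpha  (alpha < 0)
    ratio_low = (egfr / base) ** (1.0 / alpha)
    # ratio > 1 branch: egfr = base * ratio^-1.2
    ratio_high = (egfr / base) ** (-1.0 / 1.2)
    ratio = np.where(egfr >= base, np.minimum(ratio_low, 1.0), np.maximum(ratio_high, 1.0))
    scr = ratio * kappa
    return scr if scr.ndim else float(scr)


def _is_female(sex, shape):
    sexarr = np.asarray(sex)
    if sexarr.dtype.kind in "UOS":
        female = np.char.lower(sexarr.astype(str)) == "female"
    else:
        # numeric: 1 = male indicator convention
        female = np.asarray(sexarr) == 0
    return np.broadcast_to(female, shape)


def derive_outcome(
    baseline_egfr: pd.Series,
    egfr_trajectory: pd.DataFrame | None,
    event_records: pd.DataFrame | None,
    horizon: float = 10.0,
    which: str = "composite",
) -> pd.DataFrame:
    """Derive the survival outcome from eGFR decline and clinical events.

    Kidney events are long-term dialysis, ESKD, transplantation, or the first
    visit with a >=40% decline in eGFR from baseline; the composite adds
    all-cause death.  For ``which="kidney"``, death censors; for
    ``which="death"``, kidney events are ignored.  All times are truncated at
    ``horizon`` (events after it count as censoring at the horizon).

    ``event_records`` columns: subject_id, event_type (dialysis / eskd /
    transplant / death), time_years.
    """
    if which not in ("composite", "kidney", "death"):
        raise ValueError("which must be composite, kidney or death")
    if (baseline_egfr <= 0).any():
        raise ValueError("baseline eGFR must be positive")
    subjects = baseline_egfr.index
    kidney_time = pd.Series(np.inf, index=subjects)
    death_time = pd.Series(np.inf, index=subjects)
    followup = pd.Series(float(horizon), index=subjects)

    if egfr_trajectory is not None and len(egfr_trajectory):
        traj = egfr_trajectory.sort_values(["subject_id", "visit_year"], kind="mergesort")
        if (traj["visit_year"] < 0).any():
            raise ValueError("negative visit times")
        for sid, grp in traj.groupby("subject_id", sort=False):
            base = baseline_egfr.get(sid)
            if base is None:
                continue
            declined = grp["egfr"].to_numpy() <= 0.6 * base
            if declined.any():
                t = float(grp["visit_year"].to_numpy()[declined.argmax()])
                kidney_time[sid] = min(kidney_time[sid], t)

    if event_records is not None and len(event_records):
        rec = event_records
        if (rec["time_years"] < 0).any():
            raise ValueError("negative event times")
        for _, row in rec.iterrows():
            sid = row["subject_id"]
            if sid not in subjects:
                continue
            et, tt = str(row["event_type"]).lower(), float(row["time_years"])
            if et in ("dialysis", "eskd", "transplant", "kidney"):
                kidney_time[sid] = min(kidney_time[sid], tt)
            elif et == "death":
                death_time[sid] = min(death_time[sid], tt)
            elif et in ("censor", "loss_to_followup"):
                followup[sid] = min(followup[sid], tt)
            else:
                raise ValueError(f"unknown event type {et!r}")

    if which == "composite":
        etime = np.minimum(kidney_time, death_time)
        label = np.where(kidney_time <= death_time, "kidney", "death")
    elif which == "kidney":
        etime = kidney_time.copy()
        # death censors kidney outcomes
        followup = np.minimum(followup, death_time.replace(np.inf, horizon))
        followup = pd.Series(followup, index=subjects)
        label = np.full(len(subjects), "kidney")
    else:
        etime = death_time.copy()
        label = np.full(len(subjects), "death")

    event = (etime <= np.minimum(followup, horizon)).to_numpy()
    time = np.minimum(np.minimum(etime, followup), horizon)
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "time_years": time.to_numpy(dtype=float),
            "event": event.astype(int),
            "event_type": np.where(event, label, "none"),
        }
    ).reset_index(drop=True)


def stratified_split(outcomes: pd.DataFrame, fraction: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """80/20-style split stratified on the event indicator.

    Returns a table (subject_id, fold) with fold in {train, test}.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    out = check_outcomes(outcomes, require_events=5)
    y = out["event"].to_numpy(dtype=int)
    sss = StratifiedShuffleSplit(n_splits=1, train_size=fraction, random_state=seed)
    tr_idx, te_idx = next(sss.split(np.zeros(len(y)), y))
    fold = np.empty(len(y), dtype=object)
    fold[tr_idx] = "train"
    fold[te_idx] = "test"
    return pd.DataFrame({"subject_id": out["subject_id"], "fold": fold})


def cross_platform_impute(
    source_train: pd.DataFrame,
    target: pd.DataFrame,
    penalty: float = 1.0,
) -> pd.DataFrame:
    """Fill absent target-platform proteins from overlapping ones.

    Overlapping columns of ``target`` are first affinely rescaled to the
    source scale (median/IQR matching, rank-preserving); the absent columns
    (all-missing in ``target`` but present in ``source_train``) are then
    predicted by a multi-output ridge regression fit only on
    ``source_train``.  Observed target values are left untouched (returned
    on their rescaled source scale alongside the imputed columns).
    """
    absent = [c for c in target.columns if target[c].isna().all() and c in source_train.columns]
    overlap = [c for c in target.columns if not target[c].isna().all() and c in source_train.columns]
    if not overlap:
        raise ValueError("no overlapping proteins between platforms")
    rescaled = target[overlap].copy()
    for c in overlap:
        src, tgt = source_train[c], target[c]
        s_iqr = np.subtract(*np.percentile(src.dropna(), [75, 25]))
        t_iqr = np.subtract(*np.percentile(tgt.dropna(), [75, 25]))
        slope = s_iqr / t_iqr if t_iqr > 0 else 1.0
        rescaled[c] = (tgt - tgt.median()) * slope + src.median()
    out = rescaled
    if absent:
        model = Ridge(alpha=penalty)
        model.fit(source_train[overlap], source_train[absent])
        pred = np.asarray(model.predict(rescaled[overlap])).reshape(len(rescaled), len(absent))
        for i, c in enumerate(absent):
            out[c] = pred[:, i]
    extra = [c for c in target.columns if c not in out.columns]
    if extra:
        warnings.warn(f"target columns unknown to the source platform kept as-is: {extra}")
        out = pd.concat([out, target[extra]], axis=1)
    return out[target.columns]
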