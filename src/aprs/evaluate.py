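"""Time-dependent performance evaluation, decision analytics and design tools.

Implements the inverse-probability-of-censoring-weighted (IPCW) metric
framework for survival risk scores: cumulative-case / dynamic-control
time-dependent AUC, confusion-matrix metrics at the Youden-optimal
threshold, survival-weighted metric means

    M_bar = sum_t M_t * S(t) / sum_t S(t),

Kaplan-Meier / log-rank utilities, Aalen-Johansen competing-risk cumulative
incidence, decision-curve net benefit, number needed to treat, and Cox
sample-size calculators (Schoenfeld and events-per-variable).

Unless noted otherwise, AUC and summary report values are on a 0-100% scale;
single confusion-matrix rates are fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from ._utils import check_outcomes, time_event_arrays

__all__ = [
    "TimepointMetrics",
    "EvaluationReport",
    "SampleSizeSpec",
    "censoring_survival",
    "ipcw_weights",
    "time_dependent_auc",
    "threshold_metrics",
    "weighted_mean_metrics",
    "km_logrank",
    "competing_risk_cif",
    "decision_curve",
    "nnt",
    "sample_size",
    "panel_correlation_layout",
    "evaluate_model",
]

_METRICS = ("sensitivity", "specificity", "f1", "accuracy", "mcc", "ppv", "npv")


@dataclass
class TimepointMetrics:
    """Confusion-matrix metrics at one horizon (rates as fractions)."""

    time: float
    threshold: float
    tp: float
    fp: float
    tn: float
    fn: float
    auc: float  # percent
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    mcc: float
    ppv: float
    npv: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvaluationReport:
    """Per-timepoint metrics plus survival-weighted summaries (percent)."""

    timepoints: list[TimepointMetrics]
    weighted_means: dict[str, float]
    tauc: float
    cindex: float
    survival: pd.Series = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.timepoints]).set_index("time")

    def to_dict(self) -> dict:
        return {
            "tauc_pct": self.tauc,
            "cindex_pct": self.cindex,
            "weighted_means_pct": self.weighted_means,
            "timepoints": [m.as_dict() for m in self.timepoints],
        }


def censoring_survival(outcomes: pd.DataFrame) -> KaplanMeierFitter:
    """Kaplan-Meier estimate of the censoring distribution (roles swapped)."""
    out = check_outcomes(outcomes)
    t, e = time_event_arrays(out)
    km = KaplanMeierFitter()
    km.fit(t, 1 - e)
    return km


def _cens_surv_at(km: KaplanMeierFitter, times, left: bool = False) -> np.ndarray:
    """Censoring survival at ``times``; ``left`` gives the left limit S(t-)."""
    tt = np.asarray(times, dtype=float)
    if left:
        tt = np.nextafter(tt, -np.inf)
    return np.asarray(km.predict(tt), dtype=float).reshape(np.shape(times))


def ipcw_weights(outcomes: pd.DataFrame, t: float, cap: float | None = 20.0) -> pd.Series:
    """Per-subject IPCW at horizon ``t``: 1 / P(uncensored).

    Cases (event by t) are weighted by 1/S_c(T_i-); event-free subjects still
    under observation at t by 1/S_c(t); subjects censored before t carry
    weight 0 (they are uninformative at this horizon).  Weights are capped at
    ``cap`` (None disables), with capping logged via a warning.
    """
    out = check_outcomes(outcomes)
    tt, ee = time_event_arrays(out)
    if t < 0 or t > tt.max():
        raise ValueError("t must lie within the observed follow-up range")
    km = censoring_survival(out)
    w = np.zeros(len(tt))
    case = (ee == 1) & (tt <= t)
    ctrl = tt > t
    w[case] = 1.0 / np.clip(_cens_surv_at(km, tt[case], left=True), 1e-12, None)
    w[ctrl] = 1.0 / np.clip(_cens_surv_at(km, [t])[0], 1e-12, None)
    if cap is not None and (w > cap).any():
        import warnings

        warnings.warn(f"{int((w > cap).sum())} IPCW weights capped at {cap}")
        w = np.minimum(w, cap)
    return pd.Series(w, index=out["subject_id"], name="ipcw")


def _risk_array(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        col = "lp" if "lp" in scores.columns else "score"
        return scores[col].to_numpy(dtype=float)
    return np.asarray(scores, dtype=float)


def _auc_at(risk, tt, ee, w) -> float:
    """IPCW Wilcoxon AUC for given case/control weights (fraction)."""
    case = w[0] > 0
    ctrl = w[1] > 0
    if not case.any() or not ctrl.any():
        return np.nan
    rc, wc = risk[case], w[0][case]
    rk, wk = risk[ctrl], w[1][ctrl]
    diff = rc[:, None] - rk[None, :]
    win = (diff > 0) + 0.5 * (diff == 0)
    ww = wc[:, None] * wk[None, :]
    return float((win * ww).sum() / ww.sum())


def _case_control_weights(out, t, km):
    tt, ee = time_event_arrays(out)
    wcase = np.zeros(len(tt))
    wctrl = np.zeros(len(tt))
    case = (ee == 1) & (tt <= t)
    ctrl = tt > t
    wcase[case] = 1.0 / np.clip(_cens_surv_at(km, tt[case], left=True), 1e-12, None)
    wctrl[ctrl] = 1.0 / np.clip(_cens_surv_at(km, [t])[0], 1e-12, None)
    return wcase, wctrl


def time_dependent_auc(scores, outcomes: pd.DataFrame, times) -> tuple[pd.DataFrame, float]:
    """Cumulative-case / dynamic-control AUC(t) with IPCW, on a 0-100% scale.

    Cases at horizon t are subjects with an event by t; controls are those
    still event-free beyond t.  Returns (per-time table, tAUC) where tAUC is
    the survival-weighted mean of AUC(t) over the requested times.
    """
    out = check_outcomes(outcomes)
    risk = _risk_array(scores)
    if len(risk) != len(out):
        raise ValueError("scores and outcomes disagree on sample count")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    km_c = censoring_survival(out)
    t_all, e_all = time_event_arrays(out)
    km_s = KaplanMeierFitter().fit(t_all, e_all)
    rows = []
    for t in times:
        wcase, wctrl = _case_control_weights(out, t, km_c)
        auc = _auc_at(risk, t_all, e_all, (wcase, wctrl))
        if np.isnan(auc):
            import warnings

            warnings.warn(f"no usable cases/controls at t={t}; skipped")
            continue
        rows.append((t, 100.0 * auc, float(km_s.predict(t))))
    tab = pd.DataFrame(rows, columns=["time", "auc_pct", "survival"])
    if tab.empty:
        raise ValueError("AUC undefined at every requested time")
    tauc = float((tab["auc_pct"] * tab["survival"]).sum() / tab["survival"].sum())
    return tab, tauc


def threshold_metrics(scores, outcomes: pd.DataFrame, t: float) -> TimepointMetrics:
    """IPCW confusion-matrix metrics at the Youden-optimal threshold.

    The threshold maximizes sensitivity + specificity over observed score
    values; ties are broken toward the higher threshold (higher specificity).
    Counts are IPCW-weighted; rates are fractions, AUC is percent.
    """
    out = check_outcomes(outcomes)
    risk = _risk_array(scores)
    km_c = censoring_survival(out)
    wcase, wctrl = _case_control_weights(out, t, km_c)
    P = wcase.sum()
    N = wctrl.sum()
    if P <= 0 or N <= 0:
        raise ValueError(f"need cases and controls at t={t}")
    cand = np.unique(risk)
    best = None
    for thr in cand:
        pos = risk >= thr
        tp = wcase[pos].sum()
        fp = wctrl[pos].sum()
        sens = tp / P
        spec = 1.0 - fp / N
        youden = sens + spec
        # ties go to the larger threshold, i.e. the more specific rule
        if best is None or youden > best[0] + 1e-12 or (
            abs(youden - best[0]) <= 1e-12 and thr > best[1]
        ):
            best = (youden, thr, tp, fp)
    _, thr, tp, fp = best
    fn = P - tp
    tn = N - fp
    auc = 100.0 * _auc_at(risk, *time_event_arrays(out), (wcase, wctrl))
    prec = tp / (tp + fp) if tp + fp > 0 else np.nan
    rec = tp / (tp + fn)
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return TimepointMetrics(
        time=float(t),
        threshold=float(thr),
        tp=float(tp),
        fp=float(fp),
        tn=float(tn),
        fn=float(fn),
        auc=float(auc),
        sensitivity=float(rec),
        specificity=float(tn / (tn + fp)),
        f1=float(2 * prec * rec / (prec + rec)) if prec + rec > 0 else 0.0,
        accuracy=float((tp + tn) / (tp + fp + tn + fn)),
        mcc=float((tp * tn - fp * fn) / denom) if denom > 0 else 0.0,
        ppv=float(prec),
        npv=float(tn / (tn + fn)) if tn + fn > 0 else np.nan,
    )


def weighted_mean_metrics(metrics: pd.DataFrame, survival) -> pd.Series:
    """Survival-weighted mean of each metric column.

    ``metrics`` rows are timepoints; ``survival`` gives S(t) per row.
    """
    if len(metrics) == 0:
        raise ValueError("no timepoints")
    s = np.asarray(survival, dtype=float)
    if len(s) != len(metrics):
        raise ValueError("survival weights must match timepoint count")
    w = s / s.sum()
    return metrics.mul(w, axis=0).sum(axis=0)


def km_logrank(outcomes: pd.DataFrame, groups) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test."""
    out = check_outcomes(outcomes)
    g = pd.Series(np.asarray(groups), index=out.index)
    curves = {}
    for val, idx in g.groupby(g).groups.items():
        sub = out.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty group {val!r}")
        km = KaplanMeierFitter().fit(
            sub["time_years"], sub["event"], label=str(val)
        )
        curves[val] = km.survival_function_
    levels = list(curves)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if len(levels) == 2:
        m = g == levels[0]
        r = logrank_test(
            out.loc[m.values, "time_years"], out.loc[~m.values, "time_years"],
            out.loc[m.values, "event"], out.loc[~m.values, "event"],
        )
    else:
        r = multivariate_logrank_test(out["time_years"], g, out["event"])
    return {
        "curves": curves,
        "statistic": float(r.test_statistic),
        "p": float(r.p_value),
    }


def competing_risk_cif(
    outcomes: pd.DataFrame,
    scores=None,
    times=None,
    competing_as_controls: bool = True,
) -> dict:
    """Aalen-Johansen cumulative incidence per cause (kidney, death).

    With ``scores`` and ``times``, also computes cause-specific time-dependent
    AUC; by default subjects with the competing event stay in the control set
    (``competing_as_controls=False`` censors them instead), and the choice is
    recorded in the output.
    """
    out = check_outcomes(outcomes)
    types = set(out.loc[out["event"] == 1, "event_type"])
    result = {"competing_as_controls": competing_as_controls}
    t_all = out["time_years"].to_numpy(dtype=float)
    causes = ["kidney", "death"]
    if len(types - {"none"}) < 2:
        import warnings

        warnings.warn("single event type present; CIF reduces to 1 - KM")
    code = np.select(
        [out["event_type"] == "kidney", out["event_type"] == "death"], [1, 2], 0
    )
    for ci, cause in enumerate(causes, start=1):
        if (code == ci).sum() == 0:
            result[f"cif_{cause}"] = None
            continue
        aj = AalenJohansenFitter(calculate_variance=False)
        aj.fit(t_all, code, event_of_interest=ci)
        result[f"cif_{cause}"] = aj.cumulative_density_
    if scores is not None and times is not None:
        risk = _risk_array(scores)
        km_c = censoring_survival(out)
        km_s = KaplanMeierFitter().fit(t_all, out["event"])
        for ci, cause in enumerate(causes, start=1):
            rows = []
            for t in np.atleast_1d(times):
                wcase = np.zeros(len(t_all))
                wctrl = np.zeros(len(t_all))
                case = (code == ci) & (t_all <= t)
                if competing_as_controls:
                    ctrl = (t_all > t) | ((code != ci) & (code != 0) & (t_all <= t))
                else:
                    ctrl = t_all > t
                wcase[case] = 1.0 / np.clip(
                    _cens_surv_at(km_c, t_all[case], left=True), 1e-12, None
                )
                sc_t = np.clip(_cens_surv_at(km_c, [t])[0], 1e-12, None)
                late = ctrl & (t_all > t)
                early = ctrl & ~late
                wctrl[late] = 1.0 / sc_t
                wctrl[early] = 1.0 / np.clip(
                    _cens_surv_at(km_c, t_all[early], left=True), 1e-12, None
                )
                auc = _auc_at(risk, t_all, out["event"].to_numpy(), (wcase, wctrl))
                if not np.isnan(auc):
                    rows.append((float(t), 100.0 * auc, float(km_s.predict(t))))
            if rows:
                tab = pd.DataFrame(rows, columns=["time", "auc_pct", "survival"])
                result[f"tauc_{cause}_pct"] = float(
                    (tab["auc_pct"] * tab["survival"]).sum() / tab["survival"].sum()
                )
                result[f"auc_{cause}"] = tab
    return result


def decision_curve(risks, outcomes: pd.DataFrame, thresholds, t: float = 5.0) -> pd.DataFrame:
    """Net benefit of treat-by-risk versus treat-all / treat-none at horizon t.

    net_benefit(p) = TP/n - (FP/n) * p/(1-p) with IPCW-weighted event status
    at t; ``risks`` are predicted event probabilities by t in [0, 1].
    """
    r = np.asarray(risks, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must be probabilities in [0, 1]")
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds < 0.0):
        raise ValueError("thresholds must lie in [0, 1)")
    out = check_outcomes(outcomes)
    km_c = censoring_survival(out)
    wcase, wctrl = _case_control_weights(out, t, km_c)
    n = wcase.sum() + wctrl.sum()
    prev = wcase.sum() / n
    rows = []
    for p in thresholds:
        odds = p / (1.0 - p)
        pos = r >= p
        nb = wcase[pos].sum() / n - wctrl[pos].sum() / n * odds
        nb_all = prev - (1.0 - prev) * odds
        rows.append((p, nb, nb_all, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "net_benefit", "treat_all", "treat_none"])


def nnt(control_event_rate: float, rrr: float = 0.27) -> float:
    """Number needed to treat: 1 / (control event rate x relative risk reduction)."""
    if not 0.0 < control_event_rate <= 1.0 or not 0.0 < rrr <= 1.0:
        raise ValueError("rates must lie in (0, 1]")
    return 1.0 / (control_event_rate * rrr)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs for Cox-model sample-size calculations."""

    alpha: float = 0.05  # two-sided
    power: float = 0.85
    hazard_ratio: float = 1.648
    marker_positive: float = 0.30
    event_rate: float = 0.25
    epv: float = 15.0
    n_predictors: int = 13

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.hazard_ratio <= 0 or self.hazard_ratio == 1.0:
            raise ValueError("hazard ratio must be positive and != 1")
        if not 0 < self.marker_positive < 1 or not 0 < self.event_rate <= 1:
            raise ValueError("proportions must be valid")


def sample_size(spec: SampleSizeSpec, method: str = "schoenfeld") -> dict:
    """Required sample size for a Cox model.

    ``schoenfeld``: events d = (z_{1-a/2} + z_{1-b})^2 / (p(1-p) ln(HR)^2),
    n = d / event_rate (n rounded to nearest, events rounded up).
    ``epv``: events = EPV * n_predictors, n = events / event_rate.
    """
    if method == "schoenfeld":
        za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        zb = stats.norm.ppf(spec.power)
        p = spec.marker_positive
        d = (za + zb) ** 2 / (p * (1.0 - p) * np.log(spec.hazard_ratio) ** 2)
        n = d / spec.event_rate
        return {"events": int(np.ceil(d)), "n": int(round(n)), "method": method}
    if method == "epv":
        d = spec.epv * spec.n_predictors
        n = d / spec.event_rate
        return {"events": int(np.ceil(d)), "n": int(round(n)), "method": method}
    raise ValueError("method must be 'schoenfeld' or 'epv'")


def achieved_power(n: int, spec: SampleSizeSpec) -> float:
    """Invert the Schoenfeld formula: power achieved at sample size ``n``."""
    d = n * spec.event_rate
    p = spec.marker_positive
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = np.sqrt(d * p * (1.0 - p) * np.log(spec.hazard_ratio) ** 2) - za
    return float(stats.norm.cdf(zb))


def panel_correlation_layout(correlations: pd.DataFrame, panel: list[str]) -> dict:
    """Angular (radar) layout from a correlation matrix.

    Panel proteins are ordered by a greedy traversal of their correlation
    submatrix (start at the first panel protein; repeatedly move to the most
    strongly correlated unvisited one) and placed at equal angles; every
    other protein sits at the circular mean of the panel angles weighted by
    its absolute correlations with the panel.
    """
    C = correlations
    if not np.allclose(C.values, C.values.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C.values), 1.0, atol=1e-8):
        raise ValueError("correlation matrix needs a unit diagonal")
    panel = [str(p) for p in panel]
    order = [panel[0]]
    left = set(panel[1:])
    while left:
        cur = order[-1]
        nxt = max(sorted(left), key=lambda q: abs(C.loc[cur, q]))
        order.append(nxt)
        left.remove(nxt)
    k = len(order)
    angles = {p: 2.0 * np.pi * i / k for i, p in enumerate(order)}
    others = {}
    for q in C.index:
        if q in angles or q not in C.columns:
            continue
        w = np.array([abs(C.loc[q, p]) for p in order])
        if w.sum() == 0:
            others[q] = np.nan
            continue
        th = np.array([angles[p] for p in order])
        ang = np.arctan2((w * np.sin(th)).sum(), (w * np.cos(th)).sum())
        others[q] = float(ang % (2.0 * np.pi))
    return {"order": order, "panel_angles": angles, "other_angles": others}


def evaluate_model(
    scores,
    outcomes: pd.DataFrame,
    times,
) -> EvaluationReport:
    """Full evaluation: per-timepoint metrics, weighted means, tAUC, C-index."""
    from ._coxnet import harrell_cindex_multi

    out = check_outcomes(outcomes)
    risk = _risk_array(scores)
    auc_tab, tauc = time_dependent_auc(risk, out, times)
    tps = [threshold_metrics(risk, out, t) for t in auc_tab["time"]]
    mat = pd.DataFrame([{m: getattr(tp, m) for m in _METRICS} for tp in tps])
    wmeans = weighted_mean_metrics(mat, auc_tab["survival"])
    t_all, e_all = time_event_arrays(out)
    cindex = 100.0 * float(harrell_cindex_multi(risk.reshape(-1, 1), t_all, e_all)[0])
    return EvaluationReport(
        timepoints=tps,
        weighted_means={k: 100.0 * float(v) for k, v in wmeans.items()},
        tauc=tauc,
        cindex=cindex,
        survival=auc_tab.set_index("time")["survival"],
    )
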