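"""Core survival-model machinery.

Penalized and unpenalized Cox proportional-hazards fitting (elastic net,
Breslow ties), univariate screening with Benjamini–Hochberg adjustment,
cross-validated concordance, and Grambsch–Therneau proportional-hazards
diagnostics.

The penalized objective is

    -(1/n) log PL(beta) + lambda * (alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2)

with ``alpha`` the L1/L2 mixing parameter and ``lambda`` the strength;
the per-subject 1/n scaling makes lambda comparable across sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._coxnet import (
    cox_information,
    cox_working,
    fit_path,
    harrell_cindex_multi,
    tie_last_indices,
    univariate_newton,
)
from ._utils import (
    align_outcomes,
    check_outcomes,
    spawn_seed,
    stratified_folds,
    time_event_arrays,
)

__all__ = [
    "PenaltySpec",
    "CoxFit",
    "ScreenResult",
    "CoxElasticNet",
    "cox_fit",
    "univariate_screen",
    "cv_cindex",
    "ph_test_schoenfeld",
    "schoenfeld_residuals",
]


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty: mixing ``alpha`` in [0,1], strength ``lam`` >= 0.

    ``penalize`` optionally names the covariates subject to the penalty;
    ``None`` penalizes everything.
    """

    alpha: float = 0.5
    lam: float = 0.0
    penalize: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0.0:
            raise ValueError("lambda must be non-negative")


@dataclass
class CoxFit:
    """Result of a (penalized) Cox fit with named coefficients."""

    names: list[str]
    coef: np.ndarray
    loglik: float
    converged: bool
    penalty: PenaltySpec | None = None
    se: np.ndarray | None = None

    @property
    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names, name="coef")

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame({"coef": self.coef, "hr": np.exp(self.coef)}, index=self.names)
        if self.se is not None:
            tab["se"] = self.se
            z = self.coef / self.se
            tab["z"] = z
            tab["p"] = 2.0 * stats.norm.sf(np.abs(z))
        return tab

    def to_dict(self) -> dict:
        d = {
            "coefficients": dict(zip(self.names, map(float, self.coef))),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
        }
        if self.penalty is not None:
            d["penalty"] = {
                "alpha": self.penalty.alpha,
                "lambda": self.penalty.lam,
                "penalize": list(self.penalty.penalize) if self.penalty.penalize else None,
            }
        if self.se is not None:
            d["se"] = dict(zip(self.names, map(float, self.se)))
        return d


@dataclass
class ScreenResult:
    """Univariate screening output: per-protein statistics and retained ids."""

    table: pd.DataFrame  # index protein, columns beta, hr, se, p, p_adj
    retained: list[str] = field(default_factory=list)
    adj_p_max: float = 0.05
    top_fraction: float = 0.20

    @property
    def n_tested(self) -> int:
        return len(self.table)


def _newton_cox(Xs, es, tl, max_iter: int, tol: float):
    """Full-Hessian Newton-Raphson for the unpenalized Breslow likelihood."""
    n, p = Xs.shape
    beta = np.zeros(p)
    _, _, ll = cox_working(np.zeros(n), es, tl)
    for _ in range(max_iter):
        eta = Xs @ beta
        grad, _, ll = cox_working(eta, es, tl)
        score = Xs.T @ grad
        info = cox_information(Xs, eta, es, tl)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving keeps the likelihood monotone
        for _half in range(30):
            cand = beta + step
            _, _, ll_new = cox_working(Xs @ cand, es, tl)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < max(tol, 1e-12):
            break
    _, _, ll = cox_working(Xs @ beta, es, tl)
    return beta, float(ll)


def _as_xy(X, outcomes):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        out = align_outcomes(X, outcomes)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim != 2:
            raise ValueError("X must be two-dimensional")
        names = [f"x{j}" for j in range(Xv.shape[1])]
        out = check_outcomes(outcomes)
        if len(out) != Xv.shape[0]:
            raise ValueError("X and outcomes disagree on sample count")
    if np.isnan(Xv).any():
        raise ValueError("X contains missing values; impute first")
    return Xv, names, out


class CoxElasticNet(BaseEstimator):
    """Elastic-net penalized Cox proportional-hazards model.

    Parameters
    ----------
    alpha : float
        Penalty strength (lambda). ``0`` gives the unpenalized partial
        likelihood maximizer, in which case standard errors are computed.
    l1_ratio : float
        Mixing between L1 (``1``) and L2 (``0``).
    penalty_mask : sequence of bool or None
        Which columns are penalized; ``None`` penalizes all.
    tol, max_iter : float, int
        Coordinate-descent tolerance and IRLS iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
    loglik_ : float, Breslow log partial likelihood at the solution
    se_ : ndarray or None, Wald standard errors (unpenalized fits only)
    converged_ : bool
    """

    def __init__(self, alpha=0.0, l1_ratio=0.5, penalty_mask=None, tol=1e-9, max_iter=200):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.penalty_mask = penalty_mask
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        Xv, names, out = _as_xy(X, y)
        out = check_outcomes(out, require_events=1)
        if self.alpha < 0:
            raise ValueError("alpha (penalty strength) must be >= 0")
        t, e = time_event_arrays(out)
        order = np.argsort(t, kind="mergesort")
        # centering leaves the partial likelihood (and coefficients) unchanged
        # but keeps the coordinate updates well conditioned
        Xv = Xv - Xv.mean(axis=0)
        Xs = np.asfortranarray(Xv[order])
        ts, es = t[order], e[order]
        tl = tie_last_indices(ts)
        p = Xs.shape[1]
        if self.penalty_mask is None:
            mask = np.ones(p, dtype=bool)
        else:
            mask = np.asarray(self.penalty_mask, dtype=bool)
            if mask.shape != (p,):
                raise ValueError("penalty_mask length must match number of columns")
        if self.alpha == 0.0:
            self.coef_, self.loglik_ = _newton_cox(Xs, es, tl, self.max_iter, self.tol)
        else:
            lams = np.array([float(self.alpha)])
            coefs, lls, _ = fit_path(
                Xs, es, tl, float(self.l1_ratio), lams, mask, self.tol, self.max_iter, 0.0
            )
            self.coef_ = coefs[0]
            self.loglik_ = float(lls[0])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        # convergence: penalized subgradient condition on free directions
        grad, _, _ = cox_working(Xs @ self.coef_, es, tl)
        g = Xs.T @ grad / len(ts)
        lam, a = float(self.alpha), float(self.l1_ratio)
        resid = np.where(
            mask,
            np.where(
                self.coef_ != 0.0,
                np.abs(g - lam * ((1 - a) * self.coef_ + a * np.sign(self.coef_))),
                np.maximum(np.abs(g) - lam * a, 0.0),
            ),
            np.abs(g),
        )
        self.converged_ = bool(np.max(resid, initial=0.0) < 1e-4 * max(1.0, np.abs(g).max()) + 1e-6)
        if not self.converged_:
            warnings.warn("Cox elastic-net fit did not fully converge", RuntimeWarning)
        if np.abs(self.coef_).max(initial=0.0) > 50:
            warnings.warn(
                "very large coefficients: possible complete separation", RuntimeWarning
            )
        self.se_ = None
        if self.alpha == 0.0:
            info = cox_information(Xs, Xs @ self.coef_, es, tl)
            cov = np.linalg.pinv(info)
            self.se_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            self.covariance_ = cov
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard)."""
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return Xv @ self.coef_

    def score(self, X, y):
        """Harrell's concordance index of the linear predictor."""
        out = align_outcomes(X, y) if isinstance(X, pd.DataFrame) else check_outcomes(y)
        t, e = time_event_arrays(out)
        pred = self.predict(X).reshape(-1, 1)
        return float(harrell_cindex_multi(pred, t, e)[0])


def cox_fit(X, outcomes, penalty: PenaltySpec | None = None) -> CoxFit:
    """Fit a Cox model; ``penalty=None`` gives the unpenalized MLE with SEs."""
    spec = penalty or PenaltySpec(alpha=0.5, lam=0.0)
    if isinstance(X, pd.DataFrame) and spec.penalize is not None:
        mask = np.array([c in spec.penalize for c in X.columns])
    else:
        mask = None
    est = CoxElasticNet(alpha=spec.lam, l1_ratio=spec.alpha, penalty_mask=mask)
    est.fit(X, outcomes)
    return CoxFit(
        names=list(est.feature_names_in_),
        coef=est.coef_,
        loglik=est.loglik_,
        converged=est.converged_,
        penalty=penalty,
        se=est.se_,
    )


def univariate_screen(
    proteome: pd.DataFrame,
    outcomes: pd.DataFrame,
    adj_p_max: float = 0.05,
    top_fraction: float = 0.20,
) -> ScreenResult:
    """Single-protein Cox screening with BH adjustment.

    Each protein is fit in its own single-covariate Cox model; Wald p-values
    are Benjamini–Hochberg adjusted across all tested proteins.  The retained
    set keeps proteins with adjusted p below ``adj_p_max``, truncated to the
    best ``top_fraction`` of all tested proteins by p-value rank.  Constant
    columns are skipped with a warning.
    """
    out = align_outcomes(proteome, outcomes)
    out = check_outcomes(out, require_events=1)
    t, e = time_event_arrays(out)
    order = np.argsort(t, kind="mergesort")
    ts, es = t[order], e[order]
    tl = tie_last_indices(ts)
    rows = []
    for col in proteome.columns:
        x = proteome[col].to_numpy(dtype=float)[order]
        if np.nanstd(x) == 0.0 or np.isnan(x).any():
            warnings.warn(f"skipping degenerate or incomplete protein column {col!r}")
            continue
        beta, se, ll = univariate_newton(x, es, tl, 50, 1e-10)
        z = beta / se if se > 0 else 0.0
        rows.append((str(col), beta, np.exp(beta), se, 2.0 * stats.norm.sf(abs(z))))
    if not rows:
        raise ValueError("no testable protein columns")
    tab = pd.DataFrame(rows, columns=["protein", "beta", "hr", "se", "p"]).set_index("protein")
    tab["p_adj"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
    k = int(np.floor(top_fraction * len(tab)))
    significant = tab[tab["p_adj"] < adj_p_max]
    retained = significant.sort_values("p", kind="mergesort").head(k).index.tolist()
    return ScreenResult(table=tab, retained=retained, adj_p_max=adj_p_max, top_fraction=top_fraction)


def uno_cindex(scores, outcomes, tau: float | None = None) -> float:
    """Uno's IPCW concordance: censoring-weighted comparable pairs up to tau."""
    out = check_outcomes(outcomes, require_events=1)
    t, e = time_event_arrays(out)
    s = np.asarray(scores, dtype=float)
    if tau is None:
        tau = float(t.max())
    from lifelines import KaplanMeierFitter

    kmc = KaplanMeierFitter().fit(t, 1 - e)
    G = np.asarray(kmc.predict(np.nextafter(t, -np.inf)), dtype=float)
    G = np.clip(G, 1e-12, None)
    num = den = 0.0
    for i in range(len(t)):
        if e[i] != 1 or t[i] > tau:
            continue
        w = 1.0 / (G[i] * G[i])
        later = t > t[i]
        if not later.any():
            continue
        den += w * later.sum()
        num += w * ((s[i] > s[later]).sum() + 0.5 * (s[i] == s[later]).sum())
    if den == 0:
        return float("nan")
    return float(num / den)


def cv_cindex(
    X,
    outcomes,
    penalty: PenaltySpec,
    k: int = 8,
    seed: int = 0,
    max_refold: int = 5,
    method: str = "harrell",
) -> float:
    """Mean held-out concordance over event-stratified k-fold CV.

    ``method`` selects Harrell's pairwise C (default) or Uno's IPCW-weighted
    version.
    """
    Xv, names, out = _as_xy(X, outcomes)
    t, e = time_event_arrays(out)
    if int(e.sum()) < k:
        raise ValueError("fewer events than folds")
    mask = None
    if penalty.penalize is not None:
        mask = np.array([c in penalty.penalize for c in names])
    for attempt in range(max_refold):
        folds = stratified_folds(e, k, spawn_seed(seed, attempt))
        cs = []
        ok = True
        for f in range(k):
            tr = folds != f
            te = ~tr
            if e[te].sum() == 0 or e[tr].sum() == 0:
                ok = False
                break
            est = CoxElasticNet(
                alpha=penalty.lam,
                l1_ratio=penalty.alpha,
                penalty_mask=mask,
                tol=1e-7,
                max_iter=50,
            )
            est.fit(Xv[tr], out.iloc[tr].reset_index(drop=True))
            pred = Xv[te] @ est.coef_
            if method == "uno":
                c = uno_cindex(pred, out.iloc[te].reset_index(drop=True))
            else:
                c = harrell_cindex_multi(pred.reshape(-1, 1), t[te], e[te])[0]
            if np.isnan(c):
                ok = False
                break
            cs.append(c)
        if ok:
            return float(np.mean(cs))
    raise RuntimeError("could not build folds with events in every fold")


def schoenfeld_residuals(X, outcomes, coef: np.ndarray | None = None):
    """Schoenfeld residuals (one row per event) for a fitted Cox model.

    Returns (event_times, residual matrix (d, p), information matrix, d).
    """
    Xv, names, out = _as_xy(X, outcomes)
    out = check_outcomes(out, require_events=1)
    t, e = time_event_arrays(out)
    order = np.argsort(t, kind="mergesort")
    Xs = np.asfortranarray(Xv[order])
    ts, es = t[order], e[order]
    tl = tie_last_indices(ts)
    if coef is None:
        est = CoxElasticNet(alpha=0.0).fit(Xv, out)
        coef = est.coef_
    eta = Xs @ coef
    ex = np.exp(eta - eta.max())
    n, p = Xs.shape
    # suffix sums over the risk set at each tie group
    resid = []
    etimes = []
    S0 = 0.0
    S1 = np.zeros(p)
    i = n - 1
    starts = []
    while i >= 0:
        first = i
        while first > 0 and tl[first - 1] == tl[i]:
            first -= 1
        starts.append((first, tl[i]))
        i = first - 1
    for first, last in starts:
        for k_ in range(last, first - 1, -1):
            S0 += ex[k_]
            S1 += Xs[k_] * ex[k_]
        xbar = S1 / S0
        for k_ in range(first, last + 1):
            if es[k_] == 1.0:
                resid.append(Xs[k_] - xbar)
                etimes.append(ts[k_])
    # events were collected walking backwards through time; restore order
    etimes = np.asarray(etimes)[::-1]
    resid = np.asarray(resid)[::-1]
    info = cox_information(Xs, eta, es, tl)
    return etimes, resid, info, names


def ph_test_schoenfeld(
    X,
    outcomes,
    fit: CoxFit | None = None,
    transform: str = "km",
) -> dict:
    """Grambsch–Therneau proportional-hazards test.

    Score test of a time-varying coefficient alternative ``beta(t) = beta +
    theta * g(t)`` using Schoenfeld residuals; ``transform`` chooses g as the
    identity, the event-time rank, or the left-continuous Kaplan–Meier scale
    (as in standard survival software).  Returns per-covariate and global
    chi-square statistics with p-values, plus a residual-vs-time table for
    plotting.
    """
    coef = None
    if fit is not None:
        if fit.penalty is not None and fit.penalty.lam > 0:
            raise ValueError("PH diagnostics require an unpenalized fit")
        coef = fit.coef
    etimes, resid, info, names = schoenfeld_residuals(X, outcomes, coef)
    d, p = resid.shape
    if d <= p:
        raise ValueError("fewer events than covariates")
    if transform == "identity":
        g = etimes.astype(float)
    elif transform == "rank":
        g = stats.rankdata(etimes, method="average")
    elif transform == "km":
        out = check_outcomes(align_outcomes(X, outcomes) if isinstance(X, pd.DataFrame) else outcomes)
        t, e = time_event_arrays(out)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(t, e)
        surv = km.survival_function_["KM_estimate"]
        # left-continuous KM at each event time
        g = np.array([surv[surv.index < et].iloc[-1] if (surv.index < et).any() else 1.0 for et in etimes])
        g = 1.0 - g
    else:
        raise ValueError("transform must be 'identity', 'rank' or 'km'")
    gc = g - g.mean()
    u = gc @ resid  # (p,)
    vinv = np.linalg.pinv(info)
    denom = float(gc @ gc)
    # per-covariate score test on the scaled residuals
    rstar = d * resid @ vinv
    per_cov = {}
    for j, name in enumerate(names):
        num = float(gc @ rstar[:, j]) ** 2
        den = d * vinv[j, j] * denom
        chi = num / den if den > 0 else np.nan
        per_cov[name] = (chi, float(stats.chi2.sf(chi, 1)))
    chi_global = float(d / denom * (u @ vinv @ u))
    p_global = float(stats.chi2.sf(chi_global, p))
    table = pd.DataFrame(
        {name: resid[:, j] for j, name in enumerate(names)},
        index=pd.Index(etimes, name="event_time"),
    )
    return {
        "per_covariate": pd.DataFrame(per_cov, index=["chi2", "p"]).T,
        "global_chi2": chi_global,
        "global_p": p_global,
        "df": p,
        "transform": transform,
        "residuals": table,
    }
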