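"""Ensemble marker selection over random candidate protein panels.

The procedure resamples the *feature space*: candidate panels are drawn by
sampling 40-90% of the screened proteins without replacement; each panel is
fit with elastic-net Cox models over a full (alpha, lambda) grid scored by
k-fold cross-validated C-index; proteins are then ranked by how often their
coefficient is non-zero at the per-panel optimum, and the stable set keeps
those selected in at least 30% of the panels that contained them.  A final
elastic-net refit of the stable proteins plus clinical covariates (age, sex,
eGFR, log2 UACR; unpenalized by default) yields the risk-score model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._coxnet import fit_path, harrell_cindex_multi, lambda_max, tie_last_indices
from ._utils import align_outcomes, check_outcomes, spawn_seed, stratified_folds, time_event_arrays
from .scoring import CLINICAL_TERMS, ScoreModel
from .survmodel import ScreenResult

__all__ = [
    "PanelCandidate",
    "EnsembleResult",
    "sample_panels",
    "grid_search_panel",
    "ensemble_frequencies",
    "final_refit",
    "EnsemblePanelSelector",
]

DEFAULT_ALPHAS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass
class PanelCandidate:
    """One candidate panel and, after grid search, its optimum."""

    proteins: tuple[str, ...]
    fraction: float
    best_alpha: float | None = None
    best_lambda: float | None = None
    cv_cindex: float | None = None
    nonzero: tuple[str, ...] = ()
    grid_shape: tuple[int, int] | None = None


@dataclass
class EnsembleResult:
    """Per-protein selection frequencies across candidate panels."""

    frequencies: pd.Series  # NaN for proteins never sampled
    n_panels: int
    threshold: float
    panels: list[PanelCandidate] = field(default_factory=list)

    @property
    def stable(self) -> list[str]:
        f = self.frequencies
        return f.index[(f >= self.threshold).fillna(False)].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency": self.frequencies, "n_panels": self.n_panels}
        ).rename_axis("protein")


def _screened_ids(screened) -> list[str]:
    if isinstance(screened, ScreenResult):
        ids = screened.retained
    else:
        ids = list(screened)
    if not ids:
        raise ValueError("screened set is empty")
    return [str(s) for s in ids]


def panel_capacity(n_proteins: int, fraction_range: tuple[float, float] = (0.4, 0.9)) -> int:
    """Number of distinct subsets available to :func:`sample_panels`."""
    lo, hi = fraction_range
    k_lo = max(1, int(round(lo * n_proteins)))
    k_hi = max(k_lo, int(round(hi * n_proteins)))
    return sum(comb(n_proteins, k) for k in range(k_lo, k_hi + 1))


def sample_panels(
    screened,
    n_panels: int,
    fraction_range: tuple[float, float] = (0.4, 0.9),
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Draw unique candidate panels without replacement within each panel.

    Panel size is a uniform fraction of the screened set within
    ``fraction_range``; duplicate panels are re-drawn.
    """
    ids = _screened_ids(screened)
    m = len(ids)
    lo, hi = fraction_range
    if not 0.0 < lo <= hi <= 1.0:
        raise ValueError("fraction_range must lie in (0, 1]")
    k_lo = max(1, int(round(lo * m)))
    k_hi = max(k_lo, int(round(hi * m)))
    capacity = sum(comb(m, k) for k in range(k_lo, k_hi + 1))
    if n_panels > capacity:
        raise ValueError(
            f"{n_panels} unique panels requested but only {capacity} distinct "
            f"subsets exist for sizes {k_lo}..{k_hi} of {m} proteins"
        )
    rng = np.random.default_rng(seed)
    panels: list[tuple[str, ...]] = []
    seen = set()
    attempts = 0
    while len(panels) < n_panels:
        attempts += 1
        if attempts > 1000 * n_panels:
            raise RuntimeError("panel sampling stalled; widen fraction_range")
        frac = rng.uniform(lo, hi)
        k = int(np.clip(round(frac * m), 1, m))
        panel = tuple(sorted(rng.choice(m, size=k, replace=False)))
        if panel in seen:
            continue
        seen.add(panel)
        panels.append(tuple(ids[j] for j in panel))
    return panels


class _SurvivalData:
    """Pre-sorted full-data and CV-fold views of a standardized matrix."""

    def __init__(self, X: pd.DataFrame, outcomes: pd.DataFrame, k: int, seed: int,
                 standardize: bool = True):
        out = align_outcomes(X, outcomes)
        out = check_outcomes(out, require_events=max(k, 1))
        self.names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
        if np.isnan(Xv).any():
            raise ValueError("matrix contains missing values; impute first")
        self.means = Xv.mean(axis=0)
        sds = Xv.std(axis=0, ddof=0)
        if standardize:
            if np.any(sds == 0):
                bad = [self.names[j] for j in np.flatnonzero(sds == 0)]
                raise ValueError(f"constant columns cannot be standardized: {bad}")
            Xv = (Xv - self.means) / sds
        else:
            # centering is coefficient-neutral but conditions the solver
            Xv = Xv - self.means
        self.sds = sds
        self.t, self.e = time_event_arrays(out)
        self.n = len(self.t)
        order = np.argsort(self.t, kind="mergesort")
        self.X_full = np.asfortranarray(Xv[order])
        self.t_full = self.t[order]
        self.e_full = self.e[order]
        self.tl_full = tie_last_indices(self.t_full)
        self.folds = stratified_folds(self.e, k, seed) if k > 1 else None
        self.fold_views = []
        if k > 1:
            for f in range(k):
                tr = self.folds != f
                tt, ee = self.t[tr], self.e[tr]
                o = np.argsort(tt, kind="mergesort")
                self.fold_views.append(
                    dict(
                        X=np.asfortranarray(Xv[tr][o]),
                        e=ee[o],
                        tl=tie_last_indices(tt[o]),
                        X_test=Xv[~tr],
                        t_test=self.t[~tr],
                        e_test=self.e[~tr],
                    )
                )
        # gradient of the null model depends only on outcomes; reuse for
        # per-panel lambda_max computations
        from ._coxnet import cox_working

        grad0, _, _ = cox_working(np.zeros(self.n), self.e_full, self.tl_full)
        self.null_grad_by_col = np.abs(self.X_full.T @ grad0) / self.n


def _grid_search(
    data: _SurvivalData,
    col_idx: np.ndarray,
    alphas,
    n_lambda: int,
    lambda_min_ratio: float,
    pen_mask: np.ndarray,
    tol: float,
    max_outer: int,
    dev_stop: float,
):
    """Mean CV C-index over the (alpha, lambda) grid for one column subset.

    Returns (best_alpha, best_lambda, cv_cindex, coefficients at optimum,
    lambda grids, mean C matrix).
    """
    alphas = np.asarray(alphas, dtype=float)
    A, L = len(alphas), n_lambda
    mean_c = np.full((A, L), np.nan)
    lam_grids = np.empty((A, L))
    gmax = data.null_grad_by_col[col_idx][pen_mask].max()
    for ai, a in enumerate(alphas):
        lmax = gmax / max(a, 1e-3)
        lams = lmax * np.logspace(0.0, np.log10(lambda_min_ratio), L)
        lam_grids[ai] = lams
        csum = np.zeros(L)
        for view in data.fold_views:
            Xp = np.asfortranarray(view["X"][:, col_idx])
            coefs, _, _ = fit_path(
                Xp, view["e"], view["tl"], a, lams, pen_mask, tol, max_outer, dev_stop
            )
            preds = view["X_test"][:, col_idx] @ coefs.T
            csum += harrell_cindex_multi(preds, view["t_test"], view["e_test"])
        mean_c[ai] = csum / len(data.fold_views)
    # optimum: max mean C; ties resolved toward sparser (larger lambda),
    # then smaller alpha — deterministic reporting
    flat = np.round(mean_c, 12)
    best = np.unravel_index(np.argmax(flat), flat.shape)
    best_c = flat[best]
    ties = np.argwhere(flat == best_c)
    ties = ties[np.lexsort((ties[:, 0], ties[:, 1]))]  # smallest lambda index first
    ai, li = ties[0]
    best_alpha = float(alphas[ai])
    best_lambda = float(lam_grids[ai, li])
    # refit on the full data down the path to the optimum
    coefs, _, _ = fit_path(
        np.asfortranarray(data.X_full[:, col_idx]),
        data.e_full,
        data.tl_full,
        best_alpha,
        lam_grids[ai, : li + 1],
        pen_mask,
        min(tol, 1e-5),
        max(max_outer, 4),
        0.0,
    )
    return best_alpha, best_lambda, float(mean_c[ai, li]), coefs[-1], lam_grids, mean_c


def grid_search_panel(
    panel,
    proteome: pd.DataFrame,
    outcomes: pd.DataFrame,
    alphas=DEFAULT_ALPHAS,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    k: int = 8,
    seed: int = 0,
    tol: float = 1e-4,
    max_outer: int = 2,
    dev_stop: float = 1e-5,
) -> PanelCandidate:
    """Grid-search one candidate panel; standalone (slower) entry point."""
    proteins = tuple(panel.proteins) if isinstance(panel, PanelCandidate) else tuple(panel)
    missing = set(proteins) - set(map(str, proteome.columns))
    if missing:
        raise ValueError(f"panel proteins absent from proteome: {sorted(missing)}")
    data = _SurvivalData(proteome[list(proteins)], outcomes, k, spawn_seed(seed, 17))
    idx = np.arange(len(proteins))
    pen = np.ones(len(proteins), dtype=bool)
    a, lam, c, coefs, _, mean_c = _grid_search(
        data, idx, alphas, n_lambda, lambda_min_ratio, pen, tol, max_outer, dev_stop
    )
    nz = tuple(p for p, b in zip(proteins, coefs) if b != 0.0)
    frac = len(proteins) / proteome.shape[1]
    return PanelCandidate(
        proteins=proteins,
        fraction=frac,
        best_alpha=a,
        best_lambda=lam,
        cv_cindex=c,
        nonzero=nz,
        grid_shape=(len(alphas), n_lambda),
    )


def ensemble_frequencies(panels: list[PanelCandidate], threshold: float = 0.30,
                         universe=None) -> EnsembleResult:
    """Selection frequency per protein across fitted panels.

    Frequency = (#panels where the coefficient was non-zero at the panel
    optimum) / (#panels containing the protein); proteins never sampled get
    a missing frequency.
    """
    if not panels:
        raise ValueError("need at least one fitted panel")
    contains: dict[str, int] = {}
    selected: dict[str, int] = {}
    for cand in panels:
        for prot in cand.proteins:
            contains[prot] = contains.get(prot, 0) + 1
        for prot in cand.nonzero:
            selected[prot] = selected.get(prot, 0) + 1
    ids = list(universe) if universe is not None else sorted(contains)
    freq = pd.Series(
        {p: (selected.get(p, 0) / contains[p]) if contains.get(p) else np.nan for p in ids},
        name="selection_frequency",
    )
    return EnsembleResult(frequencies=freq, n_panels=len(panels), threshold=threshold, panels=list(panels))


class EnsemblePanelSelector(BaseEstimator):
    """Stability selection over random candidate panels (sklearn-style).

    ``fit(X, y)`` takes the screened proteomic matrix (subjects x proteins,
    no missing values) and an outcome table; ``transform(X)`` restricts to
    the stable protein set.

    Parameters mirror the selection procedure: ``n_panels`` candidate panels
    with sizes drawn from ``fraction_range``; per panel a grid of
    ``alphas`` x ``n_lambda`` log-spaced lambdas scored by ``cv``-fold
    cross-validated C-index; proteins with selection frequency >=
    ``threshold`` across the panels containing them form the stable set.
    ``tol``/``max_outer``/``dev_stop`` tune the path solver (speed versus
    exactness of individual solutions).
    """

    def __init__(
        self,
        n_panels: int = 300,
        fraction_range: tuple[float, float] = (0.4, 0.9),
        alphas=DEFAULT_ALPHAS,
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-3,
        cv: int = 8,
        threshold: float = 0.30,
        random_state: int = 0,
        tol: float = 1e-4,
        max_outer: int = 2,
        dev_stop: float = 1e-5,
    ):
        self.n_panels = n_panels
        self.fraction_range = fraction_range
        self.alphas = alphas
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.threshold = threshold
        self.random_state = random_state
        self.tol = tol
        self.max_outer = max_outer
        self.dev_stop = dev_stop

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        names = [str(c) for c in X.columns]
        panels = sample_panels(
            names, self.n_panels, self.fraction_range, spawn_seed(self.random_state, 1)
        )
        data = _SurvivalData(X, y, self.cv, spawn_seed(self.random_state, 2))
        col_of = {nm: j for j, nm in enumerate(names)}
        fitted: list[PanelCandidate] = []
        for proteins in panels:
            idx = np.fromiter((col_of[p] for p in proteins), dtype=np.int64)
            pen = np.ones(len(idx), dtype=bool)
            a, lam, c, coefs, _, _ = _grid_search(
                data, idx, self.alphas, self.n_lambda, self.lambda_min_ratio,
                pen, self.tol, self.max_outer, self.dev_stop,
            )
            nz = tuple(p for p, b in zip(proteins, coefs) if b != 0.0)
            fitted.append(
                PanelCandidate(
                    proteins=proteins,
                    fraction=len(proteins) / len(names),
                    best_alpha=a,
                    best_lambda=lam,
                    cv_cindex=c,
                    nonzero=nz,
                    grid_shape=(len(tuple(self.alphas)), self.n_lambda),
                )
            )
        result = ensemble_frequencies(fitted, self.threshold, universe=names)
        self.ensemble_result_ = result
        self.selection_frequencies_ = result.frequencies
        self.stable_set_ = result.stable
        self.panels_ = fitted
        self.n_panels_ = len(fitted)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "stable_set_"):
            raise RuntimeError("selector is not fitted")
        return X[self.stable_set_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def final_refit(
    stable,
    proteome: pd.DataFrame,
    clinical: pd.DataFrame,
    outcomes: pd.DataFrame,
    alphas=DEFAULT_ALPHAS,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    cv: int = 8,
    seed: int = 0,
    penalize_clinical: bool = False,
    corr_prefilter: float | None = None,
) -> ScoreModel:
    """Elastic-net Cox refit of the stable proteins plus clinical terms.

    Proteins are standardized (training mean/SD, stored in the returned
    model); clinical covariates enter on the score's conventional scales
    (age per 10 years, eGFR per 5 units, UACR per doubling, male indicator)
    and are unpenalized unless ``penalize_clinical``.  The (alpha, lambda)
    optimum is chosen by ``cv``-fold cross-validated C-index, as in the
    per-panel search.  ``corr_prefilter`` optionally drops the later of any
    protein pair correlated above the given |R| before fitting.
    """
    stable = list(stable.retained) if isinstance(stable, ScreenResult) else list(stable)
    if not stable:
        raise ValueError("no panel survives the stability threshold")
    stable = [str(s) for s in stable]
    if corr_prefilter is not None and len(stable) > 1:
        corr = proteome[stable].corr().abs().to_numpy()
        keep = []
        for j, prot in enumerate(stable):
            if all(corr[j, i] <= corr_prefilter for i, _ in enumerate(stable[:j]) if stable[i] in keep):
                keep.append(prot)
        stable = keep
    prot = proteome[stable]
    means = prot.mean(axis=0)
    sds = prot.std(axis=0, ddof=0)
    if (sds == 0).any():
        raise ValueError("constant protein columns in the stable set")
    design = (prot - means) / sds
    design = design.copy()
    design["uacr_per_doubling"] = np.log2(clinical["uacr"].to_numpy(dtype=float))
    design["age_per_10y"] = clinical["age"].to_numpy(dtype=float) / 10.0
    design["egfr_per_5"] = clinical["egfr"].to_numpy(dtype=float) / 5.0
    design["male"] = (clinical["sex"].astype(str).str.lower() == "male").astype(float)

    data = _SurvivalData(design, outcomes, cv, spawn_seed(seed, 3), standardize=False)
    idx = np.arange(design.shape[1])
    pen = np.ones(design.shape[1], dtype=bool)
    if not penalize_clinical:
        pen[len(stable):] = False
    a, lam, c, coefs, _, _ = _grid_search(
        data, idx, alphas, n_lambda, lambda_min_ratio, pen,
        tol=1e-6, max_outer=8, dev_stop=0.0,
    )
    names = list(design.columns)
    coef_map = {nm: float(b) for nm, b in zip(names, coefs)}
    return ScoreModel(
        coefficients=coef_map,
        protein_scaling={p: (float(means[p]), float(sds[p])) for p in stable},
        meta={
            "alpha": a,
            "lambda": lam,
            "cv_cindex": c,
            "n_proteins": len(stable),
            "penalize_clinical": penalize_clinical,
        },
    )
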