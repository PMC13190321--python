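"""Risk-score application and risk-stratification analyses.

A :class:`ScoreModel` is a named coefficient vector defining

    score = exp( sum_j beta_j * x_j )

over protein terms (z-scored log2 abundances by convention) and clinical
terms on fixed scales: UACR per doubling (log2 of mg/g), age per 10 years,
eGFR per 5 ml/min/1.73 m^2, and a male indicator.  The published
13-term APOL1 proteomic risk score ships as
:meth:`ScoreModel.published_aprs`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from ._utils import align_outcomes, check_outcomes

__all__ = [
    "ScoreModel",
    "CLINICAL_TERMS",
    "APRS_PROTEINS",
    "aprs_score",
    "quintile_stratify",
    "quintile_gradient",
    "interaction_hr",
]

#: clinical term names and how raw covariates map onto them
CLINICAL_TERMS = ("uacr_per_doubling", "age_per_10y", "egfr_per_5", "male")

#: the nine proteins of the published score, in the printed order
APRS_PROTEINS = (
    "SPON1", "SUMO2", "EPHA10", "REG3A", "WFDC2", "LYZ", "MMP7", "NPPB", "CILP2",
)

_PUBLISHED_COEFFICIENTS = {
    "SPON1": 1.72,
    "SUMO2": 1.18,
    "EPHA10": 1.08,
    "REG3A": 0.89,
    "WFDC2": 1.37,
    "LYZ": 1.56,
    "MMP7": 0.68,
    "NPPB": 0.55,
    "CILP2": -0.95,
    "uacr_per_doubling": 0.22,
    "age_per_10y": 0.19,
    "egfr_per_5": -0.27,
    "male": 0.49,
}


@dataclass
class ScoreModel:
    """Named coefficients plus covariate scaling conventions.

    ``protein_scaling`` maps protein names to (mean, sd) used to z-score
    log2 abundances before applying the coefficient; ``None`` means protein
    inputs are taken as already standardized.
    """

    coefficients: dict[str, float]
    protein_scaling: dict[str, tuple[float, float]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError("coefficient names must be unique")

    @property
    def protein_terms(self) -> list[str]:
        return [k for k in self.coefficients if k not in CLINICAL_TERMS]

    @property
    def clinical_terms(self) -> list[str]:
        return [k for k in self.coefficients if k in CLINICAL_TERMS]

    @classmethod
    def published_aprs(cls) -> "ScoreModel":
        """The published 13-term score (nine proteins + four clinical terms).

        Protein inputs are interpreted as standardized log2 abundances; pass
        pre-standardized values or attach cohort scalings via
        ``protein_scaling``.
        """
        return cls(coefficients=dict(_PUBLISHED_COEFFICIENTS), meta={"source": "published"})

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": self.coefficients,
            "protein_scaling": self.protein_scaling,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScoreModel":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        scaling = payload.get("protein_scaling")
        if scaling is not None:
            scaling = {k: tuple(v) for k, v in scaling.items()}
        return cls(
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            protein_scaling=scaling,
            meta=payload.get("meta", {}),
        )

    def score(self, proteins, clinical) -> pd.DataFrame:
        return aprs_score(self, proteins, clinical)


def _clinical_design(clinical: pd.DataFrame, terms) -> pd.DataFrame:
    cols = {}
    if "uacr_per_doubling" in terms:
        uacr = clinical["uacr"].to_numpy(dtype=float)
        if np.any(uacr <= 0) or np.isnan(uacr).any():
            raise ValueError("UACR must be positive and present")
        cols["uacr_per_doubling"] = np.log2(uacr)
    if "age_per_10y" in terms:
        cols["age_per_10y"] = clinical["age"].to_numpy(dtype=float) / 10.0
    if "egfr_per_5" in terms:
        cols["egfr_per_5"] = clinical["egfr"].to_numpy(dtype=float) / 5.0
    if "male" in terms:
        sex = clinical["sex"]
        if sex.dtype.kind in "OUS":
            cols["male"] = (sex.astype(str).str.lower() == "male").astype(float).to_numpy()
        else:
            cols["male"] = sex.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=clinical.index)


def aprs_score(model: ScoreModel, proteins, clinical) -> pd.DataFrame:
    """Apply a score model; returns subject_id, lp and score = exp(lp).

    ``proteins`` must contain every protein term (no silent zero-fill);
    ``clinical`` must provide uacr, age, egfr (on their natural scales) and
    sex for whichever clinical terms the model includes.
    """
    prot_terms = model.protein_terms
    if isinstance(proteins, dict):
        proteins = pd.DataFrame(proteins, index=clinical.index if hasattr(clinical, "index") else [0])
    missing = [p for p in prot_terms if p not in proteins.columns]
    if missing:
        raise ValueError(f"missing protein inputs: {missing}")
    if proteins[prot_terms].isna().any().any():
        raise ValueError("protein inputs contain missing values")
    X = proteins[prot_terms].astype(float)
    if model.protein_scaling:
        for p in prot_terms:
            mu, sd = model.protein_scaling.get(p, (0.0, 1.0))
            X[p] = (X[p] - mu) / sd
    lp = X.to_numpy() @ np.array([model.coefficients[p] for p in prot_terms])
    cterms = model.clinical_terms
    if cterms:
        cd = _clinical_design(clinical, cterms)
        lp = lp + cd.to_numpy() @ np.array([model.coefficients[c] for c in cterms])
    idx = proteins.index
    return pd.DataFrame({"subject_id": idx, "lp": lp, "score": np.exp(lp)}).reset_index(drop=True)


def quintile_stratify(scores, outcomes: pd.DataFrame | None = None, horizon: float = 10.0):
    """Assign score quintiles (1 = lowest risk) and summarize event burden.

    Boundaries sit at the empirical 20/40/60/80 percentiles; ties spanning a
    boundary are broken by stable subject order, so group sizes are n/5 +/- 1.
    With outcomes given, each quintile's Kaplan-Meier cumulative incidence at
    ``horizon`` years is reported.
    """
    s = scores["score"] if isinstance(scores, pd.DataFrame) else pd.Series(scores)
    n = len(s)
    if n < 5:
        raise ValueError("need at least 5 subjects for quintiles")
    order = np.argsort(s.to_numpy(), kind="mergesort")  # stable in subject order
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    labels = pd.Series(1 + (ranks * 5) // n, index=s.index, name="quintile")
    vals = s.to_numpy()
    for q in range(1, 5):
        cut = np.percentile(vals, 20 * q)
        span = (vals == cut).sum()
        if span > 1 and (labels[vals == cut].nunique() > 1):
            import warnings

            warnings.warn(f"ties span the quintile {q}/{q+1} boundary at score {cut:g}")
    if outcomes is None:
        return labels
    out = check_outcomes(outcomes).set_index("subject_id").loc[s.index]
    rows = []
    for q in range(1, 6):
        m = labels == q
        km = KaplanMeierFitter().fit(out.loc[m.values, "time_years"], out.loc[m.values, "event"])
        surv = float(km.predict(horizon))
        rows.append((q, int(m.sum()), int(out.loc[m.values, "event"].sum()), 100.0 * (1.0 - surv)))
    summary = pd.DataFrame(rows, columns=["quintile", "n", "events", "cum_incidence_pct"])
    return labels, summary


def _ordinal_fit(frames: dict[str, np.ndarray], outcomes: pd.DataFrame) -> CoxPHFitter:
    df = pd.DataFrame(frames)
    df["T"] = outcomes["time_years"].to_numpy(dtype=float)
    df["E"] = outcomes["event"].to_numpy(dtype=int)
    return CoxPHFitter().fit(df, "T", "E")


def quintile_gradient(scores_a, scores_b, outcomes: pd.DataFrame):
    """Compare per-quintile risk gradients of two scores on the same subjects.

    Each score enters one Cox model as an ordinal per-quintile-step covariate
    (0..4); the gradient contrast Delta is the difference of per-step log
    hazard ratios, tested with a two-sided Wald test.  Returns a dict with
    per-score slopes/HRs, Delta, its standard error and p-value.
    """
    sa = scores_a["score"] if isinstance(scores_a, pd.DataFrame) else pd.Series(scores_a)
    sb = scores_b["score"] if isinstance(scores_b, pd.DataFrame) else pd.Series(scores_b)
    if len(sa) != len(sb):
        raise ValueError("scores must cover the same subjects")
    out = check_outcomes(outcomes)
    qa = quintile_stratify(sa).to_numpy(dtype=float) - 1.0
    qb = quintile_stratify(sb).to_numpy(dtype=float) - 1.0
    if np.std(qa) == 0 or np.std(qb) == 0:
        raise ValueError("degenerate quintile assignment")
    if np.array_equal(qa, qb):
        # identical assignments: the contrast is exactly null by symmetry
        delta, se, z = 0.0, np.nan, np.nan
        fa = _ordinal_fit({"q": qa}, out)
        fb = fa
        return {
            "slope_a": float(fa.params_["q"]),
            "slope_b": float(fa.params_["q"]),
            "per_step_hr_a": float(np.exp(fa.params_["q"])),
            "per_step_hr_b": float(np.exp(fa.params_["q"])),
            "delta_log_hr": 0.0,
            "delta_hr": 1.0,
            "se": 0.0,
            "p": 1.0,
        }
    fit = _ordinal_fit({"q_a": qa, "q_b": qb}, out)
    slope_a, slope_b = fit.params_["q_a"], fit.params_["q_b"]
    V = fit.variance_matrix_
    var_d = V.loc["q_a", "q_a"] + V.loc["q_b", "q_b"] - 2.0 * V.loc["q_a", "q_b"]
    delta = slope_a - slope_b
    se = float(np.sqrt(max(var_d, 0.0)))
    z = delta / se if se > 0 else np.nan
    # per-quintile HRs from separate single-score ordinal fits (cross-check view)
    fa = _ordinal_fit({"q": qa}, out)
    fb = _ordinal_fit({"q": qb}, out)
    return {
        "slope_a": float(slope_a),
        "slope_b": float(slope_b),
        "per_step_hr_a": float(np.exp(fa.params_["q"])),
        "per_step_hr_b": float(np.exp(fb.params_["q"])),
        "delta_log_hr": float(delta),
        "delta_hr": float(np.exp(delta)),
        "se": se,
        "p": float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
    }


def interaction_hr(scores, modifier, outcomes: pd.DataFrame):
    """Effect modification: Cox model with score, class and score x class.

    ``modifier`` is a binary class label (e.g. genotype high_risk/low_risk);
    returns the interaction hazard ratio exp(coefficient) with a two-sided
    Wald p-value.
    """
    s = scores["lp"] if isinstance(scores, pd.DataFrame) and "lp" in scores else (
        scores["score"] if isinstance(scores, pd.DataFrame) else pd.Series(scores)
    )
    mod = pd.Series(modifier)
    classes = sorted(mod.unique())
    if len(classes) != 2:
        raise ValueError("modifier must have exactly two classes")
    out = check_outcomes(outcomes)
    g = (mod == classes[1]).astype(float).to_numpy()
    for cls_val in (0.0, 1.0):
        m = g == cls_val
        if out.loc[m, "event"].sum() == 0:
            raise ValueError("each modifier class needs at least one event")
    x = np.asarray(s, dtype=float)
    fit = _ordinal_fit({"score": x, "class": g, "score_x_class": x * g}, out)
    beta = float(fit.params_["score_x_class"])
    se = float(fit.standard_errors_["score_x_class"])
    return {
        "interaction_hr": float(np.exp(beta)),
        "interaction_log_hr": beta,
        "se": se,
        "p": float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
        "reference_class": str(classes[0]),
    }
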