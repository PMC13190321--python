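"""End-to-end orchestration: simulate -> preprocess -> select -> score -> evaluate.

A :class:`RunConfig` captures every input path, seed and tuning knob; a run
writes the fitted score model (JSON), per-subject scores (TSV), the ensemble
frequency table (TSV), an evaluation report (JSON) and a manifest recording
the configuration hash and artifact checksums, so outputs are regenerable
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import spawn_seed
from .evaluate import evaluate_model
from .panelselect import EnsemblePanelSelector, final_refit
from .preprocess import filter_missing, impute_chained, stratified_split
from .scoring import aprs_score
from .syndata import CohortConfig, generate_cohort, write_cohort
from .survmodel import univariate_screen

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "aprs_run"
    seed: int = 0
    # inputs: either simulate or read tables
    simulate: bool = True
    n_subjects: int = 851
    n_proteins: int = 1000
    n_signal: int = 9
    proteome_path: str | None = None
    clinical_path: str | None = None
    outcomes_path: str | None = None
    # preprocessing
    max_missing: float = 0.15
    train_fraction: float = 0.8
    # screening & selection
    adj_p_max: float = 0.05
    top_fraction: float = 0.20
    n_panels: int = 300
    threshold: float = 0.30
    cv: int = 8
    # evaluation
    times: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dict (also written)."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(stage, msg):
        log.append(f"{stage}: {msg}")

    # ---- inputs -------------------------------------------------------
    if cfg.simulate:
        cohort = generate_cohort(
            CohortConfig(
                n_subjects=cfg.n_subjects,
                n_proteins=cfg.n_proteins,
                n_signal=cfg.n_signal,
                true_betas=_default_betas(cfg.n_signal),
                seed=spawn_seed(cfg.seed, 11),
            )
        )
        proteome, clinical, outcomes = cohort.proteome, cohort.clinical, cohort.outcomes
        write_cohort(cohort, outdir / "cohort")
        note("simulate", f"{cfg.n_subjects} subjects x {cfg.n_proteins} proteins, "
                         f"{int(outcomes['event'].sum())} events")
    else:
        for name, p in (("proteome", cfg.proteome_path), ("clinical", cfg.clinical_path),
                        ("outcomes", cfg.outcomes_path)):
            if p is None or not Path(p).exists():
                raise StageError("inputs", f"{name} table not found: {p}")
        proteome = pd.read_csv(cfg.proteome_path, sep="\t", index_col=0)
        clinical = pd.read_csv(cfg.clinical_path, sep="\t", index_col=0)
        outcomes = pd.read_csv(cfg.outcomes_path, sep="\t")
        note("inputs", f"loaded {proteome.shape[0]} subjects x {proteome.shape[1]} proteins")

    # ---- preprocess ---------------------------------------------------
    try:
        proteome, filt_report = filter_missing(proteome, cfg.max_missing)
        note("filter", f"kept {filt_report['n_kept']}/{filt_report['n_in']} proteins")
        split = stratified_split(outcomes, cfg.train_fraction, spawn_seed(cfg.seed, 12))
        train_ids = split.loc[split["fold"] == "train", "subject_id"]
        test_ids = split.loc[split["fold"] == "test", "subject_id"]
        if proteome.isna().any().any():
            tr_res, te_res = impute_chained(
                proteome.loc[train_ids], proteome.loc[test_ids],
                seed=spawn_seed(cfg.seed, 13),
            )
            proteome = pd.concat([tr_res.first, te_res.first]).loc[proteome.index]
            note("impute", f"imputed {len(tr_res.columns_imputed)} columns per fold")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc

    out_idx = outcomes.set_index("subject_id")
    train_out = out_idx.loc[train_ids].reset_index()
    test_out = out_idx.loc[test_ids].reset_index()

    # ---- screen + select (training set only) --------------------------
    try:
        screen = univariate_screen(
            proteome.loc[train_ids], train_out, cfg.adj_p_max, cfg.top_fraction
        )
        note("screen", f"{len(screen.retained)} of {screen.n_tested} proteins retained")
        if not screen.retained:
            raise StageError("screen", "no proteins pass the univariate screen")
        from .panelselect import panel_capacity

        n_panels = min(cfg.n_panels, panel_capacity(len(screen.retained)))
        if n_panels < cfg.n_panels:
            note("select", f"panel count clamped to subset capacity {n_panels}")
        selector = EnsemblePanelSelector(
            n_panels=n_panels, cv=cfg.cv, threshold=cfg.threshold,
            random_state=spawn_seed(cfg.seed, 14),
        )
        selector.fit(proteome.loc[train_ids, screen.retained], train_out)
        note("select", f"{len(selector.stable_set_)} stable proteins "
                       f"from {selector.n_panels_} panels")
        model = final_refit(
            selector.stable_set_, proteome.loc[train_ids], clinical.loc[train_ids],
            train_out, cv=cfg.cv, seed=spawn_seed(cfg.seed, 15),
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("select", str(exc)) from exc

    # ---- score + evaluate on the held-out test set ---------------------
    try:
        scores = aprs_score(model, proteome.loc[test_ids], clinical.loc[test_ids])
        report = evaluate_model(scores, test_out, list(cfg.times))
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    # ---- artifacts ----------------------------------------------------
    paths = {}
    model_path = outdir / "model.json"
    model.to_json(model_path)
    paths["model"] = model_path
    sc = scores.copy()
    sc["quintile"] = 1 + (sc["score"].rank(method="first") - 1).astype(int) * 5 // len(sc)
    scores_path = outdir / "scores.tsv"
    sc.to_csv(scores_path, sep="\t", index=False)
    paths["scores"] = scores_path
    ens_path = outdir / "ensemble.tsv"
    selector.ensemble_result_.to_frame().to_csv(ens_path, sep="\t")
    paths["ensemble"] = ens_path
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))
    paths["report"] = report_path
    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log) + "\n")

    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps({k: v for k, v in cfg.to_dict().items() if k != "outdir"},
                       sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": {k: {"path": str(v), "sha256": _sha(v)} for k, v in paths.items()},
        "stable_set": selector.stable_set_,
        "tauc_pct": report.tauc,
        "cindex_pct": report.cindex,
        "finished_unix": int(time.time()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _default_betas(k: int) -> tuple[float, ...]:
    base = CohortConfig.__dataclass_fields__["true_betas"].default
    if k == len(base):
        return base
    vals = [base[i % len(base)] for i in range(k)]
    return tuple(vals)
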