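"""End-to-end orchestration: preprocess -> QC -> split -> selection ->
consensus -> PLS evaluation -> stepwise -> Fisher -> LOO -> report.

A run is a pure function of (input files, config): every stochastic stage
derives its own seed from the master seed plus the stage name, all
intermediate artifacts are written to the run directory, and reruns with the
same inputs produce byte-identical artifacts (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fisher as fisher_mod
from . import qc_split, reporting, synthetic_data, variable_selection
from .core_io import SpectraSet, band_crop, read_spectra_csv, write_spectra_csv
from .pls import cross_validate, cv_predictions, galtier_verdict, pls_fit, set_accuracy
from .preprocessing import PreprocessChain, sdd_band_select


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2s(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    spectra_csv: str | None = None
    meta_csv: str | None = None
    simulate_tissue: str | None = None  # generate input instead of reading files
    seed: int = 42
    preprocess_steps: tuple[str, ...] = ("norris_filter", "mean_center", "standardize", "second_derivative")
    preprocess_params: dict = field(default_factory=dict)
    band_mode: str = "window"  # "window" (fixed crop) or "sdd"
    band_high: float = synthetic_data.SDD_HIGH
    band_low: float = synthetic_data.SDD_LOW
    sdd_quantile: float = 0.25
    sdd_min_run: int = 50
    qc_components: int = 5
    qc_alpha: float = 0.99
    validation_fraction: float = 1 / 3
    n_components: int = 5
    folds: int = 10
    cars: dict = field(default_factory=dict)
    mcuve: dict = field(default_factory=dict)
    spa: dict = field(default_factory=dict)
    lpg: dict = field(default_factory=dict)
    min_votes: int = 2
    f_enter: float = 3.84
    f_remove: float = 2.71

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["preprocess_steps"] = list(self.preprocess_steps)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["preprocess_steps"] = tuple(d.get("preprocess_steps", cls.preprocess_steps))
        return cls(**d)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _selection_to_json(res: variable_selection.SelectionResult, path: Path) -> None:
    _json_dump(
        {
            "method": res.method,
            "selected": [round(float(w), 6) for w in res.selected],
            "chosen_threshold": None if res.chosen_threshold is None else float(res.chosen_threshold),
            "rmsecv_path": [float(v) for v in res.rmsecv_path],
            "seed": int(res.seed),
        },
        path,
    )


def evaluate_variable_sets(
    train: SpectraSet,
    val: SpectraSet,
    variable_sets: dict[str, np.ndarray],
    n_components: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PLS-DA evaluation of each variable set, Galtier verdicts included.

    For every variable set: fit PLS on the training set, predict the
    validation samples (Y_pre), take Y_dev as the half-width of the spread
    of the 10 cross-validation sub-models' predictions, apply the Galtier
    rule with the nearest class code as candidate, and tabulate accuracy,
    R^2, RMSECV and RMSEP.
    """
    y_train = train.region_classes.astype(float)
    y_val = val.region_classes.astype(float)
    codes = tuple(sorted({int(c) for c in y_train}))
    summary_rows = []
    verdict_rows = []
    for name, wns in variable_sets.items():
        Xt, _ = train.extract(wns)
        Xv, _ = val.extract(wns)
        A_eff = max(1, min(n_components, Xt.shape[0] - 2, Xt.shape[1]))
        metrics = cross_validate(Xt, y_train, A_eff, folds=folds, seed=seed, X_val=Xv, y_val=y_val)
        model = pls_fit(Xt, y_train, A_eff)
        y_pre = model.predict(Xv)
        _, fold_preds = cv_predictions(Xt, y_train, A_eff, folds=folds, seed=seed, X_eval=Xv)
        y_dev = 0.5 * (fold_preds.max(axis=1) - fold_preds.min(axis=1))
        verdicts = []
        for sid, yp, yd in zip(val.sample_ids, y_pre, y_dev):
            cand = int(codes[int(np.argmin([abs(c - yp) for c in codes]))])
            verdicts.append(galtier_verdict(cand, yp, yd, codes=codes, sample_id=sid))
        acc = set_accuracy(verdicts, val.region_classes)
        summary_rows.append(
            {
                "variable_set": name,
                "n_variables": len(wns),
                "accuracy_pct": acc,
                "r2": round(metrics.r2, 4),
                "rmsecv": round(metrics.rmsecv, 4),
                "rmsep": round(metrics.rmsep, 4) if metrics.rmsep is not None else np.nan,
            }
        )
        for v, actual in zip(verdicts, val.region_classes):
            verdict_rows.append(
                {
                    "variable_set": name,
                    "sample_id": v.sample_id,
                    "actual_class": int(actual),
                    "candidate_class": v.candidate_class,
                    "y_pre": round(v.y_pre, 3),
                    "y_dev": round(v.y_dev, 3),
                    "flag": v.flag,
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(verdict_rows)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    stages: dict = {}

    # ------------------------------------------------------------------ input
    if cfg.simulate_tissue:
        gen_cfg = synthetic_data.default_study_config(
            cfg.simulate_tissue, seed=stage_seed(cfg.seed, "simulate")
        )
        spectra, truth = synthetic_data.generate_dataset(gen_cfg)
        _json_dump({"informative_wavenumbers": [round(float(w), 6) for w in truth]}, out / "truth.json")
    elif cfg.spectra_csv and cfg.meta_csv:
        spectra = read_spectra_csv(cfg.spectra_csv, cfg.meta_csv)
    else:
        raise PipelineError("input: provide spectra_csv+meta_csv or simulate_tissue")
    write_spectra_csv(spectra, out / "spectra_raw.csv", out / "meta.csv")

    # ------------------------------------------------------------- preprocess
    try:
        chain = PreprocessChain(steps=tuple(cfg.preprocess_steps), params=cfg.preprocess_params)
        pre = chain.apply(spectra)
    except Exception as exc:
        raise PipelineError(f"preprocess: {exc}") from exc
    stages["preprocess"] = chain.describe()

    # ------------------------------------------------------------- band select
    try:
        if cfg.band_mode == "sdd":
            window = sdd_band_select(pre, quantile=cfg.sdd_quantile, min_run=cfg.sdd_min_run)
            pre = band_crop(pre, window.start, window.end)
        else:
            pre = band_crop(pre, cfg.band_high, cfg.band_low)
    except Exception as exc:
        raise PipelineError(f"band selection: {exc}") from exc
    write_spectra_csv(pre, out / "preprocessed.csv", out / "preprocessed_meta.csv")

    # --------------------------------------------------------------------- qc
    try:
        clean, qc_report = qc_split.iterative_outlier_removal(
            pre, k=cfg.qc_components, alpha=cfg.qc_alpha
        )
    except Exception as exc:
        raise PipelineError(f"qc: {exc}") from exc
    qc_report.table.to_csv(out / "outliers.csv", index=False)
    stages["outliers"] = qc_report

    # ------------------------------------------------------------------ split
    try:
        split = qc_split.kennard_stone_split(clean, validation_fraction=cfg.validation_fraction)
    except Exception as exc:
        raise PipelineError(f"split: {exc}") from exc
    split.meta_frame().to_csv(out / "split.csv", index=False)
    train, val = split.training_set(), split.validation_set()
    stages["split"] = {
        "n_training": train.n_samples,
        "n_validation": val.n_samples,
        "validation_fraction": round(cfg.validation_fraction, 4),
    }

    # -------------------------------------------------------------- selection
    try:
        results = [
            variable_selection.cars_select(
                train, n_components=cfg.n_components, folds=cfg.folds,
                seed=stage_seed(cfg.seed, "cars"), **cfg.cars,
            ),
            variable_selection.mcuve_select(
                train, n_components=cfg.n_components, folds=cfg.folds,
                seed=stage_seed(cfg.seed, "mcuve"), **cfg.mcuve,
            ),
            variable_selection.spa_select(
                train, n_components=cfg.n_components,
                seed=stage_seed(cfg.seed, "spa"), **cfg.spa,
            ),
            variable_selection.lpg_select(train, **cfg.lpg),
        ]
    except Exception as exc:
        raise PipelineError(f"selection: {exc}") from exc
    for res in results:
        _selection_to_json(res, out / f"selection_{res.method.lower()}.json")
    consensus = variable_selection.consensus_vote(results, min_votes=cfg.min_votes)
    _json_dump({"min_votes": cfg.min_votes, "selected": [round(float(w), 6) for w in consensus]},
               out / "consensus.json")
    stages["selection"] = {
        **{r.method: f"{len(r.selected)} variables" for r in results},
        "consensus": f"{len(consensus)} common variables (>= {cfg.min_votes} votes)",
    }
    if consensus.size == 0:
        raise PipelineError(
            "stepwise: consensus variable set is empty "
            f"(min_votes={cfg.min_votes} exceeded every variable's vote count)"
        )

    # ------------------------------------------------------------- evaluation
    variable_sets = {"full": train.grid.points.copy()}
    variable_sets.update({r.method: r.selected for r in results})
    variable_sets["consensus"] = consensus
    try:
        summary, verdicts = evaluate_variable_sets(
            train, val, variable_sets,
            n_components=cfg.n_components, folds=cfg.folds,
            seed=stage_seed(cfg.seed, "evaluate"),
        )
    except Exception as exc:
        raise PipelineError(f"evaluate: {exc}") from exc
    summary.to_csv(out / "evaluation.csv", index=False)
    verdicts.to_csv(out / "verdicts.csv", index=False)
    stages["evaluation"] = summary
    stages["verdicts"] = verdicts

    # ------------------------------------------- stepwise + Fisher + LOO
    try:
        Xc, wn_c = train.extract(consensus)
        retained, trace = fisher_mod.stepwise_select(
            Xc, train.region_classes, f_enter=cfg.f_enter, f_remove=cfg.f_remove,
            wavenumbers=wn_c,
        )
        if retained.size == 0:
            raise PipelineError("stepwise retained no variables")
        Xr, wn_r = train.extract(retained)
        model = fisher_mod.fisher_fit(Xr, train.region_classes, wavenumbers=wn_r)
        model.to_json(out / "fisher_model.json")
        trace.frame().to_csv(out / "stepwise_trace.csv", index=False)
        resub_acc, resub_conf = fisher_mod.resubstitution(Xr, train.region_classes)
        loo_acc, loo_conf = fisher_mod.loo_cross_validate(Xr, train.region_classes)
        Xv, _ = val.extract(retained)
        val_pred = fisher_mod.fisher_classify(model, Xv)
        val_acc = round(100.0 * float(np.mean(val_pred == val.region_classes)), 2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"fisher: {exc}") from exc
    loo_conf.to_csv(out / "loo_confusion.csv")
    coef_table = pd.DataFrame(
        model.coefficients.T,
        index=[f"{w:.2f}" for w in model.wavenumbers],
        columns=[f"class_{c}" for c in model.classes],
    )
    coef_table.loc["constant"] = model.constants
    coef_table.to_csv(out / "fisher_coefficients.csv")
    stages["fisher"] = {
        "wavenumbers": list(model.wavenumbers),
        "resubstitution_accuracy": resub_acc,
        "coefficients": coef_table,
    }
    stages["loo"] = {"accuracy": loo_acc, "confusion": loo_conf}
    _json_dump(
        {
            "retained_wavenumbers": [round(float(w), 6) for w in model.wavenumbers],
            "resubstitution_accuracy_pct": resub_acc,
            "loo_accuracy_pct": loo_acc,
            "validation_accuracy_pct": val_acc,
        },
        out / "fisher_summary.json",
    )
    stages["annotations"] = reporting.annotate_bands(model.wavenumbers)

    reporting.render_run_report(stages, out / "report.md")
    return out
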