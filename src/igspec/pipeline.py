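"""End-to-end calibration workflow.

Stage order: preprocess -> Dixon-Q screen -> replicate averaging -> sorted
every-third split -> Monte-Carlo cross-validation -> final PLS fit ->
evaluation.  ``calibrate`` drives the stages on in-memory objects and returns
every intermediate of interest; ``run_pipeline`` adds file I/O around it and
writes all artifacts (plain CSV/JSON/YAML) into a run directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .evaluation import (
    DEFAULT_CUTOFF,
    DiagnosticReport,
    EvaluationReport,
    evaluate_model,
)
from .pls import PLSModel, save_model
from .preprocess import PRESETS, PreprocessConfig, average_replicates, preprocess_set
from .qc import DixonConfig, QcReport, screen_spectra
from .selection import MccvResult, fit_final, mccv_curve, sorted_every_third_split

__all__ = ["RunConfig", "PipelineResult", "calibrate", "run_pipeline", "compare_presets"]

logger = logging.getLogger("igspec")

FLOAT_FMT = "%.17g"


def resolve_preprocess(preprocess: str | PreprocessConfig) -> PreprocessConfig:
    if isinstance(preprocess, PreprocessConfig):
        return preprocess
    try:
        return PRESETS[preprocess]
    except KeyError:
        raise ValueError(f"unknown preprocessing preset {preprocess!r}; options: {sorted(PRESETS)}")


@dataclass
class RunConfig:
    spectra_path: str
    reference_path: str
    output_dir: str
    preprocess: str | PreprocessConfig = "smooth"
    qc: DixonConfig = field(default_factory=DixonConfig)
    factor_max: int = 30
    repeats: int = 10_000
    train_size: int | None = None
    seed: int = 0
    cutoff: float = DEFAULT_CUTOFF

    def echo(self) -> dict:
        pp = resolve_preprocess(self.preprocess)
        return {
            "spectra_path": str(self.spectra_path),
            "reference_path": str(self.reference_path),
            "output_dir": str(self.output_dir),
            "preprocess": {
                "base": pp.base,
                "window": pp.window,
                "polyorder": pp.polyorder,
                "normalization": pp.normalization,
                "regions": [list(r) for r in pp.regions],
                "order": "base -> normalization -> region selection",
            },
            "qc": {
                "confidence": self.qc.confidence,
                "exclusion_fraction": self.qc.exclusion_fraction,
                "scope": self.qc.scope,
            },
            "factor_max": self.factor_max,
            "repeats": self.repeats,
            "train_size": self.train_size,
            "seed": self.seed,
            "cutoff": self.cutoff,
        }


@dataclass
class PipelineResult:
    qc_report: QcReport
    split_test_ids: tuple[str, ...]
    split_calibration_ids: tuple[str, ...]
    mccv: MccvResult
    model: PLSModel
    evaluation: EvaluationReport
    diagnostics_test: DiagnosticReport
    diagnostics_all: DiagnosticReport
    predictions: pd.DataFrame  # sample_id, set, reference, predicted, difference
    averaged: sio.SpectrumSet


def calibrate(
    spectra: sio.SpectrumSet,
    reference: sio.ReferenceTable,
    preprocess: str | PreprocessConfig = "smooth",
    qc: DixonConfig = DixonConfig(),
    factor_max: int = 30,
    repeats: int = 10_000,
    train_size: int | None = None,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
) -> PipelineResult:
    """Run the full workflow on in-memory spectra and reference values."""
    pp = resolve_preprocess(preprocess)
    processed = preprocess_set(spectra, pp)
    screened, qc_report = screen_spectra(processed, qc)
    for key in qc_report.excluded_keys():
        logger.info("QC excluded replicate %s", key)
    averaged = average_replicates(screened)

    present = set(averaged.sample_ids())
    ref = sio.ReferenceTable(reference.table[reference.table["sample_id"].isin(present)])
    split = sorted_every_third_split(ref)

    ids_cal = list(split.calibration_ids)
    ids_test = list(split.test_ids)
    by_id = {s.sample_id: s.absorbances for s in averaged}
    X_cal = np.vstack([by_id[i] for i in ids_cal])
    X_test = np.vstack([by_id[i] for i in ids_test])
    y_cal = ref.lookup(ids_cal)
    y_test = ref.lookup(ids_test)

    n_cal = len(ids_cal)
    fmax = min(factor_max, (train_size or (n_cal + 1) // 2) - 1, X_cal.shape[1])
    mccv = mccv_curve(
        X_cal, y_cal, factor_max=fmax, repeats=repeats, train_size=train_size, seed=seed
    )
    logger.info("selected %d PLS factors (RMMCCV %.1f mg/dL)",
                mccv.selected_factors, mccv.rmmccv.min())
    model = fit_final(X_cal, y_cal, mccv.selected_factors, grid=averaged.grid)
    evaluation, diag_test, diag_all = evaluate_model(
        model, X_cal, y_cal, X_test, y_test, cutoff=cutoff
    )

    from .pls import predict  # local import avoids a cycle in docs builds

    pred_cal = predict(model, X_cal)
    pred_test = predict(model, X_test)
    predictions = pd.DataFrame(
        {
            "sample_id": ids_cal + ids_test,
            "set": ["calibration"] * len(ids_cal) + ["test"] * len(ids_test),
            "reference_mg_dl": np.concatenate([y_cal, y_test]),
            "predicted_mg_dl": np.concatenate([pred_cal, pred_test]),
        }
    )
    predictions["difference_mg_dl"] = (
        predictions["reference_mg_dl"] - predictions["predicted_mg_dl"]
    )
    return PipelineResult(
        qc_report=qc_report,
        split_test_ids=split.test_ids,
        split_calibration_ids=split.calibration_ids,
        mccv=mccv,
        model=model,
        evaluation=evaluation,
        diagnostics_test=diag_test,
        diagnostics_all=diag_all,
        predictions=predictions,
        averaged=averaged,
    )


def _metrics_frame(result: PipelineResult) -> pd.DataFrame:
    ev, dt, da = result.evaluation, result.diagnostics_test, result.diagnostics_all
    rows = [
        ("selected_factors", result.mccv.selected_factors),
        ("rmmccv_min_mg_dl", float(result.mccv.rmmccv.min())),
        ("rmsec_mg_dl", ev.rmsec),
        ("rmsep_mg_dl", ev.rmsep),
        ("r_calibration", ev.r_calibration),
        ("r_test", ev.r_test),
        ("bias_mg_dl", ev.bland_altman[0]),
        ("loa_low_mg_dl", ev.bland_altman[1]),
        ("loa_high_mg_dl", ev.bland_altman[2]),
        ("rpd", ev.rpd),
        ("rer", ev.rer),
        ("utility_class", ev.utility_class),
        ("test_tp", dt.tp), ("test_fp", dt.fp), ("test_tn", dt.tn), ("test_fn", dt.fn),
        ("test_sensitivity_pct", dt.sensitivity),
        ("test_specificity_pct", dt.specificity),
        ("test_accuracy_pct", dt.accuracy),
        ("all_tp", da.tp), ("all_fp", da.fp), ("all_tn", da.tn), ("all_fn", da.fn),
        ("all_sensitivity_pct", da.sensitivity),
        ("all_specificity_pct", da.specificity),
        ("all_accuracy_pct", da.accuracy),
        ("all_true_prevalence_pct", da.true_prevalence),
        ("all_apparent_prevalence_pct", da.apparent_prevalence),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def run_pipeline(config: RunConfig) -> Path:
    """File-to-file driver; returns the run directory with all artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run starts: seed=%d", config.seed)
        spectra = sio.read_spectra(config.spectra_path)
        reference = sio.read_reference(config.reference_path)
        result = calibrate(
            spectra,
            reference,
            preprocess=config.preprocess,
            qc=config.qc,
            factor_max=config.factor_max,
            repeats=config.repeats,
            train_size=config.train_size,
            seed=config.seed,
            cutoff=config.cutoff,
        )
        (out / "config_echo.yaml").write_text(yaml.safe_dump(config.echo(), sort_keys=False))
        result.qc_report.table.to_csv(out / "qc_report.csv", index=False, float_format=FLOAT_FMT)
        sio.write_spectra(result.averaged, out / "averaged_spectra.csv")
        pd.DataFrame(
            {
                "sample_id": list(result.split_calibration_ids) + list(result.split_test_ids),
                "set": ["calibration"] * len(result.split_calibration_ids)
                + ["test"] * len(result.split_test_ids),
            }
        ).to_csv(out / "split.csv", index=False)
        pd.DataFrame(
            {"factors": result.mccv.factor_grid, "rmmccv_mg_dl": result.mccv.rmmccv}
        ).to_csv(out / "rmmccv.csv", index=False, float_format=FLOAT_FMT)
        save_model(result.model, out / "model.json")
        result.predictions.to_csv(out / "predictions.csv", index=False, float_format=FLOAT_FMT)
        _metrics_frame(result).to_csv(out / "metrics.csv", index=False, float_format=FLOAT_FMT)
        logger.info("run complete: %d factors, RMSEP %.1f mg/dL, r_test %.3f",
                    result.mccv.selected_factors, result.evaluation.rmsep,
                    result.evaluation.r_test)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return out


def compare_presets(
    spectra: sio.SpectrumSet,
    reference: sio.ReferenceTable,
    presets: list[str] | None = None,
    **calibrate_kwargs,
) -> pd.DataFrame:
    """One row per preprocessing preset with the trial-calibration columns.

    Columns mirror a trial-comparison table: selected factors, RMMCCV, then
    calibration r/RMSEC and prediction r/RMSEP/RPD/RER; the lowest-RMMCCV
    preset is flagged ``best``.
    """
    presets = list(PRESETS) if presets is None else list(presets)
    if not presets:
        raise ValueError("need at least one preset")
    rows = []
    for name in presets:
        res = calibrate(spectra, reference, preprocess=name, **calibrate_kwargs)
        ev = res.evaluation
        rows.append(
            {
                "preset": name,
                "pls_factors": res.mccv.selected_factors,
                "rmmccv_mg_dl": float(res.mccv.rmmccv.min()),
                "r_calibration": ev.r_calibration,
                "rmsec_mg_dl": ev.rmsec,
                "r_test": ev.r_test,
                "rmsep_mg_dl": ev.rmsep,
                "rpd": ev.rpd,
                "rer": ev.rer,
            }
        )
    table = pd.DataFrame(rows)
    table["best"] = table["rmmccv_mg_dl"] == table["rmmccv_mg_dl"].min()
    return table
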