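"""Calibration performance and diagnostic metrics.

RMSEC/RMSEP, Pearson r, Bland-Altman agreement (difference taken as
reference minus IR prediction), RPD and RER with their utility bands, and
2x2 diagnostics at the low-IgG cutoff (positive = IgG strictly below the
cutoff, default 1000 mg/dL, the failure-of-passive-transfer criterion).

Utility bands: RPD < 2 poor; 2-2.5 adequate for screening; above 2.5 (or
RER > 10) acceptable for quantification; above 3 (or RER > 20) accurate
quantitative analysis.  Bands are closed on the left (RPD exactly 2.0 is
screening, exactly 2.5 still screening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pls import PLSModel, predict

__all__ = [
    "EvaluationReport",
    "DiagnosticReport",
    "rmse",
    "pearson_r",
    "bland_altman",
    "rpd_rer",
    "diagnose",
    "diagnostics_from_counts",
    "evaluate_model",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement
DEFAULT_CUTOFF = 1000.0  # mg/dL


@dataclass
class DiagnosticReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None  # percent; None when no reference positives exist
    specificity: float | None
    accuracy: float
    apparent_prevalence: float  # percent positive by the IR assay
    true_prevalence: float      # percent positive by the reference assay
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self) -> dict:
        """Display form: percents to whole numbers, as in a printed 2x2 table."""
        r = lambda v: None if v is None else int(round(v))
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Se%": r(self.sensitivity), "Sp%": r(self.specificity),
            "accuracy%": r(self.accuracy),
        }


@dataclass
class EvaluationReport:
    rmsec: float
    rmsep: float
    r_calibration: float
    r_test: float
    bland_altman: tuple[float, float, float]  # mean difference, LoA low, LoA high (mg/dL)
    rpd: float
    rer: float
    utility_class: str
    difference_direction: str = "reference_minus_prediction"


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("need equal-length nonempty vectors")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def pearson_r(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 3:
        raise ValueError("Pearson r needs at least 3 points")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def bland_altman(y_reference, y_method) -> tuple[float, float, float]:
    """(mean difference, LoA low, LoA high); difference = reference - method."""
    y_reference = np.asarray(y_reference, dtype=float)
    y_method = np.asarray(y_method, dtype=float)
    if y_reference.size < 3 or y_reference.shape != y_method.shape:
        raise ValueError("need equal-length vectors of >= 3 points")
    d = y_reference - y_method
    mean_d = float(d.mean())
    half = LOA_MULTIPLIER * float(d.std(ddof=1))
    return mean_d, mean_d - half, mean_d + half


def rpd_rer(y_test_reference, rmsep: float) -> tuple[float, float, str]:
    """(RPD, RER, utility class) from the test-set reference values and RMSEP."""
    if rmsep <= 0:
        raise ValueError("rmsep must be > 0")
    y = np.asarray(y_test_reference, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("test reference values are constant")
    rpd = float(y.std(ddof=1) / rmsep)
    rer = float(np.ptp(y) / rmsep)
    if rpd < 2.0:
        cls = "poor"
    elif rpd <= 2.5:
        cls = "screening"
    elif rpd <= 3.0:
        cls = "quantification"
    else:
        cls = "accurate"
    return rpd, rer, cls


def diagnostics_from_counts(
    tp: int, fp: int, tn: int, fn: int, cutoff: float = DEFAULT_CUTOFF
) -> DiagnosticReport:
    """Diagnostic metrics straight from a 2x2 table (percent, full precision)."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty 2x2 table")
    se = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    sp = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return DiagnosticReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=se, specificity=sp,
        accuracy=100.0 * (tp + tn) / n,
        apparent_prevalence=100.0 * (tp + fp) / n,
        true_prevalence=100.0 * (tp + fn) / n,
        cutoff=cutoff,
    )


def diagnose(y_reference, y_pred, cutoff: float = DEFAULT_CUTOFF) -> DiagnosticReport:
    """2x2 diagnostics; positive means strictly below the cutoff."""
    y_reference = np.asarray(y_reference, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_reference.shape != y_pred.shape or y_reference.size == 0:
        raise ValueError("need equal-length nonempty vectors")
    truth = y_reference < cutoff
    call = y_pred < cutoff
    tp = int(np.sum(truth & call))
    fn = int(np.sum(truth & ~call))
    fp = int(np.sum(~truth & call))
    tn = int(np.sum(~truth & ~call))
    return diagnostics_from_counts(tp, fp, tn, fn, cutoff)


def evaluate_model(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[EvaluationReport, DiagnosticReport, DiagnosticReport]:
    """Full battery: calibration fit, test prediction, agreement, diagnostics.

    Returns (evaluation, test-set diagnostics, all-data diagnostics); the
    all-data report pools calibration and test predictions, mirroring the
    whole-cohort 2x2 table.
    """
    yhat_cal = predict(model, X_cal)
    yhat_test = predict(model, X_test)
    rmsep = rmse(y_test, yhat_test)
    rpd, rer, cls = rpd_rer(y_test, rmsep)
    report = EvaluationReport(
        rmsec=rmse(y_cal, yhat_cal),
        rmsep=rmsep,
        r_calibration=pearson_r(y_cal, yhat_cal),
        r_test=pearson_r(y_test, yhat_test),
        bland_altman=bland_altman(y_test, yhat_test),
        rpd=rpd,
        rer=rer,
        utility_class=cls,
    )
    diag_test = diagnose(y_test, yhat_test, cutoff)
    diag_all = diagnose(
        np.concatenate([y_cal, y_test]), np.concatenate([yhat_cal, yhat_test]), cutoff
    )
    return report, diag_test, diag_all
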