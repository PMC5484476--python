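"""Data splitting and Monte-Carlo cross-validation factor selection.

The held-out test set is every third sample of the IgG-sorted list (ranks 3,
6, 9, ... ascending), which guarantees it spans the full concentration range;
the remainder forms the calibration set.  The calibration set is then
repeatedly split at random into training and validation halves; a PLS model
is fitted on each training draw at every factor count and validation errors
are pooled across repeats into the RMMCCV curve.  The factor count minimizing
RMMCCV wins (ties toward fewer factors), and the final model is refitted on
the whole calibration set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("igspec")

from .io import ReferenceTable
from .pls import PLSModel, fit_pls, predict_per_factor

__all__ = [
    "SplitResult",
    "MccvResult",
    "sorted_every_third_split",
    "mccv_curve",
    "select_factors",
    "fit_final",
]


@dataclass(frozen=True)
class SplitResult:
    test_ids: tuple[str, ...]
    calibration_ids: tuple[str, ...]


@dataclass
class MccvResult:
    factor_grid: np.ndarray   # 1..max_factors
    rmmccv: np.ndarray        # mg/dL per factor count
    repeats: int
    train_size: int
    validation_size: int
    seed: int
    selected_factors: int
    pooling: str = "pooled"


def sorted_every_third_split(reference: ReferenceTable) -> SplitResult:
    """Sort by IgG ascending (ties by sample_id); 1-based ranks 3, 6, ... go to test."""
    df = reference.table.sort_values(["igg_mg_dl", "sample_id"], kind="mergesort")
    ids = df["sample_id"].to_list()
    if len(ids) < 3:
        raise ValueError("need at least 3 samples to split")
    test = tuple(ids[2::3])
    cal = tuple(s for i, s in enumerate(ids) if (i + 1) % 3 != 0)
    return SplitResult(test_ids=test, calibration_ids=cal)


def mccv_curve(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    factor_max: int = 30,
    repeats: int = 10_000,
    train_size: int | None = None,
    seed: int = 0,
    pooling: str = "pooled",
) -> MccvResult:
    """RMMCCV per factor count over random train/validation partitions.

    Each repeat draws one uniform partition shared by all factor counts (the
    30 trial models of a repeat see the same split).  ``pooling="pooled"``
    returns sqrt of the grand mean squared validation error; ``"per_repeat"``
    averages per-repeat RMSEs instead (the two differ negligibly at equal
    validation sizes).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    n = y_cal.size
    if train_size is None:
        train_size = (n + 1) // 2
    val_size = n - train_size
    if val_size < 1 or train_size < 2:
        raise ValueError("train/validation split leaves an empty part")
    if factor_max > train_size - 1:
        raise ValueError(
            f"factor_max {factor_max} too large for train_size {train_size} (max {train_size - 1})"
        )
    if pooling not in ("pooled", "per_repeat"):
        raise ValueError(f"unknown pooling {pooling!r}")

    sq_sum = np.zeros(factor_max)      # pooled squared error per factor count
    rmse_sum = np.zeros(factor_max)    # per-repeat RMSE accumulator
    count = np.zeros(factor_max)
    log_every = max(1, repeats // 20)  # progress every 5% of repeats
    for rep in range(repeats):
        if repeats >= 100 and (rep + 1) % log_every == 0:
            logger.info("MCCV progress: %d/%d repeats", rep + 1, repeats)
        # counter-based substreams: reproducible and order-independent
        rng = np.random.default_rng([int(seed), 0x3CC5, rep])
        perm = rng.permutation(n)
        tr, va = perm[:train_size], perm[train_size:]
        model = fit_pls(X_cal[tr], y_cal[tr], factor_max)
        pred = predict_per_factor(model, X_cal[va])  # (val, achieved)
        err2 = (pred - y_cal[va][:, None]) ** 2
        k_ach = model.n_factors
        sq_sum[:k_ach] += err2.sum(axis=0)
        rmse_sum[:k_ach] += np.sqrt(err2.mean(axis=0))
        count[:k_ach] += 1
        if k_ach < factor_max:
            # rank-limited repeat: higher counts inherit the achieved model's error
            sq_sum[k_ach:] += err2[:, -1].sum()
            rmse_sum[k_ach:] += np.sqrt(err2[:, -1].mean())
            count[k_ach:] += 1
    if pooling == "pooled":
        rmmccv = np.sqrt(sq_sum / (count * val_size))
    else:
        rmmccv = rmse_sum / count
    result = MccvResult(
        factor_grid=np.arange(1, factor_max + 1),
        rmmccv=rmmccv,
        repeats=repeats,
        train_size=train_size,
        validation_size=val_size,
        seed=int(seed),
        selected_factors=0,
        pooling=pooling,
    )
    result.selected_factors = select_factors(result)
    return result


def select_factors(result: MccvResult) -> int:
    """Factor count with the lowest RMMCCV; ties go to the smaller count."""
    return int(result.factor_grid[int(np.argmin(result.rmmccv))])


def fit_final(
    X_cal: np.ndarray, y_cal: np.ndarray, selected_factors: int, grid: np.ndarray | None = None
) -> PLSModel:
    """Refit on the recombined calibration set with the chosen factor count."""
    return fit_pls(X_cal, y_cal, selected_factors, grid=grid)
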