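"""Decoder performance metrics and exhaustive cross-validation.

Performance is measured per test trial by the Pearson correlation ``r``
between decoded and reference angle (computed per dimension, then averaged)
and by the RMSE normalized by the 90-degree wrist range (nRMSE, pooled over
both dimensions).  Cross-validation is exhaustive over training pairs: every
(wrist training trial, grip training trial) combination defines one fold;
the model is fitted on the pair and evaluated on all remaining trials.
Grip-type test trials, where the wrist does not move, report the angle nRMSE
against the zero-angle reference (a perturbation measure) and the grip-force
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .model import SynergyLRM
from .nmf import HALSConfig
from .preprocess import AlignedTrial
from .simulate import GRIP_CONDITIONS, WRIST_CONDITIONS

__all__ = [
    "pearson_r",
    "nrmse",
    "PerformanceReport",
    "exhaustive_cv",
    "synergy_number_sweep",
    "compare_models_ttest",
]

#: nRMSE normalizer: the wrist angle range limit in degrees.
ANGLE_RANGE_DEG = 90.0


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient between two series."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def nrmse(x: np.ndarray, y: np.ndarray, a: float = ANGLE_RANGE_DEG) -> float:
    """Root-mean-square error between estimate ``x`` and reference ``y``,
    normalized by ``a`` (the 90-degree wrist range by default)."""
    if a <= 0:
        raise ValueError("normalizer a must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("estimate and reference must have equal shape")
    return float(np.sqrt(np.mean((x - y) ** 2)) / a)


@dataclass(frozen=True)
class PerformanceReport:
    """Per-trial and aggregate decoder performance across CV folds.

    ``records`` has one row per (fold, test trial) with the trial condition,
    the angle ``r`` (wrist trials only), the angle nRMSE and — on grip
    trials — the grip-force ``r``.  ``fold_summary`` aggregates per fold;
    the scalar attributes are mean/SD over folds.
    """

    records: pd.DataFrame
    fold_summary: pd.DataFrame
    strategy: str
    j_wrist: int
    wrist_r_mean: float
    wrist_r_sd: float
    wrist_nrmse_mean: float
    wrist_nrmse_sd: float
    grip_nrmse_mean: float
    grip_nrmse_sd: float
    grip_force_r_mean: float
    grip_force_r_sd: float

    def summary(self) -> str:
        lines = [
            f"Exhaustive CV — strategy={self.strategy}, j_wrist={self.j_wrist}, "
            f"{len(self.fold_summary)} folds",
            f"  wrist-motion r      : {self.wrist_r_mean:.4f} ± {self.wrist_r_sd:.4f}",
            f"  wrist-motion nRMSE  : {self.wrist_nrmse_mean:.4f} ± {self.wrist_nrmse_sd:.4f}",
            f"  grip-trial nRMSE    : {self.grip_nrmse_mean:.4f} ± {self.grip_nrmse_sd:.4f}",
            f"  grip-force r        : {self.grip_force_r_mean:.4f} ± {self.grip_force_r_sd:.4f}",
        ]
        return "\n".join(lines)


def _evaluate_trial(results, trial: AlignedTrial, a: float):
    """Metrics of one fitted model on one held-out trial."""
    est = results.predict_angles(trial.E)
    row = {"condition": trial.condition}
    if trial.condition in WRIST_CONDITIONS:
        r_x = pearson_r(est[:, 0], trial.angles[:, 0])
        r_y = pearson_r(est[:, 1], trial.angles[:, 1])
        row["r"] = 0.5 * (r_x + r_y)
        row["nrmse"] = nrmse(est, trial.angles, a)
    else:
        # no movement: angle estimate is pure perturbation versus zero
        row["r"] = np.nan
        row["nrmse"] = nrmse(est, np.zeros_like(est), a)
        if trial.force is not None:
            force_est = results.estimate_grip_force(trial.E)
            row["force_r"] = pearson_r(force_est, trial.force)
    return row


def exhaustive_cv(
    trials: list[AlignedTrial],
    *,
    strategy: str = "slrm2",
    j_wrist: int = 4,
    j_grip: int = 1,
    hals: HALSConfig | None = None,
    train_condition: str = "comfortable_max",
    grip_train_condition: str = "grip_only",
    include_grip_regressor: bool = True,
    a: float = ANGLE_RANGE_DEG,
) -> PerformanceReport:
    """Exhaustive cross-validation over training-trial pairs.

    Every combination of one ``train_condition`` trial and one
    ``grip_train_condition`` trial is a fold; the model fitted on the pair
    is evaluated on all trials outside the pair.
    """
    wrist_pool = [i for i, t in enumerate(trials) if t.condition == train_condition]
    grip_pool = [i for i, t in enumerate(trials) if t.condition == grip_train_condition]
    if len(wrist_pool) < 2 or not grip_pool:
        raise ValueError(
            "need >= 2 wrist training-condition trials and >= 1 grip trial"
        )
    if hals is None:
        hals = HALSConfig()

    rows = []
    fold = 0
    for iw in wrist_pool:
        for ig in grip_pool:
            results = SynergyLRM(
                [trials[iw]], [trials[ig]],
                strategy=strategy, j_wrist=j_wrist, j_grip=j_grip,
                hals=hals, include_grip_regressor=include_grip_regressor,
            ).fit()
            for it, trial in enumerate(trials):
                if it in (iw, ig):
                    continue
                row = _evaluate_trial(results, trial, a)
                row.update(fold=fold, train_wrist=iw, train_grip=ig, trial=it)
                rows.append(row)
            fold += 1

    records = pd.DataFrame(rows)
    is_wrist = records["condition"].isin(WRIST_CONDITIONS)
    is_grip = records["condition"].isin(GRIP_CONDITIONS)
    per_fold = pd.DataFrame({
        "wrist_r": records[is_wrist].groupby("fold")["r"].mean(),
        "wrist_nrmse": records[is_wrist].groupby("fold")["nrmse"].mean(),
        "grip_nrmse": records[is_grip].groupby("fold")["nrmse"].mean(),
    })
    if "force_r" in records.columns:
        per_fold["force_r"] = (
            records[is_grip].groupby("fold")["force_r"].mean()
        )
    else:
        per_fold["force_r"] = np.nan

    def _ms(col):
        vals = per_fold[col].dropna()
        if vals.empty:
            return np.nan, np.nan
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    wr, wrs = _ms("wrist_r")
    wn, wns = _ms("wrist_nrmse")
    gn, gns = _ms("grip_nrmse")
    fr, frs = _ms("force_r")
    return PerformanceReport(
        records=records,
        fold_summary=per_fold,
        strategy=strategy,
        j_wrist=j_wrist,
        wrist_r_mean=wr, wrist_r_sd=wrs,
        wrist_nrmse_mean=wn, wrist_nrmse_sd=wns,
        grip_nrmse_mean=gn, grip_nrmse_sd=gns,
        grip_force_r_mean=fr, grip_force_r_sd=frs,
    )


def synergy_number_sweep(
    trials: list[AlignedTrial],
    j_range=range(1, 7),
    *,
    strategy: str = "slrm2",
    **cv_kwargs,
) -> pd.DataFrame:
    """Decoder performance as a function of the wrist synergy count.

    Runs :func:`exhaustive_cv` at each count in ``j_range`` and tabulates
    the fold-aggregated metrics.
    """
    rows = []
    for j in j_range:
        rep = exhaustive_cv(trials, strategy=strategy, j_wrist=int(j), **cv_kwargs)
        rows.append({
            "j_wrist": int(j),
            "wrist_r_mean": rep.wrist_r_mean,
            "wrist_r_sd": rep.wrist_r_sd,
            "wrist_nrmse_mean": rep.wrist_nrmse_mean,
            "wrist_nrmse_sd": rep.wrist_nrmse_sd,
            "grip_nrmse_mean": rep.grip_nrmse_mean,
        })
    return pd.DataFrame(rows).set_index("j_wrist")


def compare_models_ttest(a_values, b_values) -> tuple[float, float]:
    """Two-sample Student's t-test between two sets of per-fold metrics.

    Thin wrapper over the standard two-sample statistic; no multiple-testing
    adjustment is applied.  Returns ``(t, p)``.
    """
    res = stats.ttest_ind(np.asarray(a_values), np.asarray(b_values))
    return float(res.statistic), float(res.pvalue)
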