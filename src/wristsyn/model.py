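"""Synergy-based linear regression model (SLRM) of wrist angle and grip force.

The model is fitted from one (or more) wrist-movement training trials and
one grip training trial:

1. a synergy basis ``S`` is extracted by HALS NMF, either jointly from the
   concatenated trials (strategy ``"slrm1"``) or separately per trial type
   (``"slrm2"``);
2. training activations ``M`` are the nonnegative projections of the
   training envelopes on the frozen basis;
3. the normalized sum/difference angle coordinates are regressed on the
   activations by ordinary least squares,

       theta_i = a_{0,i} + sum_j a_{j,i} m_j + eps,   i in {sum, diff};

4. grip force is read out directly from the grip synergy activation with a
   single calibration gain that maps the training grip trial's peak
   activation to normalized force 1.0 — no second regression.

``SynergyLRM`` holds the data and configuration; ``fit()`` returns a
``SynergyLRMResults`` carrying the synergy set, regression coefficients with
their standard errors, the frozen angle normalization, the grip gain, and
prediction / plotting / summary methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .angles import AngleNormalizer
from .exceptions import CalibrationError
from .nmf import (
    HALSConfig,
    SynergySet,
    extract_slrm1,
    extract_slrm2,
    project_activations,
    vaf,
)
from .preprocess import AlignedTrial

__all__ = [
    "RegressionModel",
    "fit_regression",
    "predict_sum_diff",
    "predict_angles",
    "estimate_grip_force",
    "SynergyLRM",
    "SynergyLRMResults",
]


@dataclass(frozen=True)
class RegressionModel:
    """OLS map from synergy activations to sum/difference angle targets.

    ``intercept`` is (2,) — the per-dimension angle bias; ``coef`` is
    (j, 2); ``bse`` the corresponding standard errors ((1+j, 2), intercept
    first); ``resid_rms`` the per-dimension residual RMS on training data.
    """

    intercept: np.ndarray
    coef: np.ndarray
    bse: np.ndarray
    resid_rms: np.ndarray

    @property
    def n_synergies(self) -> int:
        return self.coef.shape[0]


def fit_regression(M_train: np.ndarray, targets: np.ndarray) -> RegressionModel:
    """Per-dimension OLS of sum/difference targets on activations.

    A rank-deficient design triggers a warning and falls back to the
    minimum-norm (pseudoinverse) solution, which is what statsmodels
    computes.
    """
    M_train = np.asarray(M_train, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if M_train.shape[0] != targets.shape[0]:
        raise ValueError("activations and targets must share time length")
    if M_train.shape[0] < M_train.shape[1] + 1:
        raise ValueError("need at least j+1 samples to fit the regression")
    X = sm.add_constant(M_train, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "rank-deficient regression design; using the minimum-norm solution",
            stacklevel=2,
        )
    params = np.empty((X.shape[1], 2))
    bse = np.empty((X.shape[1], 2))
    rms = np.empty(2)
    for i in range(2):
        res = sm.OLS(targets[:, i], X).fit()
        params[:, i] = res.params
        bse[:, i] = res.bse
        rms[i] = float(np.sqrt(np.mean(res.resid**2)))
    return RegressionModel(
        intercept=params[0], coef=params[1:], bse=bse, resid_rms=rms
    )


def predict_sum_diff(M_new: np.ndarray, reg: RegressionModel) -> np.ndarray:
    M_new = np.asarray(M_new, dtype=float)
    if M_new.shape[1] != reg.n_synergies:
        raise ValueError(
            f"activation has {M_new.shape[1]} synergies, model expects "
            f"{reg.n_synergies}"
        )
    return reg.intercept + M_new @ reg.coef


def predict_angles(
    M_new: np.ndarray, reg: RegressionModel, norm: AngleNormalizer
) -> np.ndarray:
    """Apply the regression and invert the sum/difference transform,
    returning (n, 2) angles in degrees."""
    return norm.inverse(predict_sum_diff(M_new, reg))


def estimate_grip_force(
    M_new: np.ndarray, grip_column: int, grip_gain: float
) -> np.ndarray:
    """Normalized grip-force series: grip activation times the calibration
    gain."""
    return np.asarray(M_new, dtype=float)[:, grip_column] * grip_gain


class SynergyLRM:
    """Synergy-based linear regression model builder.

    Parameters
    ----------
    wrist_trials : list of AlignedTrial
        Training trials with wrist movement (typically one comfortable-
        maximum trial).
    grip_trials : list of AlignedTrial
        Grip training trials (typically one grip-only trial); the first one
        calibrates the force gain.
    strategy : {"slrm1", "slrm2"}
        Joint extraction of all synergies from the concatenated trials, or
        separate extraction per trial type.
    j_wrist, j_grip : int
        Synergy counts; the grip count is one in the reference protocol.
    hals : HALSConfig
    include_grip_regressor : bool
        Whether the grip synergy activation enters the angle regression
        (default True: the regression sums over every activation).
    """

    def __init__(
        self,
        wrist_trials: list[AlignedTrial],
        grip_trials: list[AlignedTrial],
        *,
        strategy: str = "slrm2",
        j_wrist: int = 4,
        j_grip: int = 1,
        hals: HALSConfig | None = None,
        include_grip_regressor: bool = True,
    ):
        if strategy not in ("slrm1", "slrm2"):
            raise ValueError("strategy must be 'slrm1' or 'slrm2'")
        if not wrist_trials or not grip_trials:
            raise ValueError("need at least one wrist and one grip training trial")
        self.wrist_trials = list(wrist_trials)
        self.grip_trials = list(grip_trials)
        self.strategy = strategy
        self.j_wrist = int(j_wrist)
        self.j_grip = int(j_grip)
        self.hals = hals if hals is not None else HALSConfig()
        self.include_grip_regressor = bool(include_grip_regressor)

    def fit(self) -> "SynergyLRMResults":
        E_wrist = np.vstack([t.E for t in self.wrist_trials])
        E_grip = np.vstack([t.E for t in self.grip_trials])

        if self.strategy == "slrm1":
            synergies = extract_slrm1(
                [E_wrist, E_grip], self.j_wrist, self.j_grip, self.hals
            )
        else:
            synergies = extract_slrm2(
                E_wrist, E_grip, self.j_wrist, self.j_grip, self.hals
            )

        norm = AngleNormalizer.fit([t.angles for t in self.wrist_trials])
        targets = norm.forward(
            np.vstack([t.angles for t in self.wrist_trials])
        )
        M_train = project_activations(E_wrist, synergies)
        reg_cols = self._regressor_columns(synergies)
        reg = fit_regression(M_train[:, reg_cols], targets)

        train_vaf = vaf(E_wrist, M_train, synergies.S)

        grip_col = synergies.grip_columns[0]
        M_grip = project_activations(E_grip, synergies)
        peak = float(np.max(M_grip[:, grip_col], initial=0.0))
        if peak <= 0:
            raise CalibrationError(
                "grip synergy activation is zero on the grip training trial"
            )
        grip_gain = 1.0 / peak

        return SynergyLRMResults(
            model=self,
            synergies=synergies,
            regression=reg,
            angle_norm=norm,
            grip_gain=grip_gain,
            train_vaf=train_vaf,
        )

    def _regressor_columns(self, synergies: SynergySet) -> list[int]:
        if self.include_grip_regressor:
            return list(range(synergies.j))
        return list(synergies.wrist_columns)


@dataclass(frozen=True)
class SynergyLRMResults:
    """Fitted synergy decoder: basis, regression and calibration constants."""

    model: SynergyLRM
    synergies: SynergySet
    regression: RegressionModel
    angle_norm: AngleNormalizer
    grip_gain: float
    train_vaf: float

    # -- prediction -------------------------------------------------------

    def project(self, E_new: np.ndarray) -> np.ndarray:
        """Nonnegative activations of new envelope data on the frozen basis."""
        return project_activations(E_new, self.synergies)

    def predict_angles(self, E_new: np.ndarray, *, activations=None) -> np.ndarray:
        """Decoded 2-D wrist angle (degrees) for new envelope data."""
        M = self.project(E_new) if activations is None else np.asarray(activations)
        cols = self.model._regressor_columns(self.synergies)
        return predict_angles(M[:, cols], self.regression, self.angle_norm)

    def estimate_grip_force(self, E_new: np.ndarray, *, activations=None) -> np.ndarray:
        """Normalized grip-force estimate for new envelope data."""
        M = self.project(E_new) if activations is None else np.asarray(activations)
        return estimate_grip_force(
            M, self.synergies.grip_columns[0], self.grip_gain
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        reg = self.regression
        head = [
            ["strategy", self.model.strategy],
            ["wrist synergies", str(self.model.j_wrist)],
            ["grip synergies", str(self.model.j_grip)],
            ["training VAF", f"{self.train_vaf:.4f}"],
            ["angle norm (max_x, max_y) [deg]",
             f"({self.angle_norm.max_x:.2f}, {self.angle_norm.max_y:.2f})"],
            ["grip gain", f"{self.grip_gain:.4f}"],
        ]
        rows = [
            ["bias", f"{reg.intercept[0]:.4f}", f"{reg.bse[0, 0]:.4f}",
             f"{reg.intercept[1]:.4f}", f"{reg.bse[0, 1]:.4f}"]
        ]
        cols = self.model._regressor_columns(self.synergies)
        for i, c in enumerate(cols):
            role = self.synergies.roles[c]
            rows.append([
                f"m{c + 1} ({role})",
                f"{reg.coef[i, 0]:.4f}", f"{reg.bse[i + 1, 0]:.4f}",
                f"{reg.coef[i, 1]:.4f}", f"{reg.bse[i + 1, 1]:.4f}",
            ])
        tbl1 = SimpleTable(head, title="Synergy-based linear regression model")
        tbl2 = SimpleTable(
            rows,
            headers=["regressor", "coef (sum)", "se", "coef (diff)", "se"],
        )
        return str(tbl1) + "\n" + str(tbl2)

    # -- plotting ---------------------------------------------------------

    def plot_synergies(self, ax=None):
        """Bar plot of the synergy loadings per channel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        S = self.synergies.S
        n, j = S.shape
        width = 0.8 / j
        x = np.arange(n)
        for k in range(j):
            ax.bar(x + k * width, S[:, k], width,
                   label=f"synergy {k + 1} ({self.synergies.roles[k]})")
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(self.synergies.channel_labels)
        ax.set_ylabel("loading")
        ax.legend(fontsize="small")
        return ax

    def plot_prediction(self, trial: AlignedTrial, ax=None):
        """Reference versus decoded wrist angle time series for one trial."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(trial.angles.shape[0]) / trial.rate
        est = self.predict_angles(trial.E)
        ax.plot(t, trial.angles[:, 0], "C0-", label="angle X (ref)")
        ax.plot(t, est[:, 0], "C0--", label="angle X (est)")
        ax.plot(t, trial.angles[:, 1], "C1-", label="angle Y (ref)")
        ax.plot(t, est[:, 1], "C1--", label="angle Y (est)")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("angle [deg]")
        ax.legend(fontsize="small")
        return ax
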