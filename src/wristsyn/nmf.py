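"""Muscle-synergy extraction by hierarchical alternating least squares NMF.

The envelope matrix is factorized as ``E ~ M @ S.T`` with ``E`` (time x
channel), ``S`` (channel x synergy) the synergy set and ``M`` (time x
synergy) the activation coefficients, both nonnegative.  HALS updates one
synergy (column pair ``s_k``, ``m_k``) at a time by projected least squares:

    s_k <- [ s_k + (E'M - S M'M)_k / (m_k' m_k) ]_+
    m_k <- [ m_k + (E S - M S'S)_k / (s_k' s_k) ]_+

which makes the Frobenius objective non-increasing sweep by sweep.  Unlike
canonical multiplicative updates, HALS remains usable when the number of
synergies exceeds the number of channels (overcomplete sets).  The scale
ambiguity of the factorization is resolved by unit-Euclidean-norm columns of
``S``, with the magnitude carried by ``M``.

Two extraction strategies are provided: a single joint factorization of
concatenated wrist+grip trials (SLRM1), and separate factorizations of a
wrist trial and a grip trial whose columns are then concatenated (SLRM2).
The wrist synergy count is chosen as the smallest count whose
variance-accounted-for (VAF) reaches a threshold (0.9) on every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import DegenerateDataError, SelectionError
from .simulate import CHANNELS

__all__ = [
    "HALSConfig",
    "SynergySet",
    "hals_nmf",
    "vaf",
    "select_from_vaf_table",
    "select_wrist_synergy_number",
    "extract_slrm1",
    "extract_slrm2",
    "project_activations",
    "match_synergies",
]

_FINGER_CH = (5, 6)  # FDS, FDP


@dataclass(frozen=True)
class HALSConfig:
    """Convergence and restart settings for HALS.

    ``tol`` is the relative change of the Frobenius objective between sweeps
    below which a restart stops; ``n_restarts`` random initializations are
    run and the best objective kept; ``eps`` guards denominators and floors
    dead columns.
    """

    max_sweeps: int = 500
    tol: float = 1e-8
    n_restarts: int = 10
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass(frozen=True)
class SynergySet:
    """Channel-by-synergy nonnegative basis with per-column roles.

    ``roles`` holds ``"wrist"`` or ``"grip"`` per column; columns have unit
    Euclidean norm.
    """

    S: np.ndarray
    roles: tuple
    channel_labels: tuple = CHANNELS

    def __post_init__(self):
        if self.S.shape[1] != len(self.roles):
            raise ValueError("one role per synergy column required")

    @property
    def j(self) -> int:
        return self.S.shape[1]

    @property
    def grip_columns(self) -> tuple:
        return tuple(k for k, r in enumerate(self.roles) if r == "grip")

    @property
    def wrist_columns(self) -> tuple:
        return tuple(k for k, r in enumerate(self.roles) if r == "wrist")


def _objective(E, M, S, normE2, ES):
    # ||E - M S'||_F^2 via the Gram expansion; ES = E @ S is reused.
    return normE2 - 2.0 * np.sum(M * ES) + np.sum((M.T @ M) * (S.T @ S))


def _hals_single(E, j, cfg, rng):
    m, n = E.shape
    scale = np.sqrt(max(E.mean(), cfg.eps))
    M = rng.uniform(0.0, 1.0, (m, j)) * scale
    S = rng.uniform(0.0, 1.0, (n, j))
    S /= np.maximum(np.linalg.norm(S, axis=0, keepdims=True), cfg.eps)

    normE2 = float(np.sum(E * E))
    prev = np.inf
    history = []
    for _ in range(cfg.max_sweeps):
        # --- update S columns (M fixed; B = M'M constant over this sweep,
        #     each column update is the exact projected LS minimizer)
        A = E.T @ M            # n x j
        B = M.T @ M            # j x j
        for k in range(j):
            denom = max(B[k, k], cfg.eps)
            s = S[:, k] + (A[:, k] - S @ B[:, k]) / denom
            np.clip(s, 0.0, None, out=s)
            if np.linalg.norm(s) < cfg.eps:
                # dead synergy: reseed the direction, silence its activation
                # (outer product stays zero, so the objective is untouched)
                s = rng.uniform(0.0, 1.0, n)
                s /= np.linalg.norm(s)
                M[:, k] = 0.0
                B = M.T @ M
            S[:, k] = s
        # --- update M columns (S fixed)
        C = E @ S              # m x j
        D = S.T @ S            # j x j
        for k in range(j):
            denom = max(D[k, k], cfg.eps)
            mcol = M[:, k] + (C[:, k] - M @ D[:, k]) / denom
            np.clip(mcol, 0.0, None, out=mcol)
            M[:, k] = mcol

        f = _objective(E, M, S, normE2, E @ S)
        history.append(f)
        if np.isfinite(prev) and prev - f <= cfg.tol * max(prev, cfg.eps):
            break
        prev = f

    # unit-norm columns of S, magnitude pushed into M (product preserved)
    nrm = np.linalg.norm(S, axis=0)
    alive = nrm > cfg.eps
    S[:, alive] /= nrm[alive]
    M[:, alive] *= nrm[alive]
    return M, S, history


def hals_nmf(
    E: np.ndarray, j: int, config: HALSConfig | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Factorize a nonnegative envelope matrix into ``j`` synergies.

    Runs ``config.n_restarts`` seeded random initializations of the HALS
    sweep and keeps the factors with the lowest Frobenius objective.

    Returns
    -------
    M : (m, j) ndarray
        Nonnegative activation coefficients.
    S : (n, j) ndarray
        Nonnegative synergy basis with unit-norm columns.
    info : dict
        ``objective`` (best final value), ``history`` (objective per sweep of
        the best restart), ``restart`` (index of the best restart).
    """
    if config is None:
        config = HALSConfig()
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError("E must be a 2-D time-by-channel matrix")
    if j < 1:
        raise ValueError("number of synergies j must be >= 1")
    if np.any(E < 0):
        raise ValueError("E must be nonnegative")
    if not np.any(E > 0):
        raise DegenerateDataError("E is identically zero; nothing to factorize")

    best = None
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31, size=config.n_restarts)
    for idx, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        M, S, history = _hals_single(E, j, config, rng)
        f = history[-1]
        if best is None or f < best[0]:
            best = (f, M, S, history, idx)
    f, M, S, history, idx = best
    return M, S, {"objective": f, "history": history, "restart": idx}


def vaf(E: np.ndarray, M: np.ndarray, S: np.ndarray) -> float:
    """Uncentered variance accounted for of the reconstruction ``M @ S.T``.

    ``1 - ||E - M S'||_F^2 / ||E||_F^2``; equals 1 for a perfect
    reconstruction and 0 when the model explains nothing.
    """
    E = np.asarray(E, dtype=float)
    total = np.sum(E * E)
    if total <= 0:
        raise DegenerateDataError("VAF undefined for an all-zero matrix")
    resid = E - np.asarray(M) @ np.asarray(S).T
    return float(1.0 - np.sum(resid * resid) / total)


def select_from_vaf_table(
    min_vaf: dict, threshold: float = 0.9
) -> int:
    """Smallest synergy count whose minimum-over-datasets VAF reaches the
    threshold.  Raises :class:`SelectionError` (carrying the table) if none
    qualifies."""
    for j in sorted(min_vaf):
        if min_vaf[j] >= threshold:
            return j
    raise SelectionError(
        f"no synergy count reached VAF >= {threshold}", vaf_table=dict(min_vaf)
    )


def select_wrist_synergy_number(
    datasets: list[np.ndarray],
    j_range=range(1, 7),
    threshold: float = 0.9,
    config: HALSConfig | None = None,
) -> tuple[int, dict]:
    """Choose the wrist synergy count by the all-datasets VAF criterion.

    For each candidate count, every dataset is factorized and its VAF
    recorded; the selected count is the smallest one whose *minimum* VAF
    across datasets reaches ``threshold``, so the choice holds for every
    subject/trial supplied.

    Returns the selected count and the full ``{j: [vaf per dataset]}`` table.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if config is None:
        config = HALSConfig()
    table = {}
    for j in j_range:
        vals = []
        for E in datasets:
            M, S, _ = hals_nmf(E, j, config)
            vals.append(vaf(E, M, S))
        table[int(j)] = vals
    min_table = {j: min(v) for j, v in table.items()}
    selected = select_from_vaf_table(min_table, threshold)
    return selected, table


def _label_grip_columns(S: np.ndarray, j_grip: int, finger_channels) -> SynergySet:
    """Label the ``j_grip`` columns with the largest finger-flexor loading
    fraction as grip synergies and move them to the end."""
    fingers = list(finger_channels)
    ratio = np.linalg.norm(S[fingers, :], axis=0) / np.maximum(
        np.linalg.norm(S, axis=0), 1e-300
    )
    grip_cols = list(np.argsort(ratio)[::-1][:j_grip])
    wrist_cols = [k for k in range(S.shape[1]) if k not in grip_cols]
    order = wrist_cols + sorted(grip_cols, key=lambda k: -ratio[k])
    roles = ("wrist",) * len(wrist_cols) + ("grip",) * j_grip
    return SynergySet(S[:, order], roles)


def extract_slrm1(
    joint_trials: list[np.ndarray],
    j_wrist: int,
    j_grip: int = 1,
    config: HALSConfig | None = None,
    finger_channels=_FINGER_CH,
) -> SynergySet:
    """Joint-trial strategy: one HALS factorization of all trials
    concatenated in time, with ``j_wrist + j_grip`` synergies; the grip
    synergy is identified afterwards as the column loading the finger
    flexors most."""
    if not joint_trials:
        raise ValueError("joint_trials must be non-empty")
    if j_wrist < 1 or j_grip < 1:
        raise ValueError("j_wrist and j_grip must be >= 1")
    ncols = {np.asarray(t).shape[1] for t in joint_trials}
    if len(ncols) != 1:
        raise ValueError("trials have inconsistent channel counts")
    E = np.vstack([np.asarray(t, dtype=float) for t in joint_trials])
    _, S, _ = hals_nmf(E, j_wrist + j_grip, config)
    return _label_grip_columns(S, j_grip, finger_channels)


def extract_slrm2(
    wrist_trial: np.ndarray,
    grip_trial: np.ndarray,
    j_wrist: int,
    j_grip: int = 1,
    config: HALSConfig | None = None,
) -> SynergySet:
    """Separate-trial strategy: wrist synergies from the wrist trial, grip
    synergies from the grip trial, columns concatenated (wrist first)."""
    if j_wrist < 1 or j_grip < 1:
        raise ValueError("j_wrist and j_grip must be >= 1")
    wrist_trial = np.asarray(wrist_trial, dtype=float)
    grip_trial = np.asarray(grip_trial, dtype=float)
    if wrist_trial.shape[1] != grip_trial.shape[1]:
        raise ValueError("wrist and grip trials must share channels")
    if config is None:
        config = HALSConfig()
    _, S_w, _ = hals_nmf(wrist_trial, j_wrist, config)
    # decorrelate the restart stream of the second factorization
    cfg_g = replace(config, seed=config.seed + 1)
    _, S_g, _ = hals_nmf(grip_trial, j_grip, cfg_g)
    S = np.hstack([S_w, S_g])
    roles = ("wrist",) * j_wrist + ("grip",) * j_grip
    return SynergySet(S, roles)


def project_activations(
    E_new: np.ndarray,
    S: np.ndarray | SynergySet,
    *,
    max_sweeps: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Nonnegative least-squares activations of new data on a frozen basis.

    Minimizes ``||E_new - M S'||_F`` over ``M >= 0`` by HALS sweeps with
    ``S`` fixed (block coordinate descent over activation columns, all time
    samples vectorized), which solves the per-sample NNLS problems.
    """
    if isinstance(S, SynergySet):
        S = S.S
    S = np.asarray(S, dtype=float)
    E_new = np.asarray(E_new, dtype=float)
    if E_new.shape[1] != S.shape[0]:
        raise ValueError(
            f"channel mismatch: data has {E_new.shape[1]}, basis {S.shape[0]}"
        )
    j = S.shape[1]
    M = np.zeros((E_new.shape[0], j))
    C = E_new @ S
    D = S.T @ S
    diag = np.maximum(np.diag(D), 1e-300)
    for _ in range(max_sweeps):
        delta = 0.0
        for k in range(j):
            new = M[:, k] + (C[:, k] - M @ D[:, k]) / diag[k]
            np.clip(new, 0.0, None, out=new)
            delta = max(delta, float(np.max(np.abs(new - M[:, k]), initial=0.0)))
            M[:, k] = new
        if delta <= tol * max(1.0, float(np.max(M, initial=0.0))):
            break
    return M


def match_synergies(
    S_est: np.ndarray, S_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column matching between two synergy sets.

    Hungarian assignment maximizing total cosine similarity.  Returns the
    permutation ``perm`` (``S_est[:, perm]`` aligns with ``S_ref``) and the
    per-column cosine similarities in reference order.
    """
    S_est = np.asarray(S_est, dtype=float)
    S_ref = np.asarray(S_ref, dtype=float)
    a = S_est / np.maximum(np.linalg.norm(S_est, axis=0, keepdims=True), 1e-300)
    b = S_ref / np.maximum(np.linalg.norm(S_ref, axis=0, keepdims=True), 1e-300)
    sim = a.T @ b  # est x ref
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(S_ref.shape[1], dtype=int)
    sims = np.empty(S_ref.shape[1])
    for r, c in zip(rows, cols):
        perm[c] = r
        sims[c] = sim[r, c]
    return perm, sims
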