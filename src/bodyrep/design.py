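"""Block design construction, canonical HRF, design matrices, first-level GLM.

The run layout is fixed: 20 task blocks of 12 s (10 conditions x 2
repetitions) with fixation baselines of 27 s before block 1, 12 s after
blocks 5, 10 and 15, and 15 s after block 20 — 318 s, i.e. 106 volumes at
TR 3 s. Condition boxcars are convolved with a double-gamma canonical HRF
at 0.1 s resolution and sampled at volume onsets; a discrete-cosine basis
implements 1/128 Hz high-pass filtering inside the design matrix.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps

from .conditions import CONDITIONS

BLOCK_DURATION_S = 12.0
N_BLOCKS = 20
INITIAL_BASELINE_S = 27.0
MID_BASELINE_S = 12.0  # after blocks 5, 10, 15
FINAL_BASELINE_S = 15.0


@dataclass(frozen=True)
class RunDesign:
    """Timing of one run: ordered (condition, onset s) blocks and baselines."""

    tr: float
    blocks: tuple[tuple[str, float], ...]
    baselines: tuple[tuple[float, float], ...]  # (onset, duration)
    n_volumes: int
    block_duration: float = BLOCK_DURATION_S

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma canonical HRF parameters (SPM parameterization)."""

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.response_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be > 0")
        if self.length <= self.response_delay:
            raise ValueError("kernel length must exceed the response delay")


@dataclass
class DesignMatrix:
    """Volume x regressor matrix with labeled columns."""

    values: np.ndarray
    labels: list[str]
    highpass_cutoff: float | None = None

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


@dataclass
class GLMFit:
    """First-level GLM estimates: betas, residual variance, df."""

    betas: np.ndarray  # (n_regressors, n_voxels)
    labels: list[str]
    residual_variance: np.ndarray  # (n_voxels,)
    df: int
    ar_coefficient: float | None = None
    rank_deficient: bool = False

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.labels.index(label)]

    def contrast(self, positive: str, negative: str) -> np.ndarray:
        """Simple difference contrast between two named regressors."""
        return self.beta(positive) - self.beta(negative)


def default_block_order(seed: int = 0, conditions: tuple[str, ...] = CONDITIONS) -> list[str]:
    """A pseudo-random order of 20 blocks, each condition appearing twice."""
    rng = np.random.default_rng([seed, 2971215073])
    order = list(conditions) * 2
    rng.shuffle(order)
    return order


def build_run_design(
    condition_order: list[str],
    tr: float = 3.0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> RunDesign:
    """Lay the 20 blocks of ``condition_order`` onto the fixed run schedule."""
    if Counter(condition_order) != Counter(list(conditions) * 2):
        raise ValueError(
            "condition_order must contain each of the 10 conditions exactly twice"
        )
    blocks: list[tuple[str, float]] = []
    baselines: list[tuple[float, float]] = [(0.0, INITIAL_BASELINE_S)]
    t = INITIAL_BASELINE_S
    for i, cond in enumerate(condition_order, start=1):
        blocks.append((cond, t))
        t += BLOCK_DURATION_S
        if i in (5, 10, 15):
            baselines.append((t, MID_BASELINE_S))
            t += MID_BASELINE_S
    baselines.append((t, FINAL_BASELINE_S))
    t += FINAL_BASELINE_S
    n_volumes = t / tr
    if abs(n_volumes - round(n_volumes)) > 1e-9:
        raise ValueError(f"run duration {t} s is not a whole number of TRs ({tr} s)")
    return RunDesign(
        tr=tr,
        blocks=tuple(blocks),
        baselines=tuple(baselines),
        n_volumes=int(round(n_volumes)),
    )


def canonical_hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sampled double-gamma kernel: gamma response minus scaled undershoot.

    Returns length/dt + 1 samples starting at t = 0.
    """
    t = np.arange(0.0, spec.length + spec.dt / 2, spec.dt)
    peak = sps.gamma.pdf(
        t, a=spec.response_delay / spec.response_dispersion, scale=spec.response_dispersion
    )
    under = sps.gamma.pdf(
        t,
        a=spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    return peak - under / spec.ratio


def condition_regressors(
    design: RunDesign,
    hrf: HRFSpec = HRFSpec(),
    conditions: tuple[str, ...] = CONDITIONS,
) -> np.ndarray:
    """HRF-convolved condition boxcars sampled at volume onsets.

    Boxcars are built at the HRF's microtime resolution, convolved, then
    sampled at t = k * TR. Shape (n_volumes, len(conditions)); a condition
    with no block in the run yields an all-zero column.
    """
    dt = hrf.dt
    n_fine = int(round(design.duration / dt))
    kernel = canonical_hrf(hrf)
    out = np.zeros((design.n_volumes, len(conditions)))
    vol_idx = np.round(np.arange(design.n_volumes) * design.tr / dt).astype(int)
    for c, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        for name, onset in design.blocks:
            if name == cond:
                i0 = int(round(onset / dt))
                i1 = int(round((onset + design.block_duration) / dt))
                box[i0:i1] = 1.0
        conv = np.convolve(box, kernel)[:n_fine] * dt
        out[:, c] = conv[vol_idx]
    return out


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass basis: floor(2 T / cutoff) columns.

    Column k (1-based) is cos(pi k (2n + 1) / (2 N)), the standard DCT-II
    drift basis; the constant term is excluded (carried by the intercept).
    """
    if cutoff <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed 2 x TR")
    total = n_volumes * tr
    n_basis = int(np.floor(2 * total / cutoff))
    n = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def build_design_matrix(
    design: RunDesign,
    hrf: HRFSpec = HRFSpec(),
    motion: np.ndarray | None = None,
    highpass_cutoff: float = 128.0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> DesignMatrix:
    """Full first-level design: conditions, DCT drift, motion, constant last."""
    X_cond = condition_regressors(design, hrf, conditions)
    parts = [X_cond]
    labels = list(conditions)
    dct = dct_highpass_basis(design.n_volumes, design.tr, highpass_cutoff)
    parts.append(dct)
    labels += [f"hp_dct_{k}" for k in range(1, dct.shape[1] + 1)]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != design.n_volumes:
            raise ValueError("motion trace length must equal n_volumes")
        parts.append(motion)
        labels += [f"motion_{k}" for k in range(1, motion.shape[1] + 1)]
    parts.append(np.ones((design.n_volumes, 1)))
    labels.append("constant")
    return DesignMatrix(np.hstack(parts), labels, highpass_cutoff)


def global_scale(Y: np.ndarray, target: float = 100.0) -> np.ndarray:
    """Proportional global signal scaling of a run to a grand mean of ``target``."""
    grand = Y.mean()
    if grand == 0:
        raise ValueError("cannot scale a zero-mean run")
    return Y * (target / grand)


def _ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, bool]:
    rank = np.linalg.matrix_rank(X)
    deficient = rank < X.shape[1]
    betas = np.linalg.pinv(X) @ Y if deficient else np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = Y - X @ betas
    df = Y.shape[0] - rank
    return betas, resid, df, deficient


def fit_glm(Y: np.ndarray, X: DesignMatrix, whiten: bool = False) -> GLMFit:
    """Ordinary least squares per voxel; optional pooled-AR(1) prewhitening.

    With ``whiten``, a single AR(1) coefficient is estimated from the
    pooled OLS residuals of all voxels and the model is refit on
    AR(1)-whitened data — a pooled approximation to restricted
    maximum-likelihood autocorrelation modeling.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.values.shape[0]:
        raise ValueError("Y and design matrix row counts differ")
    betas, resid, df, deficient = _ols(Y, X.values)
    rho = None
    if whiten:
        rho = pooled_ar1(resid)
        W_Y = _ar1_whiten(Y, rho)
        W_X = _ar1_whiten(X.values, rho)
        betas, resid, df, deficient = _ols(W_Y, W_X)
    resid_var = (resid**2).sum(axis=0) / max(df, 1)
    return GLMFit(
        betas=betas,
        labels=list(X.labels),
        residual_variance=resid_var,
        df=df,
        ar_coefficient=rho,
        rank_deficient=deficient,
    )


def pooled_ar1(resid: np.ndarray) -> float:
    """Lag-1 autocorrelation of residuals pooled over voxels (Yule-Walker)."""
    r = resid - resid.mean(axis=0)
    num = (r[1:] * r[:-1]).sum()
    den = (r**2).sum()
    return float(num / den) if den > 0 else 0.0


def _ar1_whiten(A: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(A, dtype=float)
    out[0] = A[0] * np.sqrt(1 - rho**2)
    out[1:] = A[1:] - rho * A[:-1]
    return out


def group_t_map(
    contrasts: np.ndarray,
    mode: str = "one-sample",
    contrasts2: np.ndarray | None = None,
    alpha: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise group t map with an uncorrected-threshold mask.

    ``contrasts`` is (n_subjects, n_voxels). One-sample tests the mean
    against 0; two-sample is an equal-variance comparison with
    ``contrasts2``. Zero-variance voxels get t = NaN and are masked out.
    Returns (t_map, suprathreshold mask at the upper-alpha quantile).
    """
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.shape[0] < 2:
        raise ValueError("group t map needs >= 2 subjects")
    if mode == "one-sample":
        n = contrasts.shape[0]
        sd = contrasts.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = contrasts.mean(axis=0) / (sd / np.sqrt(n))
        df = n - 1
    elif mode == "two-sample":
        if contrasts2 is None:
            raise ValueError("two-sample mode requires contrasts2")
        contrasts2 = np.asarray(contrasts2, dtype=float)
        n1, n2 = contrasts.shape[0], contrasts2.shape[0]
        v1 = contrasts.std(axis=0, ddof=1) ** 2
        v2 = contrasts2.std(axis=0, ddof=1) ** 2
        sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (contrasts.mean(axis=0) - contrasts2.mean(axis=0)) / np.sqrt(
                sp * (1 / n1 + 1 / n2)
            )
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not np.isfinite(t).all():
        warnings.warn("zero-variance voxels: t undefined there, masked out")
    t = np.where(np.isfinite(t), t, np.nan)
    threshold = sps.t.ppf(1 - alpha, df)
    mask = np.nan_to_num(t, nan=-np.inf) > threshold
    return t, mask
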