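"""Participant-level GLM: design construction, OLS fit, FIR and trial betas.

The design mirrors the first-level model of the study: a duration-matched
stressor regressor, a run-demeaned parametric button-press regressor,
direction/speed/interaction regressors built separately for the near and
far proximity zones (zeroed during stressors), all convolved with a gamma
variate hemodynamic response; plus six motion parameters with their
discrete temporal derivatives and per-run polynomial drift terms up to
fourth order.  Voxel/ROI intensities are normalized to a per-run mean of
100 so regression coefficients are in units of percent signal change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import paradigm as par
from .paradigm import CircleSession

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "GLMResult",
    "FIRResult",
    "hrf_gamma",
    "normalize_intensity",
    "build_design",
    "fit_glm",
    "compute_vif",
    "fit_fir",
    "lss_trial_betas",
]

TASK_ROLES = (
    "stressor",
    "presses_parametric",
    "near_direction",
    "near_speed",
    "near_interaction",
    "far_direction",
    "far_speed",
    "far_interaction",
)


class SingularDesignError(np.linalg.LinAlgError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; dependent columns: {self.columns}")


@dataclass(frozen=True)
class HRFParams:
    """Gamma variate hemodynamic response h(t) = (t/(p*q))**p * exp(p - t/q).

    With the default shape p = 8.6 and scale q = 0.547 s the response peaks
    at t = p*q ~ 4.7 s.  In this parameterization the peak value is exactly
    1; with ``peak_normalized`` False the raw gamma variate t**p * exp(-t/q)
    is used instead.
    """

    p: float = 8.6
    q: float = 0.547
    peak_normalized: bool = True

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("HRF shape and scale must be positive")


def hrf_gamma(t, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the gamma variate HRF; zero for t <= 0 (causal)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    p, q = params.p, params.q
    if params.peak_normalized:
        out[pos] = (t[pos] / (p * q)) ** p * np.exp(p - t[pos] / q)
    else:
        out[pos] = t[pos] ** p * np.exp(-t[pos] / q)
    return out


def normalize_intensity(series: np.ndarray, run_index: np.ndarray) -> np.ndarray:
    """Scale each run of each series to a mean of exactly 100."""
    series = np.asarray(series, dtype=float)
    y = series.copy()
    flat = y.ndim == 1
    if flat:
        y = y[:, None]
    for r in np.unique(run_index):
        sel = run_index == r
        m = y[sel].mean(axis=0)
        if np.any(np.abs(m) < 1e-12):
            raise ValueError(f"run {r} has (near) zero mean; cannot normalize to 100")
        y[sel] = y[sel] * (100.0 / m)
    return y[:, 0] if flat else y


@dataclass
class DesignMatrix:
    """Labeled time x regressor matrix with per-row run structure."""

    X: np.ndarray
    columns: list[str]
    roles: list[str]             # role per column (TASK_ROLES, motion, ..., polort)
    run_index: np.ndarray        # run per row (TR grid)
    tr: float

    def col(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def task_columns(self) -> list[str]:
        return [c for c, r in zip(self.columns, self.roles) if r in TASK_ROLES]

    def non_baseline_columns(self) -> list[str]:
        return [c for c, r in zip(self.columns, self.roles) if r != "polort"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "run", self.run_index)
        return df


def _legendre_drift(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)])


def build_design(
    events: pd.DataFrame,
    session: CircleSession,
    motion: np.ndarray | None = None,
    hrf: HRFParams = HRFParams(),
    polort: int = 4,
    tr: float = 1.25,
) -> DesignMatrix:
    """Build the full participant-level design matrix on the TR grid.

    Task regressors are constructed at frame resolution, convolved with the
    HRF, then averaged within TR bins.  ``motion`` is a (n_tr, 6) array on
    the TR grid (defaults to zeros-free: must be supplied for motion
    columns to be included).
    """
    cfg = session.config
    fr = session.frame_rate
    run_dur = cfg.run_duration
    if abs(run_dur / tr - round(run_dur / tr)) > 1e-9:
        raise ValueError(f"TR {tr} does not divide the run duration {run_dur}")
    n_tr_run = int(round(run_dur / tr))
    n_runs = cfg.n_runs
    n_tr = n_runs * n_tr_run

    ev = events[events.trial_type == "stressor"]
    onsets = ev.onset.to_numpy(float)
    durations = ev.duration.to_numpy(float)
    presses = ev.n_presses.to_numpy(float)
    if np.any(onsets < 0) or np.any(onsets + durations > n_runs * run_dur):
        raise ValueError("events fall outside the session time span")
    order = np.argsort(onsets)
    if np.any(onsets[order][1:] < (onsets + durations)[order][:-1] - 1e-9):
        raise ValueError("overlapping stressor events")

    # ---- frame-resolution task signals over the full (blanks included) grid
    n_frames_run = int(round(run_dur * fr))
    n_frames = n_runs * n_frames_run
    grid_idx = np.minimum((session.times * fr).round().astype(int) - 1, n_frames - 1)

    stressor_f = np.zeros(n_frames)
    for t0, d in zip(onsets, durations):
        a, b = int(round(t0 * fr)), int(round((t0 + d) * fr))
        stressor_f[a:b] = 1.0

    # parametric presses: run-demeaned press count on the same boxcars
    run_of_event = (onsets // run_dur).astype(int)
    param_f = np.zeros(n_frames)
    for r in np.unique(run_of_event):
        sel = run_of_event == r
        centered = presses[sel] - presses[sel].mean()
        for t0, d, c in zip(onsets[sel], durations[sel], centered):
            a, b = int(round(t0 * fr)), int(round((t0 + d) * fr))
            param_f[a:b] = c

    proximity = 1.0 - session.distance / session.max_distance
    near = classify = par.classify_proximity(session)
    direction_s = np.where(session.labels == par.APPROACH, 1.0,
                           np.where(session.labels == par.RETREAT, -1.0, 0.0))
    speed_s = np.zeros_like(proximity)
    speed_s[1:] = np.diff(proximity) * fr
    same_block = np.diff(session.run_index * 1000 + session.block_index) == 0
    speed_s[1:][~same_block] = 0.0
    stress_frame = session.labels == par.STRESSOR
    direction_s[stress_frame] = 0.0
    speed_s[stress_frame] = 0.0

    frame_run = session.run_index.astype(int)
    zone_cols = {}
    for zone, zmask in (("near", near), ("far", ~near)):
        dcol = np.zeros(n_frames)
        scol = np.zeros(n_frames)
        zsel = zmask & ~stress_frame
        dcol[grid_idx[zsel]] = direction_s[zsel]
        scol[grid_idx[zsel]] = speed_s[zsel]
        inter = dcol * scol
        # mean-center the interaction over its support, run by run
        for r in range(n_runs):
            rows = slice(r * n_frames_run, (r + 1) * n_frames_run)
            sup = inter[rows] != 0
            if sup.any():
                inter[rows][sup] -= inter[rows][sup].mean()
        zone_cols[f"{zone}_direction"] = dcol
        zone_cols[f"{zone}_speed"] = scol
        zone_cols[f"{zone}_interaction"] = inter

    # ---- convolve with HRF per run, then average within TR bins
    kernel = hrf_gamma(np.arange(1, int(32 * fr) + 1) / fr, hrf)
    task_names = ["stressor", "presses_parametric",
                  "near_direction", "near_speed", "near_interaction",
                  "far_direction", "far_speed", "far_interaction"]
    task_f = [stressor_f, param_f] + [zone_cols[k] for k in
                                      ["near_direction", "near_speed", "near_interaction",
                                       "far_direction", "far_speed", "far_interaction"]]
    frames_per_tr = int(round(tr * fr))
    cols, names, roles = [], [], []
    for name, sig in zip(task_names, task_f):
        conv = np.zeros(n_frames)
        for r in range(n_runs):
            rows = slice(r * n_frames_run, (r + 1) * n_frames_run)
            conv[rows] = np.convolve(sig[rows], kernel)[:n_frames_run] / fr
        col = conv.reshape(n_tr, frames_per_tr).mean(axis=1)
        cols.append(col)
        names.append(name)
        roles.append(name)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_tr, 6):
            raise ValueError(f"motion must be shaped ({n_tr}, 6)")
        deriv = np.zeros_like(motion)
        deriv[1:] = np.diff(motion, axis=0)
        run_index_tr = np.repeat(np.arange(n_runs), n_tr_run)
        deriv[np.flatnonzero(np.diff(run_index_tr)) + 1] = 0.0
        for j in range(6):
            cols.append(motion[:, j]); names.append(f"motion_{j + 1}"); roles.append("motion")
        for j in range(6):
            cols.append(deriv[:, j]); names.append(f"dmotion_{j + 1}"); roles.append("motion_derivative")

    run_index_tr = np.repeat(np.arange(n_runs), n_tr_run)
    for r in range(n_runs):
        drift = _legendre_drift(n_tr_run, polort)
        for k in range(polort + 1):
            col = np.zeros(n_tr)
            col[run_index_tr == r] = drift[:, k]
            cols.append(col); names.append(f"run{r}_poly{k}"); roles.append("polort")

    X = np.column_stack(cols)
    return DesignMatrix(X=X, columns=names, roles=roles, run_index=run_index_tr, tr=tr)


@dataclass
class GLMResult:
    betas: np.ndarray          # (n_columns,) or (n_columns, n_series)
    stderr: np.ndarray
    residuals: np.ndarray
    df_resid: int
    columns: list[str]

    def beta(self, name: str) -> float | np.ndarray:
        return self.betas[self.columns.index(name)]


def _check_rank(X: np.ndarray, columns, tol_factor: float = 1e-10):
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = tol_factor * s.max()
    bad = s < tol
    if bad.any():
        # columns loading on the (near) null space
        load = np.abs(vt[bad]).max(axis=0)
        dep = [c for c, l in zip(columns, load) if l > 1e-6]
        raise SingularDesignError(dep)
    return s


def fit_glm(Y, X: DesignMatrix | np.ndarray, columns: list[str] | None = None) -> GLMResult:
    """Ordinary least squares fit of every series in Y on the design.

    Raises :class:`SingularDesignError` for rank-deficient designs, naming
    the dependent columns.
    """
    if isinstance(X, DesignMatrix):
        columns = X.columns
        Xm = X.X
    else:
        Xm = np.asarray(X, dtype=float)
        if columns is None:
            columns = [f"x{j}" for j in range(Xm.shape[1])]
    Y = np.asarray(Y, dtype=float)
    flat = Y.ndim == 1
    Ym = Y[:, None] if flat else Y
    if Ym.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X have different numbers of rows")
    _check_rank(Xm, columns)
    betas, *_ = np.linalg.lstsq(Xm, Ym, rcond=None)
    resid = Ym - Xm @ betas
    df = Xm.shape[0] - Xm.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / max(df, 1)
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    if flat:
        betas, se, resid = betas[:, 0], se[:, 0], resid[:, 0]
    return GLMResult(betas=betas, stderr=se, residuals=resid,
                     df_resid=df, columns=list(columns))


def compute_vif(X: DesignMatrix | np.ndarray, columns: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per (non-baseline) column.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing column j on every
    other column of the full design (drift/baseline columns included as
    predictors but not reported).  Perfect collinearity yields inf.
    """
    if isinstance(X, DesignMatrix):
        report = columns if columns is not None else X.non_baseline_columns()
        names = X.columns
        Xm = X.X
    else:
        Xm = np.asarray(X, dtype=float)
        names = columns if columns is not None else [f"x{j}" for j in range(Xm.shape[1])]
        report = names
    out = {}
    for name in report:
        j = names.index(name)
        y = Xm[:, j]
        yc = y - y.mean()
        ss_tot = yc @ yc
        if ss_tot < 1e-300:
            raise ValueError(f"column {name} has zero variance")
        # implicit intercept: R^2 is computed about the column mean
        others = np.column_stack([np.delete(Xm, j, axis=1), np.ones(Xm.shape[0])])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - (resid @ resid) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class FIRResult:
    """Unassumed-shape response estimates on a TR-spaced lag grid."""

    lags: np.ndarray             # seconds, starting at 0, spacing TR
    estimates: np.ndarray        # (n_lags,) or (n_lags, n_series)
    columns: list[str]


def fit_fir(
    Y,
    events: pd.DataFrame,
    session: CircleSession,
    tr: float = 1.25,
    window: float = 15.0,
    nuisance: np.ndarray | None = None,
    polort: int = 4,
) -> FIRResult:
    """Estimate the stressor-evoked response without assuming an HRF shape.

    One stick regressor per post-onset lag bin (0, TR, 2*TR, ... < window),
    fitted alongside per-run polynomial drift (and optional extra nuisance
    columns).
    """
    cfg = session.config
    run_dur = cfg.run_duration
    n_tr_run = int(round(run_dur / tr))
    if window < tr:
        raise ValueError("window must be at least one TR")
    if window > run_dur:
        raise ValueError("window exceeds the run length")
    n_lags = int(np.floor(window / tr))
    n_tr = cfg.n_runs * n_tr_run
    onsets = events[events.trial_type == "stressor"].onset.to_numpy(float)
    if onsets.size == 0:
        raise ValueError("no stressor events to estimate a response for")
    run_of_event = (onsets // run_dur).astype(int)
    t_in_run = onsets - run_of_event * run_dur
    base = run_of_event * n_tr_run + np.round(t_in_run / tr).astype(int)

    sticks = np.zeros((n_tr, n_lags))
    for b, r in zip(base, run_of_event):
        for k in range(n_lags):
            i = b + k
            if i < (r + 1) * n_tr_run:
                sticks[i, k] += 1.0
    run_index_tr = np.repeat(np.arange(cfg.n_runs), n_tr_run)
    drift_cols = []
    for r in range(cfg.n_runs):
        drift = _legendre_drift(n_tr_run, polort)
        for k in range(polort + 1):
            col = np.zeros(n_tr)
            col[run_index_tr == r] = drift[:, k]
            drift_cols.append(col)
    blocks = [sticks, np.column_stack(drift_cols)]
    if nuisance is not None:
        blocks.insert(1, np.asarray(nuisance, dtype=float))
    Xm = np.column_stack(blocks)
    names = [f"lag_{k}" for k in range(n_lags)] + [f"n{j}" for j in range(Xm.shape[1] - n_lags)]
    res = fit_glm(Y, Xm, names)
    est = res.betas[:n_lags]
    return FIRResult(lags=np.arange(n_lags) * tr, estimates=est,
                     columns=[f"lag_{k}" for k in range(n_lags)])


def lss_trial_betas(
    Y,
    events: pd.DataFrame,
    session: CircleSession,
    X_nuisance: np.ndarray | None = None,
    hrf: HRFParams = HRFParams(),
    tr: float = 1.25,
    polort: int = 4,
) -> np.ndarray:
    """Trial-by-trial stressor amplitudes via least-squares-separate.

    For each trial, one GLM is fitted with that trial's convolved regressor
    plus a single regressor pooling all remaining trials, alongside the
    drift/nuisance model; the target trial's coefficient is its amplitude.
    """
    cfg = session.config
    fr = session.frame_rate
    run_dur = cfg.run_duration
    n_tr_run = int(round(run_dur / tr))
    n_tr = cfg.n_runs * n_tr_run
    n_frames_run = int(round(run_dur * fr))
    n_frames = cfg.n_runs * n_frames_run
    frames_per_tr = int(round(tr * fr))
    kernel = hrf_gamma(np.arange(1, int(32 * fr) + 1) / fr, hrf)

    ev = events[events.trial_type == "stressor"]
    onsets = ev.onset.to_numpy(float)
    durations = ev.duration.to_numpy(float)
    n_trials = onsets.size
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if n_trials == 1:
        warnings.warn("single trial: falling back to a single-event GLM")

    def conv_col(mask_trials):
        sig = np.zeros(n_frames)
        for t0, d in zip(onsets[mask_trials], durations[mask_trials]):
            a, b = int(round(t0 * fr)), int(round((t0 + d) * fr))
            sig[a:b] = 1.0
        conv = np.zeros(n_frames)
        for r in range(cfg.n_runs):
            rows = slice(r * n_frames_run, (r + 1) * n_frames_run)
            conv[rows] = np.convolve(sig[rows], kernel)[:n_frames_run] / fr
        return conv.reshape(n_tr, frames_per_tr).mean(axis=1)

    run_index_tr = np.repeat(np.arange(cfg.n_runs), n_tr_run)
    drift_cols = []
    for r in range(cfg.n_runs):
        drift = _legendre_drift(n_tr_run, polort)
        for k in range(polort + 1):
            col = np.zeros(n_tr)
            col[run_index_tr == r] = drift[:, k]
            drift_cols.append(col)
    base = [np.column_stack(drift_cols)]
    if X_nuisance is not None:
        base.append(np.asarray(X_nuisance, dtype=float))
    base = np.column_stack(base)

    betas = np.empty(n_trials)
    mask = np.zeros(n_trials, dtype=bool)
    for i in range(n_trials):
        mask[:] = False
        mask[i] = True
        target = conv_col(mask)
        blocks = [target[:, None]]
        if n_trials > 1:
            blocks.append(conv_col(~mask)[:, None])
        blocks.append(base)
        Xm = np.column_stack(blocks)
        res = fit_glm(Y, Xm)
        betas[i] = np.atleast_2d(res.betas)[0] if res.betas.ndim > 1 else res.betas[0]
    return betas
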