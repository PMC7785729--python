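"""Synthetic yoked cohort with known ground truth.

Generates everything the group-level analyses consume, without any real
data: anxiety covariates with the study's printed correlation structure,
ROI BOLD time series following the participant-level forward model
(task regressors convolved with the gamma-variate HRF, polynomial drift,
AR(1) noise, per-run baseline 100), voxelwise 4-D volumes for the insula
path, and skin-conductance traces whose trial amplitudes are coupled to
the trial-by-trial BOLD amplitudes at a configurable per-group level.

The uncontrollable member of each yoked pair shares the controllable
member's event schedule exactly; group differences enter only through the
stressor response amplitude (``effect_map``) and the brain-SCR coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm as fl
from ._util import rng_for
from .paradigm import CircleSession, MotionConfig, PairBehavior, WheelConfig

__all__ = [
    "ROI_NAMES",
    "GroundTruth",
    "CovariateCalibration",
    "CovariateTable",
    "ROITimeSeries",
    "SCRTrace",
    "generate_covariates",
    "simulate_motion_params",
    "simulate_roi_bold",
    "simulate_voxel_volumes",
    "simulate_scr",
    "scr_kernel",
]

# The 24 threat-processing regions summarized by one averaged time series
# each: extended amygdala (BST, central/medial and basolateral amygdala),
# PAG, thalamus, three insular sectors, midline cortices, and hippocampal
# sectors.
ROI_NAMES: tuple[str, ...] = (
    "L_BST", "R_BST",
    "L_CeM_amygdala", "R_CeM_amygdala",
    "L_BL_amygdala", "R_BL_amygdala",
    "PAG",
    "L_thalamus", "R_thalamus",
    "L_dorsal_ant_insula", "R_dorsal_ant_insula",
    "L_ventral_ant_insula", "R_ventral_ant_insula",
    "L_mid_post_insula", "R_mid_post_insula",
    "aMCC", "PCC", "PCC_precuneus",
    "post_vmPFC", "ant_vmPFC",
    "L_ant_hippocampus", "R_ant_hippocampus",
    "L_mid_hippocampus", "R_post_hippocampus",
)

# regions carrying a positive (uncontrollable > controllable) ground-truth
# effect by default: the strongest sites reported for this contrast
DEFAULT_EFFECT_ROIS = ("L_BST", "R_BST", "L_dorsal_ant_insula")


class CalibrationError(ValueError):
    """Raised when requested correlation targets are not jointly feasible."""


@dataclass(frozen=True)
class GroundTruth:
    """All ground-truth parameters of the synthetic cohort.

    Amplitudes are in percent signal change (the series are normalized to a
    per-run mean of 100).  ``effect_map`` holds the uncontrollable-minus-
    controllable stressor amplitude difference per region; regions not
    listed have no group difference.
    """

    n_pairs: int = 61
    roi_names: tuple[str, ...] = ROI_NAMES
    effect_map: dict = field(
        default_factory=lambda: {r: 0.08 for r in DEFAULT_EFFECT_ROIS}
    )
    stressor_amp: float = 0.30          # controllable-group stressor response
    trial_amp_sd: float = 0.08          # trial-to-trial arousal variation
    task_amps: dict = field(
        default_factory=lambda: {
            "near_direction": -0.04,
            "near_speed": 0.03,
            "near_interaction": 0.02,
            "far_direction": -0.02,
            "far_speed": 0.02,
            "far_interaction": 0.01,
            "presses_parametric": 0.02,
        }
    )
    hrf: fl.HRFParams = fl.HRFParams()
    ar1: float = 0.3
    noise_sd: float = 0.8               # AR(1) innovation SD, % signal
    drift_sd: float = 0.4               # per-run polynomial drift amplitude
    pair_effect_sd: float = 0.05        # pair-level shift of the contrast
    scr_coupling: dict = field(default_factory=lambda: {"CTL": 0.2, "UNCTL": 0.6})
    scr_rate: float = 250.0             # Hz
    scr_amp: float = 0.8                # microsiemens, mean response height
    tr: float = 1.25
    seed: int = 0

    def __post_init__(self):
        if not set(self.effect_map) <= set(self.roi_names):
            raise ValueError("effect_map keys must be a subset of roi_names")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        for g, c in self.scr_coupling.items():
            if not -1.0 <= c <= 1.0:
                raise CalibrationError(f"scr_coupling[{g}] outside [-1, 1]")


@dataclass(frozen=True)
class CovariateCalibration:
    """Correlation targets for the anxiety covariates.

    ``state_trait`` is the participant-level correlation between state and
    trait scores; the other two are pair-level correlations between the
    average and the (uncontrollable minus controllable) difference scores.
    Defaults are the values printed for the study sample.
    """

    state_trait: float = 0.5
    state_avg_diff: float = 0.05
    trait_avg_diff: float = -0.22
    mean: float = 35.0
    sd: float = 9.0
    avg_var_fraction: float = 55.0 / 81.0   # share of participant variance in the pair mean


@dataclass
class CovariateTable:
    """Participant anxiety scores plus derived per-pair covariates."""

    participants: pd.DataFrame   # participant, pair, group, state, trait
    pairs: pd.DataFrame          # pair, State/Trait AVG & DIFF, ButtonPressDIFF

    COVARIATE_COLUMNS = (
        "StateAnxietyDIFF", "StateAnxietyAVG",
        "TraitAnxietyDIFF", "TraitAnxietyAVG",
        "ButtonPressDIFF",
    )


def _covariance_matrix(cal: CovariateCalibration) -> np.ndarray:
    """Covariance of (state_avg, state_diff, trait_avg, trait_diff).

    The construction equates corr(avg_s, avg_t) and corr(diff_s, diff_t) to
    the participant-level state-trait target, which reproduces it exactly
    for member scores avg +- diff/2.
    """
    v = cal.sd ** 2
    va = cal.avg_var_fraction * v
    vd = 4.0 * (v - va)
    r = cal.state_trait
    c = np.array([
        [va, cal.state_avg_diff * np.sqrt(va * vd), r * va, 0.0],
        [cal.state_avg_diff * np.sqrt(va * vd), vd, 0.0, r * vd],
        [r * va, 0.0, va, cal.trait_avg_diff * np.sqrt(va * vd)],
        [0.0, r * vd, cal.trait_avg_diff * np.sqrt(va * vd), vd],
    ])
    eig = np.linalg.eigvalsh(c)
    if eig.min() < -1e-9 * eig.max():
        raise CalibrationError("target correlation structure is not positive semi-definite")
    return c


def generate_covariates(
    n_pairs: int,
    calibration: CovariateCalibration = CovariateCalibration(),
    seed: int = 0,
    press_diff: np.ndarray | None = None,
) -> CovariateTable:
    """Draw anxiety covariates for a yoked cohort.

    Pair-level (average, difference) vectors for state and trait anxiety
    are drawn from a Gaussian whose covariance reproduces the calibration
    targets; member scores are avg +- diff/2.  ``press_diff`` (one value
    per pair, uncontrollable minus controllable button-press total) is
    simulated when not supplied.
    """
    rng = rng_for(seed, "covariates")
    cov = _covariance_matrix(calibration)
    x = rng.multivariate_normal(np.zeros(4), cov, size=n_pairs, method="cholesky")
    s_avg, s_diff, t_avg, t_diff = (x[:, i] for i in range(4))
    m = calibration.mean

    rows = []
    for p in range(n_pairs):
        rows.append({"participant": f"pair{p:03d}_UNCTL", "pair": p, "group": "UNCTL",
                     "state": m + s_avg[p] + s_diff[p] / 2,
                     "trait": m + t_avg[p] + t_diff[p] / 2})
        rows.append({"participant": f"pair{p:03d}_CTL", "pair": p, "group": "CTL",
                     "state": m + s_avg[p] - s_diff[p] / 2,
                     "trait": m + t_avg[p] - t_diff[p] / 2})
    participants = pd.DataFrame(rows)

    if press_diff is None:
        # uncontrollable members answer ~76% of yoked rotations
        total = 234
        press_diff = rng.binomial(total, 0.76, size=n_pairs) - total
    pairs = pd.DataFrame({
        "pair": np.arange(n_pairs),
        "StateAnxietyDIFF": s_diff,
        "StateAnxietyAVG": m + s_avg,
        "TraitAnxietyDIFF": t_diff,
        "TraitAnxietyAVG": m + t_avg,
        "ButtonPressDIFF": np.asarray(press_diff, dtype=float),
    })
    return CovariateTable(participants=participants, pairs=pairs)


@dataclass
class ROITimeSeries:
    """Time x region BOLD matrix on the TR grid (per-run mean 100)."""

    data: pd.DataFrame          # columns = ROI names
    tr: float
    run_index: np.ndarray
    participant: str
    trial_arousal: np.ndarray   # latent per-trial amplitude deviations

    def trial_amplitudes(self, roi: str, truth: GroundTruth, group: str) -> np.ndarray:
        """Ground-truth per-trial stressor amplitudes for one region."""
        base = truth.stressor_amp + (truth.effect_map.get(roi, 0.0) if group == "UNCTL" else 0.0)
        return base + self.trial_arousal


def simulate_motion_params(n_tr: int, run_index: np.ndarray, seed: int = 0,
                           scale: float = 0.02) -> np.ndarray:
    """Six slowly wandering head-motion parameters on the TR grid."""
    rng = rng_for(seed, "motion")
    m = np.cumsum(rng.normal(0.0, scale, size=(n_tr, 6)), axis=0)
    for r in np.unique(run_index):
        sel = run_index == r
        m[sel] -= m[sel][0]
    return m


def _task_design(session: CircleSession, behavior: PairBehavior, member: str,
                 hrf: fl.HRFParams, tr: float) -> fl.DesignMatrix:
    events = pd.DataFrame({
        "onset": behavior.onsets(),
        "duration": behavior.durations(),
        "trial_type": "stressor",
        "n_presses": behavior.press_counts(member).astype(float),
    })
    return fl.build_design(events, session, motion=None, hrf=hrf, polort=0, tr=tr)


def _trial_scaled_stressor(session: CircleSession, behavior: PairBehavior,
                           weights: np.ndarray, hrf: fl.HRFParams, tr: float) -> np.ndarray:
    """Convolved stressor regressor with a separate weight per trial."""
    cfg = session.config
    fr = session.frame_rate
    run_dur = cfg.run_duration
    n_frames_run = int(round(run_dur * fr))
    n_frames = cfg.n_runs * n_frames_run
    sig = np.zeros(n_frames)
    for w, t in zip(weights, behavior.trials):
        a, b = int(round(t.onset * fr)), int(round((t.onset + t.duration) * fr))
        sig[a:b] = w
    kernel = fl.hrf_gamma(np.arange(1, int(32 * fr) + 1) / fr, hrf)
    conv = np.zeros(n_frames)
    for r in range(cfg.n_runs):
        rows = slice(r * n_frames_run, (r + 1) * n_frames_run)
        conv[rows] = np.convolve(sig[rows], kernel)[:n_frames_run] / fr
    fpt = int(round(tr * fr))
    return conv.reshape(-1, fpt).mean(axis=1)


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    e = rng.normal(0.0, sd, size=n)
    if phi == 0.0:
        return e
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - phi ** 2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def simulate_roi_bold(
    session: CircleSession,
    behavior: PairBehavior,
    truth: GroundTruth,
    member: str,
    pair: int,
    noise: bool = True,
    pair_shift: float = 0.0,
) -> ROITimeSeries:
    """Forward-simulate the 24 averaged ROI time series for one participant.

    signal = sum over regressors of (regressor (x) HRF) * true amplitude,
    demeaned per run, on a baseline of 100, plus per-run polynomial drift
    and AR(1) noise when ``noise`` is on.  The stressor amplitude varies
    trial by trial through a shared latent arousal term, and differs
    between the yoked members by ``effect_map[roi]``.
    """
    rng = rng_for(truth.seed, "bold", pair, member)
    X = _task_design(session, behavior, member, truth.hrf, truth.tr)
    n_tr = X.X.shape[0]
    run_ix = X.run_index

    arousal = rng.normal(0.0, truth.trial_amp_sd, size=behavior.n_trials)
    stress_unit = _trial_scaled_stressor(session, behavior, np.ones(behavior.n_trials),
                                         truth.hrf, truth.tr)
    stress_arousal = _trial_scaled_stressor(session, behavior, arousal, truth.hrf, truth.tr)

    other = np.zeros(n_tr)
    for name, amp in truth.task_amps.items():
        other = other + amp * X.col(name)

    cols = {}
    for roi in truth.roi_names:
        amp = truth.stressor_amp + pair_shift
        if member == "UNCTL":
            amp = amp + truth.effect_map.get(roi, 0.0)
        sig = amp * stress_unit + stress_arousal + other
        # demean per run so normalization to 100 is the identity in the
        # noise-free case and betas equal the injected amplitudes exactly
        for r in np.unique(run_ix):
            sel = run_ix == r
            sig[sel] -= sig[sel].mean()
        y = 100.0 + sig
        if noise:
            for r in np.unique(run_ix):
                sel = run_ix == r
                n_run = int(sel.sum())
                drift = fl._legendre_drift(n_run, 4)[:, 1:]
                y[sel] += drift @ rng.normal(0.0, truth.drift_sd, size=4)
                y[sel] += _ar1_noise(rng, n_run, truth.ar1, truth.noise_sd)
        cols[roi] = y
    data = pd.DataFrame(cols)
    return ROITimeSeries(data=data, tr=truth.tr, run_index=run_ix,
                         participant=f"pair{pair:03d}_{member}", trial_arousal=arousal)


def simulate_voxel_volumes(
    mask,
    spatial_effect: np.ndarray,
    truth: GroundTruth,
    session: CircleSession,
    behavior: PairBehavior,
    member: str,
    pair: int,
    noise: bool = True,
):
    """Forward-simulate a 4-D volume series restricted to a mask.

    ``spatial_effect`` gives the per-voxel uncontrollable-minus-controllable
    amplitude (same order as ``mask.coordinates()``); voxels outside the
    mask are zero.  Returns a nibabel Nifti1Image plus the latent arousal.
    """
    import nibabel as nib

    vox = mask.coordinates()
    n_vox = len(vox)
    if n_vox == 0:
        raise ValueError("mask is empty")
    spatial_effect = np.asarray(spatial_effect, dtype=float)
    if spatial_effect.shape != (n_vox,):
        raise ValueError(
            f"spatial_effect has shape {spatial_effect.shape}, expected ({n_vox},)"
        )
    rng = rng_for(truth.seed, "voxels", pair, member)
    X = _task_design(session, behavior, member, truth.hrf, truth.tr)
    n_tr = X.X.shape[0]
    run_ix = X.run_index
    arousal = rng.normal(0.0, truth.trial_amp_sd, size=behavior.n_trials)
    stress_unit = _trial_scaled_stressor(session, behavior, np.ones(behavior.n_trials),
                                         truth.hrf, truth.tr)
    stress_arousal = _trial_scaled_stressor(session, behavior, arousal, truth.hrf, truth.tr)

    amps = truth.stressor_amp + (spatial_effect if member == "UNCTL" else 0.0)
    sig = np.outer(stress_unit, np.broadcast_to(amps, (n_vox,))) + stress_arousal[:, None]
    for r in np.unique(run_ix):
        sel = run_ix == r
        sig[sel] -= sig[sel].mean(axis=0)
    y = 100.0 + sig
    if noise:
        for r in np.unique(run_ix):
            sel = run_ix == r
            n_run = int(sel.sum())
            drift = fl._legendre_drift(n_run, 4)[:, 1:]
            y[sel] += drift @ rng.normal(0.0, truth.drift_sd, size=(4, n_vox))
            e = rng.normal(0.0, truth.noise_sd, size=(n_run, n_vox))
            phi = truth.ar1
            if phi:
                e[0] /= np.sqrt(1 - phi ** 2)
                for i in range(1, n_run):
                    e[i] += phi * e[i - 1]
            y[sel] += e

    vol = np.zeros(mask.shape + (n_tr,), dtype=np.float32)
    ii, jj, kk = vox.T
    vol[ii, jj, kk, :] = y.T
    img = nib.Nifti1Image(vol, mask.affine)
    return img, arousal


def scr_kernel(rate: float, peak: float = 3.0, shape: float = 2.0,
               duration: float = 12.0) -> np.ndarray:
    """Canonical skin-conductance response: gamma bump peaking at ``peak`` s."""
    t = np.arange(1, int(duration * rate) + 1) / rate
    return (t / peak) ** shape * np.exp(shape * (1.0 - t / peak))


@dataclass
class SCRTrace:
    """Skin conductance over the full session (microsiemens)."""

    values: np.ndarray
    rate: float
    participant: str
    true_amplitudes: np.ndarray   # per-trial response heights actually injected


def simulate_scr(
    behavior: PairBehavior,
    truth: GroundTruth,
    member: str,
    pair: int,
    trial_bold: np.ndarray | None = None,
    duration: float | None = None,
    noise: bool = True,
) -> SCRTrace:
    """Simulate a skin-conductance trace with BOLD-coupled trial amplitudes.

    Each stressor elicits a canonical gamma-shaped response.  The response
    heights share a Gaussian-copula correlation of ``scr_coupling[group]``
    with the participant's trial BOLD amplitudes (the latent arousal terms
    by default), so rank correlations downstream recover the configured
    per-group coupling.
    """
    coupling = truth.scr_coupling[member]
    if not -1.0 <= coupling <= 1.0:
        raise CalibrationError("coupling outside [-1, 1]")
    rng = rng_for(truth.seed, "scr", pair, member)
    n_trials = behavior.n_trials
    if trial_bold is None:
        trial_bold = rng.normal(0.0, 1.0, size=n_trials)
    zb = np.asarray(trial_bold, dtype=float)
    sd = zb.std()
    zb = (zb - zb.mean()) / (sd if sd > 0 else 1.0)
    eps = rng.normal(0.0, 1.0, size=n_trials) if noise else np.zeros(n_trials)
    z = coupling * zb + np.sqrt(max(0.0, 1.0 - coupling ** 2)) * eps
    amps = np.maximum(truth.scr_amp + 0.25 * z, 0.05)

    rate = truth.scr_rate
    if duration is None:
        duration = behavior.onsets()[-1] + 30.0
    n = int(round(duration * rate))
    trace = np.zeros(n)
    kern = scr_kernel(rate)
    for a, t in zip(amps, behavior.trials):
        i0 = int(round(t.onset * rate))
        seg = kern[: max(0, n - i0)]
        trace[i0:i0 + len(seg)] += a * seg
    baseline = 2.0
    if noise:
        t_ax = np.arange(n) / rate
        baseline = baseline + 0.2 * np.sin(2 * np.pi * t_ax / 300.0 + rng.uniform(0, 2 * np.pi))
        slow = np.cumsum(rng.normal(0, 0.002 / np.sqrt(rate), size=n))
        trace = trace + slow
    trace = trace + baseline
    return SCRTrace(values=trace, rate=rate,
                    participant=f"pair{pair:03d}_{member}", true_amplitudes=amps)
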