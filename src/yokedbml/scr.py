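"""Trial-by-trial brain-skin-conductance coupling.

Per participant, stressor-evoked skin conductance response (SCR)
amplitudes are scored from the trace (peak in a post-onset window minus a
pre-onset baseline), Spearman-correlated with trial-by-trial brain
amplitudes, and Fisher-z transformed.  The controllability effect on the
coupling is then tested on per-pair z differences (uncontrollable minus
controllable) with a Bayesian linear model whose intercept carries the
effect; state/trait anxiety and button-press differences enter as
mean-centered covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .bayes import PosteriorDraws, pplus as _pplus
from .bml import RobustLocationModel, RobustLocationResults
from .cohort import SCRTrace

__all__ = [
    "score_scr_trials",
    "brain_scr_correlation",
    "CouplingModel",
    "CouplingResults",
    "fit_coupling_model",
]


def score_scr_trials(trace: SCRTrace, onsets, window: float = 6.0,
                     baseline: float = 1.0) -> np.ndarray:
    """Score per-trial SCR amplitudes from a conductance trace.

    amplitude = max of the trace within [onset + 1 s, onset + window]
    minus the mean over [onset - baseline, onset], floored at zero
    (a response cannot be negative).  Invariant to additive constants.
    """
    onsets = np.asarray(onsets, dtype=float)
    rate = trace.rate
    n = trace.values.size
    amps = np.empty(onsets.size)
    for i, t0 in enumerate(onsets):
        a = int(round((t0 + 1.0) * rate))
        b = int(round((t0 + window) * rate))
        b0 = int(round((t0 - baseline) * rate))
        b1 = int(round(t0 * rate))
        if b > n or b0 < 0:
            raise ValueError(f"trial at {t0:.1f}s extends outside the trace")
        base = trace.values[b0:b1].mean()
        amps[i] = max(0.0, trace.values[a:b].max() - base)
    return amps


def brain_scr_correlation(brain_amps, scr_amps) -> tuple[float, float]:
    """Spearman rank correlation and its Fisher z transform.

    Average ranks are assigned to ties.  Returns (rho, atanh(rho)); a
    constant input vector yields (nan, nan) with a warning.
    """
    x = np.asarray(brain_amps, dtype=float)
    y = np.asarray(scr_amps, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trial vectors must have matching length and order")
    if x.size < 4:
        raise ValueError("need at least 4 trials")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant trial vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho = float(spearmanr(x, y).statistic)
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    return rho, float(np.arctanh(rho_c))


@dataclass
class CouplingResults:
    """Posterior of the controllability effect on brain-SCR coupling."""

    robust: RobustLocationResults
    per_pair: pd.DataFrame       # pair, z_UNCTL, z_CTL, z_diff

    @property
    def draws(self) -> PosteriorDraws:
        return self.robust.draws

    def pplus(self, parameter: str = "b0") -> float:
        return _pplus(self.draws, parameter)

    def summary(self) -> pd.DataFrame:
        return self.robust.summary()


class CouplingModel:
    """Group comparison of brain-SCR coupling over yoked pairs.

    Built from a per-pair table with columns pair, z_UNCTL, z_CTL and
    optional covariate columns; ``fit`` models z_UNCTL - z_CTL with a
    Student-t observation model (priors as in the region-level BML), the
    intercept being the controllability effect.
    """

    def __init__(self, pair_z: pd.DataFrame, covariates: tuple[str, ...] = ()):
        required = {"pair", "z_UNCTL", "z_CTL"}
        if not required <= set(pair_z.columns):
            raise ValueError(f"pair table needs columns {sorted(required)}")
        t = pair_z.dropna(subset=["z_UNCTL", "z_CTL"]).reset_index(drop=True)
        if len(t) < 3:
            raise ValueError("need at least 3 complete pairs")
        self.table = t
        self.covariates = [c for c in covariates if c in t.columns]

    def fit(self, chains: int = 4, draws: int = 1000, warmup: int = 1000,
            seed: int = 0) -> CouplingResults:
        t = self.table
        diff = (t["z_UNCTL"] - t["z_CTL"]).to_numpy(float)
        cov = t[self.covariates] if self.covariates else None
        model = RobustLocationModel(diff, covariates=cov)
        res = model.fit(chains=chains, draws=draws, warmup=warmup, seed=seed)
        per_pair = t[["pair", "z_UNCTL", "z_CTL"]].copy()
        per_pair["z_diff"] = diff
        return CouplingResults(robust=res, per_pair=per_pair)


def fit_coupling_model(pair_z: pd.DataFrame, covariates: tuple[str, ...] = (),
                       chains: int = 4, draws: int = 1000, warmup: int = 1000,
                       seed: int = 0) -> CouplingResults:
    return CouplingModel(pair_z, covariates).fit(chains=chains, draws=draws,
                                                 warmup=warmup, seed=seed)
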