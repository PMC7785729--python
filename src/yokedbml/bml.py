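"""Group-level Bayesian multilevel inference on yoked-pair contrasts.

The unit of analysis is the yoked participant pair.  For each pair p and
region r the response is the stressor-beta difference

    Delta_{p,r} = stressor_p^UNCTL - stressor_p^CTL,

modeled jointly across all regions in a single multilevel model

    Delta_{p,r} = b0 + sum_k b_k x_{k,p} + pi_p + tau_r
                  + sum_k gamma_{k,r} x_{k,p} + eps_{p,r},

with varying intercepts for pairs (pi) and regions (tau) and varying
slopes per region (gamma) for the five pair-level covariates: state/trait
anxiety differences and averages and the button-press difference.  Because
one joint posterior is estimated for all regions, no multiplicity
correction is applied; evidence per region is reported as P+, the
posterior probability that the controllability effect
theta_r = b0 + tau_r (at covariate means) is greater than zero.

Simple robust location tests (button presses, anxiety scores, SCR z
differences) use a Student-t observation model whose degrees of freedom
are estimated from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._util import write_tsv
from .bayes import GibbsModel, PosteriorDraws, RandomTerm, convergence_report
from .bayes import pplus as _pplus
from .bayes import split_rhat
from .cohort import CovariateTable

log = logging.getLogger(__name__)

__all__ = [
    "COVARIATES",
    "BMLSpec",
    "build_pair_contrasts",
    "simulate_contrast_table",
    "ROIControllabilityBML",
    "RobustLocationModel",
    "BMLResults",
    "fit_bml_roi",
    "fit_robust_intercept",
    "pplus",
    "rhat",
    "summarize",
]

COVARIATES = list(CovariateTable.COVARIATE_COLUMNS)


def pplus(draws, parameter=None) -> float:
    """Fraction of pooled post-warmup draws strictly greater than zero."""
    return _pplus(draws, parameter)


def rhat(draws: PosteriorDraws) -> pd.Series:
    """Split-R-hat for every sampled parameter."""
    out = {}
    for nm in draws.names():
        x = np.asarray(draws[nm])
        out[nm] = split_rhat(x) if np.var(x) > 0 else np.nan
    return pd.Series(out, name="rhat")


@dataclass(frozen=True)
class BMLSpec:
    """Structure of the region-level multilevel model.

    ``covariates`` lists the pair-level fixed effects (each also gets a
    region-varying slope when ``varying_slopes``); priors are weakly
    informative: Student-t(3, 0, 10 sd) on fixed effects and half-t(3, sd)
    on every scale.
    """

    covariates: tuple[str, ...] = tuple(COVARIATES)
    varying_slopes: bool = True
    fixed_scale: float = 10.0


def build_pair_contrasts(betas: pd.DataFrame, covariates: CovariateTable) -> pd.DataFrame:
    """Assemble the (pair, region) contrast table from participant betas.

    ``betas`` must carry columns participant, pair, group, region, beta
    (stressor coefficients, % signal).  Pairs missing a member are dropped
    with a warning.  Covariates are attached per pair and mean-centered
    across pairs, matching marginal-at-the-mean reporting of the region
    effects.
    """
    wide = betas.pivot_table(index=["pair", "region"], columns="group",
                             values="beta", aggfunc="first")
    incomplete = wide.index[wide.isna().any(axis=1)].get_level_values("pair").unique()
    if len(incomplete):
        log.warning("dropping %d pair(s) missing one member: %s",
                    len(incomplete), list(incomplete))
        wide = wide[~wide.index.get_level_values("pair").isin(incomplete)]
    table = wide.reset_index()
    table["delta"] = table["UNCTL"] - table["CTL"]
    table = table[["pair", "region", "delta"]]
    cov = covariates.pairs.set_index("pair")[COVARIATES]
    cov = cov - cov.mean()
    table = table.join(cov, on="pair")
    return table.reset_index(drop=True)


def simulate_contrast_table(
    n_pairs: int = 61,
    regions=None,
    effects: dict | None = None,
    pair_sd: float = 0.2,
    region_sd: float = 0.1,
    noise_sd: float = 1.0,
    covariate_slopes: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate a contrast table with known region effects.

    A fast generative shortcut for calibration and recovery studies:
    delta = effect_r + pair shift + covariate contributions + noise, with
    covariates drawn by the cohort generator.  ``effects`` maps region
    name -> true theta_r (regions default to R00..; unlisted regions are
    null).
    """
    from ._util import rng_for
    from .cohort import generate_covariates

    if regions is None:
        regions = [f"R{i:02d}" for i in range(24)]
    rng = rng_for(seed, "contrast-table")
    cov = generate_covariates(n_pairs, seed=seed)
    x = cov.pairs[COVARIATES] - cov.pairs[COVARIATES].mean()
    effects = effects or {}
    pair_shift = rng.normal(0.0, pair_sd, size=n_pairs)
    rows = []
    for p in range(n_pairs):
        xc = x.iloc[p]
        cov_term = 0.0
        if covariate_slopes:
            cov_term = sum(w * xc[k] for k, w in covariate_slopes.items())
        for r in regions:
            delta = (effects.get(r, 0.0) + pair_shift[p] + cov_term
                     + rng.normal(0.0, noise_sd))
            rows.append({"pair": p, "region": r, "delta": delta, **xc.to_dict()})
    return pd.DataFrame(rows)


@dataclass
class BMLResults:
    """Posterior summaries of a fitted multilevel controllability model."""

    draws: PosteriorDraws
    regions: list[str]
    spec: BMLSpec
    model: "ROIControllabilityBML" = None

    def region_draws(self, region: str) -> np.ndarray:
        i = self.regions.index(region)
        return self.draws.combine({"b0": 1.0, f"region[{i}]": 1.0})

    def pplus(self, region_or_param: str) -> float:
        if region_or_param in self.regions:
            return _pplus(self.region_draws(region_or_param))
        return _pplus(self.draws, region_or_param)

    def summary(self) -> pd.DataFrame:
        """Per-region marginal summaries of theta_r = b0 + tau_r."""
        rh = rhat(self.draws)
        rows = []
        for r in self.regions:
            th = self.region_draws(r).reshape(-1)
            q = np.percentile(th, [2.5, 50, 97.5])
            rows.append({
                "region": r, "mean": th.mean(), "sd": th.std(ddof=1),
                "q2.5": q[0], "q50": q[1], "q97.5": q[2],
                "Pplus": float(np.mean(th > 0)),
                "rhat_max": float(np.nanmax(rh.values)),
            })
        return pd.DataFrame(rows)

    def fixed_summary(self) -> pd.DataFrame:
        rows = []
        for nm in ["b0", *self.spec.covariates]:
            if nm not in self.draws:
                continue
            x = self.draws.pooled(nm)
            q = np.percentile(x, [2.5, 50, 97.5])
            rows.append({"parameter": nm, "mean": x.mean(), "sd": x.std(ddof=1),
                         "q2.5": q[0], "q50": q[1], "q97.5": q[2],
                         "Pplus": float(np.mean(x > 0))})
        return pd.DataFrame(rows)

    def convergence(self) -> pd.DataFrame:
        return convergence_report(self.draws)

    def max_rhat(self) -> float:
        return float(np.nanmax(rhat(self.draws).values))

    def ridge_densities(self, grid_size: int = 128) -> pd.DataFrame:
        """Density coordinates of every region posterior, for ridge plots."""
        rows = []
        for r in self.regions:
            th = self.region_draws(r).reshape(-1)
            kde = gaussian_kde(th)
            lo, hi = np.percentile(th, [0.2, 99.8])
            xs = np.linspace(lo, hi, grid_size)
            ys = kde(xs)
            rows.append(pd.DataFrame({"region": r, "theta": xs, "density": ys}))
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        write_tsv(self.summary(), path)

    def draws_frame(self) -> pd.DataFrame:
        """Flat (chain, iter, parameter, value) export of all draws."""
        recs = []
        for nm in self.draws.names():
            arr = np.asarray(self.draws[nm])
            ch, it = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                                 indexing="ij")
            recs.append(pd.DataFrame({"chain": ch.ravel(), "iter": it.ravel(),
                                      "parameter": nm, "value": arr.ravel()}))
        return pd.concat(recs, ignore_index=True)


class ROIControllabilityBML:
    """Bayesian multilevel model of the controllability contrast across ROIs.

    Built from a long-format contrast table (columns pair, region, delta
    plus the covariates); ``fit`` runs the blocked Gibbs sampler and
    returns :class:`BMLResults`.
    """

    def __init__(self, table: pd.DataFrame, spec: BMLSpec = BMLSpec()):
        required = {"pair", "region", "delta"}
        if not required <= set(table.columns):
            raise ValueError(f"contrast table must have columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self.spec = spec
        self.regions = sorted(table["region"].unique().tolist())
        self.pairs = sorted(table["pair"].unique().tolist())
        if len(self.regions) < 2:
            raise ValueError("need at least 2 regions for the multilevel model")
        if len(self.pairs) < 3:
            raise ValueError("need at least 3 pairs")
        self.covariates = [c for c in spec.covariates if c in table.columns]

    def _build(self) -> GibbsModel:
        t = self.table
        y = t["delta"].to_numpy(float)
        pair_ix = pd.Categorical(t["pair"], categories=self.pairs).codes
        reg_ix = pd.Categorical(t["region"], categories=self.regions).codes
        F = [np.ones(len(t))]
        names = ["b0"]
        terms = [RandomTerm("pair", pair_ix, len(self.pairs)),
                 RandomTerm("region", reg_ix, len(self.regions))]
        for c in self.covariates:
            x = t[c].to_numpy(float)
            x = x - x.mean()
            F.append(x)
            names.append(c)
            if self.spec.varying_slopes:
                terms.append(RandomTerm(f"slope_{c}", reg_ix, len(self.regions),
                                        multiplier=x))
        return GibbsModel(y, np.column_stack(F), terms=terms, fixed_names=names,
                          fixed_scale=self.spec.fixed_scale)

    def fit(self, chains: int = 4, draws: int = 1000, warmup: int = 1000,
            seed: int = 0) -> BMLResults:
        model = self._build()
        post = model.sample(chains=chains, draws=draws, warmup=warmup, seed=seed)
        res = BMLResults(draws=post, regions=self.regions, spec=self.spec, model=self)
        mr = res.max_rhat()
        if mr > 1.1:
            log.warning("convergence warning: max split-R-hat %.3f > 1.1", mr)
        return res


@dataclass
class RobustLocationResults:
    draws: PosteriorDraws
    parameters: list[str]

    def pplus(self, parameter: str = "b0") -> float:
        return _pplus(self.draws, parameter)

    def summary(self) -> pd.DataFrame:
        rows = []
        for nm in self.parameters + ["sigma_eps", "nu"]:
            x = self.draws.pooled(nm)
            q = np.percentile(x, [2.5, 50, 97.5])
            rows.append({"parameter": nm, "mean": x.mean(), "sd": x.std(ddof=1),
                         "q2.5": q[0], "q50": q[1], "q97.5": q[2],
                         "Pplus": float(np.mean(x > 0))})
        return pd.DataFrame(rows)


class RobustLocationModel:
    """Student-t location model for per-pair difference scores.

    Used for the behavioral tests (button-press, state/trait anxiety
    differences) and the brain-SCR coupling comparison: the intercept is
    the effect of interest and the heavy-tailed observation model
    accommodates skew and outliers.  Optional covariates are mean-centered.
    """

    def __init__(self, differences, covariates: pd.DataFrame | None = None):
        y = np.asarray(differences, dtype=float)
        if y.size < 3:
            raise ValueError("need at least 3 pairs")
        if np.std(y) == 0:
            raise ValueError("constant differences; the location is degenerate")
        F = [np.ones(y.size)]
        names = ["b0"]
        if covariates is not None:
            for c in covariates.columns:
                x = covariates[c].to_numpy(float)
                F.append(x - x.mean())
                names.append(c)
        self.y, self.F, self.names = y, np.column_stack(F), names

    def fit(self, chains: int = 4, draws: int = 1000, warmup: int = 1000,
            seed: int = 0) -> RobustLocationResults:
        m = GibbsModel(self.y, self.F, fixed_names=self.names,
                       student_t_likelihood=True)
        post = m.sample(chains=chains, draws=draws, warmup=warmup, seed=seed)
        return RobustLocationResults(draws=post, parameters=self.names)


# ---- functional wrappers over the model classes --------------------------

def fit_bml_roi(table: pd.DataFrame, spec: BMLSpec = BMLSpec(), chains: int = 4,
                draws: int = 1000, warmup: int = 1000, seed: int = 0) -> BMLResults:
    return ROIControllabilityBML(table, spec).fit(chains=chains, draws=draws,
                                                  warmup=warmup, seed=seed)


def fit_robust_intercept(differences, covariates: pd.DataFrame | None = None,
                         chains: int = 4, draws: int = 1000, warmup: int = 1000,
                         seed: int = 0) -> RobustLocationResults:
    return RobustLocationModel(differences, covariates).fit(
        chains=chains, draws=draws, warmup=warmup, seed=seed)


def summarize(results: BMLResults, path=None) -> pd.DataFrame:
    """Per-region summary table (optionally written as TSV)."""
    s = results.summary()
    if path is not None:
        write_tsv(s, path)
    return s
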