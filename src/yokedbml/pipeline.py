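"""End-to-end orchestration of the synthetic controllability study.

One seeded configuration drives every stage: paradigm generation, yoked
cohort simulation, participant-level GLMs, the region-level Bayesian
multilevel model, the voxelwise path (three-level BML plus the standard
paired-t / cluster-extent analysis), and brain-SCR coupling.  Each stage
writes its outputs under the configured directory and is skipped on rerun
when its outputs already exist, so a broken run resumes where it stopped.
A manifest records the configuration hash and a digest of every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bml as bml_mod
from . import cohort as co
from . import glm as fl
from . import scr as scr_mod
from . import voxel as vx
from ._util import rng_for, write_tsv
from .paradigm import (MotionConfig, WheelConfig, generate_trajectory,
                       simulate_wheel_trials, write_events)

log = logging.getLogger("yokedbml.pipeline")

__all__ = ["MCMCSettings", "VoxelSettings", "PipelineConfig", "RunManifest",
           "validate_config", "load_config", "run_full", "small_preset"]


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000

    def validate(self, errors, prefix):
        if self.chains < 2:
            errors.append(f"{prefix}.chains: need >= 2 chains")
        if self.draws < 4 or self.warmup < 0:
            errors.append(f"{prefix}.draws/warmup: invalid iteration counts")


@dataclass(frozen=True)
class VoxelSettings:
    n_voxels: int = 200
    k_subrois: int = 5
    effect_subroi: int = 2          # sub-ROI receiving the injected effect
    fwhm_mm: float = 4.0
    voxel_alpha: float = 0.001
    min_extent: int = 13
    connectivity: int = 6
    chains: int = 2
    draws: int = 400
    warmup: int = 400

    def validate(self, errors, prefix):
        if self.n_voxels < self.k_subrois:
            errors.append(f"{prefix}.n_voxels: fewer voxels than sub-ROIs")
        if not 0 < self.voxel_alpha < 1:
            errors.append(f"{prefix}.voxel_alpha: must be in (0, 1)")
        if self.min_extent < 1:
            errors.append(f"{prefix}.min_extent: must be >= 1")
        if self.connectivity not in (6, 18, 26):
            errors.append(f"{prefix}.connectivity: must be 6, 18 or 26")


@dataclass(frozen=True)
class PipelineConfig:
    motion: MotionConfig = MotionConfig()
    wheel: WheelConfig = WheelConfig()
    truth: co.GroundTruth = co.GroundTruth()
    mcmc: MCMCSettings = MCMCSettings()
    voxel: VoxelSettings = VoxelSettings()
    scr_window: float = 6.0
    coupling_roi: str = "L_BST"
    out_dir: str = "yokedbml_run"
    seed: int | None = None

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.seed is None:
            errors.append("seed: an explicit seed is required")
        try:
            self.motion.validate()
        except Exception as e:
            errors.append(f"motion: {e}")
        if not -1.0 < self.truth.ar1 < 1.0:
            errors.append("truth.noise.ar1: AR(1) coefficient must be in (-1, 1)")
        if self.truth.n_pairs < 2:
            errors.append("truth.n_pairs: need >= 2 pairs")
        if self.coupling_roi not in self.truth.roi_names:
            errors.append(f"coupling_roi: {self.coupling_roi!r} not a configured ROI")
        self.mcmc.validate(errors, "mcmc")
        self.voxel.validate(errors, "voxel")
        return errors

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # scientifically identical runs hash equal
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def small_preset(seed: int = 0, out_dir: str = "yokedbml_small") -> PipelineConfig:
    """A reduced configuration for smoke tests: 12 pairs, 2 runs, 200 voxels."""
    motion = MotionConfig(n_runs=2, total_collisions=9, seed=seed)
    truth = co.GroundTruth(n_pairs=12, effect_map={r: 0.3 for r in co.DEFAULT_EFFECT_ROIS},
                           scr_rate=50.0, seed=seed)
    return PipelineConfig(
        motion=motion, truth=truth,
        mcmc=MCMCSettings(chains=2, draws=400, warmup=400),
        voxel=VoxelSettings(chains=2, draws=300, warmup=300, min_extent=5),
        out_dir=out_dir, seed=seed,
    )


def _structure(cls, data):
    """Rebuild (nested) frozen dataclasses from plain dicts."""
    if not dataclasses.is_dataclass(cls):
        return data
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("motion", "wheel", "truth",
                                                          "mcmc", "voxel", "hrf"):
            sub = {"motion": MotionConfig, "wheel": WheelConfig, "truth": co.GroundTruth,
                   "mcmc": MCMCSettings, "voxel": VoxelSettings, "hrf": fl.HRFParams}[f.name]
            try:
                v = _structure(sub, v)
            except (ValueError, TypeError) as e:
                raise ValueError(f"{f.name}: {e}") from e
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline configuration (no validation)."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as e:
            raise ValueError(f"config parse error: {e}") from e
    return _structure(PipelineConfig, data)


def validate_config(path) -> PipelineConfig:
    """Load a config file and raise with the full error list if invalid."""
    cfg = load_config(path)
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)   # stage -> {file: sha256}
    timestamps: dict = field(default_factory=dict)

    def record(self, stage: str, files: list[Path]):
        self.stages[stage] = {p.name: _digest(p) for p in files}
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, path: Path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _header_comment(cfg: PipelineConfig) -> str:
    return f"# yokedbml config_hash={cfg.config_hash()}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(_header_comment(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.9f")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


class PipelineError(RuntimeError):
    def __init__(self, stage, original, completed):
        self.stage = stage
        self.completed = completed
        super().__init__(f"stage {stage!r} failed after {completed}: {original}")


def run_full(config: PipelineConfig) -> RunManifest:
    """Execute the full synthetic-study workflow.

    paradigm -> cohort -> participant GLMs -> region BML -> voxel path
    (three-level BML + paired-t map) -> SCR coupling.  Stages whose output
    files already exist are skipped, so reruns resume after failures and a
    fixed seed reproduces identical deterministic-stage digests.
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _v
    try:
        version = _v("yokedbml")
    except Exception:  # pragma: no cover
        version = "unknown"
    manifest = RunManifest(config_hash=config.config_hash(), version=version)
    completed: list[str] = []

    state: dict = {}
    stages = [
        ("paradigm", _stage_paradigm),
        ("cohort", _stage_cohort),
        ("firstlevel", _stage_firstlevel),
        ("bml_roi", _stage_bml_roi),
        ("voxelwise", _stage_voxelwise),
        ("scr_coupling", _stage_scr),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        try:
            files = fn(config, out, state)
        except Exception as e:
            manifest.save(out / "manifest.json")
            raise PipelineError(name, e, completed) from e
        manifest.record(name, files)
        completed.append(name)
        log.info("stage %s done (%d files)", name, len(files))
    manifest.save(out / "manifest.json")
    return manifest


# ---- stages ---------------------------------------------------------------

def _stage_paradigm(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    session = generate_trajectory(replace(cfg.motion, seed=cfg.seed),
                                  cfg.wheel.duration_schedule)
    state["session"] = session
    behaviors = {}
    ev_dir = out / "events"
    ev_dir.mkdir(exist_ok=True)
    files = []
    for pair in range(cfg.truth.n_pairs):
        beh = simulate_wheel_trials(session, cfg.wheel,
                                    seed=int(rng_for(cfg.seed, "pair", pair).integers(2 ** 31)))
        behaviors[pair] = beh
        for member in ("CTL", "UNCTL"):
            p = ev_dir / f"pair{pair:03d}_{member}_events.tsv"
            if not p.exists():
                write_events(beh, session, p, member)
            files.append(p)
    state["behaviors"] = behaviors
    return files


def _stage_cohort(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    press_diff = np.array([
        state["behaviors"][p].press_total("UNCTL") - state["behaviors"][p].press_total("CTL")
        for p in range(cfg.truth.n_pairs)], dtype=float)
    covs = co.generate_covariates(cfg.truth.n_pairs, seed=cfg.seed, press_diff=press_diff)
    state["covariates"] = covs
    f1, f2 = out / "participants.tsv", out / "pair_covariates.tsv"
    if not f1.exists():
        _write_table(covs.participants, f1, cfg)
    if not f2.exists():
        _write_table(covs.pairs, f2, cfg)
    return [f1, f2]


def _participant_events(beh) -> pd.DataFrame:
    return pd.DataFrame({"onset": beh.onsets(), "duration": beh.durations(),
                         "trial_type": "stressor",
                         "n_presses": beh.press_counts("CTL").astype(float)})


def _stage_firstlevel(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    f_betas = out / "roi_betas.tsv"
    f_contrasts = out / "pair_contrasts.tsv"
    session = state["session"]
    truth = replace(cfg.truth, seed=cfg.seed)
    state["truth"] = truth
    if f_betas.exists() and f_contrasts.exists():
        state["contrasts"] = read_table(f_contrasts)
        return [f_betas, f_contrasts]
    rng = rng_for(cfg.seed, "pair-shift")
    rows = []
    coupling_store = {}
    for pair in range(truth.n_pairs):
        beh = state["behaviors"][pair]
        pair_shift = rng.normal(0.0, truth.pair_effect_sd)
        for member in ("CTL", "UNCTL"):
            ts = co.simulate_roi_bold(session, beh, truth, member, pair,
                                      noise=True, pair_shift=pair_shift)
            events = pd.DataFrame({
                "onset": beh.onsets(), "duration": beh.durations(),
                "trial_type": "stressor",
                "n_presses": beh.press_counts(member).astype(float)})
            n_tr = ts.data.shape[0]
            motion = co.simulate_motion_params(
                n_tr, ts.run_index, seed=int(rng_for(cfg.seed, "motion", pair, member).integers(2 ** 31)))
            X = fl.build_design(events, session, motion=motion, hrf=truth.hrf,
                                tr=truth.tr)
            Y = fl.normalize_intensity(ts.data.to_numpy(), ts.run_index)
            res = fl.fit_glm(Y, X)
            stress = res.betas[X.columns.index("stressor")]
            for roi, b in zip(truth.roi_names, stress):
                rows.append({"participant": ts.participant, "pair": pair,
                             "group": member, "region": roi, "beta": b})
            # keep the coupling ROI series for the SCR stage
            coupling_store[(pair, member)] = (
                ts.data[cfg.coupling_roi].to_numpy(), ts.trial_arousal, events)
    betas = pd.DataFrame(rows)
    _write_table(betas, f_betas, cfg)
    contrasts = bml_mod.build_pair_contrasts(betas, state["covariates"])
    _write_table(contrasts, f_contrasts, cfg)
    state["contrasts"] = contrasts
    state["coupling_store"] = coupling_store
    return [f_betas, f_contrasts]


def _stage_bml_roi(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    f_sum = out / "bml_roi_summary.tsv"
    f_fix = out / "bml_fixed_effects.tsv"
    f_ridge = out / "bml_ridge_densities.tsv"
    if all(p.exists() for p in (f_sum, f_fix, f_ridge)):
        state["bml_summary"] = read_table(f_sum)
        return [f_sum, f_fix, f_ridge]
    res = bml_mod.fit_bml_roi(state["contrasts"], chains=cfg.mcmc.chains,
                              draws=cfg.mcmc.draws, warmup=cfg.mcmc.warmup,
                              seed=cfg.seed)
    s = res.summary()
    _write_table(s, f_sum, cfg)
    _write_table(res.fixed_summary(), f_fix, cfg)
    _write_table(res.ridge_densities(), f_ridge, cfg)
    state["bml_summary"] = s
    return [f_sum, f_fix, f_ridge]


def _territory_mask(cfg: PipelineConfig) -> vx.VolumeMask:
    """Synthetic insula-like territory with the configured voxel count."""
    n = cfg.voxel.n_voxels
    side = int(np.ceil((2.5 * n) ** (1 / 3))) + 2
    shape = (side, side, max(4, side // 2))
    grid = np.indices(shape).reshape(3, -1).T
    center = (np.array(shape) - 1) / 2
    radii = np.array(shape) / 2
    d = (((grid - center) / radii) ** 2).sum(axis=1)
    sel = np.argsort(d)[:n]
    data = np.zeros(shape, dtype=bool)
    data[grid[sel, 0], grid[sel, 1], grid[sel, 2]] = True
    return vx.VolumeMask(data, np.diag([2.0, 2.0, 2.0, 1.0]))


def _stage_voxelwise(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    f_pplus = out / "voxel_pplus.nii"
    f_clusters = out / "voxel_clusters.tsv"
    f_tmap = out / "voxel_tmap.nii"
    if all(p.exists() for p in (f_pplus, f_clusters, f_tmap)):
        return [f_pplus, f_clusters, f_tmap]
    truth = state["truth"]
    session = state["session"]
    mask = _territory_mask(cfg)
    part = vx.kmeans_subrois(mask, cfg.voxel.k_subrois, seed=cfg.seed)
    effect_amp = max(truth.effect_map.values(), default=0.1)
    spatial_effect = np.where(part.labels == cfg.voxel.effect_subroi % part.k,
                              effect_amp, 0.0)
    ijk = mask.coordinates()
    rows = []
    beta_maps = {"CTL": [], "UNCTL": []}
    for pair in range(truth.n_pairs):
        beh = state["behaviors"][pair]
        deltas = {}
        for member in ("CTL", "UNCTL"):
            img, _ = co.simulate_voxel_volumes(mask, spatial_effect, truth, session,
                                               beh, member, pair)
            vol = np.asarray(img.dataobj)
            vol = vx.smooth_gaussian(vol, cfg.voxel.fwhm_mm, mask)
            Y = vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :].T   # time x voxel
            events = pd.DataFrame({"onset": beh.onsets(), "duration": beh.durations(),
                                   "trial_type": "stressor",
                                   "n_presses": beh.press_counts(member).astype(float)})
            X = fl.build_design(events, session, hrf=truth.hrf, tr=truth.tr)
            run_ix = X.run_index
            Y = fl.normalize_intensity(Y, run_ix)
            res = fl.fit_glm(Y, X)
            deltas[member] = res.betas[X.columns.index("stressor")]
            bm = np.zeros(mask.shape)
            bm[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = deltas[member]
            beta_maps[member].append(bm)
        d = deltas["UNCTL"] - deltas["CTL"]
        for v, dv in enumerate(d):
            rows.append({"pair": pair, "voxel": v, "delta": dv})
    table = pd.DataFrame(rows)
    res_v = vx.fit_bml_voxel(table, part, chains=cfg.voxel.chains,
                             draws=cfg.voxel.draws, warmup=cfg.voxel.warmup,
                             seed=cfg.seed)
    import nibabel as nib
    nib.save(res_v.pplus_volume(), f_pplus)
    t_map, p_map = vx.paired_ttest_map(np.stack(beta_maps["UNCTL"]),
                                       np.stack(beta_maps["CTL"]))
    # restrict to the mask; outside voxels are undefined
    p_map = np.where(mask.data, p_map, 1.0)
    ctab, labeled = vx.cluster_threshold(np.nan_to_num(p_map, nan=1.0),
                                         np.nan_to_num(t_map), cfg.voxel.voxel_alpha,
                                         cfg.voxel.min_extent, cfg.voxel.connectivity)
    _write_table(ctab, f_clusters, cfg)
    nib.save(nib.Nifti1Image(np.nan_to_num(t_map).astype(np.float32), mask.affine), f_tmap)
    state["voxel_pplus"] = res_v
    state["voxel_clusters"] = ctab
    state["voxel_partition"] = part
    state["voxel_effect"] = spatial_effect
    return [f_pplus, f_clusters, f_tmap]


def _stage_scr(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    f_amps = out / "scr_amplitudes.tsv"
    f_coupling = out / "scr_coupling_summary.tsv"
    if f_amps.exists() and f_coupling.exists():
        return [f_amps, f_coupling]
    truth = state["truth"]
    session = state["session"]
    store = state.get("coupling_store", {})
    if not store:
        # resumed run: regenerate the coupling ROI series deterministically
        rng = rng_for(cfg.seed, "pair-shift")
        for pair in range(truth.n_pairs):
            beh = state["behaviors"][pair]
            pair_shift = rng.normal(0.0, truth.pair_effect_sd)
            for member in ("CTL", "UNCTL"):
                ts = co.simulate_roi_bold(session, beh, truth, member, pair,
                                          noise=True, pair_shift=pair_shift)
                events = pd.DataFrame({
                    "onset": beh.onsets(), "duration": beh.durations(),
                    "trial_type": "stressor",
                    "n_presses": beh.press_counts(member).astype(float)})
                store[(pair, member)] = (
                    ts.data[cfg.coupling_roi].to_numpy(), ts.trial_arousal, events)
    amp_rows, pair_rows = [], []
    for pair in range(truth.n_pairs):
        beh = state["behaviors"][pair]
        zz = {}
        for member in ("CTL", "UNCTL"):
            series, arousal, events = store[(pair, member)]
            trace = co.simulate_scr(beh, truth, member, pair, trial_bold=arousal)
            scr_amps = scr_mod.score_scr_trials(trace, beh.onsets(), window=cfg.scr_window)
            nuisance = None
            brain = fl.lss_trial_betas(
                fl.normalize_intensity(series, state_run_index(session, truth)),
                events, session, X_nuisance=nuisance, hrf=truth.hrf, tr=truth.tr)
            rho, z = scr_mod.brain_scr_correlation(brain, scr_amps)
            zz[member] = z
            for k in range(len(scr_amps)):
                amp_rows.append({"pair": pair, "group": member, "trial": k,
                                 "scr": scr_amps[k], "brain": brain[k]})
        pair_rows.append({"pair": pair, "z_UNCTL": zz["UNCTL"], "z_CTL": zz["CTL"]})
    pair_z = pd.DataFrame(pair_rows).join(
        (state["covariates"].pairs.set_index("pair")
         [["StateAnxietyAVG", "TraitAnxietyAVG", "ButtonPressDIFF"]]), on="pair")
    res = scr_mod.fit_coupling_model(
        pair_z, covariates=("StateAnxietyAVG", "TraitAnxietyAVG", "ButtonPressDIFF"),
        chains=cfg.mcmc.chains, draws=cfg.mcmc.draws, warmup=cfg.mcmc.warmup,
        seed=cfg.seed)
    _write_table(pd.DataFrame(amp_rows), f_amps, cfg)
    _write_table(res.summary(), f_coupling, cfg)
    state["coupling_result"] = res
    return [f_amps, f_coupling]


def state_run_index(session, truth) -> np.ndarray:
    n_tr_run = int(round(session.config.run_duration / truth.tr))
    return np.repeat(np.arange(session.config.n_runs), n_tr_run)


def _stage_report(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    f = out / "report.json"
    report = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    if "bml_summary" in state:
        s = state["bml_summary"].sort_values("Pplus", ascending=False)
        report["top_regions_by_Pplus"] = s.head(5)[["region", "Pplus"]].to_dict("records")
        report["injected_regions"] = sorted(state["truth"].effect_map)
    if "coupling_result" in state:
        report["scr_coupling_intercept_Pplus"] = state["coupling_result"].pplus()
    if "voxel_clusters" in state:
        report["n_clusters"] = int(len(state["voxel_clusters"]))
    with open(f, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return [f]
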