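"""Voxel-level analyses: masks, sub-ROI partitioning, three-level BML,
paired-t maps with cluster-extent thresholding, and Gaussian smoothing.

The insula-style path subdivides an anatomical territory into sub-ROIs of
comparable size by k-means on millimeter coordinates, then fits one joint
multilevel model over all voxels of the territory:

    Delta_{p,v} = b0 + pi_p + s_{j(v)} + u_v + eps,

whose per-voxel effect theta_v = b0 + s_{j(v)} + u_v is summarized as a
P+ map.  The standard path compares the groups voxelwise with a paired t
test and keeps suprathreshold clusters of at least a configured extent
(the extent values are inputs; their Monte-Carlo calibration is not
reproduced here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .bayes import GibbsModel, RandomTerm
from .bml import BMLResults  # noqa: F401  (re-export convenience)

log = logging.getLogger(__name__)

__all__ = [
    "VolumeMask",
    "SubROIPartition",
    "kmeans_subrois",
    "InsulaVoxelBML",
    "VoxelBMLResults",
    "fit_bml_voxel",
    "paired_ttest_map",
    "cluster_threshold",
    "smooth_gaussian",
    "sphere_mask",
    "intersect",
    "snr_erode",
]


@dataclass
class VolumeMask:
    """Boolean 3-D mask with a voxel-to-millimeter affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("mask affine is not invertible")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel indices, in C order."""
        return np.argwhere(self.data)

    def coordinates_mm(self) -> np.ndarray:
        ijk = self.coordinates()
        return nib.affines.apply_affine(self.affine, ijk)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, img_or_path) -> "VolumeMask":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
        return cls(np.asarray(img.dataobj) > 0, img.affine)


@dataclass
class SubROIPartition:
    """k-means sub-ROI labels over the voxels of one mask."""

    mask: VolumeMask
    labels: np.ndarray          # per mask voxel, 0..k-1 (coordinates() order)
    k: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def label_volume(self) -> np.ndarray:
        vol = np.full(self.mask.shape, -1, dtype=int)
        ijk = self.mask.coordinates()
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = self.labels
        return vol


def kmeans_subrois(mask: VolumeMask, k: int, seed: int = 0) -> SubROIPartition:
    """Subdivide a mask into k spatially compact sub-ROIs of comparable size.

    Plain k-means on the millimeter coordinates of the mask voxels, 20
    restarts, best inertia kept; deterministic given the seed.
    """
    from sklearn.cluster import KMeans

    n_vox = mask.n_voxels
    if k < 1 or k > n_vox:
        raise ValueError(f"k={k} out of range for a {n_vox}-voxel mask")
    xyz = mask.coordinates_mm()
    km = KMeans(n_clusters=k, n_init=20, random_state=int(seed) & 0x7FFFFFFF)
    labels = km.fit_predict(xyz)
    # relabel deterministically: sort clusters by (x, y, z) of their centroid
    order = np.lexsort(km.cluster_centers_.T[::-1])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return SubROIPartition(mask=mask, labels=remap[labels], k=k)


@dataclass
class VoxelBMLResults:
    """Posterior P+ and effect maps of the three-level voxelwise model."""

    draws: object
    partition: SubROIPartition
    pplus: np.ndarray            # per mask voxel
    theta_mean: np.ndarray

    def pplus_volume(self) -> nib.Nifti1Image:
        vol = np.zeros(self.partition.mask.shape, dtype=np.float32)
        ijk = self.partition.mask.coordinates()
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = self.pplus
        return nib.Nifti1Image(vol, self.partition.mask.affine)

    def max_rhat(self) -> float:
        from .bml import rhat

        return float(np.nanmax(rhat(self.draws).values))


class InsulaVoxelBML:
    """Three-level (pair / sub-ROI / voxel) multilevel model of a territory.

    ``table`` is long format with columns pair, voxel (0..V-1 in mask
    coordinate order), delta, plus optional pair-level covariates.  One
    joint posterior is estimated for the whole territory.
    """

    def __init__(self, table: pd.DataFrame, partition: SubROIPartition,
                 covariates: tuple[str, ...] = ()):
        required = {"pair", "voxel", "delta"}
        if not required <= set(table.columns):
            raise ValueError(f"voxel table needs columns {sorted(required)}")
        v = table["voxel"].to_numpy(int)
        n_vox = len(partition.labels)
        if v.min() < 0 or v.max() >= n_vox:
            raise ValueError("voxel indices outside the partition")
        if len(np.unique(v)) != n_vox:
            raise ValueError("partition does not cover all voxels in the table")
        self.table = table.reset_index(drop=True)
        self.partition = partition
        self.covariates = [c for c in covariates if c in table.columns]

    def fit(self, chains: int = 4, draws: int = 500, warmup: int = 500,
            seed: int = 0) -> VoxelBMLResults:
        t = self.table
        y = t["delta"].to_numpy(float)
        pairs = sorted(t["pair"].unique().tolist())
        pair_ix = pd.Categorical(t["pair"], categories=pairs).codes
        vox = t["voxel"].to_numpy(int)
        sub = self.partition.labels[vox]
        F = [np.ones(len(t))]
        names = ["b0"]
        for c in self.covariates:
            x = t[c].to_numpy(float)
            F.append(x - x.mean())
            names.append(c)
        n_vox = len(self.partition.labels)
        model = GibbsModel(
            y, np.column_stack(F),
            terms=[RandomTerm("pair", pair_ix, len(pairs)),
                   RandomTerm("subroi", sub, self.partition.k),
                   RandomTerm("voxel", vox, n_vox)],
            fixed_names=names,
        )
        post = model.sample(chains=chains, draws=draws, warmup=warmup, seed=seed)
        b0 = np.asarray(post["b0"]).reshape(-1)
        s_draws = np.stack([post.pooled(f"subroi[{j}]") for j in range(self.partition.k)])
        u_draws = np.stack([post.pooled(f"voxel[{v}]") for v in range(n_vox)])
        theta = b0[None, :] + s_draws[self.partition.labels] + u_draws
        res = VoxelBMLResults(
            draws=post, partition=self.partition,
            pplus=(theta > 0).mean(axis=1), theta_mean=theta.mean(axis=1),
        )
        mr = res.max_rhat()
        if mr > 1.1:
            log.warning("voxel BML convergence warning: max split-R-hat %.3f", mr)
        return res


def fit_bml_voxel(table: pd.DataFrame, partition: SubROIPartition,
                  covariates: tuple[str, ...] = (), chains: int = 4,
                  draws: int = 500, warmup: int = 500, seed: int = 0) -> VoxelBMLResults:
    return InsulaVoxelBML(table, partition, covariates).fit(
        chains=chains, draws=draws, warmup=warmup, seed=seed)


def paired_ttest_map(betas_unctl: np.ndarray, betas_ctl: np.ndarray):
    """Voxelwise paired t test of uncontrollable minus controllable betas.

    Inputs are (n_pairs, ...) arrays on identical grids.  Returns (t map,
    two-sided p map); voxels with zero difference variance yield NaN with
    a warning.
    """
    a = np.asarray(betas_unctl, dtype=float)
    b = np.asarray(betas_ctl, dtype=float)
    if a.shape != b.shape:
        raise ValueError("group beta maps have different shapes")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = sd == 0
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} voxel(s) with zero variance; t/p set to NaN")
        t = np.where(bad, np.nan, t)
    p = 2.0 * t_dist.sf(np.abs(t), df=n - 1)
    return t, p


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_threshold(p_map: np.ndarray, t_map: np.ndarray, voxel_alpha: float,
                      min_extent: int, connectivity: int = 6):
    """Cluster-extent thresholding of a statistical map.

    Suprathreshold voxels (p < voxel_alpha) are grouped into connected
    components separately for each sign of the statistic; components
    smaller than ``min_extent`` voxels are removed.  Returns a cluster
    table and a labeled volume (0 = background).
    """
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = _STRUCTURES[connectivity]
    p_map = np.asarray(p_map, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    supra = (p_map < voxel_alpha) & np.isfinite(t_map)
    labeled = np.zeros(p_map.shape, dtype=int)
    rows = []
    next_label = 1
    for sign in (1, -1):
        comp, n_comp = ndimage.label(supra & (np.sign(t_map) == sign), structure=structure)
        for c in range(1, n_comp + 1):
            sel = comp == c
            size = int(sel.sum())
            if size < min_extent:
                continue
            tc = np.where(sel, t_map, 0.0)
            peak_flat = np.argmax(np.abs(tc))
            peak = np.unravel_index(peak_flat, t_map.shape)
            labeled[sel] = next_label
            rows.append({"label": next_label, "size": size, "sign": sign,
                         "peak_t": float(t_map[peak]),
                         "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2]})
            next_label += 1
    table = pd.DataFrame(rows, columns=["label", "size", "sign", "peak_t",
                                        "peak_i", "peak_j", "peak_k"])
    return table, labeled


def smooth_gaussian(series: np.ndarray, fwhm_mm: float, mask: VolumeMask,
                    voxel_size_mm=None) -> np.ndarray:
    """Mask-restricted Gaussian smoothing (normalized convolution).

    The kernel is renormalized within the mask so values never bleed in
    from outside and a constant image stays constant; fwhm 0 is the
    identity.  ``series`` is 3-D or 4-D (x, y, z[, t]).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    data = np.asarray(series, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    if voxel_size_mm is None:
        voxel_size_mm = np.sqrt((mask.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = (fwhm_mm / np.sqrt(8.0 * np.log(2.0))) / np.asarray(voxel_size_mm)
    m = mask.data.astype(float)
    norm = ndimage.gaussian_filter(m, sigma_vox)

    def _sm(vol3):
        num = ndimage.gaussian_filter(vol3 * m, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(m > 0, num / norm, 0.0)
        return out

    if data.ndim == 3:
        return _sm(data)
    out = np.empty_like(data)
    for t in range(data.shape[3]):
        out[..., t] = _sm(data[..., t])
    return out


def sphere_mask(center_mm, radius_mm: float, grid_shape, affine) -> VolumeMask:
    """Spherical ROI: voxels whose center lies within the radius."""
    ijk = np.indices(grid_shape).reshape(3, -1).T
    xyz = nib.affines.apply_affine(np.asarray(affine, float), ijk)
    d = np.linalg.norm(xyz - np.asarray(center_mm, float), axis=1)
    data = (d <= radius_mm).reshape(grid_shape)
    if not data.any():
        warnings.warn("sphere mask is empty")
    return VolumeMask(data, affine)


def intersect(m1: VolumeMask, m2: VolumeMask) -> VolumeMask:
    """Voxelwise AND of two masks on the same grid."""
    if m1.shape != m2.shape or not np.allclose(m1.affine, m2.affine):
        raise ValueError("masks are on incompatible grids")
    data = m1.data & m2.data
    if not data.any():
        warnings.warn("mask intersection is empty")
    return VolumeMask(data, m1.affine)


def snr_erode(mask: VolumeMask, series: np.ndarray, snr_min: float) -> VolumeMask:
    """Drop mask voxels whose temporal SNR (mean / SD over time) is low.

    Used e.g. to erode a periaqueductal-gray mask away from the aqueduct,
    where signal quality collapses.
    """
    data = np.asarray(series, dtype=float)
    if data.shape[:3] != mask.shape:
        raise ValueError("series grid does not match the mask")
    mean = data.mean(axis=3)
    sd = data.std(axis=3, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = np.where(sd > 0, mean / sd, np.inf)
    keep = mask.data & (snr >= snr_min)
    if not keep.any():
        warnings.warn("SNR erosion removed every voxel")
    return VolumeMask(keep, mask.affine)
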