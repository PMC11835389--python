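"""Searchlight analyses on masked voxel grids.

Two procedures, both over a 3x3x3 voxel neighborhood clipped to the brain
mask:

* mean-activation maps — per voxel, the neighborhood-mean activation per
  display condition is z-scored within condition groups (present vs absent,
  symmetric vs asymmetric) and correlated with the equally z-scored
  behavioral predictor (visual homogeneity, or response time);
* representational maps — per voxel, the neighborhood multivoxel pattern per
  single-object condition yields all pairwise Euclidean distances (a local
  neural RDM), which are correlated with the behavioral perceptual
  dissimilarities.

Group-wise z-scoring removes overall activation-level differences between
the two display groups without altering within-group structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import pearson, rng_for
from .vh_model import split_groups

_CUBE = np.ones((3, 3, 3))


@dataclass
class VoxelLayout:
    """Geometry of a synthetic volume: mask plus planted signal regions."""

    grid_shape: tuple[int, int, int]
    mask: np.ndarray
    vh_region: np.ndarray  # boolean grids
    rt_region: np.ndarray
    noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.vh_region = np.asarray(self.vh_region, dtype=bool)
        self.rt_region = np.asarray(self.rt_region, dtype=bool)
        for name in ("mask", "vh_region", "rt_region"):
            if getattr(self, name).shape != tuple(self.grid_shape):
                raise ValueError(f"{name} shape does not match grid_shape")
        if (self.vh_region & ~self.mask).any() or (self.rt_region & ~self.mask).any():
            raise ValueError("signal regions must lie inside the mask")
        if (self.vh_region & self.rt_region).any():
            raise ValueError("signal regions must be disjoint")


@dataclass
class VoxelDataset:
    """Per-condition activation volumes inside a brain mask.

    ``betas`` has shape (n_conditions, X, Y, Z); ``subject_betas`` optionally
    holds per-subject volumes (n_subjects, n_conditions, X, Y, Z), in which
    case ``betas`` is their across-subject mean.
    """

    mask: np.ndarray
    conditions: list[str]
    betas: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    subject_betas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape[0] != len(self.conditions):
            raise ValueError("betas first axis must match condition list")
        if self.betas.shape[1:] != self.mask.shape:
            raise ValueError("betas grids must match mask shape")
        if not np.all(np.isfinite(self.betas[:, self.mask])):
            raise ValueError("betas must be finite inside the mask")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass
class SearchlightMap:
    """3-D grid of Pearson r values; NaN outside the mask or where undefined."""

    values: np.ndarray
    kind: str
    n_undefined: int = 0
    neighborhood_size: np.ndarray | None = field(default=None, repr=False)


def neighborhood_indices(mask: np.ndarray, voxel) -> np.ndarray:
    """In-mask voxel indices of the 3x3x3 cube centered on ``voxel``.

    The center is included; the cube is clipped at grid edges and intersected
    with the mask, so interior voxels of a full mask get 27 indices and a
    grid corner gets 8.
    """
    mask = np.asarray(mask, dtype=bool)
    voxel = tuple(int(v) for v in voxel)
    if not mask[voxel]:
        raise ValueError(f"voxel {voxel} is outside the mask")
    lo = [max(v - 1, 0) for v in voxel]
    hi = [min(v + 1, s - 1) for v, s in zip(voxel, mask.shape)]
    out = []
    for x in range(lo[0], hi[0] + 1):
        for y in range(lo[1], hi[1] + 1):
            for z in range(lo[2], hi[2] + 1):
                if mask[x, y, z]:
                    out.append((x, y, z))
    return np.array(out)


def zscore_by_group(values: np.ndarray, labels) -> np.ndarray:
    """Z-score within each label group (sample SD, ddof=1).

    After the transform each group has mean exactly 0 and SD exactly 1; a
    zero-variance group becomes NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        g = labels == lab
        if g.sum() < 2:
            raise ValueError(f"group {lab!r} needs at least 2 conditions")
        sd = values[g].std(ddof=1)
        if sd == 0:
            warnings.warn(f"zero variance in group {lab!r}; z-scores set to NaN")
            out[g] = np.nan
        else:
            out[g] = (values[g] - values[g].mean()) / sd
    return out


def _neighborhood_means(betas: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(C, n_mask_voxels) mean activation over each voxel's clipped cube."""
    maskf = mask.astype(float)
    counts = ndimage.convolve(maskf, _CUBE, mode="constant")
    means = np.empty((betas.shape[0], int(mask.sum())))
    for c in range(betas.shape[0]):
        sums = ndimage.convolve(betas[c] * maskf, _CUBE, mode="constant")
        means[c] = (sums / counts)[mask]
    return means


def _zscore_rows_by_group(values: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Group-wise z-scoring along axis 0 of a (C, V) array."""
    out = np.empty_like(values)
    for g in (in_a, ~in_a):
        v = values[g]
        sd = v.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[g] = (v - v.mean(axis=0)) / sd
        out[g][:, sd == 0] = np.nan
    return out


def _corr_map(data: VoxelDataset, predictor: np.ndarray, labels, kind: str,
              zscore: bool) -> SearchlightMap:
    in_a, _ = split_groups(labels)
    nm = _neighborhood_means(data.betas, data.mask)  # (C, V)
    predictor = np.asarray(predictor, dtype=float)
    if zscore:
        nm = _zscore_rows_by_group(nm, in_a)
        pred = zscore_by_group(predictor, np.asarray(labels))
    else:
        pred = predictor - predictor.mean()
        nm = nm - nm.mean(axis=0)
    # after centering/z-scoring, Pearson r reduces to a normalized dot product
    x = nm - nm.mean(axis=0)
    y = pred - pred.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y[:, None]).sum(axis=0) / np.sqrt(
            (x**2).sum(axis=0) * (y**2).sum()
        )
    values = np.full(data.grid_shape, np.nan)
    values[data.mask] = r
    return SearchlightMap(values=values, kind=kind,
                          n_undefined=int(np.isnan(r).sum()))


def vh_correlation_map(data: VoxelDataset, vh: np.ndarray, labels,
                       zscore: bool = True) -> SearchlightMap:
    """Correlation of neighborhood-mean activation with visual homogeneity.

    Both the mean activations and the VH values are z-scored separately
    within the two display groups before correlating across conditions.
    """
    if len(vh) != len(data.conditions):
        raise ValueError("vh must align with the dataset's condition list")
    return _corr_map(data, vh, labels, "vh_correlation", zscore)


def rt_correlation_map(data: VoxelDataset, rts: np.ndarray, labels,
                       scope: str = "all", zscore: bool = True) -> SearchlightMap:
    """As :func:`vh_correlation_map` with response times as the predictor.

    ``scope`` restricts the correlation to one display group ("groupA",
    "groupB") or uses all conditions ("all").
    """
    if len(rts) != len(data.conditions):
        raise ValueError("rts must align with the dataset's condition list")
    if scope == "all":
        return _corr_map(data, rts, labels, "rt_correlation", zscore)
    in_a, in_b = split_groups(labels)
    keep = in_a if scope == "groupA" else in_b if scope == "groupB" else None
    if keep is None:
        raise ValueError(f"unknown scope {scope!r}")
    sub = VoxelDataset(
        mask=data.mask,
        conditions=[c for c, k in zip(data.conditions, keep) if k],
        betas=data.betas[keep],
        voxel_size=data.voxel_size,
    )
    # single group: plain (non-grouped) centering — a one-group z-score
    labels_sub = np.asarray(labels)[keep]
    if zscore:
        pred = zscore_by_group(np.asarray(rts, float)[keep], labels_sub)
    else:
        pred = np.asarray(rts, float)[keep]
    return _corr_map(sub, pred, labels_sub, "rt_correlation", zscore=False)


def rdm_correlation_map(data: VoxelDataset, perceptual_d) -> SearchlightMap:
    """Correlate each voxel's local neural RDM with perceptual dissimilarity.

    Dataset conditions must be the single-object (target-absent) displays in
    the same order as ``perceptual_d.objects``.  Per voxel, the neighborhood
    activation vectors (up to 27-dimensional; clipped at mask edges, with the
    in-neighborhood dimensionality recorded) give all pairwise Euclidean
    distances across objects, which are Pearson-correlated with the
    behavioral dissimilarities.
    """
    n_obj = len(perceptual_d.objects)
    if len(data.conditions) != n_obj:
        raise ValueError("dataset conditions must match perceptual_d objects")
    if n_obj < 3:
        raise ValueError("need at least 3 objects for an RDM correlation")
    mask = data.mask
    C = data.betas.shape[0]
    padded = np.pad(data.betas * mask[None], ((0, 0), (1, 1), (1, 1), (1, 1)))
    maskp = np.pad(mask, 1)
    win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3, 3), axis=(1, 2, 3))
    # win: (C, X, Y, Z, 3,3,3) -> in-mask voxels as (V, C, 27)
    vec = win[:, mask].reshape(C, -1, 27).transpose(1, 0, 2).copy()
    mwin = np.lib.stride_tricks.sliding_window_view(maskp, (3, 3, 3))
    nsize = mwin[mask].reshape(-1, 27).sum(axis=1)

    sq = (vec**2).sum(axis=2)  # (V, C)
    gram = vec @ vec.transpose(0, 2, 1)  # (V, C, C)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * gram
    iu = np.triu_indices(C, k=1)
    neural = np.sqrt(np.clip(d2[:, iu[0], iu[1]], 0.0, None))  # (V, P)
    behav = perceptual_d.condensed()

    x = neural - neural.mean(axis=1, keepdims=True)
    y = behav - behav.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y[None]).sum(axis=1) / np.sqrt((x**2).sum(axis=1) * (y**2).sum())
    values = np.full(data.grid_shape, np.nan)
    values[mask] = r
    sizes = np.full(data.grid_shape, np.nan)
    sizes[mask] = nsize
    return SearchlightMap(values=values, kind="rdm_correlation",
                          n_undefined=int(np.isnan(r).sum()),
                          neighborhood_size=sizes)


@dataclass
class Region:
    voxels: np.ndarray  # (n, 3) grid indices
    size: int
    centroid: np.ndarray


def define_region(slmap: SearchlightMap, threshold: float,
                  min_cluster: int = 1) -> list[Region]:
    """26-connected clusters of suprathreshold map voxels.

    Returns clusters of size >= ``min_cluster`` sorted by decreasing size;
    an empty list when nothing survives.  Centroids are in 0-based grid
    coordinates (apply an affine downstream for world coordinates).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    supra = np.nan_to_num(slmap.values, nan=-np.inf) > threshold
    labeled, n = ndimage.label(supra, structure=np.ones((3, 3, 3)))
    regions = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labeled == lab)
        if len(vox) >= min_cluster:
            regions.append(Region(voxels=vox, size=len(vox),
                                  centroid=vox.mean(axis=0)))
    regions.sort(key=lambda r: -r.size)
    return regions


@dataclass
class RegionCorrelation:
    r: float
    boot_sd: float
    boot_p: float
    n_boot: int


def region_mean_correlation(
    subject_betas: np.ndarray,
    mask: np.ndarray,
    region_voxels: np.ndarray,
    predictor: np.ndarray,
    labels,
    *,
    n_boot: int = 10_000,
    seed: int = 0,
    zscore: bool = True,
) -> RegionCorrelation:
    """Correlation between a region's mean activation and a predictor, with a
    participant-resampling bootstrap.

    ``subject_betas`` is (n_subjects, n_conditions, X, Y, Z).  The region
    mean activation is averaged over region voxels and subjects, z-scored by
    group, and Pearson-correlated with the group-z-scored predictor.  The
    bootstrap resamples subjects with replacement (default 10,000 draws); its
    SD is the error estimate and its one-sided p is the fraction of draws in
    which the observed trend (sign of r) is violated.  A single subject skips
    the bootstrap with a warning.
    """
    subject_betas = np.asarray(subject_betas, dtype=float)
    if subject_betas.ndim != 5:
        raise ValueError("subject_betas must be (subjects, conditions, X, Y, Z)")
    region_voxels = np.asarray(region_voxels)
    if len(region_voxels) == 0:
        raise ValueError("region is empty")
    ix, iy, iz = region_voxels[:, 0], region_voxels[:, 1], region_voxels[:, 2]
    per_subject = subject_betas[:, :, ix, iy, iz].mean(axis=2)  # (S, C)
    labels = np.asarray(labels)
    predictor = np.asarray(predictor, dtype=float)
    pred = zscore_by_group(predictor, labels) if zscore else predictor

    def corr(mean_act: np.ndarray) -> float:
        act = zscore_by_group(mean_act, labels) if zscore else mean_act
        return pearson(act, pred, context="region mean activation")

    r = corr(per_subject.mean(axis=0))
    n_sub = per_subject.shape[0]
    if n_sub < 2:
        warnings.warn("single subject: bootstrap skipped")
        return RegionCorrelation(r=r, boot_sd=float("nan"), boot_p=float("nan"),
                                 n_boot=0)
    rng = rng_for(seed, 77)
    draws = rng.integers(0, n_sub, size=(n_boot, n_sub))
    rs = np.empty(n_boot)
    for b in range(n_boot):
        rs[b] = corr(per_subject[draws[b]].mean(axis=0))
    violated = (rs <= 0) if r > 0 else (rs >= 0)
    return RegionCorrelation(r=r, boot_sd=float(rs.std(ddof=1)),
                             boot_p=float(violated.mean()), n_boot=n_boot)
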