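"""Segmentation evaluation metrics and volumetric group analysis.

Six measures compare an estimated mask R with a reference G:

* SI — volumetric similarity (mean overlap, Dice), percent;
* VO — volumetric union overlap (Jaccard), percent;
* VD — relative absolute volume difference, percent of the reference;
* AD / RMSD / MD — average / root-mean-square / maximum symmetric surface
  distance in mm (MD is the symmetric Hausdorff distance).

Surface distances pool both directions: every border voxel of R contributes
its minimum Euclidean distance (in physical mm) to the border of G and vice
versa; AD is the mean, RMSD the root mean square and MD the maximum of the
pooled distances. Border voxels are foreground voxels with at least one
face-adjacent background voxel.

Group analysis compares caudate volumes (voxel count times voxel volume)
between independent groups with the classical pooled-variance Student
t-test at alpha = 0.05; paired method comparisons use the paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import BinaryMask

ALPHA = 0.05


@dataclass(frozen=True)
class EvalReport:
    """The six validation measures for one structure."""

    SI: float
    VO: float
    VD: float
    AD: float
    RMSD: float
    MD: float
    voxel_dims: tuple[float, ...] = ()
    structure: str = ""


@dataclass(frozen=True)
class GroupTestResult:
    """Two-sample (or paired) t-test summary at alpha = 0.05."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    diff: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    df: float
    reject: bool


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.astype_bool()
    return np.asarray(mask).astype(bool)


def overlap_metrics(R, G) -> tuple[float, float, float]:
    """(SI, VO, VD): Dice and Jaccard in percent, plus the relative absolute
    volume difference in percent of the reference volume."""
    r = _as_bool(R)
    g = _as_bool(G)
    if r.shape != g.shape:
        raise ValueError("masks must share one shape")
    if not g.any():
        raise ValueError("reference mask is empty (VD undefined)")
    inter = float((r & g).sum())
    nr, ng = float(r.sum()), float(g.sum())
    si = 200.0 * inter / (nr + ng)
    vo = 100.0 * inter / float((r | g).sum())
    vd = 100.0 * abs(nr - ng) / ng
    return si, vo, vd


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background voxel (or lying on
    the array border)."""
    m = _as_bool(mask)
    struct = ndimage.generate_binary_structure(m.ndim, 1)
    inner = ndimage.binary_erosion(m, structure=struct)  # border_value=0
    return m & ~inner


def surface_distances(R, G, voxel_dims=None) -> tuple[float, float, float]:
    """(AD, RMSD, MD) in mm from pooled bidirectional border distances."""
    r = _as_bool(R)
    g = _as_bool(G)
    if r.shape != g.shape:
        raise ValueError("masks must share one shape")
    if not (r.any() and g.any()):
        raise ValueError("surface distances need two nonempty masks")
    if voxel_dims is None:
        voxel_dims = (
            R.spacing if isinstance(R, BinaryMask) and R.spacing else (1.0,) * r.ndim
        )
    dims = np.asarray(voxel_dims, dtype=float)
    br = np.argwhere(border_voxels(r)) * dims
    bg = np.argwhere(border_voxels(g)) * dims
    d_rg, _ = cKDTree(bg).query(br)
    d_gr, _ = cKDTree(br).query(bg)
    pooled = np.concatenate([d_rg, d_gr])
    return float(pooled.mean()), float(np.sqrt((pooled**2).mean())), float(pooled.max())


def evaluate_masks(R, G, voxel_dims=None, structure: str = "") -> EvalReport:
    si, vo, vd = overlap_metrics(R, G)
    ad, rmsd, md = surface_distances(R, G, voxel_dims)
    dims = tuple(voxel_dims) if voxel_dims is not None else ()
    return EvalReport(SI=si, VO=vo, VD=vd, AD=ad, RMSD=rmsd, MD=md, voxel_dims=dims, structure=structure)


def caudate_volume_mm3(mask, voxel_dims=None) -> float:
    """Structure volume: foreground voxel count times voxel volume."""
    m = _as_bool(mask)
    if voxel_dims is None:
        voxel_dims = (
            mask.spacing if isinstance(mask, BinaryMask) and mask.spacing else (1.0,) * m.ndim
        )
    return float(m.sum()) * float(np.prod(voxel_dims))


# ---------------------------------------------------------------------------
# Statistics


def group_volume_test(volumes_a, volumes_b) -> GroupTestResult:
    """Independent-samples pooled-variance Student t-test on group volumes,
    with the 95% CI of the mean difference."""
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se == 0:
        if diff == 0:
            raise ValueError("zero variance in both groups with equal means")
        t = np.inf if diff > 0 else -np.inf
        p = 0.0
    else:
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1.0 - ALPHA / 2.0, df)
    return GroupTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        diff=diff,
        t=float(t),
        p=float(p),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        df=float(df),
        reject=bool(p < ALPHA),
    )


def paired_method_test(scores_a, scores_b) -> GroupTestResult:
    """Paired Student t-test on per-subject score differences.

    Zero-variance differences (e.g. identical methods) are reported as a
    degenerate result with t = 0 and p = 1 rather than an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two equal-length samples of size >= 2")
    d = a - b
    df = d.size - 1
    sd = d.std(ddof=1)
    mean_d = float(d.mean())
    if sd == 0:
        if mean_d == 0:
            t, p, se = 0.0, 1.0, 0.0
        else:
            t, p, se = (np.inf if mean_d > 0 else -np.inf), 0.0, 0.0
    else:
        se = sd / np.sqrt(d.size)
        t = mean_d / se
        p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1.0 - ALPHA / 2.0, df)
    return GroupTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        diff=mean_d,
        t=float(t),
        p=float(p),
        ci_low=float(mean_d - tcrit * se),
        ci_high=float(mean_d + tcrit * se),
        df=float(df),
        reject=bool(p < ALPHA),
    )


def fit_volume_histogram(volumes, bins: int = 10):
    """Maximum-likelihood Gaussian fit (mean, sd with ddof=0) plus a binned
    histogram for plotting the group volume distributions."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 volumes")
    counts, edges = np.histogram(v, bins=bins)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),
        "hist_counts": counts,
        "hist_edges": edges,
    }
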