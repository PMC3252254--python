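"""Unary (region) energy: unsupervised seed-histogram potentials, supervised
correlogram-classifier potentials, and their sum.

The unsupervised term models the caudate from the graylevel histogram of the
caudate seeds on the slice at hand: P_u(cau | g) is the relative frequency
of graylevel g among seed pixels, clipped to [eps, 1-eps], and
P_u(back | g) = 1 - P_u(cau | g). Potentials are negative log probabilities,
so all costs are finite and bounded by -ln(eps).

The supervised term describes each pixel by a correlogram: a disk of radius
c*r around the pixel partitioned into n = c*r bins (c concentric rings, each
split into r equal angular sectors), summarized by the signed differences of
bin mean graylevels over all n(n-1)/2 bin pairs. A linear maximum-margin
classifier on these descriptors, with a Platt-style logistic calibration of
its margin, yields the caudate confidence fed to the -ln potentials.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .core import BinaryMask, SliceImage

__all__ = [
    "IntensityModel",
    "CorrelogramDescriptor",
    "TrainedPixelClassifier",
    "UnaryPotentials",
    "fit_seed_intensity_model",
    "unsupervised_potentials",
    "correlogram_bin_masks",
    "bin_mean_maps",
    "extract_correlogram",
    "dense_descriptors",
    "sample_training_pixels",
    "train_pixel_classifier",
    "supervised_potentials",
    "combine_unary",
]

N_GRAYLEVELS = 256


@dataclass(frozen=True)
class UnaryPotentials:
    """Per-pixel label costs U_p("cau") and U_p("back")."""

    cau: np.ndarray
    back: np.ndarray

    def __post_init__(self) -> None:
        if self.cau.shape != self.back.shape:
            raise ValueError("potential fields must share one shape")
        if not (np.all(np.isfinite(self.cau)) and np.all(np.isfinite(self.back))):
            raise ValueError("unary potentials must be finite")
        if self.cau.min() < 0 or self.back.min() < 0:
            raise ValueError("unary potentials must be non-negative")

    @property
    def shape(self):
        return self.cau.shape


@dataclass(frozen=True)
class IntensityModel:
    """P_u(cau | graylevel) from the caudate-seed frequency histogram."""

    p_cau: np.ndarray  # length-256 probability per integer graylevel
    eps: float

    def __post_init__(self) -> None:
        if self.p_cau.shape != (N_GRAYLEVELS,):
            raise ValueError("intensity model must cover 256 graylevels")
        if self.p_cau.min() < self.eps - 1e-12 or self.p_cau.max() > 1 - self.eps + 1e-12:
            raise ValueError("probabilities must lie in [eps, 1-eps]")


def fit_seed_intensity_model(
    img: SliceImage, cau_seeds: np.ndarray, eps: float = 1e-3, smooth_sd: float = 0.0
) -> IntensityModel:
    """Relative-frequency histogram of seed graylevels, clipped to [eps, 1-eps].

    ``cau_seeds`` is a boolean grid over the (0-255 normalized) slice.
    ``smooth_sd`` > 0 applies a Gaussian (Parzen) kernel of that width in
    graylevels before normalization — the usual density estimate when the
    seed set is too small to populate 256 bins.
    """
    seeds = np.asarray(cau_seeds, dtype=bool)
    if not seeds.any():
        raise ValueError("caudate seed set is empty")
    return intensity_model_from_levels(img.pixels[seeds], eps, smooth_sd)


def intensity_model_from_levels(
    levels: np.ndarray, eps: float = 1e-3, smooth_sd: float = 0.0
) -> IntensityModel:
    """Fit the seed-histogram model from a flat array of seed graylevels
    (e.g. pooled over all slices of a volume)."""
    levels = np.asarray(levels).ravel()
    if levels.size == 0:
        raise ValueError("no seed graylevels given")
    binned = np.clip(np.round(levels), 0, 255).astype(int)
    counts = np.bincount(binned, minlength=N_GRAYLEVELS).astype(float)
    if smooth_sd > 0:
        counts = ndimage.gaussian_filter1d(counts, smooth_sd, mode="constant")
    p = np.clip(counts / counts.sum(), eps, 1.0 - eps)
    return IntensityModel(p_cau=p, eps=eps)


def unsupervised_potentials(img: SliceImage, model: IntensityModel) -> UnaryPotentials:
    """UU_p("cau") = -ln P_u(cau | I_p), UU_p("back") = -ln(1 - P_u(cau | I_p))."""
    levels = np.clip(np.round(img.pixels), 0, 255).astype(int)
    p = model.p_cau[levels]
    return UnaryPotentials(cau=-np.log(p), back=-np.log(1.0 - p))


# ---------------------------------------------------------------------------
# Correlogram descriptors


@dataclass(frozen=True)
class CorrelogramDescriptor:
    """Signed bin-pair mean-graylevel differences around one pixel."""

    values: np.ndarray
    center: tuple[int, int]
    c: int
    r: int

    def __post_init__(self) -> None:
        n = self.c * self.r
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError("descriptor length must be n(n-1)/2 with n = c*r")


def correlogram_bin_masks(c: int, r: int) -> np.ndarray:
    """Boolean offset masks of the n = c*r bins of the correlogram disk.

    Ring k (1..c) covers Euclidean offset distances in ((k-1)*r, k*r], the
    center pixel belonging to ring 1; each ring is split into r equal angular
    sectors starting at angle 0. Returns an (n, 2R+1, 2R+1) array, R = c*r.
    """
    n = c * r
    if n < 2:
        raise ValueError("need at least 2 bins (c*r >= 2)")
    R = c * r
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    dist = np.hypot(yy, xx)
    inside = dist <= R
    ring = np.ceil(dist / r).astype(int)
    ring[dist == 0] = 1
    ang = np.mod(np.arctan2(yy, xx), 2 * np.pi)
    sector = np.minimum((ang / (2 * np.pi / r)).astype(int), r - 1)
    masks = np.zeros((n, 2 * R + 1, 2 * R + 1), dtype=bool)
    for k in range(1, c + 1):
        for s in range(r):
            masks[(k - 1) * r + s] = inside & (ring == k) & (sector == s)
    return masks


def bin_mean_maps(img: SliceImage, c: int, r: int) -> np.ndarray:
    """Mean graylevel of every correlogram bin at every pixel.

    Computed as normalized correlations with the bin masks under reflection
    padding; returns an (n, H, W) stack.
    """
    masks = correlogram_bin_masks(c, r)
    px = img.pixels
    out = np.empty((masks.shape[0],) + px.shape)
    for i, m in enumerate(masks):
        kern = m.astype(float) / m.sum()
        out[i] = ndimage.correlate(px, kern, mode="reflect")
    return out


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.array(list(itertools.combinations(range(n), 2)))
    return pairs[:, 0], pairs[:, 1]


def descriptor_from_bin_means(means: np.ndarray) -> np.ndarray:
    """Bin means (n, ...) -> pairwise differences (n(n-1)/2, ...),
    fixed lexicographic order, d_k = mean(b_i) - mean(b_j) for i < j."""
    i, j = _pair_index(means.shape[0])
    return means[i] - means[j]


def extract_correlogram(img: SliceImage, p: tuple[int, int], c: int, r: int) -> CorrelogramDescriptor:
    """Correlogram descriptor for a single pixel (reflection-padded)."""
    y, x = p
    if not (0 <= y < img.shape[0] and 0 <= x < img.shape[1]):
        raise ValueError(f"pixel {p} outside image of shape {img.shape}")
    means = bin_mean_maps(img, c, r)[:, y, x]
    return CorrelogramDescriptor(values=descriptor_from_bin_means(means), center=(y, x), c=c, r=r)


def dense_descriptors(img: SliceImage, c: int, r: int) -> np.ndarray:
    """Descriptors for all pixels: (H*W, n(n-1)/2), row-major pixel order."""
    means = bin_mean_maps(img, c, r)
    d = descriptor_from_bin_means(means)
    return d.reshape(d.shape[0], -1).T


# ---------------------------------------------------------------------------
# Training-pixel sampling


def sample_training_pixels(
    img: SliceImage,
    gt: BinaryMask | np.ndarray,
    seed: int,
    n_blocks: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced training sample: all ground-truth foreground pixels plus an
    equal number of background pixels, block-stratified over the slice.

    The background is tiled into ``n_blocks`` x ``n_blocks`` rectangular
    blocks and sampled proportionally to each block's background pixel count
    (largest-remainder apportionment), so every region contributes.

    Returns (pixel_indices, labels): indices of shape (m, 2) and labels in
    {1 foreground, 0 background}.
    """
    g = gt.astype_bool() if isinstance(gt, BinaryMask) else np.asarray(gt).astype(bool)
    if g.shape != img.shape:
        raise ValueError("ground truth shape must match the slice")
    fg = np.argwhere(g)
    if fg.shape[0] == 0:
        raise ValueError("ground truth is empty on this slice")
    n_fg = fg.shape[0]
    bg_mask = ~g
    if bg_mask.sum() < n_fg:
        raise ValueError("background smaller than foreground count")

    rng = np.random.default_rng(seed)
    H, W = g.shape
    row_edges = np.linspace(0, H, n_blocks + 1).astype(int)
    col_edges = np.linspace(0, W, n_blocks + 1).astype(int)
    blocks = []
    counts = []
    for bi in range(n_blocks):
        for bj in range(n_blocks):
            sub = np.zeros_like(bg_mask)
            sub[row_edges[bi] : row_edges[bi + 1], col_edges[bj] : col_edges[bj + 1]] = True
            pix = np.argwhere(bg_mask & sub)
            blocks.append(pix)
            counts.append(pix.shape[0])
    counts = np.array(counts, dtype=float)
    quota = n_fg * counts / counts.sum()
    take = np.floor(quota).astype(int)
    remainder = quota - take
    short = n_fg - take.sum()
    # Largest remainders get the leftover slots (ties by block order).
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        if take[idx] < counts[idx]:
            take[idx] += 1
    # If capacity truncation left a shortfall, fill from blocks with room.
    while take.sum() < n_fg:
        room = np.nonzero(take < counts)[0]
        take[room[0]] += 1

    bg_sel = []
    for pix, k in zip(blocks, take):
        if k > 0:
            sel = rng.choice(pix.shape[0], size=k, replace=False)
            bg_sel.append(pix[np.sort(sel)])
    bg = np.vstack(bg_sel)
    pixels = np.vstack([fg, bg])
    labels = np.concatenate([np.ones(n_fg, dtype=int), np.zeros(n_fg, dtype=int)])
    return pixels, labels


# ---------------------------------------------------------------------------
# Classifier


@dataclass(frozen=True)
class TrainedPixelClassifier:
    """Linear max-margin pixel classifier with logistic margin calibration.

    Operates on standardized correlogram descriptors; ``predict_proba``
    returns calibrated caudate probabilities strictly inside (0, 1)
    (clipped to [eps, 1-eps]).
    """

    weights: np.ndarray
    bias: float
    platt_a: float
    platt_b: float
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    c: int
    r: int
    eps: float = 1e-3

    def margins(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feat_mean) / self.feat_scale
        return Z @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(self.platt_a * self.margins(X) + self.platt_b, -500, 500)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.clip(p, self.eps, 1.0 - self.eps)

    def save(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "feat_mean": self.feat_mean.tolist(),
            "feat_scale": self.feat_scale.tolist(),
            "c": self.c,
            "r": self.r,
            "eps": self.eps,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPixelClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            bias=float(d["bias"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            feat_mean=np.array(d["feat_mean"]),
            feat_scale=np.array(d["feat_scale"]),
            c=int(d["c"]),
            r=int(d["r"]),
            eps=float(d["eps"]),
        )


def train_pixel_classifier(
    X: np.ndarray,
    y: np.ndarray,
    c: int,
    r: int,
    eps: float = 1e-3,
    svm_c: float = 1.0,
) -> TrainedPixelClassifier:
    """Fit the linear SVM (hinge loss, L2 regularization) and calibrate its
    margin to a probability with a held-in logistic (Platt) map."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be (n_samples, n_features)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    Z = (X - mean) / scale
    svm = LinearSVC(C=svm_c, loss="squared_hinge", dual=False, tol=1e-6, max_iter=20000)
    svm.fit(Z, y)
    w = svm.coef_.ravel()
    b = float(svm.intercept_[0])
    margins = Z @ w + b
    platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    platt.fit(margins.reshape(-1, 1), y)
    return TrainedPixelClassifier(
        weights=w,
        bias=b,
        platt_a=float(platt.coef_[0, 0]),
        platt_b=float(platt.intercept_[0]),
        feat_mean=mean,
        feat_scale=scale,
        c=c,
        r=r,
        eps=eps,
    )


def supervised_potentials(
    img: SliceImage, clf: TrainedPixelClassifier, c: int | None = None, r: int | None = None
) -> UnaryPotentials:
    """SU_p("cau") = -ln p_hat, SU_p("back") = -ln(1 - p_hat) from the
    calibrated classifier confidence at every pixel."""
    c = clf.c if c is None else c
    r = clf.r if r is None else r
    if (c, r) != (clf.c, clf.r):
        raise ValueError(f"classifier trained with (c, r)=({clf.c}, {clf.r}), asked for ({c}, {r})")
    X = dense_descriptors(img, c, r)
    if X.shape[1] != clf.weights.shape[0]:
        raise ValueError("descriptor length does not match classifier weights")
    p = clf.predict_proba(X).reshape(img.shape)
    return UnaryPotentials(cau=-np.log(p), back=-np.log(1.0 - p))


def combine_unary(uu: UnaryPotentials, su: UnaryPotentials) -> UnaryPotentials:
    """U_p(l) = UU_p(l) + SU_p(l)."""
    if uu.shape != su.shape:
        raise ValueError("unary fields must share one shape")
    return UnaryPotentials(cau=uu.cau + su.cau, back=uu.back + su.back)
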