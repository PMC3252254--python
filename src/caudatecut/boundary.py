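"""Boundary (pairwise) energy for the seeded cut.

Two similarity terms are mixed per neighbor pair {p, q}:

* N_{p,q} = exp(-(I_p - I_q)^2 / 2 sigma^2) / dist(p,q) — penalizes cutting
  between pixels of similar intensity;
* O_{p,q} = exp(-theta^2 / 2 beta^2) / dist(p,q) — penalizes cutting between
  pixels whose minimum-variation directions (Hessian eigenvectors at the
  smallest eigenvalue) are aligned; theta in [0, pi/2] is the orientation
  angle between the two eigenvectors (sign-free, mod pi).

sigma and beta adapt to the image: root-mean-square of the neighbor
intensity differences and pair angles respectively, floored at 1 graylevel
and pi/36 so flat slices cannot blow up the exponents.

Gaussian derivatives are taken at a per-pixel scale selected by maximizing
the local window entropy over a discrete scale grid, with optional Lindeberg
normalization s^ell (ell = 0 by default, i.e. no renormalization).

A multi-scale edgeness map J in [0, 1] — binary Canny maps averaged over a
grid of hysteresis thresholds, minimized over a grid of smoothing scales,
then Gaussian-smoothed — modulates the mix: by default the pair weight is
(1 - Jbar) * (alpha*N + (1-alpha)*O), so probable boundary pixels are less
regularized and the cut there is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters.rank import entropy as rank_entropy

from .core import SliceImage

SIGMA_FLOOR = 1.0          # graylevels
BETA_FLOOR = np.pi / 36.0  # radians

# Neighbor offsets (dy, dx) with dy > 0 or (dy == 0, dx > 0): each unordered
# pair appears once. 4-neighborhood uses the first two.
OFFSETS_4 = ((0, 1), (1, 0))
OFFSETS_8 = ((0, 1), (1, 0), (1, 1), (1, -1))


def neighbor_offsets(neighborhood: int):
    if neighborhood == 4:
        return OFFSETS_4
    if neighborhood == 8:
        return OFFSETS_8
    raise ValueError("neighborhood must be 4 or 8")


@dataclass(frozen=True)
class ScaleMap:
    """Per-pixel Gaussian scale selected from a discrete grid."""

    scales: np.ndarray
    grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.all(np.isin(np.unique(self.scales), np.asarray(self.grid))):
            raise ValueError("scale map contains values outside the grid")


@dataclass(frozen=True)
class DerivativeField:
    """Gaussian derivative responses and Hessian orientation per pixel."""

    ix: np.ndarray
    iy: np.ndarray
    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray
    # Unit eigenvector of the Hessian at the smallest eigenvalue (minimum
    # variation direction), sign-canonicalized to the upper half-plane.
    orient_y: np.ndarray
    orient_x: np.ndarray


@dataclass(frozen=True)
class EdgenessMap:
    """Per-pixel edge probability J* in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("edgeness must lie in [0, 1]")


@dataclass(frozen=True)
class BoundaryPotentials:
    """Symmetric non-negative pair weights B_{p,q} on a pixel grid.

    ``weights[off]`` holds, for offset (dy, dx), the weights of pairs
    (p, p+off); entry [y, x] is the pair ((y, x), (y+dy, x+dx)).
    """

    shape: tuple[int, int]
    weights: dict[tuple[int, int], np.ndarray]
    alpha: float
    sigma: float
    beta: float

    def neighbor_sum(self) -> np.ndarray:
        """Sum of B_{p,q} over the neighbors q of each pixel p."""
        total = np.zeros(self.shape)
        for (dy, dx), w in self.weights.items():
            H, W = self.shape
            ys = slice(max(0, -dy), H - max(0, dy))
            xs = slice(max(0, -dx), W - max(0, dx))
            ys2 = slice(max(0, dy), H - max(0, -dy))
            xs2 = slice(max(0, dx), W - max(0, -dx))
            total[ys, xs] += w
            total[ys2, xs2] += w
        return total


# ---------------------------------------------------------------------------
# Scale selection


def window_entropy(img: SliceImage, side: int) -> np.ndarray:
    """Shannon entropy (bits) of the graylevel distribution in a side x side
    window around each pixel. side == 1 gives zero everywhere."""
    if side <= 1:
        return np.zeros(img.shape)
    u8 = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    return rank_entropy(u8, np.ones((side, side), dtype=np.uint8))


def _window_side(s: float) -> int:
    return max(1, int(np.floor(s + 0.5)))  # round half up, deterministic


def select_scales(img: SliceImage, grid) -> ScaleMap:
    """Per-pixel scale by entropy maximization over the grid.

    The window entropy H(R_p(s)) is evaluated for window sides round(s); the
    selected scale is the grid member attaining the largest interior local
    maximum of H along the (unique-window) scale axis. Ties and pixels with
    no interior local maximum fall back to the smallest qualifying scale
    (least smoothing preserves thin structures).
    """
    grid = tuple(float(s) for s in grid)
    if len(grid) == 0:
        raise ValueError("scale grid must be non-empty")
    sides = [_window_side(s) for s in grid]
    uniq_sides = sorted(set(sides))
    ent = {side: window_entropy(img, side) for side in uniq_sides}
    # Smallest grid scale per unique window side.
    side_to_scale = {}
    for s, side in zip(grid, sides):
        side_to_scale.setdefault(side, s)

    H = np.stack([ent[s] for s in uniq_sides], axis=0)  # (k, H, W)
    k = H.shape[0]
    best_scale = np.full(img.shape, grid[0])
    if k >= 3:
        interior = H[1:-1]
        is_max = (interior >= H[:-2]) & (interior >= H[2:]) & (
            (interior > H[:-2]) | (interior > H[2:])
        )
        masked = np.where(is_max, interior, -np.inf)
        any_max = is_max.any(axis=0)
        # Largest local maximum; np.argmax takes the first (smallest scale) on ties.
        best_idx = np.argmax(masked, axis=0) + 1
        scale_of_side = np.array([side_to_scale[s] for s in uniq_sides])
        best_scale = np.where(any_max, scale_of_side[best_idx], grid[0])
    return ScaleMap(scales=best_scale, grid=grid)


# ---------------------------------------------------------------------------
# Gaussian derivatives and Hessian orientation


def gaussian_derivatives(img: SliceImage, scales: ScaleMap, ell: float = 0.0) -> DerivativeField:
    """First/second Gaussian-derivative responses at each pixel's selected
    scale, multiplied by the Lindeberg factor s^ell, plus the Hessian
    minimum-eigenvalue eigenvector (smallest-variation direction).

    Axes: y = rows, x = columns; derivative order (y, x) in ndimage terms.
    """
    px = img.pixels
    out = {name: np.zeros(px.shape) for name in ("ix", "iy", "ixx", "ixy", "iyy")}
    for s in np.unique(scales.scales):
        sel = scales.scales == s
        f = float(s) ** ell
        resp = {
            "ix": ndimage.gaussian_filter(px, s, order=(0, 1)),
            "iy": ndimage.gaussian_filter(px, s, order=(1, 0)),
            "ixx": ndimage.gaussian_filter(px, s, order=(0, 2)),
            "ixy": ndimage.gaussian_filter(px, s, order=(1, 1)),
            "iyy": ndimage.gaussian_filter(px, s, order=(2, 0)),
        }
        for name in out:
            out[name][sel] = f * resp[name][sel]

    oy, ox = _min_eigvec(out["ixx"], out["ixy"], out["iyy"])
    return DerivativeField(orient_y=oy, orient_x=ox, **out)


def _min_eigvec(ixx: np.ndarray, ixy: np.ndarray, iyy: np.ndarray):
    """Unit eigenvector of [[ixx, ixy], [ixy, iyy]] at the smallest (signed)
    eigenvalue, canonicalized to the upper half-plane."""
    half_tr = 0.5 * (ixx + iyy)
    root = np.hypot(0.5 * (ixx - iyy), ixy)
    lam = half_tr - root  # smallest eigenvalue
    # (H - lam I) v = 0 -> v proportional to (ixy, lam - ixx) or (lam - iyy, ixy).
    vx1, vy1 = ixy, lam - ixx
    vx2, vy2 = lam - iyy, ixy
    use2 = np.hypot(vx1, vy1) < np.hypot(vx2, vy2)
    vx = np.where(use2, vx2, vx1)
    vy = np.where(use2, vy2, vy1)
    norm = np.hypot(vx, vy)
    degenerate = norm < 1e-12  # isotropic Hessian: any direction; pick +x
    vx = np.where(degenerate, 1.0, vx)
    vy = np.where(degenerate, 0.0, vy)
    norm = np.hypot(vx, vy)
    vx, vy = vx / norm, vy / norm
    flip = (vy < 0) | ((vy == 0) & (vx < 0))
    return np.where(flip, -vy, vy), np.where(flip, -vx, vx)


def orientation_angle(v1: tuple[float, float], v2: tuple[float, float]) -> float:
    """Angle in [0, pi/2] between two orientations (sign-free, mod pi)."""
    dot = abs(v1[0] * v2[0] + v1[1] * v2[1])
    n1 = np.hypot(*v1)
    n2 = np.hypot(*v2)
    return float(np.arccos(np.clip(dot / (n1 * n2), 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Scalar pair terms (reference forms; the dense builder vectorizes them)


def intensity_boundary(ip: float, iq: float, sigma: float, dist: float = 1.0) -> float:
    """N_{p,q} = exp(-(I_p - I_q)^2 / 2 sigma^2) / dist(p, q)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-((ip - iq) ** 2) / (2.0 * sigma**2)) / dist)


def orientation_boundary(theta: float, beta: float, dist: float = 1.0) -> float:
    """O_{p,q} = exp(-theta^2 / 2 beta^2) / dist(p, q), theta in [0, pi/2]."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(np.exp(-(theta**2) / (2.0 * beta**2)) / dist)


# ---------------------------------------------------------------------------
# Dense pair fields


def _pair_views(arr: np.ndarray, off: tuple[int, int]):
    """Views of arr at p and at p+off for every valid pair."""
    dy, dx = off
    H, W = arr.shape
    ys = slice(0, H - dy)
    xs = slice(max(0, -dx), W - max(0, dx))
    ys_q = slice(dy, H)
    xs_q = slice(max(0, dx), W - max(0, -dx))
    return arr[ys, xs], arr[ys_q, xs_q]


def _pair_angles(field: DerivativeField, off: tuple[int, int]) -> np.ndarray:
    oy_p, oy_q = _pair_views(field.orient_y, off)
    ox_p, ox_q = _pair_views(field.orient_x, off)
    dot = np.abs(oy_p * oy_q + ox_p * ox_q)
    return np.arccos(np.clip(dot, 0.0, 1.0))


def estimate_sigma_beta(
    img: SliceImage,
    field: DerivativeField,
    neighborhood: int = 4,
    sigma_estimator: str = "rms",
) -> tuple[float, float]:
    """Adapt sigma and beta to the slice at hand.

    sigma: "rms" uses the root-mean-square neighbor intensity difference
    (floor 1 graylevel); "robust" uses 1.4826 * median absolute difference,
    which estimates the noise scale without being inflated by strong tissue
    edges. beta = RMS pair orientation angle (floor pi/36).
    """
    abs_int = []
    sq_ang = []
    for off in neighbor_offsets(neighborhood):
        ip, iq = _pair_views(img.pixels, off)
        abs_int.append(np.abs(ip - iq).ravel())
        sq_ang.append((_pair_angles(field, off) ** 2).ravel())
    diffs = np.concatenate(abs_int)
    if sigma_estimator == "rms":
        sigma = float(np.sqrt((diffs**2).mean()))
    elif sigma_estimator == "robust":
        sigma = 1.4826 * float(np.median(diffs))
    else:
        raise ValueError(f"unknown sigma estimator {sigma_estimator!r}")
    beta = float(np.sqrt(np.concatenate(sq_ang).mean()))
    return max(sigma, SIGMA_FLOOR), max(beta, BETA_FLOOR)


def edgeness_map(
    img: SliceImage,
    gamma_grid,
    scale_grid,
    smooth_sd: float = 1.0,
) -> EdgenessMap:
    """Multi-scale Canny edgeness: for each smoothing scale s_j average the
    binary Canny maps over the threshold grid gamma_k, take the minimum over
    scales, then Gaussian-smooth. gamma_k is the high hysteresis threshold as
    a fraction of the maximum smoothed-gradient magnitude at that scale
    (the classical Canny convention); low threshold = 0.4 * gamma_k.
    """
    gamma_grid = tuple(gamma_grid)
    scale_grid = tuple(scale_grid)
    if not gamma_grid or not scale_grid:
        raise ValueError("threshold and scale grids must be non-empty")
    px = img.pixels / 255.0
    per_scale = np.empty((len(scale_grid),) + img.shape)
    for j, s in enumerate(scale_grid):
        gx = ndimage.gaussian_filter(px, s, order=(0, 1))
        gy = ndimage.gaussian_filter(px, s, order=(1, 0))
        gmax = float(np.hypot(gx, gy).max())
        acc = np.zeros(img.shape)
        if gmax > 0:
            for g in gamma_grid:
                acc += canny(
                    px, sigma=s, low_threshold=0.4 * g * gmax, high_threshold=g * gmax
                )
        per_scale[j] = acc / len(gamma_grid)
    j_star = per_scale.min(axis=0)
    if smooth_sd > 0:
        j_star = ndimage.gaussian_filter(j_star, smooth_sd)
    return EdgenessMap(values=np.clip(j_star, 0.0, 1.0))


def boundary_potentials(
    img: SliceImage,
    field: DerivativeField,
    edges: EdgenessMap | None,
    alpha: float,
    sigma: float,
    beta: float,
    neighborhood: int = 4,
    mode: str = "damp-J",
    distance_exponent: int = 1,
) -> BoundaryPotentials:
    """Assemble B_{p,q} for every neighbor pair.

    mode "damp-J" (default): B = (1 - Jbar) (alpha N + (1-alpha) O), Jbar the
    mean edgeness of the pair — probable boundaries are less regularized.
    mode "multiply-J": B = Jbar (alpha N + (1-alpha) O) (the literal reading).
    mode "off": B = alpha N + (1-alpha) O.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if mode not in ("damp-J", "multiply-J", "off"):
        raise ValueError(f"unknown boundary mode {mode!r}")
    weights = {}
    for off in neighbor_offsets(neighborhood):
        dist = float(np.hypot(*off)) ** distance_exponent
        ip, iq = _pair_views(img.pixels, off)
        n_term = np.exp(-((ip - iq) ** 2) / (2.0 * sigma**2)) / dist
        theta = _pair_angles(field, off)
        o_term = np.exp(-(theta**2) / (2.0 * beta**2)) / dist
        w = alpha * n_term + (1.0 - alpha) * o_term
        if mode != "off":
            if edges is None:
                raise ValueError(f"mode {mode!r} needs an edgeness map")
            jp, jq = _pair_views(edges.values, off)
            jbar = 0.5 * (jp + jq)
            w = (1.0 - jbar) * w if mode == "damp-J" else jbar * w
        weights[off] = w
    return BoundaryPotentials(
        shape=img.shape, weights=weights, alpha=alpha, sigma=sigma, beta=beta
    )
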