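"""Synthetic caudate-like phantoms with ground truth and perturbed priors.

Each phantom subject is a small grayscale volume holding two bean-shaped
foreground structures (left/right "caudates"): a rounded head tapering into
an elongated, slightly curved body across slices — the head/body transition
being the classically hard region for atlas-seeded segmentation. The
background is a two-level piecewise-smooth gray-matter/white-matter texture
with the foreground only mildly brighter than GM (the low-contrast regime),
plus additive Gaussian noise and a multiplicative low-frequency bias field.
A dark CSF band medial to each bean emulates the lateral ventricle — the
contextual structure that borders the caudate in vivo and that the
correlogram-based supervised energy relies on.

The prior mask emulates the output of an external atlas pipeline: the
ground truth translated by a random in-plane offset and corrupted by random
boundary-voxel flips. It is guaranteed nonempty and overlapping the ground
truth, so erosion-based seeding can succeed.

All generation is deterministic given (params, seed); cohorts derive one
independent RNG stream per subject from (master seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, VolumeImage


@dataclass(frozen=True)
class PhantomParams:
    """Study conditions for phantom generation.

    Graylevels are arbitrary units; volumes in mm^3. Defaults encode a
    caudate-like regime: ~4800 +/- 600 mm^3 structures (per side), contrast
    of 20 graylevels over GM with noise sd 8, 10% bias-field amplitude, and
    an atlas-like prior jittered by up to 2 px with 20% boundary flips.
    """

    image_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fg_mean: float = 120.0
    bg_gm_mean: float = 100.0
    bg_wm_mean: float = 150.0
    csf_mean: float = 40.0
    noise_sd: float = 8.0
    bias_amplitude: float = 0.10
    target_volume_mm3: float = 4800.0
    volume_sd_mm3: float = 600.0
    prior_jitter_px: int = 2
    prior_boundary_noise: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sd > 0 and abs(self.fg_mean - self.bg_gm_mean) < self.noise_sd:
            raise ValueError("foreground/GM contrast must be at least one noise sd")
        if self.target_volume_mm3 <= 0 or self.volume_sd_mm3 < 0:
            raise ValueError("volume distribution must be positive")
        if not 0.0 <= self.prior_boundary_noise <= 1.0:
            raise ValueError("boundary noise is a probability")


@dataclass(frozen=True)
class PhantomSubject:
    """One synthetic subject: volume, per-side ground truth and priors."""

    volume: VolumeImage
    gt_left: BinaryMask
    gt_right: BinaryMask
    prior_left: BinaryMask
    prior_right: BinaryMask
    group: str
    rng_seed: int

    def gt(self, side: str) -> BinaryMask:
        return self.gt_left if side == "left" else self.gt_right

    def prior(self, side: str) -> BinaryMask:
        return self.prior_left if side == "left" else self.prior_right


# ---------------------------------------------------------------------------
# Bean geometry

_HEAD_R_MM = 9.0       # base head radius before volume scaling
_BODY_SAMPLES = 25


def _bean_field(shape, voxel_dims, x_frac: float, x_sign: float) -> np.ndarray:
    """Normalized distance field of one bean (head sphere + tapered curved
    body tube): mask = field <= u for a volume scale factor u."""
    ii, jj, kk = np.indices(shape)
    y = (ii + 0.5) * voxel_dims[0]
    x = (jj + 0.5) * voxel_dims[1]
    z = (kk + 0.5) * voxel_dims[2]
    fov = tuple(s * d for s, d in zip(shape, voxel_dims))

    y0, x0, z0 = 0.40 * fov[0], x_frac * fov[1], 0.28 * fov[2]
    f = np.sqrt((y - y0) ** 2 + (x - x0) ** 2 + (z - z0) ** 2) / _HEAD_R_MM
    for t in np.linspace(0.0, 1.0, _BODY_SAMPLES):
        cy = y0 + 0.10 * fov[0] * t * t          # body bends away from the head
        cx = x0 + x_sign * 0.05 * fov[1] * t
        cz = z0 + 0.55 * fov[2] * t              # elongation across slices
        radius = _HEAD_R_MM * (1.0 - 0.45 * t)   # taper
        d = np.sqrt((y - cy) ** 2 + (x - cx) ** 2 + (z - cz) ** 2) / radius
        f = np.minimum(f, d)
    return f


def _mask_at_volume(fieldv: np.ndarray, target_mm3: float, voxel_mm3: float) -> np.ndarray:
    """Bisection on the radius scale u so the mask volume matches the target."""
    lo, hi = 0.05, 1.8
    if (fieldv <= hi).sum() * voxel_mm3 < target_mm3:
        raise ValueError("image too small to contain the target volume")
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if (fieldv <= mid).sum() * voxel_mm3 < target_mm3:
            lo = mid
        else:
            hi = mid
    return fieldv <= hi


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_phantom(
    params: PhantomParams,
    seed: int,
    group: str = "control",
    left_mean_mm3: float | None = None,
    right_mean_mm3: float | None = None,
) -> PhantomSubject:
    """Generate one deterministic phantom subject.

    Per-side ground-truth volumes are drawn from a Gaussian around the
    (optionally overridden) group means; the image is composed as
    piecewise-smooth background + exact foreground graylevel, then the bias
    field and noise are applied.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = params.image_shape
    vd = params.voxel_dims
    voxel_mm3 = float(np.prod(vd))

    targets = {}
    for side, mean in (("right", right_mean_mm3), ("left", left_mean_mm3)):
        mu = params.target_volume_mm3 if mean is None else mean
        targets[side] = max(500.0, rng.normal(mu, params.volume_sd_mm3))

    gt = {}
    for side, x_frac, x_sign in (("right", 0.70, 1.0), ("left", 0.30, -1.0)):
        fieldv = _bean_field(shape, vd, x_frac, x_sign)
        gt[side] = _mask_at_volume(fieldv, targets[side], voxel_mm3)

    wm_region = _smooth_field(rng, shape, 3.0) > 0.0
    bg = np.where(wm_region, params.bg_wm_mean, params.bg_gm_mean)
    bg = ndimage.gaussian_filter(bg.astype(float), 1.0)
    img = bg.copy()
    # Lateral-ventricle-like CSF bands medial to each bean: the contextual
    # neighbor of the caudate in vivo.
    fg_all = gt["right"] | gt["left"]
    for side, x_frac, x_sign in (("right", 0.70, 1.0), ("left", 0.30, -1.0)):
        vent = _bean_field(
            shape, vd, x_frac - x_sign * 0.17, x_sign
        ) <= 0.75
        img[vent & ~fg_all] = params.csf_mean
    img[fg_all] = params.fg_mean
    if params.bias_amplitude > 0:
        img = img * (1.0 + params.bias_amplitude * _smooth_field(rng, shape, 8.0))
    if params.noise_sd > 0:
        img = img + params.noise_sd * rng.standard_normal(shape)

    priors = {}
    for side in ("right", "left"):
        priors[side] = make_prior_mask(
            BinaryMask(gt[side].astype(np.uint8), vd),
            params.prior_jitter_px,
            params.prior_boundary_noise,
            seed=int(rng.integers(2**31 - 1)),
        )

    return PhantomSubject(
        volume=VolumeImage(img, vd),
        gt_left=BinaryMask(gt["left"].astype(np.uint8), vd),
        gt_right=BinaryMask(gt["right"].astype(np.uint8), vd),
        prior_left=priors["left"],
        prior_right=priors["right"],
        group=group,
        rng_seed=seed,
    )


def make_prior_mask(
    gt: BinaryMask,
    jitter_px: int,
    boundary_noise: float,
    seed: int,
    max_retries: int = 10,
) -> BinaryMask:
    """Atlas-like prior: ground truth shifted by a random in-plane offset of
    Euclidean magnitude <= jitter_px, with boundary voxels flipped with the
    given probability. Guaranteed nonempty and intersecting the truth."""
    g = gt.astype_bool()
    if not g.any():
        raise ValueError("ground-truth mask is empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(max_retries):
        if jitter_px > 0:
            while True:
                dy, dx = rng.integers(-jitter_px, jitter_px + 1, size=2)
                if dy * dy + dx * dx <= jitter_px * jitter_px:
                    break
        else:
            dy = dx = 0
        shifted = _shift2d(g, int(dy), int(dx))
        if boundary_noise > 0:
            struct = ndimage.generate_binary_structure(g.ndim, 1)  # face connectivity
            border = ndimage.binary_dilation(shifted, struct) & ~ndimage.binary_erosion(
                shifted, struct
            )
            flips = border & (rng.random(g.shape) < boundary_noise)
            shifted = shifted ^ flips
        if shifted.any() and (shifted & g).any():
            return BinaryMask(shifted.astype(np.uint8), gt.spacing)
    raise ValueError("could not generate a nonempty overlapping prior")


def _shift2d(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """In-plane integer translation with zero fill (rows, cols axes)."""
    out = np.zeros_like(mask)
    src_y = slice(max(0, -dy), mask.shape[0] - max(0, dy))
    src_x = slice(max(0, -dx), mask.shape[1] - max(0, dx))
    dst_y = slice(max(0, dy), mask.shape[0] - max(0, -dy))
    dst_x = slice(max(0, dx), mask.shape[1] - max(0, -dx))
    out[dst_y, dst_x, ...] = mask[src_y, src_x, ...]
    return out


def make_cohort(
    n_control: int,
    n_case: int,
    right_volume_deficit: float,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> list[PhantomSubject]:
    """Two-group cohort with a controllable right-caudate volume effect.

    Case subjects' right-caudate target mean is reduced by the deficit
    fraction and the left by half of it (a sub-threshold effect), mirroring
    the right-lateralized volume reduction the group analysis is meant to
    detect. Deterministic per (params, seed); each subject has its own
    stream derived from (seed, subject index).
    """
    if n_control < 2 or n_case < 2:
        raise ValueError("each group needs at least 2 subjects")
    if not 0.0 <= right_volume_deficit <= 0.5:
        raise ValueError("deficit must lie in [0, 0.5]")
    params = params or PhantomParams()
    base = params.target_volume_mm3
    subjects = []
    for i in range(n_control + n_case):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31 - 1))
        if i < n_control:
            subjects.append(make_phantom(params, child, group="control"))
        else:
            subjects.append(
                make_phantom(
                    params,
                    child,
                    group="case",
                    right_mean_mm3=base * (1.0 - right_volume_deficit),
                    left_mean_mm3=base * (1.0 - right_volume_deficit / 2.0),
                )
            )
    return subjects
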