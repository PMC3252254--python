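"""End-to-end orchestration: classifier training over phantom subjects,
leave-one-subject-out evaluation, and the cohort analysis chain
(generate -> train -> segment -> evaluate -> group test).

Training follows the balanced-sampling protocol: per slice, every
ground-truth caudate pixel plus an equal number of block-stratified
background pixels; descriptors are extracted from the preprocessed slice
exactly as at segmentation time. The classifier applied to a subject is
trained on all other subjects (leave-one-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, CaudateCutConfig, preprocess_slice
from .graphcut import segment_volume
from .metrics import caudate_volume_mm3, evaluate_masks, group_volume_test
from .phantoms import PhantomSubject, make_cohort, PhantomParams
from .unary import (
    TrainedPixelClassifier,
    dense_descriptors,
    sample_training_pixels,
    train_pixel_classifier,
)

SIDES = ("left", "right")


def _canonical_slice(sl, flip: bool):
    """Mirror a slice left-right so both hemispheres share one orientation.

    The correlogram's angular sectors are orientation specific, and the two
    caudates are mirror images of each other: pooling them without a
    canonical orientation cancels the lateralized context (the ventricle
    lies medially). The right-side orientation is the canonical one.
    """
    if not flip:
        return sl
    from .core import SliceImage

    return SliceImage(sl.pixels[:, ::-1].copy(), sl.spacing, sl.slice_index)


def subject_training_data(
    subject: PhantomSubject, config: CaudateCutConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Descriptors and labels for all usable slices of one subject.

    Slices are preprocessed as at segmentation time; both caudate sides
    contribute, the left mirrored into the canonical (right) orientation.
    Deterministic per (subject, seed).
    """
    X_parts, y_parts = [], []
    vol = subject.volume
    for k in range(vol.n_slices):
        sl = preprocess_slice(vol.get_slice(k), config)
        for s_i, side in enumerate(SIDES):
            gt2d = subject.gt(side).astype_bool()[:, :, k]
            if not gt2d.any():
                continue
            flip = side == "left"
            sl_c = _canonical_slice(sl, flip)
            gt_c = gt2d[:, ::-1] if flip else gt2d
            feats = dense_descriptors(sl_c, config.c, config.r)
            pix, lab = sample_training_pixels(sl_c, gt_c, seed=seed + 977 * k + s_i)
            flat = pix[:, 0] * sl_c.shape[1] + pix[:, 1]
            X_parts.append(feats[flat])
            y_parts.append(lab)
    if not X_parts:
        return np.empty((0, 0)), np.empty(0, dtype=int)
    return np.vstack(X_parts), np.concatenate(y_parts)


def train_from_subjects(
    subjects: list[PhantomSubject],
    config: CaudateCutConfig,
    seed: int = 0,
    cache: dict | None = None,
) -> TrainedPixelClassifier:
    """Train one classifier from the pooled samples of the given subjects."""
    X_parts, y_parts = [], []
    for i, s in enumerate(subjects):
        key = id(s)
        if cache is not None and key in cache:
            Xi, yi = cache[key]
        else:
            Xi, yi = subject_training_data(s, config, seed=seed + 7919 * s.rng_seed)
            if cache is not None:
                cache[key] = (Xi, yi)
        if Xi.size:
            X_parts.append(Xi)
            y_parts.append(yi)
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    return train_pixel_classifier(X, y, config.c, config.r, eps=config.epsilon_prob)


def segment_subject_side(
    subject: PhantomSubject,
    side: str,
    clf,
    config: CaudateCutConfig,
) -> BinaryMask:
    """Segment one caudate side of a subject, mirroring the left hemisphere
    into canonical orientation for the classifier and mirroring back."""
    from .core import VolumeImage

    vol = subject.volume
    prior = subject.prior(side)
    flip = side == "left"
    if flip:
        vol = VolumeImage(vol.data[:, ::-1, :].copy(), vol.voxel_dims)
        prior = BinaryMask(prior.values[:, ::-1, :].copy(), prior.spacing)
    mask, _ = segment_volume(vol, prior, clf, config)
    if flip:
        mask = BinaryMask(mask.values[:, ::-1, :].copy(), mask.spacing)
    return mask


@dataclass
class SubjectEvaluation:
    subject: int
    group: str
    side: str
    report_cut: object
    report_prior: object
    volume_cut: float
    volume_gt: float


def segment_cohort(
    subjects: list[PhantomSubject],
    config: CaudateCutConfig | None = None,
    seed: int = 0,
    leave_one_out: bool = True,
) -> list[SubjectEvaluation]:
    """Leave-one-subject-out training + segmentation + evaluation.

    For each subject and side, the volume is segmented against that side's
    prior with a classifier trained on every other subject; SI & co. are
    computed against the ground truth and against the prior baseline.
    """
    config = config or CaudateCutConfig.phantom_preset()
    cache: dict = {}
    evals: list[SubjectEvaluation] = []
    shared_clf = None
    if not leave_one_out:
        shared_clf = train_from_subjects(subjects, config, seed=seed, cache=cache)
    for i, subj in enumerate(subjects):
        if leave_one_out:
            others = [s for j, s in enumerate(subjects) if j != i]
            clf = train_from_subjects(others, config, seed=seed, cache=cache)
        else:
            clf = shared_clf
        for side in SIDES:
            mask = segment_subject_side(subj, side, clf, config)
            gt = subj.gt(side)
            evals.append(
                SubjectEvaluation(
                    subject=i,
                    group=subj.group,
                    side=side,
                    report_cut=evaluate_masks(mask, gt, subj.volume.voxel_dims),
                    report_prior=evaluate_masks(subj.prior(side), gt, subj.volume.voxel_dims),
                    volume_cut=caudate_volume_mm3(mask),
                    volume_gt=caudate_volume_mm3(gt),
                )
            )
    return evals


def cohort_group_analysis(
    evals: list[SubjectEvaluation], side: str, use: str = "cut"
) -> "object":
    """Independent-samples t-test of control vs case volumes on one side."""
    attr = "volume_cut" if use == "cut" else "volume_gt"
    ctrl = [getattr(e, attr) for e in evals if e.side == side and e.group == "control"]
    case = [getattr(e, attr) for e in evals if e.side == side and e.group == "case"]
    return group_volume_test(ctrl, case)


def gt_volume_analysis(
    n_control: int,
    n_case: int,
    deficit: float,
    params: PhantomParams | None = None,
    seed: int = 0,
):
    """Group analysis on ground-truth volumes only (no segmentation):
    generates the cohort and t-tests control vs case volumes per side."""
    subjects = make_cohort(n_control, n_case, deficit, params, seed)
    out = {}
    for side in SIDES:
        ctrl = [caudate_volume_mm3(s.gt(side)) for s in subjects if s.group == "control"]
        case = [caudate_volume_mm3(s.gt(side)) for s in subjects if s.group == "case"]
        out[side] = group_volume_test(ctrl, case)
    return out
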