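"""Smoothing, brain-mean normalization, ROI definition and sample assembly.

The preprocessing chain mirrors how the acute and chronic stacks are
prepared before voxel-wise learning: every channel is smoothed with a 3x3
unity (box) filter to damp mis-registration effects, intensities are
normalized to the mean over a brain mask (making features insensitive to
scanner gain), the lesion ROI is the supra-threshold region of the chronic
T2WI, and the "normal" ROI is that region mirrored across the brain
midline into contralateral tissue.  One training sample per ROI voxel is
assembled: 4 acute intensities as features, the normalized chronic T2WI
intensity as the continuous target, and the ROI membership as a binary
label kept for ROC-style evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import CHANNELS, CHRONIC, SubjectStudy

log = logging.getLogger(__name__)


def smooth_image(image: np.ndarray) -> np.ndarray:
    """3x3 unity-filter (box mean) of one 2D slice, reflected borders.

    Each interior voxel becomes the mean of its 3x3 neighbourhood; at the
    borders the image is padded by edge reflection so brain-edge voxels are
    not darkened the way zero padding would.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"image must be 2D and at least 3x3, got shape {image.shape}")
    out = ndimage.uniform_filter(image, size=3, mode="reflect")
    # the separable accumulation can leave ~1e-17 negatives on zero background
    return np.clip(out, 0.0, None)


def smooth_study(study: SubjectStudy, channels: tuple[str, ...] | None = None) -> SubjectStudy:
    """Smooth every slice of every channel (chronic target included)."""
    channels = channels or study.channels
    images = {
        ch: (
            np.stack([smooth_image(sl) for sl in study.images[ch]])
            if ch in channels
            else study.images[ch].copy()
        )
        for ch in study.channels
    }
    return SubjectStudy(study.subject_id, images, study.class_map, dict(study.provenance))


def brain_mask(study: SubjectStudy, threshold_fraction: float = 0.10) -> np.ndarray:
    """Brain support from the acute T2WI of a (smoothed) study: voxels at or
    above ``threshold_fraction`` of the slice stack's maximum.

    Apply :func:`smooth_study` first; the mask itself does not re-smooth, so
    on a clean phantom it equals the nonzero support exactly.
    """
    if "t2" not in study.images:
        raise ValueError("study has no acute T2WI channel")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    t2 = study.images["t2"]
    mask = t2 >= threshold_fraction * t2.max()
    if not mask.any():
        raise ValueError("brain mask is empty")
    return mask


def normalize_study(study: SubjectStudy, mask: np.ndarray) -> SubjectStudy:
    """Divide each channel by its in-mask mean over the whole study.

    One mean per channel per subject (not per slice), so inter-slice
    contrast is preserved; afterwards every channel has in-mask mean 1, and
    the result is invariant to any positive gain applied beforehand.
    """
    if mask.shape != study.shape:
        raise ValueError(f"mask shape {mask.shape} != study shape {study.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    images = {}
    for ch, im in study.images.items():
        m = im[mask].mean()
        if m <= 0:
            raise ValueError(f"channel {ch} has non-positive in-mask mean {m}")
        images[ch] = im / m
    return SubjectStudy(study.subject_id, images, study.class_map, dict(study.provenance))


@dataclass
class RoiSet:
    """Lesion and contralateral-normal masks plus the resulting prevalence
    (lesion voxels / all ROI voxels)."""

    lesion: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        if (self.lesion & self.normal).any():
            raise ValueError("lesion and normal masks overlap")

    @property
    def prevalence(self) -> float:
        n_les = int(self.lesion.sum())
        n_nor = int(self.normal.sum())
        return n_les / (n_les + n_nor)


def define_rois(
    chronic_t2: np.ndarray,
    threshold: float,
    midline: float | None = None,
    target_prevalence: float | None = None,
) -> RoiSet:
    """Lesion ROI by thresholding the normalized chronic T2WI; normal ROI by
    mirroring it across the midline column.

    ``midline`` defaults to the central image column ``(cols - 1) / 2``.
    Mirrored voxels that land outside the grid are dropped; voxels where the
    mirrored region overlaps the lesion itself (midline-crossing lesions)
    are removed from the normal mask with a logged warning.  If
    ``target_prevalence`` is given, the normal mask is eroded/dilated
    slice-wise until the prevalence is within +/-2 percentage points of it.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    chronic_t2 = np.asarray(chronic_t2, dtype=float)
    n_slices, h, w = chronic_t2.shape
    if midline is None:
        midline = (w - 1) / 2

    lesion = chronic_t2 > threshold
    if not lesion.any():
        raise ValueError(
            f"no chronic voxel exceeds threshold {threshold} (max {chronic_t2.max():.3g})"
        )

    normal = np.zeros_like(lesion)
    for s in range(n_slices):
        rows, cols = np.nonzero(lesion[s])
        mcols = np.rint(2 * midline - cols).astype(int)
        keep = (mcols >= 0) & (mcols < w)
        if not keep.all():
            log.warning(
                "slice %d: %d mirrored voxels fall outside the grid and are dropped",
                s, int((~keep).sum()),
            )
        normal[s, rows[keep], mcols[keep]] = True
    overlap = normal & lesion
    if overlap.any():
        log.warning(
            "mirrored normal ROI overlaps the lesion in %d voxels; removing them "
            "from the normal mask", int(overlap.sum()),
        )
        normal &= ~lesion
    if not normal.any():
        raise ValueError("contralateral normal mask is empty")

    rois = RoiSet(lesion, normal)
    if target_prevalence is not None:
        rois = _adjust_prevalence(rois, target_prevalence)
    return rois


def _adjust_prevalence(rois: RoiSet, target: float, max_iter: int = 50) -> RoiSet:
    """Shrink (raise prevalence) or grow (lower it) the normal mask to the
    voxel count that realizes the requested prevalence; the lesion mask is
    never touched.

    The mask is resized boundary-first: when shrinking, the shallowest
    voxels (smallest in-mask distance to the outside) are peeled off; when
    growing, in-plane dilation rings are added (never onto the lesion) and
    the excess peeled back.  Fully deterministic.
    """
    if not 0 < target < 1:
        raise ValueError("target prevalence must be in (0, 1)")
    n_lesion = int(rois.lesion.sum())
    needed = int(round(n_lesion * (1.0 / target - 1.0)))
    if needed < 1:
        raise ValueError(f"target prevalence {target} leaves no normal voxels")
    normal = rois.normal.copy()
    structure = np.zeros((1, 3, 3), dtype=bool)
    structure[0] = True
    for _ in range(max_iter):
        if int(normal.sum()) >= needed:
            break
        grown = ndimage.binary_dilation(normal, structure=structure) & ~rois.lesion
        if grown.sum() == normal.sum():
            log.warning(
                "cannot grow normal mask beyond %d voxels (target %d)",
                int(normal.sum()), needed,
            )
            break
        normal = grown
    excess = int(normal.sum()) - needed
    if excess > 0:
        # peel boundary-first: keep the `needed` deepest voxels, ties broken
        # by flat voxel index for determinism
        depth = ndimage.distance_transform_edt(normal, sampling=(1e6, 1.0, 1.0))
        flat = np.nonzero(normal.ravel())[0]
        order = np.lexsort((flat, -depth.ravel()[flat]))
        drop = flat[order[needed:]]
        normal = normal.copy()
        normal.ravel()[drop] = False
    return RoiSet(rois.lesion, normal)


@dataclass
class SampleSet:
    """Per-voxel training samples.

    ``features``: (n, 4) normalized acute intensities in channel order
    (DWI, T1WI, T2WI, PDWI); ``target``: normalized chronic T2WI intensity
    (nominal range 0-3); ``label``: 1 = lesion ROI, 0 = contralateral
    normal ROI; plus subject / slice / voxel coordinates so every sample is
    traceable to one voxel.
    """

    features: np.ndarray
    target: np.ndarray
    label: np.ndarray
    subject: np.ndarray
    slice_index: np.ndarray
    row: np.ndarray
    col: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.target)
        if self.features.shape != (n, len(CHANNELS)):
            raise ValueError(f"features must be (n, {len(CHANNELS)})")
        for name in ("label", "subject", "slice_index", "row", "col"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.target)

    @property
    def prevalence(self) -> float:
        return float(self.label.mean())

    @property
    def subject_ids(self) -> list[str]:
        return sorted(set(self.subject.tolist()))

    def for_subjects(self, ids) -> "SampleSet":
        keep = np.isin(self.subject, list(ids))
        return SampleSet(
            self.features[keep], self.target[keep], self.label[keep],
            self.subject[keep], self.slice_index[keep], self.row[keep], self.col[keep],
        )

    @classmethod
    def concatenate(cls, sets: list["SampleSet"]) -> "SampleSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        return cls(
            np.concatenate([s.features for s in sets]),
            np.concatenate([s.target for s in sets]),
            np.concatenate([s.label for s in sets]),
            np.concatenate([s.subject for s in sets]),
            np.concatenate([s.slice_index for s in sets]),
            np.concatenate([s.row for s in sets]),
            np.concatenate([s.col for s in sets]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "slice": self.slice_index,
                "row": self.row,
                "col": self.col,
                "dwi": self.features[:, 0],
                "t1": self.features[:, 1],
                "t2": self.features[:, 2],
                "pd": self.features[:, 3],
                "target": self.target,
                "label": self.label,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSet":
        return cls(
            frame[["dwi", "t1", "t2", "pd"]].to_numpy(float),
            frame["target"].to_numpy(float),
            frame["label"].to_numpy(int),
            frame["subject"].to_numpy(),
            frame["slice"].to_numpy(int),
            frame["row"].to_numpy(int),
            frame["col"].to_numpy(int),
        )


def extract_samples(study: SubjectStudy, rois: RoiSet) -> SampleSet:
    """One sample per ROI voxel of a normalized study."""
    for ch in CHANNELS + (CHRONIC,):
        if ch not in study.images:
            raise ValueError(f"study {study.subject_id} is missing channel '{ch}'")
    if rois.lesion.shape != study.shape:
        raise ValueError("ROI masks do not match the study grid")
    if not rois.normal.any():
        raise ValueError("normal mask is empty")
    sets = []
    for mask, lab in ((rois.lesion, 1), (rois.normal, 0)):
        sl, rows, cols = np.nonzero(mask)
        feats = np.column_stack([study.images[ch][sl, rows, cols] for ch in CHANNELS])
        sets.append(
            SampleSet(
                feats,
                study.images[CHRONIC][sl, rows, cols],
                np.full(len(sl), lab, dtype=np.uint8),
                np.full(len(sl), study.subject_id, dtype=object),
                sl, rows, cols,
            )
        )
    out = SampleSet.concatenate(sets)
    log.info(
        "%s: %d samples (%d lesion / %d normal, prevalence %.3f)",
        study.subject_id, len(out), int(out.label.sum()),
        int((1 - out.label).sum()), out.prevalence,
    )
    return out


def preprocess_study(
    study: SubjectStudy,
    roi_threshold: float,
    midline: float | None = None,
    mask_fraction: float = 0.10,
    target_prevalence: float | None = None,
) -> tuple[SubjectStudy, np.ndarray, RoiSet, SampleSet]:
    """Full chain for one subject: smooth -> mask -> normalize -> ROIs ->
    samples.  Returns (normalized study, brain mask, ROIs, samples)."""
    smoothed = smooth_study(study)
    mask = brain_mask(smoothed, mask_fraction)
    normalized = normalize_study(smoothed, mask)
    rois = define_rois(
        normalized.images[CHRONIC], roi_threshold, midline, target_prevalence
    )
    samples = extract_samples(normalized, rois)
    return normalized, mask, rois, samples
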