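"""Synthetic multi-parametric stroke MRI phantoms.

Real studies of this kind pair four co-registered acute-phase contrasts
(DWI, T1WI, T2WI, PDWI) with a chronic (~3 month) T2WI per subject.  No
such cohort ships with this package, so this module generates phantom
cohorts with the statistical structure the downstream analysis assumes:
three tissue populations (normal parenchyma, ischemic lesion, CSF) whose
class-conditional intensities — on the brain-mean ≈ 1 normalized scale —
differ by channel the way stroke tissue does (lesion bright / CSF dark on
DWI, both bright on chronic T2WI), with spatially coherent noise and an
optional integer-voxel mis-registration of the chronic channel.

Intensities are class-conditional Gaussians truncated at zero.  Spatial
coherence is imposed by smoothing the noise field only; class boundaries
stay crisp so that mask-based counting tests are exact.  All randomness
descends from one explicit seed through ``numpy.random.SeedSequence``
spawning.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: acute input channels, in feature order
CHANNELS = ("dwi", "t1", "t2", "pd")
#: the outcome channel
CHRONIC = "chronic_t2"
ALL_CHANNELS = CHANNELS + (CHRONIC,)

#: integer codes of the true class map
BACKGROUND, NORMAL, LESION, CSF = 0, 1, 2, 3
CLASS_NAMES = {"normal": NORMAL, "lesion": LESION, "csf": CSF}


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid of one phantom subject: ``n_slices`` axial slices of
    ``shape = (rows, cols)``."""

    n_slices: int = 7
    shape: tuple[int, int] = (40, 40)

    def __post_init__(self) -> None:
        if self.n_slices < 1 or min(self.shape) < 3:
            raise ValueError(f"grid must be positive and at least 3x3, got {self}")


@dataclass(frozen=True)
class LesionSpec:
    """Disk lesion: centre ``(row, col)`` and a radius per slice (a scalar
    radius applies to every slice).  Radius 0 means no lesion."""

    center: tuple[float, float] = (20.0, 10.0)
    radius: float | Sequence[float] = 5.0

    def radii(self, n_slices: int) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.radius, dtype=float))
        if r.size == 1:
            r = np.full(n_slices, r[0])
        if r.size != n_slices:
            raise ValueError(f"need {n_slices} radii, got {r.size}")
        if np.any(r < 0):
            raise ValueError("lesion radii must be >= 0")
        return r


# Default class-conditional means/SDs on the brain-mean ≈ 1 scale.  Lesion is
# bright on DWI/T2/PD and slightly dark on T1; CSF is dark on DWI/T1 and
# bright on T2/PD; on chronic T2 the infarct and CSF are both bright.
_DEFAULT_MEANS = {
    "normal": {"dwi": 1.0, "t1": 1.0, "t2": 1.0, "pd": 1.0, CHRONIC: 1.0},
    "lesion": {"dwi": 1.6, "t1": 0.9, "t2": 1.5, "pd": 1.3, CHRONIC: 1.8},
    "csf": {"dwi": 0.5, "t1": 0.6, "t2": 2.2, "pd": 1.4, CHRONIC: 2.4},
}
_DEFAULT_SDS = {
    "normal": {c: 0.12 for c in ALL_CHANNELS},
    "lesion": {c: 0.15 for c in ALL_CHANNELS},
    "csf": {c: 0.15 for c in ALL_CHANNELS},
}


@dataclass(frozen=True)
class TissueModel:
    """Class-conditional intensity model plus lesion geometry.

    ``means``/``sds`` map class name -> channel -> value (unitless, brain
    mean ≈ 1).  ``noise_smooth_sigma`` is the Gaussian kernel width (voxels)
    applied to the noise field; ``misregistration_voxels`` shifts the chronic
    channel by up to that many integer voxels per in-plane axis (default 0 =
    perfectly co-registered).  ``chronic_lesion`` may differ from ``lesion``
    to emulate infarct growth or recovery; by default they coincide.
    ``csf_radius`` places a mid-line CSF disk (ventricle stand-in).
    """

    means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_MEANS
    )
    sds: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: _DEFAULT_SDS)
    noise_smooth_sigma: float = 0.8
    misregistration_voxels: int = 0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    chronic_lesion: LesionSpec | None = None
    csf_radius: float = 2.5

    def __post_init__(self) -> None:
        for cls in CLASS_NAMES:
            for ch in ALL_CHANNELS:
                if self.sds[cls][ch] < 0:
                    raise ValueError(f"negative SD for {cls}/{ch}")
        if not self.means["lesion"][CHRONIC] > self.means["normal"][CHRONIC]:
            raise ValueError("lesion must be brighter than normal on chronic T2")
        if not self.means["csf"]["dwi"] < self.means["normal"]["dwi"]:
            raise ValueError("CSF must be darker than normal on DWI")
        if not self.means["csf"][CHRONIC] > self.means["normal"][CHRONIC]:
            raise ValueError("CSF must be brighter than normal on chronic T2")

    @property
    def chronic_geometry(self) -> LesionSpec:
        return self.chronic_lesion if self.chronic_lesion is not None else self.lesion


@dataclass
class SubjectStudy:
    """One subject's co-registered slice stacks.

    ``images`` maps channel name -> float array of shape
    ``(n_slices, rows, cols)``.  ``class_map`` (phantoms only) holds the true
    tissue class of every voxel using the chronic lesion geometry, i.e. the
    outcome truth.  ``provenance`` records the seed and generator parameters.
    """

    subject_id: str
    images: dict[str, np.ndarray]
    class_map: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: im.shape for ch, im in self.images.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree on grid: {shapes}")
        for ch, im in self.images.items():
            if not np.all(np.isfinite(im)) or np.any(im < 0):
                raise ValueError(f"channel {ch} has non-finite or negative voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.images.values())).shape

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.images)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _brain_ellipse(shape: tuple[int, int], margin: float = 3.0) -> np.ndarray:
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    a, b = h / 2 - margin, w / 2 - margin
    return ((rr - (h - 1) / 2) / a) ** 2 + ((cc - (w - 1) / 2) / b) ** 2 <= 1.0


def _check_lesion_in_grid(spec: LesionSpec, geometry: GridSpec) -> None:
    radii = spec.radii(geometry.n_slices)
    h, w = geometry.shape
    for s, r in enumerate(radii):
        if r == 0:
            continue
        r0, c0 = spec.center
        if r0 - r < 0 or r0 + r > h - 1 or c0 - r < 0 or c0 + r > w - 1:
            raise ValueError(
                f"lesion (center {spec.center}, radius {r}) leaves the "
                f"{h}x{w} grid on slice {s}"
            )


def _class_map(geometry: GridSpec, model: TissueModel, lesion: LesionSpec) -> np.ndarray:
    h, w = geometry.shape
    radii = lesion.radii(geometry.n_slices)
    out = np.empty((geometry.n_slices, h, w), dtype=np.uint8)
    brain = _brain_ellipse(geometry.shape)
    csf = brain & _disk_mask(geometry.shape, ((h - 1) / 2, (w - 1) / 2), model.csf_radius)
    for s in range(geometry.n_slices):
        cls = np.where(brain, NORMAL, BACKGROUND).astype(np.uint8)
        cls[csf] = CSF
        if radii[s] > 0:
            les = brain & _disk_mask(geometry.shape, lesion.center, radii[s])
            cls[les] = LESION
        out[s] = cls
    return out


def _coherent_noise(rng: np.random.Generator, shape: tuple[int, int, int], sigma: float) -> np.ndarray:
    """Unit-variance noise field, smoothed slice-wise for spatial coherence."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        for s in range(shape[0]):
            sl = ndimage.gaussian_filter(noise[s], sigma, mode="reflect")
            sd = sl.std()
            noise[s] = sl / sd if sd > 0 else sl
    return noise


def _render_channel(
    rng: np.random.Generator,
    cls_map: np.ndarray,
    model: TissueModel,
    channel: str,
) -> np.ndarray:
    mean_map = np.zeros(cls_map.shape)
    sd_map = np.zeros(cls_map.shape)
    for name, code in CLASS_NAMES.items():
        mean_map[cls_map == code] = model.means[name][channel]
        sd_map[cls_map == code] = model.sds[name][channel]
    noise = _coherent_noise(rng, cls_map.shape, model.noise_smooth_sigma)
    return np.clip(mean_map + sd_map * noise, 0.0, None)


def generate_study(
    seed: int | np.random.SeedSequence,
    geometry: GridSpec | None = None,
    model: TissueModel | None = None,
    subject_id: str = "sub-01",
) -> SubjectStudy:
    """Generate one phantom subject.

    Voxels are drawn class-wise from the model's per-channel truncated
    Gaussians; the chronic T2WI uses the chronic lesion geometry (elevated
    inside the infarct) and is optionally shifted by an integer mis-
    registration jitter.  Identical ``(seed, parameters)`` give bit-identical
    output.
    """
    geometry = geometry or GridSpec()
    model = model or TissueModel()
    _check_lesion_in_grid(model.lesion, geometry)
    _check_lesion_in_grid(model.chronic_geometry, geometry)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    acute_cls = _class_map(geometry, model, model.lesion)
    chronic_cls = _class_map(geometry, model, model.chronic_geometry)

    images: dict[str, np.ndarray] = {}
    # one child stream per channel, in fixed order
    children = ss.spawn(len(ALL_CHANNELS) + 1)
    for child, ch in zip(children, ALL_CHANNELS):
        cls = chronic_cls if ch == CHRONIC else acute_cls
        images[ch] = _render_channel(np.random.default_rng(child), cls, model, ch)

    if model.misregistration_voxels > 0:
        jit_rng = np.random.default_rng(children[-1])
        j = model.misregistration_voxels
        dr, dc = jit_rng.integers(-j, j + 1, size=2)
        images[CHRONIC] = np.roll(images[CHRONIC], (int(dr), int(dc)), axis=(1, 2))

    prov = {
        "seed": ss.entropy if not ss.spawn_key else list(ss.spawn_key),
        "n_slices": geometry.n_slices,
        "shape": list(geometry.shape),
        "noise_smooth_sigma": model.noise_smooth_sigma,
        "misregistration_voxels": model.misregistration_voxels,
    }
    return SubjectStudy(subject_id, images, class_map=chronic_cls, provenance=prov)


@dataclass(frozen=True)
class GeometryVariation:
    """Per-subject randomization of the lesion: uniform integer jitter of the
    centre (voxels) and radius (voxels) around the model's nominal values."""

    center_jitter: int = 2
    radius_jitter: float = 1.0


def generate_cohort(
    n_subjects: int,
    seed: int,
    model: TissueModel | None = None,
    geometry: GridSpec | None = None,
    variation: GeometryVariation | None = GeometryVariation(),
) -> list[SubjectStudy]:
    """Generate ``n_subjects`` phantom subjects with distinct sub-seeds.

    With ``variation=None`` all subjects share the same geometry and differ
    only in their noise draws.  At least 2 subjects are required (subject-
    level cross-validation needs >= 2 folds).
    """
    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2 for subject-level cross-validation")
    model = model or TissueModel()
    geometry = geometry or GridSpec()
    root = np.random.SeedSequence(seed)
    cohort = []
    for i, child in enumerate(root.spawn(n_subjects)):
        m = model
        if variation is not None:
            var_rng = np.random.default_rng(child.spawn(1)[0])
            dr, dc = var_rng.integers(
                -variation.center_jitter, variation.center_jitter + 1, size=2
            )
            drad = var_rng.uniform(-variation.radius_jitter, variation.radius_jitter)
            base = model.lesion
            radii = base.radii(geometry.n_slices)
            new_lesion = LesionSpec(
                center=(base.center[0] + int(dr), base.center[1] + int(dc)),
                radius=np.maximum(radii + drad, 0.0),
            )
            m = replace(model, lesion=new_lesion, chronic_lesion=None)
            if model.chronic_lesion is not None:
                scale = np.mean(model.chronic_geometry.radii(geometry.n_slices)) / max(
                    np.mean(radii), 1e-9
                )
                m = replace(
                    m,
                    chronic_lesion=LesionSpec(
                        center=new_lesion.center,
                        radius=np.maximum(radii + drad, 0.0) * scale,
                    ),
                )
        cohort.append(
            generate_study(child, geometry, m, subject_id=f"sub-{i + 1:02d}")
        )
    return cohort


# ---------------------------------------------------------------------------
# cohort demographics fixture
# ---------------------------------------------------------------------------

_RAW_COLUMNS = [
    "Pt",
    "Age/Gender",
    "Stroke Location",
    "Ischemic Stroke Subtype",
    "Onset-Acute MRI (hours)",
    "Onset-Outcome MRI (days)",
]


@dataclass
class CohortTable:
    """Demographics of the 12-patient cohort (parsed view of the packaged
    table).  ``frame`` columns: pt, age, gender, location, subtype,
    onset_to_acute_hours, onset_to_outcome_days."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.frame["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if (self.frame[["onset_to_acute_hours", "onset_to_outcome_days"]] <= 0).any().any():
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return [f"pt-{p:02d}" for p in self.frame["pt"]]

    def to_csv(self, path: str | Path) -> None:
        """Round-trip to CSV with the original column headers."""
        raw = pd.DataFrame(
            {
                "Pt": self.frame["pt"],
                "Age/Gender": self.frame["age"].astype(str) + "/" + self.frame["gender"],
                "Stroke Location": self.frame["location"],
                "Ischemic Stroke Subtype": self.frame["subtype"],
                "Onset-Acute MRI (hours)": self.frame["onset_to_acute_hours"],
                "Onset-Outcome MRI (days)": self.frame["onset_to_outcome_days"],
            }
        )
        raw.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CohortTable":
        raw = pd.read_csv(path_or_buf)
        missing = [c for c in _RAW_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"demographic table missing columns: {missing}")
        age_gender = raw["Age/Gender"].str.split("/", expand=True)
        frame = pd.DataFrame(
            {
                "pt": raw["Pt"].astype(int),
                "age": age_gender[0].astype(float),
                "gender": age_gender[1],
                "location": raw["Stroke Location"],
                "subtype": raw["Ischemic Stroke Subtype"],
                "onset_to_acute_hours": raw["Onset-Acute MRI (hours)"].astype(float),
                "onset_to_outcome_days": raw["Onset-Outcome MRI (days)"].astype(float),
            }
        )
        return cls(frame)


def demographic_table() -> CohortTable:
    """The packaged 12-patient demographic table."""
    ref = importlib.resources.files("infarctnet.data") / "table1_demographics.csv"
    with importlib.resources.as_file(ref) as path:
        table = CohortTable.from_csv(path)
    if len(table) != 12:
        raise RuntimeError("packaged demographic table is corrupt")
    return table


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def save_study(study: SubjectStudy, directory: str | Path) -> list[Path]:
    """Write one float32 NIfTI per channel (``<subject>_<channel>.nii.gz``),
    a uint8 class map when present, and a JSON sidecar with provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for ch, im in study.images.items():
        # internal (slice, row, col) -> NIfTI (row, col, slice)
        vol = np.transpose(im, (1, 2, 0)).astype(np.float32)
        p = directory / f"{study.subject_id}_{ch}.nii.gz"
        nib.save(nib.Nifti1Image(vol, np.eye(4)), p)
        written.append(p)
    if study.class_map is not None:
        vol = np.transpose(study.class_map, (1, 2, 0)).astype(np.uint8)
        p = directory / f"{study.subject_id}_classmap.nii.gz"
        nib.save(nib.Nifti1Image(vol, np.eye(4)), p)
        written.append(p)
    sidecar = directory / f"{study.subject_id}.json"
    sidecar.write_text(json.dumps(study.provenance, indent=2, default=str))
    written.append(sidecar)
    return written


def load_study(
    directory: str | Path,
    subject_id: str,
    channels: Sequence[str] = ALL_CHANNELS,
) -> SubjectStudy:
    """Read a study written by :func:`save_study`; inverse within float32."""
    directory = Path(directory)
    images = {}
    shapes = {}
    for ch in channels:
        p = directory / f"{subject_id}_{ch}.nii.gz"
        if not p.exists():
            raise FileNotFoundError(f"missing channel '{ch}' for {subject_id}: {p}")
        vol = np.asarray(nib.load(p).dataobj, dtype=np.float64)
        shapes[ch] = vol.shape
        images[ch] = np.transpose(vol, (2, 0, 1))
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channel grids disagree: {shapes}")
    class_map = None
    pc = directory / f"{subject_id}_classmap.nii.gz"
    if pc.exists():
        class_map = np.transpose(np.asarray(nib.load(pc).dataobj), (2, 0, 1))
    prov = {}
    sidecar = directory / f"{subject_id}.json"
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return SubjectStudy(subject_id, images, class_map=class_map, provenance=prov)
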