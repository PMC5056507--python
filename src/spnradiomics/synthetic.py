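"""Synthetic nodule cohorts under four CT acquisition conditions.

Real chest-CT slices of solitary pulmonary nodules are not redistributable,
so this module builds a fully seeded stand-in cohort that preserves the
study design every downstream stage depends on:

* two texture classes — benign nodules are smoother (lower HU variance,
  longer spatial correlation) than malignant ones — realised as stationary
  Gaussian random fields inside an elliptical ROI on a lung-like background;
* a *paired* acquisition design: each subject has one underlying texture
  observed under four acquisition groups,

    group 1  non-contrast, 1.25 mm slices, standard kernel   (reference)
    group 2  contrast-enhanced, 1.25 mm, standard kernel
    group 3  non-contrast, 5 mm, standard kernel
    group 4  non-contrast, 5 mm, lung (high-pass) kernel

  emulated by operators applied to the same base image: contrast adds a
  global HU offset plus a smooth multiplicative confound field that is
  independent of the class; thick slices apply partial-volume Gaussian
  blurring with width tied to the 5/1.25 thickness ratio; the lung kernel
  applies an unsharp high-pass boost and re-injects band-pass noise.

With all degradation strengths at zero the four group images are
byte-identical, which pins down the operators exactly.  Default strengths
are a single documented config block (see docs/methods.md); none of them
come from measured scanner data.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .images import ImageSlice, ROIMask, write_image, write_mask

__all__ = [
    "AcquisitionGroup",
    "GROUPS",
    "TextureParams",
    "DegradationParams",
    "CohortSpec",
    "generate_nodule",
    "simulate_cohort",
    "generate_cohort",
    "SyntheticSubject",
]

CLASSES = ("benign", "malignant")
MANIFEST_COLUMNS = ("subject", "class", "cohort", "group", "image", "mask")


@dataclass(frozen=True)
class AcquisitionGroup:
    """One of the four acquisition conditions; only these four exist."""

    id: int
    contrast_enhanced: bool
    slice_thickness: float  # mm
    kernel: str  # "standard" | "lung"

    def __post_init__(self) -> None:
        valid = {
            1: (False, 1.25, "standard"),
            2: (True, 1.25, "standard"),
            3: (False, 5.0, "standard"),
            4: (False, 5.0, "lung"),
        }
        if self.id not in valid or valid[self.id] != (
            self.contrast_enhanced,
            self.slice_thickness,
            self.kernel,
        ):
            raise ValueError(
                f"invalid acquisition group {self.id}: only the four study "
                "combinations are constructible"
            )

    @classmethod
    def from_id(cls, group_id: int) -> "AcquisitionGroup":
        try:
            return GROUPS[int(group_id)]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"unknown acquisition group {group_id!r}; use 1-4") from exc


GROUPS: dict[int, AcquisitionGroup] = {
    1: AcquisitionGroup(1, False, 1.25, "standard"),
    2: AcquisitionGroup(2, True, 1.25, "standard"),
    3: AcquisitionGroup(3, False, 5.0, "standard"),
    4: AcquisitionGroup(4, False, 5.0, "lung"),
}


@dataclass(frozen=True)
class TextureParams:
    """Per-class in-nodule texture: lognormal subject-level draws around
    a class-typical HU standard deviation and correlation length (pixels).

    The between-subject spread makes the classes overlap, so discrimination
    is imperfect, as in patient data."""

    base_hu: float = 25.0
    sd_hu: float = 18.0
    corr_len: float = 2.0
    sd_spread: float = 0.35  # lognormal sigma of subject-level sd_hu
    corr_spread: float = 0.25  # lognormal sigma of subject-level corr_len


DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "benign": TextureParams(base_hu=25.0, sd_hu=18.0, corr_len=2.0),
    "malignant": TextureParams(base_hu=25.0, sd_hu=26.0, corr_len=1.5),
}


@dataclass(frozen=True)
class DegradationParams:
    """Strengths of the three acquisition operators (one config block).

    All-zero strengths make every group identical to group 1."""

    contrast_offset_hu: float = 45.0  # group 2 global enhancement
    confound_strength: float = 0.4  # group 2 multiplicative field amplitude
    confound_corr_len: float = 6.0  # px, smoothness of the confound field
    pv_blur_px_per_ratio: float = 0.4  # partial-volume sigma per unit excess
    sharpen_amount: float = 0.8  # group 4 unsharp-mask gain
    sharpen_radius: float = 1.0  # px
    kernel_noise_sd_hu: float = 12.0  # group 4 band-pass noise amplitude
    noise_band_px: tuple[float, float] = (0.5, 1.5)  # DoG band edges

    def pv_sigma(self, thickness: float) -> float:
        return self.pv_blur_px_per_ratio * (thickness / 1.25 - 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """How many subjects to simulate and under which settings."""

    n_benign: int = 30
    n_malignant: int = 90
    cohort_label: str = "primary"
    seed: int = 0
    image_size: int = 64
    spacing_mm: float = 0.7
    background_hu: float = -820.0
    background_noise_sd: float = 12.0
    radius_range_px: tuple[float, float] = (8.0, 16.0)
    texture_params: dict[str, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    degradation_params: DegradationParams = field(default_factory=DegradationParams)

    def __post_init__(self) -> None:
        if self.n_benign <= 0 or self.n_malignant <= 0:
            raise ValueError("cohort counts must be positive")
        if self.cohort_label not in ("primary", "validation"):
            raise ValueError("cohort_label must be 'primary' or 'validation'")


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """White noise smoothed to correlation length ``corr_len`` and rescaled
    to unit sample variance (zero mean)."""
    white = rng.standard_normal(shape)
    if corr_len > 0:
        f = ndimage.gaussian_filter(white, corr_len, mode="wrap")
    else:
        f = white
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _subject_rng(spec: CohortSpec, subject_seed: int, *extra: int) -> np.random.Generator:
    ss = np.random.SeedSequence([spec.seed, 0 if spec.cohort_label == "primary" else 1, subject_seed, *extra])
    return np.random.default_rng(ss)


def _base_nodule(
    class_label: str, spec: CohortSpec, subject_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Group-independent base image and elliptical mask for one subject."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}; use 'benign' or 'malignant'")
    tex = spec.texture_params[class_label]
    n = spec.image_size
    rng = _subject_rng(spec, subject_seed)

    # subject-level texture draws (class separation with overlap)
    sd_hu = tex.sd_hu * float(np.exp(tex.sd_spread * rng.standard_normal()))
    corr_len = tex.corr_len * float(np.exp(tex.corr_spread * rng.standard_normal()))

    # elliptical ROI with randomised axes and orientation
    lo, hi = spec.radius_range_px
    a, b = rng.uniform(lo, hi, size=2)
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy = cx = (n - 1) / 2.0
    u = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
    v = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    background = spec.background_hu + spec.background_noise_sd * rng.standard_normal((n, n))
    texture = tex.base_hu + sd_hu * _smooth_unit_field(rng, (n, n), corr_len)
    image = np.where(mask, texture, background)
    return image, mask


def _apply_group(
    base: np.ndarray,
    group: AcquisitionGroup,
    spec: CohortSpec,
    subject_seed: int,
) -> np.ndarray:
    """Transform the base (group-1) image into the given acquisition group."""
    deg = spec.degradation_params
    img = base.copy()
    if group.contrast_enhanced:
        rng = _subject_rng(spec, subject_seed, 2)
        confound = _smooth_unit_field(rng, img.shape, deg.confound_corr_len)
        img = img * (1.0 + deg.confound_strength * confound) + deg.contrast_offset_hu
    sigma_pv = deg.pv_sigma(group.slice_thickness)
    if sigma_pv > 0:
        img = ndimage.gaussian_filter(img, sigma_pv, mode="nearest")
    if group.kernel == "lung":
        if deg.sharpen_amount > 0:
            low = ndimage.gaussian_filter(img, deg.sharpen_radius, mode="nearest")
            img = img + deg.sharpen_amount * (img - low)
        if deg.kernel_noise_sd_hu > 0:
            rng = _subject_rng(spec, subject_seed, 4)
            white = rng.standard_normal(img.shape)
            s_lo, s_hi = deg.noise_band_px
            band = ndimage.gaussian_filter(white, s_lo, mode="wrap") - ndimage.gaussian_filter(
                white, s_hi, mode="wrap"
            )
            band_sd = band.std()
            if band_sd > 0:
                img = img + deg.kernel_noise_sd_hu * band / band_sd
    return np.clip(img, -1024.0, 3071.0)


def generate_nodule(
    class_label: str,
    group: AcquisitionGroup | int,
    spec: CohortSpec,
    subject_seed: int,
) -> tuple[ImageSlice, ROIMask]:
    """One nodule image and its ROI under the requested acquisition group.

    The same (spec, subject_seed) always yields the same base texture and
    mask; only the acquisition operator differs between groups, so the four
    group images of a subject form a matched set.
    """
    if isinstance(group, int):
        group = AcquisitionGroup.from_id(group)
    base, mask = _base_nodule(class_label, spec, subject_seed)
    pixels = _apply_group(base, group, spec, subject_seed)
    image = ImageSlice(
        pixels=pixels,
        spacing=(spec.spacing_mm, spec.spacing_mm),
        meta={"group": group.id, "class": class_label, "subject_seed": subject_seed},
    )
    return image, ROIMask(mask=mask)


@dataclass
class SyntheticSubject:
    """All four acquisition views of one simulated subject."""

    subject_id: str
    class_label: str
    cohort: str
    images: dict[int, ImageSlice]
    mask: ROIMask


def simulate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Simulate the full paired cohort in memory (all four groups/subject)."""
    subjects: list[SyntheticSubject] = []
    labels = ["benign"] * spec.n_benign + ["malignant"] * spec.n_malignant
    for idx, label in enumerate(labels):
        images: dict[int, ImageSlice] = {}
        mask: ROIMask | None = None
        for gid in GROUPS:
            img, mask = generate_nodule(label, gid, spec, subject_seed=idx)
            images[gid] = img
        subjects.append(
            SyntheticSubject(
                subject_id=f"{spec.cohort_label[:4]}-{idx:04d}",
                class_label=label,
                cohort=spec.cohort_label,
                images=images,
                mask=mask,
            )
        )
    return subjects


def generate_cohort(spec: CohortSpec, outdir: str | Path) -> Path:
    """Write the cohort to disk and return the manifest CSV path.

    Layout: ``<outdir>/<subject>_g<k>.tif`` (+ JSON sidecars) and one mask
    per subject; manifest columns ``subject,class,cohort,group,image,mask``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    if not outdir.is_dir():
        raise OSError(f"output path {outdir} is not a writable directory")
    manifest = outdir / f"manifest_{spec.cohort_label}.csv"
    rows = []
    for subject in simulate_cohort(spec):
        mask_path = outdir / f"{subject.subject_id}_mask.tif"
        write_mask(subject.mask, mask_path)
        for gid, image in subject.images.items():
            img_path = outdir / f"{subject.subject_id}_g{gid}.tif"
            write_image(image, img_path)
            rows.append(
                {
                    "subject": subject.subject_id,
                    "class": subject.class_label,
                    "cohort": subject.cohort,
                    "group": gid,
                    "image": img_path.name,
                    "mask": mask_path.name,
                }
            )
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def cohort_digest(subjects: list[SyntheticSubject]) -> str:
    """SHA-256 over all pixel data — used to assert determinism/leak-freedom."""
    h = hashlib.sha256()
    for s in subjects:
        for gid in sorted(s.images):
            h.update(np.ascontiguousarray(s.images[gid].pixels))
        h.update(np.ascontiguousarray(s.mask.mask))
    return h.hexdigest()
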