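"""Digital striatal phantom, synthetic subjects and mismatched templates.

Everything the pipeline needs can be generated here without any scan:

* a striatal phantom whose compartments carry fixed activity ratios over a
  uniform head background (caudate 3x, right putamen 2x, left putamen 1x);
* synthetic subjects: a striatum-dominant tracer volume plus a pseudo-T1
  anatomical channel, both pushed through a known rigid/affine
  misalignment so that registration accuracy can be scored exactly;
* a synthetic MNI label atlas (caudate, putamen, occipital);
* a deliberately mismatched, cortex-dominant "perfusion-like" template
  reproducing the failure mode of normalizing a striatum-dominant tracer
  to a cerebral blood-flow template.

Geometry is built from axis-aligned ellipsoids with centers on the 2-mm
MNI lattice, so mirrored/translated structures occupy exactly equal voxel
counts on the default grid and closed-form uptake-ratio arithmetic holds
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from datquant.register import AffineParams
from datquant.quantify import LabelAtlas
from datquant.volume import GridSpec, VolumeImage, gaussian_smooth, resample_trilinear

# name -> (center mm, semiaxes mm); centers sit on the 2-mm lattice
DEFAULT_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "caudate_L": ((-14.0, 14.0, 8.0), (6.0, 10.0, 6.0)),
    "caudate_R": ((14.0, 14.0, 8.0), (6.0, 10.0, 6.0)),
    "putamen_L": ((-28.0, -2.0, 2.0), (6.0, 10.0, 6.0)),
    "putamen_R": ((28.0, -2.0, 2.0), (6.0, 10.0, 6.0)),
    "occipital_L": ((-24.0, -80.0, 2.0), (10.0, 12.0, 10.0)),
    "occipital_R": ((24.0, -80.0, 2.0), (10.0, 12.0, 10.0)),
}

REGION_LABELS = {
    "caudate_L": 1, "caudate_R": 2,
    "putamen_L": 3, "putamen_R": 4,
    "occipital_L": 5, "occipital_R": 6,
}

HEAD_CENTER = (0.0, -18.0, 8.0)
HEAD_SEMIAXES = (72.0, 92.0, 76.0)
BRAIN_SCALE = 0.86  # brain outline relative to the outer head/scalp surface


def _ellipsoid_mask(grid: GridSpec, center, semiaxes) -> np.ndarray:
    dims = grid.dims
    aff = grid.affine
    coords = [
        aff[d, d] * np.arange(dims[d]) + aff[d, 3] for d in range(3)
    ]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    cx, cy, cz = center
    ax, ay, az = semiaxes
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r2 <= 1.0


def head_mask(grid: GridSpec, scale: float = 1.0) -> np.ndarray:
    """Boolean head (scalp-outline) mask; ``scale`` shrinks toward the center."""
    semi = tuple(s * scale for s in HEAD_SEMIAXES)
    return _ellipsoid_mask(grid, HEAD_CENTER, semi)


@dataclass
class PhantomSpec:
    """Generative parameters for the digital striatal phantom.

    Ratios are relative to the uniform head background: both caudate
    nuclei at 3x background, the right putamen at 2x and the left putamen
    at 1x by default. ``psf_fwhm_mm`` emulates post-reconstruction
    resolution as a Gaussian blur of the activity map; noise is either
    absent, relative Gaussian, or Poisson at a count scale.
    """

    background_level: float = 1.0
    ratio_caudate: float = 3.0
    ratio_putamen_right: float = 2.0
    ratio_putamen_left: float = 1.0
    geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))
    psf_fwhm_mm: float = 0.0
    noise: str = "none"            # none | gaussian | poisson
    noise_level: float = 0.0       # gaussian: relative sigma; poisson: counts per unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level <= 0:
            raise ValueError("background_level must be > 0")
        for name, r in (
            ("ratio_caudate", self.ratio_caudate),
            ("ratio_putamen_right", self.ratio_putamen_right),
            ("ratio_putamen_left", self.ratio_putamen_left),
        ):
            if r <= 0:
                raise ValueError(f"{name} must be > 0, got {r}")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model: {self.noise!r}")


@dataclass
class SubjectSpec:
    """Generative parameters for one synthetic subject.

    ``defect_severity`` in [0, 1] removes specific (above-background)
    uptake: fully from the putamen and half from the caudate at severity 1,
    emulating the posterior-dominant dopaminergic loss pattern. The
    misalignment (drawn from ``seed`` when not given explicitly) is a small
    rigid+zoom perturbation shared by the tracer and pseudo-T1 channels;
    the tracer additionally carries a small known rigid offset relative to
    the T1, which is what rigid coregistration must recover.
    """

    defect_severity: float = 0.0
    global_scale: float = 1.0
    misalignment: Optional[AffineParams] = None
    max_translation_mm: float = 10.0
    max_rotation_rad: float = 0.1
    zoom_range: tuple[float, float] = (0.95, 1.05)
    spect_t1_offset: Optional[AffineParams] = None
    max_offset_translation_mm: float = 4.0
    max_offset_rotation_rad: float = 0.04
    psf_fwhm_mm: float = 8.0
    noise: str = "gaussian"
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.defect_severity <= 1.0:
            raise ValueError("defect_severity must lie in [0, 1]")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be > 0")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model: {self.noise!r}")


def _check_grid_contains(grid: GridSpec, geometry: dict) -> None:
    lo = np.asarray(grid.bbox_min)
    hi = np.asarray(grid.bbox_max)
    for name, (center, semi) in geometry.items():
        c = np.asarray(center)
        s = np.asarray(semi)
        if np.any(c - s < lo) or np.any(c + s > hi):
            raise ValueError(f"grid {grid.bbox_min}..{grid.bbox_max} does not contain structure {name}")


def _atlas_from_geometry(grid: GridSpec, geometry: dict) -> LabelAtlas:
    _check_grid_contains(grid, geometry)
    labels = np.zeros(grid.dims, dtype=np.int32)
    masks = {}
    for name, (center, semi) in geometry.items():
        m = _ellipsoid_mask(grid, center, semi)
        if not m.any():
            raise ValueError(f"structure {name} contains no voxels on this grid")
        masks[name] = m
    for a in masks:
        for b in masks:
            if a < b and (masks[a] & masks[b]).any():
                raise ValueError(f"structures {a} and {b} overlap")
    for name, m in masks.items():
        labels[m] = REGION_LABELS[name]
    region_map = {name: (lab,) for name, lab in REGION_LABELS.items()}
    return LabelAtlas(labels=labels, affine=grid.affine, region_map=region_map)


def make_label_atlas(grid: GridSpec) -> LabelAtlas:
    """Synthetic stand-in for an MNI label atlas (deterministic).

    Integer labels for caudate_L/R, putamen_L/R and occipital_L/R as fixed
    ellipsoids at anatomically plausible MNI coordinates; 0 elsewhere.
    """
    return _atlas_from_geometry(grid, DEFAULT_GEOMETRY)


def _apply_noise(data: np.ndarray, noise: str, level: float, rng: np.random.Generator) -> np.ndarray:
    if noise == "none" or level == 0:
        return data
    if noise == "gaussian":
        scale = float(np.mean(data[data > 0])) if np.any(data > 0) else 1.0
        return data + rng.normal(0.0, level * scale, size=data.shape)
    if noise == "poisson":
        # level = expected counts per intensity unit; preserves nonnegativity
        return rng.poisson(np.maximum(data, 0.0) * level).astype(float) / level
    raise ValueError(f"unknown noise model: {noise!r}")


def make_striatal_phantom(spec: PhantomSpec, grid: GridSpec) -> tuple[VolumeImage, LabelAtlas]:
    """Generate the digital striatal phantom and its pre-blur truth atlas.

    Head-shaped background at ``background_level``; caudate/putamen
    compartments at their ratios times background; then PSF blur, then
    noise. The truth atlas describes the activity map before degradation.
    """
    truth = _atlas_from_geometry(grid, spec.geometry)
    data = np.zeros(grid.dims, dtype=np.float64)
    data[head_mask(grid)] = spec.background_level
    ratios = {
        "caudate_L": spec.ratio_caudate,
        "caudate_R": spec.ratio_caudate,
        "putamen_L": spec.ratio_putamen_left,
        "putamen_R": spec.ratio_putamen_right,
        "occipital_L": 1.0,
        "occipital_R": 1.0,
    }
    for name, ratio in ratios.items():
        data[truth.mask(name)] = ratio * spec.background_level
    img = VolumeImage(data=data, affine=grid.affine, description="striatal_phantom")
    if spec.psf_fwhm_mm > 0:
        img = gaussian_smooth(img, spec.psf_fwhm_mm)
    rng = np.random.default_rng(spec.seed)
    noisy = _apply_noise(img.data, spec.noise, spec.noise_level, rng)
    img = img.copy(data=np.maximum(noisy, 0.0) if spec.noise == "gaussian" else noisy,
                   description="striatal_phantom")
    return img, truth


def _draw_affine(rng: np.random.Generator, max_t: float, max_r: float,
                 zoom_range: tuple[float, float]) -> AffineParams:
    t = rng.uniform(-max_t, max_t, size=3)
    r = rng.uniform(-max_r, max_r, size=3)
    z = rng.uniform(zoom_range[0], zoom_range[1], size=3)
    return AffineParams(tx=t[0], ty=t[1], tz=t[2], rx=r[0], ry=r[1], rz=r[2],
                        zx=z[0], zy=z[1], zz=z[2])


@dataclass
class SubjectTruth:
    """Ground-truth generative transforms of a synthetic subject.

    ``misalignment`` maps acquired-space world coordinates to atlas-space
    world coordinates (resampling the acquired volume through its inverse
    restores atlas alignment). ``spect_offset`` is the extra rigid
    transform of the tracer channel relative to the T1 channel; rigid
    coregistration of tracer onto T1 should recover its inverse.
    """

    misalignment: np.ndarray
    spect_offset: np.ndarray


def _aligned_subject_volumes(spec: SubjectSpec, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, LabelAtlas]:
    truth = _atlas_from_geometry(grid, DEFAULT_GEOMETRY)
    head = head_mask(grid)
    brain = head_mask(grid, BRAIN_SCALE)
    sev = spec.defect_severity

    ventricle = _ellipsoid_mask(grid, (0.0, -10.0, 14.0), (12.0, 26.0, 12.0))

    spect = np.zeros(grid.dims)
    spect[head] = 1.0
    spect[ventricle & brain] = 0.25                   # CSF: near-absent tracer uptake
    caudate_ratio = 1.0 + 2.0 * (1.0 - 0.5 * sev)     # 3x healthy -> 2x at full defect
    putamen_ratio = 1.0 + 1.5 * (1.0 - sev)           # 2.5x healthy -> 1x at full defect
    for name in ("caudate_L", "caudate_R"):
        spect[truth.mask(name)] = caudate_ratio
    for name in ("putamen_L", "putamen_R"):
        spect[truth.mask(name)] = putamen_ratio
    spect *= spec.global_scale

    t1 = np.zeros(grid.dims)
    t1[head] = 1.0                                    # scalp/skull shell bright
    t1[brain] = 0.65                                  # brain parenchyma
    t1[ventricle & brain] = 0.15
    for name in ("caudate_L", "caudate_R", "putamen_L", "putamen_R"):
        t1[truth.mask(name)] = 0.8
    return spect, t1, truth


def aligned_subject(spec: SubjectSpec, grid: GridSpec) -> tuple[VolumeImage, VolumeImage, LabelAtlas]:
    """Atlas-aligned, noiseless tracer and pseudo-T1 volumes of a subject.

    Applies the PSF blur but neither misalignment nor noise — the
    ground-truth reference against which registration and quantification
    accuracy are scored.
    """
    spect_al, t1_al, truth = _aligned_subject_volumes(spec, grid)
    spect_img = VolumeImage(spect_al, grid.affine, "subject_spect_aligned")
    t1_img = VolumeImage(t1_al, grid.affine, "subject_t1_aligned")
    if spec.psf_fwhm_mm > 0:
        spect_img = gaussian_smooth(spect_img, spec.psf_fwhm_mm)
        t1_img = gaussian_smooth(t1_img, max(spec.psf_fwhm_mm / 4.0, 1.0))
    return spect_img, t1_img, truth


def make_synthetic_subject(
    spec: SubjectSpec, grid: GridSpec
) -> tuple[VolumeImage, VolumeImage, LabelAtlas, SubjectTruth]:
    """Generate one misaligned tracer/pseudo-T1 pair with known truth.

    Returns ``(spect, t1, truth_atlas, ground_truth)`` where the truth
    atlas lives in aligned (atlas) space and ``ground_truth`` records the
    misalignment applied.
    """
    rng = np.random.default_rng(spec.seed)
    mis = spec.misalignment
    if mis is None:
        mis = _draw_affine(rng, spec.max_translation_mm, spec.max_rotation_rad, spec.zoom_range)
    off = spec.spect_t1_offset
    if off is None:
        t = rng.uniform(-spec.max_offset_translation_mm, spec.max_offset_translation_mm, size=3)
        r = rng.uniform(-spec.max_offset_rotation_rad, spec.max_offset_rotation_rad, size=3)
        off = AffineParams(tx=t[0], ty=t[1], tz=t[2], rx=r[0], ry=r[1], rz=r[2])

    spect_img, t1_img, truth = aligned_subject(spec, grid)

    M = mis.to_matrix()
    M_spect = M @ off.to_matrix()
    spect_out = resample_trilinear(spect_img, grid, M_spect)
    t1_out = resample_trilinear(t1_img, grid, M)

    noisy = _apply_noise(spect_out.data, spec.noise, spec.noise_level, rng)
    spect_out = spect_out.copy(data=np.maximum(noisy, 0.0), description="subject_spect")
    t1_out = t1_out.copy(description="subject_t1")
    return spect_out, t1_out, truth, SubjectTruth(misalignment=M, spect_offset=off.to_matrix())


def make_t1_template(grid: GridSpec, smooth_fwhm_mm: float = 4.0) -> VolumeImage:
    """Atlas-aligned pseudo-T1 template (deterministic, noiseless)."""
    _, t1, _ = _aligned_subject_volumes(SubjectSpec(noise="none", psf_fwhm_mm=0.0), grid)
    img = VolumeImage(t1, grid.affine, "t1_template")
    if smooth_fwhm_mm > 0:
        img = gaussian_smooth(img, smooth_fwhm_mm)
    return img.copy(description="t1_template")


def make_perfusion_like_template(grid: GridSpec) -> VolumeImage:
    """Cortex-dominant template deliberately mismatched to tracer images.

    Emulates a cerebral-blood-flow template: intensity concentrated in a
    cortical shell, no striatal dominance, and an outline that follows the
    brain (not the scalp) — so normalizing a striatum-dominant,
    scalp-to-scalp tracer image against it reproduces the shrinkage and
    ROI-misplacement failure mode.
    """
    brain = head_mask(grid, BRAIN_SCALE)
    inner = head_mask(grid, BRAIN_SCALE * 0.72)
    data = np.zeros(grid.dims)
    data[brain] = 1.0
    data[inner] = 0.45
    img = VolumeImage(data, grid.affine, "perfusion_like_template")
    img = gaussian_smooth(img, 8.0)
    return img.copy(data=np.maximum(img.data, 0.0), description="perfusion_like_template")


@dataclass
class CohortRecord:
    subject_id: str
    stratum: str                  # healthy | patient
    defect_severity: float
    seed: int
    spec: SubjectSpec


def make_cohort(
    n: int,
    healthy_fraction: float = 0.5,
    base_spec: SubjectSpec | None = None,
    seed: int = 0,
    severity_range: tuple[float, float] = (0.3, 0.9),
) -> list[CohortRecord]:
    """Draw a reproducible synthetic cohort.

    The first ``round(n * healthy_fraction)`` subjects are healthy
    (defect_severity 0); the rest draw severity uniformly from
    ``severity_range``. Each subject receives a derived sub-seed, so the
    cohort is fully determined by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= healthy_fraction <= 1.0:
        raise ValueError("healthy_fraction must lie in [0, 1]")
    base = base_spec if base_spec is not None else SubjectSpec()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    n_healthy = int(round(n * healthy_fraction))
    records = []
    for i in range(n):
        healthy = i < n_healthy
        sev = 0.0 if healthy else float(
            np.random.default_rng(sub_seeds[i] + 1).uniform(*severity_range)
        )
        spec = replace(base, defect_severity=sev, seed=int(sub_seeds[i]),
                       misalignment=None, spect_t1_offset=None)
        records.append(CohortRecord(
            subject_id=f"sub-{i + 1:03d}",
            stratum="healthy" if healthy else "patient",
            defect_severity=sev,
            seed=int(sub_seeds[i]),
            spec=spec,
        ))
    return records
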