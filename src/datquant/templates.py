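"""Tracer-template construction in MNI space.

Two procedures are provided:

* **iterative** (two-pass group averaging): normalize every tracer volume
  to a seed template, average to get a preliminary template, re-normalize
  all original volumes to that preliminary template, average again, and
  smooth. The second pass tightens spatial alignment because the interim
  target already has the tracer's own uptake distribution.
* **indirect** (anatomy-transfer): for subjects with a paired anatomical
  (T1-like) scan, rigidly coregister the tracer volume to its T1,
  normalize the T1 to a T1 template, apply those normalization parameters
  to the coregistered tracer volume, then average and smooth. The
  anatomical channel carries far more spatial information than the tracer
  distribution, so the resulting template sits most accurately in
  standard space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from datquant.register import (
    RegistrationConfig,
    coregister_rigid,
    normalise_estimate,
    normalise_write,
)
from datquant.volume import (
    GridSpec,
    VolumeImage,
    average_volumes,
    gaussian_smooth,
    resample_trilinear,
)

log = logging.getLogger(__name__)


@dataclass
class TemplateBuildReport:
    """Provenance of a template build: per-input outcomes and settings."""

    mode: str                       # iterative | indirect
    n_inputs: int
    passes: int
    smooth_fwhm_mm: float
    subjects: list[dict] = field(default_factory=list)
    output_path: str | None = None
    #: unsmoothed per-pass group averages (not serialized) — lets callers
    #: compare preliminary- and final-pass alignment quality
    pass_averages: list = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "n_inputs": self.n_inputs,
                "passes": self.passes,
                "smooth_fwhm_mm": self.smooth_fwhm_mm,
                "subjects": self.subjects,
                "output_path": self.output_path,
            },
            indent=2,
        )


def build_template_iterative(
    images: list[VolumeImage],
    seed_template: VolumeImage,
    smooth_fwhm_mm: float = 8.0,
    passes: int = 2,
    grid: GridSpec | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[VolumeImage, TemplateBuildReport]:
    """Two-pass iterative group-average template.

    Pass 1 normalizes each image to ``seed_template`` and averages the
    normalized volumes into a preliminary template (no intermediate
    smoothing). Pass 2 re-normalizes the *original* images to the
    preliminary template and averages again. The final average is smoothed
    at ``smooth_fwhm_mm``. A subject whose normalization hard-fails is
    excluded with a logged reason; if all fail, the build errors.
    """
    if len(images) == 0:
        raise ValueError("need at least one input image")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if grid is None:
        vox = seed_template.voxel_size
        lo = seed_template.affine[:3, 3]
        hi = lo + (np.asarray(seed_template.shape) - 1) * vox
        grid = GridSpec(tuple(lo), tuple(hi), tuple(vox))

    report = TemplateBuildReport(
        mode="iterative", n_inputs=len(images), passes=passes, smooth_fwhm_mm=smooth_fwhm_mm
    )
    target = resample_trilinear(seed_template, grid)
    current = target
    for p in range(passes):
        normalized = []
        for i, img in enumerate(images):
            entry = {"index": i, "pass": p + 1, "description": img.description}
            try:
                params = normalise_estimate(img, current, config)
                normalized.append(normalise_write(img, params, grid))
                entry["status"] = "ok"
                entry["converged"] = bool(params.meta.get("affine_converged", True))
            except Exception as exc:  # noqa: BLE001 — exclusion-with-log policy
                entry["status"] = f"excluded: {exc}"
                log.warning("template build: input %d excluded in pass %d: %s", i, p + 1, exc)
            report.subjects.append(entry)
        if not normalized:
            raise RuntimeError(f"all inputs failed normalization in pass {p + 1}")
        current = average_volumes(normalized)
        report.pass_averages.append(current)
    template = gaussian_smooth(current, smooth_fwhm_mm)
    return template.copy(description="iterative_template"), report


def build_template_indirect(
    pairs: list[tuple[VolumeImage, VolumeImage]],
    t1_template: VolumeImage,
    smooth_fwhm_mm: float = 8.0,
    grid: GridSpec | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[VolumeImage, TemplateBuildReport]:
    """Anatomy-transfer template from (tracer, T1) pairs.

    Per pair: rigidly coregister tracer -> T1; normalize T1 -> T1
    template; reslice the coregistered tracer through the T1's
    normalization parameters; then average all resliced tracers and
    smooth. Failures are excluded with a logged reason.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (tracer, T1) pair")
    if grid is None:
        vox = t1_template.voxel_size
        lo = t1_template.affine[:3, 3]
        hi = lo + (np.asarray(t1_template.shape) - 1) * vox
        grid = GridSpec(tuple(lo), tuple(hi), tuple(vox))

    report = TemplateBuildReport(
        mode="indirect", n_inputs=len(pairs), passes=1, smooth_fwhm_mm=smooth_fwhm_mm
    )
    normalized = []
    for i, (spect, t1) in enumerate(pairs):
        entry = {"index": i, "description": spect.description}
        try:
            rigid = coregister_rigid(spect, t1, config=config)
            coreg = resample_trilinear(spect, t1, rigid.to_matrix())
            params = normalise_estimate(t1, t1_template, config)
            normalized.append(normalise_write(coreg, params, grid))
            entry["status"] = "ok"
            entry["converged"] = bool(params.meta.get("affine_converged", True))
        except Exception as exc:  # noqa: BLE001
            entry["status"] = f"excluded: {exc}"
            log.warning("template build: pair %d excluded: %s", i, exc)
        report.subjects.append(entry)
    if not normalized:
        raise RuntimeError("all pairs failed coregistration/normalization")
    template = gaussian_smooth(average_volumes(normalized), smooth_fwhm_mm)
    return template.copy(description="indirect_template"), report
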