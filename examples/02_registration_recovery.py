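"""Spatial-normalization parameter recovery on a synthetic subject.

A synthetic tracer volume is pushed through a known affine misalignment
(translation, rotation, anisotropic zoom); the affine estimator must
invert it. The printed residuals are the translation (mm), rotation
(rad) and zoom error of the composed transform `truth @ estimate`, which
would be exactly the identity for perfect recovery.
"""

import numpy as np

from datquant import AffineParams, default_grid, estimate_affine
from datquant.register import decompose_matrix_error
from datquant.synth import SubjectSpec, aligned_subject, make_synthetic_subject

grid = default_grid(2.0)
mis = AffineParams(tx=6, ty=-4, tz=2, rx=0.05, rz=-0.03, zx=1.04, zy=1.0, zz=0.98)
spec = SubjectSpec(seed=3, noise="none", misalignment=mis, spect_t1_offset=AffineParams())

spect, _, _, truth = make_synthetic_subject(spec, grid)
template, _, _ = aligned_subject(spec, grid)

params, scale, info = estimate_affine(spect, template)
err = decompose_matrix_error(truth.misalignment @ params.to_matrix())

print(f"applied misalignment : t=({mis.tx},{mis.ty},{mis.tz}) mm, "
      f"r=({mis.rx},{mis.ry},{mis.rz}) rad, z=({mis.zx},{mis.zy},{mis.zz})")
print(f"residual after recovery: {err['translation_mm']:.3f} mm, "
      f"{err['rotation_rad']:.4f} rad, zoom error {err['zoom_error']:.4f}")
print(f"intensity scale {scale:.3f}, converged={info['converged']}")
print("\nSub-voxel residuals mean the estimator inverted the simulated head")
print("misalignment; the objective trace is monotone non-increasing:")
for i, trace in enumerate(info["traces"]):
    print(f"  stage {i + 1} (blur level): {len(trace) - 1} accepted steps, "
          f"objective {trace[0]:.3g} -> {trace[-1]:.3g}")
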