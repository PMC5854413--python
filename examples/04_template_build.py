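"""Build a tracer template by anatomy transfer and check its placement.

Generates two synthetic subjects (tracer + pseudo-T1 pairs, each with a
random head misalignment and a small tracer-vs-T1 offset), builds the
MRI-indirect template — rigid coregistration of tracer to T1,
normalization of T1 to a T1 template, parameter transfer — and reports
where the template's hot (striatal) region sits relative to a perfectly
aligned reference. Runs in about a minute on one CPU.
"""

import numpy as np

from datquant import default_grid, make_cohort, make_synthetic_subject, make_t1_template
from datquant.register import RegistrationConfig
from datquant.synth import SubjectSpec, aligned_subject
from datquant.templates import build_template_indirect
from datquant.volume import gaussian_smooth

grid = default_grid(2.0)
config = RegistrationConfig(working_voxel_mm=6.0, n_iter_nonlinear=4, rigid_metric="msd")

records = make_cohort(2, healthy_fraction=1.0, seed=7)
pairs = []
for rec in records:
    spect, t1, _, _ = make_synthetic_subject(rec.spec, grid)
    pairs.append((spect, t1))

template, report = build_template_indirect(pairs, make_t1_template(grid),
                                           grid=grid, config=config)
print(f"built indirect template from {report.n_inputs} tracer/T1 pairs; "
      f"statuses: {[s['status'] for s in report.subjects]}")


def hot_centroid(volume):
    hot = volume.data >= 0.75 * volume.data.max()
    idx = np.argwhere(hot).astype(float)
    return idx.mean(axis=0) * 2.0 + np.array(grid.bbox_min)


reference, _, _ = aligned_subject(SubjectSpec(noise="none"), grid)
reference = gaussian_smooth(reference, 8.0)
offset = hot_centroid(template) - hot_centroid(reference)
print(f"hot-region centroid offset vs aligned reference: "
      f"({offset[0]:+.2f}, {offset[1]:+.2f}, {offset[2]:+.2f}) mm, "
      f"|offset| = {np.linalg.norm(offset):.2f} mm")
print("\nA sub-voxel to few-mm offset means the anatomy-transfer chain put")
print("the striatal uptake where the atlas expects it, despite the random")
print("misalignments of the input subjects.")
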