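"""ROI definition and specific-uptake-ratio (SUR) quantification.

SUR = (mean target - mean background) / mean background, with the
striatum (caudate plus putamen) as the target region and the occipital
lobe as the low-binding background reference. Two quantification styles
are provided:

* the automatic path: spatially normalize the tracer volume to a template,
  then apply an MNI-space label atlas;
* the manual-method emulation: sum the three transverse slices with the
  greatest activity and apply supplied 2D (or collapsed 3D) masks — the
  slab protocol radiology technicians use when drawing ROIs by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from datquant.register import (
    NormalizationParams,
    RegistrationConfig,
    normalise_estimate,
    normalise_write,
)
from datquant.volume import GridSpec, VolumeImage, read_volume

COMPOSITE_REGIONS = {
    "striatum": ("caudate_L", "caudate_R", "putamen_L", "putamen_R"),
    "caudate": ("caudate_L", "caudate_R"),
    "putamen": ("putamen_L", "putamen_R"),
    "occipital": ("occipital_L", "occipital_R"),
    "background": ("occipital_L", "occipital_R"),
}


@dataclass
class LabelAtlas:
    """Integer-label volume on an MNI grid with named regions.

    ``region_map`` maps base region names (caudate_L, caudate_R,
    putamen_L, putamen_R, occipital_L, occipital_R) to label values.
    Composite names are resolved automatically: ``striatum`` is caudate
    plus putamen, ``background``/``occipital`` the union of the occipital
    labels.
    """

    labels: np.ndarray
    affine: np.ndarray
    region_map: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.labels).tolist())
        for name, labs in self.region_map.items():
            missing = set(labs) - present
            if missing:
                raise ValueError(f"region {name!r}: labels {sorted(missing)} absent from volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def resolve(self, region: str) -> tuple[int, ...]:
        if region in self.region_map:
            return tuple(self.region_map[region])
        if region in COMPOSITE_REGIONS:
            labs: list[int] = []
            for part in COMPOSITE_REGIONS[region]:
                labs.extend(self.region_map[part])
            return tuple(labs)
        raise KeyError(f"unknown region {region!r}")

    def mask(self, region: str) -> np.ndarray:
        return np.isin(self.labels, self.resolve(region))

    def as_volume(self) -> VolumeImage:
        return VolumeImage(self.labels.astype(float), self.affine, "label_atlas")


def load_label_atlas(labels_path: Union[str, Path], region_map_path: Union[str, Path]) -> LabelAtlas:
    """Load a NIfTI integer-label atlas plus a JSON name->label(s) map.

    This is how a real anatomical-labeling atlas (with its caudate,
    putamen and occipital labels) is plugged into the automatic path; the
    synthetic atlas is the shipped stand-in.
    """
    vol = read_volume(labels_path)
    rounded = np.round(vol.data)
    if not np.allclose(vol.data, rounded, atol=1e-3):
        raise ValueError(f"{labels_path} does not contain integer labels")
    raw = json.loads(Path(region_map_path).read_text())
    region_map = {
        name: tuple(v) if isinstance(v, (list, tuple)) else (int(v),)
        for name, v in raw.items()
    }
    return LabelAtlas(labels=rounded.astype(np.int32), affine=vol.affine, region_map=region_map)


@dataclass
class SURResult:
    """One SUR measurement: per-region means and their ratio."""

    subject_id: str
    method: str                       # "manual" or "auto:<template name>"
    target_mean: float
    background_mean: float
    sur: float
    params: Optional[NormalizationParams] = None
    extra: dict = field(default_factory=dict)


def compute_sur(target_mean: float, background_mean: float) -> float:
    """(target - background) / background; may legitimately be negative.

    A non-positive background mean signals a failed normalization or an
    empty reference region and raises.
    """
    if background_mean <= 0:
        raise ValueError(
            f"background mean must be > 0, got {background_mean} "
            "(failed normalization or empty reference region?)"
        )
    return (target_mean - background_mean) / background_mean


def roi_means(
    image: VolumeImage,
    atlas: LabelAtlas,
    regions: Sequence[str],
    exclude_zeros: bool = False,
) -> dict[str, float]:
    """Mean image intensity over each named atlas region.

    With ``exclude_zeros`` the exactly-zero voxels (out-of-field fill from
    reslicing) are dropped from each region before averaging; the dropped
    fraction per region is available via :func:`roi_means_detailed`.
    """
    return {k: v[0] for k, v in roi_means_detailed(image, atlas, regions, exclude_zeros).items()}


def roi_means_detailed(
    image: VolumeImage,
    atlas: LabelAtlas,
    regions: Sequence[str],
    exclude_zeros: bool = False,
) -> dict[str, tuple[float, float]]:
    """Like :func:`roi_means` but returns (mean, dropped_fraction) pairs."""
    if image.shape != atlas.shape or not np.allclose(image.affine, atlas.affine, atol=1e-4):
        raise ValueError("image and atlas are not on the identical grid")
    out: dict[str, tuple[float, float]] = {}
    for region in regions:
        mask = atlas.mask(region)
        n_total = int(mask.sum())
        values = image.data[mask]
        dropped = 0.0
        if exclude_zeros:
            nonzero = values != 0
            dropped = 1.0 - (float(nonzero.sum()) / max(n_total, 1))
            values = values[nonzero]
        if values.size == 0:
            raise ValueError(f"region {region!r} is empty after zero exclusion")
        out[region] = (float(values.mean()), dropped)
    return out


def auto_quantify(
    image: VolumeImage,
    template: VolumeImage,
    atlas: LabelAtlas,
    config: RegistrationConfig | None = None,
    subject_id: str = "",
    template_name: str = "template",
    target_region: str = "striatum",
    background_region: str = "occipital",
    exclude_zeros: bool = True,
    params: NormalizationParams | None = None,
) -> SURResult:
    """Template-normalize a tracer volume and quantify SUR with atlas ROIs.

    Normalization parameters are estimated against ``template`` (or reuse
    ``params`` when given), the image is resliced onto the atlas grid, and
    SUR is computed with the striatum as target and the occipital region
    as background. Zero-fill voxels from reslicing are excluded from the
    ROI means by default so they cannot dilute the occipital reference.
    """
    if params is None:
        params = normalise_estimate(image, template, config)
    grid = _grid_of_atlas(atlas)
    normalized = normalise_write(image, params, grid)
    means = roi_means(normalized, atlas, [target_region, background_region], exclude_zeros)
    target, background = means[target_region], means[background_region]
    return SURResult(
        subject_id=subject_id,
        method=f"auto:{template_name}",
        target_mean=target,
        background_mean=background,
        sur=compute_sur(target, background),
        params=params,
        extra={"normalized_mean": float(normalized.data.mean())},
    )


def _grid_of_atlas(atlas: LabelAtlas) -> GridSpec:
    aff = atlas.affine
    vox = np.linalg.norm(aff[:3, :3], axis=0)
    lo = aff[:3, 3]
    hi = lo + (np.asarray(atlas.shape) - 1) * vox
    return GridSpec(tuple(lo), tuple(hi), tuple(vox))


def hottest_slab(image: VolumeImage, n_slices: int = 3) -> tuple[np.ndarray, list[int]]:
    """Sum the ``n_slices`` transverse slices with the greatest activity.

    Slices are ranked by total in-slice intensity; ties resolve to the
    lower slice index. Returns the summed 2D slab and the selected
    indices (ascending).
    """
    depth = image.shape[2]
    if not 1 <= n_slices <= depth:
        raise ValueError(f"n_slices must be in [1, {depth}], got {n_slices}")
    totals = image.data.sum(axis=(0, 1))
    # stable argsort on negated totals -> ties break toward lower index
    order = np.argsort(-totals, kind="stable")
    chosen = sorted(int(i) for i in order[:n_slices])
    slab = image.data[:, :, chosen].sum(axis=2)
    return slab, chosen


def manual_slab_quantify(
    image: VolumeImage,
    target_mask: np.ndarray,
    background_mask: np.ndarray,
    n_slices: int = 3,
    subject_id: str = "",
) -> SURResult:
    """Manual-method emulation: hottest-slice slab plus supplied masks.

    Masks may be 2D (applied to the summed slab directly) or 3D (collapsed
    to 2D by union over the *selected* slices, i.e. the structure's
    footprint within the slab — the region an operator outlining the
    visible uptake would draw).
    """
    slab, chosen = hottest_slab(image, n_slices)

    def collapse(mask: np.ndarray, what: str) -> np.ndarray:
        mask = np.asarray(mask, bool)
        if mask.ndim == 3:
            if mask.shape != image.shape:
                raise ValueError(f"3D {what} mask shape {mask.shape} != image {image.shape}")
            full = mask.any(axis=2)
            mask = mask[:, :, chosen].any(axis=2)
            if not mask.any():  # structure absent from the slab: fall back to full footprint
                mask = full
        if mask.shape != slab.shape:
            raise ValueError(f"2D {what} mask shape {mask.shape} != slab {slab.shape}")
        if not mask.any():
            raise ValueError(f"{what} mask is empty")
        return mask

    tmask = collapse(target_mask, "target")
    bmask = collapse(background_mask, "background")
    target = float(slab[tmask].mean())
    background = float(slab[bmask].mean())
    return SURResult(
        subject_id=subject_id,
        method="manual",
        target_mean=target,
        background_mean=background,
        sur=compute_sur(target, background),
        extra={"slices": chosen},
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1 = identical, 0 = disjoint)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
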