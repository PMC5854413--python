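"""Volume data model, NIfTI I/O, grid algebra and basic image operators.

Conventions used throughout the package:

* world frame is MNI RAS in millimetres;
* voxel indices are 0-based; ``affine`` maps voxel index (i, j, k, 1) to
  world (x, y, z, 1);
* all transforms act on world coordinates;
* out-of-field values produced by resampling are filled with 0;
* on-disk dtype is float32, in-memory arrays are float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Bounding box of the normalized MNI grid (mm), inclusive endpoints.
DEFAULT_BBOX_MIN = (-90.0, -126.0, -72.0)
DEFAULT_BBOX_MAX = (90.0, 90.0, 108.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VolumeImage:
    """A 3D intensity volume with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity values in arbitrary count units.
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel indices to world millimetres (RAS).
    description : str
        Free-text provenance tag.
    """

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine spatial submatrix is singular")
        if np.isnan(self.data).any():
            raise ValueError("volume data contains NaN")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy(self, data: np.ndarray | None = None, description: str | None = None) -> "VolumeImage":
        return VolumeImage(
            data=self.data.copy() if data is None else data,
            affine=self.affine.copy(),
            description=self.description if description is None else description,
        )

    def same_grid(self, other: "VolumeImage", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass(frozen=True)
class GridSpec:
    """A world-aligned sampling grid defined by an inclusive bounding box.

    The grid has ``(bbox_max - bbox_min) / voxel_size + 1`` points per axis,
    with voxel (0,0,0) at ``bbox_min`` and the last voxel at ``bbox_max``.
    """

    bbox_min: tuple[float, float, float]
    bbox_max: tuple[float, float, float]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.bbox_min, dtype=float)
        hi = np.asarray(self.bbox_max, dtype=float)
        vox = np.asarray(self.voxel_size, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,) or vox.shape != (3,):
            raise ValueError("bbox_min, bbox_max and voxel_size must be length-3")
        if np.any(vox <= 0):
            raise ValueError("voxel_size must be positive")
        if np.any(hi < lo):
            raise ValueError("bbox_max must be >= bbox_min componentwise")
        steps = (hi - lo) / vox
        if not np.allclose(steps, np.round(steps), atol=1e-6):
            raise ValueError(
                f"(bbox_max - bbox_min)/voxel_size = {steps} is not integral"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        lo = np.asarray(self.bbox_min, dtype=float)
        hi = np.asarray(self.bbox_max, dtype=float)
        vox = np.asarray(self.voxel_size, dtype=float)
        return tuple(int(round(s)) + 1 for s in (hi - lo) / vox)  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.bbox_min
        return aff


def default_grid(voxel_size_mm: float = 2.0) -> GridSpec:
    """The standard normalized MNI grid: 91 x 109 x 91 at 2 mm."""
    return GridSpec(DEFAULT_BBOX_MIN, DEFAULT_BBOX_MAX, (voxel_size_mm,) * 3)


def grid_from_bbox(spec: GridSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Return (dims, affine) for a bounding-box grid.

    The affine maps voxel (0,0,0) to ``bbox_min`` and voxel ``dims - 1`` to
    ``bbox_max``; axes are world-aligned.
    """
    return spec.dims, spec.affine


def read_volume(path: Union[str, Path]) -> VolumeImage:
    """Read a single-frame NIfTI-1 volume (.nii or .nii.gz).

    The sform affine is preferred; qform is the fallback. A 4D file with a
    single frame is accepted and squeezed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(
                f"{path} has {data.shape[3]} temporal frames; expected a single 3D frame"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {data.ndim}D")
    sform, scode = img.get_sform(coded=True)
    qform, qcode = img.get_qform(coded=True)
    if scode != 0:
        affine = sform
    elif qcode != 0:
        affine = qform
    elif img.affine is not None:
        affine = img.affine
    else:
        raise ValueError(f"{path} carries no usable affine (sform/qform both unset)")
    return VolumeImage(data=data, affine=np.asarray(affine), description=str(path))


def write_volume(image: VolumeImage, path: Union[str, Path]) -> None:
    """Write a volume as NIfTI-1 (float32 on disk, sform = affine)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if np.isnan(image.data).any():
        raise ValueError("refusing to write a volume containing NaN")
    img = nib.Nifti1Image(image.data.astype(np.float32), image.affine)
    img.set_sform(image.affine, code=2)
    img.set_qform(image.affine, code=2)
    nib.save(img, str(path))


TransformLike = Union[np.ndarray, Callable[[np.ndarray], np.ndarray], None]


def _target_grid(target: Union[GridSpec, VolumeImage]) -> tuple[tuple[int, int, int], np.ndarray]:
    if isinstance(target, GridSpec):
        return target.dims, target.affine
    return target.shape, target.affine


def world_grid(target: Union[GridSpec, VolumeImage]) -> np.ndarray:
    """World coordinates of every voxel center of a grid, shape (N, 3)."""
    dims, aff = _target_grid(target)
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    return ijk @ aff[:3, :3].T + aff[:3, 3]


def sample_at_world(image: VolumeImage, xyz: np.ndarray, order: int = 1) -> np.ndarray:
    """Trilinearly sample ``image`` at world points (N, 3); outside -> 0."""
    inv = np.linalg.inv(image.affine)
    vox = xyz @ inv[:3, :3].T + inv[:3, 3]
    return ndimage.map_coordinates(
        image.data, vox.T, order=order, mode="constant", cval=0.0, prefilter=False
    )


def resample_trilinear(
    image: VolumeImage,
    target: Union[GridSpec, VolumeImage],
    transform: TransformLike = None,
) -> VolumeImage:
    """Resample ``image`` onto ``target`` through a world-to-world mapping.

    ``transform`` maps target-world points to source-world points: a 4x4
    matrix, a callable ``(N, 3) -> (N, 3)``, or None for identity. Each
    output voxel holds the trilinear interpolation of the source at the
    mapped location; locations outside the source field of view become 0.
    """
    dims, aff = _target_grid(target)
    xyz = world_grid(target)
    if transform is None:
        src_xyz = xyz
    elif callable(transform):
        src_xyz = np.asarray(transform(xyz), dtype=float)
    else:
        mat = np.asarray(transform, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("matrix transform must be 4x4")
        if abs(np.linalg.det(mat[:3, :3])) < 1e-12:
            raise ValueError("singular world-to-world transform")
        src_xyz = xyz @ mat[:3, :3].T + mat[:3, 3]
    values = sample_at_world(image, src_xyz)
    return VolumeImage(
        data=values.reshape(dims), affine=aff,
        description=f"resampled({image.description})",
    )


def gaussian_smooth(image: VolumeImage, fwhm_mm: Union[float, Sequence[float]]) -> VolumeImage:
    """Separable Gaussian smoothing with kernel width given as FWHM in mm.

    sigma(mm) = FWHM / (2 * sqrt(2 * ln 2)) per axis, converted to voxel
    units through the affine. ``fwhm_mm = 0`` is the identity.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError("fwhm_mm must be >= 0")
    if np.all(fwhm == 0):
        return image.copy()
    sigma_vox = fwhm * FWHM_TO_SIGMA / image.voxel_size
    smoothed = ndimage.gaussian_filter(image.data, sigma=sigma_vox, mode="reflect")
    return image.copy(data=smoothed, description=f"smooth{tuple(fwhm)}({image.description})")


def average_volumes(images: Sequence[VolumeImage]) -> VolumeImage:
    """Voxelwise arithmetic mean of volumes on an identical grid."""
    if len(images) == 0:
        raise ValueError("average_volumes requires at least one image")
    ref = images[0]
    for i, img in enumerate(images[1:], start=1):
        if img.shape != ref.shape:
            raise ValueError(f"image {i} shape {img.shape} != {ref.shape}")
        if not np.allclose(img.affine, ref.affine, atol=1e-4):
            raise ValueError(f"image {i} affine differs from the first image's")
    mean = np.mean([img.data for img in images], axis=0)
    return ref.copy(data=mean, description=f"mean(n={len(images)})")
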