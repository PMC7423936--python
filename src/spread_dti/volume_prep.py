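"""Containers and preprocessing for registered FA volume pairs.

An :class:`FAVolume` is a 3-D fractional-anisotropy scalar field (values in
[0, 1]) together with a boolean foreground mask and an isotropic voxel size.
A :class:`ScanPair` holds the pre- and post-season volumes of one subject on
an identical grid with a shared foreground.

Preprocessing consists of two steps applied to already co-registered pairs:

* :func:`mount_doom` — removal of edge ringing artifacts by deleting every
  foreground voxel whose Euclidean distance (mm, center-to-center) to the
  nearest background voxel is at or below a threshold (default 4 mm);
* :func:`crop_to_bbox` — cropping to the tightest axis-aligned box containing
  all nonzero-FA voxels, with the offset recorded so detections map back to
  the original grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class FAVolume:
    """A 3-D FA scalar field with foreground mask and isotropic voxel size."""

    values: np.ndarray
    foreground: np.ndarray
    voxel_size_mm: float = 2.0
    provenance: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"FA volume must be 3-D, got ndim={self.values.ndim}")
        if self.values.shape != self.foreground.shape:
            raise ValueError("values and foreground shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FA values must be finite")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        # background is structurally zero
        self.values = np.where(self.foreground, self.values, 0.0)
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ScanPair:
    """Pre/post FAVolumes of one subject on an identical grid.

    ``offset_vox`` tracks the voxel offset of this (possibly cropped) grid
    relative to the original scanner grid.
    """

    pre: FAVolume
    post: FAVolume
    subject_id: str = ""
    offset_vox: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError("pre/post shapes differ")
        if self.pre.voxel_size_mm != self.post.voxel_size_mm:
            raise ValueError("pre/post voxel sizes differ")
        if not np.array_equal(self.pre.foreground, self.post.foreground):
            raise ValueError("pre/post foreground masks differ")

    @property
    def foreground(self) -> np.ndarray:
        return self.pre.foreground

    @property
    def voxel_size_mm(self) -> float:
        return self.pre.voxel_size_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pre.shape

    def difference(self) -> np.ndarray:
        """Voxel-wise post − pre FA difference (zero outside foreground)."""
        return self.post.values - self.pre.values


def _load_scalar_volume(path) -> tuple[np.ndarray, float, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(f"{path}: anisotropic voxels {zooms} are not supported")
    return data.astype(np.float64), float(zooms[0]), np.asarray(img.affine)


def read_pair(pre_path, post_path, subject_id: str = "") -> ScanPair:
    """Read two co-registered NIfTI-1 FA volumes as a ScanPair.

    Foreground is the union of nonzero voxels of the two scans. Values are
    clamped to [0, 1]; a warning reports the number of out-of-range voxels.
    """
    pre, vs_pre, aff = _load_scalar_volume(pre_path)
    post, vs_post, _ = _load_scalar_volume(post_path)
    if pre.shape != post.shape:
        raise ValueError(f"dimension mismatch: {pre.shape} vs {post.shape}")
    if not np.isclose(vs_pre, vs_post, rtol=1e-3):
        raise ValueError(f"voxel-size mismatch: {vs_pre} vs {vs_post}")
    foreground = (pre != 0) | (post != 0)
    if not foreground.any():
        raise ValueError("empty foreground: both volumes are identically zero")
    n_clamped = int(np.sum((pre < 0) | (pre > 1)) + np.sum((post < 0) | (post > 1)))
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} out-of-range FA voxels to [0, 1]", stacklevel=2)
    pre = np.clip(pre, 0.0, 1.0)
    post = np.clip(post, 0.0, 1.0)
    return ScanPair(
        pre=FAVolume(pre, foreground, vs_pre, provenance=str(pre_path), affine=aff),
        post=FAVolume(post, foreground, vs_post, provenance=str(post_path), affine=aff),
        subject_id=subject_id,
    )


def write_pair(pair: ScanPair, pre_path, post_path) -> None:
    """Write a ScanPair as two NIfTI-1 files sharing one affine."""
    affine = pair.pre.affine
    nib.save(nib.Nifti1Image(pair.pre.values, affine), str(pre_path))
    nib.save(nib.Nifti1Image(pair.post.values, affine), str(post_path))


def background_distance_mm(foreground: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Center-to-center Euclidean distance (mm) of each voxel to the nearest
    background voxel of the given mask (0 on background itself)."""
    return ndimage.distance_transform_edt(foreground, sampling=voxel_size_mm)


def mount_doom(vol: FAVolume, threshold_mm: float = 4.0) -> FAVolume:
    """Remove edge ringing artifacts near the foreground/background boundary.

    Every foreground voxel whose Euclidean distance to the nearest background
    voxel of the *original* mask is <= ``threshold_mm`` is reassigned to
    background with value 0. Single-pass: distances are measured against the
    input background, so re-running with the same original mask is stable.
    """
    fg = vol.foreground
    if not fg.any():
        raise ValueError("mount_doom: empty foreground")
    if fg.all():
        raise ValueError("mount_doom: empty background, no boundary to measure from")
    dist = background_distance_mm(fg, vol.voxel_size_mm)
    keep = fg & (dist > threshold_mm)
    if not keep.any():
        raise ValueError(
            f"mount_doom: threshold {threshold_mm} mm removed the entire foreground "
            f"(max boundary distance {dist[fg].max():.2f} mm)"
        )
    return replace(vol, values=np.where(keep, vol.values, 0.0), foreground=keep)


def mount_doom_pair(pair: ScanPair, threshold_mm: float = 4.0) -> ScanPair:
    """Apply :func:`mount_doom` to both scans using the shared foreground."""
    pre = mount_doom(pair.pre, threshold_mm)
    post = replace(
        pair.post,
        values=np.where(pre.foreground, pair.post.values, 0.0),
        foreground=pre.foreground,
    )
    return replace(pair, pre=pre, post=post)


def crop_to_bbox(pair: ScanPair) -> ScanPair:
    """Crop both scans to the tightest box containing all nonzero-FA voxels.

    The crop is joint over both scans; the accumulated voxel offset is stored
    on the returned pair so detections can be mapped back.
    """
    nonzero = (pair.pre.values != 0) | (pair.post.values != 0)
    if not nonzero.any():
        raise ValueError("crop_to_bbox: no nonzero voxels")
    slices = ndimage.find_objects(nonzero.astype(np.int8))[0]
    offset = tuple(
        int(o + s.start) for o, s in zip(pair.offset_vox, slices)
    )

    def _crop(vol: FAVolume) -> FAVolume:
        return replace(vol, values=vol.values[slices], foreground=vol.foreground[slices])

    return ScanPair(
        pre=_crop(pair.pre), post=_crop(pair.post),
        subject_id=pair.subject_id, offset_vox=offset,  # type: ignore[arg-type]
    )
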