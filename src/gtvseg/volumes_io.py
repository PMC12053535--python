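"""NIfTI volume/mask IO, grid resampling, and original-grid restoration.

Conventions used throughout the package:

* voxel indices are 0-based and axis order is ``(x, y, z)``, matching the
  order of the NIfTI header spacing;
* every image is reoriented to the closest canonical (RAS) orientation on
  read, so patch coordinates are unambiguous; ``origin_meta`` records what is
  needed to restore the source grid and orientation exactly on write;
* intensities are held as 32-bit floats in memory regardless of the on-disk
  dtype; label masks are small unsigned integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from nibabel import orientations as nio
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMask",
    "MissingFileError",
    "NonVolumetricImageError",
    "HeaderReadError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample",
    "restore_to_origin",
]


class MissingFileError(FileNotFoundError):
    """The given path does not name a readable file."""


class NonVolumetricImageError(ValueError):
    """The image on disk is not a 3D volume."""


class HeaderReadError(ValueError):
    """The file exists but its header cannot be parsed as NIfTI."""


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and source-grid metadata.

    Parameters
    ----------
    data
        3D float32 array of intensities in arbitrary (scanner) units.
    spacing
        Voxel size in mm per axis, strictly positive.
    origin_meta
        Opaque record of the source grid (shape, spacing, affine, and the
        orientation transform back to the on-disk axes). ``None`` for
        volumes created in memory.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin_meta: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise NonVolumetricImageError(
                f"volume data must be 3D with all dims >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """A 3D integer mask over {0=background, 1=GTVp, 2=GTVn}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin_meta: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("label mask contains fractional values")
            arr = rounded.astype(np.uint8)
        self.labels = arr.astype(np.uint8, copy=False)
        if self.labels.ndim != 3:
            raise NonVolumetricImageError(
                f"mask must be 3D, got shape {self.labels.shape}"
            )
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _load_canonical(path):
    p = Path(path)
    if not p.is_file():
        raise MissingFileError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
        img_canon = nib.as_closest_canonical(img)
        data = np.asanyarray(img_canon.dataobj)
    except MissingFileError:
        raise
    except Exception as exc:  # malformed header / truncated file
        raise HeaderReadError(f"cannot read NIfTI header of {p}: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise NonVolumetricImageError(
            f"{p} is a {data.ndim}D image; only 3D volumes are supported"
        )
    spacing = tuple(float(z) for z in img_canon.header.get_zooms()[:3])
    # orientation transform mapping canonical axes back to the on-disk axes
    src_ornt = nio.io_orientation(img.affine)
    canon_ornt = nio.axcodes2ornt(("R", "A", "S"))
    from_canonical = nio.ornt_transform(canon_ornt, src_ornt)
    meta = {
        "shape": tuple(int(s) for s in data.shape),
        "spacing": spacing,
        "affine": np.asarray(img_canon.affine, dtype=np.float64),
        "source_affine": np.asarray(img.affine, dtype=np.float64),
        "from_canonical": from_canonical,
    }
    return data, spacing, meta


def read_volume(path) -> Volume:
    """Read a 3D NIfTI image into a canonically oriented :class:`Volume`.

    Raises
    ------
    MissingFileError, NonVolumetricImageError, HeaderReadError
    """
    data, spacing, meta = _load_canonical(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing, meta)


def read_mask(path) -> LabelMask:
    """Read a 3D integer NIfTI mask into a :class:`LabelMask`."""
    data, spacing, meta = _load_canonical(path)
    return LabelMask(np.asarray(data), spacing, meta)


def _write(data: np.ndarray, spacing, origin_meta, path) -> None:
    if origin_meta is not None:
        affine = origin_meta["source_affine"]
        data = nio.apply_orientation(data, origin_meta["from_canonical"])
    else:
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms([float(abs(s)) for s in nib.affines.voxel_sizes(affine)])
    nib.save(img, str(path))


def write_volume(v: Volume, path) -> None:
    """Write a volume as float32 NIfTI, restoring the source orientation."""
    _write(v.data.astype(np.float32), v.spacing, v.origin_meta, path)


def write_mask(m: LabelMask, path) -> None:
    """Write a label mask as uint8 NIfTI, restoring the source orientation."""
    _write(m.labels.astype(np.uint8), m.spacing, m.origin_meta, path)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _resample_grid(data, in_spacing, out_shape, out_spacing, order):
    """Resample onto an explicit output grid (corner-aligned voxel centers)."""
    coords = np.meshgrid(
        *[
            np.arange(n, dtype=np.float64) * (ts / s)
            for n, ts, s in zip(out_shape, out_spacing, in_spacing)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest")


def resample(v, target_spacing):
    """Resample a :class:`Volume` (linear) or :class:`LabelMask` (nearest).

    The output shape per axis is ``round(shape * spacing / target_spacing)``
    with ties rounded away from zero, minimum 1. ``origin_meta`` is carried
    over from the source so the original grid can be restored later.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be 3 positive values, got {target_spacing}")
    is_mask = isinstance(v, LabelMask)
    data = v.labels if is_mask else v.data
    out_shape = tuple(
        int(max(1, _round_half_away(n * s / ts)))
        for n, s, ts in zip(data.shape, v.spacing, target_spacing)
    )
    if out_shape == data.shape and tuple(v.spacing) == target_spacing:
        return replace(v)
    if is_mask:
        out = _resample_grid(data, v.spacing, out_shape, target_spacing, order=0)
        return LabelMask(out.astype(np.uint8), target_spacing, v.origin_meta)
    out = _resample_grid(data.astype(np.float64), v.spacing, out_shape, target_spacing, order=1)
    return Volume(out.astype(np.float32), target_spacing, v.origin_meta)


def restore_to_origin(m: LabelMask) -> LabelMask:
    """Resample a mask back onto its source grid (nearest-neighbor only)."""
    if m.origin_meta is None:
        raise ValueError("mask has no origin_meta; cannot restore the source grid")
    out_shape = tuple(m.origin_meta["shape"])
    out_spacing = tuple(m.origin_meta["spacing"])
    if m.shape == out_shape and tuple(m.spacing) == out_spacing:
        return replace(m)
    out = _resample_grid(m.labels, m.spacing, out_shape, out_spacing, order=0)
    return LabelMask(out.astype(np.uint8), out_spacing, m.origin_meta)
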