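"""Training-patch extraction and z-score intensity normalization.

Two normalization modes exist deliberately. *Patch-wise* normalization
(the default) z-scores intensities after patch extraction, so every model
input has mean 0 / sd 1 regardless of the scanner's intensity scale — this
is the mechanism that removes inter-scan intensity shifts and the
location-dependence of patch statistics. *Image-wise* normalization
(:func:`normalize_image`) z-scores the whole volume before patching and is
kept as the comparison baseline: patches extracted from an image-wise
normalized volume have means that vary with patch location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import LabelMask, Volume

__all__ = [
    "PatchSpec",
    "sample_patch_spec",
    "extract_patch",
    "normalize_patch",
    "normalize_image",
    "pad_to_size",
]

#: default training patch extent in voxels (x, y, z)
DEFAULT_PATCH_SIZE = (320, 320, 64)


@dataclass(frozen=True)
class PatchSpec:
    """Location and size of one patch on a (padded) volume grid.

    ``start`` is the 0-based inclusive corner voxel; the patch covers
    ``start[a] .. start[a] + size[a] - 1`` on each axis.
    """

    start: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self):
        if any(s < 0 for s in self.start):
            raise ValueError(f"patch start must be >= 0, got {self.start}")
        if any(s < 1 for s in self.size):
            raise ValueError(f"patch size must be >= 1, got {self.size}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, a + s) for a, s in zip(self.start, self.size))


def _padding(shape, size):
    """Symmetric padding taking each axis up to at least the patch size."""
    pads = []
    for n, s in zip(shape, size):
        missing = max(0, s - n)
        pads.append((missing // 2, missing - missing // 2))
    return pads


def pad_to_size(arr: np.ndarray, size, value=0):
    """Zero-pad ``arr`` symmetrically so every axis is >= ``size``."""
    pads = _padding(arr.shape, size)
    if any(lo or hi for lo, hi in pads):
        arr = np.pad(arr, pads, mode="constant", constant_values=value)
    return arr


def sample_patch_spec(
    mask: LabelMask,
    size=DEFAULT_PATCH_SIZE,
    target_fraction: float = 0.9,
    rng: np.random.Generator | None = None,
) -> PatchSpec:
    """Sample a patch position with the stated target-class bias.

    With probability ``target_fraction`` the patch is forced to contain at
    least one GTVp/GTVn voxel: a target class is drawn uniformly among the
    classes present, then a voxel of that class uniformly, then the patch
    start uniformly among the starts covering it. (Class-balanced voxel
    choice keeps the small nodal lesions from being starved by the much
    larger primary volume.) Otherwise — and always when the mask has no
    target voxels — the start is uniform over all valid positions.
    Positions refer to the symmetrically zero-padded grid used by
    :func:`extract_patch`.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in [0,1], got {target_fraction}")
    rng = np.random.default_rng() if rng is None else rng
    size = tuple(int(s) for s in size)
    pads = _padding(mask.shape, size)
    padded = tuple(n + lo + hi for n, (lo, hi) in zip(mask.shape, pads))
    if any(s > p for s, p in zip(size, padded)):
        raise ValueError(f"patch size {size} exceeds padded volume shape {padded}")

    present = [c for c in (1, 2) if (mask.labels == c).any()]
    if present and rng.random() < target_fraction:
        cls = present[rng.integers(len(present))]
        class_idx = np.argwhere(mask.labels == cls)
        vox = class_idx[rng.integers(len(class_idx))]
        start = []
        for a in range(3):
            v = int(vox[a]) + pads[a][0]  # voxel index on the padded grid
            lo = max(0, v - size[a] + 1)
            hi = min(v, padded[a] - size[a])
            start.append(int(rng.integers(lo, hi + 1)))
        return PatchSpec(tuple(start), size)

    start = tuple(int(rng.integers(0, padded[a] - size[a] + 1)) for a in range(3))
    return PatchSpec(start, size)


def extract_patch(v, spec: PatchSpec) -> np.ndarray:
    """Extract the sub-array given by ``spec``.

    Accepts a :class:`Volume`, :class:`LabelMask`, or bare 3D array.
    Volumes smaller than the patch are zero-padded symmetrically first.
    """
    if isinstance(v, Volume):
        arr = v.data
    elif isinstance(v, LabelMask):
        arr = v.labels
    else:
        arr = np.asarray(v)
    arr = pad_to_size(arr, spec.size)
    if any(a + s > n for a, s, n in zip(spec.start, spec.size, arr.shape)):
        raise ValueError(
            f"patch {spec} out of bounds for padded shape {arr.shape}"
        )
    return arr[spec.slices].copy()


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Z-score a patch to mean 0 / sd 1 (population convention).

    A constant patch (zero variance — e.g. a fully padded corner) maps to
    all zeros rather than raising.
    """
    patch = np.asarray(patch, dtype=np.float32)
    if patch.size == 0:
        raise ValueError("empty patch")
    mean = patch.mean(dtype=np.float64)
    sd = patch.std(dtype=np.float64)
    if sd == 0:
        return np.zeros_like(patch)
    return ((patch - mean) / sd).astype(np.float32)


def normalize_image(v: Volume) -> Volume:
    """Whole-volume z-score (the image-wise baseline mode)."""
    return Volume(normalize_patch(v.data), v.spacing, v.origin_meta)
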