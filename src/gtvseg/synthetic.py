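"""Synthetic T2w-like phantoms with two lesion classes, and patient-wise folds.

The generator emulates the properties of head-and-neck MRI that this
package's methods target, not anatomy: a smooth band-limited background
"tissue" field; zero or one bright primary-tumor lesion (GTVp, label 1)
and zero or more nodal lesions (GTVn, label 2) as ellipsoids with distinct
intensity contrast; a smooth multiplicative bias field; a per-image global
intensity scale/shift (MRI's non-standardized intensity scale — the reason
z-score normalization matters); and additive Gaussian noise. Paired
pre-/mid-treatment phantoms share lesion geometry with the mid lesions
shrunk isotropically, mimicking treatment response, and draw independent
intensity corruptions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes_io import LabelMask, Volume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_paired_phantom",
    "make_folds",
    "make_cohort",
]

#: default lesion intensity contrast relative to the background mean
GTVP_CONTRAST = 0.30
GTVN_CONTRAST = 0.50


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scan.

    ``intensity_scale``/``intensity_shift`` apply a global affine map to
    the finished image, emulating scanner-dependent intensity scales.
    ``bias_amplitude`` is the relative amplitude of the smooth
    multiplicative field; ``noise_sd`` the additive noise level relative
    to the background mean.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_gtvp: int = 1
    n_gtvn: int = 1
    intensity_shift: float = 0.0
    intensity_scale: float = 1.0
    bias_amplitude: float = 0.2
    noise_sd: float = 0.05
    gtvp_contrast: float = GTVP_CONTRAST
    gtvn_contrast: float = GTVN_CONTRAST
    seed: int = 0

    def __post_init__(self):
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")
        if self.n_gtvp not in (0, 1):
            raise ValueError("n_gtvp must be 0 or 1")
        if self.n_gtvn < 0:
            raise ValueError("n_gtvn must be >= 0")


def _smooth_field(shape, grid, rng):
    coarse = rng.normal(size=(grid,) * 3)
    f = ndimage.zoom(coarse, [s / grid for s in shape], order=3)
    f = f[tuple(slice(0, s) for s in shape)]
    pads = [(0, s - fs) for s, fs in zip(shape, f.shape)]
    if any(hi for _, hi in pads):
        f = np.pad(f, pads, mode="edge")
    return f / max(1e-12, np.abs(f).max())


def _ellipsoid_mask(shape, center, semi_axes):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


#: ellipsoid semi-axis fractions of the volume extent per class; the
#: primary tumor is one large, central mass while nodal lesions are small
#: and peripheral, so the classes stay distinguishable by size/position
#: even after patch-wise normalization removes absolute intensity
_LESION_GEOMETRY = {
    1: {"xy": (0.10, 0.15), "z": (0.12, 0.20), "central": True},
    2: {"xy": (0.05, 0.09), "z": (0.08, 0.12), "central": False},
}


def _draw_lesions(spec: PhantomSpec, rng, max_tries: int = 200):
    """Sample disjoint ellipsoid parameter records (class, center, semi-axes)."""
    lesions = []
    occupied = np.zeros(spec.shape, dtype=bool)
    wanted = [(1, spec.gtvp_contrast)] * spec.n_gtvp + [(2, spec.gtvn_contrast)] * spec.n_gtvn
    for label, contrast in wanted:
        geom = _LESION_GEOMETRY[label]
        for _ in range(max_tries):
            semi = np.array(
                [
                    rng.uniform(*geom["xy"]) * spec.shape[0],
                    rng.uniform(*geom["xy"]) * spec.shape[1],
                    rng.uniform(*geom["z"]) * spec.shape[2],
                ]
            )
            if geom["central"]:
                center = np.array(
                    [rng.uniform(n / 3, 2 * n / 3) for n in spec.shape]
                )
            else:
                center = np.array(
                    [rng.uniform(1.5 * a, n - 1 - 1.5 * a) for a, n in zip(semi, spec.shape)]
                )
            mask = _ellipsoid_mask(spec.shape, center, semi)
            if not (mask & occupied).any():
                occupied |= mask
                lesions.append({"label": label, "contrast": contrast,
                                "center": center, "semi_axes": semi})
                break
        else:
            raise RuntimeError(
                f"could not place a disjoint class-{label} lesion after {max_tries} tries"
            )
    return lesions


def _build(spec: PhantomSpec, lesions, anatomy_rng, corrupt_rng):
    """Deterministically assemble image + mask from a lesion record list."""
    background = 1.0 + 0.15 * _smooth_field(spec.shape, 6, anatomy_rng)
    background = np.clip(background, 0.1, None)
    bg_mean = float(background.mean())

    img = background.copy()
    labels = np.zeros(spec.shape, dtype=np.uint8)
    for les in lesions:
        mask = _ellipsoid_mask(spec.shape, les["center"], les["semi_axes"])
        img[mask] += les["contrast"] * bg_mean
        labels[mask] = les["label"]

    bias = 1.0 + spec.bias_amplitude * _smooth_field(spec.shape, 4, corrupt_rng)
    img = img * bias
    img = spec.intensity_scale * img + spec.intensity_shift
    img = img + corrupt_rng.normal(
        0.0, spec.noise_sd * bg_mean * spec.intensity_scale, size=spec.shape
    )
    return (
        Volume(img.astype(np.float32), spec.spacing),
        LabelMask(labels, spec.spacing),
    )


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Generate one phantom scan and its label mask, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    lesions = _draw_lesions(spec, rng)
    return _build(spec, lesions, anatomy_rng=np.random.default_rng(spec.seed + 10_000),
                  corrupt_rng=rng)


def generate_paired_phantom(
    spec: PhantomSpec, shrink: float = 0.7
) -> tuple[Volume, LabelMask, Volume, LabelMask]:
    """Generate a registered pre-/mid-treatment pair on one voxel grid.

    The mid scan shares the pre scan's anatomy and lesion geometry with
    every lesion's semi-axes scaled by ``shrink`` (volume scales as
    ``shrink**3``; ``shrink = 0`` removes the lesions entirely), and draws
    independent bias/noise/scale corruptions.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    lesions = _draw_lesions(spec, rng)
    anatomy_seed = spec.seed + 10_000
    pre = _build(spec, lesions, np.random.default_rng(anatomy_seed), rng)
    if shrink == 0.0:
        mid_lesions = []
    else:
        mid_lesions = [dict(l, semi_axes=l["semi_axes"] * shrink) for l in lesions]
    mid_rng = np.random.default_rng(spec.seed + 20_000)
    mid_spec = replace(
        spec,
        intensity_scale=spec.intensity_scale * mid_rng.uniform(0.7, 1.4),
        intensity_shift=spec.intensity_shift + mid_rng.uniform(-0.1, 0.1),
    )
    mid = _build(mid_spec, mid_lesions, np.random.default_rng(anatomy_seed), mid_rng)
    return pre[0], pre[1], mid[0], mid[1]


def make_folds(patient_ids, k: int = 5, seed: int = 0) -> dict:
    """Partition patients into ``k`` near-equal folds, deterministic per seed.

    Every patient (and hence every one of their images) lands in exactly
    one fold; fold sizes differ by at most one.
    """
    ids = list(dict.fromkeys(patient_ids))  # unique, order-preserving
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"{len(ids)} patients cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(len(ids))
    return {ids[int(i)]: int(pos % k) for pos, i in enumerate(order)}


def make_cohort(
    out_dir,
    n_patients: int = 6,
    k_folds: int = 3,
    shape=(96, 96, 48),
    spacing=(1.0, 1.0, 2.0),
    seed: int = 0,
    scale_range=(0.5, 5.0),
    shift_range=(-0.5, 0.5),
    gtvp_contrast: float = GTVP_CONTRAST,
    gtvn_contrast: float = GTVN_CONTRAST,
) -> Path:
    """Write a phantom cohort: one image/mask NIfTI pair per patient plus
    ``folds.csv``. Per-image intensity scale/shift are drawn from wide
    ranges so whole-image statistics differ strongly across the cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ids = [f"patient_{i:03d}" for i in range(n_patients)]
    for i, pid in enumerate(ids):
        spec = PhantomSpec(
            shape=tuple(shape),
            spacing=tuple(spacing),
            n_gtvp=int(rng.random() < 0.9),
            n_gtvn=int(rng.integers(1, 3)),
            intensity_scale=float(np.exp(rng.uniform(*np.log(scale_range)))),
            intensity_shift=float(rng.uniform(*shift_range)),
            gtvp_contrast=gtvp_contrast,
            gtvn_contrast=gtvn_contrast,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, mask = generate_phantom(spec)
        write_volume(vol, out / f"{pid}_img.nii.gz")
        write_mask(mask, out / f"{pid}_mask.nii.gz")
    folds = make_folds(ids, k=k_folds, seed=seed)
    with open(out / "folds.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "fold"])
        for pid in ids:
            w.writerow([pid, folds[pid]])
    return out


def make_paired_cohort(
    out_dir,
    n_patients: int = 6,
    k_folds: int = 3,
    shape=(96, 96, 48),
    spacing=(1.0, 1.0, 2.0),
    seed: int = 0,
    scale_range=(0.5, 5.0),
    shift_range=(-0.5, 0.5),
    shrink_range=(0.3, 0.9),
    gtvp_contrast: float = GTVP_CONTRAST,
    gtvn_contrast: float = GTVN_CONTRAST,
) -> Path:
    """Write a pre-/mid-treatment cohort for the prior-guided (Task-2) mode.

    Per patient: ``<pid>_pre_img``, ``<pid>_pre_mask``, ``<pid>_mid_img``,
    ``<pid>_mid_mask`` (all NIfTI, registered by construction) plus
    ``folds.csv``. Mid lesions are shrunk by a per-patient factor drawn
    from ``shrink_range``, emulating treatment response.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ids = [f"patient_{i:03d}" for i in range(n_patients)]
    for pid in ids:
        spec = PhantomSpec(
            shape=tuple(shape),
            spacing=tuple(spacing),
            n_gtvp=int(rng.random() < 0.9),
            n_gtvn=int(rng.integers(1, 3)),
            intensity_scale=float(np.exp(rng.uniform(*np.log(scale_range)))),
            intensity_shift=float(rng.uniform(*shift_range)),
            gtvp_contrast=gtvp_contrast,
            gtvn_contrast=gtvn_contrast,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        shrink = float(rng.uniform(*shrink_range))
        pre_v, pre_m, mid_v, mid_m = generate_paired_phantom(spec, shrink=shrink)
        write_volume(pre_v, out / f"{pid}_pre_img.nii.gz")
        write_mask(pre_m, out / f"{pid}_pre_mask.nii.gz")
        write_volume(mid_v, out / f"{pid}_mid_img.nii.gz")
        write_mask(mid_m, out / f"{pid}_mid_mask.nii.gz")
    folds = make_folds(ids, k=k_folds, seed=seed)
    with open(out / "folds.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "fold"])
        for pid in ids:
            w.writerow([pid, folds[pid]])
    return out
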