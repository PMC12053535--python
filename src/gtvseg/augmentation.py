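"""Training-time transforms and the scheduled probability policy.

Six transforms are available — mirroring, in-plane rotation, gamma
contrast adjustment, a smooth multiplicative bias field, motion-artifact
imitation (ghosting along one axis), and additive Gaussian noise. During
training each fires independently with the same probability ``p``, and ``p``
itself follows a schedule rising linearly from ``p_start`` to ``p_end``
over the run, adjusted every ``block`` batches — more synthetic variety
late in training, when overfitting is the dominant risk.

Spatial transforms are applied identically to the image and the label
patch (labels via nearest-neighbor, so the label set never grows);
intensity transforms touch the image only. Augmentation is applied before
patch normalization, so injected noise/bias statistics are re-standardized
by the z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ScheduleState", "AugmentConfig", "schedule_probability", "apply_augmentations"]


@dataclass
class ScheduleState:
    """Position of a training run within the augmentation schedule."""

    iteration: int
    total_iterations: int
    p_start: float = 0.05
    p_end: float = 0.25
    block: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.p_start <= self.p_end <= 1.0:
            raise ValueError("need 0 <= p_start <= p_end <= 1")
        if self.block < 1 or self.total_iterations < self.block:
            raise ValueError("need block >= 1 and total_iterations >= block")


@dataclass
class AugmentConfig:
    """Per-transform enable flags and parameter ranges.

    The ranges are conventional choices (they are not pinned by any
    published protocol): rotations are in-plane and uniform in ±15°, gamma
    contrast in [0.8, 1.25], bias-field relative amplitude 0.3, ghosting
    weight up to 0.3, additive noise sd up to 0.1 of the patch sd.
    """

    mirror: bool = True
    rotation: bool = True
    contrast: bool = True
    bias_field: bool = True
    motion: bool = True
    noise: bool = True

    mirror_axes: tuple[int, ...] = (0, 1, 2)
    rotation_max_deg: float = 15.0
    gamma_range: tuple[float, float] = (0.8, 1.25)
    bias_amplitude: float = 0.3
    bias_grid: int = 4
    motion_max_weight: float = 0.3
    noise_max_sd: float = 0.1

    p_start: float = 0.05
    p_end: float = 0.25
    block: int = 1000

    @property
    def enabled(self) -> tuple[str, ...]:
        return tuple(
            t for t in ("mirror", "rotation", "contrast", "bias_field", "motion", "noise")
            if getattr(self, t)
        )


def schedule_probability(s: ScheduleState) -> float:
    """Piecewise-constant per-transform probability at ``s.iteration``.

    With ``k = iteration // block`` and ``K = total_iterations // block``
    the probability is ``p_start + (p_end - p_start) * k / (K - 1)`` —
    constant within each block, non-decreasing, and attaining both
    endpoints (the first block yields exactly ``p_start``, the last exactly
    ``p_end``).
    """
    if not 0 <= s.iteration < s.total_iterations:
        raise ValueError(
            f"iteration {s.iteration} outside [0, {s.total_iterations})"
        )
    k = s.iteration // s.block
    n_blocks = s.total_iterations // s.block
    if n_blocks == 1:
        return float(s.p_start)
    # iterations in a ragged final partial block belong to the last full block
    k = min(k, n_blocks - 1)
    return float(s.p_start + (s.p_end - s.p_start) * k / (n_blocks - 1))


# ---------------------------------------------------------------------------
# individual transforms
#
# each operates on a channel-first stack (C, X, Y, Z) plus the label patch;
# `ich` lists the intensity (image) channels — spatial transforms move every
# channel identically (binary channels via nearest-neighbor), intensity
# transforms touch only the image channels, with parameters drawn once so
# all channels see the same corruption


def _mirror(stack, mask, cfg, rng, ich):
    for ax in cfg.mirror_axes:
        stack = np.flip(stack, axis=ax + 1)
        mask = np.flip(mask, axis=ax)
    return np.ascontiguousarray(stack), np.ascontiguousarray(mask)


def _rotation(stack, mask, cfg, rng, ich):
    angle = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)
    out = np.empty_like(stack)
    for c in range(stack.shape[0]):
        if c in ich:
            out[c] = ndimage.rotate(stack[c], angle, axes=(0, 1), reshape=False,
                                    order=1, mode="nearest")
        else:
            out[c] = ndimage.rotate(stack[c], angle, axes=(0, 1), reshape=False,
                                    order=0, mode="constant", cval=0)
    mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False, order=0,
                          mode="constant", cval=0)
    return out, mask


def _contrast(stack, mask, cfg, rng, ich):
    gamma = rng.uniform(*cfg.gamma_range)
    stack = stack.copy()
    for c in ich:
        img = stack[c]
        lo, hi = float(img.min()), float(img.max())
        if hi - lo < 1e-12:
            continue
        x = (img - lo) / (hi - lo)
        stack[c] = x**gamma * (hi - lo) + lo
    return stack, mask


def _smooth_field(shape, grid, rng):
    coarse = rng.uniform(-1.0, 1.0, size=(grid,) * 3)
    zoom = [s / grid for s in shape]
    f = ndimage.zoom(coarse, zoom, order=3)
    # zoom can come out one voxel off on ragged ratios; crop/pad to shape
    f = f[tuple(slice(0, s) for s in shape)]
    pads = [(0, s - fs) for s, fs in zip(shape, f.shape)]
    if any(hi for _, hi in pads):
        f = np.pad(f, pads, mode="edge")
    return f


def _bias_field(stack, mask, cfg, rng, ich):
    f = _smooth_field(stack.shape[1:], cfg.bias_grid, rng)
    peak = max(1e-12, np.abs(f).max())
    field = 1.0 + cfg.bias_amplitude * f / peak
    stack = stack.copy()
    for c in ich:
        stack[c] = stack[c] * field
    return stack, mask


def _motion(stack, mask, cfg, rng, ich):
    axis = int(rng.integers(0, 3))
    max_shift = max(1, stack.shape[axis + 1] // 8)
    shift = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
    w = rng.uniform(0.1, cfg.motion_max_weight)
    stack = stack.copy()
    for c in ich:
        ghost = np.roll(stack[c], shift, axis=axis)
        stack[c] = (1.0 - w) * stack[c] + w * ghost
    return stack, mask


def _noise(stack, mask, cfg, rng, ich):
    stack = stack.copy()
    for c in ich:
        sd = rng.uniform(0.0, cfg.noise_max_sd) * max(1e-12, float(stack[c].std()))
        stack[c] = stack[c] + rng.normal(0.0, sd, size=stack[c].shape)
    return stack, mask


_TRANSFORMS = {
    "mirror": _mirror,
    "rotation": _rotation,
    "contrast": _contrast,
    "bias_field": _bias_field,
    "motion": _motion,
    "noise": _noise,
}


def apply_augmentations(
    patch: np.ndarray,
    mask_patch: np.ndarray,
    p: float,
    rng: np.random.Generator,
    cfg: AugmentConfig | None = None,
    return_info: bool = False,
    intensity_channels=None,
):
    """Apply each enabled transform independently with probability ``p``.

    ``patch`` is a 3D array or a channel-first ``(C, X, Y, Z)`` stack (the
    prior-guided four-channel mode); ``intensity_channels`` selects the
    channels that receive intensity transforms (default: all) — the other
    channels (binary priors) are moved spatially via nearest-neighbor and
    otherwise left untouched. Returns ``(patch, mask_patch)``, or
    ``(patch, mask_patch, fired)`` with ``return_info=True`` where
    ``fired`` lists the transforms applied. With ``p = 0`` the inputs are
    returned unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0,1], got {p}")
    single = np.ndim(patch) == 3
    stack = np.asarray(patch, dtype=np.float32)
    if single:
        stack = stack[None]
    if stack.shape[1:] != np.shape(mask_patch):
        raise ValueError(
            f"patch/mask shape mismatch: {stack.shape[1:]} vs {np.shape(mask_patch)}"
        )
    ich = set(range(stack.shape[0])) if intensity_channels is None else set(intensity_channels)
    cfg = AugmentConfig() if cfg is None else cfg
    mask = np.asarray(mask_patch)
    fired = []
    for name in cfg.enabled:
        if rng.random() < p:
            stack, mask = _TRANSFORMS[name](stack, mask, cfg, rng, ich)
            fired.append(name)
    mask = mask.astype(mask_patch.dtype, copy=False)
    out = stack[0] if single else stack
    if return_info:
        return out, mask, fired
    return out, mask
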