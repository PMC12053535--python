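"""Training loop, configuration, and Task-2 input assembly.

The loop reproduces the method's training procedure at configurable
scale: patches sampled with a 90/10 target-class bias, augmented at the
scheduled probability, z-scored patch-wise, optimized with Adam under a
cosine-decayed learning rate on the present-class batch Dice loss, with
periodic sliding-window validation; the checkpoint with the best
validation mean DSCagg over the tumor classes is retained.
"""

from __future__ import annotations

import csv
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._nn import Adam, dice_loss_and_grad
from .augmentation import AugmentConfig, ScheduleState, apply_augmentations, schedule_probability
from .inference import gaussian_weight_map, labels_from_probs, sliding_window_predict, uniform_weight_map
from .losses_metrics import dsc_agg
from .network import NetworkConfig, UNet3D, build_unet, save_checkpoint
from .patching import extract_patch, normalize_patch, sample_patch_spec
from .volumes_io import LabelMask, Volume, read_mask, read_volume, resample

__all__ = ["TrainConfig", "TrainResult", "cosine_lr", "train", "task2_inputs", "load_cohort"]


@dataclass
class TrainConfig:
    """Everything a training run needs, nested sub-configs included.

    The full-scale protocol (100K iterations, batch size 2, patch
    320×320×64, lr 1e-3 → 1e-5) is expressed by the defaults of the
    individual fields; the toy defaults here are desk-scale so a run
    finishes in minutes on one CPU.
    """

    task_mode: str = "task1"
    iterations: int = 2000
    batch_size: int = 2
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    eval_every: int = 500
    seed: int = 0
    patch_size: tuple[int, int, int] = (32, 32, 16)
    fg_fraction: float = 0.9
    normalize: str = "patch"  # "patch" | "image"
    weighting: str = "gaussian"  # "gaussian" | "uniform"
    edge_value: float = 0.1
    stride: tuple[int, int, int] | None = None
    working_spacing: tuple[float, float, float] | None = None
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(base_width=4, n_stages=3, kernel_by_stage=[3, 3, 3])
    )
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be >= 1")
        if not self.lr_start >= self.lr_end > 0:
            raise ValueError("need lr_start >= lr_end > 0")
        if self.task_mode not in ("task1", "task2"):
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        if self.normalize not in ("patch", "image"):
            raise ValueError(f"normalize must be 'patch' or 'image', got {self.normalize!r}")
        if isinstance(self.network, dict):
            self.network = NetworkConfig(**self.network)
        if isinstance(self.augment, dict):
            self.augment = AugmentConfig(**self.augment)
        self.patch_size = tuple(self.patch_size)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TrainResult:
    """Fitted model, its best checkpoint, and the training history."""

    model: UNet3D
    best_state: list
    best_score: float
    history: pd.DataFrame
    checkpoint_path: Path | None = None

    def restore_best(self) -> UNet3D:
        self.model.load_state_arrays(self.best_state)
        return self.model


def cosine_lr(iteration: int, total: int, lr_start: float = 1e-3, lr_end: float = 1e-5) -> float:
    """Cosine-decayed learning rate from ``lr_start`` down to ``lr_end``."""
    if not 0 <= iteration <= total:
        raise ValueError(f"iteration {iteration} outside [0, {total}]")
    return lr_end + (lr_start - lr_end) * (1.0 + np.cos(np.pi * iteration / total)) / 2.0


def task2_inputs(mid: Volume, pre_reg: Volume, pre_mask: LabelMask) -> np.ndarray:
    """Stack the four Task-2 input channels on one grid.

    Channels: mid-treatment image, registered pre-treatment image, and the
    two binary prior masks (GTVp, GTVn) from the pre-treatment ground
    truth. Downstream normalization must touch only channels 0–1 (pass
    ``normalize_channels=(0, 1)``); the binary channels stay as-is.
    """
    if mid.shape != pre_reg.shape or mid.shape != pre_mask.shape:
        raise ValueError(
            f"grid mismatch: {mid.shape} / {pre_reg.shape} / {pre_mask.shape}"
        )
    return np.stack(
        [
            mid.data,
            pre_reg.data,
            (pre_mask.labels == 1).astype(np.float32),
            (pre_mask.labels == 2).astype(np.float32),
        ]
    )


def load_cohort(cohort_dir, working_spacing=None, paired: bool = False):
    """Load a cohort directory written by the synthetic cohort writers.

    Returns ``(records, folds)``. For the plain (Task-1) layout each record
    holds the patient id, its volume, its mask, and ``net_input`` (the
    volume's data). With ``paired=True`` the pre-/mid-treatment layout is
    read instead and ``net_input`` is the four-channel stack
    ``[mid, pre, pre GTVp, pre GTVn]`` from :func:`task2_inputs`, with the
    mid-treatment mask as the target.
    """
    cohort = Path(cohort_dir)
    folds_csv = cohort / "folds.csv"
    if not folds_csv.is_file():
        raise FileNotFoundError(f"no folds.csv in {cohort}")
    with open(folds_csv) as fh:
        folds = {row["patient_id"]: int(row["fold"]) for row in csv.DictReader(fh)}
    if not folds:
        raise ValueError(f"empty cohort: no patients listed in {folds_csv}")
    records = []
    for pid in sorted(folds):
        if paired:
            mid = read_volume(cohort / f"{pid}_mid_img.nii.gz")
            pre = read_volume(cohort / f"{pid}_pre_img.nii.gz")
            pre_mask = read_mask(cohort / f"{pid}_pre_mask.nii.gz")
            mask = read_mask(cohort / f"{pid}_mid_mask.nii.gz")
            if working_spacing is not None:
                mid = resample(mid, working_spacing)
                pre = resample(pre, working_spacing)
                pre_mask = resample(pre_mask, working_spacing)
                mask = resample(mask, working_spacing)
            records.append({
                "patient_id": pid, "volume": mid, "mask": mask,
                "net_input": task2_inputs(mid, pre, pre_mask),
            })
        else:
            vol = read_volume(cohort / f"{pid}_img.nii.gz")
            mask = read_mask(cohort / f"{pid}_mask.nii.gz")
            if working_spacing is not None:
                vol = resample(vol, working_spacing)
                mask = resample(mask, working_spacing)
            records.append({
                "patient_id": pid, "volume": vol, "mask": mask,
                "net_input": vol.data[None],
            })
    return records, folds


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[labels].transpose(0, 4, 1, 2, 3)


def _validate(model, val_records, cfg) -> dict:
    wmap = (
        gaussian_weight_map(cfg.patch_size, cfg.edge_value)
        if cfg.weighting == "gaussian"
        else uniform_weight_map(cfg.patch_size)
    )
    intensity = (0, 1) if cfg.task_mode == "task2" else None
    truths, preds = [], []
    for rec in val_records:
        probs = sliding_window_predict(
            rec["net_input"],
            model,
            patch_size=cfg.patch_size,
            stride=cfg.stride,
            wmap=wmap,
            normalize=cfg.normalize,
            normalize_channels=intensity,
        )
        preds.append(labels_from_probs(probs, like=rec["volume"]).labels)
        truths.append(rec["mask"].labels)
    scores = {
        c: dsc_agg([(t == c, p == c) for t, p in zip(truths, preds)]) for c in (1, 2)
    }
    scores["mean"] = float(np.mean([scores[1], scores[2]]))
    return scores


def train(cfg: TrainConfig, cohort_dir, fold: int = 0, checkpoint_path=None,
          verbose: bool = False) -> TrainResult:
    """Train one model on all patients outside ``fold``; validate on ``fold``.

    Deterministic given ``(cfg, fold)``: patch sampling, augmentation and
    weight init all derive from ``cfg.seed``.
    """
    paired = cfg.task_mode == "task2"
    if paired and cfg.network.in_channels != 4:
        raise ValueError("task2 mode needs a 4-input-channel network config")
    records, folds = load_cohort(cohort_dir, cfg.working_spacing, paired=paired)
    train_recs = [r for r in records if folds[r["patient_id"]] != fold]
    val_recs = [r for r in records if folds[r["patient_id"]] == fold]
    if not train_recs:
        raise ValueError(f"no training patients outside fold {fold}")
    if not val_recs:
        raise ValueError(f"fold {fold} has no validation patients")
    intensity_channels = (0, 1) if paired else (0,)

    n_classes = cfg.network.out_classes
    model = build_unet(cfg.network, seed=cfg.seed)
    optimizer = Adam(model.params(), lr=cfg.lr_start)
    rng = np.random.default_rng(cfg.seed + 1)

    norm_image_cache = {}
    if cfg.normalize == "image":
        for rec in train_recs:
            stack = rec["net_input"].copy()
            for c in intensity_channels:
                stack[c] = normalize_patch(stack[c])
            norm_image_cache[rec["patient_id"]] = stack

    history = []
    best_state, best_score = None, -np.inf
    t0 = time.time()
    for it in range(cfg.iterations):
        p_aug = schedule_probability(
            ScheduleState(
                it, cfg.iterations,
                p_start=cfg.augment.p_start, p_end=cfg.augment.p_end,
                block=min(cfg.augment.block, cfg.iterations),
            )
        )
        xs, ys = [], []
        for _ in range(cfg.batch_size):
            rec = train_recs[rng.integers(len(train_recs))]
            spec = sample_patch_spec(rec["mask"], cfg.patch_size, cfg.fg_fraction, rng)
            net_input = (
                norm_image_cache[rec["patient_id"]]
                if cfg.normalize == "image"
                else rec["net_input"]
            )
            stack = np.stack([extract_patch(net_input[c], spec)
                              for c in range(net_input.shape[0])])
            msk_p = extract_patch(rec["mask"], spec)
            stack, msk_p = apply_augmentations(
                stack, msk_p, p_aug, rng, cfg.augment,
                intensity_channels=intensity_channels,
            )
            if cfg.normalize == "patch":
                for c in intensity_channels:
                    stack[c] = normalize_patch(stack[c])
            xs.append(stack)
            ys.append(msk_p)
        x = np.stack(xs)
        onehot = _onehot(np.stack(ys).astype(np.int64), n_classes)

        lr = cosine_lr(it, cfg.iterations, cfg.lr_start, cfg.lr_end)
        optimizer.zero_grad()
        logits = model.forward(x, train=True)
        loss, dlogits = dice_loss_and_grad(logits, onehot)
        model.backward(dlogits)
        optimizer.step(lr)
        row = {"iteration": it, "loss": loss, "lr": lr, "p_aug": p_aug}

        if (it + 1) % cfg.eval_every == 0 or it + 1 == cfg.iterations:
            scores = _validate(model, val_recs, cfg)
            row.update(
                val_dsc_agg_gtvp=scores[1], val_dsc_agg_gtvn=scores[2],
                val_dsc_agg_mean=scores["mean"],
            )
            if scores["mean"] > best_score:
                best_score = scores["mean"]
                best_state = [p.value.copy() for p in model.params()]
            if verbose:
                print(
                    f"iter {it + 1}/{cfg.iterations} loss={loss:.4f} "
                    f"DSCagg GTVp={scores[1]:.3f} GTVn={scores[2]:.3f} "
                    f"mean={scores['mean']:.3f} [{time.time() - t0:.0f}s]"
                )
        history.append(row)

    if best_state is None:  # eval never ran (iterations < eval_every)
        best_state = [p.value.copy() for p in model.params()]
        best_score = float("nan")
    result = TrainResult(model, best_state, best_score, pd.DataFrame(history))
    if checkpoint_path is not None:
        result.restore_best()
        save_checkpoint(model, checkpoint_path)
        result.checkpoint_path = Path(checkpoint_path)
    return result
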