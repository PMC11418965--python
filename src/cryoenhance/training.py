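"""Training loop: masked MSE, geometric augmentation, LR schedule, Adam.

The loss is a masked mean square error: voxels that are zero in *both* the
network output and the simulated target carry no signal (empty solvent
region) and are excluded; the mean runs over the surviving voxels only.
Augmentation applies one of the 24 proper 90-degree cube rotations plus
independent per-axis flips — exact voxel permutations, so they commute with
the loss.  The learning rate starts at 5e-4 and is halved, down to a floor
of 1e-5, after two consecutive validations without improvement over the
running best.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ArchitectureConfig, EnhancerNetwork, save_checkpoint
from .nn import Adam, Tensor
from .tiling import random_crop

__all__ = [
    "LossSpec",
    "TrainingConfig",
    "LRSchedule",
    "AugmentTransform",
    "masked_mse",
    "masked_mse_tensor",
    "augment_pair",
    "pairs_from_maps",
    "train",
]


# ---------------------------------------------------------------------------
# loss


@dataclass
class LossSpec:
    """Masking rule for the loss: |prediction| <= zero_tolerance counts as zero."""

    zero_tolerance: float = 0.0

    def __post_init__(self):
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be nonnegative")


def _mask_keep(pred: np.ndarray, target: np.ndarray, eps: float) -> np.ndarray:
    return ~((np.abs(pred) <= eps) & (target == 0))


def masked_mse(prediction: np.ndarray, target: np.ndarray,
               spec: LossSpec | None = None) -> float:
    """Mean square error over voxels not zero in both prediction and target."""
    spec = spec or LossSpec()
    prediction = np.asarray(prediction)
    target = np.asarray(target)
    if prediction.shape != target.shape:
        raise ValueError("prediction and target must share a shape")
    keep = _mask_keep(prediction, target, spec.zero_tolerance)
    n = int(keep.sum())
    if n == 0:
        return 0.0
    diff = prediction[keep] - target[keep]
    return float((diff**2).sum() / n)


def masked_mse_tensor(prediction: Tensor, target: np.ndarray,
                      spec: LossSpec | None = None) -> tuple[Tensor, int]:
    """Differentiable masked MSE; the mask is held fixed w.r.t. gradients.

    Returns (loss, n_unmasked); a fully masked pair yields a constant zero
    loss with n_unmasked == 0.
    """
    spec = spec or LossSpec()
    target = np.asarray(target)
    if prediction.shape != target.shape:
        raise ValueError("prediction and target must share a shape")
    keep = _mask_keep(prediction.data, target, spec.zero_tolerance)
    n = int(keep.sum())
    if n == 0:
        return Tensor(np.array(0.0)), 0
    mask = keep.astype(prediction.data.dtype)
    diff = (prediction - Tensor(target)) * Tensor(mask)
    return (diff**2).sum() * (1.0 / n), n


# ---------------------------------------------------------------------------
# augmentation

# the 24 proper rotations of a cube: axis permutation + flips with det +1
def _proper_rotations() -> list[tuple[tuple[int, int, int], tuple[bool, bool, bool]]]:
    rots = []
    for perm in itertools.permutations(range(3)):
        parity = 1
        p = list(perm)
        for i in range(3):
            for j in range(i + 1, 3):
                if p[i] > p[j]:
                    parity = -parity
        for flips in itertools.product((False, True), repeat=3):
            det = parity * (-1) ** sum(flips)
            if det == 1:
                rots.append((perm, flips))
    return rots


ROTATIONS_24 = _proper_rotations()


@dataclass(frozen=True)
class AugmentTransform:
    """A cube rotation followed by independent per-axis flips; invertible exactly."""

    perm: tuple[int, int, int]
    rot_flips: tuple[bool, bool, bool]
    post_flips: tuple[bool, bool, bool]

    def apply(self, volume: np.ndarray) -> np.ndarray:
        v = np.transpose(volume, self.perm)
        for ax, f in enumerate(self.rot_flips):
            if f:
                v = np.flip(v, axis=ax)
        for ax, f in enumerate(self.post_flips):
            if f:
                v = np.flip(v, axis=ax)
        return np.ascontiguousarray(v)

    def invert(self, volume: np.ndarray) -> np.ndarray:
        v = volume
        for ax, f in enumerate(self.post_flips):
            if f:
                v = np.flip(v, axis=ax)
        for ax, f in enumerate(self.rot_flips):
            if f:
                v = np.flip(v, axis=ax)
        inv_perm = tuple(np.argsort(self.perm))
        return np.ascontiguousarray(np.transpose(v, inv_perm))


def augment_pair(input_block: np.ndarray, target_block: np.ndarray,
                 rng: np.random.Generator, rot90: bool = True, flip: bool = True
                 ) -> tuple[np.ndarray, np.ndarray, AugmentTransform]:
    """Apply the same random rotation+flip to both blocks of a training pair."""
    if input_block.shape != target_block.shape:
        raise ValueError("paired blocks must share a shape")
    edge = input_block.shape[0]
    if input_block.shape != (edge,) * 3:
        raise ValueError("augmentation requires cubic blocks")
    if rot90:
        perm, rot_flips = ROTATIONS_24[int(rng.integers(0, 24))]
    else:
        perm, rot_flips = (0, 1, 2), (False, False, False)
    post = tuple(bool(rng.integers(0, 2)) for _ in range(3)) if flip \
        else (False, False, False)
    t = AugmentTransform(tuple(perm), tuple(rot_flips), post)
    return t.apply(input_block), t.apply(target_block), t


# ---------------------------------------------------------------------------
# dataset plumbing


def pairs_from_maps(input_map, target_map, block_size: int, stride: int,
                    min_fraction: float = 0.0, target_voxel: float = 1.0,
                    percentile: float = 99.999
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Training block pairs from one (experimental, simulated) map pair.

    Resamples both maps to the common grid spacing, normalizes the input by
    its high-percentile density, splits both into the same block lattice and
    drops pairs whose target block is empty.
    """
    from .map_io import normalize_percentile, resample_to_grid
    from .tiling import filter_nonempty, split_blocks

    inp = resample_to_grid(input_map, target_voxel)
    tgt = resample_to_grid(target_map, target_voxel)
    if inp.shape != tgt.shape:
        raise ValueError("input and target maps must share a grid")
    inp, _ = normalize_percentile(inp, percentile)
    in_blocks = split_blocks(inp, block_size, stride)
    tg_blocks = split_blocks(tgt, block_size, stride)
    in_blocks, tg_blocks = filter_nonempty(in_blocks, tg_blocks, min_fraction)
    return list(zip(in_blocks.blocks, tg_blocks.blocks))


# ---------------------------------------------------------------------------
# learning-rate schedule


@dataclass
class LRSchedule:
    """Halve the LR after `patience` consecutive non-improving validations.

    "Improve" means a strict decrease below the running best validation
    loss; the LR never drops below `floor`.
    """

    lr: float = 5e-4
    floor: float = 1e-5
    patience: int = 2
    best: float = field(default=np.inf)
    bad_count: int = 0

    def step(self, validation_loss: float) -> float:
        if validation_loss < self.best:
            self.best = validation_loss
            self.bad_count = 0
        else:
            self.bad_count += 1
            if self.bad_count >= self.patience:
                self.lr = max(self.lr / 2.0, self.floor)
                self.bad_count = 0
        return self.lr


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainingConfig:
    initial_lr: float = 5e-4
    lr_floor: float = 1e-5
    lr_halving_patience: int = 2
    validate_every: int = 5
    batch_size: int = 4          # desk-scale default; 15 reproduces the full-scale run
    max_epochs: int = 30
    seed: int = 0
    crop_size: int | None = None  # e.g. 48 to crop from 64^3 blocks; None disables
    rot90: bool = True
    flip: bool = True
    loss: LossSpec = field(default_factory=LossSpec)
    clip_norm: float | None = None


@dataclass
class TrainingResult:
    network: EnhancerNetwork
    history: pd.DataFrame
    best_val_loss: float
    best_state: dict[str, np.ndarray]


def _forward_loss(net: EnhancerNetwork, inputs: np.ndarray, targets: np.ndarray,
                  spec: LossSpec) -> tuple[Tensor, int]:
    x = Tensor(inputs[:, None].astype(np.float32))
    pred = net(x)
    return masked_mse_tensor(pred, targets[:, None].astype(np.float32), spec)


def _validation_loss(net: EnhancerNetwork, val_pairs, spec: LossSpec,
                     batch_size: int) -> float:
    net.eval()
    losses, weights = [], []
    for i in range(0, len(val_pairs), batch_size):
        chunk = val_pairs[i:i + batch_size]
        inputs = np.stack([p[0] for p in chunk])
        targets = np.stack([p[1] for p in chunk])
        loss, n = _forward_loss(net, inputs, targets, spec)
        losses.append(float(loss.data))
        weights.append(max(n, 1))
    net.train()
    return float(np.average(losses, weights=weights))


def train(pairs, val_pairs, arch: ArchitectureConfig, config: TrainingConfig,
          out_dir=None, verbose: bool = False,
          initial_state: dict[str, np.ndarray] | None = None) -> TrainingResult:
    """Train an EnhancerNetwork on (experimental, simulated) block pairs.

    `pairs` and `val_pairs` are sequences of (input_block, target_block)
    cubic numpy arrays.  Each step optionally crops 64->48 style, augments
    with random rotations/flips, and minimizes the masked MSE with Adam.
    The run is fully reproducible from (seed, config, data order).
    `initial_state` warm-starts from a previous run's parameters instead of
    a fresh initialization.
    """
    if len(pairs) < 1 or len(val_pairs) < 1:
        raise ValueError("need at least one training and one validation pair")
    rng = np.random.default_rng(config.seed)
    net = EnhancerNetwork(arch, seed=int(rng.integers(0, 2**31 - 1)))
    if initial_state is not None:
        net.load_state_dict(initial_state)
    net.train()
    opt = Adam(net.parameters(), lr=config.initial_lr, clip_norm=config.clip_norm)
    schedule = LRSchedule(lr=config.initial_lr, floor=config.lr_floor,
                          patience=config.lr_halving_patience)
    history: list[dict] = []
    best_val = np.inf
    best_state = net.state_dict()

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(pairs))
        epoch_losses, epoch_weights = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_in, batch_tg = [], []
            for i in idx:
                inp, tgt = pairs[i]
                if config.crop_size is not None and config.crop_size < inp.shape[0]:
                    inp, tgt = random_crop(inp, tgt, config.crop_size, rng)
                if config.rot90 or config.flip:
                    inp, tgt, _ = augment_pair(inp, tgt, rng,
                                               rot90=config.rot90, flip=config.flip)
                batch_in.append(inp)
                batch_tg.append(tgt)
            loss, n = _forward_loss(net, np.stack(batch_in), np.stack(batch_tg),
                                    config.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"batch starting at shuffled index {start} (pairs {idx.tolist()})"
                )
            if n > 0:
                opt.zero_grad()
                loss.backward()
                opt.step()
            epoch_losses.append(float(loss.data))
            epoch_weights.append(max(n, 1))
        train_loss = float(np.average(epoch_losses, weights=epoch_weights))
        record = {"epoch": epoch, "train_loss": train_loss, "lr": opt.lr,
                  "val_loss": np.nan}
        if epoch % config.validate_every == 0:
            val_loss = _validation_loss(net, val_pairs, config.loss,
                                        config.batch_size)
            record["val_loss"] = val_loss
            opt.lr = schedule.step(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.state_dict()
        history.append(record)
        if verbose:
            print(f"epoch {epoch:4d}  train {train_loss:.5f}  lr {opt.lr:.2e}")

    history_df = pd.DataFrame(history)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        final_state = net.state_dict()
        net.load_state_dict(best_state)
        save_checkpoint(out_dir / "best.npz", net,
                        extra={"best_val_loss": float(best_val)})
        net.load_state_dict(final_state)
        save_checkpoint(out_dir / "final.npz", net)
        history_df.to_csv(out_dir / "history.csv", index=False)
    return TrainingResult(net, history_df, float(best_val), best_state)
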