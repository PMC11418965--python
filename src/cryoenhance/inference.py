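"""Full-map enhancement: normalize, tile, batch-forward, reassemble.

The pipeline mirrors the training-time preprocessing: the input map is
resampled to a 1 Å grid, normalized by its 99.999th-percentile density,
split into overlapping cubes, pushed through the network in batches with
all stochastic layers off, and mean-assembled back into a map of the same
(resampled) shape with the input's origin.  The network's native output
scale is kept; the normalization divisor is recorded in the run manifest so
callers can rescale.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .map_io import DensityMap, normalize_percentile, resample_to_grid
from .tiling import assemble_blocks, split_blocks

__all__ = ["IdentityModel", "enhance_map", "run_manifest"]

_VERSION = "0.1.0"


class IdentityModel:
    """A pass-through stand-in for a trained network; exercises the plumbing."""

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.asarray(batch)


@dataclass
class EnhanceSettings:
    block_size: int = 48
    stride: int = 38
    batch_size: int = 8
    target_voxel: float = 1.0
    percentile: float = 99.999


def enhance_map(dmap: DensityMap, model, block_size: int = 48, stride: int = 38,
                batch_size: int = 8, target_voxel: float = 1.0,
                percentile: float = 99.999) -> DensityMap:
    """Enhance a density map with a trained (or stub) block model.

    `model` needs a ``predict(batch)`` method mapping (B, 1, E, E, E) arrays
    to arrays of the same shape in inference mode.  The result lives on the
    resampled grid and keeps the input's origin, so it superimposes on the
    input in any viewer.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    resampled = resample_to_grid(dmap, target_voxel)
    normalized, _ = normalize_percentile(resampled, percentile)
    blocks = split_blocks(normalized, block_size, stride)
    outputs: list[np.ndarray] = []
    for start in range(0, len(blocks), batch_size):
        chunk = blocks.blocks[start:start + batch_size]
        batch = np.stack(chunk)[:, None].astype(np.float32)
        pred = model.predict(batch)
        if pred.shape != batch.shape:
            raise ValueError(
                f"model returned shape {pred.shape}, expected {batch.shape} "
                "(checkpoint/architecture mismatch?)"
            )
        outputs.extend(np.asarray(p[0], dtype=np.float64) for p in pred)
    data = assemble_blocks(blocks, outputs)
    return DensityMap(data, (target_voxel,) * 3, resampled.origin)


def _sha256_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _sha256_file(path) -> str | None:
    path = Path(path)
    if not path.exists():
        return None
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_manifest(dmap: DensityMap, checkpoint_path, settings: EnhanceSettings,
                 out_path=None) -> dict:
    """Provenance record for an enhancement run (JSON-serializable).

    Recomputes the preprocessing deterministically, so two runs over the
    same inputs differ only in the timestamp.
    """
    resampled = resample_to_grid(dmap, settings.target_voxel)
    _, record = normalize_percentile(resampled, settings.percentile)
    blocks = split_blocks(resampled, settings.block_size, settings.stride)
    manifest = {
        "software": f"cryoenhance {_VERSION}",
        "input_sha256": _sha256_array(dmap.data),
        "input_shape": list(dmap.shape),
        "checkpoint_sha256": _sha256_file(checkpoint_path) if checkpoint_path else None,
        "normalization": {
            "percentile": record.percentile,
            "scale": record.scale,
            "clip_low": record.clip_low,
        },
        "tiling": {
            "block_size": settings.block_size,
            "stride": settings.stride,
            "n_blocks": len(blocks),
            "resampled_shape": list(resampled.shape),
            "target_voxel": settings.target_voxel,
        },
        "batch_size": settings.batch_size,
        "timestamp": time.time(),
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(manifest, indent=2))
    return manifest
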