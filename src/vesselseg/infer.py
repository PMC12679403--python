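"""Tiled inference: apply a network to arbitrarily large volumes.

The volume is covered by overlapping tiles of the network's input shape
(default overlap 16 voxels per axis); each tile is predicted in inference
mode (dropout off) and overlapping predictions are blended by weighted
averaging with weights summing to one at every voxel. Uniform averaging is
the default; a cosine (Hann) window is available to down-weight tile edges.
Volumes smaller than a tile are reflect-padded and cropped back. Tiles are
processed one at a time, so resident memory is independent of volume size
apart from the output accumulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TilingPlan", "plan_tiles", "predict_volume", "binarize"]


@dataclass
class TilingPlan:
    volume_shape: tuple[int, int, int]
    tile_shape: tuple[int, int, int]
    overlap: tuple[int, int, int]
    origins: list = field(default_factory=list)    # tile origins, (z,y,x)
    pad: tuple[int, int, int] = (0, 0, 0)          # reflect-pad per axis


def _axis_origins(length: int, tile: int, overlap: int) -> list[int]:
    stride = tile - overlap
    origins = list(range(0, length - tile + 1, stride))
    if not origins:
        origins = [0]
    if origins[-1] + tile < length:
        origins.append(length - tile)   # final tile shifted flush
    return origins


def plan_tiles(volume_shape, tile_shape=(64, 64, 64),
               overlap=16) -> TilingPlan:
    """Plan tile origins so that every voxel is covered at least once."""
    volume_shape = tuple(int(s) for s in volume_shape)
    tile_shape = tuple(int(s) for s in tile_shape)
    if np.isscalar(overlap):
        overlap = (int(overlap),) * 3
    overlap = tuple(int(o) for o in overlap)
    if any(o < 0 or o >= t for o, t in zip(overlap, tile_shape)):
        raise ValueError(f"overlap {overlap} must satisfy 0 <= overlap < "
                         f"tile {tile_shape}")
    pad = tuple(max(t - v, 0) for t, v in zip(tile_shape, volume_shape))
    padded = tuple(v + p for v, p in zip(volume_shape, pad))
    per_axis = [_axis_origins(l, t, o)
                for l, t, o in zip(padded, tile_shape, overlap)]
    origins = [(z, y, x) for z in per_axis[0]
               for y in per_axis[1] for x in per_axis[2]]
    return TilingPlan(volume_shape=volume_shape, tile_shape=tile_shape,
                      overlap=overlap, origins=origins, pad=pad)


def _blend_window(tile_shape, mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.ones(tile_shape, dtype=np.float32)
    if mode == "cosine":
        wins = [np.hanning(s + 2)[1:-1].astype(np.float32)
                for s in tile_shape]
        w = wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]
        return np.maximum(w, 1e-3)
    raise ValueError(f"unknown blend mode {mode!r}")


def predict_volume(net, volume, plan: TilingPlan | None = None,
                   overlap=16, blend: str = "uniform",
                   vessel_channel: int = 1,
                   progress: bool = False) -> np.ndarray:
    """Vessel-channel probability volume for ``volume`` (array or store).

    Overlapping tile predictions are combined by weighted averaging; the
    per-voxel blend weights are normalized to sum to one, so regions covered
    by a single tile reproduce the direct forward pass exactly.
    """
    if hasattr(volume, "read_subvolume"):      # VolumeStore
        reader = volume.read_subvolume
        shape = volume.shape
    else:
        volume = np.asarray(volume, dtype=np.float32)
        shape = volume.shape

        def reader(origin, tile_shape, which="image"):
            sl = tuple(slice(o, o + s) for o, s in zip(origin, tile_shape))
            return volume[sl]

    tile_shape = tuple(net.config.input_shape)
    if plan is None:
        if np.isscalar(overlap):
            overlap = (int(overlap),) * 3
        # cap at half the tile so the stride never degenerates
        overlap = tuple(min(int(o), t // 2) for o, t in zip(overlap, tile_shape))
        plan = plan_tiles(shape, tile_shape, overlap)
    pad = plan.pad
    padded_shape = tuple(v + p for v, p in zip(shape, pad))
    accum = np.zeros(padded_shape, dtype=np.float32)
    weight = np.zeros(padded_shape, dtype=np.float32)
    window = _blend_window(tile_shape, blend)

    padded = None
    if any(pad):
        full = (reader((0, 0, 0), shape) if hasattr(volume, "read_subvolume")
                else volume)
        padded = np.pad(full, tuple((0, p) for p in pad), mode="reflect")

    iterator = plan.origins
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic
        iterator = tqdm(iterator, desc="tiles")
    for origin in iterator:
        sl = tuple(slice(o, o + s) for o, s in zip(origin, tile_shape))
        tile = padded[sl] if padded is not None else reader(origin, tile_shape)
        probs = net.forward(tile[None, ..., None].astype(np.float32),
                            train=False)
        accum[sl] += probs[0, ..., vessel_channel] * window
        weight[sl] += window
    out = accum / weight
    if any(pad):
        out = out[tuple(slice(0, s) for s in shape)]
    return np.clip(out, 0.0, 1.0)


def binarize(prob_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard mask: ``prob >= threshold``. Threshold must lie in (0, 1)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    prob = np.asarray(prob_volume)
    return (prob >= threshold).astype(np.uint8)
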