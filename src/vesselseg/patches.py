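"""Training-batch generation: weighted patch sampling plus augmentation.

Batches of 64^3 subvolumes are read from randomly selected stores at random
coordinates (which doubles as a translation augmentation). Two weighting
mechanisms counter class imbalance and dataset-size imbalance:

* store selection is drawn with probability proportional to per-dataset
  weights (e.g. 5:4:1:1 across four stores, so small datasets are not
  overfitted);
* candidate patches whose vessel fraction falls below a threshold (default
  0.1%) are kept only with probability ``background_retain_prob`` —
  rejection sampling that biases batches toward vessel-containing patches
  while still showing the model occasional empty ones.

Augmentations, applied identically to image and label: in-plane rotation
(default +/-30 deg), in-plane isotropic rescale (default 1.0-1.25x), and
reflection in one or both in-plane axes. Images are interpolated linearly
and clamped back to [0,1]; labels use nearest-neighbour so they stay binary.
"In-plane" is the (y, x) plane of the (z, y, x) axis order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["SamplerPolicy", "AugmentationConfig", "PatchBatch",
           "sample_origin", "draw_augmentation_params", "apply_augmentation",
           "invert_augmentation_params", "augment_pair", "make_batch"]

REJECTION_CAP = 1000


@dataclass
class SamplerPolicy:
    """How patches are drawn from a collection of stores."""

    patch_shape: tuple[int, int, int] = (64, 64, 64)
    dataset_weights: tuple[float, ...] = (1.0,)
    vessel_fraction_threshold: float = 0.001
    background_retain_prob: float = 0.1
    regions: tuple | None = None  # optional per-store (origin, shape) boxes

    def __post_init__(self) -> None:
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        w = np.asarray(self.dataset_weights, dtype=float)
        if w.sum() <= 0 or np.any(w < 0):
            raise ValueError("dataset_weights must be nonnegative with a "
                             "positive sum")
        if not 0.0 <= self.background_retain_prob <= 1.0:
            raise ValueError("background_retain_prob must be in [0, 1]")
        if not 0.0 <= self.vessel_fraction_threshold < 1.0:
            raise ValueError("vessel_fraction_threshold must be in [0, 1)")


@dataclass
class AugmentationConfig:
    rotation_range_deg: tuple[float, float] = (-30.0, 30.0)
    rescale_range: tuple[float, float] = (1.0, 1.25)
    reflect_axes: tuple[int, ...] = (1, 2)   # in-plane axes of (z, y, x)
    enable_rotation: bool = True
    enable_rescale: bool = True
    enable_reflection: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if not (-180.0 <= lo <= hi <= 180.0):
            raise ValueError("rotation range must lie within [-180, 180]")
        slo, shi = self.rescale_range
        if not (0.0 < slo <= shi):
            raise ValueError("rescale range must be positive")


@dataclass
class PatchBatch:
    images: np.ndarray                  # (B, z, y, x) in [0, 1]
    labels: np.ndarray                  # (B, z, y, x) binary
    provenance: list = field(default_factory=list)


def _valid_extent(store, policy: SamplerPolicy, store_index: int):
    """(origin_lo, origin_hi_exclusive) of valid patch origins per axis."""
    if policy.regions is not None and policy.regions[store_index] is not None:
        r_origin, r_shape = policy.regions[store_index]
    else:
        r_origin, r_shape = (0, 0, 0), store.shape
    lo = tuple(int(o) for o in r_origin)
    hi = tuple(o + s - p + 1 for o, s, p in
               zip(lo, r_shape, policy.patch_shape))
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError(
            f"store/region {tuple(r_shape)} smaller than patch "
            f"{policy.patch_shape}")
    return lo, hi


def sample_origin(stores, policy: SamplerPolicy,
                  rng: np.random.Generator) -> tuple[int, tuple[int, int, int]]:
    """Draw ``(store_index, origin)`` for one training patch.

    The store is drawn with probability proportional to
    ``policy.dataset_weights``; the origin is uniform over valid positions.
    Candidates below the vessel-fraction threshold are retained only with
    ``background_retain_prob``. After ``REJECTION_CAP`` rejections the last
    candidate is returned with a warning (termination guarantee).
    """
    w = np.asarray(policy.dataset_weights, dtype=float)
    if len(w) != len(stores):
        raise ValueError(f"{len(w)} weights for {len(stores)} stores")
    probs = w / w.sum()
    patch = policy.patch_shape
    n_vox = int(np.prod(patch))
    for attempt in range(REJECTION_CAP):
        idx = int(rng.choice(len(stores), p=probs))
        store = stores[idx]
        lo, hi = _valid_extent(store, policy, idx)
        origin = tuple(int(rng.integers(l, h)) for l, h in zip(lo, hi))
        if policy.vessel_fraction_threshold == 0.0 or store.labels is None:
            return idx, origin
        label_win = store.read_subvolume(origin, patch, which="labels")
        fraction = label_win.sum() / n_vox
        if fraction >= policy.vessel_fraction_threshold:
            return idx, origin
        if rng.random() < policy.background_retain_prob:
            return idx, origin
    warnings.warn(f"patch rejection cap ({REJECTION_CAP}) reached; "
                  "returning a below-threshold patch")
    return idx, origin


# -- augmentation -----------------------------------------------------------

def draw_augmentation_params(config: AugmentationConfig,
                             rng: np.random.Generator) -> dict:
    params = {"angle_deg": 0.0, "scale": 1.0, "flip_axes": ()}
    if config.enable_rotation:
        params["angle_deg"] = float(rng.uniform(*config.rotation_range_deg))
    if config.enable_rescale:
        params["scale"] = float(rng.uniform(*config.rescale_range))
    if config.enable_reflection:
        params["flip_axes"] = tuple(
            ax for ax in config.reflect_axes if rng.random() < 0.5)
    return params


def _rotate_rescale_inplane(vol: np.ndarray, angle_deg: float, scale: float,
                            order: int) -> np.ndarray:
    """Centre-anchored in-plane rotation + isotropic rescale, one resample.

    Composed into a single affine transform so image and label are only
    interpolated once per augmentation. Output shape equals input shape:
    scale > 1 magnifies (edges crop away), scale < 1 shrinks (zero fill).
    """
    if angle_deg == 0.0 and scale == 1.0:
        return vol
    theta = np.deg2rad(angle_deg)
    # affine_transform maps output -> input coords: rotate by -theta, zoom 1/s
    rot = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]]) / scale
    matrix = np.eye(3)
    matrix[1:, 1:] = rot
    centre = (np.asarray(vol.shape) - 1) / 2.0
    offset = centre - matrix @ centre
    return ndimage.affine_transform(vol, matrix, offset=offset, order=order,
                                    mode="constant", cval=0.0,
                                    prefilter=(order > 1))


def apply_augmentation(image: np.ndarray, label: np.ndarray,
                       params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Apply a drawn parameter set: rotation, then rescale, then reflection.

    Rotation and rescale commute (the rescale is isotropic in-plane) and are
    composed into a single resampling. Image uses linear interpolation
    (clamped to [0,1]); label uses nearest-neighbour and stays binary.
    Shapes are preserved.
    """
    if image.shape != label.shape:
        raise ValueError(f"image/label shape mismatch: {image.shape} vs "
                         f"{label.shape}")
    img = _rotate_rescale_inplane(image.astype(np.float32),
                                  params["angle_deg"], params["scale"],
                                  order=1)
    lab = _rotate_rescale_inplane(label.astype(np.float32),
                                  params["angle_deg"], params["scale"],
                                  order=0)
    for ax in params["flip_axes"]:
        img = np.flip(img, axis=ax)
        lab = np.flip(lab, axis=ax)
    img = np.clip(img, 0.0, 1.0)
    lab = (lab > 0.5).astype(np.uint8)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def invert_augmentation_params(params: dict) -> dict:
    """Parameter set undoing ``params`` under ``apply_augmentation``.

    With T = Flip ∘ (Rotate(θ) ∘ Scale(s)), the inverse in the same
    fixed operation order is Flip ∘ (Rotate(θ') ∘ Scale(1/s)) with
    θ' = +θ when an odd number of in-plane flips was applied (a single
    reflection conjugates a rotation into its inverse) and θ' = -θ
    otherwise.
    """
    sign = 1.0 if len(params["flip_axes"]) % 2 == 1 else -1.0
    return {"angle_deg": sign * params["angle_deg"],
            "scale": 1.0 / params["scale"],
            "flip_axes": params["flip_axes"]}


def augment_pair(image: np.ndarray, label: np.ndarray,
                 config: AugmentationConfig, rng: np.random.Generator):
    """Draw one parameter set and apply it identically to image and label."""
    params = draw_augmentation_params(config, rng)
    img, lab = apply_augmentation(image, label, params)
    return img, lab, params


def make_batch(stores, policy: SamplerPolicy, aug_config: AugmentationConfig,
               batch_size: int = 6,
               rng: np.random.Generator | None = None) -> PatchBatch:
    """Assemble a training batch: sample origins, read windows, augment."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = rng or np.random.default_rng()
    images, labels, provenance = [], [], []
    for _ in range(batch_size):
        idx, origin = sample_origin(stores, policy, rng)
        store = stores[idx]
        img = store.read_subvolume(origin, policy.patch_shape, "image")
        lab = store.read_subvolume(origin, policy.patch_shape, "labels")
        if aug_config is not None:
            img, lab, params = augment_pair(img, lab, aug_config, rng)
        else:
            params = None
        images.append(img)
        labels.append(lab)
        provenance.append({"store": store.name, "store_index": idx,
                           "origin": origin, "augmentation": params})
    return PatchBatch(images=np.stack(images).astype(np.float32),
                      labels=np.stack(labels).astype(np.uint8),
                      provenance=provenance)
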