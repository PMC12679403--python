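"""Chunked on-disk volume store with lazy subvolume reads.

Large microscopy volumes (multi-page TIFF or NIfTI) are ingested once:
intensities are min-max normalized to [0, 1], an optional axis-aligned crop
is applied, and image and label arrays are written as Zarr chunked arrays
(default chunk 64x64x64) with a human-readable JSON sidecar header carrying
the metadata the training pipeline needs. Training then reads random 64^3
windows straight from disk; Zarr touches only the chunks intersecting a
window, so resident memory stays bounded by the window plus touched chunks
regardless of total volume size.

Conventions: axis order (z, y, x), 0-based indexing, half-open windows
``[origin, origin + shape)``. Labels are binarized on ingest (any nonzero
value -> 1), tolerating 8-bit 0/255 masks.

Store layout on disk::

    <path>/
        header.json     # DatasetHeader sidecar
        image/          # Zarr array, float32 in [0,1]
        labels/         # Zarr array, uint8 in {0,1}  (optional)
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import zarr

__all__ = ["RawVolume", "DatasetHeader", "VolumeStore", "normalize_volume",
           "build_store", "read_tiff_volume", "read_nifti_volume",
           "load_volume"]

HEADER_FILENAME = "header.json"
FORMAT_VERSION = "1.0"
DEFAULT_CHUNK = (64, 64, 64)


@dataclass
class RawVolume:
    """A 3D greyscale volume as read from disk, axis order (z, y, x)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    source_modality: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")


@dataclass
class DatasetHeader:
    """Sidecar metadata persisted next to the chunked arrays."""

    name: str
    shape: tuple[int, int, int]
    chunk_shape: tuple[int, int, int]
    intensity_min_raw: float
    intensity_max_raw: float
    voxel_size: tuple[float, float, float] | None = None
    modality: str = ""
    has_labels: bool = False
    created: str = ""
    format_version: str = FORMAT_VERSION
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.chunk_shape = tuple(int(s) for s in self.chunk_shape)
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.chunk_shape):
            raise ValueError("shape and chunk_shape must be strictly positive")
        if self.intensity_min_raw > self.intensity_max_raw:
            raise ValueError("intensity_min_raw must be <= intensity_max_raw")
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DatasetHeader":
        d = json.loads(text)
        d["shape"] = tuple(d["shape"])
        d["chunk_shape"] = tuple(d["chunk_shape"])
        if d.get("voxel_size") is not None:
            d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: Path) -> "DatasetHeader":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def normalize_volume(raw: RawVolume | np.ndarray,
                     clip_percentiles: tuple[float, float] | None = None
                     ) -> np.ndarray:
    """Min-max normalize a volume to [0, 1] (global per-volume statistics).

    A constant volume maps to all zeros rather than raising. With
    ``clip_percentiles=(lo, hi)`` intensities are first clipped to those
    percentiles (opt-in; plain min-max is the default).
    """
    voxels = raw.voxels if isinstance(raw, RawVolume) else np.asarray(raw)
    if not np.all(np.isfinite(voxels)):
        raise ValueError("cannot normalize: non-finite voxel values present")
    v = voxels.astype(np.float32)
    if clip_percentiles is not None:
        lo, hi = np.percentile(v, clip_percentiles)
        v = np.clip(v, lo, hi)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)


class VolumeStore:
    """Handle on an on-disk chunked image (+ optional labels) store."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self.header = DatasetHeader.load(self.path / HEADER_FILENAME)
        group = zarr.open_group(str(self.path), mode="r")
        self.image = group["image"]
        self.labels = group["labels"] if self.header.has_labels else None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.header.shape

    @property
    def name(self) -> str:
        return self.header.name

    def read_subvolume(self, origin, shape, which: str = "image") -> np.ndarray:
        """Read the half-open window ``[origin, origin+shape)`` lazily.

        Only chunks intersecting the window are read from disk.
        """
        origin = tuple(int(o) for o in origin)
        shape = tuple(int(s) for s in shape)
        if any(o < 0 for o in origin):
            raise ValueError(f"origin must be >= 0, got {origin}")
        if any(o + s > d for o, s, d in zip(origin, shape, self.shape)):
            raise ValueError(
                f"window {origin}+{shape} exceeds store shape {self.shape}")
        if which == "image":
            arr = self.image
        elif which == "labels":
            if self.labels is None:
                raise ValueError(f"store {self.name!r} has no labels")
            arr = self.labels
        else:
            raise ValueError(f"which must be 'image' or 'labels', got {which!r}")
        sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
        return np.asarray(arr[sl])

    def read_full(self, which: str = "image") -> np.ndarray:
        return self.read_subvolume((0, 0, 0), self.shape, which)


def build_store(raw: RawVolume | np.ndarray,
                labels: np.ndarray | None = None,
                crop: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
                out_path: str | Path = "store.zarr",
                chunk_shape: tuple[int, int, int] = DEFAULT_CHUNK,
                name: str | None = None,
                clip_percentiles: tuple[float, float] | None = None,
                extra_metadata: dict | None = None) -> VolumeStore:
    """Normalize, optionally crop, and persist a volume (+ labels) as a store.

    Parameters
    ----------
    raw : the image volume; normalization statistics are computed on the
        full volume before any cropping.
    labels : optional label volume, same shape as ``raw`` before cropping;
        binarized as (labels != 0).
    crop : optional ``(origin, shape)`` axis-aligned box, (z, y, x).
    """
    if not isinstance(raw, RawVolume):
        raw = RawVolume(np.asarray(raw))
    image = normalize_volume(raw, clip_percentiles)
    vmin = float(raw.voxels.min())
    vmax = float(raw.voxels.max())
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != raw.voxels.shape:
            raise ValueError(f"label shape {labels.shape} != image shape "
                             f"{raw.voxels.shape}")
        labels = (labels != 0).astype(np.uint8)
    if crop is not None:
        origin, shape = (tuple(int(v) for v in crop[0]),
                         tuple(int(v) for v in crop[1]))
        if (any(o < 0 for o in origin)
                or any(o + s > d for o, s, d in
                       zip(origin, shape, image.shape))):
            raise ValueError(f"crop box {origin}+{shape} out of bounds for "
                             f"volume {image.shape}")
        sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
        image = image[sl]
        if labels is not None:
            labels = labels[sl]

    out_path = Path(out_path)
    header = DatasetHeader(
        name=name or out_path.stem,
        shape=image.shape,
        chunk_shape=chunk_shape,
        intensity_min_raw=vmin,
        intensity_max_raw=vmax,
        voxel_size=raw.voxel_size,
        modality=raw.source_modality,
        has_labels=labels is not None,
        extra=extra_metadata or {},
    )
    group = zarr.open_group(str(out_path), mode="w")
    arr = group.create_array("image", shape=image.shape, chunks=chunk_shape,
                             dtype="float32")
    arr[:] = image
    if labels is not None:
        larr = group.create_array("labels", shape=labels.shape,
                                  chunks=chunk_shape, dtype="uint8")
        larr[:] = labels
    header.save(out_path / HEADER_FILENAME)
    return VolumeStore(out_path)


# -- file readers -----------------------------------------------------------

def read_tiff_volume(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as a (z, y, x) array."""
    import tifffile
    arr = tifffile.imread(str(path))
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D TIFF stack, got shape {arr.shape}")
    return arr


def read_nifti_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI volume, reordering (x, y, z) storage to (z, y, x)."""
    import nibabel as nib
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {arr.shape}")
    return np.ascontiguousarray(arr.transpose(2, 1, 0))


def load_volume(path: str | Path) -> np.ndarray:
    """Dispatch on extension: .tif/.tiff or .nii/.nii.gz."""
    p = Path(path)
    suffixes = "".join(p.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        return read_tiff_volume(p)
    if suffixes.endswith((".nii", ".nii.gz")):
        return read_nifti_volume(p)
    raise ValueError(f"unsupported volume format: {p.name}")
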