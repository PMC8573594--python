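"""Preprocessing from brain-extracted volumes onward.

Implements intensity Gaussian normalisation, FOV cropping around the brain,
per-plane slice extraction with bilinear resizing, and reassembly of planar
probability slices into 3D volumes in the original geometry. Upstream steps
(brain extraction, bias correction, registration, MNI reorientation) are a
precondition of the input contract.

Axis convention: volumes are (x, y, z); sagittal slices are fixed-x planes,
coronal fixed-y and axial fixed-z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as sk_resize

__all__ = [
    "PLANES",
    "PLANE_AXES",
    "DEFAULT_RESIZE",
    "PreprocConfig",
    "PlaneSliceStack",
    "gaussian_normalise",
    "crop_fov",
    "extract_plane_slices",
    "assemble_probability_volume",
]

PLANES = ("axial", "sagittal", "coronal")
#: axis normal to each plane in (x, y, z) volumes
PLANE_AXES = {"axial": 2, "sagittal": 0, "coronal": 1}

#: per-plane slice dimensions used for full-size clinical volumes
DEFAULT_RESIZE = {"axial": (128, 192), "sagittal": (192, 120), "coronal": (128, 80)}


@dataclass
class PreprocConfig:
    resize: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_RESIZE))
    crop_margin: int = 2


@dataclass
class PlaneSliceStack:
    """Ordered 2D slices of a cropped volume along one plane's normal axis.

    `slices` has shape (n_slices, channels, rows, cols); the stored geometry
    (`original_shape`, `crop_box`) makes reassembly lossless.
    """

    plane: str
    slices: np.ndarray
    original_shape: tuple[int, int, int]
    crop_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    resize_dims: tuple[int, int]

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        axis = PLANE_AXES[self.plane]
        extent = self.crop_box[axis][1] - self.crop_box[axis][0]
        if self.slices.shape[0] != extent:
            raise ValueError("slice count does not match crop-box extent along the plane normal")


def gaussian_normalise(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Zero-mean unit-std intensities inside the mask; zeros outside."""
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    vals = volume[mask]
    std = vals.std()
    if std == 0:
        raise ValueError("constant-intensity volume cannot be normalised")
    out = np.zeros_like(volume)
    out[mask] = (vals - vals.mean()) / std
    return out


def crop_fov(volume: np.ndarray, brain_mask: np.ndarray, margin: int = 2):
    """Restrict the volume to the mask bounding box padded by `margin`.

    Returns (cropped volume, crop_box) with crop_box as per-axis half-open
    intervals clipped to the volume shape.
    """
    mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    volume = np.asarray(volume)
    box = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.any(axis=other)
        idx = np.nonzero(profile)[0]
        lo = max(0, int(idx[0]) - margin)
        hi = min(volume.shape[axis], int(idx[-1]) + 1 + margin)
        box.append((lo, hi))
    crop_box = tuple(box)
    sl = tuple(slice(lo, hi) for lo, hi in crop_box)
    return volume[sl], crop_box


def _resize_slice(sl: np.ndarray, dims: tuple[int, int], interpolation: str) -> np.ndarray:
    if sl.shape == tuple(dims):
        return sl.astype(np.float64)
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    out = sk_resize(sl.astype(np.float64), dims, order=order,
                    anti_aliasing=False, preserve_range=True, mode="edge")
    return out


def extract_plane_slices(volume: np.ndarray, plane: str,
                         resize_dims: tuple[int, int] | None = None,
                         interpolation: str = "bilinear",
                         original_shape: tuple[int, int, int] | None = None,
                         crop_box=None) -> PlaneSliceStack:
    """Slice a (cropped, normalised) volume along one plane and resize.

    `volume` may have a leading channel axis (C, X, Y, Z); intensity
    channels use bilinear interpolation, masks should be extracted with
    ``interpolation="nearest"`` and re-binarised by the caller.
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    if interpolation not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    vol = np.asarray(volume)
    if vol.ndim == 3:
        vol = vol[None]
    axis = PLANE_AXES[plane]
    shape3 = vol.shape[1:]
    if original_shape is None:
        original_shape = shape3
    if crop_box is None:
        crop_box = tuple((0, s) for s in shape3)
    moved = np.moveaxis(vol, axis + 1, 1)  # (C, n_slices, rows, cols)
    native = moved.shape[2:]
    dims = tuple(resize_dims) if resize_dims is not None else native
    n_slices = moved.shape[1]
    out = np.empty((n_slices, vol.shape[0], dims[0], dims[1]), dtype=np.float64)
    for i in range(n_slices):
        for c in range(vol.shape[0]):
            out[i, c] = _resize_slice(moved[c, i], dims, interpolation)
    return PlaneSliceStack(plane=plane, slices=out, original_shape=tuple(original_shape),
                           crop_box=tuple(tuple(b) for b in crop_box), resize_dims=dims)


def assemble_probability_volume(stack: PlaneSliceStack) -> np.ndarray:
    """Stack per-slice probabilities back into the original uncropped geometry.

    Slices are resized back to the crop-box dims (bilinear), stacked along
    the plane normal, embedded in a zero background of `original_shape`, and
    clipped to [0, 1]. Single-channel stacks only.
    """
    axis = PLANE_AXES[stack.plane]
    crop_shape = tuple(hi - lo for lo, hi in stack.crop_box)
    n_expected = crop_shape[axis]
    if stack.slices.shape[0] != n_expected:
        raise ValueError(
            f"expected {n_expected} slices along {stack.plane} normal, got {stack.slices.shape[0]}")
    if stack.slices.ndim == 4:
        if stack.slices.shape[1] != 1:
            raise ValueError("probability stacks must have a single channel")
        slices = stack.slices[:, 0]
    else:
        slices = stack.slices
    in_plane = tuple(s for a, s in enumerate(crop_shape) if a != axis)
    restored = np.empty((slices.shape[0],) + in_plane, dtype=np.float64)
    for i in range(slices.shape[0]):
        restored[i] = _resize_slice(slices[i], in_plane, "bilinear")
    cropped = np.moveaxis(restored, 0, axis)
    out = np.zeros(stack.original_shape, dtype=np.float64)
    sl = tuple(slice(lo, hi) for lo, hi in stack.crop_box)
    out[sl] = cropped
    return np.clip(out, 0.0, 1.0)
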