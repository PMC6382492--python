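"""Volume and mask data model, NIfTI I/O, morphology, connected components, Dice.

All grids are 3-D and share one voxel lattice per case; registration happens
upstream and is not handled here.  Masks are plain boolean grids; morphological
primitives use the full 3x3x3 (26-neighbour) structuring element, and cavity
filling uses the 6-connected background, matching the composite
"hole-filling-closing" operator used throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: full 3x3x3 box = 26-neighbour structuring element for dilation/erosion
CUBE_STRUCT = np.ones((3, 3, 3), dtype=bool)
#: 6-neighbour (face-connected) structuring element
FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return FACE_STRUCT
    if connectivity == 26:
        return CUBE_STRUCT
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass
class IntensityVolume:
    """A 3-D scalar grid with voxel spacing (mm) and an optional NIfTI affine."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            log.warning("volume contains %d NaN voxels; mapped to 0", n_nan)
            self.data = np.nan_to_num(self.data, nan=0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A 3-D boolean grid on the same lattice as its companion volumes."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        """Number of true voxels, |mask|."""
        return int(self.data.sum())

    def like(self, data: np.ndarray) -> "BinaryMask":
        """New mask on this mask's grid."""
        return BinaryMask(data, spacing=self.spacing, affine=self.affine)


@dataclass
class Component:
    """One connected component of a binary map with its scoring statistics.

    ``o``, ``s`` and ``l`` are overlap counts with the FLAIR hyper-intensity
    map and the susceptibility and lesion masks; ``w`` is the resulting
    selection weight and ``shape_score`` the solidity/roundness surrogate
    |x|^3 / |B(x)|^2 where B(x) is the minimal axis-aligned bounding box.
    """

    voxels: np.ndarray  # (n, 3) integer coordinates, lexicographically sorted
    volume: int
    bbox_volume: int
    shape_score: float
    o: int = 0
    s: int = 0
    l: int = 0
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.volume < 1:
            raise ValueError("component must contain at least one voxel")
        if self.bbox_volume < self.volume:
            raise ValueError("bounding box cannot be smaller than the component")

    def to_mask(self, shape: tuple[int, int, int], template: BinaryMask | None = None) -> BinaryMask:
        data = np.zeros(shape, dtype=bool)
        data[tuple(self.voxels.T)] = True
        if template is not None:
            return template.like(data)
        return BinaryMask(data)

    def stats_dict(self) -> dict:
        return {
            "volume": self.volume,
            "bbox_volume": self.bbox_volume,
            "shape_score": self.shape_score,
            "o": self.o,
            "s": self.s,
            "l": self.l,
            "w": self.w,
        }


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str | Path) -> IntensityVolume:
    """Load a 3-D NIfTI-1/2 image; 4-D images with a singleton last axis are squeezed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    if not np.all(spacing > 0):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    return IntensityVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def _affine(spacing: np.ndarray, affine: np.ndarray | None) -> np.ndarray:
    if affine is not None:
        return np.asarray(affine)
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(vol: IntensityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.spacing, vol.affine))
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Masks are written as uint8 {0, 1}."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.affine))
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))


def save_labels(data: np.ndarray, spacing: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(np.int32), _affine(np.asarray(spacing, float), affine))
    img.header.set_zooms(tuple(np.asarray(spacing, float)))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Mask primitives


def binarize_nonzero(vol: IntensityVolume) -> BinaryMask:
    """True exactly where intensity is nonzero (removes zero-padded voxels)."""
    return BinaryMask(vol.data != 0, spacing=vol.spacing, affine=vol.affine)


def fill_cavities(mask: BinaryMask) -> BinaryMask:
    """Fill background cavities not 6-connected to the grid border."""
    return mask.like(ndimage.binary_fill_holes(mask.data, structure=FACE_STRUCT))


def dilate(mask: BinaryMask, n: int = 1) -> BinaryMask:
    if n == 0:
        return mask.like(mask.data.copy())
    return mask.like(ndimage.binary_dilation(mask.data, structure=CUBE_STRUCT, iterations=n))


def erode(mask: BinaryMask, n: int = 1) -> BinaryMask:
    """Erode with the 3x3x3 kernel; outside the grid counts as background."""
    if n == 0:
        return mask.like(mask.data.copy())
    return mask.like(ndimage.binary_erosion(mask.data, structure=CUBE_STRUCT, iterations=n, border_value=0))


def hole_filling_closing(mask: BinaryMask, n: int) -> BinaryMask:
    """N dilations (3x3x3 kernel), 6-connected cavity filling, N erosions.

    The closing erosions treat outside-grid as foreground (the adjoint of the
    dilation), which makes the operator extensive for every mask, including
    ones touching the grid border.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dilated = fill_cavities(dilate(mask, n))
    closed = ndimage.binary_erosion(dilated.data, structure=CUBE_STRUCT, iterations=n, border_value=1)
    return mask.like(closed)


def connected_components(mask: BinaryMask, connectivity: int = 6) -> list[Component]:
    """Maximal connected sets of true voxels under 6- or 26-connectivity.

    Ordering is deterministic: descending volume, ties broken by the
    lexicographically smallest voxel coordinate, so downstream argmax
    tie-breaking is reproducible.
    """
    labelled, n = ndimage.label(mask.data, structure=_structure(connectivity))
    comps: list[Component] = []
    if n == 0:
        return comps
    objects = ndimage.find_objects(labelled)
    for lab, slc in enumerate(objects, start=1):
        sub = labelled[slc] == lab
        voxels = np.argwhere(sub)
        voxels += np.array([s.start for s in slc])
        volume = voxels.shape[0]
        extents = voxels.max(axis=0) - voxels.min(axis=0) + 1
        bbox_volume = int(np.prod(extents))
        comps.append(
            Component(
                voxels=voxels,
                volume=volume,
                bbox_volume=bbox_volume,
                shape_score=volume**3 / bbox_volume**2,
            )
        )
    comps.sort(key=lambda c: (-c.volume, tuple(c.voxels[0])))
    return comps


def shape_score(c: Component) -> float:
    """Solidity/roundness surrogate S(x) = |x|^3 / |B(x)|^2.

    Equals the volume for any full axis-aligned cuboid and is strictly smaller
    otherwise; always <= volume since |x| <= |B(x)|.
    """
    return c.volume**3 / c.bbox_volume**2


def dice_score(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|X n Y| / (|X| + |Y|); two empty masks score 1 (logged)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        log.warning("Dice of two empty masks defined as 1.0")
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)
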