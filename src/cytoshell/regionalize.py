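"""Distance-shell regionalization of a single-cell mask.

The exact Euclidean distance of every in-mask voxel center to the nearest
background voxel center is computed with anisotropic physical spacing, the
image border counting as background. The cell is then partitioned into three
concentric shells — membrane-associated ``[0, b1)``, peripheral ``[b1, b2)``
and deep ``[b2, inf)`` micrometers, default boundaries (1, 3) — and,
separately, bisected into ventral/dorsal halves of equal in-mask volume along
an annotated axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from cytoshell.segmentation import CellMask

REGION_NAMES = ("membrane", "peripheral", "deep")

#: integer codes used in label volumes
REGION_CODES = {"background": 0, "membrane": 1, "peripheral": 2, "deep": 3}

DEFAULT_BOUNDARIES = (1.0, 3.0)


@dataclasses.dataclass(frozen=True)
class DistanceMap:
    """Per-voxel distance (um) to the nearest background voxel center.

    ``dist`` is defined (and strictly positive) on in-mask voxels and 0
    elsewhere; ``mask`` records the domain.
    """

    dist: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]


@dataclasses.dataclass(frozen=True)
class RegionPartition:
    """Shell labels covering a cell mask exactly.

    ``label`` holds the codes of :data:`REGION_CODES`; ``region_volumes`` and
    ``cell_volume`` are in um^3 and satisfy ``sum(region_volumes.values()) ==
    cell_volume`` (voxel counts times a constant voxel volume).
    """

    label: np.ndarray
    boundaries: tuple[float, float]
    spacing: tuple[float, float, float]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def region_mask(self, name: str) -> np.ndarray:
        return self.label == REGION_CODES[name]

    def region_counts(self) -> dict[str, int]:
        return {name: int((self.label == REGION_CODES[name]).sum()) for name in REGION_NAMES}

    @property
    def region_volumes(self) -> dict[str, float]:
        v = self.voxel_volume_um3
        return {name: count * v for name, count in self.region_counts().items()}

    @property
    def cell_volume(self) -> float:
        return float((self.label > 0).sum()) * self.voxel_volume_um3


@dataclasses.dataclass(frozen=True)
class HalfSplit:
    """Ventral/dorsal bisection of a cell mask by equal in-mask volume.

    ``half_label`` is +1 on ventral in-mask voxels, -1 on dorsal ones, 0
    outside. ``plane_offset`` is the last plane index (along ``axis_index``)
    assigned to the lower-index side.
    """

    half_label: np.ndarray
    axis: str
    axis_index: int
    plane_offset: int

    def half_mask(self, which: str) -> np.ndarray:
        if which not in ("ventral", "dorsal"):
            raise ValueError("which must be 'ventral' or 'dorsal'")
        return self.half_label == (1 if which == "ventral" else -1)


def distance_map(mask: CellMask) -> DistanceMap:
    """Anisotropy-aware exact Euclidean distance transform of *mask*.

    For each in-mask voxel the distance (um) to the nearest background voxel
    center is returned, using the physical spacing; the array border is
    treated as background, so boundary voxels get the one-step distance
    rather than 0.
    """
    member = mask.member
    if not member.any():
        raise ValueError("empty mask")
    padded = np.pad(member, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=mask.spacing)
    dist = dist[1:-1, 1:-1, 1:-1]
    return DistanceMap(dist=dist, mask=member, spacing=mask.spacing)


def assign_regions(
    dmap: DistanceMap, boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
) -> RegionPartition:
    """Partition the cell into membrane / peripheral / deep shells.

    Half-open intervals: membrane ``dist < b1``, peripheral ``b1 <= dist <
    b2``, deep ``dist >= b2``. Empty regions are permitted.
    """
    b1, b2 = (float(b) for b in boundaries)
    if not 0 < b1 < b2:
        raise ValueError(f"boundaries must satisfy 0 < b1 < b2, got {boundaries}")
    label = np.zeros(dmap.dist.shape, dtype=np.uint8)
    inside = dmap.mask
    d = dmap.dist
    label[inside & (d < b1)] = REGION_CODES["membrane"]
    label[inside & (d >= b1) & (d < b2)] = REGION_CODES["peripheral"]
    label[inside & (d >= b2)] = REGION_CODES["deep"]
    return RegionPartition(label=label, boundaries=(b1, b2), spacing=dmap.spacing)


def split_halves(mask: CellMask, axis: str) -> HalfSplit:
    """Bisect the cell into ventral/dorsal halves of (near-)equal volume.

    The bisection plane is perpendicular to the annotated axis (``"+z"``,
    ``"-y"``, ...); the plane offset is chosen so the in-mask voxel counts on
    the two sides are as equal as possible (they can differ by at most one
    plane's worth). The sign gives the ventral direction: for ``"+y"`` the
    high-y side is ventral.
    """
    member = mask.member
    if not member.any():
        raise ValueError("empty mask")
    if len(axis) != 2 or axis[0] not in "+-" or axis[1] not in "zyx":
        raise ValueError(f"axis must look like '+z'/'-x', got {axis!r}")
    axis_index = "zyx".index(axis[1])
    sign = 1 if axis[0] == "+" else -1

    counts = member.sum(axis=tuple(i for i in range(3) if i != axis_index))
    cum = np.cumsum(counts)
    total = cum[-1]
    # plane_offset = last index of the low side; minimize count imbalance,
    # ties broken toward the smallest offset for determinism.
    imbalance = np.abs(2 * cum - total)
    plane_offset = int(np.argmin(imbalance))

    coords = np.arange(member.shape[axis_index])
    low_side = coords <= plane_offset
    shape = [1, 1, 1]
    shape[axis_index] = member.shape[axis_index]
    low_side = low_side.reshape(shape)

    half_label = np.zeros(member.shape, dtype=np.int8)
    # positive-direction side (high indices) is ventral when sign == +1
    half_label[member & ~low_side] = sign
    half_label[member & low_side] = -sign
    return HalfSplit(half_label=half_label, axis=axis, axis_index=axis_index, plane_offset=plane_offset)
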