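"""Single-cell segmentation from an intensity z-stack.

The pipeline: per-plane 2D Gaussian smoothing, scaled-Otsu binarization over
the full-stack histogram, per-plane dilate / fill holes / erode to close
staining gaps, a 3D erosion, deletion of components below a minimum volume,
and a matching 3D redilation. If more than one component survives pruning the
largest is kept and the event logged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk

from cytoshell.io_config import VoxelGrid3D, logger


class SegmentationError(RuntimeError):
    """No usable foreground could be extracted from the stack."""


@dataclasses.dataclass(frozen=True)
class CellMask:
    """Boolean single-cell mask with the spacing of its source grid."""

    member: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        member = np.asarray(self.member, dtype=bool)
        if member.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "member", member)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.member.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        return float(self.member.sum()) * self.voxel_volume_um3


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of :func:`segment_cell`; defaults follow the reference protocol."""

    smooth_sigma_um: float = 0.5
    otsu_scale: float = 1.0
    disk_radius_px: int = 2  # plane-wise dilate/erode element
    erode_3d_iterations: int = 1  # 6-connected cross, erode then redilate
    min_volume_um3: float = 10.0

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown segmentation parameters: {sorted(unknown)}")
        return cls(**d)


def _smooth_planewise(values: np.ndarray, spacing, sigma_um: float) -> np.ndarray:
    """2D Gaussian smooth applied independently to each z-plane."""
    if sigma_um <= 0:
        return np.asarray(values, dtype=np.float64)
    _, dy, dx = spacing
    sigma_px = (sigma_um / dy, sigma_um / dx)
    out = np.empty(values.shape, dtype=np.float64)
    for z in range(values.shape[0]):
        out[z] = gaussian(values[z], sigma=sigma_px, preserve_range=True)
    return out


def scaled_otsu_threshold(grid: VoxelGrid3D, scale: float = 1.0) -> float:
    """Otsu's between-class-variance threshold over the full-stack histogram,
    multiplied by *scale*.

    Raises
    ------
    SegmentationError
        If the image is constant (degenerate histogram).
    """
    values = grid.values
    if values.min() == values.max():
        raise SegmentationError("constant image: Otsu threshold undefined")
    # ravel: the threshold is computed over the full-stack histogram, and a
    # flat array sidesteps skimage's RGB-shape heuristics
    return float(threshold_otsu(values.ravel())) * float(scale)


def segment_cell(grid: VoxelGrid3D, params: SegmentationParams | None = None) -> CellMask:
    """Segment the single cell in *grid*; see module docstring for the pipeline.

    Raises
    ------
    SegmentationError
        If thresholding yields no foreground or no component reaches
        ``params.min_volume_um3``.
    """
    params = params or SegmentationParams()
    smoothed = _smooth_planewise(grid.values, grid.spacing, params.smooth_sigma_um)
    smoothed_grid = VoxelGrid3D(np.maximum(smoothed, 0.0), grid.spacing)
    threshold = scaled_otsu_threshold(smoothed_grid, params.otsu_scale)
    mask = smoothed > threshold
    if not mask.any():
        raise SegmentationError("no foreground voxels after thresholding")

    # Plane-wise closing with hole filling; image border is background.
    selem2d = disk(params.disk_radius_px)
    for z in range(mask.shape[0]):
        plane = ndimage.binary_dilation(mask[z], structure=selem2d)
        plane = ndimage.binary_fill_holes(plane)
        mask[z] = ndimage.binary_erosion(plane, structure=selem2d)

    cross3d = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=cross3d, iterations=params.erode_3d_iterations)

    voxel_volume = grid.voxel_volume_um3
    labels, n = ndimage.label(eroded, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        raise SegmentationError("no foreground left after 3D erosion")
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts * voxel_volume >= params.min_volume_um3) + 1
    if keep.size == 0:
        raise SegmentationError(
            f"no component reaches the minimum volume of {params.min_volume_um3} um^3"
        )
    if keep.size > 1:
        largest = keep[np.argmax(counts[keep - 1])]
        logger.warning(
            "segmentation found %d components >= %.1f um^3; keeping the largest",
            keep.size,
            params.min_volume_um3,
        )
        keep = np.array([largest])
    pruned = labels == keep[0]

    final = ndimage.binary_dilation(pruned, structure=cross3d, iterations=params.erode_3d_iterations)
    return CellMask(member=final, spacing=grid.spacing)


def qc_overlay(grid: VoxelGrid3D, mask: CellMask, path) -> None:
    """Write a two-panel QC image: mid-plane and max projection, with the mask
    contour overlaid, for human review of the segmentation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if grid.shape != mask.shape:
        raise ValueError("grid and mask shapes differ")
    if not mask.member.any():
        raise ValueError("mask has no foreground voxels")

    mid = grid.shape[0] // 2
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].imshow(grid.values[mid], cmap="gray")
    axes[0].contour(mask.member[mid].astype(float), levels=[0.5], colors="r", linewidths=0.8)
    axes[0].set_title(f"mid plane z={mid}")
    axes[1].imshow(grid.values.max(axis=0), cmap="gray")
    axes[1].contour(mask.member.max(axis=0).astype(float), levels=[0.5], colors="r", linewidths=0.8)
    axes[1].set_title("max projection")
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
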