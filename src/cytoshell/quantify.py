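"""Puncta thresholding and the per-cell distribution statistics.

Three statistics are produced from percentile-thresholded puncta masks:

* regional fold enrichment
  ``E_region = (V_puncta_in_region / V_region) / (V_puncta_in_cell / V_cell)``,
* object-overlap colocalization ``MOC(A, B) = V(A & B) / V(A)`` (asymmetric),
  whole-cell and per shell,
* the ventral/dorsal puncta-volume ratio after volume bisection.

Volumes enter every ratio as voxel counts (the constant voxel volume
cancels); absolute um^3 values are carried alongside for reporting.
Statistics whose denominator is empty are flagged as undefined (NaN), never
silently dropped.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np

from cytoshell.io_config import CellRecord, VoxelGrid3D, logger
from cytoshell.regionalize import (
    DEFAULT_BOUNDARIES,
    REGION_NAMES,
    HalfSplit,
    RegionPartition,
    assign_regions,
    distance_map,
    split_halves,
)
from cytoshell.segmentation import CellMask, SegmentationParams, segment_cell, _smooth_planewise

DEFAULT_PERCENTILE = 95.0
DEFAULT_SIGMA_UM = 0.1


class NoSignalError(RuntimeError):
    """A statistic was requested for a cell with no puncta at all."""


@dataclasses.dataclass(frozen=True)
class PunctaMask:
    """Thresholded signal voxels of one channel, constrained to the cell mask."""

    member: np.ndarray
    spacing: tuple[float, float, float]
    source_channel: str = ""
    threshold: float = float("nan")

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def count(self) -> int:
        return int(self.member.sum())

    @property
    def volume_um3(self) -> float:
        return self.count * self.voxel_volume_um3


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Per-region fold enrichment with the volume terms that produced it."""

    enrichment: dict[str, float]  # region -> E (NaN where region volume is 0)
    puncta_counts: dict[str, int]
    region_counts: dict[str, int]
    puncta_count_cell: int
    cell_count: int


@dataclasses.dataclass(frozen=True)
class ColocResult:
    """Whole-cell and per-region MOC of channel A against channel B.

    ``moc_cell = V(A & B in cell) / V(A in cell)``; regional terms use the
    same formula restricted to a shell. NaN marks an empty denominator.
    """

    moc_cell: float
    moc_region: dict[str, float]
    overlap_counts: dict[str, int]
    a_counts: dict[str, int]
    overlap_count_cell: int
    a_count_cell: int


@dataclasses.dataclass(frozen=True)
class PolarityResult:
    """Ventral/dorsal puncta-volume ratio; NaN (flagged) when dorsal is empty."""

    vd_ratio: float
    ventral_count: int
    dorsal_count: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.vd_ratio)


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the smallest order statistic whose rank is at
    or above ``percentile/100 * n``. No interpolation, well defined under
    integer ties."""
    values = np.asarray(values).ravel()
    n = values.size
    if n == 0:
        raise ValueError("empty value set")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(np.partition(values, rank - 1)[rank - 1])


def threshold_puncta(
    grid: VoxelGrid3D,
    mask: CellMask,
    sigma_um: float = DEFAULT_SIGMA_UM,
    percentile: float = DEFAULT_PERCENTILE,
    channel_name: str = "",
) -> PunctaMask:
    """Binarize puncta: per-plane Gaussian smooth, then keep in-mask voxels
    strictly above the nearest-rank percentile of in-mask smoothed intensity.

    A constant in-mask intensity yields an empty puncta mask with a warning
    (nothing lies strictly above the threshold); an empty cell mask is an
    error.
    """
    if grid.shape != mask.shape:
        raise ValueError("grid and mask shapes differ")
    if not mask.member.any():
        raise ValueError("empty cell mask")
    smoothed = _smooth_planewise(grid.values, grid.spacing, sigma_um)
    inside = smoothed[mask.member]
    threshold = nearest_rank_threshold(inside, percentile)
    member = mask.member & (smoothed > threshold)
    if inside.min() == inside.max():
        logger.warning("constant in-mask intensity for channel %r: empty puncta mask", channel_name)
    return PunctaMask(
        member=member, spacing=grid.spacing, source_channel=channel_name, threshold=threshold
    )


def regional_enrichment(puncta: PunctaMask, partition: RegionPartition) -> EnrichmentResult:
    """Fold enrichment of puncta density per shell relative to the whole cell.

    ``E = (V_in_region / V_region) / (V_in_cell / V_cell)``; a region of zero
    volume gets NaN. Raises :class:`NoSignalError` when the cell holds no
    puncta at all.
    """
    cell = partition.label > 0
    if np.any(puncta.member & ~cell):
        raise ValueError("puncta mask extends outside the cell")
    n_cell = int(cell.sum())
    n_puncta = int(puncta.member.sum())
    if n_puncta == 0:
        raise NoSignalError("no puncta in cell: enrichment undefined")
    region_counts = partition.region_counts()
    puncta_counts = {
        name: int((puncta.member & partition.region_mask(name)).sum()) for name in REGION_NAMES
    }
    cell_density = n_puncta / n_cell
    enrichment = {}
    for name in REGION_NAMES:
        if region_counts[name] == 0:
            enrichment[name] = float("nan")
        else:
            enrichment[name] = (puncta_counts[name] / region_counts[name]) / cell_density
    return EnrichmentResult(
        enrichment=enrichment,
        puncta_counts=puncta_counts,
        region_counts=region_counts,
        puncta_count_cell=n_puncta,
        cell_count=n_cell,
    )


def manders_overlap(
    puncta_a: PunctaMask, puncta_b: PunctaMask, partition: RegionPartition
) -> ColocResult:
    """Object-overlap colocalization of A against B, whole-cell and per shell.

    Asymmetric: ``MOC(A, B) = V(A & B) / V(A)``. Empty denominators are
    flagged NaN rather than raised.
    """
    cell = partition.label > 0
    if np.any(puncta_a.member & ~cell) or np.any(puncta_b.member & ~cell):
        raise ValueError("puncta mask extends outside the cell")
    overlap = puncta_a.member & puncta_b.member
    a_count_cell = int(puncta_a.member.sum())
    overlap_count_cell = int(overlap.sum())
    moc_cell = overlap_count_cell / a_count_cell if a_count_cell else float("nan")
    a_counts, overlap_counts, moc_region = {}, {}, {}
    for name in REGION_NAMES:
        region = partition.region_mask(name)
        a_counts[name] = int((puncta_a.member & region).sum())
        overlap_counts[name] = int((overlap & region).sum())
        moc_region[name] = (
            overlap_counts[name] / a_counts[name] if a_counts[name] else float("nan")
        )
    return ColocResult(
        moc_cell=moc_cell,
        moc_region=moc_region,
        overlap_counts=overlap_counts,
        a_counts=a_counts,
        overlap_count_cell=overlap_count_cell,
        a_count_cell=a_count_cell,
    )


def ventral_dorsal_ratio(puncta: PunctaMask, split: HalfSplit) -> PolarityResult:
    """Ratio of ventral to dorsal puncta volume; NaN-flagged when the dorsal
    half carries no puncta."""
    ventral = int((puncta.member & split.half_mask("ventral")).sum())
    dorsal = int((puncta.member & split.half_mask("dorsal")).sum())
    ratio = ventral / dorsal if dorsal else float("nan")
    return PolarityResult(vd_ratio=ratio, ventral_count=ventral, dorsal_count=dorsal)


def quantify_cell(
    channels: Mapping[str, VoxelGrid3D],
    record: CellRecord,
    mask: CellMask | None = None,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
    percentile: float = DEFAULT_PERCENTILE,
    sigma_um: float = DEFAULT_SIGMA_UM,
    segmentation_params: SegmentationParams | None = None,
    receptor_channel: str = "receptor",
    marker_channel: str = "rab",
) -> dict:
    """Run the full per-cell analysis and return one flat results row.

    *channels* maps channel names to grids; the receptor channel is required,
    the endosomal marker channel optional (colocalization fields are left NaN
    without it). If *mask* is None the receptor channel is segmented first.
    """
    if receptor_channel not in channels:
        raise KeyError(f"receptor channel {receptor_channel!r} missing from stack")
    receptor = channels[receptor_channel]
    if mask is None:
        mask = segment_cell(receptor, segmentation_params)

    dmap = distance_map(mask)
    partition = assign_regions(dmap, boundaries)
    split = split_halves(mask, record.ventral_axis)

    puncta_a = threshold_puncta(receptor, mask, sigma_um, percentile, receptor_channel)
    enr = regional_enrichment(puncta_a, partition)
    pol = ventral_dorsal_ratio(puncta_a, split)

    voxvol = mask.voxel_volume_um3
    row: dict = {
        "cell_id": record.cell_id,
        "condition": record.condition,
        "stage": record.stage,
        "ventral_axis": record.ventral_axis,
        "cell_volume_um3": mask.volume_um3,
        "puncta_volume_um3": puncta_a.count * voxvol,
        "puncta_threshold": puncta_a.threshold,
        "vd_ratio": pol.vd_ratio,
        "b1_um": boundaries[0],
        "b2_um": boundaries[1],
        "percentile": percentile,
        "sigma_um": sigma_um,
    }
    for name in REGION_NAMES:
        row[f"E_{name}"] = enr.enrichment[name]
        row[f"V_{name}_um3"] = enr.region_counts[name] * voxvol

    if marker_channel in channels:
        puncta_b = threshold_puncta(
            channels[marker_channel], mask, sigma_um, percentile, marker_channel
        )
        coloc = manders_overlap(puncta_a, puncta_b, partition)
        row["moc_cell"] = coloc.moc_cell
        for name in REGION_NAMES:
            row[f"moc_{name}"] = coloc.moc_region[name]
    else:
        row["moc_cell"] = float("nan")
        for name in REGION_NAMES:
            row[f"moc_{name}"] = float("nan")
    return row
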