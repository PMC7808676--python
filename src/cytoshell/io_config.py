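"""Image-stack and tabular I/O, pipeline configuration, logging setup.

Axis order is fixed as ``(z, y, x)`` for single-channel grids and
``(c, z, y, x)`` for multi-channel stacks. Voxel spacing is carried in
micrometers as ``(dz, dy, dx)``; a config override always wins over file
metadata.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("cytoshell")

#: Stage vocabulary accepted in cell metadata. Treatment conditions may add
#: their own labels via config; these are the built-in cell-cycle stages.
STAGE_VOCABULARY = ("premitotic", "prophase", "metaphase", "anaphase", "postmitotic")

VALID_AXES = ("+z", "-z", "+y", "-y", "+x", "-x")


class SpacingError(ValueError):
    """Voxel spacing unavailable from metadata and no override supplied."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid3D:
    """A single-channel 3D intensity image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Non-negative intensities, arbitrary units.
    spacing : tuple of float
        Physical voxel spacing ``(dz, dy, dx)`` in micrometers.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if any(s < 2 for s in values.shape):
            raise ValueError(f"need at least 2 voxels per axis, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("intensities must be finite")
        if values.min() < 0:
            raise ValueError("intensities must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclasses.dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata: condition, mitotic stage, dorsal-ventral axis.

    ``ventral_axis`` names the signed image axis pointing ventrally,
    e.g. ``"+y"`` means larger y-indices are ventral.
    """

    cell_id: str
    condition: str = "control"
    stage: str = "premitotic"
    ventral_axis: str = "+y"

    def __post_init__(self) -> None:
        if self.ventral_axis not in VALID_AXES:
            raise ValueError(f"ventral_axis must be one of {VALID_AXES}, got {self.ventral_axis!r}")


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in um from ImageJ or OME metadata, else None."""
    # OME-TIFF: physical sizes in the OME-XML.
    if tf.ome_metadata:
        try:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                dz = px.get("PhysicalSizeZ")
                dy = px.get("PhysicalSizeY")
                dx = px.get("PhysicalSizeX")
                if dz and dy and dx:
                    return (float(dz), float(dy), float(dx))
        except Exception:  # malformed OME block: fall through to ImageJ tags
            pass
    # ImageJ-style: 'spacing' for z, resolution tags for x/y (pixels per um).
    ij = tf.imagej_metadata
    if ij is not None and "spacing" in ij:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None and yres is not None:
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            if xr > 0 and yr > 0:
                return (float(ij["spacing"]), 1.0 / yr, 1.0 / xr)
    return None


def read_stack(
    path: str | Path,
    channel: int = 0,
    spacing_override: Sequence[float] | None = None,
) -> VoxelGrid3D:
    """Read one channel of a TIFF / OME-TIFF z-stack as a :class:`VoxelGrid3D`.

    Spacing precedence: ``spacing_override`` > file metadata. Axis order is
    normalized to (z, y, x) regardless of on-disk layout.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    IndexError
        If *channel* is out of range.
    SpacingError
        If no spacing is available from metadata and no override is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'ZYX', 'ZCYX', 'CZYX'
        spacing = _spacing_from_tiff(tf)

    # Normalize to (C, Z, Y, X): treat I/Q page axes as Z, squeeze singleton
    # extras (T, S), then reorder.
    axes = axes.replace("I", "Z").replace("Q", "Z")
    keep = [i for i, a in enumerate(axes) if a in "CZYX"]
    extras = [i for i, a in enumerate(axes) if a not in "CZYX"]
    if any(data.shape[i] != 1 for i in extras):
        raise ValueError(f"cannot interpret non-singleton axes {axes!r} as a (C, Z, Y, X) stack")
    data = data.transpose(keep + extras).reshape([data.shape[i] for i in keep])
    axes = "".join(axes[i] for i in keep)
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    if sorted(axes) != sorted("CZYX"):
        raise ValueError(f"cannot interpret axes {axes!r} as a (C, Z, Y, X) stack")
    data = np.transpose(data, [axes.index(a) for a in "CZYX"])

    n_channels = data.shape[0]
    if not 0 <= channel < n_channels:
        raise IndexError(f"channel {channel} out of range for {n_channels}-channel stack")

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise SpacingError(f"{path}: no voxel spacing in metadata and no override supplied")
    return VoxelGrid3D(values=np.asarray(data[channel], dtype=np.float64), spacing=spacing)


def write_stack(
    path: str | Path,
    channels: Sequence[np.ndarray] | np.ndarray,
    spacing: Sequence[float],
) -> None:
    """Write one or more (z, y, x) channels as an ImageJ-compatible TIFF.

    Spacing is recorded so :func:`read_stack` round-trips it: z-step in the
    ImageJ ``spacing`` field, x/y pixel size in the resolution tags.
    """
    data = np.asarray(channels)
    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise ValueError("channels must be a (z,y,x) array or a stack of them")
    dz, dy, dx = (float(s) for s in spacing)
    # ImageJ hyperstacks expect TZCYX ordering: transpose (C,Z,Y,X) -> (Z,C,Y,X).
    data = np.ascontiguousarray(np.transpose(data, (1, 0, 2, 3)))
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZCYX"},
    )


def write_results_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write per-cell statistics rows as CSV, lossless to 12 significant digits.

    An empty collection yields a header-only file (header inferred from the
    default result schema is not possible, so an empty frame is written).
    """
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Parse a YAML pipeline configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
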