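import numpy as np
import pytest

from cytoshell.segmentation import CellMask


def brute_force_distance_map(member: np.ndarray, spacing) -> np.ndarray:
    """All-pairs minimum distance from in-mask voxel centers to background
    voxel centers (border padded as background). Independent oracle for the
    EDT; O(n^2), only usable on tiny masks."""
    from scipy.spatial.distance import cdist

    padded = np.pad(member, 1, mode="constant", constant_values=False)
    spacing = np.asarray(spacing, dtype=float)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, dtype=float)
    if fg.size:
        d = cdist(fg * spacing, bg * spacing).min(axis=1)
        out[tuple(fg.T)] = d
    return out[1:-1, 1:-1, 1:-1]


def random_mask(rng: np.random.Generator, max_side: int = 16) -> tuple[np.ndarray, tuple]:
    """A random nonempty blob-ish mask with random anisotropic spacing."""
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    p = rng.uniform(0.2, 0.7)
    member = rng.random(shape) < p
    if not member.any():
        member[tuple(s // 2 for s in shape)] = True
    spacing = tuple(rng.uniform(0.05, 0.5, size=3))
    return member, spacing


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube_mask():
    """5x5x5 cube centered in a 7x7x7 grid, isotropic 1 um spacing."""
    member = np.zeros((7, 7, 7), dtype=bool)
    member[1:6, 1:6, 1:6] = True
    return CellMask(member=member, spacing=(1.0, 1.0, 1.0))
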