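"""Raw depth frame -> binarized super-pixel occupancy grid.

The chain is DF -> DFm (floor clamp) -> CF (null fill) -> FF (reference-frame
slicing) -> FFSobel (edge carving) -> FFs (block binarization).  Each step
checks the stage tag of its input, so frames cannot skip ahead.

Depth-level slicing is the trick that makes a fixed Sobel threshold work: any
pixel that deviates from the person-free reference frame by more than
``th_person`` is boosted by ``gap_coeff`` (6,000 mm), so the boundary between
a new element (a person) and whatever it touches always carries a gradient
far above ``th_sobel``, no matter how similar their raw depths are.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .frames import DepthFrame, Stage, SystemConfig

__all__ = [
    "SuperPixelFrame",
    "clamp_floor",
    "fill_nulls",
    "compute_foreground",
    "carve_edges",
    "superpixelize",
    "capture_reference",
]


@dataclasses.dataclass
class SuperPixelFrame:
    """Binary occupancy grid; one cell per block of the source frame."""

    grid: np.ndarray  # (40, 40) of {0, 1} at the default geometry
    source_index: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("super-pixel grid must be binary")


def clamp_floor(frame: DepthFrame, cfg: SystemConfig) -> DepthFrame:
    """Snap every pixel within ``floor_band`` of the floor onto the floor.

    Nulls (0) are left untouched; so are pixels farther than the band from
    ``max_height``.
    """
    frame.require_stage(Stage.DF)
    g = frame.grid
    out = g.copy()
    near_floor = (g != 0) & (cfg.max_height - g.astype(np.int64) <= cfg.floor_band)
    out[near_floor] = cfg.max_height
    return frame.with_grid(out, Stage.DFM)


def fill_nulls(frame: DepthFrame, cfg: SystemConfig | None = None) -> DepthFrame:
    """Replace every null pixel with the first valid value in its row.

    Interior and trailing null runs take the nearest valid value to their
    left; a leading run takes the first valid value to its right; a row with
    no valid value at all becomes the floor (``max_height``).  The operation
    is total (no zero survives) and idempotent.
    """
    frame.require_stage(Stage.DFM, Stage.DF)
    max_height = (cfg.max_height if cfg is not None else 3000)
    g = frame.grid
    rows, cols = g.shape
    valid = g != 0
    col_idx = np.arange(cols)

    # forward fill: index of the nearest valid column at or before each cell
    fwd = np.where(valid, col_idx[None, :], -1)
    np.maximum.accumulate(fwd, axis=1, out=fwd)
    # backward fill for leading runs
    bwd = np.where(valid, col_idx[None, :], cols)
    bwd = np.flip(np.minimum.accumulate(np.flip(bwd, axis=1), axis=1), axis=1)

    out = np.empty_like(g)
    row_idx = np.arange(rows)[:, None]
    use_fwd = fwd >= 0
    use_bwd = ~use_fwd & (bwd < cols)
    out[use_fwd] = g[row_idx * np.ones_like(fwd), np.clip(fwd, 0, None)][use_fwd]
    out[use_bwd] = g[row_idx * np.ones_like(bwd), np.clip(bwd, None, cols - 1)][use_bwd]
    out[~use_fwd & ~use_bwd] = max_height  # entirely null row
    return frame.with_grid(out, Stage.CF)


def compute_foreground(cf: DepthFrame, rf: DepthFrame, cfg: SystemConfig) -> DepthFrame:
    """Depth-level slicing of the current frame against the reference frame.

    FF(x, y) = CF(x, y) + gap_coeff  where |CF - RF| > th_person, else CF.
    The inequality is strict: a deviation of exactly ``th_person`` is treated
    as background.
    """
    cf.require_stage(Stage.CF)
    rf.require_stage(Stage.RF, Stage.CF)
    if cf.shape != rf.shape:
        raise ValueError(f"shape mismatch: CF {cf.shape} vs RF {rf.shape}")
    diff = np.abs(cf.grid.astype(np.int64) - rf.grid.astype(np.int64))
    out = cf.grid.astype(np.int64).copy()
    out[diff > cfg.th_person] += cfg.gap_coeff
    return cf.with_grid(out, Stage.FF)


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
_SOBEL_Y = _SOBEL_X.T


def sobel_magnitude(grid: np.ndarray) -> np.ndarray:
    """|Gx| + |Gy| with the standard 3x3 kernels and edge replication.

    The L1 combination keeps the computation exact in integers; ``th_sobel``
    is calibrated against it (a clean step of D between neighbours reads as
    4*D).
    """
    g = np.asarray(grid, dtype=np.int64)
    gx = ndimage.convolve(g, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(g, _SOBEL_Y, mode="nearest")
    return np.abs(gx) + np.abs(gy)


def carve_edges(ff: DepthFrame, cfg: SystemConfig) -> DepthFrame:
    """Set high-gradient pixels (object bounds) to the floor depth level."""
    ff.require_stage(Stage.FF)
    mag = sobel_magnitude(ff.grid)
    out = ff.grid.copy()
    out[mag >= cfg.th_sobel] = cfg.max_height
    return ff.with_grid(out, Stage.FFSOBEL)


def superpixelize(fs: DepthFrame, cfg: SystemConfig) -> SuperPixelFrame:
    """Binarize into blocks: a super-pixel is 1 iff no pixel of its block
    sits at the floor depth level."""
    fs.require_stage(Stage.FFSOBEL)
    h, w = fs.shape
    if h % cfg.block_h or w % cfg.block_w:
        raise ValueError("frame dimensions not divisible by block dimensions")
    gh, gw = h // cfg.block_h, w // cfg.block_w
    occupied = (fs.grid != cfg.max_height)
    blocks = occupied.reshape(gh, cfg.block_h, gw, cfg.block_w)
    grid = blocks.all(axis=(1, 3)).astype(np.uint8)
    return SuperPixelFrame(grid=grid, source_index=fs.index)


def capture_reference(frames: list[DepthFrame], n: int | None = None) -> DepthFrame:
    """Pixel-wise median of the first ``n`` person-free CF frames.

    The reference is captured once, in the initial phase, and kept static for
    the whole run.  The caller is responsible for the scene being empty of
    people.
    """
    if n is None:
        n = len(frames)
    if n < 1 or not frames:
        raise ValueError("capture_reference needs at least one frame")
    stack = []
    for frame in frames[:n]:
        frame.require_stage(Stage.CF)
        stack.append(frame.grid)
    med = np.median(np.stack(stack), axis=0).astype(frames[0].grid.dtype)
    return DepthFrame(grid=med, stage=Stage.RF, index=frames[0].index,
                      fps=frames[0].fps)
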