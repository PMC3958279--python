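"""Anthropometric identification of human subjects in a top-view depth frame.

A blob is accepted as a person when, looking outward from its peak point
(normally the head apex), three features hold:

* **head-ground gap** — along some scan direction a single-pixel step drops
  by at least half the depth at the peak (the silhouette edge of a standing
  body seen from above);
* **head-shoulder gap** — in at least ``min_drop_directions`` directions the
  cumulative drop from the peak first lands inside the 200-300 mm window
  (head height above the shoulders) before overshooting it;
* **head dimension** — the four diameters through the peak (N-S, NE-SW, E-W,
  SE-NW), converted to millimeters at the peak's depth, all fall in the
  200-400 mm range and are mutually comparable (max/min bounded).

Pixel extents are converted to real lengths with the pinhole relation
``Wr = 2 * d * tan(half_fov) * Wp / frame_size``; diagonal runs combine the
two axis conversions in quadrature.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .frames import DepthFrame, Stage, SystemConfig

__all__ = [
    "DIRECTIONS",
    "BodyPoints",
    "DirectionalScan",
    "PersonCheck",
    "central_superpixel",
    "block_center_pixel",
    "blob_pixel_mask",
    "peak_point",
    "directional_scan",
    "head_ground_gap",
    "head_shoulder_gap",
    "pixel_to_mm",
    "mm_to_pixels",
    "head_dimensions",
    "is_person",
]

# (drow, dcol) steps; order fixed: principal directions first four, opposites
# at index + 4
DIRECTIONS: dict[str, tuple[int, int]] = {
    "N": (-1, 0), "NE": (-1, 1), "E": (0, 1), "SE": (1, 1),
    "S": (1, 0), "SW": (1, -1), "W": (0, -1), "NW": (-1, -1),
}
_OPPOSITE = {"N": "S", "NE": "SW", "E": "W", "SE": "NW"}
_AXIS = {"N": "vertical", "S": "vertical", "E": "horizontal", "W": "horizontal",
         "NE": "diagonal", "SE": "diagonal", "SW": "diagonal", "NW": "diagonal"}


@dataclasses.dataclass
class BodyPoints:
    """Anchor points of a blob, in 0-based (row, col) coordinates.

    ``scp``/``smp`` live on the super-pixel grid, ``cp``/``mp`` on the pixel
    grid.  ``scp`` is the blob member nearest its coordinate centroid (used
    for tracking); ``mp`` is the averaged peak point (normally the head).
    """

    cp: tuple[int, int]
    scp: tuple[int, int]
    mp: tuple[int, int]
    smp: tuple[int, int]


@dataclasses.dataclass
class DirectionalScan:
    """Adjacent-step depth differences from a point to the frame border.

    ``diffs[d][i]`` is CF(step i+1) - CF(step i) walking direction ``d``; a
    positive value is a drop away from the sensor.  ``border[d]`` is the
    number of steps to the frame boundary.
    """

    origin: tuple[int, int]
    diffs: dict[str, np.ndarray]
    border: dict[str, int]


def central_superpixel(cells: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Member cell nearest the blob's coordinate mean; ties break to the
    smallest row, then smallest column."""
    if not len(cells):
        raise ValueError("empty blob")
    arr = np.asarray(cells, dtype=float)
    mid = arr.mean(axis=0)
    d2 = ((arr - mid) ** 2).sum(axis=1)
    best = np.lexsort((arr[:, 1], arr[:, 0], d2))[0]
    r, c = cells[int(best)]
    return int(r), int(c)


def block_center_pixel(sp: tuple[int, int], cfg: SystemConfig) -> tuple[int, int]:
    """Center pixel of a super-pixel's block on the full-resolution frame."""
    r, c = sp
    return (r * cfg.block_h + cfg.block_h // 2, c * cfg.block_w + cfg.block_w // 2)


def blob_pixel_mask(cells: Iterable[tuple[int, int]], cfg: SystemConfig) -> np.ndarray:
    """Boolean pixel-footprint of a set of super-pixel cells."""
    mask = np.zeros(cfg.frame_shape, dtype=bool)
    bh, bw = cfg.block_h, cfg.block_w
    for r, c in cells:
        mask[r * bh:(r + 1) * bh, c * bw:(c + 1) * bw] = True
    return mask


def pixel_to_mm(wp: float, d: float, axis: str, cfg: SystemConfig) -> float:
    """Convert a pixel extent at depth ``d`` into millimeters.

    ``axis`` is 'horizontal', 'vertical' or 'diagonal'; a diagonal step
    advances one row and one column at a time, so its real length is the
    quadrature sum of the two axis conversions at the same step count.
    """
    if d <= 0:
        raise ValueError("depth must be positive")
    if wp < 0:
        raise ValueError("pixel extent must be non-negative")
    wx = 2.0 * d * math.tan(math.radians(cfg.fov_half_x)) * wp / cfg.frame_width
    wy = 2.0 * d * math.tan(math.radians(cfg.fov_half_y)) * wp / cfg.frame_height
    if axis == "horizontal":
        return wx
    if axis == "vertical":
        return wy
    if axis == "diagonal":
        return math.hypot(wx, wy)
    raise ValueError(f"unknown axis: {axis!r}")


def mm_to_pixels(wr: float, d: float, axis: str, cfg: SystemConfig) -> float:
    """Inverse of :func:`pixel_to_mm` for the two axis cases."""
    if axis == "horizontal":
        return wr * cfg.frame_width / (2.0 * d * math.tan(math.radians(cfg.fov_half_x)))
    if axis == "vertical":
        return wr * cfg.frame_height / (2.0 * d * math.tan(math.radians(cfg.fov_half_y)))
    raise ValueError(f"unknown axis: {axis!r}")


def peak_point(cells: Sequence[tuple[int, int]], cf: DepthFrame,
               cfg: SystemConfig) -> tuple[int, int]:
    """Averaged location of the blob's closest approach to the sensor.

    The pixel of minimum depth is found first (ties resolve to the pixel
    nearest the blob's pixel centroid, then row-major), then all blob pixels
    within ``peak_planar_radius`` mm planar distance and ``peak_depth_window``
    mm of that minimum are averaged.  The result is snapped back into the
    blob footprint if rounding pushed it out.
    """
    cf.require_stage(Stage.CF)
    if not len(cells):
        raise ValueError("empty blob")
    mask = blob_pixel_mask(cells, cfg)
    rows, cols = np.nonzero(mask)
    depths = cf.grid[rows, cols].astype(np.int64)
    dmin = depths.min()

    centroid = (rows.mean(), cols.mean())
    at_min = depths == dmin
    d2 = (rows[at_min] - centroid[0]) ** 2 + (cols[at_min] - centroid[1]) ** 2
    order = np.lexsort((cols[at_min], rows[at_min], d2))[0]
    pr = rows[at_min][int(order)]
    pc = cols[at_min][int(order)]

    # millimeters per pixel at the peak's depth, per axis
    sx = pixel_to_mm(1, int(dmin), "horizontal", cfg)
    sy = pixel_to_mm(1, int(dmin), "vertical", cfg)
    planar = ((rows - pr) * sy) ** 2 + ((cols - pc) * sx) ** 2
    near = (planar <= cfg.peak_planar_radius ** 2) & \
           (depths <= dmin + cfg.peak_depth_window)
    mr = int(round(rows[near].mean()))
    mc = int(round(cols[near].mean()))
    if not mask[mr, mc]:
        d2 = (rows[near] - mr) ** 2 + (cols[near] - mc) ** 2
        j = int(np.argmin(d2))
        mr, mc = int(rows[near][j]), int(cols[near][j])
    return mr, mc


def directional_scan(cf: DepthFrame, mp: tuple[int, int]) -> DirectionalScan:
    """Adjacent-step depth differences from ``mp`` to the border, 8 ways."""
    cf.require_stage(Stage.CF)
    h, w = cf.shape
    r0, c0 = mp
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("scan origin outside the frame")
    g = cf.grid.astype(np.int64)
    diffs: dict[str, np.ndarray] = {}
    border: dict[str, int] = {}
    for name, (dr, dc) in DIRECTIONS.items():
        steps_r = (r0 if dr < 0 else h - 1 - r0) if dr else None
        steps_c = (c0 if dc < 0 else w - 1 - c0) if dc else None
        n = min(s for s in (steps_r, steps_c) if s is not None)
        rr = r0 + dr * np.arange(n + 1)
        cc = c0 + dc * np.arange(n + 1)
        line = g[rr, cc]
        diffs[name] = np.diff(line)
        border[name] = n
    return DirectionalScan(origin=(r0, c0), diffs=diffs, border=border)


def head_ground_gap(scan: DirectionalScan, depth_at_mp: int) -> bool:
    """True iff some direction holds a single step >= half the peak depth."""
    half = depth_at_mp / 2.0
    return any((d >= half).any() for d in scan.diffs.values() if d.size)


def _ground_gap_distance(diffs: np.ndarray, half: float) -> int | None:
    hits = np.flatnonzero(diffs >= half)
    return int(hits[0]) + 1 if hits.size else None


def _shoulder_gap_distance(diffs: np.ndarray, lo: int, hi: int) -> int | None:
    """Steps until the cumulative drop first lands in [lo, hi]; ``None`` if it
    overshoots the window or never reaches it."""
    cum = np.cumsum(diffs)
    for i, v in enumerate(cum):
        if lo <= v <= hi:
            return i + 1
        if v > hi:
            return None
    return None


def head_shoulder_gap(scan: DirectionalScan, cfg: SystemConfig) -> int:
    """Number of directions whose cumulative drop lands in the head-shoulder
    window before exceeding it."""
    lo, hi = cfg.head_drop_range
    return sum(
        _shoulder_gap_distance(scan.diffs[name], lo, hi) is not None
        for name in DIRECTIONS
    )


def head_dimensions(scan: DirectionalScan, d: int, cfg: SystemConfig) -> dict[str, float]:
    """The four real lengths (mm) through the peak: N+S, NE+SW, E+W, SE+NW.

    Per direction the extent is the distance at which a depth-gap condition
    (head-shoulder, else head-ground) is first met; a direction meeting
    neither contributes its distance to the frame border, which pushes the
    sum of a non-head shape out of range.
    """
    lo, hi = cfg.head_drop_range
    half = d / 2.0
    extent: dict[str, int] = {}
    for name in DIRECTIONS:
        diffs = scan.diffs[name]
        cands = [x for x in (_shoulder_gap_distance(diffs, lo, hi),
                             _ground_gap_distance(diffs, half)) if x is not None]
        extent[name] = min(cands) if cands else scan.border[name]
    out: dict[str, float] = {}
    for name, opp in _OPPOSITE.items():
        wp = extent[name] + extent[opp]
        out[f"{name}+{opp}"] = pixel_to_mm(wp, d, _AXIS[name], cfg)
    return out


@dataclasses.dataclass
class PersonCheck:
    """Outcome of the three anthropometric checks for one blob."""

    mp: tuple[int, int]
    depth_at_mp: int
    ground_gap: bool
    drop_directions: int
    dimensions: dict[str, float]

    @property
    def dimensions_ok(self) -> bool:
        vals = list(self.dimensions.values())
        lo, hi = self._diag_range
        if not all(lo <= v <= hi for v in vals):
            return False
        return max(vals) / min(vals) <= self._ratio

    _diag_range: tuple[int, int] = (200, 400)
    _ratio: float = 1.5

    @property
    def accepted(self) -> bool:
        return self.ground_gap and self.drop_directions >= self._min_dirs \
            and self.dimensions_ok

    _min_dirs: int = 2


def check_person(cells: Sequence[tuple[int, int]], cf: DepthFrame,
                 cfg: SystemConfig) -> PersonCheck:
    """Run the three checks and return the full evidence."""
    mp = peak_point(cells, cf, cfg)
    d = int(cf.grid[mp])
    scan = directional_scan(cf, mp)
    check = PersonCheck(
        mp=mp,
        depth_at_mp=d,
        ground_gap=head_ground_gap(scan, d),
        drop_directions=head_shoulder_gap(scan, cfg),
        dimensions=head_dimensions(scan, d, cfg),
    )
    check._diag_range = tuple(cfg.head_diag_range)  # type: ignore[assignment]
    check._ratio = cfg.head_comparability_ratio
    check._min_dirs = cfg.min_drop_directions
    return check


def is_person(cells: Sequence[tuple[int, int]], cf: DepthFrame,
              cfg: SystemConfig) -> bool:
    """Whether a blob passes all three anthropometric checks."""
    return check_person(cells, cf, cfg).accepted
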