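"""Depth-frame data model, system configuration, and sequence / event I/O.

The sensor is assumed ceiling-mounted, looking straight down, at
``max_height`` millimeters above the floor.  A frame is a 240x320 grid of
unsigned 16-bit depth values in millimeters; 0 encodes a sensor dropout
(null).  Frames carry a *stage* tag that records how far through the
preprocessing chain they are:

DF       raw input depth frame (nulls allowed)
DFm      floor-clamped frame (nulls allowed)
CF       current frame, nulls filled (no zeros)
RF       reference frame: a person-free CF of the static scene
FF       foreground frame: CF with changed pixels boosted by ``gap_coeff``
FFSOBEL  FF with high-gradient object bounds carved to the floor level
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Stage",
    "SystemConfig",
    "DepthFrame",
    "FallEvent",
    "read_sequence",
    "write_sequence",
    "write_events",
    "read_events",
    "write_heights_csv",
]


class Stage(enum.Enum):
    """Preprocessing stage of a depth frame."""

    DF = "DF"
    DFM = "DFm"
    CF = "CF"
    RF = "RF"
    FF = "FF"
    FFSOBEL = "FFSobel"


@dataclasses.dataclass
class SystemConfig:
    """All tunable parameters of the pipeline, in one flat structure.

    Units are millimeters unless stated otherwise.  The defaults are the
    operating point for a sensor mounted 3 m above the floor.
    """

    max_height: int = 3000          # sensor-to-floor distance (MaxHeight)
    floor_band: int = 200           # clamp-to-floor band below max_height
    th_person: int = 50             # |CF-RF| threshold revealing new elements
    gap_coeff: int = 6000           # depth-level slicing boost for foreground
    th_sobel: int = 2000            # gradient-magnitude carve threshold
    fall_threshold: int = 400       # person height below this -> fall
    head_drop_range: tuple[int, int] = (200, 300)   # head-shoulder drop window
    head_diag_range: tuple[int, int] = (200, 400)   # admissible head extents
    min_drop_directions: int = 2    # directions that must show the drop
    fov_half_x: float = 28.5        # horizontal half angle of view, degrees
    fov_half_y: float = 21.5        # vertical half angle of view, degrees
    frame_width: int = 320          # pixels
    frame_height: int = 240         # pixels
    block_w: int = 8                # super-pixel block width, pixels
    block_h: int = 6                # super-pixel block height, pixels
    fps: int = 30                   # frame rate, Hz
    fusion_split_radius: int = 5    # Chebyshev radius for fusion splitting, super-pixels
    head_comparability_ratio: float = 1.5   # max/min ratio of head extents
    peak_planar_radius: int = 100   # planar window for peak averaging, mm
    peak_depth_window: int = 50     # depth window for peak averaging, mm
    track_grace_frames: int = 15    # frames an unmatched person survives

    def __post_init__(self) -> None:
        if self.frame_width % self.block_w or self.frame_height % self.block_h:
            raise ValueError("frame dimensions must be divisible by block dimensions")
        for name in ("max_height", "floor_band", "th_person", "gap_coeff",
                     "th_sobel", "fall_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.th_person < self.gap_coeff:
            raise ValueError("th_person must be smaller than gap_coeff")
        if not self.fall_threshold < self.max_height:
            raise ValueError("fall_threshold must be below max_height")
        self.head_drop_range = tuple(self.head_drop_range)  # type: ignore[assignment]
        self.head_diag_range = tuple(self.head_diag_range)  # type: ignore[assignment]

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the super-pixel grid (40x40 at the defaults)."""
        return (self.frame_height // self.block_h, self.frame_width // self.block_w)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height, self.frame_width)

    # -- flat key=value config files ------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SystemConfig":
        """Load a flat ``key = value`` config file; later keys win."""
        values: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise KeyError(f"unknown config key: {key!r}")
            values[key] = _parse_value(val.strip())
        values.update(overrides)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(text: str):
    if "," in text:
        return tuple(_parse_value(t) for t in text.split(","))
    try:
        return int(text)
    except ValueError:
        return float(text)


@dataclasses.dataclass
class DepthFrame:
    """A single depth frame: 240x320 grid of mm values plus a stage tag."""

    grid: np.ndarray
    stage: Stage = Stage.DF
    index: int = 0
    fps: int = 30

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("depth grid must be 2-D")
        if self.stage in (Stage.CF, Stage.RF, Stage.FF, Stage.FFSOBEL):
            if (self.grid == 0).any():
                raise ValueError(f"stage {self.stage.value} frame may not contain nulls")

    @property
    def timestamp(self) -> float:
        """Capture time in seconds."""
        return self.index / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def with_grid(self, grid: np.ndarray, stage: Stage) -> "DepthFrame":
        return DepthFrame(grid=grid, stage=stage, index=self.index, fps=self.fps)

    def require_stage(self, *stages: Stage) -> None:
        if self.stage not in stages:
            wanted = "/".join(s.value for s in stages)
            raise ValueError(f"expected a {wanted} frame, got {self.stage.value}")


@dataclasses.dataclass(frozen=True)
class FallEvent:
    """A tracked person whose central point dropped below the fall threshold."""

    frame_index: int
    person_id: int
    height_above_floor: int  # mm, strictly below cfg.fall_threshold


def _expected_bytes(shape: tuple[int, int]) -> int:
    return shape[0] * shape[1] * 2


def read_sequence(path: str | Path, format: str = "raw16",
                  shape: tuple[int, int] = (240, 320)) -> list[DepthFrame]:
    """Read an ordered DF sequence.

    ``raw16``: one flat little-endian uint16 file holding N concatenated
    frames.  ``image16``: a directory of 16-bit single-channel images, one
    frame per file, in lexicographic order.  Zeros (dropouts) are preserved
    bit-exactly; values are never scaled or clipped.
    """
    path = Path(path)
    if format == "raw16":
        payload = path.read_bytes()
        per = _expected_bytes(shape)
        if len(payload) == 0 or len(payload) % per:
            raise ValueError(
                f"raw16 payload of {len(payload)} bytes is not a positive "
                f"multiple of {per}")
        data = np.frombuffer(payload, dtype="<u2").reshape(-1, *shape)
        return [DepthFrame(grid=frame.copy(), stage=Stage.DF, index=i)
                for i, frame in enumerate(data)]
    if format == "image16":
        import imageio.v3 as iio
        files = sorted(p for p in path.iterdir() if p.is_file())
        frames = []
        for i, f in enumerate(files):
            arr = iio.imread(f)
            if arr.dtype != np.uint16 or arr.ndim != 2:
                raise ValueError(f"{f.name}: expected a 16-bit single-channel image")
            frames.append(DepthFrame(grid=arr, stage=Stage.DF, index=i))
        if not frames:
            raise ValueError(f"no image files found in {path}")
        return frames
    raise ValueError(f"unknown sequence format: {format!r}")


def write_sequence(frames: Sequence[DepthFrame], path: str | Path,
                   format: str = "raw16") -> None:
    """Write frames in order; the exact inverse of :func:`read_sequence`."""
    path = Path(path)
    if format == "raw16":
        with open(path, "wb") as fh:
            for frame in frames:
                fh.write(np.ascontiguousarray(frame.grid, dtype="<u2").tobytes())
        return
    if format == "image16":
        import imageio.v3 as iio
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png",
                        np.asarray(frame.grid, dtype=np.uint16))
        return
    raise ValueError(f"unknown sequence format: {format!r}")


def write_events(events: Iterable[FallEvent], path: str | Path) -> None:
    """Write fall events as JSON lines, one record per event."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps({
                "frame_index": ev.frame_index,
                "person_id": ev.person_id,
                "height_above_floor": ev.height_above_floor,
            }) + "\n")


def read_events(path: str | Path) -> list[FallEvent]:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        events.append(FallEvent(frame_index=rec["frame_index"],
                                person_id=rec["person_id"],
                                height_above_floor=rec["height_above_floor"]))
    return events


def write_heights_csv(rows: Iterable[tuple[int, int, int]], path: str | Path) -> None:
    """Write per-frame tracked heights as CSV (frame_index, person_id, height_mm)."""
    with open(path, "w") as fh:
        fh.write("frame_index,person_id,height_mm\n")
        for frame_index, person_id, height in rows:
            fh.write(f"{frame_index},{person_id},{height}\n")
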