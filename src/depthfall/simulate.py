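"""Synthetic top-view depth-scene generator with per-frame ground truth.

The renderer emulates a ceiling-mounted depth sensor looking straight down
from ``ceiling`` millimeters: perspective projection with half angles of
view of 28.5 deg (x) and 21.5 deg (y), depth measured from the sensor plane
to the nearest surface along each pixel's ray.  Scenes hold a flat floor,
axis-aligned furniture slabs, and articulated-enough human figures: a
spherical head cap over a shoulder slab over a torso cylinder while upright,
collapsing into a prone slab (350 mm thick by default — the body thickness a
top-view sensor reads on the floor) during a fall interval.  Sensor dropouts
are emulated by zeroing an exact, seeded fraction of pixels.

Floor coordinates are millimeters, origin directly under the sensor, x to
the right (columns), y downward in the image (rows).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .frames import DepthFrame, Stage, SystemConfig

__all__ = [
    "Furniture",
    "Actor",
    "SceneSpec",
    "GroundTruthFrame",
    "GroundTruth",
    "render_frame",
    "render_sequence",
    "reference_frame",
    "inject_nulls",
    "make_scenario",
    "SCENARIOS",
]


@dataclasses.dataclass
class Furniture:
    """An axis-aligned slab: a desk, chair seat, shelf, ..."""

    center: tuple[float, float]     # (x, y) floor mm
    size: tuple[float, float]       # (width_x, depth_y) mm
    height: float                   # top surface above the floor, mm


@dataclasses.dataclass
class Actor:
    """A human figure with piecewise-linear floor trajectory.

    ``trajectory`` is a list of (time s, x mm, y mm) waypoints; positions are
    interpolated linearly and held at the ends.  During ``fall`` the body
    collapses (height interpolated down over ``collapse_s`` seconds) into a
    prone slab of ``prone_thickness`` mm, its long side along x, centered at
    the trajectory position plus ``prone_offset``.
    """

    height: float = 1700.0
    head_diameter: float = 250.0
    shoulder_breadth: float = 450.0
    shoulder_drop: float = 250.0
    trajectory: list[tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: [(0.0, 0.0, 0.0)])
    fall: Optional[tuple[float, float]] = None
    prone_thickness: float = 350.0
    collapse_s: float = 0.15
    prone_offset: tuple[float, float] = (0.0, 0.0)

    def position(self, t: float) -> tuple[float, float]:
        pts = self.trajectory
        times = [p[0] for p in pts]
        x = float(np.interp(t, times, [p[1] for p in pts]))
        y = float(np.interp(t, times, [p[2] for p in pts]))
        return x, y

    def fallen(self, t: float) -> bool:
        return self.fall is not None and self.fall[0] <= t <= self.fall[1]

    def body_height(self, t: float) -> float:
        """Top of the body above the floor at time t."""
        if not self.fallen(t):
            return self.height
        frac = min(1.0, (t - self.fall[0]) / self.collapse_s) if self.collapse_s else 1.0
        return self.height + frac * (self.prone_thickness - self.height)


@dataclasses.dataclass
class SceneSpec:
    """A full scenario: static scene, actors, dropout rate, seed."""

    ceiling: float = 3000.0
    furniture: list[Furniture] = dataclasses.field(default_factory=list)
    actors: list[Actor] = dataclasses.field(default_factory=list)
    null_rate: float = 0.0
    seed: int = 0
    noise_amp: int = 0   # optional +-amp mm integer depth noise, default off

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_rate < 1.0:
            raise ValueError("null_rate must be in [0, 1)")
        for actor in self.actors:
            if actor.height >= self.ceiling:
                raise ValueError("actor height must be below the ceiling")

    def without_actors(self) -> "SceneSpec":
        return dataclasses.replace(self, actors=[], null_rate=0.0, noise_amp=0)


@dataclasses.dataclass
class GroundTruthFrame:
    index: int
    centers: list[tuple[int, int] | None]   # (row, col) per actor, None if absent
    heights: list[float]                    # body top above floor, mm
    fallen: list[bool]
    masks: np.ndarray                       # (n_actors, H, W) bool, disjoint


@dataclasses.dataclass
class GroundTruth:
    frames: list[GroundTruthFrame]

    def fall_intervals(self, actor: int, fps: int = 30) -> list[tuple[int, int]]:
        """Maximal runs of frames with the fallen flag set, as (first, last)."""
        flags = [f.fallen[actor] for f in self.frames]
        runs, start = [], None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            if not f and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(flags) - 1))
        return runs


def _ray_grids(cfg: SystemConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ray slopes u = X/z, v = Y/z."""
    tx = math.tan(math.radians(cfg.fov_half_x))
    ty = math.tan(math.radians(cfg.fov_half_y))
    cols = (np.arange(cfg.frame_width) + 0.5 - cfg.frame_width / 2) \
        / (cfg.frame_width / 2) * tx
    rows = (np.arange(cfg.frame_height) + 0.5 - cfg.frame_height / 2) \
        / (cfg.frame_height / 2) * ty
    return np.meshgrid(cols, rows)  # u (H,W), v (H,W)


def _slab_depth(u: np.ndarray, v: np.ndarray, center: tuple[float, float],
                size: tuple[float, float], z: float) -> np.ndarray:
    """Depth map of a horizontal rectangle at sensor distance z (inf outside)."""
    x, y = u * z, v * z
    inside = (np.abs(x - center[0]) <= size[0] / 2) & \
             (np.abs(y - center[1]) <= size[1] / 2)
    return np.where(inside, z, np.inf)


def _disk_depth(u: np.ndarray, v: np.ndarray, center: tuple[float, float],
                radius: float, z: float) -> np.ndarray:
    x, y = u * z, v * z
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2
    return np.where(inside, z, np.inf)


def _head_depth(u: np.ndarray, v: np.ndarray, center: tuple[float, float],
                radius: float, z_apex: float) -> np.ndarray:
    """Upper hemisphere of a head: apex at z_apex, sphere center z_apex + r.

    The planar footprint is evaluated at the mid-cap plane; one fixed-point
    step is plenty at these distances.
    """
    zc = z_apex + radius
    z0 = z_apex + radius / 2
    x, y = u * z0, v * z0
    rho2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    inside = rho2 <= radius ** 2
    z = np.where(inside, zc - np.sqrt(np.maximum(radius ** 2 - rho2, 0.0)), np.inf)
    return z


def _actor_depth(actor: Actor, t: float, u: np.ndarray, v: np.ndarray,
                 ceiling: float) -> np.ndarray:
    """Depth contribution of one actor (inf where the actor is not seen)."""
    x, y = actor.position(t)
    h = actor.body_height(t)
    if actor.fallen(t):
        px, py = actor.prone_offset
        frac = min(1.0, (t - actor.fall[0]) / actor.collapse_s) \
            if actor.collapse_s else 1.0
        # the footprint grows as the body tips over
        length = actor.shoulder_breadth + frac * (actor.height - actor.shoulder_breadth)
        return _slab_depth(u, v, (x + px * frac, y + py * frac),
                           (length, actor.shoulder_breadth), ceiling - h)
    z_head = ceiling - h
    z_shoulder = ceiling - (h - actor.shoulder_drop)
    head = _head_depth(u, v, (x, y), actor.head_diameter / 2, z_head)
    shoulders = _slab_depth(u, v, (x, y),
                            (actor.shoulder_breadth, actor.head_diameter + 60),
                            z_shoulder)
    torso = _disk_depth(u, v, (x, y), actor.shoulder_breadth / 3, z_shoulder)
    return np.minimum(head, np.minimum(shoulders, torso))


def render_frame(spec: SceneSpec, t: float, cfg: SystemConfig | None = None,
                 index: int = 0) -> tuple[DepthFrame, GroundTruthFrame]:
    """Render one raw DF frame plus its ground-truth slice at time t."""
    cfg = cfg or SystemConfig(max_height=int(spec.ceiling))
    u, v = _ray_grids(cfg)
    layers = [np.full(cfg.frame_shape, spec.ceiling)]
    for f in spec.furniture:
        layers[0] = np.minimum(layers[0],
                               _slab_depth(u, v, f.center, f.size,
                                           spec.ceiling - f.height))
    actor_layers = [_actor_depth(a, t, u, v, spec.ceiling) for a in spec.actors]
    stack = np.stack(layers + actor_layers)
    owner = np.argmin(stack, axis=0)     # ties go to the background layer
    depth = np.take_along_axis(stack, owner[None], axis=0)[0]

    masks = np.stack([owner == i + 1 for i in range(len(spec.actors))]) \
        if spec.actors else np.zeros((0, *cfg.frame_shape), dtype=bool)
    centers: list[tuple[int, int] | None] = []
    heights: list[float] = []
    fallen: list[bool] = []
    for i, actor in enumerate(spec.actors):
        heights.append(actor.body_height(t))
        fallen.append(actor.fallen(t))
        if masks[i].any():
            rows, cols = np.nonzero(masks[i])
            centers.append((int(round(rows.mean())), int(round(cols.mean()))))
        else:
            centers.append(None)

    grid = np.rint(depth).astype(np.int64)
    if spec.noise_amp:
        rng = np.random.default_rng((spec.seed, index, 7))
        grid = grid + rng.integers(-spec.noise_amp, spec.noise_amp + 1,
                                   size=grid.shape)
    frame = DepthFrame(grid=np.clip(grid, 1, 65535).astype(np.uint16),
                       stage=Stage.DF, index=index, fps=cfg.fps)
    if spec.null_rate:
        frame = inject_nulls(frame, spec.null_rate, seed=spec.seed + index)
    gt = GroundTruthFrame(index=index, centers=centers, heights=heights,
                          fallen=fallen, masks=masks)
    return frame, gt


def render_sequence(spec: SceneSpec, duration: float,
                    cfg: SystemConfig | None = None) -> tuple[list[DepthFrame], GroundTruth]:
    """Render duration * fps frames, deterministically per (spec, seed)."""
    cfg = cfg or SystemConfig(max_height=int(spec.ceiling))
    n = int(round(duration * cfg.fps))
    frames, gts = [], []
    for i in range(n):
        frame, gt = render_frame(spec, i / cfg.fps, cfg, index=i)
        frames.append(frame)
        gts.append(gt)
    return frames, GroundTruth(frames=gts)


def reference_frame(spec: SceneSpec, cfg: SystemConfig | None = None) -> DepthFrame:
    """A person-free raw frame of the static scene (for RF capture)."""
    frame, _ = render_frame(spec.without_actors(), 0.0, cfg)
    return frame


def inject_nulls(frame: DepthFrame, rate: float, seed: int) -> DepthFrame:
    """Zero an exact count of pixels, drawn without replacement per seed."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n_pixels = frame.grid.size
    k = int(round(rate * n_pixels))
    if k == 0:
        return frame
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_pixels, size=k, replace=False)
    grid = frame.grid.copy()
    grid.flat[flat] = 0
    return DepthFrame(grid=grid, stage=frame.stage, index=frame.index,
                      fps=frame.fps)


# ---------------------------------------------------------------------------
# canonical scenarios
# ---------------------------------------------------------------------------

def _simple_fall(seed: int) -> tuple[SceneSpec, float]:
    """One subject walks through open floor and falls; a desk sits clear of
    the trajectory."""
    actor = Actor(
        trajectory=[(0.0, -450.0, -250.0), (3.0, 150.0, 0.0)],
        fall=(3.5, 6.0),
    )
    spec = SceneSpec(
        furniture=[Furniture(center=(900.0, -600.0), size=(600.0, 400.0),
                             height=750.0)],
        actors=[actor],
        null_rate=0.002,
        seed=seed,
    )
    return spec, 6.0


def _complex_fall(seed: int) -> tuple[SceneSpec, float]:
    """The subject walks in shoulder contact with a tall desk, brushes a
    chair, and falls alongside both.

    The desk top (1,250 mm) sits within 500 mm of the walking subject's
    shoulders, which is exactly the regime where edge carving cannot separate
    the two unless the reference frame has boosted the subject first.
    """
    actor = Actor(
        trajectory=[(0.0, -350.0, -420.0), (2.5, 250.0, -420.0)],
        fall=(3.0, 6.0),
        prone_offset=(0.0, -250.0),
    )
    spec = SceneSpec(
        furniture=[
            Furniture(center=(100.0, 50.0), size=(1600.0, 700.0), height=1250.0),
            Furniture(center=(-100.0, -700.0), size=(400.0, 400.0), height=450.0),
        ],
        actors=[actor],
        null_rate=0.002,
        seed=seed,
    )
    return spec, 6.0


def _fusion_walk(seed: int) -> tuple[SceneSpec, float]:
    """Two subjects converge to shoulder contact, then separate; three
    furniture pieces populate the rest of the scene."""
    a = Actor(height=1700.0,
              trajectory=[(0.0, -500.0, 0.0), (1.5, -222.0, 0.0),
                          (2.5, -222.0, 0.0), (4.0, -500.0, 0.0)])
    b = Actor(height=1680.0,
              trajectory=[(0.0, 500.0, 0.0), (1.5, 222.0, 0.0),
                          (2.5, 222.0, 0.0), (4.0, 500.0, 0.0)])
    spec = SceneSpec(
        furniture=[
            Furniture(center=(1000.0, -600.0), size=(600.0, 400.0), height=750.0),
            Furniture(center=(-1000.0, 600.0), size=(400.0, 400.0), height=450.0),
            Furniture(center=(900.0, 600.0), size=(500.0, 300.0), height=900.0),
        ],
        actors=[a, b],
        null_rate=0.002,
        seed=seed,
    )
    return spec, 4.0


def _outstretched_arms(seed: int) -> tuple[SceneSpec, float]:
    """One subject with both arms extended forward: two thin slabs at
    shoulder height produce the U-shaped blob whose branches only join at
    the shoulder row."""
    actor = Actor(trajectory=[(0.0, 0.0, 150.0)])
    arms = [
        Furniture(center=(-175.0, 150.0 - 155.0 - 300.0), size=(100.0, 600.0),
                  height=1450.0),
        Furniture(center=(175.0, 150.0 - 155.0 - 300.0), size=(100.0, 600.0),
                  height=1450.0),
    ]
    spec = SceneSpec(furniture=arms, actors=[actor], null_rate=0.0, seed=seed)
    return spec, 1.0 / 3.0


def _table1_seven_blobs(seed: int) -> tuple[SceneSpec, float]:
    """Seven disjoint static clusters (no people)."""
    slabs = [
        Furniture(center=(-800.0, -500.0), size=(300.0, 300.0), height=700.0),
        Furniture(center=(0.0, -520.0), size=(350.0, 300.0), height=500.0),
        Furniture(center=(800.0, -480.0), size=(300.0, 320.0), height=900.0),
        Furniture(center=(-420.0, 20.0), size=(320.0, 300.0), height=600.0),
        Furniture(center=(430.0, 0.0), size=(300.0, 340.0), height=800.0),
        Furniture(center=(-780.0, 500.0), size=(300.0, 300.0), height=450.0),
        Furniture(center=(760.0, 520.0), size=(340.0, 300.0), height=650.0),
    ]
    spec = SceneSpec(furniture=slabs, actors=[], null_rate=0.0, seed=seed)
    return spec, 1.0 / 6.0


SCENARIOS = {
    "simple_fall": _simple_fall,
    "complex_fall": _complex_fall,
    "fusion_walk": _fusion_walk,
    "outstretched_arms": _outstretched_arms,
    "table1_seven_blobs": _table1_seven_blobs,
}


def make_scenario(name: str, seed: int = 0,
                  cfg: SystemConfig | None = None
                  ) -> tuple[SceneSpec, list[DepthFrame], GroundTruth]:
    """Build a canonical scenario and render its full frame sequence."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario: {name!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    spec, duration = SCENARIOS[name](seed)
    frames, truth = render_sequence(spec, duration, cfg)
    return spec, frames, truth
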