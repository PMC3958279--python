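"""Frame-to-frame association, fusion handling, and the fall rule.

Tracking is anchor-based: a person (or object) recognized at frame *k-1* is
carried into frame *k* by dropping its stored central super-pixel (scp) into
the new blob partition — the blob that contains the point inherits the
identity.  Every blob row is then classified:

* **A** — no tracked person and at most one tracked object: a lone element;
  the anthropometric checks run on it (identification happens only on blobs
  not yet classified as human) and it is promoted to a person or kept as an
  object;
* **B** — exactly one person, no object: plain continuation; the person's
  anchor points are recomputed on the new blob shape;
* **C** — anything else: a fusion (e.g. two subjects in shoulder contact).
  The blob is cut into per-member sub-blobs around each member's peak
  super-pixel and every member is re-anchored to its own piece, so no
  identity is lost while the silhouettes stay merged.

A fall is flagged for a tracked person whose central-point height above the
floor drops strictly below ``fall_threshold`` (400 mm, the body thickness a
top-view sensor reads for a person lying on the floor).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .frames import DepthFrame, FallEvent, Stage, SystemConfig
from .person import BodyPoints, block_center_pixel, central_superpixel, \
    is_person, peak_point
from .preprocess import SuperPixelFrame, carve_edges, clamp_floor, \
    compute_foreground, fill_nulls, superpixelize
from .segment import Blob, BlobTable, distinguish_objects

__all__ = [
    "Track",
    "TrackRegistry",
    "TrackingInfoRow",
    "compute_body_points",
    "build_tracking_info",
    "classify_row",
    "split_fusion",
    "update_tracks",
    "detect_fall",
    "PipelineState",
    "FrameResult",
    "process_frame",
    "run_sequence",
    "RunReport",
]


@dataclasses.dataclass
class Track:
    points: BodyPoints
    missed: int = 0  # consecutive frames without a matching blob


@dataclasses.dataclass
class TrackRegistry:
    """Stable-id bookkeeping for persons and scene objects."""

    persons: dict[int, Track] = dataclasses.field(default_factory=dict)
    objects: dict[int, Track] = dataclasses.field(default_factory=dict)
    next_person_id: int = 1
    next_object_id: int = 1

    def new_person(self, points: BodyPoints) -> int:
        pid = self.next_person_id
        self.next_person_id += 1
        self.persons[pid] = Track(points=points)
        return pid

    def new_object(self, points: BodyPoints) -> int:
        oid = self.next_object_id
        self.next_object_id += 1
        self.objects[oid] = Track(points=points)
        return oid


@dataclasses.dataclass
class TrackingInfoRow:
    """Who, from the previous frame, landed inside one current blob."""

    blob_index: int
    pers: list[int]
    obj: list[int]

    @property
    def n_pers(self) -> int:
        return len(self.pers)

    @property
    def n_obj(self) -> int:
        return len(self.obj)


def compute_body_points(cells: Sequence[tuple[int, int]], cf: DepthFrame,
                        cfg: SystemConfig) -> BodyPoints:
    """All four anchor points of a blob on the current frame."""
    scp = central_superpixel(cells)
    cp = block_center_pixel(scp, cfg)
    mp = peak_point(cells, cf, cfg)
    smp = (mp[0] // cfg.block_h, mp[1] // cfg.block_w)
    return BodyPoints(cp=cp, scp=scp, mp=mp, smp=smp)


def build_tracking_info(registry: TrackRegistry, table: BlobTable,
                        grid_shape: tuple[int, int]) -> list[TrackingInfoRow]:
    """One row per current blob, listing the tracked ids whose stored central
    super-pixel lies inside it."""
    label = table.label_grid(grid_shape)
    rows = {blob.oid: TrackingInfoRow(blob_index=blob.oid, pers=[], obj=[])
            for blob in table}

    def _lookup(sp: tuple[int, int]) -> int:
        r, c = sp
        if 0 <= r < grid_shape[0] and 0 <= c < grid_shape[1]:
            return int(label[r, c])
        return 0

    for pid in sorted(registry.persons):
        hit = _lookup(registry.persons[pid].points.scp)
        if hit:
            rows[hit].pers.append(pid)
    for oid in sorted(registry.objects):
        hit = _lookup(registry.objects[oid].points.scp)
        if hit:
            rows[hit].obj.append(oid)
    return [rows[blob.oid] for blob in table]


def classify_row(row: TrackingInfoRow) -> str:
    """Total classification of a tracking row into condition A, B or C."""
    if row.n_pers == 0 and row.n_obj <= 1:
        return "A"
    if row.n_pers == 1 and row.n_obj == 0:
        return "B"
    return "C"


def split_fusion(cells: Sequence[tuple[int, int]],
                 members: Sequence[tuple[int, int]],
                 radius: int) -> list[list[tuple[int, int]]]:
    """Cut a fused blob into per-member sub-blobs.

    For each member's peak super-pixel, blob cells within the given Chebyshev
    radius are kept (cells inside several members' windows go to the nearest
    peak, ties to the lower member index), re-labeled, and the connected
    piece containing the peak is returned for that member.
    """
    cell_set = set(map(tuple, cells))
    for smp in members:
        if tuple(smp) not in cell_set:
            raise ValueError(f"fusion member {smp} is not inside the blob")
    arr = np.asarray(list(cells))
    centers = np.asarray(list(members))
    # Chebyshev window membership per member
    cheb = np.maximum(np.abs(arr[:, None, 0] - centers[None, :, 0]),
                      np.abs(arr[:, None, 1] - centers[None, :, 1]))
    inside = cheb <= radius
    eucl2 = (arr[:, None, 0] - centers[None, :, 0]) ** 2 + \
            (arr[:, None, 1] - centers[None, :, 1]) ** 2
    eucl2 = np.where(inside, eucl2, np.iinfo(np.int64).max)
    owner = np.argmin(eucl2, axis=1)          # ties -> lower member index
    owner[~inside.any(axis=1)] = -1           # discarded cells

    out: list[list[tuple[int, int]]] = []
    rmax = int(arr[:, 0].max()) + 1
    cmax = int(arr[:, 1].max()) + 1
    for m, smp in enumerate(members):
        mine = arr[owner == m]
        if mine.size == 0:
            out.append([])
            continue
        grid = np.zeros((rmax, cmax), dtype=np.uint8)
        grid[mine[:, 0], mine[:, 1]] = 1
        sub = distinguish_objects(grid)
        label = sub.label_grid((rmax, cmax))
        target = int(label[tuple(smp)])
        if target == 0:
            out.append([])
            continue
        out.append(next(b.cells for b in sub if b.oid == target))
    return out


def _snap_into(sp: tuple[int, int], cells: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Nearest blob cell to a point (the point itself if already a member)."""
    cell_set = set(map(tuple, cells))
    if tuple(sp) in cell_set:
        return tuple(sp)
    arr = np.asarray(list(cells))
    d2 = (arr[:, 0] - sp[0]) ** 2 + (arr[:, 1] - sp[1]) ** 2
    j = int(np.lexsort((arr[:, 1], arr[:, 0], d2))[0])
    return (int(arr[j, 0]), int(arr[j, 1]))


def update_tracks(registry: TrackRegistry, table: BlobTable, cf: DepthFrame,
                  cfg: SystemConfig) -> TrackRegistry:
    """Advance the registry by one frame against the new blob partition."""
    rows = build_tracking_info(registry, table, cfg.grid_shape)
    blobs = {blob.oid: blob for blob in table}
    matched_persons: set[int] = set()
    matched_objects: set[int] = set()

    for row in rows:
        blob = blobs[row.blob_index]
        cond = classify_row(row)
        if cond == "A":
            # identification runs only on blobs not yet classified as human
            if is_person(blob.cells, cf, cfg):
                for oid in row.obj:
                    registry.objects.pop(oid, None)
                points = compute_body_points(blob.cells, cf, cfg)
                pid = registry.new_person(points)
                matched_persons.add(pid)
            elif row.obj:
                oid = row.obj[0]
                registry.objects[oid] = Track(
                    points=compute_body_points(blob.cells, cf, cfg))
                matched_objects.add(oid)
            else:
                oid = registry.new_object(
                    compute_body_points(blob.cells, cf, cfg))
                matched_objects.add(oid)
        elif cond == "B":
            pid = row.pers[0]
            registry.persons[pid] = Track(
                points=compute_body_points(blob.cells, cf, cfg))
            matched_persons.add(pid)
        else:  # condition C: fusion
            member_ids = [("p", pid) for pid in row.pers] + \
                         [("o", oid) for oid in row.obj]
            smps = []
            for kind, mid in member_ids:
                track = registry.persons[mid] if kind == "p" else registry.objects[mid]
                smps.append(_snap_into(track.points.smp, blob.cells))
            pieces = split_fusion(blob.cells, smps, cfg.fusion_split_radius)
            for (kind, mid), piece in zip(member_ids, pieces):
                if not piece:
                    continue  # member lost its window this frame; grace applies
                points = compute_body_points(piece, cf, cfg)
                if kind == "p":
                    registry.persons[mid] = Track(points=points)
                    matched_persons.add(mid)
                else:
                    registry.objects[mid] = Track(points=points)
                    matched_objects.add(mid)

    for pid in list(registry.persons):
        if pid in matched_persons:
            registry.persons[pid].missed = 0
        else:
            registry.persons[pid].missed += 1
            if registry.persons[pid].missed > cfg.track_grace_frames:
                del registry.persons[pid]
    for oid in list(registry.objects):
        if oid not in matched_objects:
            del registry.objects[oid]
    return registry


def detect_fall(registry: TrackRegistry, cf: DepthFrame, cfg: SystemConfig,
                below: set[int] | None = None,
                frame_index: int = 0) -> tuple[list[FallEvent], dict[int, int]]:
    """Apply the fall rule to every tracked person.

    Height above the floor is read at the central point; an event is emitted
    on the frame the height first drops strictly below ``fall_threshold``
    (edge-triggered), and per-frame heights are returned for logging.
    """
    cf.require_stage(Stage.CF)
    if below is None:
        below = set()
    events: list[FallEvent] = []
    heights: dict[int, int] = {}
    for pid in sorted(registry.persons):
        cp = registry.persons[pid].points.cp
        height = int(cfg.max_height - cf.grid[cp])
        heights[pid] = height
        if height < cfg.fall_threshold:
            if pid not in below:
                events.append(FallEvent(frame_index=frame_index, person_id=pid,
                                        height_above_floor=height))
                below.add(pid)
        else:
            below.discard(pid)
    return events, heights


@dataclasses.dataclass
class PipelineState:
    """Everything carried between frames of a run."""

    cfg: SystemConfig
    rf: DepthFrame
    registry: TrackRegistry = dataclasses.field(default_factory=TrackRegistry)
    below: set[int] = dataclasses.field(default_factory=set)


@dataclasses.dataclass
class FrameResult:
    frame_index: int
    table: BlobTable
    heights: dict[int, int]
    events: list[FallEvent]


def process_frame(df: DepthFrame, state: PipelineState) -> tuple[PipelineState, FrameResult]:
    """Run the full per-frame chain on one raw depth frame."""
    cfg = state.cfg
    cf = fill_nulls(clamp_floor(df, cfg), cfg)
    ff = compute_foreground(cf, state.rf, cfg)
    fs = superpixelize(carve_edges(ff, cfg), cfg)
    table = distinguish_objects(fs)
    update_tracks(state.registry, table, cf, cfg)
    events, heights = detect_fall(state.registry, cf, cfg, state.below,
                                  frame_index=df.index)
    return state, FrameResult(frame_index=df.index, table=table,
                              heights=heights, events=events)


@dataclasses.dataclass
class RunReport:
    """Summary of a processed sequence."""

    frames_processed: int
    persons_tracked: int
    events: list[FallEvent]
    heights: list[tuple[int, int, int]]  # (frame_index, person_id, height_mm)


def run_sequence(frames: Sequence[DepthFrame], rf: DepthFrame,
                 cfg: SystemConfig) -> RunReport:
    """Process an ordered DF sequence against a fixed reference frame."""
    state = PipelineState(cfg=cfg, rf=rf)
    events: list[FallEvent] = []
    heights: list[tuple[int, int, int]] = []
    for df in frames:
        state, result = process_frame(df, state)
        events.extend(result.events)
        heights.extend((result.frame_index, pid, h)
                       for pid, h in sorted(result.heights.items()))
    return RunReport(frames_processed=len(frames),
                     persons_tracked=state.registry.next_person_id - 1,
                     events=events, heights=heights)
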