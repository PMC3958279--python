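"""Row-scan blob labeling of the binary super-pixel grid.

The procedure scans one row at a time.  Maximal runs of occupied cells in a
row are *object parts* (spans); a span continues the object of any span it
column-overlaps in the previous row (a bitwise AND of the two rows'
occupancy vectors), otherwise it opens a new object.  When one span overlaps
several previously distinct objects — a person with outstretched arms whose
arms and body meet further down the frame — those objects collapse into one
and the table is renumbered.  The resulting partition is exactly the set of
4-connected components, labeled in row-major first-occurrence order.

Coordinates are 0-based (row, column) internally; the grid width/height are
not fixed, so the labeler works on any binary matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .preprocess import SuperPixelFrame

__all__ = [
    "RowSpan",
    "RowState",
    "Blob",
    "BlobTable",
    "scan_row",
    "match_spans",
    "assign_row",
    "distinguish_objects",
    "merge_objects",
]


@dataclasses.dataclass
class RowSpan:
    """A maximal run of occupied cells in one row; oi == 0 means unclassified."""

    first_col: int
    last_col: int
    oi: int = 0

    def __post_init__(self) -> None:
        if self.first_col > self.last_col:
            raise ValueError("span first_col must not exceed last_col")

    def overlaps(self, other: "RowSpan") -> bool:
        return not (self.last_col < other.first_col or other.last_col < self.first_col)


@dataclasses.dataclass
class RowState:
    """Working state of the row scan: current/previous spans and the two
    occupancy vectors used for the bitwise comparison."""

    current: list[RowSpan]
    previous: list[RowSpan]
    width: int

    @property
    def cvo(self) -> np.ndarray:
        """Occupancy of the previously processed row (CompareVectorAllOld)."""
        v = np.zeros(self.width, dtype=np.uint8)
        for sp in self.previous:
            v[sp.first_col:sp.last_col + 1] = 1
        return v

    def cv(self, span: RowSpan) -> np.ndarray:
        """Occupancy vector holding a single current span (CompareVector)."""
        v = np.zeros(self.width, dtype=np.uint8)
        v[span.first_col:span.last_col + 1] = 1
        return v


@dataclasses.dataclass
class Blob:
    oid: int
    cells: list[tuple[int, int]]  # (row, col), row-major discovery order


@dataclasses.dataclass
class BlobTable:
    """Ordered labeled blobs; ids are 1-based and dense."""

    objects: list[Blob]

    def __len__(self) -> int:
        return len(self.objects)

    def __iter__(self):
        return iter(self.objects)

    def label_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """Dense label image: 0 background, blob ids elsewhere."""
        lab = np.zeros(shape, dtype=np.int32)
        for blob in self.objects:
            for r, c in blob.cells:
                lab[r, c] = blob.oid
        return lab


def scan_row(row: Sequence[int] | np.ndarray) -> list[RowSpan]:
    """Split one binary row into its maximal occupied runs, left to right."""
    row = np.asarray(row)
    spans: list[RowSpan] = []
    padded = np.concatenate(([0], (row != 0).astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    for s, e in zip(starts, ends):
        spans.append(RowSpan(int(s), int(e)))
    return spans


def match_spans(state: RowState) -> list[tuple[RowSpan, list[int]]]:
    """For each current span, the ids of all previous-row spans it overlaps.

    The comparison is the bitwise AND of the span's occupancy vector with the
    previous row's; a non-null result means the object continues, an empty
    result means a new object.
    """
    cvo = state.cvo
    out: list[tuple[RowSpan, list[int]]] = []
    for span in state.current:
        hit = state.cv(span) & cvo
        ids: list[int] = []
        if hit.any():
            for prev in state.previous:
                if span.overlaps(prev) and prev.oi not in ids:
                    ids.append(prev.oi)
        out.append((span, sorted(ids)))
    return out


def assign_row(previous: list[RowSpan], current: list[RowSpan], width: int,
               next_id: int) -> tuple[list[RowSpan], list[tuple[int, int]], int]:
    """Label the current row's spans against the previous row's.

    Returns the labeled current spans, a list of (kept_id, absorbed_id) merges
    triggered by spans bridging several previous objects, and the updated next
    free id.  The surviving id of a merge is the smallest involved id.
    """
    state = RowState(current=current, previous=previous, width=width)
    merges: list[tuple[int, int]] = []
    labeled: list[RowSpan] = []
    for span, ids in match_spans(state):
        if not ids:
            oi = next_id
            next_id += 1
        else:
            oi = min(ids)
            for absorbed in ids:
                if absorbed != oi:
                    merges.append((oi, absorbed))
        labeled.append(RowSpan(span.first_col, span.last_col, oi))
    return labeled, merges, next_id


def distinguish_objects(fs: SuperPixelFrame | np.ndarray) -> BlobTable:
    """Label every occupied super-pixel of a binary grid into ordered blobs."""
    grid = fs.grid if isinstance(fs, SuperPixelFrame) else np.asarray(fs)
    if not np.isin(grid, (0, 1)).all():
        raise ValueError("distinguish_objects requires a binary grid")
    height, width = grid.shape

    cells: dict[int, list[tuple[int, int]]] = {}
    previous: list[RowSpan] = []
    next_id = 1
    for r in range(height):
        current = scan_row(grid[r])
        labeled, merges, next_id = assign_row(previous, current, width, next_id)
        # side effect: several previously distinct objects collapse; merges
        # may chain within one row, so resolve aliases as they accumulate
        alias: dict[int, int] = {}

        def _resolve(x: int) -> int:
            while x in alias:
                x = alias[x]
            return x

        for kept, absorbed in merges:
            k, a = _resolve(kept), _resolve(absorbed)
            if k == a:
                continue
            if a < k:
                k, a = a, k
            cells[k].extend(cells.pop(a))
            alias[a] = k
        if alias:
            for sp in labeled:
                sp.oi = _resolve(sp.oi)
        for sp in labeled:
            cells.setdefault(sp.oi, []).extend(
                (r, c) for c in range(sp.first_col, sp.last_col + 1))
        previous = labeled

    # renumber densely, ordered by row-major first occurrence
    ordered = sorted(cells.items(), key=lambda kv: min(kv[1]))
    return BlobTable(objects=[
        Blob(oid=i + 1, cells=sorted(body)) for i, (_, body) in enumerate(ordered)
    ])


def merge_objects(table: BlobTable, ids: list[int]) -> BlobTable:
    """Collapse the given objects into the smallest id, renumbering compactly.

    Cell lists are concatenated in ascending id order, each keeping its own
    discovery order.
    """
    if not ids:
        raise ValueError("merge_objects needs at least one id")
    known = {b.oid for b in table.objects}
    for oid in ids:
        if oid not in known:
            raise KeyError(f"unknown object id: {oid}")
    targets = sorted(set(ids))
    keep = targets[0]
    merged_cells: list[tuple[int, int]] = []
    survivors: list[Blob] = []
    for blob in table.objects:
        if blob.oid in targets:
            merged_cells.extend(blob.cells)
            if blob.oid == keep:
                survivors.append(Blob(oid=keep, cells=merged_cells))
        else:
            survivors.append(blob)
    return BlobTable(objects=[
        Blob(oid=i + 1, cells=b.cells) for i, b in enumerate(survivors)
    ])
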