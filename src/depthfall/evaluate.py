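"""Scoring detected fall events against simulator ground truth."""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .frames import FallEvent
from .simulate import GroundTruth

__all__ = ["EvalReport", "evaluate_events"]


@dataclasses.dataclass
class EvalReport:
    """Detection score of a run against ground-truth fall intervals.

    An interval counts as detected if some event falls inside it dilated by
    ``tolerance`` frames; an event matching no dilated interval is a false
    alarm.  ``latencies`` holds, per detected interval, the first matching
    event frame minus the interval start (negative = early, within
    tolerance).
    """

    intervals: list[tuple[int, int]]
    detections: int
    misses: int
    false_alarms: int
    latencies: list[int]

    @property
    def recall(self) -> float:
        total = self.detections + self.misses
        return self.detections / total if total else 1.0


def evaluate_events(events: Sequence[FallEvent], truth: GroundTruth,
                    tolerance: int = 5) -> EvalReport:
    intervals: list[tuple[int, int]] = []
    for actor in range(len(truth.frames[0].fallen) if truth.frames else 0):
        intervals.extend(truth.fall_intervals(actor))
    intervals.sort()

    detections = 0
    latencies: list[int] = []
    matched_events: set[int] = set()
    for start, end in intervals:
        hits = [ev for ev in events
                if start - tolerance <= ev.frame_index <= end + tolerance]
        if hits:
            detections += 1
            first = min(ev.frame_index for ev in hits)
            latencies.append(first - start)
            matched_events.update(id(ev) for ev in hits)
    false_alarms = sum(1 for ev in events if id(ev) not in matched_events)
    return EvalReport(intervals=intervals, detections=detections,
                      misses=len(intervals) - detections,
                      false_alarms=false_alarms, latencies=latencies)
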