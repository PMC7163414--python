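"""Gaze-to-data-item translation, dwell accumulation, labeling and session QC.

A review session yields two time-stamped streams: ~60 Hz gaze coordinates on
the monitor, and a piecewise-constant layout of interface elements (one
element per medical record data item) that changes as the reviewer scrolls.
Dwell time per item is accumulated by attributing each valid gaze sample to
the element whose rectangle contains it under the layout snapshot active at
that sample's timestamp. Items gazed at for at least a threshold (250 ms by
default) receive a positive gaze-derived label; manual labels come from the
checkbox selections recorded in the session.

Coordinates are screen pixels with the origin at the top-left and y growing
downward; rectangles are half-open: a point (x, y) is inside [x0, x1) x
[y0, y1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from gazerel.errors import InputError, SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from gazerel.simulate import SessionSim

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
ABSENT = "absent"

#: default dwell threshold in milliseconds; a dwell of exactly this value is
#: labeled positive (threshold comparison is inclusive).
DWELL_THRESHOLD_MS = 250.0


@dataclass(frozen=True)
class GazeSample:
    timestamp_ms: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class Element:
    """One on-screen interface element: a data item's rectangle in pixels."""

    item_id: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise InputError(
                f"degenerate rectangle for {self.item_id}: "
                f"({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class LayoutSnapshot:
    timestamp_ms: float
    elements: list[Element]

    def __post_init__(self) -> None:
        ids = [e.item_id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate item ids in snapshot at {self.timestamp_ms}")


@dataclass
class GazeStream:
    """Columnar gaze stream; timestamps must be strictly increasing."""

    timestamps_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps_ms)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise InputError("gaze stream columns have unequal lengths")
        if n > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise InputError("gaze timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps_ms)

    @property
    def valid_fraction(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.mean(self.valid))

    @classmethod
    def from_samples(cls, samples: Iterable[GazeSample]) -> "GazeStream":
        rows = list(samples)
        return cls(
            np.array([s.timestamp_ms for s in rows], dtype=float),
            np.array([s.x for s in rows], dtype=float),
            np.array([s.y for s in rows], dtype=float),
            np.array([s.valid for s in rows], dtype=bool),
        )


@dataclass
class LayoutStream:
    snapshots: list[LayoutSnapshot]

    def __post_init__(self) -> None:
        ts = [s.timestamp_ms for s in self.snapshots]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InputError("layout snapshots must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.snapshots)

    def item_universe(self) -> set[str]:
        return {e.item_id for s in self.snapshots for e in s.elements}


@dataclass
class DwellTable:
    """Accumulated per-item gaze dwell for one session, in milliseconds."""

    dwell_ms: dict[str, float]
    session_duration_ms: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.dwell_ms.values()):
            raise InputError("negative dwell time")

    def get(self, item_id: str) -> float:
        return self.dwell_ms.get(item_id, 0.0)


@dataclass
class LabelSet:
    """Per-item relevance labels from one capture channel.

    ``labels`` holds positive/negative for every item present in the case;
    any item outside the mapping is absent (no data for that case).
    """

    source: str  # "manual" or "gaze"
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.source not in ("manual", "gaze"):
            raise InputError(f"unknown label source {self.source!r}")
        bad = {v for v in self.labels.values()} - {POSITIVE, NEGATIVE}
        if bad:
            raise InputError(f"labels must be positive/negative, got {bad}")

    def get(self, item_id: str) -> str:
        return self.labels.get(item_id, ABSENT)

    def positives(self) -> set[str]:
        return {k for k, v in self.labels.items() if v == POSITIVE}


@dataclass
class SessionQCReport:
    valid: bool
    reasons: list[str] = field(default_factory=list)
    valid_sample_fraction: float = 0.0

    def __post_init__(self) -> None:
        assert self.valid == (len(self.reasons) == 0)


def attribute_sample(sample: GazeSample, snapshot: LayoutSnapshot) -> str | None:
    """Map one gaze sample to the data item whose rectangle contains it.

    Containment is half-open (x0 <= x < x1, y0 <= y < y1). Invalid samples
    and samples outside every element attribute to ``None``. If overlapping
    rectangles both contain the point, the first element in snapshot order
    wins.
    """
    if snapshot.timestamp_ms > sample.timestamp_ms:
        raise InputError(
            f"snapshot at {snapshot.timestamp_ms} is later than sample at "
            f"{sample.timestamp_ms}"
        )
    if not sample.valid:
        return None
    hits = [e.item_id for e in snapshot.elements if e.contains(sample.x, sample.y)]
    if not hits:
        return None
    if len(hits) > 1:
        logger.warning(
            "gaze sample at %s falls in %d overlapping elements; first wins",
            sample.timestamp_ms,
            len(hits),
        )
    return hits[0]


def _nominal_period_ms(timestamps: np.ndarray, max_gap_ms: float) -> float:
    if len(timestamps) > 1:
        return float(np.median(np.diff(timestamps)))
    return max_gap_ms


def compute_dwell(
    gaze: GazeStream, layout: LayoutStream, max_gap_ms: float = 100.0
) -> DwellTable:
    """Accumulate per-item dwell time from a gaze stream and a layout stream.

    Each valid sample contributes ``min(next_timestamp - timestamp,
    max_gap_ms)`` to the item it attributes to under the latest snapshot at
    or before its timestamp; the last sample contributes the nominal sample
    period (median inter-sample gap). Invalid samples contribute nothing.
    """
    if len(gaze) == 0 or len(layout) == 0:
        raise InputError("gaze and layout streams must be nonempty")
    ts = gaze.timestamps_ms
    snap_ts = np.array([s.timestamp_ms for s in layout.snapshots])
    if snap_ts[0] > ts[0]:
        raise InputError(
            f"no layout snapshot precedes the first gaze sample at {ts[0]}"
        )
    period = _nominal_period_ms(ts, max_gap_ms)
    durations = np.empty(len(ts))
    durations[:-1] = np.diff(ts)
    durations[-1] = period
    np.minimum(durations, max_gap_ms, out=durations)

    snap_idx = np.searchsorted(snap_ts, ts, side="right") - 1
    dwell: dict[str, float] = {}
    overlap_warned = False
    # process samples grouped by active snapshot so containment is vectorized
    for k in np.unique(snap_idx):
        snap = layout.snapshots[k]
        sel = (snap_idx == k) & gaze.valid
        if not np.any(sel) or not snap.elements:
            continue
        px, py, pd = gaze.x[sel], gaze.y[sel], durations[sel]
        rects = np.array([(e.x0, e.y0, e.x1, e.y1) for e in snap.elements])
        inside = (
            (px[:, None] >= rects[None, :, 0])
            & (px[:, None] < rects[None, :, 2])
            & (py[:, None] >= rects[None, :, 1])
            & (py[:, None] < rects[None, :, 3])
        )
        n_hits = inside.sum(axis=1)
        if not overlap_warned and np.any(n_hits > 1):
            logger.warning("overlapping elements contain gaze samples; first wins")
            overlap_warned = True
        hit = n_hits > 0
        first = np.argmax(inside[hit], axis=1)
        for e_idx, dur in zip(first, pd[hit]):
            item = snap.elements[e_idx].item_id
            dwell[item] = dwell.get(item, 0.0) + float(dur)
    duration = float(ts[-1] - ts[0] + period)
    return DwellTable(dwell_ms=dwell, session_duration_ms=duration)


def derive_gaze_labels(
    dwell: DwellTable,
    present_items: set[str],
    threshold_ms: float = DWELL_THRESHOLD_MS,
) -> LabelSet:
    """Binary gaze labels: positive iff accumulated dwell >= threshold.

    The threshold comparison is inclusive: a dwell of exactly 250 ms is
    positive. Items with data in the case but never gazed at are negative;
    items without data are absent (not in the returned mapping).
    """
    if threshold_ms <= 0:
        raise InputError("threshold_ms must be > 0")
    stray = set(dwell.dwell_ms) - set(present_items)
    if stray:
        raise SchemaError(
            f"dwell table contains items outside the layout universe: {sorted(stray)}"
        )
    labels = {
        item: (POSITIVE if dwell.get(item) >= threshold_ms else NEGATIVE)
        for item in sorted(present_items)
    }
    return LabelSet(source="gaze", labels=labels)


def derive_manual_labels(selections: set[str], present_items: set[str]) -> LabelSet:
    """Manual-selection labels: positive iff the item's checkbox was selected."""
    stray = set(selections) - set(present_items)
    if stray:
        raise InputError(
            f"selections reference items not present in the case: {sorted(stray)}"
        )
    labels = {
        item: (POSITIVE if item in selections else NEGATIVE)
        for item in sorted(present_items)
    }
    return LabelSet(source="manual", labels=labels)


def qc_session(session: "SessionSim", min_valid_fraction: float = 0.5) -> SessionQCReport:
    """Session quality control; never raises, always reports.

    A session is discarded when its gaze capture is incomplete (empty stream
    or valid-sample fraction below ``min_valid_fraction``) or when the
    selection task was skipped (no selection record).
    """
    reasons: list[str] = []
    frac = session.gaze_stream.valid_fraction if len(session.gaze_stream) else 0.0
    if len(session.gaze_stream) == 0 or frac < min_valid_fraction:
        reasons.append("gaze_incomplete")
    if session.manual_selections is None:
        reasons.append("selection_skipped")
    return SessionQCReport(valid=not reasons, reasons=reasons, valid_sample_fraction=frac)
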