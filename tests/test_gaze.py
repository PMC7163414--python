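"""Unit, oracle and property tests for gaze attribution, dwell and QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazerel.errors import InputError, SchemaError
from gazerel.gaze import (
    DwellTable,
    Element,
    GazeSample,
    GazeStream,
    LayoutSnapshot,
    LayoutStream,
    attribute_sample,
    compute_dwell,
    derive_gaze_labels,
    derive_manual_labels,
    qc_session,
)
from gazerel.simulate import SessionSim


def naive_dwell_oracle(gaze: GazeStream, layout: LayoutStream, max_gap_ms: float):
    """Independent per-sample loop: attribute each sample, accumulate time."""
    ts = gaze.timestamps_ms
    period = float(np.median(np.diff(ts))) if len(ts) > 1 else max_gap_ms
    snap_ts = [s.timestamp_ms for s in layout.snapshots]
    dwell: dict[str, float] = {}
    for i in range(len(ts)):
        if not gaze.valid[i]:
            continue
        dur = min((ts[i + 1] - ts[i]) if i + 1 < len(ts) else period, max_gap_ms)
        k = max(j for j, t in enumerate(snap_ts) if t <= ts[i])
        hit = None
        for e in layout.snapshots[k].elements:
            if e.x0 <= gaze.x[i] < e.x1 and e.y0 <= gaze.y[i] < e.y1:
                hit = e.item_id
                break
        if hit is not None:
            dwell[hit] = dwell.get(hit, 0.0) + dur
    return dwell


def _random_session(rng: np.random.Generator, allow_overlap: bool = False):
    n_elem = int(rng.integers(3, 8))
    n_snaps = int(rng.integers(1, 4))
    snaps = []
    for k in range(n_snaps):
        elements = []
        for e in range(n_elem):
            if allow_overlap:
                x0, y0 = rng.uniform(0, 800, size=2)
            else:
                x0, y0 = 10.0 + 120.0 * e, 50.0 - 30.0 * k
            elements.append(Element(f"it{e}", x0, y0, x0 + 100.0, y0 + 40.0))
        snaps.append(LayoutSnapshot(timestamp_ms=1000.0 * k, elements=elements))
    layout = LayoutStream(snapshots=snaps)
    n = int(rng.integers(50, 200))
    ts = np.cumsum(rng.uniform(5.0, 40.0, size=n))
    gaze = GazeStream(
        ts,
        rng.uniform(-50, 1000, size=n),
        rng.uniform(-50, 400, size=n),
        rng.random(n) > 0.1,
    )
    return gaze, layout


class TestAttributeSample:
    SNAP = LayoutSnapshot(
        timestamp_ms=0.0,
        elements=[Element("a", 10.0, 10.0, 110.0, 60.0), Element("b", 110.0, 10.0, 210.0, 60.0)],
    )

    def test_half_open_lower_corner_inside(self):
        assert attribute_sample(GazeSample(5.0, 10.0, 10.0), self.SNAP) == "a"

    def test_half_open_upper_corner_outside(self):
        assert attribute_sample(GazeSample(5.0, 210.0, 60.0), self.SNAP) is None

    def test_shared_edge_goes_to_right_element(self):
        assert attribute_sample(GazeSample(5.0, 110.0, 30.0), self.SNAP) == "b"

    def test_invalid_sample_attributes_to_none(self):
        assert attribute_sample(GazeSample(5.0, 50.0, 30.0, valid=False), self.SNAP) is None

    def test_overlap_first_element_wins(self):
        snap = LayoutSnapshot(
            timestamp_ms=0.0,
            elements=[Element("a", 0.0, 0.0, 100.0, 100.0), Element("b", 50.0, 50.0, 150.0, 150.0)],
        )
        assert attribute_sample(GazeSample(5.0, 60.0, 60.0), snap) == "a"

    def test_snapshot_after_sample_rejected(self):
        with pytest.raises(InputError):
            attribute_sample(GazeSample(5.0, 50.0, 30.0), LayoutSnapshot(10.0, []))

    def test_matches_brute_force_on_random_points(self, rng):
        """Attribution equals an independent containment scan over 10^4 points."""
        elements = []
        for i in range(6):
            x0, y0 = rng.uniform(0, 400, size=2)
            elements.append(Element(f"e{i}", x0, y0, x0 + rng.uniform(20, 200), y0 + rng.uniform(20, 200)))
        snap = LayoutSnapshot(0.0, elements)
        pts = rng.uniform(-50, 650, size=(10_000, 2))
        for x, y in pts:
            expected = None
            for e in elements:
                if e.x0 <= x < e.x1 and e.y0 <= y < e.y1:
                    expected = e.item_id
                    break
            assert attribute_sample(GazeSample(1.0, x, y), snap) == expected


class TestComputeDwell:
    def test_all_invalid_samples_give_empty_table(self):
        gaze = GazeStream(np.arange(10.0) * 16.0, np.full(10, 50.0), np.full(10, 30.0),
                          np.zeros(10, dtype=bool))
        layout = LayoutStream([LayoutSnapshot(0.0, [Element("a", 0, 0, 100, 100)])])
        table = compute_dwell(gaze, layout)
        assert table.dwell_ms == {}

    def test_sixty_samples_approximate_one_second(self):
        period = 1000.0 / 60.0
        ts = np.arange(60) * period
        gaze = GazeStream(ts, np.full(60, 50.0), np.full(60, 30.0), np.ones(60, dtype=bool))
        layout = LayoutStream([LayoutSnapshot(0.0, [Element("a", 0, 0, 100, 100)])])
        table = compute_dwell(gaze, layout)
        assert abs(table.get("a") - 1000.0) <= period

    def test_scroll_moves_element_but_dwell_follows_item(self):
        """Two snapshots; the element shifts up 100 px at t=500; samples that
        track the moved rectangle keep accruing to the same item."""
        snaps = [
            LayoutSnapshot(0.0, [Element("a", 0, 100, 100, 200)]),
            LayoutSnapshot(500.0, [Element("a", 0, 0, 100, 100)]),
        ]
        layout = LayoutStream(snaps)
        # 5 samples at y=150 (inside before scroll), 5 at y=50 (inside after)
        ts = np.array([0, 100, 200, 300, 400, 500, 600, 700, 800, 900], dtype=float)
        ys = np.array([150.0] * 5 + [50.0] * 5)
        gaze = GazeStream(ts, np.full(10, 50.0), ys, np.ones(10, dtype=bool))
        table = compute_dwell(gaze, layout, max_gap_ms=150.0)
        # hand-computed: every gap is 100 ms, last sample adds the nominal
        # period (median gap = 100 ms): 10 x 100 = 1000 ms
        assert table.get("a") == pytest.approx(1000.0)

    def test_max_gap_caps_contribution(self):
        ts = np.array([0.0, 1000.0, 1016.0])
        gaze = GazeStream(ts, np.full(3, 50.0), np.full(3, 50.0), np.ones(3, dtype=bool))
        layout = LayoutStream([LayoutSnapshot(0.0, [Element("a", 0, 0, 100, 100)])])
        table = compute_dwell(gaze, layout, max_gap_ms=100.0)
        # contributions: min(1000,100)=100, min(16,100)=16, last = median gap
        # capped at 100 -> 100 + 16 + 100
        assert table.get("a") == pytest.approx(216.0)

    def test_unsorted_gaze_rejected_at_construction(self):
        with pytest.raises(InputError, match="increasing"):
            GazeStream(np.array([0.0, 10.0, 5.0]), np.zeros(3), np.zeros(3), np.ones(3, bool))

    def test_sample_before_first_snapshot_rejected(self):
        gaze = GazeStream(np.array([0.0, 10.0]), np.zeros(2), np.zeros(2), np.ones(2, bool))
        layout = LayoutStream([LayoutSnapshot(5.0, [Element("a", 0, 0, 10, 10)])])
        with pytest.raises(InputError, match="0.0"):
            compute_dwell(gaze, layout)

    def test_matches_naive_oracle_on_random_sessions(self, rng):
        for _ in range(25):
            gaze, layout = _random_session(rng, allow_overlap=False)
            table = compute_dwell(gaze, layout, max_gap_ms=100.0)
            oracle = naive_dwell_oracle(gaze, layout, 100.0)
            assert set(table.dwell_ms) == set(oracle)
            for item in oracle:
                assert table.dwell_ms[item] == pytest.approx(oracle[item])

    def test_dwell_conservation(self, rng):
        for _ in range(10):
            gaze, layout = _random_session(rng)
            table = compute_dwell(gaze, layout, max_gap_ms=100.0)
            ts = gaze.timestamps_ms
            period = float(np.median(np.diff(ts)))
            assert sum(table.dwell_ms.values()) <= ts[-1] - ts[0] + period + 1e-9


class TestLabels:
    def test_exact_threshold_dwell_is_positive(self):
        table = DwellTable({"a": 250.0, "b": 249.999}, 10_000.0)
        labels = derive_gaze_labels(table, {"a", "b"}, threshold_ms=250.0)
        assert labels.labels == {"a": "positive", "b": "negative"}

    def test_never_gazed_item_is_negative(self):
        labels = derive_gaze_labels(DwellTable({}, 1000.0), {"a"})
        assert labels.labels["a"] == "negative"

    def test_stray_dwell_item_rejected(self):
        with pytest.raises(SchemaError, match="ghost"):
            derive_gaze_labels(DwellTable({"ghost": 300.0}, 1000.0), {"a"})

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 2000), min_size=1, max_size=20),
           st.floats(1, 500), st.floats(1, 500))
    def test_threshold_monotonicity(self, dwells, t1, t2):
        """Raising the threshold never creates new positives."""
        lo, hi = sorted((t1, t2))
        items = {f"i{k}" for k in range(len(dwells))}
        table = DwellTable({f"i{k}": d for k, d in enumerate(dwells)}, 1e9)
        pos_lo = derive_gaze_labels(table, items, lo).positives()
        pos_hi = derive_gaze_labels(table, items, hi).positives()
        assert pos_hi <= pos_lo

    def test_manual_labels_counts(self):
        items = {f"i{k}" for k in range(7)}
        labels = derive_manual_labels({"i0", "i3", "i5"}, items)
        assert sum(v == "positive" for v in labels.labels.values()) == 3
        assert sum(v == "negative" for v in labels.labels.values()) == 4

    def test_manual_labels_limits(self):
        items = {"a", "b"}
        assert derive_manual_labels(set(), items).positives() == set()
        assert derive_manual_labels(items, items).positives() == items

    def test_selection_outside_case_rejected(self):
        with pytest.raises(InputError, match="not present"):
            derive_manual_labels({"z"}, {"a"})

    def test_absent_for_unknown_items(self):
        labels = derive_manual_labels({"a"}, {"a"})
        assert labels.get("zz") == "absent"


def _session(gaze, selections):
    layout = LayoutStream([LayoutSnapshot(0.0, [Element("a", 0, 0, 10, 10)])])
    return SessionSim(case_id="c", gaze_stream=gaze, layout_stream=layout,
                      manual_selections=selections)


class TestQC:
    def _gaze(self, n_valid, n_invalid):
        n = n_valid + n_invalid
        valid = np.array([True] * n_valid + [False] * n_invalid)
        return GazeStream(np.arange(n, dtype=float), np.zeros(n), np.zeros(n), valid)

    def test_clean_session_passes(self):
        report = qc_session(_session(self._gaze(10, 0), {"a"}))
        assert report.valid and report.reasons == []

    def test_empty_gaze_flagged_incomplete(self):
        report = qc_session(_session(self._gaze(0, 0), {"a"}))
        assert not report.valid and "gaze_incomplete" in report.reasons

    def test_low_valid_fraction_flagged(self):
        report = qc_session(_session(self._gaze(4, 6), {"a"}), min_valid_fraction=0.5)
        assert "gaze_incomplete" in report.reasons
        assert report.valid_sample_fraction == pytest.approx(0.4)

    def test_missing_selection_record_flagged(self):
        report = qc_session(_session(self._gaze(10, 0), None))
        assert not report.valid and report.reasons == ["selection_skipped"]

    def test_empty_selection_set_is_not_skipped(self):
        report = qc_session(_session(self._gaze(10, 0), set()))
        assert report.valid
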