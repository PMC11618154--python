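import pytest

from gazecal.geometry import ScreenPoint
from gazecal.session import (
    CalibrationController,
    Command,
    Session,
    run_loop,
    replay_source,
)

from conftest import DT_60HZ, constant_source, make_sample


def feed_constant(session, pos, n, t0=None, **kwargs):
    """Feed n consecutive 60 Hz samples fixating ``pos``."""
    t0 = session.now + DT_60HZ if t0 is None else t0
    events = []
    for i in range(n):
        events += session.feed(make_sample(t0 + i * DT_60HZ, pos, **kwargs))
    return events


def collect_point(session, pid, pos=None, n=40):
    """Start collection for a point and feed enough on-target samples."""
    target = session.targets[session.mode][pid].pos
    pos = pos or (target.x, target.y)
    session.dispatch(Command("start_collection", point_id=pid))
    return feed_constant(session, pos, n)


@pytest.fixture
def session(geometry):
    return Session(geometry)


class TestCommandValidation:
    def test_unknown_verb_rejected(self):
        with pytest.raises(ValueError):
            Command("explode")

    def test_missing_payload_rejected(self):
        with pytest.raises(ValueError):
            Command("start_collection")
        with pytest.raises(ValueError):
            Command("set_eyes", eye="middle")


class TestTargetLifecycle:
    def test_collection_success_path(self, session):
        events = collect_point(session, 3)
        kinds = [e.kind for e in events]
        assert "collection_succeeded" in kinds
        assert session.targets["calibration"][3].status == "collected"
        assert 3 in session.cal_data.points

    def test_collection_fails_without_valid_samples(self, session):
        session.dispatch(Command("start_collection", point_id=1))
        feed_constant(session, None, 40, left_valid=False, right_valid=False)
        assert session.event_log[-1].kind == "collection_failed"
        assert session.targets["calibration"][1].status == "not_collected"

    def test_off_screen_gaze_does_not_count(self, session):
        session.dispatch(Command("start_collection", point_id=1))
        feed_constant(session, (1.4, 0.6), 40)  # valid but far off-screen
        assert session.event_log[-1].kind == "collection_failed"

    def test_per_eye_success_with_one_eye_blinking(self, session):
        session.dispatch(Command("start_collection", point_id=2))
        feed_constant(session, (0.9, 0.1), 40, left_valid=False)
        ev = [e for e in session.event_log if e.kind == "collection_succeeded"][-1]
        assert ev.payload["n_valid"]["left"] == 0
        assert ev.payload["n_valid"]["right"] >= session.min_samples_per_point

    def test_start_while_collecting_rejected(self, session):
        session.dispatch(Command("start_collection", point_id=1))
        events = session.dispatch(Command("start_collection", point_id=2))
        assert events[0].kind == "error"

    def test_unknown_point_error_event(self, session):
        events = session.dispatch(Command("enqueue_point", point_id=99))
        assert events[0].kind == "error"

    def test_enqueue_forms_fifo_queue(self, session):
        session.dispatch(Command("enqueue_point", point_id=1))
        session.dispatch(Command("enqueue_point", point_id=2))
        assert session.targets["calibration"][1].status == "showing"
        assert session.targets["calibration"][2].status == "enqueued"
        assert session.active_point_id == 1

    def test_discard_point_resets_status_and_data(self, session):
        collect_point(session, 1)
        session.dispatch(Command("discard_point", point_id=1))
        assert session.targets["calibration"][1].status == "not_collected"
        assert 1 not in session.cal_data.points

    def test_status_lattice_transitions_only(self, session):
        collect_point(session, 1)
        collect_point(session, 2)
        session.dispatch(Command("discard_all"))
        allowed = {
            ("not_collected", "enqueued"), ("not_collected", "showing"),
            ("enqueued", "showing"), ("showing", "collecting"),
            ("collecting", "collected"), ("collecting", "not_collected"),
            ("collected", "not_collected"), ("showing", "not_collected"),
            ("enqueued", "not_collected"),
        }
        for _t, _mode, _pid, old, new in session.transition_log:
            assert (old, new) in allowed


class TestCalibrationCommands:
    def test_compute_without_data_fails(self, session):
        events = session.dispatch(Command("compute_calibration"))
        assert events[0].kind == "calibration_failed"
        assert session.active_result.is_default  # active unchanged

    def test_compute_updates_active_result(self, session):
        for pid in (1, 2, 3):
            collect_point(session, pid)
        events = session.dispatch(Command("compute_calibration"))
        assert events[0].kind == "calibration_computed"
        assert sorted(events[0].payload["points_used"]) == [1, 2, 3]
        assert not session.active_result.is_default

    def test_snapshot_restore_after_discard_all(self, session):
        for pid in (1, 2, 3, 4, 5):
            collect_point(session, pid)
        session.dispatch(Command("compute_calibration"))
        before = session.active_result.to_json()
        session.dispatch(Command("take_snapshot", label="A"))
        session.dispatch(Command("discard_all"))
        session.dispatch(Command("compute_calibration"))  # fails, data gone
        session.dispatch(Command("load_snapshot", label="A"))
        assert session.active_result.to_json() == before

    def test_snapshot_labels_unique(self, session):
        session.dispatch(Command("take_snapshot", label="A"))
        events = session.dispatch(Command("take_snapshot", label="A"))
        assert events[0].kind == "error"

    def test_load_unknown_snapshot_error(self, session):
        events = session.dispatch(Command("load_snapshot", label="nope"))
        assert events[0].kind == "error"

    def test_snapshot_is_immutable_copy(self, session):
        collect_point(session, 1)
        session.dispatch(Command("compute_calibration"))
        session.dispatch(Command("take_snapshot", label="A"))
        stored = session.snapshots["A"].result.to_json()
        for pid in (2, 3, 4):
            collect_point(session, pid)
        session.dispatch(Command("compute_calibration"))
        assert session.snapshots["A"].result.to_json() == stored


class TestModes:
    def test_validation_collection_goes_to_val_data(self, session):
        session.dispatch(Command("switch_mode", mode="validation"))
        assert session.mode == "validation"
        collect_point(session, 1)
        assert 1 in session.val_data
        assert len(session.cal_data) == 0

    def test_mode_switch_emits_event_and_clears_active(self, session):
        session.dispatch(Command("enqueue_point", point_id=1))
        events = session.dispatch(Command("switch_mode", mode="validation"))
        assert events[-1].kind == "mode_changed"
        assert session.active_point_id is None


class TestCalibratedReporting:
    def test_reported_gaze_is_calibrated(self, session):
        # calibrate out a pure translation, then check the buffer stream
        raw_shift = (0.05, -0.02)
        target = session.targets["calibration"][3].pos  # (0.5, 0.5)
        session.dispatch(Command("start_collection", point_id=3))
        feed_constant(session, (target.x + raw_shift[0], target.y + raw_shift[1]), 40)
        session.dispatch(Command("compute_calibration"))
        feed_constant(session, (0.6 + raw_shift[0], 0.7 + raw_shift[1]), 5)
        last = session.buffer.last
        assert last.left.screen_pos.x == pytest.approx(0.6, abs=1e-9)
        assert last.left.screen_pos.y == pytest.approx(0.7, abs=1e-9)


class TestRunLoop:
    def test_null_controller_leaves_state_unchanged(self, geometry):
        session = Session(geometry)
        log = run_loop(session, CalibrationController(),
                       constant_source((0.5, 0.5)), max_ticks=100)
        assert log.n_ticks == 100
        assert len(session.event_log) == 0
        assert len(session.cal_data) == 0
        assert len(session.buffer) > 0

    def test_set_auto_event_echoed_to_controller(self, geometry):
        class AutoOnce(CalibrationController):
            def __init__(self):
                self.received = []
                self.sent = False

            def tick(self, session):
                if not self.sent:
                    self.sent = True
                    return [Command("set_auto", on=True)]
                return []

            def receive_update(self, event):
                self.received.append(event.kind)

        ctl = AutoOnce()
        run_loop(Session(geometry), ctl, constant_source((0.5, 0.5)),
                 max_ticks=5)
        assert "auto_toggled" in ctl.received

    def test_scripted_controller_equals_direct_dispatch(self, geometry):
        script = [Command("enqueue_point", point_id=1),
                  Command("set_eyes", eye="left"),
                  Command("switch_mode", mode="validation"),
                  Command("set_auto", on=True)]

        class Scripted(CalibrationController):
            def __init__(self, cmds):
                self.cmds = list(cmds)

            def tick(self, session):
                return [self.cmds.pop(0)] if self.cmds else []

        s1 = Session(geometry)
        run_loop(s1, Scripted(script), constant_source((0.5, 0.5)), max_ticks=10)

        s2 = Session(geometry)
        for i in range(10):
            s2.feed(make_sample(i * DT_60HZ, (0.5, 0.5)))
            if i < len(script):
                s2.dispatch(script[i])
        assert s1.mode == s2.mode
        assert s1.selected_eyes == s2.selected_eyes
        assert s1.auto_active == s2.auto_active
        assert [e.kind for e in s1.event_log] == [e.kind for e in s2.event_log]

    def test_controller_exception_halts_cleanly(self, geometry):
        class Broken(CalibrationController):
            def tick(self, session):
                if session.now > 50:
                    raise RuntimeError("boom")
                return []

        log = run_loop(Session(geometry), Broken(),
                       constant_source((0.5, 0.5)), max_ticks=100)
        assert log.error is not None and "boom" in log.error
        assert log.n_ticks < 100

    def test_replay_source_ends_stream(self, geometry):
        samples = [make_sample(i * DT_60HZ, (0.5, 0.5)) for i in range(10)]
        session = Session(geometry)
        log = run_loop(session, CalibrationController(),
                       replay_source(samples), max_ticks=50)
        assert len(log.reported_samples) == 10

    def test_at_most_one_target_active_per_tick(self, geometry):
        class Greedy(CalibrationController):
            def tick(self, session):
                return [Command("enqueue_point", point_id=1 + (len(session.command_log) % 5))]

        session = Session(geometry)
        log = run_loop(session, Greedy(), constant_source((0.5, 0.5)),
                       max_ticks=60)
        assert all(ok for _t, _pid, ok in log.ticks)
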