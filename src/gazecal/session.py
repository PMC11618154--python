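"""Calibration/validation session state machine and controller run loop.

The session models the advanced calibration interface as an explicitly
dispatched state machine: operator inputs (mouse clicks, keyboard
shortcuts) and automated-controller decisions both become
:class:`Command` objects fed through a single :meth:`Session.dispatch`
path, and every state change is reported as an :class:`Event`.  This
keeps the manual and automated operation modes on one code path and makes
full sessions replayable and testable without any GUI.

Target lifecycle::

    not_collected -> enqueued -> showing -> collecting -> collected
                                                      \\-> not_collected (failure)

At most one target is showing/collecting at a time; enqueued targets form
a FIFO queue whose head is promoted when no target is active.

A *controller* automates the interface through a four-method contract
(:class:`CalibrationController`): ``tick`` is called every frame and may
return commands, ``receive_update`` is notified of every event,
``get_status_text`` supplies operator-screen status, and ``draw`` returns
the stimulus records to present.  Controller methods are invoked every
tick regardless of whether auto mode is active, so e.g. reward gating can
run before, during and after the automated procedure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .calibration import (
    MIN_SAMPLES_PER_POINT,
    RESIDUAL_SANITY_BOUND,
    CalibrationData,
    CalibrationResult,
    apply_calibration,
    default_calibration,
    fit_calibration,
    merge_monocular,
)
from .gaze_stream import (
    GAZE_HISTORY_WINDOW_MS,
    SMOOTHING_WINDOW_MS,
    EyeSample,
    GazeBuffer,
    GazeSample,
)
from .geometry import ScreenGeometry, ScreenPoint
from .quality import COLLECTION_WINDOW_MS, SessionReport, compute_point_quality

# Default target layouts (normalized coordinates, ids assigned 1..n).
# Calibration: center plus four corners at 10% margins; validation: a
# four-point diamond.  Both are fully configurable.
DEFAULT_CAL_LAYOUT = (ScreenPoint(0.1, 0.1), ScreenPoint(0.9, 0.1),
                      ScreenPoint(0.5, 0.5), ScreenPoint(0.1, 0.9),
                      ScreenPoint(0.9, 0.9))
DEFAULT_VAL_LAYOUT = (ScreenPoint(0.5, 0.2), ScreenPoint(0.2, 0.5),
                      ScreenPoint(0.8, 0.5), ScreenPoint(0.5, 0.8))

CAL = "calibration"
VAL = "validation"

#: Documented operator keyboard mapping, translated to commands.
KEYBOARD_COMMANDS = {
    "digit": "enqueue_point (shift: discard_point)",
    "c": "compute_calibration",
    "s": "take_snapshot",
    "a": "set_auto (toggle)",
    "m": "switch_mode",
    "e": "set_eyes",
    "x": "skip_phase",
    "j": "manual_reward",
    "enter": "finish (continue)",
    "shift+escape": "finish (exit)",
}


@dataclass(frozen=True)
class Command:
    """One operator or controller instruction to the interface."""

    verb: str
    point_id: int | None = None
    label: str | None = None
    eye: str | None = None
    mode: str | None = None
    on: bool | None = None

    _VERBS = frozenset({
        "enqueue_point", "start_collection", "discard_point", "discard_all",
        "compute_calibration", "take_snapshot", "load_snapshot", "switch_mode",
        "set_eyes", "set_auto", "finish", "skip_phase", "manual_reward",
    })

    def __post_init__(self) -> None:
        if self.verb not in self._VERBS:
            raise ValueError(f"unknown command verb {self.verb!r}")
        needs_point = {"enqueue_point", "start_collection", "discard_point"}
        if self.verb in needs_point and self.point_id is None:
            raise ValueError(f"{self.verb} requires point_id")
        if self.verb in {"take_snapshot", "load_snapshot"} and self.label is None:
            raise ValueError(f"{self.verb} requires label")
        if self.verb == "set_eyes" and self.eye not in ("left", "right", "both"):
            raise ValueError("set_eyes requires eye in left/right/both")
        if self.verb == "set_auto" and self.on is None:
            raise ValueError("set_auto requires on")


@dataclass(frozen=True)
class Event:
    """One state-change notification; ``seq`` is a session-global counter."""

    kind: str
    t: float
    seq: int
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "t": self.t, "seq": self.seq,
                "payload": self.payload}


@dataclass
class TargetPoint:
    """A calibration or validation location with its lifecycle status."""

    id: int
    pos: ScreenPoint
    status: str = "not_collected"


@dataclass(frozen=True)
class CalibrationSnapshot:
    """An immutable stored copy of a computed calibration."""

    label: str
    result: CalibrationResult
    validation: SessionReport | None = None


@dataclass(frozen=True)
class StimulusRecord:
    """What the participant screen shows: a media rectangle."""

    media_id: str
    center: ScreenPoint
    size_px: tuple[float, float]

    def contains(self, p: ScreenPoint, g: ScreenGeometry) -> bool:
        """Closed-region membership test in pixel space."""
        dx = abs((p.x - self.center.x) * g.width_px)
        dy = abs((p.y - self.center.y) * g.height_px)
        return dx <= self.size_px[0] / 2.0 and dy <= self.size_px[1] / 2.0


class CalibrationController:
    """Base class for the four-method automated-operation contract."""

    def tick(self, session: "Session") -> list[Command]:
        return []

    def receive_update(self, event: Event) -> None:
        pass

    def get_status_text(self) -> str | None:
        return None

    def draw(self) -> list[StimulusRecord]:
        return []


@dataclass
class ValidationCollection:
    """Samples gathered during one validation point's window."""

    target: ScreenPoint
    samples: list[GazeSample]       # calibrated, as reported by the tracker
    raw_samples: list[GazeSample]   # uncalibrated, for pre-calibration readouts
    duration_ms: float


class Session:
    """State of one calibration/validation session.

    The session starts in calibration mode with the default (identity)
    calibration active, i.e. an effectively uncalibrated tracker.
    """

    def __init__(self, geometry: ScreenGeometry,
                 cal_layout: Sequence[ScreenPoint] = DEFAULT_CAL_LAYOUT,
                 val_layout: Sequence[ScreenPoint] = DEFAULT_VAL_LAYOUT,
                 *,
                 rate_hz: float = 60.0,
                 min_samples_per_point: int = MIN_SAMPLES_PER_POINT,
                 collection_window_ms: float = COLLECTION_WINDOW_MS,
                 smoothing_window_ms: float = SMOOTHING_WINDOW_MS,
                 history_window_ms: float = GAZE_HISTORY_WINDOW_MS,
                 residual_bound: float = RESIDUAL_SANITY_BOUND,
                 trimmed_refit: bool = False,
                 accuracy_statistic: str = "mean",
                 collection_position_margin: float = 0.1,
                 metadata: dict | None = None) -> None:
        self.geometry = geometry
        self.rate_hz = rate_hz
        self.tick_dt = 1000.0 / rate_hz
        self.min_samples_per_point = min_samples_per_point
        self.collection_window_ms = collection_window_ms
        self.smoothing_window_ms = smoothing_window_ms
        self.history_window_ms = history_window_ms
        self.residual_bound = residual_bound
        self.trimmed_refit = trimmed_refit
        self.accuracy_statistic = accuracy_statistic
        self.collection_position_margin = collection_position_margin
        self.metadata = dict(metadata or {})

        self.targets: dict[str, dict[int, TargetPoint]] = {
            CAL: {i + 1: TargetPoint(i + 1, p) for i, p in enumerate(cal_layout)},
            VAL: {i + 1: TargetPoint(i + 1, p) for i, p in enumerate(val_layout)},
        }
        self.mode = CAL
        self.queue: list[int] = []
        self.active_point_id: int | None = None
        self.collecting = False
        self._collect_start_t = 0.0
        self._collect_samples: list[tuple[GazeSample, GazeSample]] = []

        self.cal_data = CalibrationData()
        self.val_data: dict[int, ValidationCollection] = {}
        self.active_result: CalibrationResult = default_calibration()
        self.snapshots: dict[str, CalibrationSnapshot] = {}
        self.auto_active = False
        self.selected_eyes = "both"
        self.show_gaze = False
        self.show_head = False
        self.finished = False

        self.buffer = GazeBuffer(keep_ms=max(2000.0, history_window_ms * 2))
        self.now = 0.0
        self._seq = 0
        self.event_log: list[Event] = []
        self.command_log: list[tuple[float, Command]] = []
        self.transition_log: list[tuple[float, str, int, str, str]] = []

    # -- internals ---------------------------------------------------------

    def _event(self, kind: str, **payload) -> Event:
        ev = Event(kind=kind, t=self.now, seq=self._seq, payload=payload)
        self._seq += 1
        self.event_log.append(ev)
        return ev

    def _set_status(self, point: TargetPoint, status: str) -> None:
        if point.status != status:
            self.transition_log.append(
                (self.now, self.mode, point.id, point.status, status))
            point.status = status

    def _current_targets(self) -> dict[int, TargetPoint]:
        return self.targets[self.mode]

    def target_pos(self, point_id: int, mode: str | None = None) -> ScreenPoint:
        return self.targets[mode or self.mode][point_id].pos

    def _promote_queue(self) -> None:
        while self.active_point_id is None and self.queue:
            pid = self.queue.pop(0)
            point = self._current_targets().get(pid)
            if point is None:
                continue
            self.active_point_id = pid
            self._set_status(point, "showing")

    def _apply_active(self, raw: GazeSample) -> GazeSample:
        """Reported (calibrated) sample: the active mapping applied per eye.

        An eye without a fitted mapping passes through unchanged, matching
        a tracker that is uncalibrated for that eye.
        """
        res = self.active_result

        def conv(e: EyeSample, eye: str) -> EyeSample:
            if not e.valid or eye not in res.mappings:
                return e
            pos = apply_calibration(e.screen_pos, res, eye)
            return EyeSample(screen_pos=pos, valid=True, origin=e.origin,
                             pupil_diameter_mm=e.pupil_diameter_mm,
                             openness=e.openness)

        return GazeSample(t=raw.t, left=conv(raw.left, "left"),
                          right=conv(raw.right, "right"))

    # -- sample ingestion --------------------------------------------------

    def feed(self, raw: GazeSample) -> list[Event]:
        """Ingest one raw tracker sample; returns any resulting events.

        The sample enters the gaze buffer in calibrated (reported) form;
        if a collection window is open the sample is appended to it, and
        the window is finalized once the configured duration has elapsed.
        """
        start = len(self.event_log)
        reported = self._apply_active(raw)
        self.buffer.append(reported)
        self.now = raw.t
        if self.collecting:
            self._collect_samples.append((reported, raw))
            if raw.t - self._collect_start_t >= self.collection_window_ms:
                self._finalize_collection()
        return self.event_log[start:]

    def _finalize_collection(self) -> None:
        pid = self.active_point_id
        point = self._current_targets()[pid]
        samples = self._collect_samples
        self.collecting = False
        self._collect_samples = []
        self.active_point_id = None

        # A sample is usable for an eye when it is valid and its raw
        # position lies on or near the screen: a participant looking far
        # off-screen yields no usable calibration/validation data.
        lo, hi = -self.collection_position_margin, 1.0 + self.collection_position_margin

        def usable(e: EyeSample) -> bool:
            return (e.valid and lo <= e.screen_pos.x <= hi
                    and lo <= e.screen_pos.y <= hi)

        n_valid = {eye: sum(1 for _rep, raw in samples if usable(raw.eye(eye)))
                   for eye in ("left", "right")}
        wanted = (("left", "right") if self.selected_eyes == "both"
                  else (self.selected_eyes,))
        ok = any(n_valid[e] >= self.min_samples_per_point for e in wanted)
        if ok:
            if self.mode == CAL:
                self.cal_data.discard(pid)
                entry = self.cal_data.add_point(pid, point.pos)
                for _rep, raw in samples:
                    if usable(raw.left):
                        entry.left.append(raw.left.screen_pos)
                    if usable(raw.right):
                        entry.right.append(raw.right.screen_pos)
            else:
                self.val_data[pid] = ValidationCollection(
                    target=point.pos,
                    samples=[rep for rep, _raw in samples],
                    raw_samples=[raw for _rep, raw in samples],
                    duration_ms=self.collection_window_ms)
            self._set_status(point, "collected")
            self._event("collection_succeeded", mode=self.mode, point=pid,
                        n_valid=n_valid)
        else:
            self._set_status(point, "not_collected")
            self._event("collection_failed", mode=self.mode, point=pid,
                        n_valid=n_valid)
        self._promote_queue()

    # -- command dispatch --------------------------------------------------

    def dispatch(self, cmd: Command) -> list[Event]:
        """Execute one command; invalid commands yield an error event."""
        start = len(self.event_log)
        self.command_log.append((self.now, cmd))
        handler = getattr(self, f"_cmd_{cmd.verb}")
        handler(cmd)
        return self.event_log[start:]

    def _error(self, message: str, **payload) -> None:
        self._event("error", message=message, **payload)

    def _cmd_enqueue_point(self, cmd: Command) -> None:
        point = self._current_targets().get(cmd.point_id)
        if point is None:
            self._error(f"unknown point id {cmd.point_id}", point=cmd.point_id)
            return
        if cmd.point_id in self.queue or cmd.point_id == self.active_point_id:
            return
        self._set_status(point, "enqueued")
        self.queue.append(cmd.point_id)
        self._promote_queue()

    def _cmd_start_collection(self, cmd: Command) -> None:
        if self.collecting:
            self._error("collection already in progress", point=cmd.point_id)
            return
        point = self._current_targets().get(cmd.point_id)
        if point is None:
            self._error(f"unknown point id {cmd.point_id}", point=cmd.point_id)
            return
        pid = cmd.point_id
        if self.active_point_id != pid:
            # Promote this point directly, displacing any passively-shown one.
            if self.active_point_id is not None:
                prev = self._current_targets()[self.active_point_id]
                self._set_status(prev, "enqueued")
                self.queue.insert(0, self.active_point_id)
            if point.status == "collected":
                # Recollection: drop the stale data first.
                self._discard_data(pid)
                self._set_status(point, "not_collected")
            self.active_point_id = pid
            self._set_status(point, "showing")
        elif point.status == "collected":
            self._discard_data(pid)
            self._set_status(point, "not_collected")
            self._set_status(point, "showing")
        self._set_status(point, "collecting")
        self.collecting = True
        self._collect_start_t = self.now
        self._collect_samples = []
        self._event("collection_started", mode=self.mode, point=pid)

    def _discard_data(self, pid: int) -> None:
        if self.mode == CAL:
            self.cal_data.discard(pid)
        else:
            self.val_data.pop(pid, None)

    def _cmd_discard_point(self, cmd: Command) -> None:
        point = self._current_targets().get(cmd.point_id)
        if point is None:
            self._error(f"unknown point id {cmd.point_id}", point=cmd.point_id)
            return
        pid = cmd.point_id
        self._discard_data(pid)
        if pid == self.active_point_id:
            self.collecting = False
            self._collect_samples = []
            self.active_point_id = None
        if pid in self.queue:
            self.queue.remove(pid)
        self._set_status(point, "not_collected")
        self._event("point_discarded", mode=self.mode, point=pid)
        self._promote_queue()

    def _cmd_discard_all(self, cmd: Command) -> None:
        if self.mode == CAL:
            self.cal_data.clear()
        else:
            self.val_data.clear()
        self.collecting = False
        self._collect_samples = []
        self.active_point_id = None
        self.queue.clear()
        for point in self._current_targets().values():
            self._set_status(point, "not_collected")
        self._event("point_discarded", mode=self.mode, point=None)

    def _cmd_compute_calibration(self, cmd: Command) -> None:
        result = fit_calibration(self.cal_data, eyes=self.selected_eyes,
                                 min_samples_per_point=self.min_samples_per_point,
                                 residual_bound=self.residual_bound,
                                 trimmed_refit=self.trimmed_refit)
        if result.succeeded:
            if (self.selected_eyes != "both"
                    and self.active_result.succeeded
                    and set(self.active_result.mappings) - set(result.mappings)):
                result = merge_monocular(self.active_result, result)
            self.active_result = result
            self._event("calibration_computed", eyes=result.eyes,
                        points_used=list(result.points_used))
        else:
            self._event("calibration_failed", reason=result.failure_reason)

    def _cmd_take_snapshot(self, cmd: Command) -> None:
        if cmd.label in self.snapshots:
            self._error(f"snapshot label {cmd.label!r} already exists",
                        label=cmd.label)
            return
        validation = self.validation_report() if self.val_data else None
        snap = CalibrationSnapshot(label=cmd.label,
                                   result=copy.deepcopy(self.active_result),
                                   validation=validation)
        self.snapshots[cmd.label] = snap
        self._event("snapshot_taken", label=cmd.label)

    def _cmd_load_snapshot(self, cmd: Command) -> None:
        snap = self.snapshots.get(cmd.label)
        if snap is None:
            self._error(f"unknown snapshot label {cmd.label!r}", label=cmd.label)
            return
        self.active_result = copy.deepcopy(snap.result)
        self._event("snapshot_loaded", label=cmd.label)

    def _cmd_switch_mode(self, cmd: Command) -> None:
        new_mode = cmd.mode or (VAL if self.mode == CAL else CAL)
        if new_mode not in (CAL, VAL):
            self._error(f"unknown mode {new_mode!r}")
            return
        if new_mode == self.mode:
            return
        if self.collecting and self.active_point_id is not None:
            point = self._current_targets()[self.active_point_id]
            self._set_status(point, "not_collected")
        elif self.active_point_id is not None:
            point = self._current_targets()[self.active_point_id]
            self._set_status(point, "not_collected")
        self.collecting = False
        self._collect_samples = []
        self.active_point_id = None
        self.queue.clear()
        self.mode = new_mode
        self._event("mode_changed", mode=new_mode)

    def _cmd_set_eyes(self, cmd: Command) -> None:
        self.selected_eyes = cmd.eye
        self._event("eyes_changed", eye=cmd.eye)

    def _cmd_set_auto(self, cmd: Command) -> None:
        if self.auto_active != cmd.on:
            self.auto_active = cmd.on
            self._event("auto_toggled", on=cmd.on)

    def _cmd_finish(self, cmd: Command) -> None:
        self.finished = True
        self._event("finished")

    def _cmd_skip_phase(self, cmd: Command) -> None:
        self._event("phase_skip_requested")

    def _cmd_manual_reward(self, cmd: Command) -> None:
        self._event("manual_reward")

    # -- reports -----------------------------------------------------------

    def validation_report(self, use_raw: bool = False) -> SessionReport:
        """Quality report over the collected validation points.

        ``use_raw`` computes the same report on the uncalibrated samples,
        i.e. what a default (identity) calibration would have reported.
        """
        points = []
        for pid in sorted(self.val_data):
            coll = self.val_data[pid]
            samples = coll.raw_samples if use_raw else coll.samples
            points.append(compute_point_quality(
                samples, coll.target, self.geometry, coll.duration_ms,
                self.rate_hz, accuracy_statistic=self.accuracy_statistic))
        meta = dict(self.metadata)
        meta["calibration_points_used"] = list(self.active_result.points_used)
        meta["signal"] = "raw" if use_raw else "calibrated"
        return SessionReport(points=points, metadata=meta)


# ---------------------------------------------------------------------------
# Run loop

GazeSource = Callable[[float, list[StimulusRecord]], GazeSample | None]


@dataclass
class SessionLog:
    """Everything a run loop produced, for inspection and archiving."""

    events: list[Event] = field(default_factory=list)
    commands: list[tuple[float, Command]] = field(default_factory=list)
    stimuli: list[tuple[float, tuple[StimulusRecord, ...]]] = field(default_factory=list)
    status_texts: list[tuple[float, str]] = field(default_factory=list)
    ticks: list[tuple[float, int | None, bool]] = field(default_factory=list)
    raw_samples: list[GazeSample] = field(default_factory=list)
    reported_samples: list[GazeSample] = field(default_factory=list)
    n_ticks: int = 0
    error: str | None = None


def run_loop(session: Session, controller: CalibrationController,
             gaze_source: GazeSource, *, max_ticks: int,
             record_gaze: bool = True) -> SessionLog:
    """Drive the session with a controller and a gaze source.

    Each tick: new gaze is fed to the session, ``controller.tick`` runs and
    its commands are dispatched, every event is forwarded to
    ``controller.receive_update``, the status text is queried, and the
    draw hook provides the stimuli the gaze source will react to on the
    next tick.  A controller exception halts the loop cleanly with the
    error recorded in the log.
    """
    log = SessionLog()
    stimuli: list[StimulusRecord] = []
    last_status: str | None = None
    dt = session.tick_dt
    try:
        for k in range(max_ticks):
            t = k * dt
            raw = gaze_source(t, stimuli)
            events: list[Event] = []
            if raw is not None:
                if record_gaze:
                    log.raw_samples.append(raw)
                events.extend(session.feed(raw))
                if record_gaze:
                    log.reported_samples.append(session.buffer.last)
            commands = controller.tick(session) or []
            for cmd in commands:
                events.extend(session.dispatch(cmd))
            for ev in events:
                controller.receive_update(ev)
            status = controller.get_status_text()
            if status != last_status and status is not None:
                log.status_texts.append((session.now, status))
                last_status = status
            stimuli = list(controller.draw() or [])
            log.stimuli.append((t, tuple(stimuli)))
            n_active = sum(1 for p in session._current_targets().values()
                           if p.status in ("showing", "collecting"))
            log.ticks.append((t, session.active_point_id, n_active <= 1))
            log.n_ticks = k + 1
            if session.finished:
                break
    except Exception as exc:  # noqa: BLE001 - contract: halt cleanly, log error
        log.error = f"{type(exc).__name__}: {exc}"
    log.events = list(session.event_log)
    log.commands = list(session.command_log)
    return log


def replay_source(samples: Iterable[GazeSample]) -> GazeSource:
    """Gaze source replaying a recorded stream, ignoring stimuli."""
    it = iter(samples)

    def source(t: float, stimuli: list[StimulusRecord]) -> GazeSample | None:
        return next(it, None)

    return source
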