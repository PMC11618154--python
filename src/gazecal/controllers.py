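"""Automated calibration controllers and reward gating.

Two controllers are provided on top of the session's four-method
controller contract:

* :class:`NHPController` — the automated procedure for participants who
  cannot follow instructions (designed for nonhuman primates).  Three
  phases: an attention-grabbing phase playing a full-screen video that
  progressively shrinks while watched down to the calibration-video size;
  a calibration phase in which data collection for each target is
  triggered once the binocular-average gaze has dwelt within one third of
  the vertical screen size of the video center for at least 500 ms; and a
  validation phase collecting a 2-row × 4-column grid of points, with the
  stricter requirement that gaze dwell on the video rectangle itself.
  Failed calibrations discard all collected data and restart collection;
  a successful calibration switches auto mode off so the operator can
  inspect and confirm before validation.

* :class:`AdultDemoController` — a gaze-contingent three-stage demo for
  instructable participants: a single center point, then two rounds of
  three simultaneous points with arc-shaped AOIs deciding which target is
  being looked at; a calibration is computed at the end of each stage.

Reward delivery is abstracted behind :class:`RewardSink`: the automatic
gate activates the sink only while gaze is inside the currently shown
video rectangle (never for on-screen gaze elsewhere), and the operator
can pulse it manually at any time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import ScreenGeometry, ScreenPoint
from .session import (
    VAL,
    CalibrationController,
    Command,
    Event,
    Session,
    StimulusRecord,
)

#: Calibration-video size, px (the size the attention video shrinks to).
VIDEO_CAL_SIZE_PX = (300.0, 300.0)

#: Dwell-trigger distance criterion: fraction of the vertical screen size.
DWELL_DISTANCE_FRAC = 1.0 / 3.0

#: Minimum continuous qualifying dwell before collection is triggered, ms.
DWELL_DURATION_MS = 500.0

#: Default calibration locations for the automated procedure (two).
DEFAULT_NHP_CAL_POINTS = (ScreenPoint(0.3, 0.5), ScreenPoint(0.7, 0.5))


def validation_grid(rows: int = 2, cols: int = 4) -> tuple[ScreenPoint, ...]:
    """Evenly spread rows × cols grid of validation locations."""
    return tuple(ScreenPoint((2 * c + 1) / (2 * cols), (2 * r + 1) / (2 * rows))
                 for r in range(rows) for c in range(cols))


class RewardSink:
    """Abstract reward interface (e.g. a juice pump).

    ``set_active`` switches continuous delivery; ``pulse`` dispenses a
    single manually-triggered reward.  Implementations used in tests must
    be side-effect-free fakes.
    """

    def set_active(self, active: bool, t: float) -> None:  # pragma: no cover
        raise NotImplementedError

    def pulse(self, duration_ms: float, t: float) -> None:  # pragma: no cover
        raise NotImplementedError


class LoggingRewardSink(RewardSink):
    """Fake sink recording activation intervals and manual pulses."""

    def __init__(self) -> None:
        self.is_active = False
        self.transitions: list[tuple[float, bool]] = []
        self.pulses: list[tuple[float, float]] = []

    def set_active(self, active: bool, t: float) -> None:
        if active != self.is_active:
            self.is_active = active
            self.transitions.append((t, active))

    def pulse(self, duration_ms: float, t: float) -> None:
        self.pulses.append((t, duration_ms))


def reward_gate(gaze: ScreenPoint | None, video: StimulusRecord | None,
                sink: RewardSink, t: float, g: ScreenGeometry) -> bool:
    """Activate the sink iff gaze is present and inside the video rectangle.

    Gaze on-screen but outside the video never activates the reward.
    """
    active = (gaze is not None and video is not None
              and video.contains(gaze, g))
    sink.set_active(active, t)
    return active


@dataclass
class NHPConfig:
    """Tunable parameters of the automated nonhuman-primate procedure.

    All values are defaults and can be overridden.  Durations in ms,
    sizes in pixels, positions in normalized screen coordinates.
    """

    attention_duration_ms: float = 30_000.0
    shrink_duration_ms: float = 10_000.0
    video_cal_size_px: tuple[float, float] = VIDEO_CAL_SIZE_PX
    cal_points: tuple[ScreenPoint, ...] = DEFAULT_NHP_CAL_POINTS
    dwell_distance_frac: float = DWELL_DISTANCE_FRAC
    dwell_duration_ms: float = DWELL_DURATION_MS
    val_rows: int = 2
    val_cols: int = 4
    smoothing_window_ms: float = 200.0
    blink_grace_samples: int = 1
    max_retries: int | None = None
    manual_reward_pulse_ms: float = 200.0
    attention_media: str = "attention_video"
    cal_media: str = "cal_video"

    def __post_init__(self) -> None:
        if self.dwell_duration_ms <= 0:
            raise ValueError("dwell_duration_ms must be positive")
        if len(self.cal_points) < 1:
            raise ValueError("at least one calibration location is required")

    def val_points(self) -> tuple[ScreenPoint, ...]:
        return validation_grid(self.val_rows, self.val_cols)


@dataclass
class _Dwell:
    """Continuous-dwell timer with a short grace for absent gaze."""

    onset_t: float | None = None
    invalid_run: int = 0

    def reset(self) -> None:
        self.onset_t = None
        self.invalid_run = 0


class NHPController(CalibrationController):
    """Three-phase automated calibration/validation procedure.

    The session driving this controller must use ``cal_points`` as its
    calibration layout and the validation grid as its validation layout
    (ids 1..n in order); :func:`build_nhp_session` in the simulator module
    wires this up.
    """

    def __init__(self, config: NHPConfig, geometry: ScreenGeometry,
                 reward: RewardSink | None = None) -> None:
        self.cfg = config
        self.g = geometry
        self.reward = reward
        self.phase = "attention"
        self.watched_ms = 0.0
        self.shrink_progress_ms = 0.0
        self.video_size: tuple[float, float] = (geometry.width_px, geometry.height_px)
        self.video_center = ScreenPoint(0.5, 0.5)
        self.cal_index = 0
        self.val_index = 0
        self.retry_count = 0
        self.calibrated = False
        self.dwell = _Dwell()
        self.last_dwell_elapsed_ms: float | None = None
        self._announced: int | None = None
        self._awaiting_collection = False
        self._awaiting_calibration = False
        self._pending: list[str] = []
        self.trace: list[tuple[float, str, dict]] = []
        self._last_t = 0.0

    # -- helpers -----------------------------------------------------------

    def _note(self, t: float, what: str, **info) -> None:
        self.trace.append((t, what, info))

    def _enter_phase(self, t: float, phase: str) -> None:
        self.phase = phase
        self.dwell.reset()
        self._announced = None
        self._note(t, "phase", phase=phase)

    def _video_rect(self) -> StimulusRecord | None:
        if self.phase == "done":
            return None
        media = (self.cfg.attention_media if self.phase == "attention"
                 else self.cfg.cal_media)
        return StimulusRecord(media_id=media, center=self.video_center,
                              size_px=self.video_size)

    def _dist_px(self, a: ScreenPoint, b: ScreenPoint) -> float:
        dx = (a.x - b.x) * self.g.width_px
        dy = (a.y - b.y) * self.g.height_px
        return math.hypot(dx, dy)

    def _dwell_step(self, t: float, gaze: ScreenPoint | None,
                    qualifying: bool) -> bool:
        """Advance the dwell timer; True when the trigger criterion is met.

        The timer resets on a non-qualifying gaze position; up to
        ``blink_grace_samples`` consecutive ticks without any gaze are
        tolerated (the timer holds but does not advance through them).
        """
        if gaze is None:
            self.dwell.invalid_run += 1
            if self.dwell.invalid_run > self.cfg.blink_grace_samples:
                self.dwell.reset()
            return False
        self.dwell.invalid_run = 0
        if not qualifying:
            self.dwell.onset_t = None
            return False
        if self.dwell.onset_t is None:
            self.dwell.onset_t = t
            self._note(t, "dwell_onset", phase=self.phase)
        elapsed = t - self.dwell.onset_t
        if elapsed >= self.cfg.dwell_duration_ms:
            self.last_dwell_elapsed_ms = elapsed
            self._note(t, "dwell_trigger", elapsed_ms=elapsed, phase=self.phase)
            self.dwell.reset()
            return True
        return False

    # -- contract ----------------------------------------------------------

    def tick(self, session: Session) -> list[Command]:
        t = session.now
        dt = session.tick_dt
        self._last_t = t
        fg = session.buffer.filtered(self.cfg.smoothing_window_ms)
        gaze = fg.pos
        video = self._video_rect()
        if self.reward is not None:
            reward_gate(gaze, video, self.reward, t, self.g)

        cmds: list[Command] = []
        # Flush state changes queued by events received last tick.
        while self._pending:
            action = self._pending.pop(0)
            if action == "compute":
                self._awaiting_calibration = True
                cmds.append(Command("compute_calibration"))
            elif action == "discard_all":
                cmds.append(Command("discard_all"))
            elif action == "auto_off":
                cmds.append(Command("set_auto", on=False))
            elif action == "switch_val":
                cmds.append(Command("switch_mode", mode=VAL))
            elif action == "finish":
                cmds.append(Command("finish"))

        if not session.auto_active or self.phase == "done":
            return cmds

        if self.phase == "attention":
            self._tick_attention(t, dt, gaze)
        elif self.phase == "calibration":
            cmds.extend(self._tick_calibration(t, gaze))
        elif self.phase == "validation":
            cmds.extend(self._tick_validation(t, gaze))
        return cmds

    def _tick_attention(self, t: float, dt: float, gaze: ScreenPoint | None) -> None:
        full = (self.g.width_px, self.g.height_px)
        cal = self.cfg.video_cal_size_px
        if self.watched_ms < self.cfg.attention_duration_ms:
            if gaze is not None and gaze.on_screen():
                self.watched_ms += dt
            return
        # Shrink linearly over shrink_duration of watched time, pausing
        # whenever the video is not being watched.
        rect = self._video_rect()
        if gaze is not None and rect is not None and rect.contains(gaze, self.g):
            self.shrink_progress_ms += dt
        frac = min(1.0, self.shrink_progress_ms / self.cfg.shrink_duration_ms)
        self.video_size = (full[0] + (cal[0] - full[0]) * frac,
                           full[1] + (cal[1] - full[1]) * frac)
        if frac >= 1.0:
            self.video_size = cal
            self.cal_index = 0
            self._enter_phase(t, "calibration")

    def _tick_calibration(self, t: float, gaze: ScreenPoint | None) -> list[Command]:
        cmds: list[Command] = []
        if (self._awaiting_collection or self._awaiting_calibration
                or self.calibrated or self.cal_index >= len(self.cfg.cal_points)):
            return cmds
        pid = self.cal_index + 1
        self.video_center = self.cfg.cal_points[self.cal_index]
        self.video_size = self.cfg.video_cal_size_px
        if self._announced != pid:
            cmds.append(Command("enqueue_point", point_id=pid))
            self._announced = pid
        threshold = self.cfg.dwell_distance_frac * self.g.height_px
        qualifying = (gaze is not None
                      and self._dist_px(gaze, self.video_center) < threshold)
        if self._dwell_step(t, gaze, qualifying):
            cmds.append(Command("start_collection", point_id=pid))
            self._awaiting_collection = True
        return cmds

    def _tick_validation(self, t: float, gaze: ScreenPoint | None) -> list[Command]:
        cmds: list[Command] = []
        if self._awaiting_collection:
            return cmds
        points = self.cfg.val_points()
        pid = self.val_index + 1
        self.video_center = points[self.val_index]
        self.video_size = self.cfg.video_cal_size_px
        if self._announced != pid:
            cmds.append(Command("enqueue_point", point_id=pid))
            self._announced = pid
        rect = self._video_rect()
        qualifying = gaze is not None and rect.contains(gaze, self.g)
        if self._dwell_step(t, gaze, qualifying):
            cmds.append(Command("start_collection", point_id=pid))
            self._awaiting_collection = True
        return cmds

    def receive_update(self, event: Event) -> None:
        kind = event.kind
        if kind == "collection_succeeded":
            if not self._awaiting_collection:
                return
            self._awaiting_collection = False
            self.dwell.reset()
            self._announced = None
            if self.phase == "calibration":
                self.cal_index += 1
                if self.cal_index >= len(self.cfg.cal_points):
                    self._pending.append("compute")
            elif self.phase == "validation":
                self.val_index += 1
                if self.val_index >= len(self.cfg.val_points()):
                    self._enter_phase(event.t, "done")
                    self._pending.extend(["auto_off", "finish"])
        elif kind == "collection_failed":
            if self._awaiting_collection:
                self._awaiting_collection = False
                self.dwell.reset()
        elif kind == "calibration_computed":
            if self._awaiting_calibration:
                self._awaiting_calibration = False
                self.calibrated = True
                self._note(event.t, "calibration_success")
                self._pending.append("auto_off")
        elif kind == "calibration_failed":
            if self._awaiting_calibration:
                self._awaiting_calibration = False
                self.retry_count += 1
                self._note(event.t, "calibration_failed", retry=self.retry_count)
                if (self.cfg.max_retries is not None
                        and self.retry_count > self.cfg.max_retries):
                    self._enter_phase(event.t, "done")
                    self._pending.extend(["auto_off", "finish"])
                else:
                    self.cal_index = 0
                    self._announced = None
                    self.dwell.reset()
                    self._pending.append("discard_all")
        elif kind == "auto_toggled":
            if (event.payload.get("on") and self.phase == "calibration"
                    and self.calibrated):
                # Operator confirmed the calibration: proceed to validation.
                self.val_index = 0
                self._enter_phase(event.t, "validation")
                self._pending.append("switch_val")
        elif kind == "phase_skip_requested":
            if self.phase == "attention":
                self.watched_ms = self.cfg.attention_duration_ms
                self.shrink_progress_ms = self.cfg.shrink_duration_ms
                self.video_size = self.cfg.video_cal_size_px
                self.cal_index = 0
                self._enter_phase(event.t, "calibration")
        elif kind == "manual_reward":
            if self.reward is not None:
                self.reward.pulse(self.cfg.manual_reward_pulse_ms, event.t)

    def get_status_text(self) -> str | None:
        if self.phase == "attention":
            return f"attention: watched {self.watched_ms / 1000:.1f} s"
        if self.phase == "calibration":
            return (f"calibration: point {min(self.cal_index + 1, len(self.cfg.cal_points))}"
                    f"/{len(self.cfg.cal_points)}, attempt {self.retry_count + 1}")
        if self.phase == "validation":
            n = len(self.cfg.val_points())
            return f"validation: point {min(self.val_index + 1, n)}/{n}"
        return "done"

    def draw(self) -> list[StimulusRecord]:
        rect = self._video_rect()
        return [rect] if rect is not None else []


# ---------------------------------------------------------------------------
# Gaze-contingent adult demo controller


@dataclass
class AdultDemoConfig:
    """Parameters of the three-stage gaze-contingent demo.

    Targets sit on a circle around the screen center; each later-stage
    target owns an annular-sector AOI spanning the angular third that
    contains it, with inner/outer radii at configurable multiples of the
    target eccentricity.  AOIs are closed regions (boundaries included).
    """

    eccentricity_frac: float = 0.35       # of screen height, in px
    stage2_angles_deg: tuple[float, ...] = (90.0, 210.0, 330.0)
    stage3_angles_deg: tuple[float, ...] = (30.0, 150.0, 270.0)
    aoi_inner_frac: float = 0.5           # × eccentricity
    aoi_outer_frac: float = 1.5
    aoi_halfwidth_deg: float = 60.0
    center_radius_frac: float = 0.15      # stage-1 proximity, of screen height
    target_media: str = "cal_target"


def _ring_angle_deg(dx_px: float, dy_px: float) -> float:
    """Placement angle: 0° rightward, counterclockwise, y up on screen."""
    return math.degrees(math.atan2(-dy_px, dx_px)) % 360.0


class AdultDemoController(CalibrationController):
    """Three-stage gaze-contingent calibration for instructable adults.

    Stage 1 collects and calibrates a single center point as soon as gaze
    comes close enough to it; stages 2 and 3 each show three points at
    once and trigger collection for whichever point's arc AOI the
    (smoothed) gaze falls inside, recalibrating at the end of each stage.
    """

    def __init__(self, config: AdultDemoConfig, geometry: ScreenGeometry,
                 smoothing_window_ms: float = 200.0) -> None:
        self.cfg = config
        self.g = geometry
        self.smoothing_window_ms = smoothing_window_ms
        self.stage = 1
        self.collected: set[int] = set()
        self._awaiting_collection: int | None = None
        self._awaiting_calibration = False
        self._pending: list[str] = []
        self.calibrations_computed = 0
        self.trace: list[tuple[float, str, dict]] = []

        ecc_px = config.eccentricity_frac * geometry.height_px
        cx, cy = 0.5 * geometry.width_px, 0.5 * geometry.height_px

        def at_angle(a_deg: float) -> ScreenPoint:
            a = math.radians(a_deg)
            return ScreenPoint((cx + ecc_px * math.cos(a)) / geometry.width_px,
                               (cy - ecc_px * math.sin(a)) / geometry.height_px)

        self.points: dict[int, ScreenPoint] = {1: ScreenPoint(0.5, 0.5)}
        self.angles: dict[int, float] = {}
        pid = 2
        for a in config.stage2_angles_deg + config.stage3_angles_deg:
            self.points[pid] = at_angle(a)
            self.angles[pid] = a % 360.0
            pid += 1
        self.stage_ids = {1: [1],
                          2: list(range(2, 2 + len(config.stage2_angles_deg))),
                          3: list(range(2 + len(config.stage2_angles_deg), pid))}
        self.ecc_px = ecc_px

    def layout(self) -> tuple[ScreenPoint, ...]:
        """Calibration layout to configure on the driving session."""
        return tuple(self.points[i] for i in sorted(self.points))

    def in_aoi(self, gaze: ScreenPoint, pid: int) -> bool:
        """Closed annular-sector membership for a later-stage target."""
        dx = (gaze.x - 0.5) * self.g.width_px
        dy = (gaze.y - 0.5) * self.g.height_px
        r = math.hypot(dx, dy)
        if not (self.cfg.aoi_inner_frac * self.ecc_px <= r
                <= self.cfg.aoi_outer_frac * self.ecc_px):
            return False
        a = _ring_angle_deg(dx, dy)
        diff = abs((a - self.angles[pid] + 180.0) % 360.0 - 180.0)
        return diff <= self.cfg.aoi_halfwidth_deg

    def tick(self, session: Session) -> list[Command]:
        cmds: list[Command] = []
        while self._pending:
            action = self._pending.pop(0)
            if action == "compute":
                self._awaiting_calibration = True
                cmds.append(Command("compute_calibration"))
            elif action == "auto_off":
                cmds.append(Command("set_auto", on=False))
            elif action == "finish":
                cmds.append(Command("finish"))
            elif action == "discard_all":
                cmds.append(Command("discard_all"))
        if not session.auto_active or self.stage == 0:
            return cmds
        if self._awaiting_collection is not None or self._awaiting_calibration:
            return cmds
        gaze = session.buffer.filtered(self.smoothing_window_ms).pos
        if gaze is None:
            return cmds
        if self.stage == 1:
            radius = self.cfg.center_radius_frac * self.g.height_px
            dx = (gaze.x - 0.5) * self.g.width_px
            dy = (gaze.y - 0.5) * self.g.height_px
            if math.hypot(dx, dy) <= radius:
                cmds.append(Command("start_collection", point_id=1))
                self._awaiting_collection = 1
        else:
            for pid in self.stage_ids[self.stage]:
                if pid in self.collected:
                    continue
                if self.in_aoi(gaze, pid):
                    cmds.append(Command("start_collection", point_id=pid))
                    self._awaiting_collection = pid
                    break
        return cmds

    def receive_update(self, event: Event) -> None:
        kind = event.kind
        if kind == "collection_succeeded":
            pid = event.payload.get("point")
            if pid == self._awaiting_collection:
                self._awaiting_collection = None
                self.collected.add(pid)
                if all(i in self.collected for i in self.stage_ids[self.stage]):
                    self._pending.append("compute")
        elif kind == "collection_failed":
            if event.payload.get("point") == self._awaiting_collection:
                self._awaiting_collection = None
        elif kind == "calibration_computed":
            if self._awaiting_calibration:
                self._awaiting_calibration = False
                self.calibrations_computed += 1
                self.trace.append((event.t, "stage_calibrated",
                                   {"stage": self.stage}))
                if self.stage >= 3:
                    self.stage = 0  # done
                    self._pending.extend(["auto_off", "finish"])
                else:
                    self.stage += 1
        elif kind == "calibration_failed":
            if self._awaiting_calibration:
                self._awaiting_calibration = False
                self.collected.clear()
                self.stage = 1
                self._pending.append("discard_all")

    def get_status_text(self) -> str | None:
        if self.stage == 0:
            return "auto calibration finished"
        return (f"stage {self.stage}: collected "
                f"{len(self.collected & set(self.stage_ids[self.stage]))}"
                f"/{len(self.stage_ids[self.stage])}")

    def draw(self) -> list[StimulusRecord]:
        if self.stage == 0:
            return []
        size = (60.0, 60.0)
        out = []
        for pid in self.stage_ids[self.stage]:
            if pid not in self.collected:
                out.append(StimulusRecord(media_id=self.cfg.target_media,
                                          center=self.points[pid],
                                          size_px=size))
        return out
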