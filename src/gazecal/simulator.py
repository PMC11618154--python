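"""Synthetic participant and gaze-stream generator.

Replaces the eye tracker and the participant with a generative model so
the whole calibration/validation procedure runs end-to-end with known
ground truth.  The participant orients to the currently shown stimulus
after a lognormal latency, fixates its center with isotropic Gaussian
noise in angular space (projected to the screen through the viewing
geometry), blinks and lapses attention as Poisson processes, and the
"tracker" reports a per-eye *raw* gaze obtained by applying a
ground-truth distortion to the true gaze.  Calibration must recover the
inverse of that distortion.

All stochastic processes draw from a single seeded generator in a fixed
per-tick order, so identical seed and configuration give bitwise
identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import EyeMapping
from .controllers import NHPConfig, NHPController, RewardSink
from .gaze_stream import EyeSample, GazeSample, INVALID_EYE
from .geometry import (
    ScreenGeometry,
    ScreenPoint,
    UCSPoint,
    angular_to_screen,
    screen_to_angular,
)
from .quality import SessionReport
from .session import (
    CalibrationController,
    Command,
    Event,
    Session,
    SessionLog,
    StimulusRecord,
    run_loop,
)

#: Half the interocular distance assumed for reported 3-D eye origins, mm.
_EYE_HALF_SEPARATION_MM = 32.0


@dataclass(frozen=True)
class ParticipantModel:
    """Ground-truth generative model of one simulated participant.

    Defaults describe a moderately compliant primate-like participant:
    a quarter-second median orienting latency, half a degree of fixation
    noise, ~10 blinks per minute of ~150 ms, and occasional attention
    lapses off-screen.  The per-eye distortion is the tracker's
    uncalibrated raw error; identity means an already-accurate tracker.
    """

    orienting_latency_median_ms: float = 250.0
    orienting_latency_sigma: float = 0.4        # lognormal shape (log-space SD)
    fixation_noise_sigma_deg: float = 0.5       # per axis, per eye
    drift_rate_deg_s: float = 0.0
    blink_rate_per_min: float = 10.0
    blink_duration_median_ms: float = 150.0
    blink_duration_sigma: float = 0.3
    lapse_rate_per_min: float = 2.0
    lapse_duration_median_ms: float = 1500.0
    lapse_duration_sigma: float = 0.5
    distortion: dict[str, EyeMapping] = field(
        default_factory=lambda: {"left": EyeMapping.identity(),
                                 "right": EyeMapping.identity()})
    interocular_offset_deg: float = 0.0
    sampling_rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixation_noise_sigma_deg < 0:
            raise ValueError("fixation_noise_sigma_deg must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


def similarity_distortion(offset_deg: tuple[float, float] = (0.0, 0.0),
                          rotation_deg: float = 0.0, scale: float = 1.0,
                          g: ScreenGeometry | None = None) -> EyeMapping:
    """Build a ground-truth raw-gaze distortion within the similarity family.

    ``offset_deg`` is a constant angular offset converted to normalized
    screen units at the screen center through the viewing geometry.
    """
    if g is None:
        raise ValueError("geometry required to convert degrees to screen units")
    center = ScreenPoint(0.5, 0.5)
    shifted = angular_to_screen(
        (offset_deg[0], offset_deg[1]), g)
    dx, dy = shifted.x - center.x, shifted.y - center.y
    th = math.radians(rotation_deg)
    a = scale * math.cos(th)
    b = scale * math.sin(th)
    # rotate/scale about the screen center, then translate
    bx = dx + 0.5 - (a * 0.5 - b * 0.5)
    by = dy + 0.5 - (b * 0.5 + a * 0.5)
    return EyeMapping("similarity", ((a, -b), (b, a)), (bx, by))


class GazeSimulator:
    """Stateful raw-gaze generator reacting to a live stimulus schedule."""

    def __init__(self, model: ParticipantModel, geometry: ScreenGeometry,
                 rng: np.random.Generator | None = None) -> None:
        self.model = model
        self.g = geometry
        self.rng = rng if rng is not None else np.random.default_rng(model.seed)
        self.dt = 1000.0 / model.sampling_rate_hz
        self._attended: ScreenPoint = ScreenPoint(0.5, 0.5)
        self._pending: tuple[ScreenPoint, float] | None = None
        self._fixation_start = 0.0
        self._drift_dir = (0.0, 0.0)
        self._blink_until = -1.0
        self._next_blink = self._draw_interval(model.blink_rate_per_min, 0.0)
        self._lapse_until = -1.0
        self._next_lapse = self._draw_interval(model.lapse_rate_per_min, 0.0)
        self._lapse_target = ScreenPoint(1.3, 0.6)

    def _draw_interval(self, rate_per_min: float, t: float) -> float:
        if rate_per_min <= 0:
            return math.inf
        return t + self.rng.exponential(60_000.0 / rate_per_min)

    def _lognormal_ms(self, median: float, sigma: float) -> float:
        if median <= 0:
            return 0.0
        return float(median * math.exp(self.rng.normal(0.0, sigma)))

    def _retarget(self, t: float, target: ScreenPoint) -> None:
        latency = self._lognormal_ms(self.model.orienting_latency_median_ms,
                                     self.model.orienting_latency_sigma)
        self._pending = (target, t + latency)

    def sample(self, t: float, stimuli: list[StimulusRecord]) -> GazeSample:
        m = self.model
        # 1) stimulus-following with orienting latency
        if stimuli:
            target = stimuli[0].center
            current = self._pending[0] if self._pending else self._attended
            if (abs(target.x - current.x) > 1e-9
                    or abs(target.y - current.y) > 1e-9):
                self._retarget(t, target)
        if self._pending is not None and t >= self._pending[1]:
            self._attended = self._pending[0]
            self._pending = None
            self._fixation_start = t
            if m.drift_rate_deg_s > 0:
                a = self.rng.uniform(0.0, 2.0 * math.pi)
                self._drift_dir = (math.cos(a), math.sin(a))

        # 2) blink / lapse processes
        if t >= self._next_blink:
            self._blink_until = t + self._lognormal_ms(
                m.blink_duration_median_ms, m.blink_duration_sigma)
            self._next_blink = self._draw_interval(m.blink_rate_per_min,
                                                   self._blink_until)
        if t >= self._next_lapse:
            self._lapse_until = t + self._lognormal_ms(
                m.lapse_duration_median_ms, m.lapse_duration_sigma)
            self._next_lapse = self._draw_interval(m.lapse_rate_per_min,
                                                   self._lapse_until)
        blinking = t < self._blink_until
        lapsing = t < self._lapse_until

        # 3) true gaze in angular coordinates
        true_pos = self._lapse_target if lapsing else self._attended
        tax, tay = screen_to_angular(true_pos, self.g)
        if m.drift_rate_deg_s > 0 and not lapsing:
            amt = m.drift_rate_deg_s * (t - self._fixation_start) / 1000.0
            tax += amt * self._drift_dir[0]
            tay += amt * self._drift_dir[1]

        # 4) per-eye measurement: interocular offset, noise, distortion
        noise = self.rng.normal(0.0, m.fixation_noise_sigma_deg, 4)
        eyes = {}
        for i, (eye, sign) in enumerate((("left", -1.0), ("right", 1.0))):
            if blinking:
                eyes[eye] = INVALID_EYE
                continue
            ax = tax + sign * m.interocular_offset_deg / 2.0 + noise[2 * i]
            ay = tay + noise[2 * i + 1]
            eye_true = angular_to_screen((ax, ay), self.g)
            raw = m.distortion[eye].apply(eye_true)
            origin = UCSPoint(sign * _EYE_HALF_SEPARATION_MM, 0.0,
                              self.g.viewing_distance_mm)
            eyes[eye] = EyeSample(screen_pos=raw, valid=True, origin=origin,
                                  pupil_diameter_mm=4.0, openness=1.0)
        return GazeSample(t=t, left=eyes["left"], right=eyes["right"])

    def __call__(self, t: float, stimuli: list[StimulusRecord]) -> GazeSample:
        return self.sample(t, stimuli)


def generate_stream(model: ParticipantModel, schedule: list[tuple[float, ScreenPoint]],
                    geometry: ScreenGeometry, duration_ms: float,
                    rng: np.random.Generator | None = None) -> list[GazeSample]:
    """Open-loop stream generation against a fixed stimulus schedule.

    ``schedule`` holds ``(t_start_ms, stimulus center)`` entries in time
    order; the stimulus active at each tick is the last one whose start
    time has passed.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    sim = GazeSimulator(model, geometry, rng=rng)
    samples = []
    n = int(round(duration_ms / sim.dt))
    for k in range(n):
        t = k * sim.dt
        center = schedule[0][1]
        for t0, c in schedule:
            if t >= t0:
                center = c
        rect = StimulusRecord(media_id="stimulus", center=center,
                              size_px=(300.0, 300.0))
        samples.append(sim.sample(t, [rect]))
    return samples


class AutoConfirmOperator(CalibrationController):
    """Controller wrapper standing in for the human operator.

    Enables auto mode at session start (optionally first skipping the
    attention phase with the documented "x" shortcut) and, when the inner
    NHP controller has switched itself off after a successful calibration,
    re-enables auto mode after a configurable inspection delay — the
    operator confirming the calibration to start validation.
    """

    def __init__(self, inner: CalibrationController,
                 skip_attention: bool = False,
                 confirm_delay_ms: float = 500.0) -> None:
        self.inner = inner
        self.skip_attention = skip_attention
        self.confirm_delay_ms = confirm_delay_ms
        self._started = False
        self._confirm_at: float | None = None

    def tick(self, session: Session) -> list[Command]:
        cmds: list[Command] = []
        if not self._started:
            self._started = True
            cmds.append(Command("set_auto", on=True))
            if self.skip_attention:
                cmds.append(Command("skip_phase"))
        if (self._confirm_at is not None and session.now >= self._confirm_at
                and not session.auto_active):
            self._confirm_at = None
            cmds.append(Command("set_auto", on=True))
        cmds.extend(self.inner.tick(session))
        return cmds

    def receive_update(self, event: Event) -> None:
        self.inner.receive_update(event)
        if (event.kind == "auto_toggled" and not event.payload.get("on")
                and getattr(self.inner, "phase", None) == "calibration"
                and getattr(self.inner, "calibrated", False)):
            self._confirm_at = event.t + self.confirm_delay_ms

    def get_status_text(self) -> str | None:
        return self.inner.get_status_text()

    def draw(self) -> list[StimulusRecord]:
        return self.inner.draw()


def build_nhp_session(geometry: ScreenGeometry, config: NHPConfig,
                      **session_kwargs) -> Session:
    """Session whose target layouts match the NHP controller's points."""
    return Session(geometry,
                   cal_layout=config.cal_points,
                   val_layout=config.val_points(),
                   **session_kwargs)


@dataclass
class ClosedLoopResult:
    """Artifacts of one simulated end-to-end session."""

    session: Session
    log: SessionLog
    report: SessionReport | None
    report_raw: SessionReport | None
    controller: CalibrationController


def closed_loop(model: ParticipantModel, geometry: ScreenGeometry,
                controller: CalibrationController | None = None,
                session: Session | None = None, *,
                nhp_config: NHPConfig | None = None,
                reward: RewardSink | None = None,
                skip_attention: bool = False,
                max_ticks: int = 20_000,
                record_gaze: bool = True,
                metadata: dict | None = None) -> ClosedLoopResult:
    """Run a full simulated session and return all artifacts.

    With no controller given, the NHP procedure is run under an
    auto-confirming operator.  The returned report is the validation
    quality of the calibrated signal; ``report_raw`` is the same windows
    evaluated on the uncalibrated raw signal (what the default identity
    calibration would have achieved).
    """
    if controller is None:
        nhp_config = nhp_config or NHPConfig()
        inner = NHPController(nhp_config, geometry, reward=reward)
        controller = AutoConfirmOperator(inner, skip_attention=skip_attention)
        if session is None:
            session = build_nhp_session(
                geometry, nhp_config, rate_hz=model.sampling_rate_hz,
                metadata=metadata)
    if session is None:
        session = Session(geometry, rate_hz=model.sampling_rate_hz,
                          metadata=metadata)
    sim = GazeSimulator(model, geometry)
    log = run_loop(session, controller, sim, max_ticks=max_ticks,
                   record_gaze=record_gaze)
    report = session.validation_report() if session.val_data else None
    report_raw = session.validation_report(use_raw=True) if session.val_data else None
    return ClosedLoopResult(session=session, log=log, report=report,
                            report_raw=report_raw, controller=controller)
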