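"""Session configuration: a validated TOML file covering every tunable.

The configuration is a single human-editable TOML document with blocks
for the screen geometry, the session parameters, the controller, the
simulated participant, and session metadata.  Unknown keys are rejected
and validation errors carry the full field path.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .calibration import EyeMapping
from .controllers import AdultDemoConfig, NHPConfig
from .geometry import ScreenGeometry, ScreenPoint
from .session import DEFAULT_CAL_LAYOUT, DEFAULT_VAL_LAYOUT, Session
from .simulator import ParticipantModel


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScreenBlock(_Block):
    width_px: float = 1920.0
    height_px: float = 1080.0
    width_mm: float = 509.8
    height_mm: float = 286.8
    viewing_distance_mm: float = 600.0


class SessionBlock(_Block):
    min_samples_per_point: int = 10
    collection_window_ms: float = 600.0
    smoothing_window_ms: float = 200.0
    history_window_ms: float = 500.0
    residual_bound: float = 0.25
    trimmed_refit: bool = False
    accuracy_statistic: Literal["mean", "median"] = "mean"
    cal_layout: list[tuple[float, float]] | None = None
    val_layout: list[tuple[float, float]] | None = None


class NHPBlock(_Block):
    attention_duration_ms: float = 30_000.0
    shrink_duration_ms: float = 10_000.0
    video_cal_size_px: tuple[float, float] = (300.0, 300.0)
    cal_points: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.3, 0.5), (0.7, 0.5)])
    dwell_distance_frac: float = 1.0 / 3.0
    dwell_duration_ms: float = 500.0
    val_rows: int = 2
    val_cols: int = 4
    smoothing_window_ms: float = 200.0
    blink_grace_samples: int = 1
    max_retries: int | None = None
    manual_reward_pulse_ms: float = 200.0


class AdultBlock(_Block):
    eccentricity_frac: float = 0.35
    stage2_angles_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)
    stage3_angles_deg: tuple[float, float, float] = (30.0, 150.0, 270.0)
    aoi_inner_frac: float = 0.5
    aoi_outer_frac: float = 1.5
    aoi_halfwidth_deg: float = 60.0
    center_radius_frac: float = 0.15


class ControllerBlock(_Block):
    kind: Literal["nhp", "adult", "none"] = "nhp"
    skip_attention: bool = False
    confirm_delay_ms: float = 500.0
    nhp: NHPBlock = Field(default_factory=NHPBlock)
    adult: AdultBlock = Field(default_factory=AdultBlock)


class DistortionBlock(_Block):
    family: str = "identity"
    a: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    b: tuple[float, float] = (0.0, 0.0)


class ParticipantBlock(_Block):
    orienting_latency_median_ms: float = 250.0
    orienting_latency_sigma: float = 0.4
    fixation_noise_sigma_deg: float = 0.5
    drift_rate_deg_s: float = 0.0
    blink_rate_per_min: float = 10.0
    blink_duration_median_ms: float = 150.0
    blink_duration_sigma: float = 0.3
    lapse_rate_per_min: float = 2.0
    lapse_duration_median_ms: float = 1500.0
    lapse_duration_sigma: float = 0.5
    interocular_offset_deg: float = 0.0
    sampling_rate_hz: float = 60.0
    distortion: dict[str, DistortionBlock] = Field(default_factory=dict)


class SessionConfig(_Block):
    """Root of a session configuration document."""

    seed: int = 0
    max_ticks: int = 20_000
    screen: ScreenBlock = Field(default_factory=ScreenBlock)
    session: SessionBlock = Field(default_factory=SessionBlock)
    controller: ControllerBlock = Field(default_factory=ControllerBlock)
    participant: ParticipantBlock = Field(default_factory=ParticipantBlock)
    metadata: dict[str, str] = Field(default_factory=dict)


def load_config(path: str | Path) -> SessionConfig:
    """Parse and validate a TOML session configuration file."""
    text = Path(path).read_text()
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: TOML syntax error: {exc}") from exc
    try:
        return SessionConfig.model_validate(data)
    except ValidationError as exc:
        lines = [f"{path}: invalid configuration:"]
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"  {loc}: {err['msg']}")
        raise ConfigError("\n".join(lines)) from exc


# -- object builders --------------------------------------------------------

def build_geometry(cfg: SessionConfig) -> ScreenGeometry:
    s = cfg.screen
    return ScreenGeometry(width_px=s.width_px, height_px=s.height_px,
                          width_mm=s.width_mm, height_mm=s.height_mm,
                          viewing_distance_mm=s.viewing_distance_mm)


def build_nhp_config(cfg: SessionConfig) -> NHPConfig:
    n = cfg.controller.nhp
    return NHPConfig(
        attention_duration_ms=n.attention_duration_ms,
        shrink_duration_ms=n.shrink_duration_ms,
        video_cal_size_px=tuple(n.video_cal_size_px),
        cal_points=tuple(ScreenPoint(*p) for p in n.cal_points),
        dwell_distance_frac=n.dwell_distance_frac,
        dwell_duration_ms=n.dwell_duration_ms,
        val_rows=n.val_rows, val_cols=n.val_cols,
        smoothing_window_ms=n.smoothing_window_ms,
        blink_grace_samples=n.blink_grace_samples,
        max_retries=n.max_retries,
        manual_reward_pulse_ms=n.manual_reward_pulse_ms)


def build_adult_config(cfg: SessionConfig) -> AdultDemoConfig:
    a = cfg.controller.adult
    return AdultDemoConfig(
        eccentricity_frac=a.eccentricity_frac,
        stage2_angles_deg=tuple(a.stage2_angles_deg),
        stage3_angles_deg=tuple(a.stage3_angles_deg),
        aoi_inner_frac=a.aoi_inner_frac, aoi_outer_frac=a.aoi_outer_frac,
        aoi_halfwidth_deg=a.aoi_halfwidth_deg,
        center_radius_frac=a.center_radius_frac)


def build_participant(cfg: SessionConfig, seed: int | None = None) -> ParticipantModel:
    p = cfg.participant
    distortion = {"left": EyeMapping.identity(), "right": EyeMapping.identity()}
    for eye, d in p.distortion.items():
        if eye not in ("left", "right"):
            raise ConfigError(f"participant.distortion: unknown eye {eye!r}")
        distortion[eye] = EyeMapping(d.family, (tuple(d.a[0]), tuple(d.a[1])),
                                     tuple(d.b))
    return ParticipantModel(
        orienting_latency_median_ms=p.orienting_latency_median_ms,
        orienting_latency_sigma=p.orienting_latency_sigma,
        fixation_noise_sigma_deg=p.fixation_noise_sigma_deg,
        drift_rate_deg_s=p.drift_rate_deg_s,
        blink_rate_per_min=p.blink_rate_per_min,
        blink_duration_median_ms=p.blink_duration_median_ms,
        blink_duration_sigma=p.blink_duration_sigma,
        lapse_rate_per_min=p.lapse_rate_per_min,
        lapse_duration_median_ms=p.lapse_duration_median_ms,
        lapse_duration_sigma=p.lapse_duration_sigma,
        distortion=distortion,
        interocular_offset_deg=p.interocular_offset_deg,
        sampling_rate_hz=p.sampling_rate_hz,
        seed=cfg.seed if seed is None else seed)


def build_session(cfg: SessionConfig, geometry: ScreenGeometry) -> Session:
    s = cfg.session
    if cfg.controller.kind == "nhp":
        nhp = build_nhp_config(cfg)
        cal_layout = nhp.cal_points
        val_layout = nhp.val_points()
    else:
        cal_layout = (tuple(ScreenPoint(*p) for p in s.cal_layout)
                      if s.cal_layout else DEFAULT_CAL_LAYOUT)
        val_layout = (tuple(ScreenPoint(*p) for p in s.val_layout)
                      if s.val_layout else DEFAULT_VAL_LAYOUT)
    if cfg.controller.kind == "adult":
        from .controllers import AdultDemoController
        ctl = AdultDemoController(build_adult_config(cfg), geometry)
        cal_layout = ctl.layout()
    return Session(geometry, cal_layout=cal_layout, val_layout=val_layout,
                   rate_hz=cfg.participant.sampling_rate_hz,
                   min_samples_per_point=s.min_samples_per_point,
                   collection_window_ms=s.collection_window_ms,
                   smoothing_window_ms=s.smoothing_window_ms,
                   history_window_ms=s.history_window_ms,
                   residual_bound=s.residual_bound,
                   trimmed_refit=s.trimmed_refit,
                   accuracy_statistic=s.accuracy_statistic,
                   metadata=dict(cfg.metadata))


EXAMPLE_CONFIG = """\
# Example session configuration: a simulated nonhuman-primate calibration
# session run entirely against the built-in gaze simulator.

seed = 1
max_ticks = 20000

[screen]
width_px = 1920.0
height_px = 1080.0
width_mm = 509.8
height_mm = 286.8
viewing_distance_mm = 600.0

[session]
min_samples_per_point = 10
collection_window_ms = 600.0   # per-target data-collection window
smoothing_window_ms = 200.0    # controller-internal temporal averaging
history_window_ms = 500.0      # operator gaze-history display window

[controller]
kind = "nhp"
skip_attention = false
confirm_delay_ms = 500.0

[controller.nhp]
attention_duration_ms = 30000.0  # ~half a minute of attracted attention
shrink_duration_ms = 10000.0
video_cal_size_px = [300.0, 300.0]      # calibration-video size
cal_points = [[0.3, 0.5], [0.7, 0.5]]   # two calibration locations
dwell_distance_frac = 0.33333333333333333  # one third of vertical screen size
dwell_duration_ms = 500.0               # minimum continuous dwell
val_rows = 2                            # validation grid: 2 rows x 4 columns
val_cols = 4

[participant]
orienting_latency_median_ms = 250.0
fixation_noise_sigma_deg = 0.5
blink_rate_per_min = 10.0
lapse_rate_per_min = 2.0
sampling_rate_hz = 60.0

# Ground-truth raw-gaze distortion the calibration must recover.
[participant.distortion.left]
family = "translation"
a = [[1.0, 0.0], [0.0, 1.0]]
b = [0.03, 0.02]

[participant.distortion.right]
family = "translation"
a = [[1.0, 0.0], [0.0, 1.0]]
b = [0.03, 0.02]

[metadata]
participant = "sim01"
group = "simulated"
"""
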