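"""Data-quality metrics for validation data.

Implements the four standard gaze data-quality measures computed per
validation point and per eye channel:

* **accuracy** — mean angular offset between recorded gaze and the target,
  in degrees of visual angle;
* **RMS-S2S precision** — root mean square of the angular distances between
  consecutive valid samples (pairs spanning an invalid gap are excluded);
* **STD precision** — root of the summed per-axis variances of the gaze
  angles about their centroid (RMS deviation from the mean position);
* **data loss** — percentage of expected samples missing or invalid.

Metrics are computed for the left eye, the right eye, and the "average"
channel, i.e. the per-sample binocular-average position signal.  Session
reports aggregate per-point values by unweighted mean over the points for
which data is available, and multi-session tables summarize per-participant
medians with min–max ranges and per-group means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_stream import GazeSample, binocular_average
from .geometry import ScreenGeometry, ScreenPoint, UCSPoint, angular_offset, screen_to_angular

CHANNELS = ("left", "right", "average")
EYES = ("left", "right")

#: Default length of a validation-point collection window, ms.
COLLECTION_WINDOW_MS = 600.0


def accuracy(positions: Sequence[ScreenPoint], target: ScreenPoint,
             g: ScreenGeometry, eye: UCSPoint | None = None,
             statistic: str = "mean") -> float | None:
    """Mean angular offset of the valid gaze positions from the target.

    ``statistic`` may be ``"median"`` for a per-point median offset
    instead of the default mean.
    """
    offsets = [angular_offset(p, target, g, eye) for p in positions if p is not None]
    if not offsets:
        return None
    if statistic == "mean":
        return float(np.mean(offsets))
    if statistic == "median":
        return float(np.median(offsets))
    raise ValueError(f"unknown statistic {statistic!r}")


def rms_s2s(positions: Sequence[ScreenPoint | None], g: ScreenGeometry,
            eye: UCSPoint | None = None) -> float | None:
    """RMS of the sample-to-sample angular distance.

    ``positions`` is the time-ordered per-channel position sequence with
    ``None`` marking invalid samples; only pairs of consecutive valid
    samples contribute, so invalid gaps do not manufacture artificial
    jumps.  Absent when fewer than two valid samples (or no adjacent valid
    pair) exist.
    """
    sq = []
    for a, b in zip(positions, positions[1:]):
        if a is not None and b is not None:
            d = angular_offset(a, b, g, eye)
            sq.append(d * d)
    if not sq:
        return None
    return float(math.sqrt(np.mean(sq)))


def std_precision(positions: Sequence[ScreenPoint | None], g: ScreenGeometry,
                  eye: UCSPoint | None = None) -> float | None:
    """Dispersion of gaze about its centroid, in degrees.

    Computed as the root of the sum of the per-axis population variances of
    the gaze angles — the RMS deviation from the mean position.
    """
    angles = [screen_to_angular(p, g, eye) for p in positions if p is not None]
    if len(angles) < 2:
        return None
    arr = np.asarray(angles)
    return float(math.sqrt(arr[:, 0].var() + arr[:, 1].var()))


def data_loss(n_valid: int, duration_ms: float, rate_hz: float | None,
              n_received: int | None = None) -> tuple[float, bool]:
    """Percentage of expected samples missing or flagged invalid.

    The expected count is ``round(duration · rate)``; when the nominal
    sampling rate is unknown the number of received samples is used as the
    denominator instead and the returned flag is set.  Clamped to
    ``[0, 100]``.
    """
    if rate_hz is not None:
        if duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        n_expected = round(duration_ms / 1000.0 * rate_hz)
        fallback = False
    else:
        if n_received is None:
            raise ValueError("n_received required when rate_hz is unknown")
        n_expected = n_received
        fallback = True
    if n_expected <= 0:
        return 0.0, fallback
    pct = 100.0 * (1.0 - n_valid / n_expected)
    return float(min(100.0, max(0.0, pct))), fallback


def channel_positions(samples: Sequence[GazeSample], channel: str) -> list[ScreenPoint | None]:
    """Time-ordered positions of one channel, ``None`` where invalid."""
    out: list[ScreenPoint | None] = []
    for s in samples:
        if channel == "average":
            out.append(binocular_average(s))
        else:
            e = s.eye(channel)
            out.append(e.screen_pos if e.valid else None)
    return out


@dataclass(frozen=True)
class ChannelQuality:
    accuracy_deg: float | None
    rms_s2s_deg: float | None
    std_deg: float | None
    n_valid: int


@dataclass(frozen=True)
class PointQuality:
    """Quality of the gaze data collected for one validation target."""

    target: ScreenPoint
    n_samples: int
    channels: Mapping[str, ChannelQuality]
    data_loss_pct: Mapping[str, float]
    data_loss_flagged: bool = False

    @property
    def has_data(self) -> bool:
        return any(c.n_valid > 0 for c in self.channels.values())

    def to_dict(self) -> dict:
        return {
            "target": [self.target.x, self.target.y],
            "n_samples": self.n_samples,
            "channels": {
                ch: {"accuracy_deg": c.accuracy_deg, "rms_s2s_deg": c.rms_s2s_deg,
                     "std_deg": c.std_deg, "n_valid": c.n_valid}
                for ch, c in self.channels.items()
            },
            "data_loss_pct": dict(self.data_loss_pct),
            "data_loss_flagged": self.data_loss_flagged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PointQuality":
        return cls(
            target=ScreenPoint(*d["target"]),
            n_samples=d["n_samples"],
            channels={ch: ChannelQuality(**c) for ch, c in d["channels"].items()},
            data_loss_pct=d["data_loss_pct"],
            data_loss_flagged=d.get("data_loss_flagged", False),
        )


def compute_point_quality(samples: Sequence[GazeSample], target: ScreenPoint,
                          g: ScreenGeometry, duration_ms: float,
                          rate_hz: float | None,
                          eye_pos: UCSPoint | None = None,
                          accuracy_statistic: str = "mean") -> PointQuality:
    """All quality metrics for one validation point's collection window."""
    channels = {}
    for ch in CHANNELS:
        pos = channel_positions(samples, ch)
        valid = [p for p in pos if p is not None]
        channels[ch] = ChannelQuality(
            accuracy_deg=accuracy(valid, target, g, eye_pos, accuracy_statistic),
            rms_s2s_deg=rms_s2s(pos, g, eye_pos),
            std_deg=std_precision(pos, g, eye_pos),
            n_valid=len(valid),
        )
    loss = {}
    flagged = False
    for eye in EYES:
        n_valid = sum(1 for s in samples if s.eye(eye).valid)
        pct, fb = data_loss(n_valid, duration_ms, rate_hz, n_received=len(samples))
        loss[eye] = pct
        flagged = flagged or fb
    return PointQuality(target=target, n_samples=len(samples), channels=channels,
                       data_loss_pct=loss, data_loss_flagged=flagged)


@dataclass
class SessionReport:
    """Per-point validation quality plus aggregates for one session.

    The aggregate of each metric is the unweighted mean over the
    validation points for which that metric is available.
    """

    points: list[PointQuality]
    metadata: dict = field(default_factory=dict)

    def aggregate(self) -> dict:
        agg: dict = {"channels": {}, "data_loss_pct": {}}
        for ch in CHANNELS:
            vals: dict[str, list[float]] = {"accuracy_deg": [], "rms_s2s_deg": [], "std_deg": []}
            for p in self.points:
                c = p.channels.get(ch)
                if c is None:
                    continue
                for m in vals:
                    v = getattr(c, m)
                    if v is not None:
                        vals[m].append(v)
            agg["channels"][ch] = {m: (float(np.mean(v)) if v else None)
                                   for m, v in vals.items()}
        for eye in EYES:
            v = [p.data_loss_pct[eye] for p in self.points if eye in p.data_loss_pct]
            agg["data_loss_pct"][eye] = float(np.mean(v)) if v else None
        return agg

    def to_dict(self) -> dict:
        return {"metadata": self.metadata,
                "points": [p.to_dict() for p in self.points],
                "aggregate": self.aggregate()}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionReport":
        return cls(points=[PointQuality.from_dict(p) for p in d["points"]],
                   metadata=d.get("metadata", {}))

    @classmethod
    def from_json(cls, s: str) -> "SessionReport":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Multi-session summaries (per-participant medians, group means)

SUMMARY_METRICS = ("accuracy_left", "accuracy_right", "accuracy_average",
                   "data_loss_left", "data_loss_right")


def report_summary_row(report: SessionReport) -> dict:
    """Flatten a session report's aggregate into one summary-table row."""
    agg = report.aggregate()
    row = dict(report.metadata)
    for ch in CHANNELS:
        row[f"accuracy_{ch}"] = agg["channels"][ch]["accuracy_deg"]
    for eye in EYES:
        row[f"data_loss_{eye}"] = agg["data_loss_pct"][eye]
    return row


def summarize_sessions(sessions: pd.DataFrame,
                       metrics: Sequence[str] = SUMMARY_METRICS,
                       participant_col: str = "participant",
                       group_col: str = "group") -> tuple[pd.DataFrame, pd.Series]:
    """Session-level summary: per-participant medians, per-group means.

    ``sessions`` has one row per session with participant/group labels and
    metric columns.  Returns a per-participant table holding, for each
    metric, the median over that participant's sessions together with the
    min–max range, and a per-group series holding the unweighted mean over
    participants of the median binocular-average accuracy.
    """
    if sessions.empty:
        raise ValueError("no sessions to summarize")
    for col in (participant_col, group_col):
        if col not in sessions.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for (grp, pid), sub in sessions.groupby([group_col, participant_col], sort=False):
        row: dict = {group_col: grp, participant_col: pid, "n_sessions": len(sub)}
        for m in metrics:
            if m not in sub.columns:
                continue
            vals = sub[m].dropna()
            if vals.empty:
                row[f"{m}_median"] = np.nan
                continue
            row[f"{m}_median"] = float(vals.median())
            row[f"{m}_min"] = float(vals.min())
            row[f"{m}_max"] = float(vals.max())
        rows.append(row)
    table = pd.DataFrame(rows)
    group_means = table.groupby(group_col, sort=False)["accuracy_average_median"].mean()
    return table, group_means


def format_summary_table(table: pd.DataFrame, group_means: pd.Series,
                         participant_col: str = "participant",
                         group_col: str = "group") -> str:
    """Human-readable summary: per-participant ``median (min–max)`` rows
    grouped with a trailing per-group mean line."""

    def fmt(row, m):
        med = row.get(f"{m}_median")
        if med is None or (isinstance(med, float) and math.isnan(med)):
            return "-"
        lo, hi = row.get(f"{m}_min"), row.get(f"{m}_max")
        if lo is None or hi is None or row["n_sessions"] <= 1:
            return f"{med:.2f}"
        return f"{med:.2f} ({lo:.1f}-{hi:.1f})"

    lines = ["participant\tacc_left\tacc_right\tacc_average\tloss_left\tloss_right"]
    for grp, sub in table.groupby(group_col, sort=False):
        lines.append(f"# {grp}")
        for _, row in sub.iterrows():
            cells = [str(row[participant_col])]
            cells += [fmt(row, m) for m in SUMMARY_METRICS]
            lines.append("\t".join(cells))
        lines.append(f"# {grp} mean accuracy (average eye): {group_means[grp]:.2f}")
    return "\n".join(lines) + "\n"
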