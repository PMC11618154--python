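"""Binocular gaze-sample data model, temporal filtering, and log I/O.

A gaze stream is a time-ordered sequence of :class:`GazeSample` objects,
one per tracker tick, each holding a left- and a right-eye measurement
with a validity flag.  Consumers must ignore the position of an invalid
eye sample.  Controllers smooth the stream with a trailing moving-average
filter before using it for dwell detection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .geometry import ScreenPoint, UCSPoint

#: Default length of the on-screen gaze-history window shown to the
#: operator, in milliseconds.
GAZE_HISTORY_WINDOW_MS = 500.0

#: Default length of the controller-internal smoothing window, in
#: milliseconds.  Short enough for responsive dwell detection at 60–600 Hz.
SMOOTHING_WINDOW_MS = 200.0


@dataclass(frozen=True, slots=True)
class EyeSample:
    """One eye's measurement at one tick.

    ``screen_pos`` must be ignored whenever ``valid`` is false.  ``origin``
    is the 3-D eye position in the user coordinate system when the tracker
    provides it.
    """

    screen_pos: ScreenPoint | None
    valid: bool
    origin: UCSPoint | None = None
    pupil_diameter_mm: float | None = None
    openness: float | None = None

    def __post_init__(self) -> None:
        if self.openness is not None and not (0.0 <= self.openness <= 1.0):
            raise ValueError("openness must lie in [0, 1]")


INVALID_EYE = EyeSample(screen_pos=None, valid=False)


@dataclass(frozen=True, slots=True)
class GazeSample:
    """One timestamped binocular measurement; ``t`` in stream milliseconds."""

    t: float
    left: EyeSample
    right: EyeSample

    def eye(self, which: str) -> EyeSample:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError(f"unknown eye {which!r}")


@dataclass(frozen=True)
class FilteredGaze:
    """Output of the moving-average filter.

    ``pos`` is the binocular position (mean of the available per-eye
    means); absent when no eye had a valid sample in the window.
    ``n_valid`` counts samples that contributed at least one valid eye.
    """

    pos: ScreenPoint | None
    left: ScreenPoint | None
    right: ScreenPoint | None
    n_valid: int


def binocular_average(s: GazeSample) -> ScreenPoint | None:
    """Gaze position averaged over the left and right eyes.

    Falls back to the single valid eye when the other is invalid, so
    unilateral data loss does not stall gaze-contingent procedures;
    absent when neither eye is valid.
    """
    lv, rv = s.left.valid, s.right.valid
    if lv and rv:
        return ScreenPoint((s.left.screen_pos.x + s.right.screen_pos.x) / 2.0,
                           (s.left.screen_pos.y + s.right.screen_pos.y) / 2.0)
    if lv:
        return s.left.screen_pos
    if rv:
        return s.right.screen_pos
    return None


def _eye_mean(samples: Sequence[GazeSample], which: str) -> tuple[ScreenPoint | None, int]:
    sx = sy = 0.0
    n = 0
    for s in samples:
        e = s.left if which == "left" else s.right
        if e.valid:
            sx += e.screen_pos.x
            sy += e.screen_pos.y
            n += 1
    if n == 0:
        return None, 0
    return ScreenPoint(sx / n, sy / n), n


def moving_average_filter(samples: Sequence[GazeSample], window_ms: float,
                          now: float | None = None) -> FilteredGaze:
    """Trailing moving-average over valid samples in the last ``window_ms``.

    Per-eye means are computed over the valid samples whose timestamp lies
    within the window ending at ``now`` (default: the last sample's
    timestamp); the binocular position is the mean of the available
    per-eye means.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if not samples:
        return FilteredGaze(pos=None, left=None, right=None, n_valid=0)
    if now is None:
        now = samples[-1].t
    cutoff = now - window_ms
    recent = [s for s in samples if s.t > cutoff]
    left, _ = _eye_mean(recent, "left")
    right, _ = _eye_mean(recent, "right")
    n_valid = sum(1 for s in recent if s.left.valid or s.right.valid)
    if left is not None and right is not None:
        pos = ScreenPoint((left.x + right.x) / 2.0, (left.y + right.y) / 2.0)
    else:
        pos = left if left is not None else right
    return FilteredGaze(pos=pos, left=left, right=right, n_valid=n_valid)


def gaze_history(samples: Sequence[GazeSample], window_ms: float = GAZE_HISTORY_WINDOW_MS,
                 now: float | None = None) -> dict[str, list[tuple[float, ScreenPoint]]]:
    """Valid per-eye samples within the trailing window, ordered by time.

    This backs the operator-screen display of recent gaze positions
    (default window 500 ms).
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    out: dict[str, list[tuple[float, ScreenPoint]]] = {"left": [], "right": []}
    if not samples:
        return out
    if now is None:
        now = samples[-1].t
    cutoff = now - window_ms
    for s in samples:
        if s.t <= cutoff:
            continue
        if s.left.valid:
            out["left"].append((s.t, s.left.screen_pos))
        if s.right.valid:
            out["right"].append((s.t, s.right.screen_pos))
    return out


class GazeBuffer:
    """Bounded buffer of recent gaze samples with filter/history views.

    Timestamps must be strictly increasing; the buffer retains at least
    ``keep_ms`` of history.
    """

    def __init__(self, keep_ms: float = 2000.0) -> None:
        self.keep_ms = keep_ms
        self._samples: deque[GazeSample] = deque()

    def append(self, sample: GazeSample) -> None:
        if self._samples and sample.t <= self._samples[-1].t:
            raise ValueError("gaze timestamps must be strictly increasing")
        self._samples.append(sample)
        cutoff = sample.t - self.keep_ms
        while self._samples and self._samples[0].t <= cutoff:
            self._samples.popleft()

    def __len__(self) -> int:
        return len(self._samples)

    @property
    def last(self) -> GazeSample | None:
        return self._samples[-1] if self._samples else None

    def filtered(self, window_ms: float = SMOOTHING_WINDOW_MS,
                 now: float | None = None) -> FilteredGaze:
        return moving_average_filter(tuple(self._samples), window_ms, now=now)

    def history(self, window_ms: float = GAZE_HISTORY_WINDOW_MS):
        return gaze_history(tuple(self._samples), window_ms)


# ---------------------------------------------------------------------------
# Gaze log I/O: delimited text, one row per sample, header mandatory.

_CORE_COLS = ["t_ms", "left_x", "left_y", "left_valid",
              "right_x", "right_y", "right_valid"]
_OPT_COLS = ["left_origin_x", "left_origin_y", "left_origin_z",
             "right_origin_x", "right_origin_y", "right_origin_z",
             "left_pupil_mm", "right_pupil_mm",
             "left_openness", "right_openness"]


def _eye_to_row(e: EyeSample, side: str, row: dict) -> None:
    row[f"{side}_x"] = e.screen_pos.x if e.valid else float("nan")
    row[f"{side}_y"] = e.screen_pos.y if e.valid else float("nan")
    row[f"{side}_valid"] = int(e.valid)
    if e.origin is not None:
        row[f"{side}_origin_x"] = e.origin.x
        row[f"{side}_origin_y"] = e.origin.y
        row[f"{side}_origin_z"] = e.origin.z
    if e.pupil_diameter_mm is not None:
        row[f"{side}_pupil_mm"] = e.pupil_diameter_mm
    if e.openness is not None:
        row[f"{side}_openness"] = e.openness


def write_gaze_log(samples: Iterable[GazeSample], path) -> None:
    rows = []
    for s in samples:
        row: dict = {"t_ms": s.t}
        _eye_to_row(s.left, "left", row)
        _eye_to_row(s.right, "right", row)
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in _CORE_COLS + _OPT_COLS if c in df.columns]
    df = df.reindex(columns=cols) if rows else pd.DataFrame(columns=_CORE_COLS)
    df.to_csv(path, index=False)


def _row_to_eye(row, side: str) -> EyeSample:
    valid = bool(int(row[f"{side}_valid"]))
    pos = ScreenPoint(float(row[f"{side}_x"]), float(row[f"{side}_y"])) if valid else None
    origin = None
    ox = row.get(f"{side}_origin_x")
    if ox is not None and ox == ox:  # not NaN
        origin = UCSPoint(float(ox), float(row[f"{side}_origin_y"]),
                          float(row[f"{side}_origin_z"]))
    pupil = row.get(f"{side}_pupil_mm")
    pupil = float(pupil) if pupil is not None and pupil == pupil else None
    openness = row.get(f"{side}_openness")
    openness = float(openness) if openness is not None and openness == openness else None
    return EyeSample(screen_pos=pos, valid=valid, origin=origin,
                     pupil_diameter_mm=pupil, openness=openness)


def read_gaze_log(path) -> list[GazeSample]:
    df = pd.read_csv(path)
    missing = [c for c in _CORE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze log is missing required columns: {missing}")
    samples = []
    for row in df.to_dict("records"):
        samples.append(GazeSample(t=float(row["t_ms"]),
                                  left=_row_to_eye(row, "left"),
                                  right=_row_to_eye(row, "right")))
    return samples
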