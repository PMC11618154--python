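"""Per-eye raw-to-calibrated gaze mapping (tracker calibration stand-in).

A commercial tracker fits its calibration internally from samples
collected while the participant looks at known targets.  This module
provides that fit for the simulated tracker: per eye, a least-squares
mapping from raw (uncalibrated) normalized screen coordinates to true
target coordinates.  The mapping family degrades gracefully with the
number of usable calibration points, because automated procedures may
calibrate from as few as one or two locations:

* 1 usable point  → pure translation;
* 2 distinct points → similarity (translation + rotation + uniform scale);
* ≥3 non-collinear points → full affine.

Degenerate layouts (coincident or collinear raw centroids) fall back to
the next-lower family.  A point is usable for an eye when it holds at
least ``min_samples_per_point`` valid samples for that eye.  The fit is
plain least squares over all samples of the usable points; an optional
trimmed refit drops the worst 20% of residuals once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import ScreenPoint

EYES = ("left", "right")

#: Minimum valid samples for a point to be usable for an eye.
MIN_SAMPLES_PER_POINT = 10

#: Residual RMS (normalized units) above which a fit is declared failed.
RESIDUAL_SANITY_BOUND = 0.25

_COINCIDENT_EPS = 1e-9


class CalibrationError(RuntimeError):
    """Raised when applying a calibration for an uncalibrated eye."""


@dataclass(frozen=True)
class EyeMapping:
    """An affine-representable raw→calibrated mapping for one eye."""

    family: str  # identity | translation | similarity | affine
    a: tuple[tuple[float, float], tuple[float, float]]
    b: tuple[float, float]

    @classmethod
    def identity(cls) -> "EyeMapping":
        return cls("identity", ((1.0, 0.0), (0.0, 1.0)), (0.0, 0.0))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "EyeMapping":
        return cls("translation", ((1.0, 0.0), (0.0, 1.0)), (dx, dy))

    def apply(self, p: ScreenPoint) -> ScreenPoint:
        (a00, a01), (a10, a11) = self.a
        return ScreenPoint(a00 * p.x + a01 * p.y + self.b[0],
                           a10 * p.x + a11 * p.y + self.b[1])

    def to_dict(self) -> dict:
        return {"family": self.family, "a": [list(self.a[0]), list(self.a[1])],
                "b": list(self.b)}

    @classmethod
    def from_dict(cls, d: dict) -> "EyeMapping":
        return cls(d["family"], (tuple(d["a"][0]), tuple(d["a"][1])), tuple(d["b"]))


@dataclass
class PointData:
    """Raw samples collected while one calibration target was shown."""

    target: ScreenPoint
    left: list[ScreenPoint] = field(default_factory=list)
    right: list[ScreenPoint] = field(default_factory=list)

    def eye(self, which: str) -> list[ScreenPoint]:
        return self.left if which == "left" else self.right


@dataclass
class CalibrationData:
    """Per-target raw sample lists; each point id appears at most once."""

    points: dict[int, PointData] = field(default_factory=dict)

    def add_point(self, point_id: int, target: ScreenPoint) -> PointData:
        if point_id in self.points:
            raise ValueError(f"point {point_id} already present")
        pd_ = PointData(target=target)
        self.points[point_id] = pd_
        return pd_

    def discard(self, point_id: int) -> None:
        self.points.pop(point_id, None)

    def clear(self) -> None:
        self.points.clear()

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CalibrationResult:
    """Outcome of a calibration-computation request."""

    status: str  # success | failure
    eyes: str  # left | right | both
    mappings: dict[str, EyeMapping] = field(default_factory=dict)
    points_used: list[int] = field(default_factory=list)
    failure_reason: str | None = None
    notes: list[str] = field(default_factory=list)
    is_default: bool = False

    @property
    def succeeded(self) -> bool:
        return self.status == "success"

    def to_dict(self) -> dict:
        return {"status": self.status, "eyes": self.eyes,
                "mappings": {e: m.to_dict() for e, m in self.mappings.items()},
                "points_used": list(self.points_used),
                "failure_reason": self.failure_reason,
                "notes": list(self.notes), "is_default": self.is_default}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(status=d["status"], eyes=d["eyes"],
                   mappings={e: EyeMapping.from_dict(m) for e, m in d["mappings"].items()},
                   points_used=list(d["points_used"]),
                   failure_reason=d.get("failure_reason"),
                   notes=list(d.get("notes", [])),
                   is_default=d.get("is_default", False))

    @classmethod
    def from_json(cls, s: str) -> "CalibrationResult":
        return cls.from_dict(json.loads(s))


def default_calibration() -> CalibrationResult:
    """The identity calibration active before any data is collected."""
    return CalibrationResult(status="success", eyes="both",
                             mappings={e: EyeMapping.identity() for e in EYES},
                             points_used=[], is_default=True)


def _fit_translation(raw: np.ndarray, tgt: np.ndarray) -> EyeMapping:
    d = (tgt - raw).mean(axis=0)
    return EyeMapping.translation(float(d[0]), float(d[1]))


def _fit_similarity(raw: np.ndarray, tgt: np.ndarray) -> EyeMapping:
    # params (a, b, tx, ty) with matrix [[a, -b], [b, a]]
    n = raw.shape[0]
    m = np.zeros((2 * n, 4))
    m[0::2, 0] = raw[:, 0]
    m[0::2, 1] = -raw[:, 1]
    m[0::2, 2] = 1.0
    m[1::2, 0] = raw[:, 1]
    m[1::2, 1] = raw[:, 0]
    m[1::2, 3] = 1.0
    rhs = tgt.reshape(-1)
    (a, b, tx, ty), *_ = np.linalg.lstsq(m, rhs, rcond=None)
    return EyeMapping("similarity", ((float(a), float(-b)), (float(b), float(a))),
                      (float(tx), float(ty)))


def _fit_affine(raw: np.ndarray, tgt: np.ndarray) -> EyeMapping:
    m = np.column_stack([raw, np.ones(raw.shape[0])])
    coef, *_ = np.linalg.lstsq(m, tgt, rcond=None)
    a = ((float(coef[0, 0]), float(coef[1, 0])),
         (float(coef[0, 1]), float(coef[1, 1])))
    return EyeMapping("affine", a, (float(coef[2, 0]), float(coef[2, 1])))


def _collinear(centroids: np.ndarray, tol: float = 1e-6) -> bool:
    c = centroids - centroids.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(1.0, s[0])


def _fit_eye(data: CalibrationData, eye: str, min_samples: int,
             trim: bool) -> tuple[EyeMapping | None, list[int], float | None, list[str]]:
    notes: list[str] = []
    usable = [(pid, pd_) for pid, pd_ in sorted(data.points.items())
              if len(pd_.eye(eye)) >= min_samples]
    if not usable:
        return None, [], None, notes
    raw = np.array([[p.x, p.y] for _, pd_ in usable for p in pd_.eye(eye)])
    tgt = np.array([[pd_.target.x, pd_.target.y]
                    for _, pd_ in usable for _p in pd_.eye(eye)])
    centroids = np.array([np.mean([[p.x, p.y] for p in pd_.eye(eye)], axis=0)
                          for _, pd_ in usable])

    n_pts = len(usable)
    family = "translation" if n_pts == 1 else ("similarity" if n_pts == 2 else "affine")
    if family == "similarity":
        if np.linalg.norm(centroids[0] - centroids[1]) < math.sqrt(_COINCIDENT_EPS):
            notes.append(f"{eye}: coincident raw centroids, fell back to translation")
            family = "translation"
    elif family == "affine":
        if _collinear(centroids):
            notes.append(f"{eye}: collinear raw centroids, fell back to similarity")
            family = "similarity"

    def do_fit(r, t):
        if family == "translation":
            return _fit_translation(r, t)
        if family == "similarity":
            return _fit_similarity(r, t)
        return _fit_affine(r, t)

    mapping = do_fit(raw, tgt)
    pred = np.array([[*_apply_arr(mapping, r)] for r in raw])
    resid = np.linalg.norm(pred - tgt, axis=1)
    if trim and raw.shape[0] >= 5:
        keep = resid <= np.quantile(resid, 0.8)
        if keep.sum() >= max(2, int(0.5 * raw.shape[0])):
            mapping = do_fit(raw[keep], tgt[keep])
            pred = np.array([[*_apply_arr(mapping, r)] for r in raw])
            resid = np.linalg.norm(pred - tgt, axis=1)
            notes.append(f"{eye}: trimmed refit dropped {int((~keep).sum())} samples")
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return mapping, [pid for pid, _ in usable], rms, notes


def _apply_arr(m: EyeMapping, r: np.ndarray) -> tuple[float, float]:
    (a00, a01), (a10, a11) = m.a
    return (a00 * r[0] + a01 * r[1] + m.b[0], a10 * r[0] + a11 * r[1] + m.b[1])


def fit_calibration(data: CalibrationData, eyes: str = "both",
                    min_samples_per_point: int = MIN_SAMPLES_PER_POINT,
                    residual_bound: float = RESIDUAL_SANITY_BOUND,
                    trimmed_refit: bool = False) -> CalibrationResult:
    """Fit per-eye raw→calibrated mappings from collected calibration data.

    Returns a failure result (never raises) when no requested eye has a
    usable point or when the residual RMS exceeds the sanity bound.
    Deterministic given identical inputs.
    """
    if eyes not in ("left", "right", "both"):
        raise ValueError(f"eyes must be left/right/both, got {eyes!r}")
    wanted = EYES if eyes == "both" else (eyes,)
    if len(data) == 0:
        return CalibrationResult(status="failure", eyes=eyes,
                                 failure_reason="no calibration data collected")
    mappings: dict[str, EyeMapping] = {}
    used: set[int] = set()
    notes: list[str] = []
    worst_rms = 0.0
    for eye in wanted:
        mapping, pids, rms, eye_notes = _fit_eye(data, eye, min_samples_per_point,
                                                 trimmed_refit)
        notes.extend(eye_notes)
        if mapping is None:
            notes.append(f"{eye}: no usable calibration points")
            continue
        mappings[eye] = mapping
        used.update(pids)
        worst_rms = max(worst_rms, rms)
    if not mappings:
        return CalibrationResult(status="failure", eyes=eyes, notes=notes,
                                 failure_reason="no eye had a usable calibration point")
    if worst_rms > residual_bound:
        return CalibrationResult(
            status="failure", eyes=eyes, notes=notes,
            failure_reason=f"residual RMS {worst_rms:.4f} exceeds bound {residual_bound}")
    return CalibrationResult(status="success", eyes=eyes, mappings=mappings,
                             points_used=sorted(used), notes=notes)


def merge_monocular(base: CalibrationResult, update: CalibrationResult) -> CalibrationResult:
    """Overlay a monocular fit onto an existing calibration.

    Only the eye(s) calibrated by ``update`` are replaced; the other eye's
    mapping is carried over from ``base`` unchanged.
    """
    mappings = dict(base.mappings)
    mappings.update(update.mappings)
    covered = sorted(set(mappings))
    eyes = "both" if covered == ["left", "right"] else covered[0]
    return CalibrationResult(status="success", eyes=eyes, mappings=mappings,
                             points_used=sorted(set(base.points_used) | set(update.points_used)),
                             notes=base.notes + update.notes)


def apply_calibration(raw: ScreenPoint, result: CalibrationResult,
                      eye: str) -> ScreenPoint:
    """Apply the fitted mapping of one eye to a raw gaze position."""
    if not result.succeeded:
        raise CalibrationError("cannot apply a failed calibration")
    mapping = result.mappings.get(eye)
    if mapping is None:
        raise CalibrationError(f"eye {eye!r} is not calibrated")
    return mapping.apply(raw)
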