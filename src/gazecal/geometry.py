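"""Screen geometry, coordinate systems and angular computations.

Three coordinate frames are used throughout the package:

* **Normalized screen coordinates** (:class:`ScreenPoint`): dimensionless,
  origin at the top-left corner of the display, ``x`` rightward, ``y``
  downward, the visible screen spanning ``[0, 1]²``.  Points are stored
  unclamped so that off-screen gaze remains representable.
* **Screen-frame millimeters**: origin at the screen center, axes parallel
  to the normalized frame, used internally for angle computations.
* **User coordinate system** (:class:`UCSPoint`): the tracker-centered 3-D
  millimeter frame in which eye/head positions are reported, ``z`` toward
  the participant.

The screen is modeled as a planar rectangle facing the participant, its
center a configurable viewing distance in front of the nominal eye
position.  All angular quantities (accuracy, precision) are visual angles
subtended at the eye.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field


class DegenerateGeometryError(ValueError):
    """Raised when the eye lies in the screen plane and angles are undefined."""


@dataclass(frozen=True, slots=True)
class ScreenPoint:
    """A position in normalized screen coordinates (top-left origin)."""

    x: float
    y: float

    def on_screen(self) -> bool:
        return 0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0


@dataclass(frozen=True, slots=True)
class UCSPoint:
    """A 3-D position in the tracker's user coordinate system, in mm."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the display.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    width_mm, height_mm
        Physical size of the visible area in millimeters.
    viewing_distance_mm
        Nominal distance from the participant's eyes to the screen center,
        used whenever per-sample 3-D eye origins are unavailable.
    """

    width_px: float
    height_px: float
    width_mm: float
    height_mm: float
    viewing_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        aspect_px = self.width_px / self.height_px
        aspect_mm = self.width_mm / self.height_mm
        if abs(aspect_px - aspect_mm) / aspect_mm > 0.05:
            warnings.warn(
                "pixel and physical aspect ratios differ by more than 5% "
                f"({aspect_px:.3f} vs {aspect_mm:.3f}); pixels are not square",
                stacklevel=2,
            )

    @property
    def nominal_eye(self) -> UCSPoint:
        """Eye position assumed when no measured origin is available."""
        return UCSPoint(0.0, 0.0, self.viewing_distance_mm)

    @property
    def px_per_mm_x(self) -> float:
        return self.width_px / self.width_mm

    @property
    def px_per_mm_y(self) -> float:
        return self.height_px / self.height_mm


def normalized_to_px(p: ScreenPoint, g: ScreenGeometry) -> tuple[float, float]:
    """Convert normalized coordinates to pixel coordinates."""
    return (p.x * g.width_px, p.y * g.height_px)


def px_to_normalized(xy: tuple[float, float], g: ScreenGeometry) -> ScreenPoint:
    """Inverse of :func:`normalized_to_px`."""
    return ScreenPoint(xy[0] / g.width_px, xy[1] / g.height_px)


def normalized_to_mm(p: ScreenPoint, g: ScreenGeometry) -> tuple[float, float]:
    """Convert to screen-frame millimeters (origin at screen center)."""
    return ((p.x - 0.5) * g.width_mm, (p.y - 0.5) * g.height_mm)


def mm_to_normalized(xy: tuple[float, float], g: ScreenGeometry) -> ScreenPoint:
    return ScreenPoint(xy[0] / g.width_mm + 0.5, xy[1] / g.height_mm + 0.5)


def _eye_or_nominal(eye: UCSPoint | None, g: ScreenGeometry) -> UCSPoint:
    eye = eye if eye is not None else g.nominal_eye
    if eye.z == 0.0:
        raise DegenerateGeometryError("eye lies in the screen plane (z == 0)")
    return eye


def angular_offset(a: ScreenPoint, b: ScreenPoint, g: ScreenGeometry,
                   eye: UCSPoint | None = None) -> float:
    """Visual angle, in degrees, subtended at the eye by two screen points.

    The eye position is expressed in screen-frame millimeters with the
    screen at ``z = 0`` and ``z`` toward the participant; when omitted the
    nominal viewing position (screen-center normal at the configured
    viewing distance) is used.  Symmetric in ``a`` and ``b``; zero iff the
    points coincide.
    """
    eye = _eye_or_nominal(eye, g)
    ax, ay = normalized_to_mm(a, g)
    bx, by = normalized_to_mm(b, g)
    va = (ax - eye.x, ay - eye.y, -eye.z)
    vb = (bx - eye.x, by - eye.y, -eye.z)
    dot = va[0] * vb[0] + va[1] * vb[1] + va[2] * vb[2]
    cx = va[1] * vb[2] - va[2] * vb[1]
    cy = va[2] * vb[0] - va[0] * vb[2]
    cz = va[0] * vb[1] - va[1] * vb[0]
    cross = math.sqrt(cx * cx + cy * cy + cz * cz)
    return math.degrees(math.atan2(cross, dot))


def screen_to_angular(p: ScreenPoint, g: ScreenGeometry,
                      eye: UCSPoint | None = None) -> tuple[float, float]:
    """Horizontal/vertical gaze angles (degrees) of a screen point.

    This is the tangent-plane angular parameterization used for per-axis
    dispersion (STD precision) and for injecting angular noise in the
    simulator; :func:`angular_to_screen` is its exact inverse.
    """
    eye = _eye_or_nominal(eye, g)
    x_mm, y_mm = normalized_to_mm(p, g)
    return (math.degrees(math.atan2(x_mm - eye.x, eye.z)),
            math.degrees(math.atan2(y_mm - eye.y, eye.z)))


def angular_to_screen(angles: tuple[float, float], g: ScreenGeometry,
                      eye: UCSPoint | None = None) -> ScreenPoint:
    """Inverse of :func:`screen_to_angular`."""
    eye = _eye_or_nominal(eye, g)
    x_mm = eye.x + eye.z * math.tan(math.radians(angles[0]))
    y_mm = eye.y + eye.z * math.tan(math.radians(angles[1]))
    return mm_to_normalized((x_mm, y_mm), g)


@dataclass(frozen=True)
class HeadStatus:
    """Offset of the head (midpoint of valid eye origins) from a desired
    position in the user coordinate system."""

    detected: bool
    offset_mm: tuple[float, float, float] | None = None
    distance_mm: float | None = None
    single_eye: bool = False


def head_position_status(left_origin: UCSPoint | None,
                         right_origin: UCSPoint | None,
                         desired: UCSPoint) -> HeadStatus:
    """Per-axis head offset from the configured desired position.

    Uses the midpoint of the valid eye origins; flags when only one eye
    origin is available, and reports "head not detected" when neither is.
    """
    origins = [o for o in (left_origin, right_origin) if o is not None]
    if not origins:
        return HeadStatus(detected=False)
    mx = sum(o.x for o in origins) / len(origins)
    my = sum(o.y for o in origins) / len(origins)
    mz = sum(o.z for o in origins) / len(origins)
    off = (mx - desired.x, my - desired.y, mz - desired.z)
    dist = math.sqrt(off[0] ** 2 + off[1] ** 2 + off[2] ** 2)
    return HeadStatus(detected=True, offset_mm=off, distance_mm=dist,
                      single_eye=len(origins) == 1)
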