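import pytest

from gazecal.geometry import ScreenGeometry, ScreenPoint
from gazecal.gaze_stream import EyeSample, GazeSample, INVALID_EYE

DT_60HZ = 1000.0 / 60.0


@pytest.fixture
def geometry() -> ScreenGeometry:
    # 23" 16:9 desktop display at a 600 mm viewing distance
    return ScreenGeometry(width_px=1920, height_px=1080,
                          width_mm=509.8, height_mm=286.8,
                          viewing_distance_mm=600.0)


def make_sample(t: float, pos: tuple[float, float] | None,
                left_valid: bool = True, right_valid: bool = True,
                left_pos: tuple[float, float] | None = None,
                right_pos: tuple[float, float] | None = None) -> GazeSample:
    """Binocular sample with both eyes at ``pos`` unless overridden."""

    def eye(valid: bool, p) -> EyeSample:
        if not valid or p is None:
            return INVALID_EYE
        return EyeSample(screen_pos=ScreenPoint(*p), valid=True)

    return GazeSample(t=t, left=eye(left_valid, left_pos or pos),
                      right=eye(right_valid, right_pos or pos))


def constant_source(pos: tuple[float, float]):
    """Gaze source fixating one position forever."""

    def source(t, stimuli):
        return make_sample(t, pos)

    return source
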