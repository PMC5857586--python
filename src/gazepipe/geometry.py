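"""Screen and viewing geometry: visual degrees <-> screen pixels.

The stimulus screen is described by its pixel resolution, physical size and
the participant's viewing distance. Angular extents are converted to on-screen
millimetres with ``2 * D * tan(deg / 2)`` and then to pixels via the per-axis
millimetre-per-pixel density. The monitor model used in the study is known but
its physical size and the viewing distance are not published; the defaults
below (1920x1080 px, 509x286 mm, 600 mm) are documented assumptions and every
value is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class ScreenGeometry:
    screen_px: tuple[int, int] = (1920, 1080)
    screen_mm: tuple[float, float] = (509.0, 286.0)
    viewing_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        if min(self.screen_px) <= 0 or min(self.screen_mm) <= 0:
            raise ConfigError("screen dimensions must be strictly positive")
        if self.viewing_distance_mm <= 0:
            raise ConfigError("viewing distance must be strictly positive")

    @property
    def mm_per_px_x(self) -> float:
        return self.screen_mm[0] / self.screen_px[0]

    @property
    def mm_per_px_y(self) -> float:
        return self.screen_mm[1] / self.screen_px[1]

    def degrees_to_pixels_x(self, degrees: float) -> float:
        """Horizontal extent subtending ``degrees`` of visual angle, in pixels."""
        mm = 2.0 * self.viewing_distance_mm * math.tan(math.radians(degrees) / 2.0)
        return mm / self.mm_per_px_x

    def degrees_to_pixels_y(self, degrees: float) -> float:
        """Vertical extent subtending ``degrees`` of visual angle, in pixels."""
        mm = 2.0 * self.viewing_distance_mm * math.tan(math.radians(degrees) / 2.0)
        return mm / self.mm_per_px_y
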