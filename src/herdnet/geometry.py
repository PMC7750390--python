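"""Barn and functional-zone geometry.

The barn is modelled as an axis-aligned rectangle in metres containing two
functional zones: the feeding zone (feeding passage and nearest passageway)
and the non-feeding zone (cubicles and remaining passageways).  Zones are
y-bands of the barn; interaction detection filters positions into a zone
after dilating it by a buffer (default 3 m) so that minor positional error
at a zone boundary does not split genuine co-location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ZONES = ("full_barn", "feeding", "non_feeding")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [xmin, xmax] x [ymin, ymax] in metres."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"inverted rectangle bounds: {self}")

    def buffered(self, buffer_m: float) -> "Rect":
        if buffer_m < 0:
            raise ValueError("buffer must be >= 0")
        return Rect(
            self.xmin - buffer_m,
            self.xmax + buffer_m,
            self.ymin - buffer_m,
            self.ymax + buffer_m,
        )

    def contains(self, x, y) -> np.ndarray:
        """Vectorised closed-boundary membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin


def _default_barn() -> Rect:
    return Rect(-1.6, 58.6, 1.62, 17.2)


def _default_feeding() -> Rect:
    return Rect(-1.6, 58.6, 10.5, 17.2)


def _default_non_feeding() -> Rect:
    return Rect(-1.6, 58.6, 1.62, 10.5)


@dataclass(frozen=True)
class BarnGeometry:
    """Barn rectangle plus the coordinate-defined functional zones.

    Defaults reproduce a ~60 m x ~16 m free-stall barn: the feeding zone is
    the y-band 10.5--17.2 m (feed face plus nearest passageway) and the
    non-feeding zone the y-band 1.62--10.5 m over x in [-1.6, 58.6] m
    (cubicle rows and passageways).  ``zone_buffer`` is the dilation applied
    when filtering positions into a zone.
    """

    barn: Rect = field(default_factory=_default_barn)
    feeding: Rect = field(default_factory=_default_feeding)
    non_feeding: Rect = field(default_factory=_default_non_feeding)
    zone_buffer: float = 3.0

    def __post_init__(self) -> None:
        if self.zone_buffer < 0:
            raise ValueError("zone_buffer must be >= 0")
        for name in ("feeding", "non_feeding"):
            z = getattr(self, name)
            if not (
                z.xmin >= self.barn.xmin
                and z.xmax <= self.barn.xmax
                and z.ymin >= self.barn.ymin
                and z.ymax <= self.barn.ymax
            ):
                raise ValueError(f"zone {name!r} is not contained in the barn rectangle")

    def zone_region(self, zone: str, buffer_m: float | None = None) -> Rect:
        """Region used to filter positions into ``zone``.

        ``full_barn`` is the union of both zones' unbuffered extents plus the
        barn rectangle, which for y-band zones is the barn rectangle itself;
        the named zones are dilated by ``buffer_m`` (default: ``zone_buffer``).
        """
        if zone == "full_barn":
            return self.barn
        if zone not in ("feeding", "non_feeding"):
            raise ValueError(f"unknown zone {zone!r}; expected one of {ZONES}")
        b = self.zone_buffer if buffer_m is None else buffer_m
        return getattr(self, zone).buffered(b)
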