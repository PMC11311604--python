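"""Physical calibration of micrographs and the puncta size gate.

Every downstream stage works in pixels, but the biology is stated in
micrometres: autophagosomes in mammalian cells have diameters of roughly
0.5–1.5 μm.  This module converts between the two unit systems and derives,
from the diameter range and the image scale, the inclusive pixel-area window
("size gate") that a connected component must fall into to count as a
candidate autophagosome, as well as the rolling-ball radius used for
background subtraction in the puncta channel.

At the default scale of 5.62 px/μm the derived quantities are:

* radius bounds 1.405–4.215 px,
* real area bounds 6.202–55.814 px² (A = πr²),
* integer gate 6–56 px² (nearest-integer rounding),
* rolling-ball radius 4.215 px (half the maximum diameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DEFAULT_PIXELS_PER_MICRON",
    "DEFAULT_MIN_DIAMETER_UM",
    "DEFAULT_MAX_DIAMETER_UM",
    "SpatialScale",
    "SizeGate",
    "um_to_px",
    "px_to_um",
    "disc_area_px",
    "derive_size_gate",
    "rolling_ball_radius",
]

#: Default image scale: 1 μm corresponds to 5.62 pixels.
DEFAULT_PIXELS_PER_MICRON = 5.62

#: Default autophagosome diameter range in mammalian cells (μm).
DEFAULT_MIN_DIAMETER_UM = 0.5
DEFAULT_MAX_DIAMETER_UM = 1.5


@dataclass(frozen=True)
class SpatialScale:
    """Isotropic pixel size of a micrograph, in pixels per micrometre."""

    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON

    def __post_init__(self) -> None:
        if not (self.pixels_per_micron > 0 and math.isfinite(self.pixels_per_micron)):
            raise ValueError(
                f"pixels_per_micron must be a positive finite number, "
                f"got {self.pixels_per_micron!r}"
            )

    def um_to_px(self, length_um: float) -> float:
        """Convert a physical length (μm) to pixels."""
        return um_to_px(length_um, self)

    def px_to_um(self, length_px: float) -> float:
        """Convert a pixel length back to micrometres."""
        return px_to_um(length_px, self)


def um_to_px(length_um: float, scale: SpatialScale) -> float:
    """Convert a non-negative length in micrometres to pixels."""
    if length_um < 0:
        raise ValueError(f"length_um must be >= 0, got {length_um}")
    return length_um * scale.pixels_per_micron


def px_to_um(length_px: float, scale: SpatialScale) -> float:
    """Convert a non-negative length in pixels to micrometres."""
    if length_px < 0:
        raise ValueError(f"length_px must be >= 0, got {length_px}")
    return length_px / scale.pixels_per_micron


def disc_area_px(radius_px: float) -> float:
    """Area of a disc of the given pixel radius: A = πr² = πd²/4."""
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    return math.pi * radius_px**2


def _round_half_away_from_zero(x: float) -> int:
    """Nearest-integer rounding with halves going away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SizeGate:
    """Acceptance window for candidate puncta, derived from a diameter range.

    Real-valued radius/area bounds are retained for documentation and
    derived computations; the *integer* area bounds are what actually filter
    connected components (inclusive on both ends).
    """

    min_diameter_um: float
    max_diameter_um: float
    min_radius_px: float
    max_radius_px: float
    min_area_px: float
    max_area_px: float
    min_area_int: int
    max_area_int: int

    def __post_init__(self) -> None:
        pairs = [
            (self.min_diameter_um, self.max_diameter_um),
            (self.min_radius_px, self.max_radius_px),
            (self.min_area_px, self.max_area_px),
            (self.min_area_int, self.max_area_int),
        ]
        for lo, hi in pairs:
            if not lo < hi:
                raise ValueError(f"size gate bounds must satisfy min < max, got {lo} >= {hi}")

    def accepts(self, area_px: int) -> bool:
        """Whether an integer component area falls inside the gate (inclusive)."""
        return self.min_area_int <= area_px <= self.max_area_int


def derive_size_gate(
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM,
    scale: SpatialScale = SpatialScale(),
) -> SizeGate:
    """Derive the pixel-area acceptance window from a physical diameter range.

    Diameters are halved to radii, converted to pixels at ``scale``, squared
    through ``disc_area_px`` and rounded to the nearest integers (half away
    from zero).  With the defaults (0.5–1.5 μm at 5.62 px/μm) this yields
    radii 1.405–4.215 px, real areas 6.202–55.814 px² and the integer gate
    6–56 px².

    A diameter range so narrow (or a scale so coarse) that both area bounds
    round to the same integer cannot gate anything on the pixel grid and is
    rejected as a domain error.
    """
    if not (0 < min_diameter_um < max_diameter_um):
        raise ValueError(
            f"need 0 < min_diameter_um < max_diameter_um, "
            f"got ({min_diameter_um}, {max_diameter_um})"
        )
    r_min = um_to_px(min_diameter_um / 2.0, scale)
    r_max = um_to_px(max_diameter_um / 2.0, scale)
    a_min = disc_area_px(r_min)
    a_max = disc_area_px(r_max)
    return SizeGate(
        min_diameter_um=min_diameter_um,
        max_diameter_um=max_diameter_um,
        min_radius_px=r_min,
        max_radius_px=r_max,
        min_area_px=a_min,
        max_area_px=a_max,
        min_area_int=_round_half_away_from_zero(a_min),
        max_area_int=_round_half_away_from_zero(a_max),
    )


def rolling_ball_radius(
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM,
    scale: SpatialScale = SpatialScale(),
) -> float:
    """Rolling-ball radius (px) for puncta background subtraction.

    The ball radius equals the largest expected punctum *radius*, i.e. half
    the maximum diameter, so the ball cannot descend into a true punctum but
    tracks any broader structure (diffuse cytosolic staining, uneven
    illumination).  1.5 μm at 5.62 px/μm gives 4.215 px.
    """
    if not max_diameter_um > 0:
        raise ValueError(f"max_diameter_um must be > 0, got {max_diameter_um}")
    return um_to_px(max_diameter_um / 2.0, scale)
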