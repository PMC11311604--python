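"""Immunoblot densitometry: integrated optical density, internal-standard
normalization, percent of control.

Band regions outlined on a grayscale blot scan are summed as optical
density.  Film scans encode signal as darkness, so 8-bit intensities are
inverted (OD = 255 − intensity) before summation; a ``linear`` mode is
available for scans already expressed as density.  The background under a
band is estimated either with a rolling-ball opening of the OD image, from
a user-supplied background region (median OD × band area), or skipped.

Each target band is normalized to the internal standard of its lane
(GAPDH here) and expressed as a percentage of the control lane, so the
control lane itself always reads exactly 100%.  The whole chain is
invariant to uniform exposure scaling of the scan up to 8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .puncta import subtract_background

__all__ = [
    "BandROI",
    "DensitometryRecord",
    "NormalizedExpression",
    "optical_density",
    "integrated_optical_density",
    "normalize_to_standard",
    "percent_of_control",
    "quantify_blot",
]


@dataclass(frozen=True)
class BandROI:
    """Axis-aligned rectangle around one band: half-open pixel bounds
    [y0, y1) × [x0, x1) on the scan, tagged with lane and target protein."""

    lane: int
    target: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"empty ROI: {self}")

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} outside image of shape {shape}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass(frozen=True)
class DensitometryRecord:
    """One band's raw, background and background-corrected IOD (a.u.)."""

    lane: int
    target: str
    iod: float
    background_iod: float

    @property
    def corrected_iod(self) -> float:
        return max(self.iod - self.background_iod, 0.0)


@dataclass(frozen=True)
class NormalizedExpression:
    """A lane's target signal relative to its internal standard, expressed
    as percent of the control lane."""

    lane: int
    target: str
    ratio_to_standard: float
    percent_of_control: float


def optical_density(img: np.ndarray, mode: str = "inverted") -> np.ndarray:
    """Map a scan to optical density: ``inverted`` = 255 − intensity for
    8-bit film scans (darker band = more signal), ``linear`` = identity."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a grayscale scan, got shape {arr.shape}")
    if mode == "inverted":
        return 255.0 - arr
    if mode == "linear":
        return arr.copy()
    raise ValueError(f"unknown OD mode {mode!r}")


def integrated_optical_density(
    img: np.ndarray,
    roi: BandROI,
    background_mode: str | BandROI | None = "rolling_ball",
    od_mode: str = "inverted",
    rolling_ball_radius_px: float = 25.0,
) -> DensitometryRecord:
    """Integrated optical density of one band with background correction.

    ``background_mode`` is one of

    * ``"rolling_ball"`` — sum, over the band ROI, of the rolling-ball
      opening of the OD image (local background under the band);
    * a :class:`BandROI` — median OD of that background region times the
      band area;
    * ``None`` — no background subtraction.
    """
    od = optical_density(img, od_mode)
    roi.validate_bounds(od.shape)
    iod = float(od[roi.slices()].sum())

    if background_mode is None:
        background = 0.0
    elif background_mode == "rolling_ball":
        od_bg = od - subtract_background(od, rolling_ball_radius_px)
        background = float(od_bg[roi.slices()].sum())
    elif isinstance(background_mode, BandROI):
        background_mode.validate_bounds(od.shape)
        area = (roi.y1 - roi.y0) * (roi.x1 - roi.x0)
        background = float(np.median(od[background_mode.slices()])) * area
    else:
        raise ValueError(f"unknown background mode {background_mode!r}")
    return DensitometryRecord(lane=roi.lane, target=roi.target, iod=iod,
                              background_iod=background)


def normalize_to_standard(
    target: DensitometryRecord, standard: DensitometryRecord
) -> float:
    """Ratio of a target band to its lane's internal standard band."""
    if standard.corrected_iod <= 0:
        raise ValueError(
            f"internal standard of lane {standard.lane} has non-positive "
            f"corrected IOD ({standard.corrected_iod}); normalization undefined"
        )
    return target.corrected_iod / standard.corrected_iod


def percent_of_control(
    ratios: dict[int, float], control_lane: int, target: str = ""
) -> list[NormalizedExpression]:
    """Express per-lane standard-normalized ratios as percent of control."""
    if control_lane not in ratios:
        raise KeyError(f"control lane {control_lane} not among lanes {sorted(ratios)}")
    control = ratios[control_lane]
    if control <= 0:
        raise ValueError(f"control ratio must be > 0, got {control}")
    return [
        NormalizedExpression(
            lane=lane,
            target=target,
            ratio_to_standard=ratio,
            percent_of_control=100.0 * ratio / control,
        )
        for lane, ratio in sorted(ratios.items())
    ]


def quantify_blot(
    img: np.ndarray,
    rois: list[BandROI],
    target: str,
    standard: str,
    control_lane: int,
    background_mode: str | BandROI | None = "rolling_ball",
    od_mode: str = "inverted",
) -> pd.DataFrame:
    """Quantify a whole blot: per lane, normalize ``target`` to ``standard``
    and express as percent of ``control_lane``.

    Returns a tidy table ``lane, target, corrected_iod, ratio,
    percent_of_control`` sorted by lane.
    """
    by_lane: dict[int, dict[str, DensitometryRecord]] = {}
    for roi in rois:
        rec = integrated_optical_density(img, roi, background_mode, od_mode)
        by_lane.setdefault(roi.lane, {})[roi.target] = rec

    ratios: dict[int, float] = {}
    for lane, bands in sorted(by_lane.items()):
        if target not in bands or standard not in bands:
            raise ValueError(f"lane {lane} is missing a {target!r} or {standard!r} band")
        ratios[lane] = normalize_to_standard(bands[target], bands[standard])

    rows = [
        {
            "lane": e.lane,
            "target": target,
            "corrected_iod": by_lane[e.lane][target].corrected_iod,
            "ratio": e.ratio_to_standard,
            "percent_of_control": e.percent_of_control,
        }
        for e in percent_of_control(ratios, control_lane, target)
    ]
    return pd.DataFrame(rows)
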