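"""Autophagosome punctum detection in the puncta (green) channel.

The detection chain mirrors a classical spot-counting recipe for small,
diffraction-limited vesicles:

1. rolling-ball background subtraction (radius = largest expected punctum
   radius, 4.215 px at the default scale) to remove diffuse cytosolic signal
   and uneven illumination;
2. a per-image threshold (Otsu by default, or a fixed value for strict
   reproducibility) to binarize candidate signal;
3. refinement at a temporarily up-scaled resolution — fill holes, then split
   touching blobs with a distance-transform watershed — mapped back to the
   original pixel grid;
4. an inclusive connected-component area gate (6–56 px² at the default
   scale) that discards objects too small or too large to be a single
   autophagosome;
5. assignment of each surviving punctum to the segmented cell whose mask
   contains its centroid; puncta outside every cell are discarded as
   non-cytosolic signal.

Areas are always accounted in original-resolution pixels so the size gate
keeps its physical meaning regardless of the refinement up-scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .calibration import SizeGate, derive_size_gate, rolling_ball_radius

__all__ = [
    "PunctaParams",
    "PunctumRecord",
    "ball_kernel",
    "subtract_background",
    "threshold_puncta",
    "refine_binary",
    "extract_candidates",
    "assign_to_cells",
    "puncta_per_cell_table",
    "detect_puncta",
]

# Down-sample the image before the morphological opening once the ball gets
# larger than this radius; exact (full-resolution) opening below it.
_EXACT_RADIUS_LIMIT = 16.0


@dataclass(frozen=True)
class PunctaParams:
    """Tunable parameters of the punctum detector."""

    rolling_ball_radius_px: float = rolling_ball_radius()
    threshold_method: Literal["otsu"] | float = "otsu"
    upscale_factor: int = 4
    size_gate: SizeGate = field(default_factory=derive_size_gate)

    def __post_init__(self) -> None:
        if not self.rolling_ball_radius_px > 0:
            raise ValueError("rolling_ball_radius_px must be > 0")
        if not (isinstance(self.upscale_factor, int) and self.upscale_factor >= 1):
            raise ValueError("upscale_factor must be an integer >= 1")


@dataclass(frozen=True)
class PunctumRecord:
    """One accepted punctum: centroid (row, col, px), integer pixel area at
    original resolution, and the owning cell id (None until assignment)."""

    id: int
    centroid: tuple[float, float]
    area: int
    cell_id: int | None = None


def ball_kernel(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Height profile and footprint of a ball structuring element.

    Returns ``(heights, footprint)`` on a (2R+1)×(2R+1) grid, R = ceil(radius):
    heights are sqrt(r² − d²) where the footprint is True (d ≤ r), 0 elsewhere.
    """
    if not radius_px > 0:
        raise ValueError(f"radius_px must be > 0, got {radius_px}")
    r_int = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    d2 = (yy**2 + xx**2).astype(float)
    footprint = d2 <= radius_px**2
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius_px**2 - d2[footprint])
    return heights, footprint


def _rolling_ball_background(img: np.ndarray, radius_px: float) -> np.ndarray:
    """Background estimate: grayscale opening with a ball of ``radius_px``."""
    heights, footprint = ball_kernel(radius_px)
    eroded = ndi.grey_erosion(img, structure=heights, footprint=footprint, mode="nearest")
    return ndi.grey_dilation(eroded, structure=heights, footprint=footprint, mode="nearest")


def subtract_background(img: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the grayscale opening of the image with a ball
    structuring element of the given radius — the surface traced by rolling a
    ball of that radius beneath the intensity landscape.  Structures narrower
    than the ball survive subtraction; anything broader is flattened.  The
    result is ``img − background`` clipped at 0, hence pixelwise ≤ ``img``.

    For radii beyond the exact-computation limit the opening runs on a
    down-sampled copy and the background is linearly up-sampled back (and
    clipped under the image), which is the standard large-ball shortcut.

    Parameters
    ----------
    img : 2-D array, any real dtype.
    radius_px : ball radius in pixels, > 0.

    Returns
    -------
    float64 array of the same shape, non-negative if ``img`` is.
    """
    if not radius_px > 0:
        raise ValueError(f"radius_px must be > 0, got {radius_px}")
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")

    if radius_px <= _EXACT_RADIUS_LIMIT:
        background = _rolling_ball_background(arr, radius_px)
    else:
        shrink = int(np.ceil(radius_px / _EXACT_RADIUS_LIMIT))
        small = ndi.zoom(arr, 1.0 / shrink, order=1, grid_mode=True, mode="nearest")
        small_bg = _rolling_ball_background(small, radius_px / shrink)
        background = ndi.zoom(small_bg, np.array(arr.shape) / np.array(small_bg.shape),
                              order=1, grid_mode=True, mode="nearest")
        # interpolation can overshoot; the true background never exceeds the image
        background = np.minimum(background, arr)
    return np.clip(arr - background, 0.0, None)


# Puncta are sparse: if thresholding marks more than this fraction of the
# field as foreground, the threshold has fallen into the background noise.
_MAX_SPOT_FRACTION = 0.05


def threshold_puncta(
    img: np.ndarray, method: Literal["otsu"] | float = "otsu"
) -> np.ndarray:
    """Binarize a background-subtracted puncta channel.

    ``method`` is either ``"otsu"`` (per-image automatic threshold) or a
    fixed numeric threshold; pixels strictly above the threshold are
    foreground.  A constant image yields an empty mask.

    The automatic mode is a *recursive* Otsu: plain Otsu degenerates when
    the foreground occupies a tiny pixel fraction (it then splits the
    background noise instead), so whenever the thresholded fraction exceeds
    ``_MAX_SPOT_FRACTION`` the threshold is recomputed on the
    above-threshold pixels only, up to a few iterations.  On images where
    plain Otsu already separates spots from background the recursion is a
    no-op.
    """
    arr = np.asarray(img, dtype=float)
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(arr) == 0:
            return np.zeros(arr.shape, dtype=bool)
        thresh = float(threshold_otsu(arr))
        for _ in range(5):
            above = arr > thresh
            if above.mean() <= _MAX_SPOT_FRACTION:
                break
            if np.ptp(arr[above]) == 0:
                break
            thresh = float(threshold_otsu(arr[above]))
    else:
        thresh = float(method)
    return arr > thresh


def _block_mode_labels(fine: np.ndarray, factor: int) -> np.ndarray:
    """Down-sample an integer label image by per-block majority vote.

    Ties resolve to the smallest value in the block (background first), via
    an all-pairs equality count on the block-sorted values.
    """
    h, w = fine.shape
    blocks = fine.reshape(h // factor, factor, w // factor, factor).swapaxes(1, 2)
    blocks = blocks.reshape(h // factor, w // factor, factor * factor)
    if blocks.shape[2] == 1:
        return blocks[:, :, 0].copy()
    blocks = np.sort(blocks, axis=2)
    counts = (blocks[:, :, :, None] == blocks[:, :, None, :]).sum(axis=3)
    winner = np.argmax(counts, axis=2)  # first max -> smallest value wins ties
    return np.take_along_axis(blocks, winner[:, :, None], axis=2)[:, :, 0]


def _interlabel_boundary(labels: np.ndarray) -> np.ndarray:
    """Pixels adjacent (4-neighbourhood) to a *different* positive label."""
    boundary = np.zeros(labels.shape, dtype=bool)
    for axis in (0, 1):
        a = np.take(labels, range(labels.shape[axis] - 1), axis=axis)
        b = np.take(labels, range(1, labels.shape[axis]), axis=axis)
        diff = (a != b) & (a > 0) & (b > 0)
        pad_lo = [(0, 0), (0, 0)]
        pad_hi = [(0, 0), (0, 0)]
        pad_lo[axis] = (0, 1)
        pad_hi[axis] = (1, 0)
        boundary |= np.pad(diff, pad_lo)
        boundary |= np.pad(diff, pad_hi)
    return boundary


def refine_binary(
    mask: np.ndarray,
    upscale_factor: int = 4,
    min_marker_distance_px: float = 1.405,
) -> np.ndarray:
    """Fill holes and split touching blobs by distance-transform watershed.

    The mask is up-scaled by ``upscale_factor`` (exact nearest-neighbour
    replication), holes are filled, markers are placed at Euclidean
    distance-transform maxima at least ``min_marker_distance_px`` (original
    pixels) apart, and watershed basins are separated by background lines.
    The result is mapped back to the original grid by per-block majority
    vote of basin labels, with a one-pixel separating line drawn between
    distinct basins so that split blobs stay split under 8-connectivity
    labelling.  Area accounting therefore remains in original-resolution
    pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    f = int(upscale_factor)
    if f < 1:
        raise ValueError("upscale_factor must be >= 1")
    if not mask.any():
        return mask.copy()

    fine = np.kron(mask, np.ones((f, f), dtype=bool)) if f > 1 else mask.copy()
    fine = ndi.binary_fill_holes(fine)

    dist = ndi.distance_transform_edt(fine)
    min_dist = max(1, int(round(min_marker_distance_px * f)))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=fine, exclude_border=False)
    if len(peaks) == 0:
        coarse_mask = fine if f == 1 else fine.reshape(
            mask.shape[0], f, mask.shape[1], f
        ).sum(axis=(1, 3)) * 2 >= f * f
        return coarse_mask

    markers = np.zeros(fine.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    basins = watershed(-dist, markers=markers, mask=fine, connectivity=1)

    coarse = basins if f == 1 else _block_mode_labels(basins, f)
    refined = coarse > 0
    refined &= ~_interlabel_boundary(coarse)
    return refined


def extract_candidates(
    mask: np.ndarray, gate: SizeGate, connectivity: int = 2
) -> list[PunctumRecord]:
    """Label a refined binary mask and keep components inside the size gate.

    Component areas are compared against the *integer* gate bounds,
    inclusively on both ends (a 6 px² and a 56 px² object both pass the
    default gate).  Survivors are returned with centroid and area;
    ``cell_id`` is left unset.
    """
    labels = cc_label(np.asarray(mask, dtype=bool), connectivity=connectivity)
    records: list[PunctumRecord] = []
    next_id = 1
    for prop in regionprops(labels):
        if gate.accepts(int(prop.area)):
            records.append(
                PunctumRecord(
                    id=next_id,
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                    area=int(prop.area),
                )
            )
            next_id += 1
    return records


def assign_to_cells(puncta: Sequence[PunctumRecord], cells) -> list[PunctumRecord]:
    """Assign puncta to cells by centroid containment; drop orphans.

    A punctum whose (rounded) centroid pixel lies inside a cell mask receives
    that cell's id; cell masks are disjoint, so at most one cell can claim a
    punctum.  Puncta whose centroids fall outside every cell mask are
    non-cytosolic signal (artifacts, contamination) and are discarded.
    """
    cells = list(cells)
    if not cells:
        return []
    shape = cells[0].mask.shape
    owner = np.zeros(shape, dtype=np.int32)
    # paint in descending id order so the lowest cell id wins any (defensive)
    # overlap of masks
    for cell in sorted(cells, key=lambda c: -c.id):
        owner[cell.mask] = cell.id

    assigned: list[PunctumRecord] = []
    for p in puncta:
        r = int(round(p.centroid[0]))
        c = int(round(p.centroid[1]))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            continue
        cell_id = int(owner[r, c])
        if cell_id > 0:
            assigned.append(replace(p, cell_id=cell_id))
    return assigned


def puncta_per_cell_table(
    puncta: Sequence[PunctumRecord],
    cells,
    field_id: str = "",
    group: str = "",
    baf: bool = False,
) -> pd.DataFrame:
    """Per-cell punctum counts with group metadata.

    One row per segmented cell, zero counts included — the zero-inflation of
    per-cell counts is real signal for the downstream nonparametric tests.
    """
    counts: dict[int, int] = {cell.id: 0 for cell in cells}
    for p in puncta:
        if p.cell_id is None:
            raise ValueError("puncta must be assigned to cells first")
        if p.cell_id in counts:
            counts[p.cell_id] += 1
    return pd.DataFrame(
        {
            "cell_id": list(counts.keys()),
            "field_id": field_id,
            "group": group,
            "baf": baf,
            "count": list(counts.values()),
        }
    )


def detect_puncta(
    puncta_channel: np.ndarray,
    cells,
    params: PunctaParams = PunctaParams(),
) -> list[PunctumRecord]:
    """Full detection chain on one field: subtract, threshold, refine, gate,
    assign.  Returns the assigned puncta."""
    sub = subtract_background(puncta_channel, params.rolling_ball_radius_px)
    mask = threshold_puncta(sub, params.threshold_method)
    refined = refine_binary(
        mask,
        upscale_factor=params.upscale_factor,
        min_marker_distance_px=params.size_gate.min_radius_px,
    )
    candidates = extract_candidates(refined, params.size_gate)
    return assign_to_cells(candidates, cells)
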