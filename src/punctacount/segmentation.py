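"""Cell and nucleus segmentation with mutual-exclusion validation.

Microglia are identified from two channels: the nuclear stain (DAPI, blue)
and the cytoplasmic marker (Iba1, red).  Each channel is preprocessed
(median noise reduction, rolling-ball background flattening, 8-bit
rescaling), thresholded (Otsu by default) and cleaned into a label map.
Adherent objects are split with watershed lines generated from filtered
intensity peaks of the preprocessed, unthresholded nuclear channel.

A candidate cell region becomes a valid ``CellRecord`` only under the
mutual-exclusion rules:

* it must contain at least one nucleus centroid (else it is anucleate
  debris);
* its mean marker intensity must reach the adequacy threshold (else it is a
  free nucleus without genuine marker staining);
* it must exceed a minimum area.

Regions holding several nucleus centroids are first split with the nucleus
centroids as watershed markers, so every kept cell carries exactly one
nucleus.  Coordinates are 0-based (row, col), pixel-centred; objects are
8-connected and watershed lines 4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, footprint_rectangle, opening
from skimage.segmentation import watershed

from .puncta import subtract_background

__all__ = [
    "ChannelImage",
    "NucleusRecord",
    "CellRecord",
    "split_channels",
    "preprocess_channel",
    "segment_objects",
    "split_adherent",
    "extract_nuclei",
    "apply_mutual_exclusion",
    "count_cells_per_field",
]

#: Default mapping of RGB planes to biological roles.
DEFAULT_CHANNEL_ROLES = ("cell_marker", "puncta", "nuclear")


@dataclass(frozen=True)
class ChannelImage:
    """A single fluorescence channel with 8-bit semantics and a role."""

    pixels: np.ndarray
    role: str = "unknown"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"channel must be a 2-D image, got shape {self.pixels.shape}")


@dataclass(frozen=True)
class NucleusRecord:
    """A segmented nucleus: label id, centroid (row, col) and pixel area."""

    id: int
    centroid: tuple[float, float]
    area: int


@dataclass(frozen=True)
class CellRecord:
    """A validated cell: mask, its single nucleus, marker summary."""

    id: int
    mask: np.ndarray
    nucleus_id: int
    mean_marker_intensity: float
    area: int
    centroid: tuple[float, float]


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Collapse common integer dtypes to 8-bit; floats are clipped."""
    arr = np.asarray(pixels)
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)  # 65535 -> 255
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def split_channels(
    image: np.ndarray, roles: Sequence[str] = DEFAULT_CHANNEL_ROLES
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Split a three-channel image into (cell_marker, puncta, nuclear) planes.

    ``roles`` names the role of each input plane in order; the default is the
    RGB convention red = cell marker, green = puncta, blue = nuclear.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an image with exactly 3 channels, got shape {arr.shape}")
    if sorted(roles) != sorted(DEFAULT_CHANNEL_ROLES):
        raise ValueError(f"roles must be a permutation of {DEFAULT_CHANNEL_ROLES}, got {roles}")
    by_role = {
        role: ChannelImage(_to_uint8(arr[:, :, i]), role) for i, role in enumerate(roles)
    }
    return by_role["cell_marker"], by_role["puncta"], by_role["nuclear"]


def preprocess_channel(
    img: ChannelImage | np.ndarray,
    median_radius: int = 1,
    background_radius_px: float | None = None,
) -> ChannelImage:
    """Noise reduction and background flattening for one channel.

    A ``(2·median_radius+1)²`` median filter removes shot noise, a
    rolling-ball subtraction (skipped when ``background_radius_px`` is None)
    flattens slowly varying background, and the result is clipped back to
    8-bit range.  Deterministic for fixed parameters.
    """
    role = img.role if isinstance(img, ChannelImage) else "unknown"
    pixels = img.pixels if isinstance(img, ChannelImage) else np.asarray(img)
    arr = _to_uint8(pixels).astype(float)
    if median_radius > 0:
        size = 2 * median_radius + 1
        arr = ndi.median_filter(arr, size=size, mode="nearest")
    if background_radius_px is not None:
        arr = subtract_background(arr, background_radius_px)
    return ChannelImage(np.clip(np.round(arr), 0, 255).astype(np.uint8), role)


def segment_objects(
    img: ChannelImage | np.ndarray,
    min_area: int = 0,
    threshold: str | float = "otsu",
    connectivity: int = 2,
    clean: bool = True,
) -> np.ndarray:
    """Threshold a preprocessed channel and label the cleaned foreground.

    Otsu (default) or a fixed threshold binarizes the channel; a 3×3 binary
    closing then opening removes pinholes and single-pixel spurs (disabled
    with ``clean=False``); components below ``min_area`` are dropped; the
    remainder is labelled with 8-connectivity (``connectivity=2``).  A blank
    field yields an all-zero label map.
    """
    pixels = img.pixels if isinstance(img, ChannelImage) else np.asarray(img)
    arr = pixels.astype(float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(arr) == 0:
            return np.zeros(arr.shape, dtype=np.int32)
        thresh = threshold_otsu(arr)
    else:
        thresh = float(threshold)
    mask = arr > thresh
    if clean:
        foot = footprint_rectangle((3, 3))
        mask = opening(closing(mask, foot), foot)
    labels = cc_label(mask, connectivity=connectivity)
    if min_area > 0 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        keep = areas >= min_area
        keep[0] = False
        mask = keep[labels]
        labels = cc_label(mask, connectivity=connectivity)
    return labels.astype(np.int32)


def split_adherent(
    labels: np.ndarray,
    intensity: ChannelImage | np.ndarray | None = None,
    min_peak_distance_px: int = 10,
    peak_threshold_abs: float | None = None,
    smoothing_sigma: float = 2.0,
    markers: np.ndarray | None = None,
) -> np.ndarray:
    """Split adherent objects along watershed lines seeded at intensity peaks.

    Local maxima of the (Gaussian-smoothed) preprocessed, unthresholded
    intensity image are detected, filtered to those coinciding with a
    labelled object, and used as markers for a watershed of the inverted
    intensity restricted to the foreground.  Alternatively, explicit marker
    coordinates (``markers``, an (n, 2) array of (row, col)) may be supplied,
    in which case the watershed floods the Euclidean distance transform of
    the foreground instead — that is the variant used when re-splitting a
    cell region that holds several nucleus centroids.

    Every input region maps to ≥ 1 output region: regions containing no
    marker are passed through unchanged.  Background stays background and
    output labels are renumbered consecutively from 1.
    """
    labels = np.asarray(labels)
    out_mask = labels > 0
    if not out_mask.any():
        return np.zeros(labels.shape, dtype=np.int32)

    if markers is None:
        if intensity is None:
            raise ValueError("either intensity or explicit markers are required")
        pixels = intensity.pixels if isinstance(intensity, ChannelImage) else intensity
        surface = ndi.gaussian_filter(np.asarray(pixels, dtype=float), smoothing_sigma)
        coords = peak_local_max(
            surface,
            min_distance=int(min_peak_distance_px),
            threshold_abs=peak_threshold_abs,
            exclude_border=False,
        )
        # filter: keep peaks that coincide with a labelled object
        coords = np.array([c for c in coords if labels[c[0], c[1]] > 0], dtype=int)
    else:
        coords = np.asarray(markers, dtype=int)
        coords = np.array([c for c in coords if labels[c[0], c[1]] > 0], dtype=int)
        surface = None

    out = np.zeros(labels.shape, dtype=np.int32)
    next_label = 1
    if len(coords) > 0:
        marker_img = np.zeros(labels.shape, dtype=np.int32)
        marker_img[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        if surface is not None:
            flood = -surface
        else:
            flood = -ndi.distance_transform_edt(out_mask)
        basins = watershed(flood, markers=marker_img, mask=out_mask, connectivity=1)
        # split only regions that actually contain >= 1 marker
        marked_regions = np.unique(labels[tuple(coords.T)])
        for region_id in marked_regions:
            region = labels == region_id
            for b in np.unique(basins[region]):
                if b == 0:
                    continue
                out[region & (basins == b)] = next_label
                next_label += 1

    # regions without any marker pass through unchanged
    remaining = np.unique(labels[out_mask & (out == 0)])
    for region_id in remaining:
        piece = (labels == region_id) & (out == 0)
        if piece.any():
            out[piece] = next_label
            next_label += 1
    return out


def extract_nuclei(labels: np.ndarray) -> list[NucleusRecord]:
    """Summarize a nucleus label map into records (id, centroid, area)."""
    return [
        NucleusRecord(
            id=int(p.label),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            area=int(p.area),
        )
        for p in regionprops(np.asarray(labels))
    ]


def _adequacy_threshold_auto(
    candidate_means: Sequence[float], background_level: float
) -> float:
    """Otsu over candidate marker means anchored by the background level.

    The background marker level is appended to the sample of per-candidate
    means so the negative class is represented even in fields where every
    candidate is a genuine cell; Otsu then lands between background and
    cells rather than mid-way through the cells.
    """
    sample = np.asarray(list(candidate_means) + [background_level], dtype=float)
    if np.ptp(sample) == 0:
        return sample[0] - 1.0  # indistinguishable: accept everything
    return float(threshold_otsu(sample))


def apply_mutual_exclusion(
    cells: np.ndarray,
    nuclei: Sequence[NucleusRecord],
    marker: ChannelImage | np.ndarray,
    adequacy_threshold: float | None = None,
    min_cell_area: int = 0,
) -> list[CellRecord]:
    """Validate candidate cell regions against the mutual-exclusion rules.

    Anucleate regions (debris) and regions with inadequate mean marker
    intensity (bare nuclei) are discarded; regions containing several
    nucleus centroids are split with those centroids as watershed markers
    before validation.  ``adequacy_threshold=None`` selects the automatic
    background-anchored Otsu threshold over candidate means.  The output is
    always a subset of the input foreground — the rules never invent cells.
    """
    labels = np.asarray(cells).copy()
    pixels = marker.pixels if isinstance(marker, ChannelImage) else np.asarray(marker)
    pixels = pixels.astype(float)

    def nucleus_at(r: float, c: float) -> tuple[int, int]:
        return int(round(r)), int(round(c))

    # nucleus centroid -> containing region
    region_nuclei: dict[int, list[NucleusRecord]] = {}
    for nuc in sorted(nuclei, key=lambda n: n.id):
        r, c = nucleus_at(*nuc.centroid)
        if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]:
            region_id = int(labels[r, c])
            if region_id > 0:
                region_nuclei.setdefault(region_id, []).append(nuc)

    # re-split regions holding several nucleus centroids
    multi = [rid for rid, nucs in region_nuclei.items() if len(nucs) > 1]
    if multi:
        sub = np.where(np.isin(labels, multi), labels, 0)
        marker_coords = np.array(
            [nucleus_at(*n.centroid) for rid in multi for n in region_nuclei[rid]],
            dtype=int,
        )
        split = split_adherent(sub, markers=marker_coords)
        split_offset = int(labels.max())
        labels[sub > 0] = np.where(split[sub > 0] > 0, split[sub > 0] + split_offset, 0)
        # re-derive the nucleus->region map on the updated label image
        region_nuclei = {}
        for nuc in sorted(nuclei, key=lambda n: n.id):
            r, c = nucleus_at(*nuc.centroid)
            if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]:
                region_id = int(labels[r, c])
                if region_id > 0:
                    region_nuclei.setdefault(region_id, []).append(nuc)

    # candidate statistics
    candidates: list[tuple[int, np.ndarray, float, int, tuple[float, float]]] = []
    for prop in regionprops(labels):
        mask = labels == prop.label
        mean_marker = float(pixels[mask].mean())
        candidates.append(
            (int(prop.label), mask, mean_marker, int(prop.area),
             (float(prop.centroid[0]), float(prop.centroid[1])))
        )

    if adequacy_threshold is None:
        background = labels == 0
        bg_level = float(np.median(pixels[background])) if background.any() else 0.0
        adequacy_threshold = _adequacy_threshold_auto(
            [c[2] for c in candidates], bg_level
        )

    records: list[CellRecord] = []
    next_id = 1
    for region_id, mask, mean_marker, area, centroid in candidates:
        nucs = region_nuclei.get(region_id, [])
        if not nucs:
            continue  # anucleate debris
        if mean_marker < adequacy_threshold:
            continue  # nucleus without adequate marker staining
        if area < min_cell_area:
            continue
        records.append(
            CellRecord(
                id=next_id,
                mask=mask,
                nucleus_id=nucs[0].id,
                mean_marker_intensity=mean_marker,
                area=area,
                centroid=centroid,
            )
        )
        next_id += 1
    return records


def count_cells_per_field(records: Sequence[CellRecord]) -> int:
    """Number of validated cells in a field of view."""
    return len(records)
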