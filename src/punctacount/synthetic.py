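"""Synthetic three-channel micrographs with exact ground truth.

The generator emulates the imaging situation the analysis pipeline assumes:
8-bit RGB fields at 5.62 px/μm containing nucleated, marker-positive cells
(red = cytoplasmic marker, blue = nuclear stain) whose cytoplasm carries
diffuse green signal plus discrete green puncta of 0.5–1.5 μm diameter,
predominantly perinuclear.  Confounders that the segmentation must reject
are included: anucleate marker-positive debris, marker-negative free nuclei,
and adherent cell pairs that have to be split.  Eight treatment groups
(control, LPS, RST, LPS+RST, each with or without bafilomycin A1
pretreatment) differ in cells per field and mean puncta per cell through
configurable multipliers.

Rendering model: cells are star-convex blobs around a central nucleus;
puncta are hard discs (pixel centres within the radius) convolved with a
1-px Gaussian point-spread function; Gaussian read noise is added per
channel; SNR is defined as punctum peak amplitude over the noise sigma.
Every scene is bit-deterministic for a fixed seed, and the returned ground
truth lists exactly the objects that were placed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .calibration import SpatialScale

__all__ = [
    "PlacementError",
    "SceneSpec",
    "PunctumTruth",
    "CellTruth",
    "GroundTruth",
    "GroupSpec",
    "StudyConfig",
    "FieldScene",
    "default_study_config",
    "sample_puncta_counts",
    "rasterized_disc_area",
    "generate_scene",
    "generate_study",
    "truth_compare",
]


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed in the field without violating
    the separation constraints, even after bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field.

    Geometry is stated in micrometres and converted at ``scale``; intensity
    levels are 8-bit counts.  ``puncta_mean``/``puncta_dispersion``
    parameterize the negative-binomial puncta-per-cell distribution
    (variance = mean + mean²/dispersion).
    """

    shape: tuple[int, int] = (600, 600)
    scale: SpatialScale = field(default_factory=SpatialScale)
    n_cells: int = 8
    nucleus_diameter_um: tuple[float, float] = (5.5, 7.0)
    cell_radius_um: tuple[float, float] = (5.5, 8.0)
    puncta_mean: float = 8.0
    puncta_dispersion: float = 2.0
    punctum_diameter_um: tuple[float, float] = (0.5, 1.5)
    perinuclear_fraction: float = 0.8
    diffuse_cytosol_level: float = 30.0
    punctum_peak: float = 160.0
    cell_marker_level: float = 130.0
    nucleus_peak: float = 210.0
    noise_sigma: float = 8.0
    n_debris: int = 2
    n_free_nuclei: int = 2
    adherent_pair_fraction: float = 0.25
    psf_sigma_px: float = 1.0
    fixed_puncta_count: int | None = None  # overrides the count distribution
    seed: int = 0

    @property
    def snr(self) -> float:
        """Punctum peak amplitude over the noise sigma."""
        return self.punctum_peak / self.noise_sigma if self.noise_sigma > 0 else np.inf


@dataclass(frozen=True)
class PunctumTruth:
    cell_id: int
    center: tuple[float, float]
    diameter_um: float
    radius_px: float
    area_px: int  # rasterized hard-disc area at original resolution


@dataclass(frozen=True)
class CellTruth:
    id: int
    center: tuple[float, float]
    radius_px: float
    nucleus_center: tuple[float, float]
    nucleus_radius_px: float
    n_puncta: int


@dataclass
class GroundTruth:
    """Everything the generator placed, with exact per-cell puncta counts."""

    cell_labels: np.ndarray
    cells: list[CellTruth]
    puncta: list[PunctumTruth]
    debris_centers: list[tuple[float, float]]
    free_nucleus_centers: list[tuple[float, float]]
    group: str = "control"
    baf: bool = False

    def counts(self) -> dict[int, int]:
        """True punctum count per cell id (zeros included)."""
        out = {c.id: 0 for c in self.cells}
        for p in self.puncta:
            out[p.cell_id] += 1
        return out


def sample_puncta_counts(
    rng: np.random.Generator, mean: float, dispersion: float, n: int
) -> np.ndarray:
    """Negative-binomial puncta-per-cell counts (mean/dispersion form)."""
    if mean < 0 or dispersion <= 0:
        raise ValueError("need mean >= 0 and dispersion > 0")
    if mean == 0:
        return np.zeros(n, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def rasterized_disc_area(
    diameter_um: float,
    scale: SpatialScale = SpatialScale(),
    center_offset: tuple[float, float] = (0.0, 0.0),
) -> int:
    """Pixel count of a hard disc rendered at the given scale.

    A pixel belongs to the disc when its centre lies within the physical
    radius of the (sub-pixel) disc centre — the same rule the renderer uses.
    """
    r = scale.um_to_px(diameter_um / 2.0)
    r_int = int(np.ceil(r)) + 1
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    d2 = (yy - center_offset[0]) ** 2 + (xx - center_offset[1]) ** 2
    return int(np.count_nonzero(d2 <= r * r))


def _star_radius(
    theta: np.ndarray, base_radius: float, coeffs: tuple[float, float, float, float]
) -> np.ndarray:
    """Radius of a mildly lobed star-convex boundary at angles ``theta``."""
    a2, p2, a3, p3 = coeffs
    return base_radius * (1.0 + 0.10 * a2 * np.cos(2 * theta + p2)
                          + 0.08 * a3 * np.cos(3 * theta + p3))


def _paint_star(
    owner: np.ndarray,
    owner_score: np.ndarray,
    label: int,
    center: tuple[float, float],
    base_radius: float,
    coeffs: tuple[float, float, float, float],
) -> None:
    """Rasterize a star-convex blob; overlaps go to the relatively nearer
    centre (distance scaled by base radius), keeping labels disjoint."""
    h, w = owner.shape
    r_max = base_radius * 1.2
    r0 = max(0, int(np.floor(center[0] - r_max)))
    r1 = min(h, int(np.ceil(center[0] + r_max)) + 1)
    c0 = max(0, int(np.floor(center[1] - r_max)))
    c1 = min(w, int(np.ceil(center[1] + r_max)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - center[0]
    dx = xx - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    inside = dist <= _star_radius(theta, base_radius, coeffs)
    score = dist / base_radius
    window_owner = owner[r0:r1, c0:c1]
    window_score = owner_score[r0:r1, c0:c1]
    take = inside & (score < window_score)
    window_owner[take] = label
    window_score[take] = score[take]


def _add_disc(channel: np.ndarray, center: tuple[float, float], radius_px: float,
              amplitude: float) -> int:
    """Add a hard disc to a float channel; returns its rasterized area."""
    h, w = channel.shape
    r_int = int(np.ceil(radius_px)) + 1
    r0 = max(0, int(np.floor(center[0])) - r_int)
    r1 = min(h, int(np.ceil(center[0])) + r_int + 1)
    c0 = max(0, int(np.floor(center[1])) - r_int)
    c1 = min(w, int(np.ceil(center[1])) + r_int + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    channel[r0:r1, c0:c1][inside] += amplitude
    return int(np.count_nonzero(inside))


def _add_gaussian_bump(channel: np.ndarray, center: tuple[float, float],
                       sigma_px: float, peak: float) -> None:
    h, w = channel.shape
    ext = int(np.ceil(3.5 * sigma_px))
    r0 = max(0, int(np.floor(center[0])) - ext)
    r1 = min(h, int(np.ceil(center[0])) + ext + 1)
    c0 = max(0, int(np.floor(center[1])) - ext)
    c1 = min(w, int(np.ceil(center[1])) + ext + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    channel[r0:r1, c0:c1] += peak * np.exp(-d2 / (2.0 * sigma_px**2))


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: Sequence[float],
    pair_of: Sequence[int | None],
    existing: Sequence[tuple[tuple[float, float], float]] = (),
    max_tries: int = 400,
    separation_factor: float = 1.15,
    adherent_factor: float = 0.85,
) -> list[tuple[float, float]]:
    """Sequentially place disc centres with pairwise separation constraints.

    ``pair_of[i]`` names an earlier index that object i adheres to (centre
    distance ``adherent_factor``·(ri+rj), i.e. overlapping); all other pairs
    keep distance ≥ ``separation_factor``·(ri+rj).  Raises PlacementError
    when a centre cannot be found within ``max_tries`` draws.
    """
    h, w = shape
    placed: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        margin = r * 1.25 + 2
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"object radius {r:.1f} px does not fit a {h}×{w} field"
            )
        partner = pair_of[i]
        for _ in range(max_tries):
            if partner is not None:
                pc, pr = placed[partner], radii[partner]
                ang = rng.uniform(0, 2 * np.pi)
                d = adherent_factor * (r + pr)
                cand = (pc[0] + d * np.sin(ang), pc[1] + d * np.cos(ang))
                if not (margin <= cand[0] <= h - margin and margin <= cand[1] <= w - margin):
                    continue
            else:
                cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            ok = True
            for j, q in enumerate(placed):
                if j == partner or pair_of[j] == i:
                    continue
                if np.hypot(cand[0] - q[0], cand[1] - q[1]) < separation_factor * (
                    r + radii[j]
                ):
                    ok = False
                    break
            if ok:
                for q, qr in existing:
                    if np.hypot(cand[0] - q[0], cand[1] - q[1]) < separation_factor * (r + qr):
                        ok = False
                        break
            if ok:
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{len(radii)} "
                f"(radius {r:.1f} px) in a {h}×{w} field"
            )
    return placed


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one field and return (H×W×3 uint8 image, ground truth).

    Deterministic for a fixed ``spec.seed``; the truth lists exactly the
    placed objects, so per-cell counts match the rendered puncta one-to-one.
    A field too crowded for the separation constraints raises
    ``PlacementError`` after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    scale = spec.scale

    red = np.zeros((h, w), dtype=float)
    green = np.zeros((h, w), dtype=float)
    blue = np.zeros((h, w), dtype=float)

    # ---- cells ---------------------------------------------------------
    n = spec.n_cells
    cell_r = scale.um_to_px(1.0) * rng.uniform(*spec.cell_radius_um, size=n)
    nuc_r = scale.um_to_px(0.5) * rng.uniform(*spec.nucleus_diameter_um, size=n)
    nuc_r = np.minimum(nuc_r, 0.62 * cell_r)
    shapes = [
        (rng.uniform(0.4, 1.0), rng.uniform(0, 2 * np.pi),
         rng.uniform(0.4, 1.0), rng.uniform(0, 2 * np.pi))
        for _ in range(n)
    ]
    n_pairs = int(round(spec.adherent_pair_fraction * n / 2.0))
    pair_of: list[int | None] = [None] * n
    for k in range(n_pairs):
        pair_of[2 * k + 1] = 2 * k

    last_err: PlacementError | None = None
    centers: list[tuple[float, float]] | None = None
    for _restart in range(20):
        try:
            centers = _place_centers(rng, (h, w), cell_r, pair_of)
            break
        except PlacementError as err:  # reshuffle and retry from scratch
            last_err = err
    if centers is None:
        raise last_err  # type: ignore[misc]

    owner = np.zeros((h, w), dtype=np.int32)
    owner_score = np.full((h, w), np.inf)
    for i, center in enumerate(centers):
        _paint_star(owner, owner_score, i + 1, center, cell_r[i], shapes[i])

    level_jitter = rng.uniform(0.9, 1.1, size=n)
    for i in range(n):
        mask = owner == i + 1
        red[mask] += spec.cell_marker_level * level_jitter[i]
        green[mask] += spec.diffuse_cytosol_level
        _add_gaussian_bump(blue, centers[i], 0.6 * nuc_r[i], spec.nucleus_peak)

    # ---- puncta --------------------------------------------------------
    if spec.fixed_puncta_count is not None:
        counts = np.full(n, spec.fixed_puncta_count, dtype=int)
    else:
        counts = sample_puncta_counts(rng, spec.puncta_mean, spec.puncta_dispersion, n)
    puncta: list[PunctumTruth] = []
    placed_xy: list[tuple[tuple[float, float], float]] = []
    for i in range(n):
        mask = owner == i + 1
        edt = ndi.distance_transform_edt(mask)
        center, nr = centers[i], nuc_r[i]
        for _ in range(int(counts[i])):
            d_um = rng.uniform(*spec.punctum_diameter_um)
            rp = scale.um_to_px(d_um / 2.0)
            for _try in range(120):
                if rng.uniform() < spec.perinuclear_fraction:
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(nr + rp + 1.0, 2.0 * nr + rp)
                    cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
                else:
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(nr + rp + 1.0, cell_r[i])
                    cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
                ri, ci = int(round(cand[0])), int(round(cand[1]))
                if not (0 <= ri < h and 0 <= ci < w) or edt[ri, ci] < rp + 1.5:
                    continue
                if any(
                    np.hypot(cand[0] - q[0], cand[1] - q[1]) < rp + qr + 1.5
                    for q, qr in placed_xy
                ):
                    continue
                area = _add_disc(green, cand, rp, spec.punctum_peak)
                puncta.append(
                    PunctumTruth(
                        cell_id=i + 1, center=cand, diameter_um=d_um,
                        radius_px=rp, area_px=area,
                    )
                )
                placed_xy.append((cand, rp))
                break
            # an unplaceable punctum is simply not part of the truth

    cells = [
        CellTruth(
            id=i + 1,
            center=centers[i],
            radius_px=float(cell_r[i]),
            nucleus_center=centers[i],
            nucleus_radius_px=float(nuc_r[i]),
            n_puncta=sum(1 for p in puncta if p.cell_id == i + 1),
        )
        for i in range(n)
    ]

    # ---- confounders ---------------------------------------------------
    occupied = [((c.center[0], c.center[1]), c.radius_px) for c in cells]
    debris_r = scale.um_to_px(1.0) * rng.uniform(2.0, 3.5, size=spec.n_debris)
    free_r = scale.um_to_px(0.5) * rng.uniform(*spec.nucleus_diameter_um,
                                               size=spec.n_free_nuclei)
    debris_centers: list[tuple[float, float]] = []
    free_centers: list[tuple[float, float]] = []
    if spec.n_debris or spec.n_free_nuclei:
        radii = list(debris_r) + list(free_r)
        extra = _place_centers(
            rng, (h, w), radii, [None] * len(radii), existing=occupied
        )
        debris_centers = extra[: spec.n_debris]
        free_centers = extra[spec.n_debris :]
        for k, center in enumerate(debris_centers):
            coeffs = (rng.uniform(0.5, 1.0), rng.uniform(0, 2 * np.pi),
                      rng.uniform(0.5, 1.0), rng.uniform(0, 2 * np.pi))
            d_owner = np.zeros((h, w), dtype=np.int32)
            d_score = np.full((h, w), np.inf)
            _paint_star(d_owner, d_score, 1, center, debris_r[k], coeffs)
            red[d_owner == 1] += spec.cell_marker_level * 0.85
        for k, center in enumerate(free_centers):
            _add_gaussian_bump(blue, center, 0.6 * free_r[k], spec.nucleus_peak)

    # ---- optics and noise ----------------------------------------------
    image = np.zeros((h, w, 3), dtype=np.uint8)
    for idx, channel in enumerate((red, green, blue)):
        if spec.psf_sigma_px > 0:
            channel = ndi.gaussian_filter(channel, spec.psf_sigma_px)
        if spec.noise_sigma > 0:
            channel = channel + rng.normal(0.0, spec.noise_sigma, size=(h, w))
        image[:, :, idx] = np.clip(np.round(channel), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        cell_labels=owner,
        cells=cells,
        puncta=puncta,
        debris_centers=debris_centers,
        free_nucleus_centers=free_centers,
    )
    return image, truth


# ---------------------------------------------------------------------------
# study-level generation (eight treatment groups)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One culture condition: treatment name, bafilomycin pretreatment flag,
    and multiplicative effects on cells/field and mean puncta/cell."""

    name: str
    baf: bool
    cell_multiplier: float = 1.0
    puncta_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.cell_multiplier <= 0 or self.puncta_multiplier <= 0:
            raise ValueError("effect multipliers must be > 0")

    @property
    def label(self) -> str:
        return f"BAF+{self.name}" if self.baf else self.name


@dataclass(frozen=True)
class StudyConfig:
    """Eight-group study layout with per-group effect multipliers."""

    groups: tuple[GroupSpec, ...]
    fields_per_group: int = 5
    base: SceneSpec = field(default_factory=SceneSpec)


#: Bafilomycin roughly halves cells per field (45–50% reduction -> 0.525)
#: and, by blocking autophagosome–lysosome fusion, raises puncta per cell.
DEFAULT_BAF_CELL_MULTIPLIER = 0.525
DEFAULT_BAF_PUNCTA_MULTIPLIER = 1.5

#: Qualitative treatment effects on mean puncta per cell (declared
#: assumptions of the generator, not measured values).
DEFAULT_TREATMENT_PUNCTA = {"control": 1.0, "LPS": 1.25, "RST": 0.8, "LPS+RST": 1.5}


def default_study_config(
    fields_per_group: int = 5,
    base: SceneSpec = SceneSpec(),
    baf_cell_multiplier: float = DEFAULT_BAF_CELL_MULTIPLIER,
    baf_puncta_multiplier: float = DEFAULT_BAF_PUNCTA_MULTIPLIER,
    treatment_puncta: dict[str, float] | None = None,
) -> StudyConfig:
    """The standard 4 treatments × BAF± = 8 group layout."""
    treatment_puncta = dict(DEFAULT_TREATMENT_PUNCTA if treatment_puncta is None
                            else treatment_puncta)
    groups = tuple(
        GroupSpec(
            name=name,
            baf=baf,
            cell_multiplier=baf_cell_multiplier if baf else 1.0,
            puncta_multiplier=mult * (baf_puncta_multiplier if baf else 1.0),
        )
        for baf in (False, True)
        for name, mult in treatment_puncta.items()
    )
    return StudyConfig(groups=groups, fields_per_group=fields_per_group, base=base)


@dataclass
class FieldScene:
    """One generated field with its provenance and ground truth."""

    field_id: str
    group: str
    baf: bool
    image: np.ndarray
    truth: GroundTruth


def _field_seed(master_seed: int, index: int) -> int:
    payload = f"{master_seed}:{index}".encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "little") % (2**31)


def generate_study(
    config: StudyConfig, seed: int, out_dir: str | Path | None = None
) -> list[FieldScene]:
    """Generate all fields of an eight-group study.

    Cells per field are Poisson around the group's expected count (minimum
    1); mean puncta per cell is the base mean times the group multiplier.
    With ``out_dir`` set, fields are written as TIFFs together with
    ``manifest.csv``, ``truth_cells.csv`` and ``truth_puncta.csv``.
    """
    scenes: list[FieldScene] = []
    index = 0
    for group in config.groups:
        for f in range(config.fields_per_group):
            field_seed = _field_seed(seed, index)
            rng = np.random.default_rng(field_seed)
            n_cells = max(1, int(rng.poisson(config.base.n_cells * group.cell_multiplier)))
            spec = replace(
                config.base,
                n_cells=n_cells,
                puncta_mean=config.base.puncta_mean * group.puncta_multiplier,
                seed=field_seed,
            )
            image, truth = generate_scene(spec)
            truth.group = group.label
            truth.baf = group.baf
            scenes.append(
                FieldScene(
                    field_id=f"{group.label}_f{f:02d}",
                    group=group.label,
                    baf=group.baf,
                    image=image,
                    truth=truth,
                )
            )
            index += 1

    if out_dir is not None:
        _write_study(scenes, Path(out_dir))
    return scenes


def _write_study(scenes: list[FieldScene], out_dir: Path) -> None:
    import tifffile

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, cell_rows, punctum_rows = [], [], []
    for scene in scenes:
        path = out_dir / f"{scene.field_id}.tif"
        tifffile.imwrite(path, scene.image)
        manifest.append(
            {"field_id": scene.field_id, "path": path.name,
             "group": scene.group, "baf": scene.baf}
        )
        for cell in scene.truth.cells:
            cell_rows.append(
                {"field_id": scene.field_id, "cell_id": cell.id,
                 "centroid_r": cell.center[0], "centroid_c": cell.center[1],
                 "n_puncta": cell.n_puncta}
            )
        for p in scene.truth.puncta:
            punctum_rows.append(
                {"field_id": scene.field_id, "cell_id": p.cell_id,
                 "centroid_r": p.center[0], "centroid_c": p.center[1],
                 "diameter_um": p.diameter_um, "area_px": p.area_px}
            )
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(cell_rows).to_csv(out_dir / "truth_cells.csv", index=False)
    pd.DataFrame(punctum_rows).to_csv(out_dir / "truth_puncta.csv", index=False)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def truth_compare(cells, puncta, truth: GroundTruth) -> dict[str, float]:
    """Compare pipeline output for one field against the generator's truth.

    Cells are matched by containment of the true nucleus centre in a
    detected cell mask; an unmatched true cell contributes its full count to
    the error.  Puncta are matched one-to-one (optimal assignment) with a
    detected centroid counting as correct when it lies within one true
    punctum radius of the true centre.

    Returns ``cell_count_error`` (detected − true), ``count_mae`` (mean
    absolute per-cell count error over true cells), ``precision`` and
    ``recall`` of punctum detection.
    """
    detected_counts: dict[int, int] = {c.id: 0 for c in cells}
    for p in puncta:
        if p.cell_id in detected_counts:
            detected_counts[p.cell_id] += 1

    # map each true cell to the detected cell containing its nucleus centre
    errors = []
    for cell in truth.cells:
        r = int(round(cell.nucleus_center[0]))
        c = int(round(cell.nucleus_center[1]))
        got = 0
        for det in cells:
            if (0 <= r < det.mask.shape[0] and 0 <= c < det.mask.shape[1]
                    and det.mask[r, c]):
                got = detected_counts[det.id]
                break
        errors.append(abs(got - cell.n_puncta))
    count_mae = float(np.mean(errors)) if errors else 0.0

    # optimal one-to-one punctum matching within one true radius
    n_det, n_true = len(puncta), len(truth.puncta)
    tp = 0
    if n_det and n_true:
        cost = np.full((n_det, n_true), 1e6)
        for i, det in enumerate(puncta):
            for j, tru in enumerate(truth.puncta):
                d = np.hypot(det.centroid[0] - tru.center[0],
                             det.centroid[1] - tru.center[1])
                if d <= tru.radius_px:
                    cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        tp = int(np.sum(cost[rows, cols] < 1e6))
    precision = tp / n_det if n_det else (1.0 if n_true == 0 else 0.0)
    recall = tp / n_true if n_true else 1.0

    return {
        "cell_count_error": float(len(cells) - len(truth.cells)),
        "count_mae": count_mae,
        "precision": float(precision),
        "recall": float(recall),
    }
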