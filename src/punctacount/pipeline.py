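"""End-to-end orchestration: configuration, per-field analysis, batch runs,
QC rendering.

``analyze_field`` is the core entry point — it takes one three-channel
image and a :class:`RunConfig` and returns validated cells, assigned puncta
and the per-cell count table.  ``run_pipeline`` batches it over a directory
of TIFF fields described by a ``manifest.csv`` (columns ``field_id, path,
group, baf``, as written by the synthetic study generator), collects tidy
CSV outputs, label maps and optional QC overlays, and finishes with the
group statistics on the pooled per-cell counts.

Runs are deterministic: identical configuration and inputs give
byte-identical CSVs, and each CSV carries the configuration hash in a
leading comment line so outputs are traceable to their settings.
Per-field failures (unreadable images) are recorded in the run manifest and
do not abort the batch; an empty input set does.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import (
    DEFAULT_MAX_DIAMETER_UM,
    DEFAULT_MIN_DIAMETER_UM,
    DEFAULT_PIXELS_PER_MICRON,
    SpatialScale,
    derive_size_gate,
    rolling_ball_radius,
)
from .puncta import PunctaParams, detect_puncta, puncta_per_cell_table
from .segmentation import (
    CellRecord,
    apply_mutual_exclusion,
    extract_nuclei,
    preprocess_channel,
    segment_objects,
    split_adherent,
    split_channels,
)
from .stats import GroupSample, analyze_groups, summarize_box

logger = logging.getLogger("punctacount")

__all__ = ["RunConfig", "FieldResult", "RunManifest", "analyze_field",
           "run_pipeline", "render_qc"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable settings for a full run.

    The defaults are the documented constants of the protocol: 5.62 px/μm,
    a 0.5–1.5 μm punctum diameter range (integer gate 6–56 px²), and a
    rolling-ball radius of 4.215 px for the puncta channel.  Segmentation
    defaults are stated in physical units and converted at the configured
    scale.
    """

    schema_version: int = 1
    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM
    max_diameter_um: float = DEFAULT_MAX_DIAMETER_UM
    # segmentation
    expected_nucleus_radius_um: float = 3.0
    min_nucleus_area_um2: float = 6.0
    min_cell_area_um2: float = 40.0
    median_radius_px: int = 1
    nuclear_peak_threshold: float = 40.0
    adequacy_threshold: float | None = None  # None -> background-anchored Otsu
    # puncta
    threshold_method: str | float = "otsu"
    upscale_factor: int = 4
    # run
    seed: int = 0

    @property
    def scale(self) -> SpatialScale:
        return SpatialScale(self.pixels_per_micron)

    @property
    def puncta_params(self) -> PunctaParams:
        return PunctaParams(
            rolling_ball_radius_px=rolling_ball_radius(self.max_diameter_um, self.scale),
            threshold_method=self.threshold_method,
            upscale_factor=self.upscale_factor,
            size_gate=derive_size_gate(
                self.min_diameter_um, self.max_diameter_um, self.scale
            ),
        )

    @property
    def nucleus_radius_px(self) -> float:
        return self.scale.um_to_px(self.expected_nucleus_radius_um)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        version = data.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        return cls(schema_version=version, **data)


@dataclass
class FieldResult:
    """Per-field outputs plus stage-by-stage object counts for auditing."""

    field_id: str
    cells: list[CellRecord]
    puncta: list
    table: pd.DataFrame
    cell_labels: np.ndarray
    stage_counts: dict[str, int]


def analyze_field(
    image: np.ndarray,
    config: RunConfig = RunConfig(),
    field_id: str = "",
    group: str = "",
    baf: bool = False,
) -> FieldResult:
    """Run calibration → segmentation → puncta detection on one field.

    The stage log mirrors the exclusion narrative: objects entering and
    leaving every filter are counted, so a field where, say, debris was
    discarded is auditable after the fact.
    """
    scale = config.scale
    marker, puncta_chan, nuclear = split_channels(image)

    # broad flattening for the structural channels; the fine 4.215-px ball
    # is reserved for the puncta channel
    broad_radius = 10.0 * config.nucleus_radius_px
    nuclear_pre = preprocess_channel(nuclear, config.median_radius_px, broad_radius)
    marker_pre = preprocess_channel(marker, config.median_radius_px, broad_radius)

    min_nucleus_area = int(round(scale.um_to_px(1.0) ** 2 * config.min_nucleus_area_um2))
    nuc_labels = segment_objects(nuclear_pre, min_area=min_nucleus_area)
    n_nuclei_raw = int(nuc_labels.max())
    nuc_labels = split_adherent(
        nuc_labels,
        intensity=nuclear_pre,
        min_peak_distance_px=max(3, int(round(config.nucleus_radius_px))),
        peak_threshold_abs=config.nuclear_peak_threshold,
    )
    nuclei = extract_nuclei(nuc_labels)

    min_cell_area = int(round(scale.um_to_px(1.0) ** 2 * config.min_cell_area_um2))
    cell_labels = segment_objects(marker_pre, min_area=min_cell_area)
    n_cells_raw = int(cell_labels.max())
    cells = apply_mutual_exclusion(
        cell_labels,
        nuclei,
        marker_pre,
        adequacy_threshold=config.adequacy_threshold,
        min_cell_area=min_cell_area,
    )

    puncta = detect_puncta(puncta_chan.pixels, cells, config.puncta_params)
    table = puncta_per_cell_table(puncta, cells, field_id=field_id, group=group, baf=baf)

    stage_counts = {
        "nuclei_raw": n_nuclei_raw,
        "nuclei_split": len(nuclei),
        "cell_regions_raw": n_cells_raw,
        "cells_valid": len(cells),
        "puncta_assigned": len(puncta),
    }
    logger.info("field %s: %s", field_id or "<unnamed>", stage_counts)

    final_labels = np.zeros(cell_labels.shape, dtype=np.int32)
    for cell in cells:
        final_labels[cell.mask] = cell.id
    return FieldResult(
        field_id=field_id,
        cells=cells,
        puncta=puncta,
        table=table,
        cell_labels=final_labels,
        stage_counts=stage_counts,
    )


@dataclass
class RunManifest:
    """Per-field accounting of a batch run."""

    rows: pd.DataFrame
    config_hash: str
    out_dir: Path


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# punctacount config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: RunConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    qc: bool = False,
) -> RunManifest:
    """Process every field listed in ``input_dir/manifest.csv``.

    Writes ``cells.csv``, ``puncta.csv``, ``per_cell_counts.csv``,
    ``box_summary.csv``, ``stats_posthoc.csv``, 16-bit label-map TIFFs and
    (optionally) QC overlay PNGs into ``out_dir``.  Returns the run
    manifest; unreadable fields are recorded there with their error and
    skipped.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    manifest_path = input_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {input_dir}")
    manifest = pd.read_csv(manifest_path, comment="#")
    if manifest.empty:
        raise RuntimeError(f"manifest {manifest_path} lists no fields")
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    cell_rows, punctum_rows, tables, run_rows = [], [], [], []
    for rec in manifest.itertuples(index=False):
        field_id = str(rec.field_id)
        group = str(getattr(rec, "group", ""))
        baf = bool(getattr(rec, "baf", False))
        path = input_dir / str(rec.path)
        try:
            image = tifffile.imread(path)
            result = analyze_field(image, config, field_id, group, baf)
        except Exception as err:  # noqa: BLE001 — per-field fault isolation
            logger.warning("field %s failed: %s", field_id, err)
            run_rows.append({"field_id": field_id, "path": str(path),
                             "group": group, "status": f"error: {err}"})
            continue
        if not result.cells:
            logger.warning("field %s: zero valid cells", field_id)
        label_path = out_dir / f"{field_id}_labels.tif"
        tifffile.imwrite(label_path, result.cell_labels.astype(np.uint16))
        if qc:
            render_qc(image, result, out_dir / f"{field_id}_qc.png")
        for cell in result.cells:
            cell_rows.append(
                {"cell_id": cell.id, "field_id": field_id,
                 "nucleus_id": cell.nucleus_id, "area_px": cell.area,
                 "mean_marker": round(cell.mean_marker_intensity, 3),
                 "centroid_r": round(cell.centroid[0], 3),
                 "centroid_c": round(cell.centroid[1], 3)}
            )
        for p in result.puncta:
            punctum_rows.append(
                {"punctum_id": p.id, "field_id": field_id, "cell_id": p.cell_id,
                 "area_px": p.area, "centroid_r": round(p.centroid[0], 3),
                 "centroid_c": round(p.centroid[1], 3)}
            )
        tables.append(result.table)
        run_rows.append({"field_id": field_id, "path": str(path), "group": group,
                         "status": "ok", **result.stage_counts})

    counts = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["cell_id", "field_id", "group", "baf", "count"])
    )
    _write_csv(pd.DataFrame(cell_rows), out_dir / "cells.csv", chash)
    _write_csv(pd.DataFrame(punctum_rows), out_dir / "puncta.csv", chash)
    _write_csv(counts, out_dir / "per_cell_counts.csv", chash)

    groups = [
        GroupSample(group=str(name), values=tuple(sub["count"].tolist()),
                    baf_pretreated=bool(sub["baf"].iloc[0]))
        for name, sub in counts.groupby("group", sort=True)
        if len(sub) > 0
    ]
    if len(groups) >= 2:
        analysis = analyze_groups(groups)
        posthoc = analysis.nonparametric.posthoc.copy()
        posthoc.insert(0, "test", analysis.nonparametric.test_name)
        _write_csv(posthoc, out_dir / "stats_posthoc.csv", chash)
        box = pd.DataFrame([summarize_box(g) for g in groups])
        _write_csv(box, out_dir / "box_summary.csv", chash)

    rows = pd.DataFrame(run_rows)
    _write_csv(rows, out_dir / "run_manifest.csv", chash)
    return RunManifest(rows=rows, config_hash=chash, out_dir=out_dir)


def render_qc(image: np.ndarray, result: FieldResult, path: str | Path) -> None:
    """Four-panel QC overlay for one field: composite, nuclear channel,
    validated cell contours, and composite with punctum markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.measure import find_contours

    fig, axes = plt.subplots(2, 2, figsize=(10, 10))
    axes = axes.ravel()
    axes[0].imshow(image)
    axes[0].set_title("composite")
    axes[1].imshow(image[:, :, 2], cmap="Blues_r")
    axes[1].set_title("nuclear channel")
    axes[2].imshow(image[:, :, 0], cmap="Reds_r")
    for cell in result.cells:
        for contour in find_contours(cell.mask.astype(float), 0.5):
            axes[2].plot(contour[:, 1], contour[:, 0], lw=0.8, color="yellow")
    axes[2].set_title(f"validated cells (n={len(result.cells)})")
    axes[3].imshow(image)
    if result.puncta:
        rr = [p.centroid[0] for p in result.puncta]
        cc = [p.centroid[1] for p in result.puncta]
        axes[3].scatter(cc, rr, s=12, facecolors="none", edgecolors="lime", lw=0.8)
    axes[3].set_title(f"puncta (n={len(result.puncta)})")
    for ax in axes:
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
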