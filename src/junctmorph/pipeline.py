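"""End-to-end orchestration: image -> skeleton -> interfaces -> results table.

The canonical output is a CSV-serialisable :class:`pandas.DataFrame` with
one row per deduplicated junction, carrying the primary and secondary
parameters for marker 1 (prefix ``m1_``) and, when present, marker 2
(``m2_``), plus the settings used.  Every exclusion (border, degenerate,
dangling, duplicate) is recorded in a log with its reason.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from . import edge_map, metrics, topology
from .edge_map import EditScript, SkeletonMap, load_edit_script
from .image_io import BinaryMask, RasterImage, load_image

__all__ = ["AnalysisConfig", "analyze_arrays", "run_pipeline", "write_results"]

_PRIMARY_FIELDS = [f.name for f in dataclasses.fields(metrics.PrimaryMeasures)]
_SECONDARY_FIELDS = [
    f.name for f in dataclasses.fields(metrics.SecondaryMeasures)
]


@dataclass
class AnalysisConfig:
    """Every knob of one analysis run; mirrors the CLI flags 1:1."""

    input_path: str | None = None
    marker2_path: str | None = None
    expression_mask_path: str | None = None
    channel: int | None = None
    dilation: int = 2
    threshold: float | None = None  # None -> Otsu on the marker image
    threshold2: float | None = None
    blur_radius: float = 2.0
    local_window: int = 15
    binarize_threshold: float = 1.2
    spur_prune: int = 5
    refine: bool = True
    refine_radius: int = 2
    corner_radius: int = 2
    min_interface_length: int = 5
    border_margin: int = 2
    exclude_border: bool = True
    expression_min_fraction: float = 0.5
    cluster_density_denominator: str = "marker_area"
    edits_path: str | None = None
    corners_path: str | None = None
    pixel_size: float | None = None  # um/px, report-level only
    seed: int = 0

    def __post_init__(self):
        if not (1 <= int(self.dilation) <= 9):
            raise ValueError("dilation must lie in [1, 9]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_manual_corners(path):
    additions, removals = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("remove"):
                removals.append(int(line.split()[1]))
            else:
                parts = line.replace(",", " ").split()
                additions.append((int(parts[-2]), int(parts[-1])))
    return additions, removals


def analyze_arrays(
    image: RasterImage,
    config: AnalysisConfig,
    marker2: RasterImage | None = None,
    expression_mask: BinaryMask | None = None,
    edits: EditScript | None = None,
    manual_corners: list | None = None,
    corner_removals: list | None = None,
    skeleton: SkeletonMap | np.ndarray | None = None,
    image_id: str = "image",
) -> tuple[pd.DataFrame, list]:
    """Run the measurement pipeline on in-memory arrays.

    ``skeleton`` bypasses automatic edge detection with a pre-validated
    boundary map (e.g. a fully user-corrected skeleton, or synthetic ground
    truth); automatic refinement is skipped in that case.  Returns the
    per-junction results table and the exclusion/settings log.
    """
    log: list = []
    if skeleton is None:
        edges = edge_map.detect_edges(
            image,
            blur_radius=config.blur_radius,
            local_window=config.local_window,
            binarize_threshold=config.binarize_threshold,
        )
        skel = edge_map.skeletonize(edges, prune_len=config.spur_prune)
        if edits is not None:
            skel = edge_map.apply_edits(skel, edits)
        if config.refine:
            skel = edge_map.refine_skeleton(
                skel, image, search_radius=config.refine_radius
            )
    else:
        skel = (
            skeleton
            if isinstance(skeleton, SkeletonMap)
            else SkeletonMap(np.asarray(skeleton, dtype=bool))
        )
        if edits is not None:
            skel = edge_map.apply_edits(skel, edits)

    labels = topology.label_cells(skel, border_margin=config.border_margin)
    corners = topology.detect_corners(
        skel, labels, radius=config.corner_radius
    )
    if manual_corners or corner_removals:
        corners = topology.adjust_corners(
            corners,
            manual_corners or [],
            corner_removals or [],
            skel,
            labels,
            radius=config.corner_radius,
        )
    interfaces = topology.extract_interfaces(
        skel,
        corners,
        labels,
        min_length=config.min_interface_length,
        exclude_border=config.exclude_border,
        zone_radius=config.corner_radius,
        log=log,
    )
    if expression_mask is not None:
        interfaces = topology.classify_junctions(
            interfaces,
            labels,
            expression_mask,
            min_fraction=config.expression_min_fraction,
        )

    threshold = (
        float(config.threshold)
        if config.threshold is not None
        else float(threshold_otsu(image.pixels))
    )
    threshold2 = None
    if marker2 is not None:
        threshold2 = (
            float(config.threshold2)
            if config.threshold2 is not None
            else float(threshold_otsu(marker2.pixels))
        )
    log.append({
        "stage": "settings",
        "image_id": image_id,
        "dilation": config.dilation,
        "threshold": threshold,
        "threshold2": threshold2,
        "n_corners": len(corners),
        "n_interfaces": len(interfaces),
    })

    rows = []
    for rec in interfaces:
        band = metrics.dilate_interface(rec, config.dilation, image.shape)
        p = metrics.measure_primary(rec, band, image, threshold)
        s = metrics.derive_secondary(p, config.cluster_density_denominator)
        row = {
            "image_id": image_id,
            "interface_id": rec.id,
            "corner_a": rec.corner_a,
            "corner_b": rec.corner_b,
            "cell_a": rec.cell_pair[0],
            "cell_b": rec.cell_pair[1],
            "junction_class": rec.junction_class,
            "dilation": config.dilation,
            "threshold": threshold,
        }
        for name in _PRIMARY_FIELDS:
            row[f"m1_{name}"] = getattr(p, name)
        for name in _SECONDARY_FIELDS:
            row[f"m1_{name}"] = getattr(s, name)
        if marker2 is not None:
            p2, s2 = metrics.measure_second_marker(
                rec, band, marker2, threshold2,
                config.cluster_density_denominator,
            )
            row["threshold2"] = threshold2
            for name in _PRIMARY_FIELDS:
                row[f"m2_{name}"] = getattr(p2, name)
            for name in _SECONDARY_FIELDS:
                row[f"m2_{name}"] = getattr(s2, name)
        if config.pixel_size:
            row["pixel_size_um"] = config.pixel_size
            row["m1_interface_contour_um"] = (
                p.interface_contour * config.pixel_size
            )
        rows.append(row)
    columns = list(rows[0].keys()) if rows else [
        "image_id", "interface_id", "corner_a", "corner_b",
        "cell_a", "cell_b", "junction_class", "dilation", "threshold",
    ]
    return pd.DataFrame(rows, columns=columns), log


def run_pipeline(config: AnalysisConfig) -> tuple[pd.DataFrame, list]:
    """File-based entry point: load rasters per ``config`` and analyze."""
    if not config.input_path:
        raise ValueError("config.input_path is required")
    image = load_image(config.input_path, channel=config.channel)
    marker2 = (
        load_image(config.marker2_path, channel=config.channel)
        if config.marker2_path
        else None
    )
    mask = None
    if config.expression_mask_path:
        m = load_image(config.expression_mask_path)
        mask = BinaryMask(m.pixels > 0)
    edits = (
        load_edit_script(config.edits_path) if config.edits_path else None
    )
    additions, removals = (None, None)
    if config.corners_path:
        additions, removals = _load_manual_corners(config.corners_path)
    return analyze_arrays(
        image,
        config,
        marker2=marker2,
        expression_mask=mask,
        edits=edits,
        manual_corners=additions,
        corner_removals=removals,
        image_id=Path(config.input_path).stem,
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write the canonical CSV (stable column order, no index)."""
    table.to_csv(path, index=False)
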