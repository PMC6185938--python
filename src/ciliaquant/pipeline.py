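"""Batch orchestration: images → segmentation → morphometry → statistics.

``run_measure`` processes every image in a manifest (path, group, sample)
independently: read, maximum-intensity project both channels, segment cilia
and nuclei with their own configurations, measure objects, summarise fields.
Thresholds are resolved per image (quantile mode), since acquisition
intensity varies between fields. A failure on one image is logged and
skipped, never fatal to the batch.

``run_stats`` folds the per-field (or per-cilium) table into group
summaries (mean ± SEM), one-way ANOVA and Dunnett's comparisons against the
named control, for both metrics (mean cilium length and incidence).

All outputs are deterministic functions of (images, config, seed); the
machine-readable run log carries resolved thresholds and per-image status
for provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_images import ChannelMap, read_image, max_intensity_projection
from .segmentation import (
    HysteresisParams,
    SegmentationConfig,
    resolve_thresholds,
    hysteresis_segment,
    remove_small_objects,
    split_touching_objects,
)
from .morphometry import measure_objects, summarize_field
from .stats import (
    QCThresholds,
    group_summary,
    anova_oneway,
    dunnett_vs_control,
    qc_flags,
    significance_stars,
)

__all__ = ["RunConfig", "run_measure", "run_stats", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one batch run needs.

    ``unit`` selects the observational unit fed to the hypothesis tests:
    ``"per_field"`` (field means/incidences; the default) or
    ``"per_cilium"`` (pooled individual lengths; length metric only).
    """

    manifest: pd.DataFrame  # columns: path, group, sample
    input_dir: Path
    out_dir: Path
    channel_map: ChannelMap = field(default_factory=ChannelMap)
    cilia_segmentation: SegmentationConfig = field(
        default_factory=SegmentationConfig.for_cilia
    )
    nuclei_segmentation: SegmentationConfig = field(
        default_factory=SegmentationConfig.for_nuclei
    )
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    control_group: str = "control"
    unit: str = "per_field"
    pixel_size_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.manifest) == 0:
            raise ValueError("empty manifest")
        if self.unit not in ("per_field", "per_cilium"):
            raise ValueError(f"unknown unit {self.unit!r}")


def _segment_with_log(image, config: SegmentationConfig):
    low, high = resolve_thresholds(image, config.hysteresis)
    mask = hysteresis_segment(image, low, high)
    mask = remove_small_objects(mask, config.min_object_area_px)
    labels = split_touching_objects(mask, config.split_min_distance_px)
    log = {
        "mode": config.hysteresis.mode,
        "low_param": config.hysteresis.low,
        "high_param": config.hysteresis.high,
        "low_resolved": low,
        "high_resolved": high,
        "min_object_area_px": config.min_object_area_px,
        "split_min_distance_px": config.split_min_distance_px,
    }
    return labels, log


def run_measure(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every image in the manifest; write objects.csv / fields.csv.

    Returns (objects, fields) DataFrames. ``run_log.json`` records the
    resolved per-image thresholds and any skipped images.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    object_rows, field_rows, log_images = [], [], []

    for row in config.manifest.itertuples(index=False):
        image_id = Path(row.path).name.replace(".ome.tif", "").replace(".tif", "")
        entry = {"image_id": image_id, "path": str(row.path), "status": "ok"}
        try:
            stack = read_image(
                Path(config.input_dir) / row.path,
                channel_map=config.channel_map,
                pixel_size_override=config.pixel_size_override,
            )
            cilia_img = max_intensity_projection(stack, config.channel_map.cilia_channel)
            nuclei_img = max_intensity_projection(
                stack, config.channel_map.nuclei_channel
            )
            cilia_labels, cilia_log = _segment_with_log(
                cilia_img, config.cilia_segmentation
            )
            nuclei_labels, nuclei_log = _segment_with_log(
                nuclei_img, config.nuclei_segmentation
            )
            entry["cilia"] = cilia_log
            entry["nuclei"] = nuclei_log

            measurements = measure_objects(
                cilia_labels, cilia_img, stack.pixel_size_um
            )
            n_nuclei = int(nuclei_labels.max())
            summary = summarize_field(measurements, n_nuclei, image_id)

            for m in measurements:
                object_rows.append(
                    {
                        "image_id": image_id,
                        "group": row.group,
                        "sample": row.sample,
                        "label": m.label,
                        "area_px": m.area_px,
                        "area_um2": m.area_um2,
                        "length_um": m.length_um,
                        "major_axis_um": m.major_axis_um,
                        "mean_intensity": m.mean_intensity,
                        "centroid_y": m.centroid[0],
                        "centroid_x": m.centroid[1],
                    }
                )
            field_rows.append(
                {
                    "image_id": image_id,
                    "group": row.group,
                    "sample": row.sample,
                    "n_cilia": summary.n_cilia,
                    "n_nuclei": summary.n_nuclei,
                    "mean_length_um": summary.mean_length_um,
                    "incidence_pct": summary.incidence_pct,
                    "qc_flags": ";".join(summary.qc_flags),
                }
            )
        except Exception as exc:  # skip-and-continue batch policy
            entry["status"] = "error"
            entry["error"] = f"{type(exc).__name__}: {exc}"
        log_images.append(entry)

    objects = pd.DataFrame(
        object_rows,
        columns=[
            "image_id", "group", "sample", "label", "area_px", "area_um2",
            "length_um", "major_axis_um", "mean_intensity",
            "centroid_y", "centroid_x",
        ],
    )
    fields = pd.DataFrame(
        field_rows,
        columns=[
            "image_id", "group", "sample", "n_cilia", "n_nuclei",
            "mean_length_um", "incidence_pct", "qc_flags",
        ],
    )
    objects.to_csv(out / "objects.csv", index=False)
    fields.to_csv(out / "fields.csv", index=False)
    log = {
        "tool": "ciliaquant",
        "version": __version__,
        "seed": config.seed,
        "n_images": len(config.manifest),
        "n_failed": sum(1 for e in log_images if e["status"] == "error"),
        "images": log_images,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return objects, fields


def _metric_groups(
    fields: pd.DataFrame, objects: pd.DataFrame | None, metric: str, unit: str
):
    """Assemble {group: values} for one metric under the chosen unit."""
    if metric == "mean_length_um" and unit == "per_cilium" and objects is not None:
        return {
            g: sub["length_um"].to_numpy()
            for g, sub in objects.groupby("group", sort=True)
        }
    vals = fields[["group", metric]].dropna()
    return {g: sub[metric].to_numpy() for g, sub in vals.groupby("group", sort=True)}


def run_stats(
    fields: pd.DataFrame,
    config: RunConfig,
    objects: pd.DataFrame | None = None,
) -> dict:
    """Group summaries + ANOVA + Dunnett vs control; write groups.csv, stats.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups_present = sorted(fields["group"].unique())
    if config.control_group not in groups_present:
        raise ValueError(
            f"control group {config.control_group!r} absent from {groups_present}"
        )

    group_rows = []
    report: dict = {
        "tool": "ciliaquant",
        "version": __version__,
        "control_group": config.control_group,
        "unit": config.unit,
        "metrics": {},
    }
    for metric in ("mean_length_um", "incidence_pct"):
        data = _metric_groups(fields, objects, metric, config.unit)
        labels = sorted(data)
        for g in labels:
            s = group_summary(data[g], g)
            group_rows.append(
                {"metric": metric, "group": g, "n": s.n, "mean": s.mean, "sem": s.sem}
            )
        metric_report: dict = {
            "groups": {
                g: asdict(group_summary(data[g], g)) for g in labels
            }
        }
        if len(labels) >= 2 and all(data[g].size >= 2 for g in labels):
            control_idx = labels.index(config.control_group)
            ordered = [data[g] for g in labels]
            anova = anova_oneway(ordered)
            dunnett = dunnett_vs_control(ordered, control=control_idx, seed=config.seed)
            metric_report["anova"] = {
                "F": anova.statistic,
                "df": list(anova.df),
                "p": anova.p_value,
                "stars": significance_stars(anova.p_value),
            }
            metric_report["dunnett"] = {
                labels[int(i)]: {
                    "t": t,
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                    "stars": significance_stars(p_adj),
                }
                for i, (t, p_raw, p_adj) in dunnett.comparisons.items()
            }
        report["metrics"][metric] = metric_report

    # QC at group level: pooled cilia / nuclei counts and field counts
    qc_report = {}
    for g, sub in fields.groupby("group", sort=True):
        counts = {
            "n_cilia": int(sub["n_cilia"].sum()),
            "n_cells": int(sub["n_nuclei"].sum()),
            "n_cells_population": int(sub["n_nuclei"].sum()),
            "n_fields": int(len(sub)),
        }
        qc_report[g] = {
            "counts": counts,
            "flags": qc_flags(counts, config.qc_thresholds),
        }
    report["qc"] = qc_report

    pd.DataFrame(group_rows).to_csv(out / "groups.csv", index=False)
    (out / "stats.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def load_run_config(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Recognised sections: ``manifest`` (CSV path, relative to the YAML),
    ``channels`` (cilia/nuclei), ``segmentation`` (cilia:/nuclei: blocks with
    mode, low, high, min_object_area_px, split_min_distance_px), ``qc``,
    ``control_group``, ``unit``, ``pixel_size_um``, ``seed``, ``out_dir``.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    manifest_path = base / cfg.get("manifest", "manifest.csv")
    manifest = pd.read_csv(manifest_path)

    ch = cfg.get("channels", {})
    channel_map = ChannelMap(
        cilia_channel=ch.get("cilia", "ARL13B"),
        nuclei_channel=ch.get("nuclei", "DAPI"),
    )

    def seg_block(name: str, default: SegmentationConfig) -> SegmentationConfig:
        block = cfg.get("segmentation", {}).get(name)
        if not block:
            return default
        hyst = HysteresisParams(
            low=block.get("low", default.hysteresis.low),
            high=block.get("high", default.hysteresis.high),
            mode=block.get("mode", default.hysteresis.mode),
        )
        return SegmentationConfig(
            hysteresis=hyst,
            min_object_area_px=block.get(
                "min_object_area_px", default.min_object_area_px
            ),
            split_min_distance_px=block.get(
                "split_min_distance_px", default.split_min_distance_px
            ),
        )

    qc_cfg = cfg.get("qc", {})
    qc = QCThresholds(
        min_cilia_per_sample=qc_cfg.get("min_cilia_per_sample", 150),
        min_cells_per_sample=qc_cfg.get("min_cells_per_sample", 300),
        min_cells_per_population=qc_cfg.get("min_cells_per_population", 100),
        min_fields=qc_cfg.get("min_fields", 10),
    )

    return RunConfig(
        manifest=manifest,
        input_dir=manifest_path.parent,
        out_dir=Path(out_dir if out_dir is not None else cfg.get("out_dir", base / "out")),
        channel_map=channel_map,
        cilia_segmentation=seg_block("cilia", SegmentationConfig.for_cilia()),
        nuclei_segmentation=seg_block("nuclei", SegmentationConfig.for_nuclei()),
        qc_thresholds=qc,
        control_group=cfg.get("control_group", "control"),
        unit=cfg.get("unit", "per_field"),
        pixel_size_override=cfg.get("pixel_size_um"),
        seed=cfg.get("seed", 0),
    )
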