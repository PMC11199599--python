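"""End-to-end pipelines tying segmentation, detection, proximity and
recruitment together, with YAML configuration, logging, and QC artifacts.

Two batch pipelines are provided:

* :func:`run_foci_pipeline` — multi-channel stills: segment nuclei from the
  Hoechst channel, gate to EGFP-expressing cells, detect foci per channel,
  score cross-channel nearest-neighbour proximity, and summarize. Tiled
  acquisitions are handled by processing each tile independently and pooling
  the per-cell records.
* :func:`run_stripe_pipeline` — laser-stripe time-lapses: extract damage and
  control traces, double-normalize, aggregate across cells (mean ± SEM),
  classify active recruitment, and fit the kinetic model.

Both write CSV tables plus a machine-readable run manifest (package version,
config hash, seed) so every output is regenerable.
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
import yaml

from . import __version__
from .detection import DetectionParams, detect_foci, gate_expressing_cells, count_foci
from .errors import FocikitError
from .image import LabelMap
from .io import (
    read_multichannel,
    read_roi_pairs,
    read_timelapse,
    read_truth,
    write_label_map,
    write_multichannel,
    write_roi_pairs,
    write_timelapse,
    write_truth,
)
from .proximity import (
    ProximityThresholds,
    nearest_neighbour_distances,
    records_table,
    summarize_proximity,
)
from .recruitment import (
    DEFAULT_BASELINE_FRAMES,
    aggregate_curves,
    auto_place_control,
    classify_recruitment,
    extract_traces,
    fit_kinetics,
    normalize_trace,
)
from .segmentation import SegmentationParams, nucleus_table, segment_nuclei
from .synthetic import (
    KineticsSpec,
    NoiseSpec,
    SceneSpec,
    generate_nuclei_scene,
    generate_stripe_movie,
    place_focus_pairs,
    place_random_foci,
    render_channels,
)

logger = logging.getLogger("focikit")

DEFAULT_CHANNEL_MAP = {"hoechst": "hoechst", "egfp": "egfp", "marker1": "53bp1"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    pipeline: str  # foci | stripe
    inputs: list[str] = field(default_factory=list)
    out_dir: str = "."
    channel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: ProximityThresholds = field(default_factory=ProximityThresholds)
    baseline_frames: list[int] = field(default_factory=lambda: list(DEFAULT_BASELINE_FRAMES))
    damage_frame: int = 5
    window: int = 10
    rois: str | None = None
    qc_overlay: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.pipeline not in {"foci", "stripe"}:
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        if self.pipeline == "foci":
            for role in ("hoechst", "egfp", "marker1"):
                if role not in self.channel_map:
                    raise ValueError(f"channel_map must assign the {role!r} role")
        if not self.baseline_frames:
            raise ValueError("baseline_frames must be non-empty")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        for key, klass in (
            ("segmentation", SegmentationParams),
            ("detection", DetectionParams),
            ("thresholds", ProximityThresholds),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "focikit_version": __version__,
        "pipeline": config.pipeline,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def run_foci_pipeline(config: RunConfig):
    """Run the still-image foci/proximity pipeline over all input images.

    Returns a result bundle dict with the pooled tables; also writes, per
    image: a label-map TIFF and foci/proximity CSVs, and pooled
    foci/proximity/summary CSVs plus manifest under ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = config.channel_map

    pooled_foci = []
    pooled_records = []
    pooled_gated: set[int] = set()
    per_image_counts = {}
    cell_offset = 0

    if not config.inputs:
        logger.warning("empty image set: writing empty outputs")

    for path in config.inputs:
        name = Path(path).stem
        image = read_multichannel(path)
        missing = [v for v in (cmap["hoechst"], cmap["egfp"], cmap["marker1"]) if v not in image.channels]
        if missing:
            raise FocikitError(f"{path}: channels {missing} not present in {image.channel_names}")

        label_map = segment_nuclei(
            image[cmap["hoechst"]], config.segmentation, pixel_scale=image.pixel_scale
        )
        write_label_map(out_dir / f"{name}_labels.tif", label_map)
        nucleus_table(label_map).to_csv(out_dir / f"{name}_nuclei.csv", index=False)

        gated = gate_expressing_cells(image[cmap["egfp"]], label_map)
        foci_a = detect_foci(
            image[cmap["egfp"]], label_map, config.detection, channel_name=cmap["egfp"]
        )
        marker_channels = [cmap[k] for k in ("marker1", "marker2") if k in cmap]
        records = []
        foci_all = list(foci_a)
        for marker in marker_channels:
            foci_b = detect_foci(
                image[marker], label_map, config.detection, channel_name=marker
            )
            foci_all.extend(foci_b)
            records.extend(
                nearest_neighbour_distances(foci_a, foci_b, config.thresholds)
            )

        logger.info(
            "%s: %d nuclei, %d expressing, %d source foci, %d proximity records",
            name, label_map.n_labels, len(gated), len(foci_a), len(records),
        )
        per_image_counts[name] = {
            "n_nuclei": label_map.n_labels,
            "n_expressing": len(gated),
            "n_foci_source": len(foci_a),
        }

        # pool with globally unique cell ids across tiles
        for f in foci_all:
            pooled_foci.append(
                {
                    "image": name,
                    "nucleus_id": f.nucleus_id + cell_offset,
                    "channel": f.channel_name,
                    "row": f.centroid[0],
                    "col": f.centroid[1],
                    "prominence": f.prominence,
                    "area_px2": f.area,
                    "mean_intensity": f.mean_intensity,
                }
            )
        tbl = records_table(records)
        tbl.insert(0, "image", name)
        tbl["nucleus_id"] += cell_offset
        pooled_records.append((tbl, records, cell_offset))
        pooled_gated.update(g + cell_offset for g in gated)
        if config.qc_overlay:
            _qc_overlay(out_dir / f"{name}_qc.png", image, cmap, label_map, foci_all, records)
        cell_offset += label_map.n_labels

    foci_df = pd.DataFrame(
        pooled_foci,
        columns=["image", "nucleus_id", "channel", "row", "col", "prominence", "area_px2", "mean_intensity"],
    )
    prox_df = (
        pd.concat([t for t, _, _ in pooled_records], ignore_index=True)
        if pooled_records
        else records_table([])
    )

    # population summary over gated cells, pooled across tiles
    all_records = []
    for _, recs, offset in pooled_records:
        for r in recs:
            r2 = dataclasses.replace(r, nucleus_id=r.nucleus_id + offset)
            all_records.append(r2)
    per_cell, population = summarize_proximity(all_records, pooled_gated)

    foci_df.to_csv(out_dir / "foci.csv", index=False)
    prox_df.to_csv(out_dir / "proximity.csv", index=False)
    per_cell.to_csv(out_dir / "per_cell_summary.csv", index=False)
    population.to_csv(out_dir / "population_summary.csv", index=False)
    _write_manifest(out_dir, config, {"images": per_image_counts})
    return {
        "foci": foci_df,
        "proximity": prox_df,
        "per_cell": per_cell,
        "population": population,
        "gated": pooled_gated,
    }


def run_stripe_pipeline(config: RunConfig):
    """Run the recruitment-kinetics pipeline over all input movies.

    ROI pairs come from ``config.rois`` (JSON) when given; otherwise each
    movie must have a ``<stem>.truth.json`` sidecar providing the damage ROI
    and nucleus mask, and the control ROI is auto-placed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    roi_pairs = read_roi_pairs(config.rois) if config.rois else None
    traces = []
    if not config.inputs:
        logger.warning("empty movie set: writing empty outputs")
    for i, path in enumerate(config.inputs):
        movie = read_timelapse(path)
        if roi_pairs is not None:
            pair = roi_pairs[i]
        else:
            sidecar = Path(path).with_suffix("").with_suffix(".truth.json")
            if not sidecar.exists():
                raise FocikitError(
                    f"{path}: no ROI file given and no sidecar {sidecar.name}"
                )
            truth = read_truth(sidecar)
            if truth.damage_roi is None:
                raise FocikitError(f"{sidecar}: sidecar lacks a damage ROI")
            nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
            pair = auto_place_control(
                truth.nucleus_masks == nid, truth.damage_roi, nucleus_id=nid
            )
        trace = normalize_trace(extract_traces(movie, pair), config.baseline_frames)
        trace.nucleus_id = i + 1
        traces.append(trace)

    rows = []
    for trace in traces:
        for k in range(trace.n_frames):
            rows.append(
                {
                    "cell": trace.nucleus_id,
                    "frame": k,
                    "t_s": trace.t[k],
                    "f_bleach": trace.f_bleach[k],
                    "f_control": trace.f_control[k],
                    "ratio": trace.ratio[k],
                }
            )
    trace_df = pd.DataFrame(rows, columns=["cell", "frame", "t_s", "f_bleach", "f_control", "ratio"])
    trace_df.to_csv(out_dir / "traces.csv", index=False)

    result = {"traces": traces, "trace_table": trace_df}
    if traces:
        agg = aggregate_curves(traces)
        agg_df = pd.DataFrame(
            {"t_s": agg.t, "mean_ratio": agg.mean_ratio, "sem": agg.sem, "n": agg.n}
        )
        agg_df.to_csv(out_dir / "aggregate.csv", index=False)
        label = classify_recruitment(agg, config.window)
        fit = fit_kinetics(agg, config.damage_frame)
        fit_payload = {
            "classification": label,
            "amplitude": fit.amplitude,
            "tau_s": fit.tau,
            "rss": fit.rss,
            "converged": fit.converged,
            "n_cells": agg.n,
        }
        (out_dir / "fit.json").write_text(json.dumps(fit_payload, indent=1))
        result.update({"aggregate": agg, "classification": label, "fit": fit})
    _write_manifest(out_dir, config, {"n_movies": len(config.inputs)})
    return result


def simulate_foci_scene(config: dict, out_dir: str | Path, seed: int | None = None):
    """Render a ground-truthed foci scene from a YAML-style dict and save it.

    Config keys: ``scene`` (SceneSpec fields), optional ``noise`` (NoiseSpec
    fields), optional ``pairs`` ({channel_a, channel_b, distances_px}), and
    optional ``random_foci`` ({channel, n_per_nucleus}).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene_kwargs = dict(config.get("scene", {}))
    if "image_shape" in scene_kwargs:
        scene_kwargs["image_shape"] = tuple(scene_kwargs["image_shape"])
    if "nucleus_radius_range" in scene_kwargs:
        scene_kwargs["nucleus_radius_range"] = tuple(scene_kwargs["nucleus_radius_range"])
    if seed is not None:
        scene_kwargs["seed"] = seed
    noise = NoiseSpec(**config["noise"]) if "noise" in config else NoiseSpec()
    spec = SceneSpec(noise=noise, **scene_kwargs)

    _, truth = generate_nuclei_scene(spec)
    if "pairs" in config:
        p = config["pairs"]
        truth = place_focus_pairs(
            truth, p["channel_a"], p["channel_b"], list(p["distances_px"])
        )
    if "random_foci" in config:
        r = config["random_foci"]
        truth = place_random_foci(truth, r["channel"], int(r["n_per_nucleus"]))
    image = render_channels(truth, spec.noise, seed=spec.seed)
    write_multichannel(out_dir / "scene.ome.tif", image)
    write_truth(out_dir / "scene.truth.json", truth, out_dir / "scene_labels.tif")
    return image, truth


def simulate_stripe_movies(config: dict, out_dir: str | Path, seed: int | None = None):
    """Render ground-truthed stripe movies (``n_movies`` cells) and save them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kin = KineticsSpec(**config.get("kinetics", {}))
    scene_kwargs = dict(config.get("scene", {}))
    if "image_shape" in scene_kwargs:
        scene_kwargs["image_shape"] = tuple(scene_kwargs["image_shape"])
    if "nucleus_radius_range" in scene_kwargs:
        scene_kwargs["nucleus_radius_range"] = tuple(scene_kwargs["nucleus_radius_range"])
    noise = NoiseSpec(**config["noise"]) if "noise" in config else NoiseSpec()
    n_movies = int(config.get("n_movies", 1))
    base_seed = seed if seed is not None else scene_kwargs.get("seed", 0)

    paths = []
    pairs = []
    for i in range(n_movies):
        spec = SceneSpec(noise=noise, **{**scene_kwargs, "seed": int(base_seed) + i})
        movie, truth = generate_stripe_movie(kin, spec)
        stem = out_dir / f"movie_{i:03d}"
        write_timelapse(f"{stem}.ome.tif", movie)
        write_truth(f"{stem}.truth.json", truth, f"{stem}_labels.tif")
        nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
        pairs.append(
            auto_place_control(truth.nucleus_masks == nid, truth.damage_roi, nucleus_id=nid)
        )
        paths.append(f"{stem}.ome.tif")
    write_roi_pairs(out_dir / "rois.json", pairs)
    return paths


def _qc_overlay(path, image, cmap, label_map: LabelMap, foci, records) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"overlapping": "lime", "proximal": "orange", "distant": "red", "unmatched": "gray"}
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image[cmap["hoechst"]], cmap="gray")
    ax.contour(label_map.labels > 0, levels=[0.5], colors="cyan", linewidths=0.5)
    for f in foci:
        ax.plot(f.centroid[1], f.centroid[0], "+", color="yellow", ms=4)
    for r in records:
        if r.nn_distance is None:
            continue
        ax.plot(
            r.source_focus.centroid[1],
            r.source_focus.centroid[0],
            "o",
            mfc="none",
            mec=colors[r.class_label],
            ms=6,
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
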