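"""Reading and writing OME-TIFF images, label maps, truth sidecars and ROI files."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .image import LabelMap, MultiChannelImage, Rect, TimeLapse
from .recruitment import RoiPair
from .synthetic import FocusSpec, KineticsSpec, NucleusSpec, SyntheticTruth


def write_multichannel(path: str | Path, image: MultiChannelImage) -> None:
    """Write a named-channel image as OME-TIFF with CYX axes."""
    names = image.channel_names
    stack = np.stack([image[ch] for ch in names]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": image.pixel_scale,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_scale,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_multichannel(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_scale: float | None = None,
) -> MultiChannelImage:
    """Read a CYX OME-TIFF into a named-channel image.

    Channel names and pixel size are taken from OME metadata when present;
    explicit arguments override.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_names, meta_scale = _ome_channel_info(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a CYX stack, got shape {data.shape}")
    names = channel_names or meta_names or [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} channels but {len(names)} channel names"
        )
    scale = pixel_scale or meta_scale or 1.0
    return MultiChannelImage(
        channels={n: data[i].astype(float) for i, n in enumerate(names)},
        pixel_scale=scale,
    )


def write_timelapse(path: str | Path, movie: TimeLapse) -> None:
    """Write a single-channel time-lapse as OME-TIFF with TYX axes."""
    tifffile.imwrite(
        str(path),
        movie.frames.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TYX",
            "TimeIncrement": movie.frame_interval_s,
            "TimeIncrementUnit": "s",
            "PhysicalSizeX": movie.pixel_scale,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_scale,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_timelapse(
    path: str | Path,
    frame_interval_s: float | None = None,
    pixel_scale: float | None = None,
) -> TimeLapse:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        interval, scale = _ome_time_info(tif)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a TYX stack, got shape {data.shape}")
    return TimeLapse(
        frames=data.astype(float),
        frame_interval_s=frame_interval_s or interval or 15.0,
        pixel_scale=pixel_scale or scale or 1.0,
    )


def _ome_channel_info(tif: "tifffile.TiffFile"):
    names, scale = None, None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        if pixels is not None:
            scale = float(pixels.get("PhysicalSizeX")) if pixels.get("PhysicalSizeX") else None
            chans = pixels.findall("ome:Channel", ns)
            if chans and all(c.get("Name") for c in chans):
                names = [c.get("Name") for c in chans]
    except Exception:
        pass
    return names, scale


def _ome_time_info(tif: "tifffile.TiffFile"):
    interval, scale = None, None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        if pixels is not None:
            if pixels.get("TimeIncrement"):
                interval = float(pixels.get("TimeIncrement"))
            if pixels.get("PhysicalSizeX"):
                scale = float(pixels.get("PhysicalSizeX"))
    except Exception:
        pass
    return interval, scale


def write_label_map(path: str | Path, label_map: LabelMap) -> None:
    tifffile.imwrite(str(path), label_map.labels.astype(np.int32))


def read_label_map(path: str | Path, pixel_scale: float = 1.0) -> LabelMap:
    return LabelMap(tifffile.imread(str(path)).astype(np.int32), pixel_scale)


def write_truth(path: str | Path, truth: SyntheticTruth, label_map_path: str | Path) -> None:
    """Sidecar JSON for a synthetic scene; nucleus masks go to a label-map TIFF."""
    label_map_path = Path(label_map_path)
    write_label_map(label_map_path, LabelMap(truth.nucleus_masks, truth.pixel_scale))
    payload = {
        "pixel_scale": truth.pixel_scale,
        "background_level": truth.background_level,
        "seed": truth.seed,
        "label_map": label_map_path.name,
        "nuclei": [asdict(n) for n in truth.nuclei],
        "foci": [asdict(f) for f in truth.foci],
        "pair_distances": [[ia, ib, d] for ia, ib, d in truth.pair_distances],
        "kinetics": asdict(truth.kinetics) if truth.kinetics else None,
        "damage_roi": truth.damage_roi.to_json() if truth.damage_roi else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    path = Path(path)
    payload = json.loads(path.read_text())
    labels = tifffile.imread(str(path.parent / payload["label_map"])).astype(np.int32)
    nuclei = [
        NucleusSpec(
            nucleus_id=n["nucleus_id"],
            center=tuple(n["center"]),
            radii=tuple(n["radii"]),
            orientation=n["orientation"],
            amplitude=n["amplitude"],
            egfp_level=n.get("egfp_level", 0.0),
        )
        for n in payload["nuclei"]
    ]
    foci = [
        FocusSpec(
            nucleus_id=f["nucleus_id"],
            channel_name=f["channel_name"],
            position=tuple(f["position"]),
            psf_sigma=f["psf_sigma"],
            amplitude=f["amplitude"],
            paired_with=tuple(f["paired_with"]) if f.get("paired_with") else None,
        )
        for f in payload["foci"]
    ]
    return SyntheticTruth(
        nuclei=nuclei,
        nucleus_masks=labels,
        pixel_scale=payload["pixel_scale"],
        foci=foci,
        pair_distances=[tuple(p) for p in payload["pair_distances"]],
        kinetics=KineticsSpec(**payload["kinetics"]) if payload.get("kinetics") else None,
        damage_roi=Rect.from_json(payload["damage_roi"]) if payload.get("damage_roi") else None,
        background_level=payload.get("background_level", 0.0),
        seed=payload.get("seed", 0),
    )


def read_roi_pairs(path: str | Path) -> list[RoiPair]:
    """ROI file: JSON list of {"damage": [r0,c0,h,w], "control": [...], "nucleus_id": n}."""
    payload = json.loads(Path(path).read_text())
    pairs = []
    for entry in payload:
        pairs.append(
            RoiPair(
                damage_roi=Rect.from_json(entry["damage"]),
                control_roi=Rect.from_json(entry["control"]),
                nucleus_id=int(entry.get("nucleus_id", 0)),
            )
        )
    return pairs


def write_roi_pairs(path: str | Path, pairs: list[RoiPair]) -> None:
    payload = [
        {
            "damage": p.damage_roi.to_json(),
            "control": p.control_roi.to_json(),
            "nucleus_id": p.nucleus_id,
        }
        for p in pairs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
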