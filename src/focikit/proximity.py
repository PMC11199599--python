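"""Cross-channel nearest-neighbour focus distances and the three-bin
overlapping / proximal / distant classification.

Records are directional: for every focus in the source channel A the nearest
focus in the comparator channel B *within the same nucleus* is found, and the
centroid distance is binned. Default bins: overlapping d <= 5 px (0.36 µm),
proximal 5 < d <= 15 px (0.36-1.07 µm), distant d > 15 px (> 1.07 µm), the
integer pixel bins read as half-open real intervals because detected centroid
distances are real-valued. The default pixel scale is derived from the
15 px <-> 1.07 µm correspondence of those bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import FocusRecord

OVERLAPPING = "overlapping"
PROXIMAL = "proximal"
DISTANT = "distant"
UNMATCHED = "unmatched"
CLASSES = (OVERLAPPING, PROXIMAL, DISTANT)

#: µm per pixel implied by the 15 px = 1.07 µm bin boundary
DEFAULT_PIXEL_SCALE = 1.07 / 15.0


@dataclass
class ProximityThresholds:
    """Distance bins in pixels plus the µm/px scale used for reporting."""

    overlap_max: float = 5.0
    proximal_max: float = 15.0
    pixel_scale: float = DEFAULT_PIXEL_SCALE

    def __post_init__(self) -> None:
        if not 0 < self.overlap_max < self.proximal_max:
            raise ValueError("need 0 < overlap_max < proximal_max")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


@dataclass
class ProximityRecord:
    """Nearest-neighbour result for one source focus (directional A -> B)."""

    nucleus_id: int
    source_focus: FocusRecord
    comparator_channel: str
    nn_distance: float | None  # px; None when unmatched
    nn_distance_um: float | None
    class_label: str


def classify_proximity(d: float, thresholds: ProximityThresholds | None = None) -> str:
    """Bin a nearest-neighbour distance (px): overlapping / proximal / distant."""
    thresholds = thresholds or ProximityThresholds()
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d <= thresholds.overlap_max:
        return OVERLAPPING
    if d <= thresholds.proximal_max:
        return PROXIMAL
    return DISTANT


def pixels_to_um(d: float, pixel_scale: float = DEFAULT_PIXEL_SCALE) -> float:
    """Convert a pixel distance to micrometres."""
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    return d * pixel_scale


def nearest_neighbour_distances(
    foci_a: list[FocusRecord],
    foci_b: list[FocusRecord],
    thresholds: ProximityThresholds | None = None,
) -> list[ProximityRecord]:
    """One record per A-focus: distance to its nearest same-nucleus B-focus.

    Ties break toward the lowest B-focus index; A-foci in nuclei with no
    B-foci are labelled ``unmatched``.
    """
    thresholds = thresholds or ProximityThresholds()
    by_nucleus: dict[int, list[tuple[int, FocusRecord]]] = {}
    for j, fb in enumerate(foci_b):
        by_nucleus.setdefault(fb.nucleus_id, []).append((j, fb))

    records = []
    for fa in foci_a:
        candidates = by_nucleus.get(fa.nucleus_id, [])
        if not candidates:
            records.append(
                ProximityRecord(
                    nucleus_id=fa.nucleus_id,
                    source_focus=fa,
                    comparator_channel=foci_b[0].channel_name if foci_b else "",
                    nn_distance=None,
                    nn_distance_um=None,
                    class_label=UNMATCHED,
                )
            )
            continue
        best, d = 0, None
        for k, (_, fb) in enumerate(candidates):
            dk = math.hypot(
                fa.centroid[0] - fb.centroid[0], fa.centroid[1] - fb.centroid[1]
            )
            if d is None or dk < d:  # strict <: ties keep the lowest B index
                best, d = k, dk
        records.append(
            ProximityRecord(
                nucleus_id=fa.nucleus_id,
                source_focus=fa,
                comparator_channel=candidates[best][1].channel_name,
                nn_distance=d,
                nn_distance_um=pixels_to_um(d, thresholds.pixel_scale),
                class_label=classify_proximity(d, thresholds),
            )
        )
    return records


def records_table(records: list[ProximityRecord]) -> pd.DataFrame:
    """Tidy table: one row per proximity record."""
    rows = []
    for r in records:
        rows.append(
            {
                "nucleus_id": r.nucleus_id,
                "source_channel": r.source_focus.channel_name,
                "comparator_channel": r.comparator_channel,
                "source_row": r.source_focus.centroid[0],
                "source_col": r.source_focus.centroid[1],
                "nn_distance_px": r.nn_distance,
                "nn_distance_um": (
                    None if r.nn_distance_um is None else round(r.nn_distance_um, 2)
                ),
                "class": r.class_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "source_channel",
            "comparator_channel",
            "source_row",
            "source_col",
            "nn_distance_px",
            "nn_distance_um",
            "class",
        ],
    )


def summarize_proximity(
    records: list[ProximityRecord],
    gated_ids: set[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell class counts/fractions and a population summary.

    Unmatched foci are excluded from class fractions but reported in their own
    column. The population summary gives, for each class, the mean per-cell
    count and the overall fraction among matched foci, plus the number of
    cells summarized.
    """
    if gated_ids is not None:
        records = [r for r in records if r.nucleus_id in gated_ids]
        cell_ids = sorted(gated_ids)
    else:
        cell_ids = sorted({r.nucleus_id for r in records})

    per_cell_rows = []
    for nid in cell_ids:
        mine = [r for r in records if r.nucleus_id == nid]
        counts = {cls: sum(r.class_label == cls for r in mine) for cls in CLASSES}
        n_unmatched = sum(r.class_label == UNMATCHED for r in mine)
        n_matched = sum(counts.values())
        row = {"nucleus_id": nid, "n_matched": n_matched, "n_unmatched": n_unmatched}
        for cls in CLASSES:
            row[f"n_{cls}"] = counts[cls]
            row[f"frac_{cls}"] = counts[cls] / n_matched if n_matched else np.nan
        per_cell_rows.append(row)
    per_cell = pd.DataFrame(per_cell_rows)

    n_cells = len(cell_ids)
    total_matched = int(per_cell["n_matched"].sum()) if n_cells else 0
    pop_rows = []
    for cls in CLASSES:
        total = int(per_cell[f"n_{cls}"].sum()) if n_cells else 0
        pop_rows.append(
            {
                "class": cls,
                "mean_count_per_cell": total / n_cells if n_cells else np.nan,
                "overall_fraction": total / total_matched if total_matched else np.nan,
                "n_cells": n_cells,
            }
        )
    population = pd.DataFrame(
        pop_rows, columns=["class", "mean_count_per_cell", "overall_fraction", "n_cells"]
    )
    return per_cell, population
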