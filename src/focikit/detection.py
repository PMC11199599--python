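"""Per-nucleus focus detection: mild Gaussian pre-blur, prominence-based local
maxima, size filtering, and gating of the analysis to EGFP-expressing cells.

A local maximum is reported when it cannot be reached from any strictly higher
maximum without descending more than ``prominence`` below its own level; the
globally highest maximum of a mask is measured against the mask minimum, so a
uniform region yields no foci. This is the classical noise-tolerance rule of
interactive spot pickers, implemented here as a topographic-persistence sweep
(union-find over pixels in descending intensity order, 8-connected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoExpressingCellsError, DegenerateHistogramError
from .image import LabelMap
from .segmentation import threshold_image

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class FocusRecord:
    """One detected focus.

    ``centroid`` is the (row, col) plateau centroid, 0-based pixel-center.
    ``prominence`` is the measured topographic prominence (intensity drop to
    the saddle toward higher terrain, or to the mask minimum for the highest
    focus). ``area`` counts pixels above half the focus prominence that are
    8-connected to the maximum within the focus's own watershed basin (so a
    bright neighbour cannot inflate the area across a shallow saddle).
    """

    nucleus_id: int
    channel_name: str
    centroid: tuple[float, float]
    prominence: float
    area: int
    mean_intensity: float


@dataclass
class DetectionParams:
    """Detection tuning: pre-blur sigma, prominence rule, size bounds.

    The prominence cutoff adapts to staining level: ``prominence_k`` times a
    robust (MAD-based) noise SD estimated from the background, floored at
    ``prominence_floor_frac`` of the channel's dynamic range so noiseless
    images still detect.
    """

    blur_sigma: float = 0.8
    prominence_k: float = 5.0
    prominence: float | None = None  # explicit override, intensity units
    prominence_floor_frac: float = 1e-4
    size_min: float = 2.0  # px²
    size_max: float = 50.0  # px²

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.size_min > self.size_max:
            raise ValueError("size_min must be <= size_max")


def preblur(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with reflective boundaries; ``sigma = 0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(channel, dtype=float)
    if sigma == 0:
        return img
    return ndimage.gaussian_filter(img, sigma=sigma, mode="reflect", truncate=6.0)


class _Component:
    __slots__ = ("peak", "min_value", "plateaus")

    def __init__(self, peak: float, pixel: int):
        self.peak = peak
        self.min_value = peak
        # live plateaus at this component's peak level; lists of flat indices
        self.plateaus: list[list[int]] = [[pixel]]


def find_maxima(
    channel: np.ndarray,
    mask: np.ndarray,
    prominence: float,
    nucleus_id: int = 0,
    channel_name: str = "",
) -> list[FocusRecord]:
    """Prominence-filtered local maxima inside a boolean mask.

    Plateaus (8-connected equal-valued maxima) merge into one record at the
    plateau centroid. Adding a constant to the image leaves the result
    unchanged; a uniform image yields no maxima.
    """
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    img = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    h, w = img.shape
    flat = img.ravel()
    idxs = np.flatnonzero(mask.ravel())
    if idxs.size == 0:
        return []
    # descending by value; among equal values order is irrelevant to the result
    order = idxs[np.argsort(-flat[idxs], kind="stable")]

    parent: dict[int, int] = {}
    comps: dict[int, _Component] = {}
    accepted: list[tuple[list[int], float, float]] = []  # (plateau, peak, dynamics)

    def kill_or_keep(plateaus: list[list[int]], peak: float, level: float) -> None:
        dyn = peak - level
        if dyn > prominence:
            for plat in plateaus:
                accepted.append((plat, peak, dyn))

    processed = np.zeros(h * w, dtype=bool)

    for p in order:
        v = flat[p]
        r, c = divmod(int(p), w)
        roots = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    q = rr * w + cc
                    if processed[q]:
                        roots.add(parent_find(parent, q))
        roots = list(roots)
        if not roots:
            parent[p] = p
            comps[p] = _Component(v, int(p))
        else:
            # merge all neighbour components at level v, then attach p
            main = roots[0]
            for other in roots[1:]:
                main = _merge(parent, comps, main, other, v, kill_or_keep)
            comp = comps[main]
            if v == comp.peak:
                # p extends the summit plateau (component is still all at v)
                comp.plateaus[0].append(int(p))
            else:
                if v < comp.min_value:
                    comp.min_value = v
            parent[p] = main
        processed[p] = True

    # survivors: measured against their component minimum
    for root, comp in comps.items():
        if parent[root] == root:
            kill_or_keep(comp.plateaus, comp.peak, comp.min_value)

    basins = _focus_basins(img, mask, [plat for plat, _, _ in accepted])
    records = []
    for k, (plat, peak, dyn) in enumerate(accepted):
        rows = np.array([q // w for q in plat], dtype=float)
        cols = np.array([q % w for q in plat], dtype=float)
        centroid = (float(rows.mean()), float(cols.mean()))
        area, mean_int = _focus_area(img, basins == k + 1, plat, peak, dyn, w)
        records.append(
            FocusRecord(
                nucleus_id=nucleus_id,
                channel_name=channel_name,
                centroid=centroid,
                prominence=float(dyn),
                area=area,
                mean_intensity=mean_int,
            )
        )
    records.sort(key=lambda f: (f.centroid[0], f.centroid[1]))
    return records


def _focus_basins(img, mask, plateaus):
    """Assign every mask pixel to one accepted maximum (watershed basins),
    so focus areas cannot bleed into a neighbouring focus."""
    from skimage.segmentation import watershed

    markers = np.zeros(img.shape, dtype=np.int32)
    for k, plat in enumerate(plateaus):
        for q in plat:
            markers[q // img.shape[1], q % img.shape[1]] = k + 1
    if not plateaus:
        return markers
    return watershed(-img, markers=markers, mask=mask, connectivity=2)


def _merge(parent, comps, r1: int, r2: int, level: float, kill_or_keep) -> int:
    r1, r2 = parent_find(parent, r1), parent_find(parent, r2)
    if r1 == r2:
        return r1
    c1, c2 = comps[r1], comps[r2]
    if c1.peak < c2.peak or (c1.peak == c2.peak and r1 > r2):
        r1, r2, c1, c2 = r2, r1, c2, c1
    # c1 is the (equal or) higher-peaked survivor
    if c2.peak < c1.peak:
        kill_or_keep(c2.plateaus, c2.peak, level)
    else:
        if level == c1.peak:
            # plateau fragments connected through a summit-level pixel: one maximum
            c1.plateaus[0].extend(pix for plat in c2.plateaus for pix in plat)
        else:
            c1.plateaus.extend(c2.plateaus)
    c1.min_value = min(c1.min_value, c2.min_value, level)
    parent[r2] = r1
    del comps[r2]
    return r1


def parent_find(parent: dict, x: int) -> int:
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


def _focus_area(img, basin, plateau, peak, dynamics, w):
    """Pixels above half the focus prominence, 8-connected to the maximum
    within the focus's own basin."""
    cut = peak - 0.5 * dynamics
    above = (img > cut) & basin
    lab, _ = ndimage.label(above, structure=_EIGHT)
    seed = plateau[0]
    comp_id = lab[seed // w, seed % w]
    comp = lab == comp_id
    return int(comp.sum()), float(img[comp].mean())


def robust_noise_sd(values: np.ndarray) -> float:
    """MAD-based noise SD: 1.4826 × median absolute deviation."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def choose_prominence(channel: np.ndarray, label_map: LabelMap, params: DetectionParams) -> float:
    """Prominence cutoff: k × background noise SD, floored at a fraction of range."""
    if params.prominence is not None:
        return params.prominence
    img = np.asarray(channel, dtype=float)
    bg = img[label_map.labels == 0]
    sd = robust_noise_sd(bg if bg.size else img)
    span = float(img.max() - img.min())
    floor = params.prominence_floor_frac * span if span > 0 else 1e-12
    return max(params.prominence_k * sd, floor, 1e-12)


def detect_foci(
    channel: np.ndarray,
    label_map: LabelMap,
    params: DetectionParams | None = None,
    channel_name: str = "",
    nucleus_ids: list[int] | None = None,
) -> list[FocusRecord]:
    """Blur, pick prominence, run find_maxima per nucleus, size-filter."""
    params = params or DetectionParams()
    blurred = preblur(channel, params.blur_sigma)
    prom = choose_prominence(blurred, label_map, params)
    ids = nucleus_ids if nucleus_ids is not None else label_map.label_ids
    foci: list[FocusRecord] = []
    for nid in ids:
        foci.extend(
            find_maxima(
                blurred,
                label_map.mask(nid),
                prom,
                nucleus_id=nid,
                channel_name=channel_name,
            )
        )
    return filter_foci(foci, params)


def filter_foci(foci: list[FocusRecord], params: DetectionParams) -> list[FocusRecord]:
    """Retain foci with ``size_min <= area <= size_max``; order preserved."""
    return [f for f in foci if params.size_min <= f.area <= params.size_max]


def gate_expressing_cells(
    egfp_channel: np.ndarray,
    label_map: LabelMap,
) -> set[int]:
    """Nuclei whose mean EGFP exceeds the Huang threshold of the whole channel.

    Raises :class:`NoExpressingCellsError` when the EGFP channel carries no
    contrast (single occupied intensity level).
    """
    if label_map.n_labels == 0:
        return set()
    img = np.asarray(egfp_channel, dtype=float)
    try:
        fg = threshold_image(img)
    except DegenerateHistogramError as exc:
        raise NoExpressingCellsError(
            f"no expressing cells: EGFP channel has no contrast ({exc})"
        ) from exc
    # recover the threshold in intensity units from the foreground mask
    threshold_value = img[fg].min() if fg.any() else img.max()
    passing = set()
    for nid in label_map.label_ids:
        if img[label_map.mask(nid)].mean() >= threshold_value:
            passing.add(nid)
    return passing


def count_foci(foci: list[FocusRecord], gated_ids: set[int]):
    """Per-cell focus counts over gated cells, plus the population mean.

    Returns ``(table, mean)`` where the table has one row per gated cell and
    ``mean`` is total foci / number of gated cells, or None when no cell
    passed the gate (missing, not zero).
    """
    import pandas as pd

    ids = sorted(gated_ids)
    counts = {nid: 0 for nid in ids}
    for f in foci:
        if f.nucleus_id in counts:
            counts[f.nucleus_id] += 1
    table = pd.DataFrame(
        {"nucleus_id": ids, "n_foci": [counts[i] for i in ids]},
        columns=["nucleus_id", "n_foci"],
    )
    mean = float(table["n_foci"].mean()) if ids else None
    return table, mean
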