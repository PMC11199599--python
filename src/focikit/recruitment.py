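"""Recruitment kinetics at laser-microirradiation stripes.

For each cell, mean fluorescence is extracted from a damage ROI superimposed
on the stripe and from a control ROI elsewhere in the same cell, both
normalized by their pre-damage baseline F(-). The double-normalized ratio

    R(t) = [F(t)/F(-)]_damage / [F(t)/F(-)]_control

cancels uniform photobleaching and global intensity drift; active recruitment
gives R > 1 while no or passive recruitment gives R <= 1. Curves are averaged
across cells (mean ± SEM) and can be fitted with the saturating exponential
R(t) = 1 + A·(1 − exp(−(t − t_dmg)/τ)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AlignmentError,
    GeometryError,
    InsufficientDataError,
    NormalizationError,
)
from .image import Rect, TimeLapse

#: damage is initiated after frame 5, so frames 0..4 are the baseline
DEFAULT_BASELINE_FRAMES = range(0, 5)


@dataclass
class RoiPair:
    """Damage and control rectangles for one cell; must be disjoint."""

    damage_roi: Rect
    control_roi: Rect
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        if self.damage_roi.overlaps(self.control_roi):
            raise ValueError("damage and control ROIs must be disjoint")


@dataclass
class RecruitmentTrace:
    """Per-cell ROI intensity time series and (after normalization) R(t)."""

    t: np.ndarray  # seconds per frame
    f_bleach: np.ndarray  # mean intensity in the damage ROI
    f_control: np.ndarray  # mean intensity in the control ROI
    nucleus_id: int = 0
    baseline_frames: list[int] = field(default_factory=list)
    f_minus_bleach: float | None = None
    f_minus_control: float | None = None
    ratio: np.ndarray | None = None  # R(t)

    @property
    def n_frames(self) -> int:
        return len(self.t)


@dataclass
class AggregateCurve:
    """Cross-cell mean recruitment curve with per-frame SEM."""

    t: np.ndarray
    mean_ratio: np.ndarray
    sem: np.ndarray  # NaN when n == 1
    n: int


@dataclass
class KineticFit:
    """Saturating-exponential fit of an aggregate recruitment curve."""

    amplitude: float  # plateau gain A
    tau: float  # seconds
    rss: float
    converged: bool


def extract_traces(movie: TimeLapse, roi_pair: RoiPair) -> RecruitmentTrace:
    """Per-frame mean intensity over the damage and control ROIs."""
    shape = movie.frames.shape[1:]
    for name, roi in (("damage", roi_pair.damage_roi), ("control", roi_pair.control_roi)):
        if not roi.within(shape):
            raise GeometryError(f"{name} ROI {roi} lies outside the {shape} frame")
    dr, dc = roi_pair.damage_roi.slices
    cr, cc = roi_pair.control_roi.slices
    return RecruitmentTrace(
        t=movie.times,
        f_bleach=movie.frames[:, dr, dc].mean(axis=(1, 2)),
        f_control=movie.frames[:, cr, cc].mean(axis=(1, 2)),
        nucleus_id=roi_pair.nucleus_id,
    )


def normalize_trace(
    trace: RecruitmentTrace,
    baseline_frames=DEFAULT_BASELINE_FRAMES,
) -> RecruitmentTrace:
    """Compute the double-normalized ratio R(t) from baseline means F(-).

    Baseline means are taken over ``baseline_frames`` (default: the five
    pre-damage frames). Zero or negative baseline means raise
    :class:`NormalizationError` (empty ROI or saturated detector).
    """
    frames = list(baseline_frames)
    if not frames:
        raise NormalizationError("baseline_frames must be non-empty")
    if max(frames) >= trace.n_frames or min(frames) < 0:
        raise NormalizationError("baseline_frames outside the trace")
    f_minus_bleach = float(trace.f_bleach[frames].mean())
    f_minus_control = float(trace.f_control[frames].mean())
    if f_minus_bleach <= 0 or f_minus_control <= 0:
        raise NormalizationError(
            f"non-positive baseline mean (damage {f_minus_bleach}, control "
            f"{f_minus_control}); check ROI placement and detector offset"
        )
    ratio = (trace.f_bleach / f_minus_bleach) / (trace.f_control / f_minus_control)
    return RecruitmentTrace(
        t=trace.t,
        f_bleach=trace.f_bleach,
        f_control=trace.f_control,
        nucleus_id=trace.nucleus_id,
        baseline_frames=frames,
        f_minus_bleach=f_minus_bleach,
        f_minus_control=f_minus_control,
        ratio=ratio,
    )


def aggregate_curves(traces: list[RecruitmentTrace]) -> AggregateCurve:
    """Pointwise mean and SEM (sd/√n, sample SD) across cells.

    Frames are aligned by index (a common protocol is assumed); unequal trace
    lengths raise :class:`AlignmentError`. With a single trace the SEM is
    reported as NaN (missing), not zero.
    """
    if not traces:
        raise AlignmentError("no traces to aggregate")
    lengths = {tr.n_frames for tr in traces}
    if len(lengths) != 1:
        raise AlignmentError(f"traces have unequal lengths: {sorted(lengths)}")
    for tr in traces:
        if tr.ratio is None:
            raise ValueError("traces must be normalized before aggregation")
    ratios = np.stack([tr.ratio for tr in traces])
    n = len(traces)
    mean = ratios.mean(axis=0)
    sem = (
        ratios.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.full(ratios.shape[1], np.nan)
    )
    return AggregateCurve(t=traces[0].t.copy(), mean_ratio=mean, sem=sem, n=n)


def classify_recruitment(curve: AggregateCurve, window: int = 10) -> str:
    """Label a mean curve ``"active"`` or ``"none"``.

    Active when the mean ratio over the final ``window`` frames exceeds
    1 + 2×SEM of that window mean (SEM of the window mean approximated as the
    mean per-frame SEM / √window; treated as 0 when unavailable), enforcing
    the strict R > 1 criterion at the boundary.
    """
    if window <= 0 or window > len(curve.mean_ratio):
        raise ValueError("window must be in 1..n_frames")
    tail = curve.mean_ratio[-window:]
    tail_sem = curve.sem[-window:]
    window_mean = float(tail.mean())
    if np.all(np.isnan(tail_sem)):
        window_sem = 0.0
    else:
        window_sem = float(np.nanmean(tail_sem)) / np.sqrt(window)
    return "active" if window_mean > 1.0 + 2.0 * window_sem else "none"


def fit_kinetics(
    curve: AggregateCurve,
    damage_frame: int = 5,
    tau_grid: tuple[float, ...] = (15.0, 60.0, 120.0, 300.0, 600.0),
) -> KineticFit:
    """Least-squares fit of R(t) = 1 + A·(1 − exp(−(t − t_dmg)/τ)).

    Fits the post-damage frames only, multi-starting τ over ``tau_grid`` and
    keeping the best residual sum of squares. Fewer than 4 post-damage frames
    raise :class:`InsufficientDataError`.
    """
    t = np.asarray(curve.t, dtype=float)
    r = np.asarray(curve.mean_ratio, dtype=float)
    if damage_frame < 0 or damage_frame >= len(t):
        raise ValueError("damage_frame outside the curve")
    t_dmg = t[damage_frame]
    post = t >= t_dmg
    if post.sum() < 4:
        raise InsufficientDataError(
            f"only {int(post.sum())} post-damage frames; need at least 4"
        )
    dt = t[post] - t_dmg
    y = r[post]

    def residuals(params):
        a, log_tau = params
        return 1.0 + a * (1.0 - np.exp(-dt / np.exp(log_tau))) - y

    a0 = max(float(y[-min(5, len(y)):].mean() - 1.0), 0.0)
    best = None
    for tau0 in tau_grid:
        res = least_squares(
            residuals,
            x0=[a0, np.log(tau0)],
            bounds=([-1.0, np.log(1e-3)], [np.inf, np.log(1e6)]),
            xtol=1e-12,
            ftol=1e-12,
        )
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    rss, res = best
    return KineticFit(
        amplitude=float(res.x[0]),
        tau=float(np.exp(res.x[1])),
        rss=rss,
        converged=bool(res.success),
    )


def auto_place_control(
    nucleus_mask: np.ndarray,
    damage_roi: Rect,
    clearance_px: int = 5,
    nucleus_id: int = 0,
) -> RoiPair:
    """Place the control ROI automatically inside the same nucleus.

    The control is the largest axis-aligned rectangle inscribed in the
    nucleus mask minus the damage ROI dilated by ``clearance_px``.
    """
    allowed = np.asarray(nucleus_mask, dtype=bool).copy()
    rs = slice(
        max(0, damage_roi.row0 - clearance_px),
        damage_roi.row0 + damage_roi.height + clearance_px,
    )
    cs = slice(
        max(0, damage_roi.col0 - clearance_px),
        damage_roi.col0 + damage_roi.width + clearance_px,
    )
    allowed[rs, cs] = False
    rect = _largest_rectangle(allowed)
    if rect is None:
        raise GeometryError(
            "no room for a control ROI in the nucleus outside the damage stripe"
        )
    return RoiPair(damage_roi=damage_roi, control_roi=rect, nucleus_id=nucleus_id)


def _largest_rectangle(mask: np.ndarray) -> Rect | None:
    """Largest axis-aligned all-True rectangle (histogram-stack method)."""
    h, w = mask.shape
    heights = np.zeros(w, dtype=int)
    best_area = 0
    best: Rect | None = None
    for i in range(h):
        heights = np.where(mask[i], heights + 1, 0)
        stack: list[int] = []
        j = 0
        while j <= w:
            cur = heights[j] if j < w else 0
            if not stack or cur >= heights[stack[-1]]:
                stack.append(j)
                j += 1
            else:
                top = stack.pop()
                height = heights[top]
                left = stack[-1] + 1 if stack else 0
                area = height * (j - left)
                if area > best_area:
                    best_area = area
                    best = Rect(row0=i - height + 1, col0=left, height=int(height), width=j - left)
    return best
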