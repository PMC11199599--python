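"""Ground-truthed synthetic fluorescence microscopy.

Renders Hoechst-stained nuclei (optionally touching), diffraction-limited foci
placed at controlled cross-channel distances, EGFP-expressing versus
non-expressing cells, and laser-stripe time-lapse movies in which recruitment
to a rectangular damage ROI starts after a configurable baseline, on top of
whole-cell exponential photobleaching and Poisson + Gaussian camera noise.

Every scene carries a :class:`SyntheticTruth` record (nucleus label map, focus
positions and pairwise distances, kinetic parameters) so downstream detection,
proximity classification and recruitment quantification can be validated
against known ground truth.

The recruitment model applied inside the damage stripe is

    S(t) = B(t) · [1 + A·(1 − exp(−(t − t_dmg)/τ))]   for t ≥ t_dmg,

with ``S(t) = B(t)`` before damage and ``B(t) = B0·exp(−bleach_rate·t)``
applied to the whole cell. Because bleaching is multiplicative and uniform, it
cancels exactly in the double-normalized damage/control ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, PlacementError
from .image import MultiChannelImage, Rect, TimeLapse

# Default focus PSF: 6 px focus diameter read as the FWHM of an isotropic
# Gaussian, sigma = FWHM / (2*sqrt(2*ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
DEFAULT_FOCUS_FWHM_PX = 6.0
DEFAULT_FOCUS_SIGMA_PX = DEFAULT_FOCUS_FWHM_PX * FWHM_TO_SIGMA  # ~2.548 px

HOECHST = "hoechst"
EGFP = "egfp"


@dataclass
class NoiseSpec:
    """Camera noise model: Poisson shot noise, then Gaussian read noise, then offset.

    ``poisson_scale`` is the photon count corresponding to one intensity unit
    (0 disables shot noise); ``read_noise_sd`` is the SD of additive Gaussian
    noise in intensity units; ``offset`` is a constant detector offset.
    """

    poisson_scale: float = 0.0
    read_noise_sd: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.read_noise_sd < 0 or self.offset < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def is_noiseless(self) -> bool:
        return self.poisson_scale == 0 and self.read_noise_sd == 0 and self.offset == 0


def noise_for_snr(amplitude: float, snr: float) -> NoiseSpec:
    """Gaussian read noise giving peak SNR ``amplitude / read_noise_sd = snr``."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return NoiseSpec(poisson_scale=0.0, read_noise_sd=amplitude / snr, offset=0.0)


@dataclass
class SceneSpec:
    """Parameters of one synthetic multi-nucleus field of view."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_scale: float = 0.11  # µm/px
    n_nuclei: int = 5
    nucleus_radius_range: tuple[float, float] = (18.0, 28.0)  # px
    allow_touching: bool = False
    background_level: float = 2.0
    nucleus_amplitude: float = 100.0
    egfp_fraction: float = 1.0  # fraction of nuclei with diffuse EGFP expression
    egfp_level: float = 20.0
    edge_falloff_px: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus_radius_range must be positive and ordered")
        if not 0.0 <= self.egfp_fraction <= 1.0:
            raise ValueError("egfp_fraction must be in [0, 1]")


@dataclass
class NucleusSpec:
    """One rendered nucleus: ellipse geometry plus channel amplitudes."""

    nucleus_id: int
    center: tuple[float, float]  # (row, col), px
    radii: tuple[float, float]  # semi-axes (row-wise, col-wise), px
    orientation: float  # radians
    amplitude: float
    egfp_level: float = 0.0

    def normalized_distance(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Elliptical norm: <=1 inside the nucleus."""
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = c * dr + s * dc
        v = -s * dr + c * dc
        return np.sqrt((u / self.radii[0]) ** 2 + (v / self.radii[1]) ** 2)

    def contains(self, row: float, col: float, margin: float = 0.0) -> bool:
        d = self.normalized_distance(np.asarray(row, float), np.asarray(col, float))
        return bool(d <= 1.0 - margin)


@dataclass
class FocusSpec:
    """One true focus: Gaussian spot inside its owning nucleus."""

    nucleus_id: int
    channel_name: str
    position: tuple[float, float]  # (row, col), px
    psf_sigma: float = DEFAULT_FOCUS_SIGMA_PX
    amplitude: float = 100.0
    paired_with: tuple[str, float] | None = None  # (channel, distance px)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.paired_with is not None and self.paired_with[1] < 0:
            raise ValueError("paired distance must be >= 0")


@dataclass
class KineticsSpec:
    """Laser-stripe protocol and recruitment kinetics.

    Defaults follow the acquisition protocol: 80 frames at 15 s intervals with
    damage initiated after frame 5, and a 6.5 µm × 1 µm damage stripe.
    """

    amplitude: float = 1.0  # plateau gain A of the normalized ratio
    tau: float = 120.0  # s
    bleach_rate: float = 0.0  # per second, whole-cell
    damage_frame: int = 5  # number of pre-damage frames
    n_frames: int = 80
    frame_interval: float = 15.0  # s
    stripe_length: float = 6.5  # µm
    stripe_width: float = 1.0  # µm

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.damage_frame < self.n_frames:
            raise ValueError("damage_frame must lie before n_frames")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def t_damage(self) -> float:
        """Damage onset time in seconds (end of the baseline frames)."""
        return self.damage_frame * self.frame_interval

    def ratio(self, t: np.ndarray | float) -> np.ndarray | float:
        """Closed-form double-normalized ratio R(t) of the generative model."""
        t = np.asarray(t, dtype=float)
        dt = np.clip(t - self.t_damage, 0.0, None)
        r = 1.0 + self.amplitude * (1.0 - np.exp(-dt / self.tau))
        r = np.where(t < self.t_damage, 1.0, r)
        return r if r.ndim else float(r)


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for one rendered scene or movie."""

    nuclei: list[NucleusSpec]
    nucleus_masks: np.ndarray  # label map, 0 = background
    pixel_scale: float
    foci: list[FocusSpec] = field(default_factory=list)
    pair_distances: list[tuple[int, int, float]] = field(default_factory=list)
    kinetics: KineticsSpec | None = None
    damage_roi: Rect | None = None
    background_level: float = 0.0
    seed: int = 0

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def nucleus(self, nucleus_id: int) -> NucleusSpec:
        for nuc in self.nuclei:
            if nuc.nucleus_id == nucleus_id:
                return nuc
        raise KeyError(f"no nucleus with id {nucleus_id}")

    def expressing_ids(self) -> set[int]:
        return {n.nucleus_id for n in self.nuclei if n.egfp_level > 0}

    def verify_pair_distances(self, atol: float = 1e-9) -> None:
        for ia, ib, d in self.pair_distances:
            pa = np.asarray(self.foci[ia].position)
            pb = np.asarray(self.foci[ib].position)
            actual = float(np.hypot(*(pa - pb)))
            if abs(actual - d) > atol:
                raise AssertionError(
                    f"pair distance mismatch: recorded {d}, recomputed {actual}"
                )


def _sub_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-step generator derived from a single global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def generate_nuclei_scene(spec: SceneSpec) -> tuple[MultiChannelImage, SyntheticTruth]:
    """Place and render elliptical nuclei; return Hoechst image plus truth.

    Placement is rejection-sampled; when ``allow_touching`` is False, nuclei
    must keep a one-pixel gap between bounding circles, and failure to place
    all nuclei raises :class:`PlacementError`.
    """
    rng = _sub_rng(spec.seed, 0)
    h, w = spec.image_shape
    lo, hi = spec.nucleus_radius_range

    nuclei: list[NucleusSpec] = []
    max_attempts = 500 * max(spec.n_nuclei, 1)
    attempts = 0
    while len(nuclei) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_nuclei} non-touching nuclei of radius "
                f"{spec.nucleus_radius_range} px in a {h}x{w} image after "
                f"{max_attempts} attempts (allow_touching={spec.allow_touching})"
            )
        attempts += 1
        r_a = rng.uniform(lo, hi)
        r_b = rng.uniform(lo, hi)
        r_max = max(r_a, r_b)
        if 2 * r_max + 2 > min(h, w):
            raise PlacementError(
                f"nucleus radius {r_max:.1f} px cannot fit in a {h}x{w} image"
            )
        center = (
            rng.uniform(r_max + 1, h - r_max - 1),
            rng.uniform(r_max + 1, w - r_max - 1),
        )
        if not spec.allow_touching:
            too_close = any(
                math.hypot(center[0] - n.center[0], center[1] - n.center[1])
                < r_max + max(n.radii) + 1.0
                for n in nuclei
            )
            if too_close:
                continue
        expressing = rng.uniform() < spec.egfp_fraction
        nuclei.append(
            NucleusSpec(
                nucleus_id=len(nuclei) + 1,
                center=center,
                radii=(r_a, r_b),
                orientation=rng.uniform(0, math.pi),
                amplitude=spec.nucleus_amplitude,
                egfp_level=spec.egfp_level if expressing else 0.0,
            )
        )

    labels = _label_map(nuclei, spec.image_shape, spec.edge_falloff_px)
    truth = SyntheticTruth(
        nuclei=nuclei,
        nucleus_masks=labels,
        pixel_scale=spec.pixel_scale,
        background_level=spec.background_level,
        seed=spec.seed,
    )
    image = render_channels(truth, spec.noise, seed=spec.seed)
    return image, truth


def _label_map(
    nuclei: list[NucleusSpec], shape: tuple[int, int], falloff_px: float = 2.0
) -> np.ndarray:
    """Assign each pixel to its nearest nucleus (elliptical norm).

    The truth boundary is drawn at the 50%-intensity contour of the rendered
    rim falloff (the FWHM convention), i.e. at normalized distance
    ``1 - falloff/2`` rather than at the zero-intensity edge.
    """
    labels = np.zeros(shape, dtype=np.int32)
    if not nuclei:
        return labels
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    best = np.full(shape, np.inf)
    for nuc in nuclei:
        d = nuc.normalized_distance(rows, cols)
        edge = 1.0 - 0.5 * falloff_px / min(nuc.radii)
        take = (d <= edge) & (d < best)
        labels[take] = nuc.nucleus_id
        best = np.where(take, d, best)
    return labels


def _nucleus_profile(nuc: NucleusSpec, shape: tuple[int, int], falloff_px: float) -> np.ndarray:
    """Unit-amplitude nucleus footprint: flat interior, smooth rim falloff."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = nuc.normalized_distance(rows, cols)
    f = max(falloff_px / min(nuc.radii), 1e-6)
    t = np.clip((1.0 - d) / f, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)  # smoothstep


def render_channels(
    truth: SyntheticTruth,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    channel_names: list[str] | None = None,
    edge_falloff_px: float = 2.0,
) -> MultiChannelImage:
    """Render Hoechst plus every focus channel from a truth record.

    Each focus becomes an isotropic Gaussian spot of its amplitude and sigma;
    diffuse nuclear EGFP (for expression gating) fills expressing nuclei in
    the ``egfp`` channel. Poisson noise is applied first, then Gaussian read
    noise and detector offset; output pixels are clipped at zero.
    """
    noise = noise or NoiseSpec()
    seed = truth.seed if seed is None else seed
    shape = truth.nucleus_masks.shape

    names: list[str] = [HOECHST]
    if any(n.egfp_level > 0 for n in truth.nuclei):
        names.append(EGFP)
    for f in truth.foci:
        if f.channel_name not in names:
            names.append(f.channel_name)
    for extra in channel_names or []:
        if extra not in names:
            names.append(extra)

    channels = {
        name: np.full(shape, truth.background_level, dtype=float) for name in names
    }
    for nuc in truth.nuclei:
        profile = None
        if nuc.amplitude > 0:
            profile = _nucleus_profile(nuc, shape, edge_falloff_px)
            channels[HOECHST] += nuc.amplitude * profile
        if nuc.egfp_level > 0:
            if profile is None:
                profile = _nucleus_profile(nuc, shape, edge_falloff_px)
            channels[EGFP] += nuc.egfp_level * profile

    for f in truth.foci:
        if f.amplitude != 0:
            channels[f.channel_name] += _gaussian_spot(
                shape, f.position, f.psf_sigma, f.amplitude
            )

    for i, name in enumerate(names):
        channels[name] = _apply_noise(channels[name], noise, _sub_rng(seed, 1, i))

    return MultiChannelImage(channels=channels, pixel_scale=truth.pixel_scale)


def _gaussian_spot(
    shape: tuple[int, int],
    position: tuple[float, float],
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    """Isotropic 2D Gaussian sampled at pixel centers, truncated at 6 sigma."""
    r0, c0 = position
    reach = int(math.ceil(6 * sigma))
    rlo, rhi = max(0, int(r0) - reach), min(shape[0], int(r0) + reach + 1)
    clo, chi = max(0, int(c0) - reach), min(shape[1], int(c0) + reach + 1)
    out = np.zeros(shape)
    if rlo >= rhi or clo >= chi:
        return out
    rows, cols = np.mgrid[rlo:rhi, clo:chi]
    out[rlo:rhi, clo:chi] = amplitude * np.exp(
        -((rows - r0) ** 2 + (cols - c0) ** 2) / (2.0 * sigma**2)
    )
    return out


def _apply_noise(img: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    out = img
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
    if noise.offset > 0:
        out = out + noise.offset
    return np.clip(np.asarray(out, dtype=float), 0.0, None)


def scene_from_nuclei(
    nuclei: list[NucleusSpec],
    image_shape: tuple[int, int],
    pixel_scale: float = 0.11,
    background_level: float = 2.0,
    edge_falloff_px: float = 2.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a truth record from hand-placed nuclei (for controlled geometry)."""
    return SyntheticTruth(
        nuclei=list(nuclei),
        nucleus_masks=_label_map(list(nuclei), image_shape, edge_falloff_px),
        pixel_scale=pixel_scale,
        background_level=background_level,
        seed=seed,
    )


def place_focus_pairs(
    truth: SyntheticTruth,
    channel_a: str,
    channel_b: str,
    distances_px: list[float],
    amplitude: float = 100.0,
    psf_sigma: float = DEFAULT_FOCUS_SIGMA_PX,
    min_separation_px: float = 8.0,
    one_pair_per_nucleus: bool = False,
    snap_to_pixel: bool = False,
    seed: int | None = None,
) -> SyntheticTruth:
    """Add one A/B focus pair per requested centroid distance.

    Both members of a pair land inside the same nucleus and the recorded pair
    distance equals the request to within 1e-9 px. Pairs are kept at least
    ``min_separation_px`` away from previously placed foci in the same channel
    so that every pair remains individually resolvable; with
    ``one_pair_per_nucleus`` each nucleus hosts at most one pair, making the
    paired focus the guaranteed nearest neighbour. Raises
    :class:`PlacementError` when a distance cannot fit in any nucleus.

    With ``snap_to_pixel`` both centroids are rounded to pixel centers, so a
    noiseless pixel-grid detector can recover them exactly; the *recorded*
    pair distance is then the post-snap separation, which may differ from the
    request by up to ~0.7 px (the truth record stays self-consistent).
    """
    rng = _sub_rng(truth.seed if seed is None else seed, 2, len(truth.foci))
    foci = list(truth.foci)
    pair_distances = list(truth.pair_distances)
    used_nuclei = {f.nucleus_id for f in foci} if one_pair_per_nucleus else set()

    for d in distances_px:
        if d < 0:
            raise ValueError("pair distance must be >= 0")
        placed = False
        order = rng.permutation(len(truth.nuclei))
        for idx in order:
            nuc = truth.nuclei[idx]
            if one_pair_per_nucleus and nuc.nucleus_id in used_nuclei:
                continue
            margin = 3.0 / min(nuc.radii)  # keep spots off the rim falloff
            if d >= 2 * min(nuc.radii) - 6.0:
                continue
            for _ in range(500):
                theta = rng.uniform(0, 2 * math.pi)
                pa = _random_point_in_ellipse(nuc, rng, margin)
                pb = (pa[0] + d * math.cos(theta), pa[1] + d * math.sin(theta))
                if snap_to_pixel:
                    pa = (float(round(pa[0])), float(round(pa[1])))
                    pb = (float(round(pb[0])), float(round(pb[1])))
                if not nuc.contains(pa[0], pa[1], margin) or not nuc.contains(
                    pb[0], pb[1], margin
                ):
                    continue
                if not _clear_of(foci, pa, channel_a, min_separation_px) or not _clear_of(
                    foci, pb, channel_b, min_separation_px
                ):
                    continue
                ia = len(foci)
                foci.append(
                    FocusSpec(
                        nucleus_id=nuc.nucleus_id,
                        channel_name=channel_a,
                        position=pa,
                        psf_sigma=psf_sigma,
                        amplitude=amplitude,
                        paired_with=(channel_b, d),
                    )
                )
                foci.append(
                    FocusSpec(
                        nucleus_id=nuc.nucleus_id,
                        channel_name=channel_b,
                        position=pb,
                        psf_sigma=psf_sigma,
                        amplitude=amplitude,
                        paired_with=(channel_a, d),
                    )
                )
                actual = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
                pair_distances.append((ia, ia + 1, actual))
                used_nuclei.add(nuc.nucleus_id)
                placed = True
                break
            if placed:
                break
        if not placed:
            raise PlacementError(
                f"no nucleus can host a focus pair at distance {d} px "
                f"(radius range of placed nuclei too small or field too crowded)"
            )

    new_truth = replace(truth, foci=foci, pair_distances=pair_distances)
    new_truth.verify_pair_distances()
    return new_truth


def _random_point_in_ellipse(
    nuc: NucleusSpec, rng: np.random.Generator, margin: float
) -> tuple[float, float]:
    for _ in range(1000):
        u = rng.uniform(-1, 1)
        v = rng.uniform(-1, 1)
        if u * u + v * v > (1 - margin) ** 2:
            continue
        c, s = math.cos(nuc.orientation), math.sin(nuc.orientation)
        dr = u * nuc.radii[0]
        dc = v * nuc.radii[1]
        return (nuc.center[0] + c * dr - s * dc, nuc.center[1] + s * dr + c * dc)
    raise PlacementError("could not sample a point inside the nucleus")


def _clear_of(
    foci: list[FocusSpec], pos: tuple[float, float], channel: str, min_sep: float
) -> bool:
    return all(
        math.hypot(pos[0] - f.position[0], pos[1] - f.position[1]) >= min_sep
        for f in foci
        if f.channel_name == channel
    )


def place_random_foci(
    truth: SyntheticTruth,
    channel: str,
    n_per_nucleus: int,
    amplitude: float = 100.0,
    psf_sigma: float = DEFAULT_FOCUS_SIGMA_PX,
    min_separation_px: float = 8.0,
    nucleus_ids: list[int] | None = None,
    seed: int | None = None,
) -> SyntheticTruth:
    """Scatter ``n_per_nucleus`` unpaired foci inside each (selected) nucleus."""
    rng = _sub_rng(truth.seed if seed is None else seed, 3, len(truth.foci))
    foci = list(truth.foci)
    targets = nucleus_ids if nucleus_ids is not None else [n.nucleus_id for n in truth.nuclei]
    for nid in targets:
        nuc = truth.nucleus(nid)
        margin = 3.0 / min(nuc.radii)
        for _ in range(n_per_nucleus):
            for _ in range(500):
                p = _random_point_in_ellipse(nuc, rng, margin)
                if _clear_of(foci, p, channel, min_separation_px):
                    foci.append(
                        FocusSpec(
                            nucleus_id=nid,
                            channel_name=channel,
                            position=p,
                            psf_sigma=psf_sigma,
                            amplitude=amplitude,
                        )
                    )
                    break
            else:
                raise PlacementError(
                    f"could not place {n_per_nucleus} foci with separation "
                    f"{min_separation_px} px in nucleus {nid}"
                )
    return replace(truth, foci=foci)


def default_stripe_scene(
    seed: int,
    snr: float | None = None,
    egfp_level: float = 100.0,
) -> SceneSpec:
    """Canonical single-cell scene for stripe movies.

    One nucleus large enough to host the 6.5 × 1 µm damage stripe at the
    0.1 µm/px acquisition scale. ``snr`` sets Gaussian read noise relative to
    the diffuse nuclear EGFP level (peak SNR = egfp_level / read_noise_sd);
    None renders noiselessly.
    """
    noise = noise_for_snr(egfp_level, snr) if snr is not None else NoiseSpec()
    return SceneSpec(
        image_shape=(128, 128),
        pixel_scale=0.1,
        n_nuclei=1,
        nucleus_radius_range=(45.0, 50.0),
        background_level=2.0,
        egfp_fraction=1.0,
        egfp_level=egfp_level,
        noise=noise,
        seed=seed,
    )


def generate_stripe_movie(
    kinetics: KineticsSpec,
    scene: SceneSpec,
) -> tuple[TimeLapse, SyntheticTruth]:
    """Simulate a laser-stripe recruitment movie for one cell.

    The damage ROI is a ``stripe_length × stripe_width`` (µm) rectangle
    centered on the largest generated nucleus; it must fit inside that nucleus
    or :class:`GeometryError` is raised. Frames before ``damage_frame`` carry
    no recruitment signal; afterwards the stripe intensity follows the
    saturating-exponential model on top of whole-cell bleaching.
    """
    spec = replace(scene, noise=NoiseSpec())  # noise is applied per frame below
    _, truth = generate_nuclei_scene(spec)
    if not truth.nuclei:
        raise GeometryError("stripe movie requires at least one nucleus")

    nuc = max(truth.nuclei, key=lambda n: min(n.radii))
    length_px = max(1, int(round(kinetics.stripe_length / scene.pixel_scale)))
    width_px = max(1, int(round(kinetics.stripe_width / scene.pixel_scale)))
    roi = Rect(
        row0=int(round(nuc.center[0] - width_px / 2)),
        col0=int(round(nuc.center[1] - length_px / 2)),
        height=width_px,
        width=length_px,
    )
    corners = [
        (roi.row0, roi.col0),
        (roi.row0, roi.col0 + roi.width - 1),
        (roi.row0 + roi.height - 1, roi.col0),
        (roi.row0 + roi.height - 1, roi.col0 + roi.width - 1),
    ]
    falloff_margin = (scene.edge_falloff_px + 1.0) / min(nuc.radii)
    if not roi.within(scene.image_shape) or not all(
        nuc.contains(r, c, falloff_margin) for r, c in corners
    ):
        raise GeometryError(
            f"{kinetics.stripe_length}x{kinetics.stripe_width} µm stripe "
            f"({length_px}x{width_px} px) does not fit inside the nucleus "
            f"(semi-axes {nuc.radii[0]:.1f}x{nuc.radii[1]:.1f} px)"
        )

    base = np.full(scene.image_shape, scene.background_level, dtype=float)
    for n in truth.nuclei:
        level = n.egfp_level if n.egfp_level > 0 else n.amplitude
        base += level * _nucleus_profile(n, scene.image_shape, scene.edge_falloff_px)

    times = np.arange(kinetics.n_frames) * kinetics.frame_interval
    ratio = np.asarray(kinetics.ratio(times))
    frames = np.empty((kinetics.n_frames, *scene.image_shape))
    rs, cs = roi.slices
    for i, t in enumerate(times):
        bleach = math.exp(-kinetics.bleach_rate * t)
        frame = base * bleach
        frame[rs, cs] *= ratio[i]
        frames[i] = _apply_noise(frame, scene.noise, _sub_rng(scene.seed, 4, i))

    movie = TimeLapse(
        frames=frames, frame_interval_s=kinetics.frame_interval, pixel_scale=scene.pixel_scale
    )
    truth = replace(truth, kinetics=kinetics, damage_roi=roi)
    return movie, truth
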