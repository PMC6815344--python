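"""Synthetic CLE phantom generator.

Real cadaveric-eye CLE recordings of this kind are not publicly available,
so every quantitative claim in this package is exercised on phantoms with
known ground truth.  The generator emulates the imaging physics the instrument reports:

* a 423 x 423 um field of view sampled on a square pixel grid,
* tubular vessels whose cross-sectional intensity is Gaussian,
  ``I(x) = A * exp(-x^2 / (2 sigma0^2))``, with the operational "diameter"
  defined as the profile FWHM ``2 sqrt(2 ln 2) sigma0``,
* an isotropic Gaussian PSF whose FWHM matches the 3.5 um lateral resolution,
* additive Gaussian background noise (intensities are arbitrary units; no
  photon calibration exists, so shot noise is not modelled),
* a saturating-exponential wash-in of intravascular fluorescein,
  ``I(t) = I_inf * (1 - exp(-(t - t0)/tau))`` for ``t >= t0``,
* a 24-position limbal sampling grid (15 degree spacing) with an
  inferior-quadrant excess in total fluorescence and large-diameter vessels
  clustered in contiguous angular runs.

Rendering is deterministic given ``(spec, vessels, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .frame import FOV_UM, FWHM_PER_SIGMA, PSF_SIGMA_UM, FrameImage
from .limbal import LIMBAL_ANGLES_DEG, LimbalSample, assign_quadrant

__all__ = [
    "FrameSpec",
    "VesselTruth",
    "WashinTruth",
    "LimbalEffectSpec",
    "InvalidSpecError",
    "generate_vessel_frame",
    "generate_washin_series",
    "generate_limbal_dataset",
    "straight_centerline",
    "sine_centerline",
    "washin_factor",
    "PORCINE_TAU_S",
    "HUMAN_TAU_S",
]

#: Wash-in time constants chosen so the noiseless 95%-of-plateau time is
#: 300 s (porcine) and 420 s (human): tau = t95 / ln 20.
PORCINE_TAU_S = 300.0 / math.log(20.0)
HUMAN_TAU_S = 420.0 / math.log(20.0)

#: Gaussian tube cross-sections are truncated at this many sigma for speed.
_TUBE_CUTOFF_SIGMA = 4.0


class InvalidSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclass
class FrameSpec:
    """Acquisition geometry and noise model of one synthetic frame."""

    fov_um: float = FOV_UM
    grid_px: int = 512
    background_au: float = 20.0
    noise_sd_au: float = 0.0
    psf_sigma_um: float = PSF_SIGMA_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fov_um > 0:
            raise InvalidSpecError("fov_um must be > 0")
        if int(self.grid_px) < 64:
            raise InvalidSpecError("grid_px must be >= 64")
        self.grid_px = int(self.grid_px)
        if self.noise_sd_au < 0:
            raise InvalidSpecError("noise_sd_au must be >= 0")
        if self.psf_sigma_um < 0:
            raise InvalidSpecError("psf_sigma_um must be >= 0")
        if not self.pitch_um > 0:
            raise InvalidSpecError("pixel pitch must be > 0")

    @property
    def pitch_um(self) -> float:
        return self.fov_um / self.grid_px


@dataclass
class VesselTruth:
    """Ground truth for one rendered vessel.

    ``centerline`` is an ordered ``(n, 2)`` array of ``(x_um, y_um)`` points;
    the rendered tube has Gaussian cross-section SD ``sigma0_um`` and peak
    intraluminal intensity ``amplitude_au`` above background.
    """

    centerline: np.ndarray
    sigma0_um: float
    amplitude_au: float

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2 or self.centerline.shape[1] != 2:
            raise InvalidSpecError("centerline must be an (n>=2, 2) array of (x_um, y_um)")
        if not self.sigma0_um > 0:
            raise InvalidSpecError("sigma0_um must be > 0")
        if not self.amplitude_au > 0:
            raise InvalidSpecError("amplitude_au must be > 0")

    @property
    def truth_diameter_um(self) -> float:
        """Operational diameter: profile FWHM = 2 sqrt(2 ln 2) sigma0."""
        return FWHM_PER_SIGMA * self.sigma0_um

    @classmethod
    def from_fwhm(cls, centerline, fwhm_um: float, amplitude_au: float) -> "VesselTruth":
        return cls(centerline, fwhm_um / FWHM_PER_SIGMA, amplitude_au)


@dataclass
class WashinTruth:
    """Parameters of the saturating-exponential fluorescein wash-in."""

    plateau_au: float = 1.0
    tau_s: float = HUMAN_TAU_S
    t0_s: float = 0.0
    duration_s: float = 480.0
    frame_interval_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.plateau_au > 0:
            raise InvalidSpecError("plateau_au must be > 0")
        if not self.tau_s > 0:
            raise InvalidSpecError("tau_s must be > 0")
        if not self.frame_interval_s > 0:
            raise InvalidSpecError("frame_interval_s must be > 0")
        if self.duration_s < 10 * self.frame_interval_s and self.duration_s != self.frame_interval_s:
            # the single-interval boundary case (exactly 2 frames) is allowed
            if self.duration_s < self.frame_interval_s:
                raise InvalidSpecError("duration_s must cover at least one frame interval")


def washin_factor(t_s: np.ndarray | float, truth: WashinTruth) -> np.ndarray | float:
    """Fractional wash-in ``1 - exp(-(t - t0)/tau)`` for ``t >= t0``, else 0."""
    t = np.asarray(t_s, dtype=float)
    f = np.where(t >= truth.t0_s, 1.0 - np.exp(-(t - truth.t0_s) / truth.tau_s), 0.0)
    return float(f) if np.isscalar(t_s) else f


@dataclass
class LimbalEffectSpec:
    """Regional effect along the 24-point limbal grid.

    Group means/SDs parameterize the per-angle total vessel fluorescence
    (au) for the inferior quadrant (225-315 degrees inclusive) versus all
    other positions.  Defaults encode the group summaries reported from
    ex-vivo human-eye imaging as the generator's stated world.
    """

    angles_deg: tuple = tuple(LIMBAL_ANGLES_DEG)
    inferior_mean_au: float = 1742.0
    other_mean_au: float = 1300.0
    inferior_sd_au: float = 271.0
    other_sd_au: float = 316.0
    diameter_range_um: tuple = (10.0, 50.0)
    cluster_span_deg: float = 45.0
    n_clusters: int = 2
    vessels_per_angle: int = 4
    n_eyes: int = 2

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        if angles.size == 0 or np.any(np.mod(angles, 15.0) != 0.0):
            raise InvalidSpecError("angles must lie on the 15-degree grid")
        if self.inferior_sd_au < 0 or self.other_sd_au < 0:
            raise InvalidSpecError("SDs must be >= 0")
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise InvalidSpecError("diameter_range_um must be increasing and positive")
        if hi >= FOV_UM / 2:
            raise InvalidSpecError("diameter_range_um must be below fov/2")
        if self.n_eyes < 1:
            raise InvalidSpecError("n_eyes must be >= 1")


# ---------------------------------------------------------------------------
# centerline helpers

def straight_centerline(spec: FrameSpec, angle_deg: float = 0.0,
                        offset_um: float = 0.0, n_points: int = 2) -> np.ndarray:
    """Straight chord through the FOV center at ``angle_deg`` from the x-axis.

    ``offset_um`` displaces the line along its normal.  Returned as
    ``(n_points, 2)`` array of (x_um, y_um), extended beyond the FOV so the
    rendered tube has no end caps inside the frame.
    """
    c = spec.fov_um / 2.0
    th = math.radians(angle_deg)
    d = np.array([math.cos(th), math.sin(th)])
    n = np.array([-math.sin(th), math.cos(th)])
    half = spec.fov_um  # overshoot: caps land outside the frame
    s = np.linspace(-half, half, n_points)
    return np.array([c, c]) + offset_um * n + s[:, None] * d


def sine_centerline(spec: FrameSpec, amplitude_um: float = 40.0,
                    period_um: float = 300.0, n_points: int = 200) -> np.ndarray:
    """Horizontal sinusoidal centerline spanning the full FOV width."""
    x = np.linspace(-0.1 * spec.fov_um, 1.1 * spec.fov_um, n_points)
    y = spec.fov_um / 2.0 + amplitude_um * np.sin(2 * math.pi * x / period_um)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# rendering

def _min_distance_to_polyline(spec: FrameSpec, centerline_um: np.ndarray) -> np.ndarray:
    """Per-pixel minimum Euclidean distance (um) from pixel centers to the polyline."""
    pitch = spec.pitch_um
    n = spec.grid_px
    coords = (np.arange(n) + 0.0) * pitch  # pixel centers at index * pitch
    X, Y = np.meshgrid(coords, coords)  # X: column -> x_um, Y: row -> y_um
    d2 = np.full((n, n), np.inf)
    p = centerline_um
    for a, b in zip(p[:-1], p[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        if L2 == 0.0:
            dx, dy = X - a[0], Y - a[1]
            d2 = np.minimum(d2, dx * dx + dy * dy)
            continue
        t = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / L2
        np.clip(t, 0.0, 1.0, out=t)
        dx = X - (a[0] + t * ab[0])
        dy = Y - (a[1] + t * ab[1])
        d2 = np.minimum(d2, dx * dx + dy * dy)
    return np.sqrt(d2)


def render_tubes(spec: FrameSpec, vessels: list[VesselTruth],
                 amplitude_scale: float = 1.0) -> np.ndarray:
    """Noise-free, background-free sum of Gaussian tubes (before PSF)."""
    img = np.zeros((spec.grid_px, spec.grid_px))
    for v in vessels:
        d = _min_distance_to_polyline(spec, v.centerline)
        prof = v.amplitude_au * amplitude_scale * np.exp(-(d * d) / (2.0 * v.sigma0_um ** 2))
        prof[d > _TUBE_CUTOFF_SIGMA * v.sigma0_um] = 0.0
        img += prof
    return img


def _finalize(spec: FrameSpec, tubes: np.ndarray, rng: np.random.Generator) -> FrameImage:
    img = tubes
    if spec.psf_sigma_um > 0:
        img = gaussian_filter(img, spec.psf_sigma_um / spec.pitch_um, mode="reflect")
    img = img + spec.background_au
    if spec.noise_sd_au > 0:
        img = img + rng.normal(0.0, spec.noise_sd_au, img.shape)
    np.clip(img, 0.0, None, out=img)
    return FrameImage(img, spec.pitch_um)


def generate_vessel_frame(spec: FrameSpec,
                          vessels: list[VesselTruth]) -> tuple[FrameImage, list[VesselTruth]]:
    """Render one frame: background + Gaussian tubes, PSF blur, additive noise.

    Centerline points outside the FOV are simply rendered off-frame (clipped
    by the grid), not an error.  Identical ``(spec, vessels)`` (the seed lives
    on the spec) yield bit-identical frames.  An empty vessel list gives a
    background-only frame.
    """
    rng = np.random.default_rng(spec.seed)
    tubes = render_tubes(spec, vessels)
    return _finalize(spec, tubes, rng), vessels


def generate_washin_series(spec: FrameSpec, truth: WashinTruth,
                           vessels: list[VesselTruth]) -> list[tuple[float, FrameImage]]:
    """Frame sequence with vessel amplitudes scaled by the wash-in factor.

    Frames are sampled at ``t = k * frame_interval_s`` for
    ``k = 0 .. floor(duration/interval)``; background and noise level are
    constant over time.
    """
    n_frames = int(math.floor(truth.duration_s / truth.frame_interval_s)) + 1
    rng = np.random.default_rng(spec.seed)
    base = render_tubes(spec, vessels)  # unit wash-in; scaling is linear
    series = []
    for k in range(n_frames):
        t = k * truth.frame_interval_s
        f = float(washin_factor(t, truth))
        series.append((t, _finalize(spec, base * (f * truth.plateau_au), rng)))
    return series


# ---------------------------------------------------------------------------
# limbal circumference dataset

def _cluster_angles(angles: np.ndarray, effect: LimbalEffectSpec,
                    rng: np.random.Generator) -> set:
    """Pick contiguous runs of grid angles (width ~ cluster_span_deg) to host
    large-diameter vessels."""
    run_len = max(1, round(effect.cluster_span_deg / 15.0))
    k = angles.size
    chosen: set = set()
    starts = rng.choice(k, size=effect.n_clusters, replace=False)
    for s in starts:
        for j in range(run_len):
            chosen.add(float(angles[(s + j) % k]))
    return chosen


def generate_limbal_dataset(spec: FrameSpec, effect: LimbalEffectSpec, seed: int,
                            render_frames: bool = False
                            ) -> tuple[list[LimbalSample], list[FrameImage | None]]:
    """Per-eye, per-angle ground-truth samples (and optionally frames).

    For each eye and each grid angle, the total vessel fluorescence is drawn
    from the inferior distribution if the angle lies in 225-315 degrees
    (inclusive) and from the other distribution otherwise; per-angle vessel
    diameters are drawn from ``diameter_range_um`` with the upper part of the
    range confined to contiguous angular clusters.

    With ``render_frames=True`` each sample also gets a rendered frame whose
    total vessel (above-background) fluorescence equals the drawn truth;
    rendering 24 frames per eye is slow at full grid size, so truths-only is
    the default for statistical work.
    """
    angles = np.asarray(effect.angles_deg, dtype=float)
    if np.any(np.mod(angles, 15.0) != 0.0):
        raise InvalidSpecError("angles must lie on the 15-degree grid")
    rng = np.random.default_rng(seed)
    lo, hi = effect.diameter_range_um
    big_lo = lo + 0.7 * (hi - lo)  # large-caliber vessels live in the top 30%

    samples: list[LimbalSample] = []
    frames: list[FrameImage | None] = []
    for eye in range(effect.n_eyes):
        eye_id = f"eye{eye + 1}"
        clustered = _cluster_angles(angles, effect, rng)
        for ang in angles:
            quadrant = assign_quadrant(float(ang))
            if quadrant == "inferior":
                total = rng.normal(effect.inferior_mean_au, effect.inferior_sd_au)
            else:
                total = rng.normal(effect.other_mean_au, effect.other_sd_au)
            total = max(total, 0.0)
            diam = rng.uniform(lo, lo + 0.5 * (hi - lo), size=effect.vessels_per_angle)
            if float(ang) in clustered:
                diam[rng.integers(diam.size)] = rng.uniform(big_lo, hi)
            sample = LimbalSample(eye_id=eye_id, angle_deg=float(ang),
                                  total_au=float(total),
                                  diameters_um=[float(d) for d in diam],
                                  quadrant=quadrant)
            samples.append(sample)
            if render_frames:
                frames.append(_render_limbal_frame(spec, sample, rng))
            else:
                frames.append(None)
    return samples, frames


def _render_limbal_frame(spec: FrameSpec, sample: LimbalSample,
                         rng: np.random.Generator) -> FrameImage:
    """One frame whose above-background vessel total matches the sample truth."""
    vessels = []
    k = len(sample.diameters_um)
    for i, d in enumerate(sample.diameters_um):
        off = (i - (k - 1) / 2.0) * spec.fov_um / (k + 1)
        ang = float(rng.uniform(0.0, 180.0))
        vessels.append(VesselTruth.from_fwhm(
            straight_centerline(spec, angle_deg=ang, offset_um=off), d, 100.0))
    tubes = render_tubes(spec, vessels)
    s = tubes.sum()
    if s > 0 and sample.total_au > 0:
        tubes *= sample.total_au / s
    return _finalize(spec, tubes, rng)
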