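"""Synthetic polydiacetylene (PDA) patch: colorimetric response and photo render.

Polydiacetylenes shift color from blue toward red when exposed to volatile
organic compounds (solvatochromism).  A four-dot array of chemically distinct
PDAs therefore responds to a VOC with a characteristic 12-dimensional
ΔRGB "fingerprint" (pre-exposure minus post-exposure mean RGB of each dot).

This module simulates that response for chlorobenzene and renders photo-like
images of the array, providing seeded, reproducible ground truth for the
imaging, calibration and dosimetry stages.  The response model:

* The fingerprint drifts along a fixed unit direction ``u`` in ΔRGB space at
  a concentration-dependent rate (PC1 units per hour of exposure).  The rate
  table is ``{10 ppm: 1.16/h, 20 ppm: 2.14/h, 40 ppm: 4.31/h}``; rates at
  intermediate concentrations are linearly interpolated.  PC1 units are
  8-bit ΔRGB Euclidean units along ``u``, so the per-hour rates are directly
  the drift speed of the fingerprint vector.
* A second, smaller response mode lies along a direction ``w`` orthogonal to
  ``u``: the four dots do not share exactly the same kinetics, so as dose
  accumulates the fingerprint bows away from the main drift axis.  This
  dot-to-dot kinetic dispersion is modeled as a smooth function of the
  cumulative drift that vanishes at zero exposure, is uncorrelated with the
  drift over the reference training design, and carries a fixed fraction
  (6.6/93.3 by default) of the drift variance — reproducing the observed
  two-component variance structure of the real patch.
* Measurement noise: i.i.d. Gaussian per fingerprint coordinate (direct
  simulation) or i.i.d. Gaussian per pixel plus per-channel illumination
  gain (image rendering).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from .schedule import ExposureSchedule

N_DOTS = 4
N_CHANNELS = 3
FINGERPRINT_DIM = N_DOTS * N_CHANNELS

#: Reference exposure-trial design: 3 concentrations x 3 replicates x 14 days,
#: 8 h of exposure per day.
DEFAULT_DESIGN = {
    "concentrations": (10.0, 20.0, 40.0),
    "n_replicates": 3,
    "n_days": 14,
    "hours_per_day": 8.0,
}


class SaturationError(ValueError):
    """A computed dot color left the 8-bit gamut: the dose exceeds the
    dynamic range of the simulated patch."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic patch response.

    The spectral defaults (``pre_rgb``, ``sensitivity_direction``,
    ``dot_factors``) are invented: no reference RGB endpoints are available
    for the real dyes.  They are chosen so that the blue-to-red chromatic
    shift holds (blue channel falls, red rises) and all four dot colors stay
    inside [0, 255] up to the maximum design dose of 4480 ppm·h.
    """

    #: pre-exposure color of each dot (8-bit RGB), blue-phase PDA
    pre_rgb: tuple[tuple[float, float, float], ...] = (
        (45.0, 50.0, 235.0),
    ) * N_DOTS
    #: common per-channel response direction (ΔR, ΔG, ΔB), unit-scaled
    sensitivity_direction: tuple[float, float, float] = (-0.58, -0.05, 0.65)
    #: relative response amplitude of each dot
    dot_factors: tuple[float, float, float, float] = (1.00, 0.85, 0.55, 0.75)
    #: PC1 drift speed (units per hour) at each calibrated concentration (ppm)
    rate_table: tuple[tuple[float, float], ...] = (
        (10.0, 1.16),
        (20.0, 2.14),
        (40.0, 4.31),
    )
    #: linearly interpolate rates between table concentrations
    interpolate_rates: bool = True
    #: variance of the secondary mode as a fraction of the drift variance
    #: over the reference design
    secondary_variance_ratio: float = 6.6 / 93.3
    #: per-dot weights of the secondary (kinetic-dispersion) mode; the
    #: composite direction is orthogonalized against the drift direction
    secondary_dot_weights: tuple[float, float, float, float] = (
        0.15,
        -0.55,
        1.0,
        -0.31,
    )
    #: sd of i.i.d. noise per fingerprint coordinate (direct simulation),
    #: 8-bit units; matches the dot-mean noise of the default image pipeline
    fingerprint_noise_sd: float = 0.25
    #: sd of i.i.d. Gaussian pixel noise (8-bit units) when rendering
    pixel_noise_sd: float = 5.0
    #: per-channel multiplicative illumination gain range when rendering.
    #: Gains stay below 1 so the white background sits under the 8-bit
    #: ceiling: clipped background pixels would bias the white-balance
    #: estimate and make the gains unrecoverable.  The upper bound keeps
    #: the background far enough below 255 that pixel noise cannot push
    #: more than a quarter of background pixels into saturation.
    illumination_gain_range: tuple[float, float] = (0.92, 0.97)
    #: master seed for replicate/day child streams
    seed: int = 0
    #: design used to calibrate the secondary-mode profile
    calibration_design: tuple = (
        DEFAULT_DESIGN["concentrations"],
        DEFAULT_DESIGN["n_replicates"],
        DEFAULT_DESIGN["n_days"],
        DEFAULT_DESIGN["hours_per_day"],
    )

    # -- derived geometry -------------------------------------------------

    @property
    def drift_direction(self) -> np.ndarray:
        """Composite 12-d unit drift direction ``u``."""
        sens = np.asarray(self.sensitivity_direction, dtype=float)
        u = np.concatenate([f * sens for f in self.dot_factors])
        n = np.linalg.norm(u)
        if n == 0:
            raise ValueError("drift direction has zero norm")
        return u / n

    @property
    def secondary_direction(self) -> np.ndarray:
        """Unit direction ``w`` of the secondary mode, orthogonal to ``u``."""
        sens = np.asarray(self.sensitivity_direction, dtype=float)
        w = np.concatenate([g * sens for g in self.secondary_dot_weights])
        u = self.drift_direction
        w = w - (w @ u) * u
        n = np.linalg.norm(w)
        if n < 1e-9:
            raise ValueError("secondary direction is parallel to the drift")
        return w / n

    def _design_drifts(self) -> np.ndarray:
        """Noise-free drift magnitudes of every observation in the
        calibration design (used to scale the secondary mode)."""
        concs, n_rep, n_days, hours = self.calibration_design
        return np.array(
            [
                self.rate_for(c) * hours * d
                for c in concs
                for _ in range(n_rep)
                for d in range(1, n_days + 1)
            ]
        )

    @property
    def secondary_profile_coeffs(self) -> tuple[float, float, float]:
        """(alpha, beta, sd) of the secondary amplitude alpha*(s^2 + beta*s),
        scaled by sd.

        The quadratic is chosen so that, over the calibration design, the
        amplitude has zero covariance with the drift magnitude ``s`` and unit
        variance; ``sd`` then sets its variance share.  It vanishes at s = 0:
        an unexposed patch shows no secondary response.
        """
        s = self._design_drifts()
        var_s = np.var(s, ddof=1)
        if var_s == 0:
            return 0.0, 0.0, 0.0
        beta = -np.cov(s**2, s, ddof=1)[0, 1] / var_s
        raw = s**2 + beta * s
        scale = np.std(raw, ddof=1)
        alpha = 1.0 / scale if scale > 0 else 0.0
        sd = float(np.sqrt(self.secondary_variance_ratio * var_s))
        return float(alpha), float(beta), sd

    def secondary_amplitude(self, drift: float | np.ndarray) -> np.ndarray:
        """Signed magnitude of the secondary mode at cumulative drift ``s``."""
        alpha, beta, sd = self.secondary_profile_coeffs
        s = np.asarray(drift, dtype=float)
        return sd * alpha * (s**2 + beta * s)

    # -- kinetics ---------------------------------------------------------

    def rate_for(self, concentration_ppm: float) -> float:
        """PC1 drift speed (units/h) at a concentration, interpolating
        linearly between table entries when enabled."""
        table = sorted(self.rate_table)
        concs = np.array([c for c, _ in table])
        rates = np.array([r for _, r in table])
        if np.any(rates <= 0):
            raise ValueError("rate_table values must be strictly positive")
        exact = np.isclose(concs, concentration_ppm)
        if exact.any():
            return float(rates[exact.argmax()])
        if concentration_ppm == 0:
            return 0.0
        if not self.interpolate_rates:
            raise ValueError(
                f"concentration {concentration_ppm} ppm not in rate table "
                "and interpolation is disabled"
            )
        if not concs[0] <= concentration_ppm <= concs[-1]:
            raise ValueError(
                f"concentration {concentration_ppm} ppm outside the "
                f"calibrated range [{concs[0]}, {concs[-1]}] ppm"
            )
        return float(np.interp(concentration_ppm, concs, rates))

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ArrayLayout:
    """Pixel geometry of the rendered 4-dot array.

    Coordinates are 0-based (row, column).  The background region is a
    rectangle (row0, col0, height, width) of bare paper used for white
    balance; it must not intersect any dot.
    """

    image_height: int = 180
    image_width: int = 240
    centers: tuple[tuple[int, int], ...] = ((75, 65), (75, 175), (135, 65), (135, 175))
    radius: int = 28
    background_region: tuple[int, int, int, int] = (0, 0, 40, 240)

    def __post_init__(self) -> None:
        if len(self.centers) != N_DOTS:
            raise ValueError(f"layout must define {N_DOTS} dot centers")
        for r, c in self.centers:
            if not (
                self.radius <= r < self.image_height - self.radius
                and self.radius <= c < self.image_width - self.radius
            ):
                raise ValueError(f"dot at ({r}, {c}) extends outside the image")
        cs = self.centers
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                d2 = (cs[i][0] - cs[j][0]) ** 2 + (cs[i][1] - cs[j][1]) ** 2
                if d2 <= (2 * self.radius) ** 2:
                    raise ValueError(f"dots {i} and {j} overlap")
        r0, c0, h, w = self.background_region
        if not (0 <= r0 and 0 <= c0 and r0 + h <= self.image_height and c0 + w <= self.image_width):
            raise ValueError("background region extends outside the image")
        for i, (r, c) in enumerate(self.centers):
            # nearest point of the rectangle to the dot center
            nr = min(max(r, r0), r0 + h - 1)
            nc = min(max(c, c0), c0 + w - 1)
            if (nr - r) ** 2 + (nc - c) ** 2 <= self.radius**2:
                raise ValueError(f"background region overlaps dot {i}")


@functools.lru_cache(maxsize=8)
def _dot_masks(layout: ArrayLayout) -> tuple[np.ndarray, ...]:
    yy, xx = np.mgrid[0 : layout.image_height, 0 : layout.image_width]
    return tuple(
        (yy - r) ** 2 + (xx - c) ** 2 <= layout.radius**2
        for r, c in layout.centers
    )


@dataclass
class SensorImage:
    """An H x W x 3 RGB image of the array.

    Noisy renders and PNG-loaded photos hold 8-bit integer values;
    noise-free renders and white-balanced images hold real values in
    [0, 255] (quantized only when written to PNG).
    """

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != N_CHANNELS:
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def to_png(self, path: str | Path) -> None:
        iio.imwrite(
            Path(path), np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)
        )

    @classmethod
    def from_png(cls, path: str | Path) -> "SensorImage":
        px = iio.imread(Path(path))
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        return cls(px)


# ---------------------------------------------------------------------------
# response simulation


def cumulative_drift(
    schedule: ExposureSchedule, config: GeneratorConfig, upto_day: int | None = None
) -> float:
    """Noise-free PC1 drift magnitude accumulated by ``upto_day``:
    sum of rate(concentration) x duration over the schedule prefix."""
    if upto_day is not None and schedule.records and upto_day > schedule.last_day:
        raise ValueError(
            f"upto_day {upto_day} exceeds the schedule's last day "
            f"{schedule.last_day}"
        )
    return sum(
        config.rate_for(r.concentration_ppm) * r.duration_h
        for r in schedule.records
        if upto_day is None or r.day <= upto_day
    )


def simulate_fingerprint(
    schedule: ExposureSchedule,
    config: GeneratorConfig,
    upto_day: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the 12-d ΔRGB fingerprint after a schedule prefix.

    The noise-free response is ``s*u + a(s)*w`` where ``s`` is the summed
    drift, ``u`` the drift direction, ``w`` the orthogonal secondary
    direction and ``a`` the kinetic-dispersion amplitude (zero at s = 0).
    Its Euclidean projection on ``u`` equals ``s`` exactly.  When ``rng`` is
    given, i.i.d. Gaussian measurement noise (``fingerprint_noise_sd``) is
    added per coordinate; with ``rng=None`` the result is deterministic.
    """
    s = cumulative_drift(schedule, config, upto_day)
    fp = s * config.drift_direction + config.secondary_amplitude(s) * config.secondary_direction
    if rng is not None and config.fingerprint_noise_sd > 0:
        fp = fp + rng.normal(0.0, config.fingerprint_noise_sd, FINGERPRINT_DIM)
    return fp


def dot_colors(fingerprint: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Post-exposure color of each dot: pre_rgb minus the per-dot ΔRGB.

    Raises :class:`SaturationError` naming the dot and channel if any color
    leaves [0, 255] — the dose is beyond the patch's dynamic range.
    """
    fp = np.asarray(fingerprint, dtype=float).reshape(N_DOTS, N_CHANNELS)
    post = np.asarray(config.pre_rgb, dtype=float) - fp
    bad = (post < 0) | (post > 255)
    if bad.any():
        d, ch = np.argwhere(bad)[0]
        raise SaturationError(
            f"dot {d + 1} channel {'RGB'[ch]} saturates at {post[d, ch]:.1f}: "
            "dose beyond the patch dynamic range"
        )
    return post


def render_array_image(
    fingerprint: np.ndarray,
    layout: ArrayLayout,
    config: GeneratorConfig,
    *,
    rng: np.random.Generator | None = None,
    gains: Sequence[float] | None = None,
    metadata: dict | None = None,
) -> SensorImage:
    """Render a photo-like 8-bit image of the array.

    Background pixels are white (255) scaled by per-channel illumination
    gains; each dot disk is filled with its post-exposure color under the
    same gains.  When ``rng`` is given, gains are drawn uniformly from
    ``config.illumination_gain_range`` (unless passed explicitly), Gaussian
    pixel noise of sd ``config.pixel_noise_sd`` is added, and the result is
    clipped to [0, 255] and quantized to 8 bits as a camera would
    (identical seeds give identical images).  Without ``rng`` the render is
    the idealized noise-free expectation and keeps continuous channel
    values, so quantization never masquerades as sensor response.
    """
    post = dot_colors(fingerprint, config)
    if gains is None:
        if rng is not None:
            lo, hi = config.illumination_gain_range
            gains = rng.uniform(lo, hi, N_CHANNELS)
        else:
            gains = np.ones(N_CHANNELS)
    gains = np.asarray(gains, dtype=float)
    img = np.full(
        (layout.image_height, layout.image_width, N_CHANNELS), 255.0
    ) * gains
    for mask, color in zip(_dot_masks(layout), post):
        img[mask] = color * gains
    if rng is not None:
        if config.pixel_noise_sd > 0:
            img = img + rng.normal(0.0, config.pixel_noise_sd, img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    else:
        img = np.clip(img, 0, 255)
    return SensorImage(img, metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class Observation:
    """One labeled daily observation of one replicate array."""

    concentration_ppm: float
    replicate: int
    day: int
    dose_ppmh: float
    fingerprint: np.ndarray
    pre_image: SensorImage | None = None
    post_image: SensorImage | None = None


def child_rng(
    seed: int, concentration_ppm: float, replicate: int, day: int
) -> np.random.Generator:
    """Reproducible child stream for one (concentration, replicate, day).

    Derived with :class:`numpy.random.SeedSequence`, which hashes the key
    tuple; stable across runs and platforms.
    """
    key = (int(seed), int(round(concentration_ppm * 1000)), int(replicate), int(day))
    # SeedSequence entropy must be non-negative; map to unsigned 64-bit
    key = tuple(k & 0xFFFFFFFFFFFFFFFF for k in key)
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_control_fingerprints(
    n: int, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Fingerprints of unexposed patches: pure measurement noise."""
    return rng.normal(0.0, config.fingerprint_noise_sd, (n, FINGERPRINT_DIM))


def generate_training_set(
    concentrations: Sequence[float],
    n_days: int,
    n_replicates: int,
    config: GeneratorConfig,
    *,
    hours_per_day: float = 8.0,
    layout: ArrayLayout | None = None,
    images: bool = False,
    replicate_offset: int = 0,
) -> list[Observation]:
    """Simulate the exposure-trial design: every daily observation of every
    replicate at every concentration.

    Returns ``len(concentrations) * n_replicates * n_days`` observations with
    ground-truth dose ``concentration x hours_per_day x day``.  Each
    (concentration, replicate, day) uses a distinct child seed derived from
    ``config.seed``, so the dataset is bit-reproducible.  With
    ``images=True`` each observation carries a rendered pre-exposure image
    (photographed once per replicate, day 0) and a daily post-exposure image;
    measurement noise then enters through the pixels, so the stored
    ``fingerprint`` is the noise-free response (the measured fingerprint is
    whatever the imaging stage extracts).  With ``images=False`` the stored
    fingerprint itself carries the coordinate measurement noise.
    ``replicate_offset`` shifts replicate indices, e.g. to generate held-out
    replicates disjoint from training ones.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("at least one concentration is required")
    if n_days < 1 or n_replicates < 1:
        raise ValueError("n_days and n_replicates must be >= 1")
    layout = layout or ArrayLayout()
    out: list[Observation] = []
    for c in concentrations:
        schedule = ExposureSchedule.constant(c, n_days, hours_per_day)
        for rep in range(replicate_offset, replicate_offset + n_replicates):
            pre_img = None
            if images:
                pre_rng = child_rng(config.seed, c, rep, 0)
                pre_img = render_array_image(
                    np.zeros(FINGERPRINT_DIM), layout, config, rng=pre_rng,
                    metadata={"concentration_ppm": c, "replicate": rep, "day": 0},
                )
            for day in range(1, n_days + 1):
                rng = child_rng(config.seed, c, rep, day)
                fp = simulate_fingerprint(
                    schedule, config, upto_day=day, rng=None if images else rng
                )
                post_img = None
                if images:
                    post_img = render_array_image(
                        fp, layout, config, rng=rng,
                        metadata={
                            "concentration_ppm": c,
                            "replicate": rep,
                            "day": day,
                            "dose_ppmh": c * hours_per_day * day,
                        },
                    )
                out.append(
                    Observation(
                        concentration_ppm=c,
                        replicate=rep,
                        day=day,
                        dose_ppmh=c * hours_per_day * day,
                        fingerprint=fp,
                        pre_image=pre_img,
                        post_image=post_img,
                    )
                )
    return out


def fingerprints_and_doses(
    observations: Iterable[Observation],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into (n, 12) fingerprints and (n,) doses."""
    obs = list(observations)
    X = np.array([o.fingerprint for o in obs])
    y = np.array([o.dose_ppmh for o in obs])
    return X, y
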