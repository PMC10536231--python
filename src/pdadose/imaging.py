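"""From photographs to ΔRGB fingerprints.

The quantitative readout of the patch is obtained from a pair of photographs
(pre-exposure reference, post-exposure) in four steps:

1. white balance each photo against the bare paper background (white-patch
   estimator: per-channel gain 255 / median over a background region);
2. locate the four PDA dots (from a known layout, or automatically);
3. average the RGB values over each dot disk (shrunk by a margin to avoid
   edge blur);
4. subtract post-exposure from pre-exposure means, dot-major and
   channel-minor, giving the 12-dimensional ΔRGB fingerprint.

Values are raw 8-bit sRGB; no gamma linearization is applied.  Pixel
coordinates are 0-based (row, column) and disk membership is by center
distance <= radius, inclusive.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import trim_mean
from skimage import measure

from .sensor_model import (
    FINGERPRINT_DIM,
    N_CHANNELS,
    N_DOTS,
    ArrayLayout,
    SensorImage,
)

#: minimum number of pixels required inside a (shrunk) dot disk
MIN_DOT_PIXELS = 50
#: default disk shrink fraction of the radius when averaging
DEFAULT_MARGIN = 0.2


@dataclass(frozen=True)
class DotReading:
    """Mean color of one dot: geometry plus the per-channel pixel average."""

    dot_index: int  # 1-based
    center: tuple[float, float]  # (row, col)
    radius: float
    mean_rgb: tuple[float, float, float]
    pixel_count: int

    def __post_init__(self) -> None:
        if not 1 <= self.dot_index <= N_DOTS:
            raise ValueError(f"dot_index must be 1..{N_DOTS}")
        if self.pixel_count <= 0:
            raise ValueError("pixel_count must be positive")
        if any(not 0 <= v <= 255 for v in self.mean_rgb):
            raise ValueError("mean RGB components must lie in [0, 255]")


def white_balance(
    image: SensorImage,
    background_region: tuple[int, int, int, int],
    *,
    layout: ArrayLayout | None = None,
) -> SensorImage:
    """White-patch normalization: scale each channel so the background
    paper reads perfectly white.

    The per-channel gain is 255 over a robust location estimate of the
    channel across the background region.  The estimate is the
    interquartile (25%-trimmed) mean: like the median it shrugs off dust
    and shadow pixels (25% breakdown point), but unlike the median of
    8-bit data it does not snap to the integer grid — a snapped estimate
    biases the gain coherently across all four dots and would dominate
    the dot-mean noise.  The returned image holds real-valued channels
    clipped to [0, 255]; applying the operation twice is equivalent to
    applying it once.
    """
    r0, c0, h, w = background_region
    H, W, _ = image.shape
    if not (0 <= r0 and 0 <= c0 and h > 0 and w > 0 and r0 + h <= H and c0 + w <= W):
        raise ValueError("background region lies outside the image")
    if layout is not None:
        for i, (r, c) in enumerate(layout.centers):
            nr = min(max(r, r0), r0 + h - 1)
            nc = min(max(c, c0), c0 + w - 1)
            if (nr - r) ** 2 + (nc - c) ** 2 <= layout.radius**2:
                warnings.warn(
                    f"background region overlaps dot {i + 1}; white balance "
                    "may be biased",
                    stacklevel=2,
                )
    px = np.asarray(image.pixels, dtype=float)
    bg = px[r0 : r0 + h, c0 : c0 + w].reshape(-1, N_CHANNELS)
    white = trim_mean(bg, 0.25, axis=0)
    if np.any(white == 0):
        ch = "RGB"[int(np.argmax(white == 0))]
        raise ValueError(
            f"background white level is 0 in channel {ch}; white balance "
            "degenerate"
        )
    out = np.clip(px * (255.0 / white), 0, 255.0)
    return SensorImage(out, metadata=dict(image.metadata, white_balanced=True))


def _auto_locate(image: SensorImage, expected: int = N_DOTS) -> list[tuple[tuple[float, float], float]]:
    """Find circular colored regions against a white background."""
    px = np.asarray(image.pixels, dtype=float)
    # distance from white; dots are strongly chromatic/dark
    dist = np.linalg.norm(255.0 - px, axis=2)
    mask = dist > 0.25 * dist.max() if dist.max() > 0 else np.zeros(dist.shape, bool)
    labels = measure.label(mask)
    found = []
    for prop in measure.regionprops(labels):
        if prop.area < MIN_DOT_PIXELS:
            continue
        r_eq = np.sqrt(prop.area / np.pi)
        # reject elongated blobs
        if prop.axis_major_length > 0 and prop.axis_minor_length / prop.axis_major_length < 0.6:
            continue
        found.append((prop.centroid, r_eq))
    if len(found) != expected:
        raise ValueError(f"auto dot detection found {len(found)} dots, expected {expected}")
    # canonical reading order: left-to-right within rows, top-to-bottom
    radius = float(np.median([r for _, r in found]))
    found.sort(key=lambda cr: (round(cr[0][0] / (2 * radius)), cr[0][1]))
    return found


def locate_dots(
    image: SensorImage, layout: ArrayLayout | str = "auto"
) -> list[tuple[tuple[float, float], float]]:
    """Return the 4 dot (center, radius) pairs in reading order.

    With an explicit :class:`ArrayLayout` the centers are returned verbatim;
    with ``"auto"`` they are detected as approximately circular non-white
    blobs and ordered left-to-right, top-to-bottom.
    """
    if isinstance(layout, ArrayLayout):
        return [((float(r), float(c)), float(layout.radius)) for r, c in layout.centers]
    if layout == "auto":
        return _auto_locate(image)
    raise ValueError("layout must be an ArrayLayout or 'auto'")


def extract_mean_rgb(
    image: SensorImage,
    center: tuple[float, float],
    radius: float,
    *,
    margin: float = DEFAULT_MARGIN,
    min_pixels: int = MIN_DOT_PIXELS,
) -> np.ndarray:
    """Arithmetic per-channel mean over the disk shrunk by ``margin``.

    The shrink (default 20% of the radius) avoids edge blur between dot and
    paper.  Unrounded means are returned.
    """
    px = np.asarray(image.pixels, dtype=float)
    H, W, _ = px.shape
    r_eff = radius * (1.0 - margin)
    cy, cx = center
    if not (r_eff <= cy <= H - 1 - r_eff and r_eff <= cx <= W - 1 - r_eff):
        raise ValueError("shrunk dot disk extends outside the image")
    yy, xx = np.mgrid[0:H, 0:W]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_eff**2
    n = int(mask.sum())
    if n < min_pixels:
        raise ValueError(f"only {n} pixels inside the shrunk disk (minimum {min_pixels})")
    return px[mask].mean(axis=0)


@functools.lru_cache(maxsize=64)
def _disk_mask(
    shape: tuple[int, int], center: tuple[float, float], r_eff: float
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_eff**2


def read_dots(
    image: SensorImage,
    layout: ArrayLayout | str = "auto",
    *,
    margin: float = DEFAULT_MARGIN,
) -> list[DotReading]:
    """Locate all four dots and extract their mean colors."""
    readings = []
    px = np.asarray(image.pixels, dtype=float)
    H, W, _ = px.shape
    for i, (center, radius) in enumerate(locate_dots(image, layout), start=1):
        r_eff = radius * (1.0 - margin)
        mask = _disk_mask((H, W), (float(center[0]), float(center[1])), r_eff)
        readings.append(
            DotReading(
                dot_index=i,
                center=center,
                radius=radius,
                mean_rgb=tuple(px[mask].mean(axis=0)),
                pixel_count=int(mask.sum()),
            )
        )
    return readings


def compute_fingerprint(pre, post) -> np.ndarray:
    """ΔRGB fingerprint: pre-exposure minus post-exposure dot means.

    Accepts sequences of four RGB triples (or :class:`DotReading` lists)
    ordered by dot index.  Component ``3*(j-1)+k`` is ``pre[j][k] -
    post[j][k]``; under the blue-to-red transition the blue-channel
    components are positive.
    """

    def _to_array(readings):
        vals = [
            r.mean_rgb if isinstance(r, DotReading) else tuple(r) for r in readings
        ]
        return np.asarray(vals, dtype=float)

    a, b = _to_array(pre), _to_array(post)
    if a.shape != (N_DOTS, N_CHANNELS) or b.shape != (N_DOTS, N_CHANNELS):
        raise ValueError(
            f"expected {N_DOTS} RGB triples for pre and post, got shapes "
            f"{a.shape} and {b.shape}"
        )
    return (a - b).reshape(FINGERPRINT_DIM)


def fingerprint_from_images(
    pre_image: SensorImage,
    post_image: SensorImage,
    layout: ArrayLayout | str = "auto",
    *,
    background_region: tuple[int, int, int, int] | None = None,
    margin: float = DEFAULT_MARGIN,
) -> np.ndarray:
    """Full imaging pipeline: white balance both photos, locate dots,
    average colors, subtract.  ``background_region`` defaults to the
    layout's region when a layout is given."""
    if background_region is None:
        if not isinstance(layout, ArrayLayout):
            raise ValueError("background_region is required with layout='auto'")
        background_region = layout.background_region
    lay = layout if isinstance(layout, ArrayLayout) else None
    pre_wb = white_balance(pre_image, background_region, layout=lay)
    post_wb = white_balance(post_image, background_region, layout=lay)
    pre_rgb = read_dots(pre_wb, layout, margin=margin)
    post_rgb = read_dots(post_wb, layout, margin=margin)
    return compute_fingerprint(pre_rgb, post_rgb)


def readings_to_csv(readings: list[DotReading], path) -> None:
    """Export readings as ``dot,r,g,b,n_pixels``."""
    import pandas as pd

    pd.DataFrame(
        [
            (r.dot_index, *r.mean_rgb, r.pixel_count)
            for r in readings
        ],
        columns=["dot", "r", "g", "b", "n_pixels"],
    ).to_csv(path, index=False)
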