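"""Time-resolved synapse analyses: spreading, kymograph flow, FRAP kinetics.

Spreading is quantified by per-frame segmentation of the TIRFM footprint
(area in μm², aspect ratio from the moment-equivalent ellipse) and the
spreading velocity as the ordinary-least-squares slope of area versus time.

Actin retrograde flow is read off a kymograph (a space × time reslice of the
movie along a lamellipodium line): the flow trace appears as a tilted streak,
and on axes pre-scaled to μm and s its angle from the time axis gives the
velocity directly as ``V (μm/s) = tan(angle in radians)``.  Angles measured
in pixel units are converted with the kymograph's physical scales first.

FRAP recovery curves are normalized to an unbleached control region (which
cancels acquisition bleaching exactly), y-shifted so the bleaching event sits
at (0, 0), and fit to the single-exponential recovery
``Y = plateau · (1 − e^(−k·t))`` with the intercept pinned to 0; the
half-life is ``ln 2 / k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import measure

from .io import ImageStack
from .segment import segment_cell

__all__ = [
    "SpreadingSeries",
    "FrapFit",
    "Kymograph",
    "spreading_timeseries",
    "aspect_ratio",
    "build_kymograph",
    "retrograde_flow_velocity",
    "kymograph_angle_to_velocity",
    "estimate_kymograph_velocity",
    "frap_normalize",
    "frap_fit",
]


@dataclass
class SpreadingSeries:
    times_s: np.ndarray
    areas_um2: np.ndarray  # NaN where segmentation failed
    aspect_ratios: np.ndarray
    velocity_um2_per_min: float
    velocity_ci: tuple[float, float]  # 95% CI on the slope

    def __post_init__(self):
        ok = np.isfinite(self.areas_um2)
        if np.any(self.areas_um2[ok] < 0) or np.any(self.aspect_ratios[np.isfinite(self.aspect_ratios)] < 1):
            raise ValueError("areas must be >= 0 and aspect ratios >= 1")


@dataclass(frozen=True)
class FrapFit:
    y0: float  # pinned to 0 by the fitting constraint
    plateau: float
    k_per_s: float
    half_life_s: float
    rss: float


@dataclass
class Kymograph:
    image: np.ndarray  # (space, time)
    space_scale_um_per_px: float
    time_scale_s_per_px: float
    source_line: tuple[tuple[float, float], tuple[float, float]]  # endpoints, μm
    line_width_px: int

    def __post_init__(self):
        if self.space_scale_um_per_px <= 0 or self.time_scale_s_per_px <= 0:
            raise ValueError("kymograph scales must be > 0")


def aspect_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio of the mask's moment-equivalent ellipse (≥ 1).

    Moment-based rather than bounding-box, so the measure is rotation
    invariant — a tilted symmetric footprint still scores 1.
    """
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    if minor == 0:
        raise ValueError("degenerate (line-like) mask: aspect ratio undefined")
    return float(props.axis_major_length / minor)


def spreading_timeseries(
    movie: ImageStack,
    channel: int | str = 0,
    *,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_um2: float = 5.0,
) -> SpreadingSeries:
    """Per-frame footprint area and symmetry, plus the spreading velocity.

    Each frame is thresholded, binarized and reduced to its largest connected
    component; frames where no cell is detectable are recorded as NaN and
    excluded from the regression (never interpolated).  The velocity is the
    OLS slope of area against time, reported in μm²/min.
    """
    if movie.n_frames < 2:
        raise ValueError("need a movie with T >= 2")
    c = movie.channel_index(channel)
    times = np.arange(movie.n_frames) * movie.frame_interval_s
    areas = np.full(movie.n_frames, np.nan)
    ars = np.full(movie.n_frames, np.nan)
    px2 = movie.pixel_area_um2
    for t in range(movie.n_frames):
        img = movie.plane(t=t, c=c)
        try:
            mask = segment_cell(
                img, movie.pixel_size_um, method=method, threshold=threshold,
                min_area_um2=min_area_um2,
            )
        except ValueError:
            continue
        areas[t] = mask.sum() * px2
        ars[t] = aspect_ratio(mask)
    ok = np.isfinite(areas)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 frames with a detectable cell")
    res = stats.linregress(times[ok], areas[ok])
    slope_min = res.slope * 60.0
    half = 1.96 * res.stderr * 60.0
    return SpreadingSeries(
        times_s=times,
        areas_um2=areas,
        aspect_ratios=ars,
        velocity_um2_per_min=float(slope_min),
        velocity_ci=(float(slope_min - half), float(slope_min + half)),
    )


def build_kymograph(
    movie: ImageStack,
    channel: int | str,
    line_um: tuple[tuple[float, float], tuple[float, float]],
    *,
    width_px: int = 1,
) -> Kymograph:
    """Reslice a movie along a line: one column of the kymograph per frame.

    The line (endpoints in μm) is sampled at one-pixel spacing with bilinear
    interpolation; intensity is averaged across ``width_px`` parallel offsets
    perpendicular to the line.  The resulting image has space on the vertical
    axis (μm per px = pixel size) and time on the horizontal (s per px =
    frame interval).
    """
    if movie.n_frames < 2:
        raise ValueError("kymograph needs T >= 2")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    c = movie.channel_index(channel)
    px = movie.pixel_size_um
    (x0, y0), (x1, y1) = line_um
    # endpoint pixel coordinates (row, col), pixel-center convention
    p0 = np.array([y0 / px - 0.5, x0 / px - 0.5])
    p1 = np.array([y1 / px - 0.5, x1 / px - 0.5])
    length_px = np.hypot(*(p1 - p0))
    n_samples = int(np.floor(length_px)) + 1
    s = np.linspace(0.0, length_px, n_samples)
    direction = (p1 - p0) / length_px
    normal = np.array([-direction[1], direction[0]])
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)[:, None, None]
    base = p0[None, :] + s[:, None] * direction[None, :]  # (n_samples, 2)
    coords = base[None, :, :] + offsets * normal[None, None, :]
    h, w = movie.shape_yx
    if coords[..., 0].min() < -0.5 or coords[..., 0].max() > h - 0.5 or \
       coords[..., 1].min() < -0.5 or coords[..., 1].max() > w - 0.5:
        raise ValueError("reslice line (with width) exits the image bounds")
    columns = []
    for t in range(movie.n_frames):
        img = movie.plane(t=t, c=c)
        sampled = ndimage.map_coordinates(
            img, [coords[..., 0].ravel(), coords[..., 1].ravel()], order=1, mode="nearest"
        ).reshape(width_px, n_samples)
        columns.append(sampled.mean(axis=0))
    return Kymograph(
        image=np.stack(columns, axis=1),
        space_scale_um_per_px=px,
        time_scale_s_per_px=movie.frame_interval_s,
        source_line=line_um,
        line_width_px=width_px,
    )


def retrograde_flow_velocity(angle_deg: float) -> float:
    """Velocity from a flow-trace angle on a physically scaled kymograph.

    The angle is measured from the time axis on a kymograph whose axes are in
    μm (space) and s (time), so ``V = tan(angle)`` is already in μm/s.  For
    angles measured in pixel units use :func:`kymograph_angle_to_velocity`.
    """
    if not 0 <= angle_deg < 90:
        raise ValueError("angle must lie in [0, 90) degrees")
    return float(np.tan(np.deg2rad(angle_deg)))


def kymograph_angle_to_velocity(angle_deg_px: float, kymo: Kymograph) -> float:
    """Convert a pixel-space kymograph angle (from the time axis) to μm/s."""
    if not 0 <= angle_deg_px < 90:
        raise ValueError("angle must lie in [0, 90) degrees")
    slope_px = np.tan(np.deg2rad(angle_deg_px))  # space px per time px
    return float(slope_px * kymo.space_scale_um_per_px / kymo.time_scale_s_per_px)


def estimate_kymograph_velocity(kymo: Kymograph) -> tuple[float, float]:
    """Trace the dominant streak of a kymograph and return (V μm/s, angle°).

    The band position in each time column is taken as the intensity-weighted
    centroid; an OLS fit of position against time gives the slope, converted
    to physical units and to the equivalent physically-scaled angle.
    Suited to single-band kymographs such as the synthetic flow-edge movie.
    """
    img = np.clip(kymo.image, 0, None)
    w = img.sum(axis=0)
    if np.any(w <= 0):
        raise ValueError("kymograph has empty time columns")
    pos = (np.arange(img.shape[0])[:, None] * img).sum(axis=0) / w
    t = np.arange(img.shape[1])
    res = stats.linregress(t, pos)
    v = abs(res.slope) * kymo.space_scale_um_per_px / kymo.time_scale_s_per_px
    return float(v), float(np.rad2deg(np.arctan(v)))


def frap_normalize(
    times_s: np.ndarray,
    bleach: np.ndarray,
    control: np.ndarray,
    bleach_frame: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Control-normalize a bleach trace and shift its origin to the bleach event.

    The bleach-ROI intensity is divided frame-by-frame by the unbleached
    control ROI of the same cell (cancelling global acquisition decay), then
    the post-bleach portion is y-shifted so the curve starts at (0, 0).
    Returns ``(t, y)`` with t = 0 at the bleaching event.
    """
    times_s = np.asarray(times_s, float)
    bleach = np.asarray(bleach, float)
    control = np.asarray(control, float)
    if not (len(times_s) == len(bleach) == len(control)):
        raise ValueError("series lengths differ")
    if not 0 <= bleach_frame < len(times_s):
        raise ValueError("bleach_frame out of range")
    if np.any(control <= 0):
        raise ValueError("control ROI reaches zero: normalization undefined")
    ratio = bleach / control
    t = times_s[bleach_frame:] - times_s[bleach_frame]
    y = ratio[bleach_frame:] - ratio[bleach_frame]
    return t, y


def frap_fit(times_s: np.ndarray, values: np.ndarray) -> FrapFit:
    """Fit ``Y = plateau · (1 − e^(−k·t))`` to a normalized recovery curve.

    The intercept is pinned to 0 (the curve is y-shifted to the bleach
    event), so plateau and rate constant k are the only free parameters.
    Initialization: plateau from the curve maximum, k from the time of
    half-maximal recovery; bounded so plateau stays positive.  The half-life
    is ``ln 2 / k̂`` by definition.
    """
    t = np.asarray(times_s, float)
    y = np.asarray(values, float)
    if len(t) < 4:
        raise ValueError("need at least 4 post-bleach points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("curve never rises above 0: k unidentifiable")
    half_idx = np.argmax(y >= ymax / 2)
    t_half = t[half_idx] if t[half_idx] > 0 else (t[1] if len(t) > 1 else 1.0)
    p0 = (ymax, 1.0 / t_half)

    def model(tt, plateau, k):
        return plateau * (1.0 - np.exp(-k * tt))

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0, bounds=([1e-12, 1e-12], [2 * max(ymax, 1e-9), np.inf]),
            maxfev=10000,
        )
    except RuntimeError as e:
        raise ValueError(f"FRAP fit did not converge: {e}") from e
    plateau, k = float(popt[0]), float(popt[1])
    resid = y - model(t, plateau, k)
    return FrapFit(
        y0=0.0,
        plateau=plateau,
        k_per_s=k,
        half_life_s=float(np.log(2) / k),
        rss=float(resid @ resid),
    )
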