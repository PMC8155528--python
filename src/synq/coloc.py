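"""Colocalization and spatial-distribution readouts.

* **Pearson colocalization** over an analysis mask, with a 90° channel
  rotation as the randomization control: rotating one channel about the mask
  centroid destroys genuine spatial correspondence while preserving the
  intensity distribution, so r_rotated ≪ r supports true colocalization.
* **Spot–channel correlation**: each detected spot (1-μm circle) is scored in
  two channels, each normalized by its frame's whole-cell total (cancelling
  expression/dosage variation), binned into discrete groups by the spot
  channel, and summarized with a rank correlation.
* **Radial quartile (clock-scan) profile**: every in-mask pixel is assigned a
  normalized radius — its distance from the cell mass center divided by the
  boundary distance along the same direction — and mean intensity is reported
  in four quartile shells from center to periphery.  This is the readout used
  for receptor clustering at the synapse center.
* **IQR outlier filter**: Tukey fences at Q1 − 1.5·IQR / Q3 + 1.5·IQR with
  linear-interpolation quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import ImageStack
from .polarity import circle_mask
from .segment import Spot, detect_spots, mask_centroid_um

__all__ = [
    "ColocResult",
    "RadialProfile",
    "pearson_coloc",
    "rotation_control",
    "spot_channel_correlation",
    "radial_quartile_profile",
    "normalized_radius_map",
    "iqr_filter",
]

MIN_PIXELS = 10


@dataclass(frozen=True)
class ColocResult:
    r: float
    r_rotated: float | None
    n_pixels: int


@dataclass
class RadialProfile:
    quartile_mfi: np.ndarray  # 4 means, center -> periphery
    quartile_bounds: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    quartile_counts: np.ndarray | None = None
    non_star_fraction: float = 0.0  # pixels whose ray exited and re-entered the mask


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel inside the mask: Pearson undefined")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_coloc(ch_a: np.ndarray, ch_b: np.ndarray, mask: np.ndarray) -> ColocResult:
    """Sample Pearson correlation of two channels over the in-mask pixels."""
    n = int(mask.sum())
    if n < MIN_PIXELS:
        raise ValueError(f"analysis mask has {n} px; need >= {MIN_PIXELS}")
    r = _pearson(np.asarray(ch_a, float)[mask], np.asarray(ch_b, float)[mask])
    return ColocResult(r=r, r_rotated=None, n_pixels=n)


def rotation_control(
    ch_a: np.ndarray, ch_b: np.ndarray, mask: np.ndarray, *, angle_deg: float = 90.0
) -> ColocResult:
    """Pearson r plus the rotated-channel control coefficient.

    ``ch_b`` is rotated by ``angle_deg`` about the mask centroid (bilinear
    resampling); ``r_rotated`` is computed over the pixels of the mask whose
    rotated source lands inside the image.  ``r`` itself is unchanged.
    """
    base = pearson_coloc(ch_a, ch_b, mask)
    ch_b = np.asarray(ch_b, float)
    rows, cols = np.nonzero(mask)
    rc = rows.mean()
    cc = cols.mean()
    th = np.deg2rad(angle_deg)
    # source position = centroid + R(-angle) (p - centroid)
    dr, dc = rows - rc, cols - cc
    src_r = rc + np.cos(th) * dr + np.sin(th) * dc
    src_c = cc - np.sin(th) * dr + np.cos(th) * dc
    h, w = ch_b.shape
    valid = (src_r >= 0) & (src_r <= h - 1) & (src_c >= 0) & (src_c <= w - 1)
    if valid.sum() < MIN_PIXELS:
        raise ValueError("rotated overlap below the minimum pixel count")
    rotated_vals = ndimage.map_coordinates(
        ch_b, [src_r[valid], src_c[valid]], order=1, mode="constant"
    )
    a_vals = np.asarray(ch_a, float)[rows[valid], cols[valid]]
    return ColocResult(
        r=base.r, r_rotated=_pearson(a_vals, rotated_vals), n_pixels=int(valid.sum())
    )


def spot_channel_correlation(
    movie: ImageStack,
    spot_channel: int | str,
    partner_channel: int | str,
    cell_masks: list[np.ndarray],
    *,
    circle_diameter_um: float = 1.0,
    quality_threshold: float = 1.0,
    n_groups: int = 5,
    spots_per_frame: list[list[Spot]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-spot two-channel intensities, grouped summary, and rank correlation.

    For every spot (detected in ``spot_channel`` unless supplied), the mean
    intensity of both channels is measured in a circle of
    ``circle_diameter_um`` and divided by that frame's whole-cell total of
    the respective channel.  Spots are then arranged into ``n_groups``
    equal-count groups by the normalized spot-channel value; the summary
    reports mean ± SD of the partner channel per group, and Spearman's rho
    over all spots quantifies the monotone association.
    """
    cs = movie.channel_index(spot_channel)
    cp = movie.channel_index(partner_channel)
    px = movie.pixel_size_um
    radius = circle_diameter_um / 2
    records = []
    for t in range(movie.n_frames):
        img_s = movie.plane(t=t, c=cs)
        img_p = movie.plane(t=t, c=cp)
        mask = cell_masks[t]
        tot_s = float(img_s[mask].sum())
        tot_p = float(img_p[mask].sum())
        if tot_s <= 0 or tot_p <= 0:
            raise ValueError(f"frame {t}: zero total intensity")
        if spots_per_frame is None:
            spots = detect_spots(
                img_s, px, quality_threshold=quality_threshold, frame=t, mask=mask
            )
        else:
            spots = spots_per_frame[t]
        for s in spots:
            circ = circle_mask(img_s.shape, s.xy, radius, px)
            if not circ.any():
                continue
            records.append(
                {
                    "frame": t,
                    "x_um": s.xy[0],
                    "y_um": s.xy[1],
                    "spot_norm": float(img_s[circ].mean()) / tot_s,
                    "partner_norm": float(img_p[circ].mean()) / tot_p,
                }
            )
    per_spot = pd.DataFrame(records)
    if per_spot.empty:
        return per_spot, pd.DataFrame(), float("nan")
    ranks = per_spot["spot_norm"].rank(method="first")
    per_spot["group"] = pd.qcut(ranks, q=min(n_groups, len(per_spot)), labels=False)
    grouped = (
        per_spot.groupby("group")
        .agg(
            spot_norm_mean=("spot_norm", "mean"),
            partner_mean=("partner_norm", "mean"),
            partner_sd=("partner_norm", "std"),
            n=("partner_norm", "size"),
        )
        .reset_index()
    )
    rho = float(stats.spearmanr(per_spot["spot_norm"], per_spot["partner_norm"]).statistic)
    return per_spot, grouped, rho


def normalized_radius_map(
    mask: np.ndarray, *, step_px: float = 0.25
) -> tuple[np.ndarray, float]:
    """Normalized radius (0 at the centroid, 1 at the boundary) per in-mask pixel.

    For each pixel, a ray is marched from the mask centroid through the pixel
    at ``step_px`` spacing, sampling the binary mask with bilinear
    interpolation; the boundary distance is the first 0.5-crossing,
    sub-pixel-interpolated.  Returns the map (NaN outside the mask) and the
    fraction of pixels whose ray crossed out of the mask before reaching them
    (non-star-shaped geometry; those pixels are clipped to radius 1).
    """
    if not mask.any():
        raise ValueError("empty mask")
    maskf = mask.astype(float)
    rows, cols = np.nonzero(mask)
    rc, cc = rows.mean(), cols.mean()
    ri, ci = int(round(rc)), int(round(cc))
    if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
        raise ValueError("mask centroid lies outside the mask")
    dr = rows - rc
    dc = cols - cc
    r_pix = np.hypot(dr, dc)
    with np.errstate(invalid="ignore"):
        ur = np.where(r_pix > 0, dr / np.where(r_pix > 0, r_pix, 1), 0.0)
        uc = np.where(r_pix > 0, dc / np.where(r_pix > 0, r_pix, 1), 0.0)

    n = len(rows)
    boundary_r = np.full(n, np.nan)
    found = np.zeros(n, bool)
    prev_val = np.ones(n)
    max_r = float(r_pix.max()) + 2.0
    n_steps = int(np.ceil(max_r / step_px)) + 2
    for k in range(1, n_steps):
        rho = k * step_px
        pr = rc + ur * rho
        pc = cc + uc * rho
        val = ndimage.map_coordinates(maskf, [pr, pc], order=1, mode="constant")
        crossing = (~found) & (prev_val >= 0.5) & (val < 0.5)
        if crossing.any():
            frac = (prev_val[crossing] - 0.5) / (prev_val[crossing] - val[crossing])
            boundary_r[crossing] = (k - 1) * step_px + frac * step_px
            found[crossing] = True
        prev_val = val
        if found.all():
            break
    boundary_r[~found] = max_r  # ray never left the sampled window (should not happen)
    rnorm = np.clip(r_pix / boundary_r, 0.0, 1.0)
    non_star = float(np.mean(r_pix > boundary_r + step_px))
    out = np.full(mask.shape, np.nan)
    out[rows, cols] = rnorm
    return out, non_star


def radial_quartile_profile(channel: np.ndarray, cell_mask: np.ndarray) -> RadialProfile:
    """Clock-scan quartile profile: mean intensity in four radial shells.

    Every in-mask pixel gets a normalized radius (distance from the cell mass
    center over the boundary distance along its own direction) and is binned
    into quartile shells at {0–0.25, 0.25–0.5, 0.5–0.75, 0.75–1}; the profile
    is the mean fluorescence intensity per shell, ordered center → periphery.
    Masks that are not star-shaped about their centroid are flagged via
    ``non_star_fraction``.
    """
    channel = np.asarray(channel, float)
    rmap, non_star = normalized_radius_map(cell_mask)
    rows, cols = np.nonzero(cell_mask)
    rnorm = rmap[rows, cols]
    bins = np.minimum((rnorm * 4).astype(int), 3)
    vals = channel[rows, cols]
    mfi = np.zeros(4)
    counts = np.zeros(4, int)
    for q in range(4):
        sel = bins == q
        counts[q] = sel.sum()
        mfi[q] = vals[sel].mean() if sel.any() else 0.0
    return RadialProfile(quartile_mfi=mfi, quartile_counts=counts, non_star_fraction=non_star)


def iqr_filter(values, *, factor: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier rejection: keep x in [Q1 − f·IQR, Q3 + f·IQR].

    Quartiles by linear interpolation on the sorted data.  Returns
    ``(kept, rejected)``; the two partitions always reassemble the input.
    """
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("IQR filtering needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]
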