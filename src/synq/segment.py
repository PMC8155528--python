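"""Masks and landmarks: cell boundary, bead region, centrosome, spots, center ellipse.

Classical thresholding throughout: images are thresholded (Otsu by default)
and binarized to find the cell boundary, the largest connected component is
kept (single-cell fields), and holes are filled.  Landmark coordinates are
returned in μm under the pixel-center convention of :mod:`synq.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "CellGeometry",
    "Spot",
    "segment_cell",
    "locate_centrosome",
    "detect_spots",
    "fit_center_ellipse",
    "bead_region",
    "mask_centroid_um",
    "spot_radius_from_area",
]


def mask_centroid_um(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Centroid of a binary mask as an (x, y) point in μm."""
    if not mask.any():
        raise ValueError("empty mask has no centroid")
    rows, cols = np.nonzero(mask)
    return ((cols.mean() + 0.5) * pixel_size_um, (rows.mean() + 0.5) * pixel_size_um)


@dataclass
class CellGeometry:
    """The landmark set every positional index consumes.

    ``cmc_xy`` (cell mass center) and ``bmc_xy`` (bead mass center) are the
    centroids of the respective masks; ``centrosome_xy`` the detected (or
    ground-truth) centrosome position.  All points in μm.
    """

    cell_mask: np.ndarray
    pixel_size_um: float
    bead_mask: np.ndarray | None = None
    centrosome_xy: tuple[float, float] | None = None
    nucleus_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.cell_mask.any():
            raise ValueError("cell mask is empty")
        self.cmc_xy = mask_centroid_um(self.cell_mask, self.pixel_size_um)
        self.bmc_xy = (
            None
            if self.bead_mask is None
            else mask_centroid_um(self.bead_mask, self.pixel_size_um)
        )

    @property
    def cell_area_um2(self) -> float:
        return float(self.cell_mask.sum()) * self.pixel_size_um**2


@dataclass(frozen=True)
class Spot:
    """One detected sub-resolution particle."""

    frame: int
    xy: tuple[float, float]  # μm
    quality: float  # blob-detector response at the detected scale
    radius_um: float


def spot_radius_from_area(area_um2: float) -> float:
    """Nominal spot radius for a circular area spec (1 μm² → ≈0.564 μm)."""
    return float(np.sqrt(area_um2 / np.pi))


def segment_cell(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_um2: float = 5.0,
) -> np.ndarray:
    """Threshold + binarize a channel and return the cell mask.

    The largest connected foreground component is selected and its holes
    filled.  ``method`` is ``"otsu"`` (automatic, the default) or ``"fixed"``
    with an explicit ``threshold``.
    """
    image = np.asarray(image, float)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("constant image: Otsu threshold undefined")
        thr = threshold_otsu(image)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    binary = image > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == best)
    area = mask.sum() * pixel_size_um**2
    if area < min_area_um2:
        raise ValueError(f"largest component area {area:.2f} μm² < min_area {min_area_um2}")
    return mask


def locate_centrosome(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_um: float,
    *,
    smooth_sigma_um: float = 0.2,
    min_contrast: float = 1.05,
) -> tuple[float, float]:
    """Position of the brightest punctum inside the cell, in μm.

    The channel is smoothed at the PSF scale before maximum search (the raw
    brightest pixel is noise-sensitive); the reported point is the
    intensity-weighted centroid of the above-half-maximum region around the
    peak.  Ties between equal maxima are broken by the highest integrated
    intensity in a 3×3 neighbourhood.  A channel whose in-mask maximum does
    not exceed ``min_contrast`` × the in-mask mean is rejected as flat.
    """
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    sm = ndimage.gaussian_filter(np.asarray(channel, float), smooth_sigma_um / pixel_size_um)
    vals = sm[cell_mask]
    if vals.max() <= 0 or vals.max() < min_contrast * vals.mean():
        raise ValueError("no centrosome-like maximum: channel is flat inside the mask")
    peak = vals.max()
    cand = np.argwhere((sm >= peak) & cell_mask)
    if len(cand) > 1:
        sums = ndimage.uniform_filter(sm, 3)  # 3x3 mean ∝ integrated intensity
        cand = cand[np.argsort([-sums[r, c] for r, c in cand], kind="stable")]
    r0, c0 = cand[0]
    # weighted centroid of the above-half-max neighbourhood around the peak
    win = max(2, int(round(3 * smooth_sigma_um / pixel_size_um)))
    rs = slice(max(r0 - win, 0), r0 + win + 1)
    cs = slice(max(c0 - win, 0), c0 + win + 1)
    patch = sm[rs, cs].copy()
    patch[patch < peak / 2] = 0.0
    rows, cols = np.mgrid[rs, cs]
    w = patch.sum()
    rr = (rows * patch).sum() / w
    cc = (cols * patch).sum() / w
    return ((cc + 0.5) * pixel_size_um, (rr + 0.5) * pixel_size_um)


def detect_spots(
    channel: np.ndarray,
    pixel_size_um: float,
    *,
    spot_area_um2: float = 1.0,
    quality_threshold: float = 1.0,
    frame: int = 0,
    mask: np.ndarray | None = None,
) -> list[Spot]:
    """Laplacian-of-Gaussian blob detection at the scale of ``spot_area_um2``.

    Quality is the (sign-flipped) LoG response at the detected scale — a
    monotone analogue of a tracking plugin's quality index with the same
    thresholding semantics; only spots with quality ≥ ``quality_threshold``
    are returned.  Centers are sub-pixel via intensity-weighted centroids of
    the response peak.
    """
    if quality_threshold <= 0:
        raise ValueError("quality_threshold must be > 0")
    channel = np.asarray(channel, float)
    radius_um = spot_radius_from_area(spot_area_um2)
    # LoG scale: a Gaussian blob of radius r responds maximally near sigma = r/sqrt(2)
    sigma_px = radius_um / np.sqrt(2) / pixel_size_um
    resp = -ndimage.gaussian_laplace(channel, sigma_px) * sigma_px**2
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        resp,
        min_distance=max(1, int(round(sigma_px))),
        threshold_abs=quality_threshold,
        exclude_border=False,
    )
    spots = []
    win = max(1, int(round(sigma_px)))
    for r0, c0 in coords:
        if mask is not None and not mask[r0, c0]:
            continue
        q = float(resp[r0, c0])
        rs = slice(max(r0 - win, 0), r0 + win + 1)
        cs = slice(max(c0 - win, 0), c0 + win + 1)
        patch = np.clip(resp[rs, cs], 0, None)
        rows, cols = np.mgrid[rs, cs]
        w = patch.sum()
        if w == 0:
            rr, cc = float(r0), float(c0)
        else:
            rr = (rows * patch).sum() / w
            cc = (cols * patch).sum() / w
        spots.append(
            Spot(
                frame=frame,
                xy=((cc + 0.5) * pixel_size_um, (rr + 0.5) * pixel_size_um),
                quality=q,
                radius_um=radius_um,
            )
        )
    spots.sort(key=lambda s: (-s.quality, s.xy))
    return spots


def fit_center_ellipse(
    cell_mask: np.ndarray,
    pixel_size_um: float,
    *,
    area_fraction: float = 1.0 / 3.0,
    min_area_px: int = 16,
) -> np.ndarray:
    """The central ellipse holding ``area_fraction`` of the cell-mask area.

    The ellipse is centred on the cell mass center with orientation and axis
    ratio taken from the mask's second central moments, then scaled so its
    rasterized area matches ``area_fraction × area(cell_mask)`` as closely as
    the pixel grid allows (bisection on the scale factor).  Returned clipped
    to the cell mask.
    """
    n_px = int(cell_mask.sum())
    if n_px < min_area_px:
        raise ValueError(f"degenerate mask: {n_px} px")
    props = measure.regionprops(cell_mask.astype(np.uint8))[0]
    cy, cx = props.centroid  # row, col
    a_px = props.axis_major_length / 2
    b_px = props.axis_minor_length / 2
    if b_px == 0:
        raise ValueError("degenerate (line-like) mask")
    # regionprops orientation: angle between major axis and the row (vertical)
    # axis, counter-clockwise; convert to angle from the x axis
    theta = np.pi / 2 - props.orientation
    target = area_fraction * n_px

    rows, cols = np.mgrid[0 : cell_mask.shape[0], 0 : cell_mask.shape[1]]
    dx, dy = cols - cx, rows - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    # normalized elliptical radius at unit scale; pixel in ellipse iff rho <= s
    rho = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)

    lo, hi = 0.0, 1.5
    for _ in range(40):
        mid = (lo + hi) / 2
        if np.count_nonzero(rho <= mid) < target:
            lo = mid
        else:
            hi = mid
    ellipse = rho <= hi
    return ellipse & cell_mask


def bead_region(
    bead_mask: np.ndarray, pixel_size_um: float, *, margin_um: float = 0.25
) -> np.ndarray:
    """The fixed analysis area around a bead: the mask dilated isotropically.

    Uses a Euclidean distance transform, so the dilation is a true metric
    ball rather than a square structuring element.
    """
    if not bead_mask.any():
        raise ValueError("empty bead mask")
    if margin_um < 0:
        raise ValueError("margin must be >= 0")
    if margin_um == 0:
        return bead_mask.copy()
    dist = ndimage.distance_transform_edt(~bead_mask, sampling=pixel_size_um)
    return dist <= margin_um
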