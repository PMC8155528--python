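"""Positional fluorescence indices of immune-synapse polarization.

These are the ratio-of-fluorescence readouts used to score whether organelles
and labels have repositioned toward the antigen contact site:

* **polarity index** — signed projection of the centrosome onto the cell→bead
  axis, normalized by the axis length; +1 means the centrosome sits at the
  bead mass center (fully polarized), −1 the mirror position (anti-polarized);
* **bead recruitment** — percent of total fluorescence found in the bead
  contact region;
* **centrosome density index** — fluorescence density in a 1-μm circle at the
  centrosome over whole-cell density (>1: accumulation, <1: depletion);
* **center recruitment** — density in the central third-of-area ellipse over
  whole-cell density, minus 1 (positive: enriched at the synapse center);
* **Z profile** — in-mask mean intensity along Z from the coverslip to the
  upper cell limit, with the peak fraction flagging synaptic localization;
* **antigen extraction** — percent fluorescence lost from a bead;
* **centrosome–nucleus distance** — μm from the centrosome to the nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageStack
from .segment import CellGeometry, fit_center_ellipse

__all__ = [
    "PolarityResult",
    "DensityIndex",
    "ZProfile",
    "polarity_index",
    "bead_recruitment",
    "centrosome_density_index",
    "center_recruitment",
    "z_profile",
    "antigen_extraction",
    "centrosome_nucleus_distance",
    "circle_mask",
]


@dataclass(frozen=True)
class PolarityResult:
    index: float
    cent_proj_xy: tuple[float, float]
    axis_length_um: float
    out_of_range: bool  # |index| > 1: centrosome projects beyond the ±axis span


@dataclass(frozen=True)
class DensityIndex:
    value: float
    f_cent: float  # summed fluorescence in the centrosome circle
    a_cent_um2: float
    d_cell: float  # whole-cell fluorescence density (per μm²)


@dataclass(frozen=True)
class ZProfile:
    fraction_means: np.ndarray  # mean in-mask intensity per Z fraction, coverslip first
    peak_fraction: int  # 1-based
    synaptic: bool  # peak within fractions 1–2


def polarity_index(geometry: CellGeometry) -> PolarityResult:
    """Signed centrosome polarity index on the CMC→BMC axis.

    The centrosome position ``Cent`` is orthogonally projected onto the line
    through the cell mass center (CMC) and bead mass center (BMC); the index
    is the signed distance CMC→CentProj divided by |CMC−BMC|, positive toward
    the bead.  The projection itself makes the sign well defined, which is
    what lets the index span −1 (anti-polarized) to +1 (fully polarized).
    Values beyond ±1 (centrosome projecting past BMC or its mirror) are
    reported raw with ``out_of_range`` set.
    """
    if geometry.bmc_xy is None:
        raise ValueError("geometry has no bead: polarity axis undefined")
    if geometry.centrosome_xy is None:
        raise ValueError("geometry has no centrosome")
    cmc = np.asarray(geometry.cmc_xy, float)
    bmc = np.asarray(geometry.bmc_xy, float)
    cent = np.asarray(geometry.centrosome_xy, float)
    axis = bmc - cmc
    length = float(np.hypot(*axis))
    if length == 0:
        raise ValueError("CMC and BMC coincide: zero-length polarity axis")
    unit = axis / length
    s = float(np.dot(cent - cmc, unit))  # signed distance CMC -> CentProj
    proj = cmc + s * unit
    index = s / length
    return PolarityResult(
        index=index,
        cent_proj_xy=(float(proj[0]), float(proj[1])),
        axis_length_um=length,
        out_of_range=abs(index) > 1.0,
    )


def bead_recruitment(
    channel: np.ndarray, bead_region_mask: np.ndarray, cell_mask: np.ndarray
) -> float:
    """Percent of whole-cell fluorescence located at the bead contact region.

    ``100 × Σ(channel in bead region) / Σ(channel in cell ∪ bead region)``.
    The denominator is the union because the bead contact area may extend
    past the segmented cell edge.
    """
    channel = np.asarray(channel, float)
    total = float(channel[cell_mask | bead_region_mask].sum())
    if total <= 0:
        raise ValueError("zero total fluorescence: recruitment undefined")
    return 100.0 * float(channel[bead_region_mask].sum()) / total


def circle_mask(
    shape: tuple[int, int], center_xy_um, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Pixels whose centers lie within ``radius_um`` of a point (μm)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = (xx + 0.5) * pixel_size_um
    y = (yy + 0.5) * pixel_size_um
    return (x - center_xy_um[0]) ** 2 + (y - center_xy_um[1]) ** 2 <= radius_um**2


def centrosome_density_index(
    channel: np.ndarray,
    centrosome_xy: tuple[float, float],
    cell_mask: np.ndarray,
    pixel_size_um: float,
    *,
    radius_um: float = 1.0,
) -> DensityIndex:
    """Fluorescence density in a circle at the centrosome over whole-cell density.

    A circle of ``radius_um`` (default 1 μm) is traced around the centrosome;
    ``DCent = FCent / ACent`` is divided by the whole-cell density
    ``DCell = FCell / ACell``.  Values above 1 indicate accumulation of the
    label at the centrosome, below 1 depletion.
    """
    channel = np.asarray(channel, float)
    circ = circle_mask(channel.shape, centrosome_xy, radius_um, pixel_size_um)
    ci = int(centrosome_xy[1] / pixel_size_um)
    cj = int(centrosome_xy[0] / pixel_size_um)
    if not (0 <= ci < cell_mask.shape[0] and 0 <= cj < cell_mask.shape[1]) or not cell_mask[
        ci, cj
    ]:
        raise ValueError("circle center lies outside the cell mask")
    px2 = pixel_size_um**2
    f_cent = float(channel[circ].sum())
    a_cent = float(circ.sum()) * px2
    f_cell = float(channel[cell_mask].sum())
    a_cell = float(cell_mask.sum()) * px2
    if f_cell <= 0:
        raise ValueError("whole-cell fluorescence is zero")
    d_cell = f_cell / a_cell
    return DensityIndex(
        value=(f_cent / a_cent) / d_cell, f_cent=f_cent, a_cent_um2=a_cent, d_cell=d_cell
    )


def center_recruitment(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_um: float,
    *,
    center_mask: np.ndarray | None = None,
    area_fraction: float = 1.0 / 3.0,
) -> float:
    """Density ratio of the central ellipse to the whole cell, minus 1.

    The central region is the concentric ellipse holding ``area_fraction``
    (default one third) of the cell area (see
    :func:`synq.segment.fit_center_ellipse`).  Positive values mean the
    fluorescence is enriched at the synapse center, negative depleted; the
    floor is −1 (no fluorescence at the center at all).
    """
    channel = np.asarray(channel, float)
    if center_mask is None:
        center_mask = fit_center_ellipse(cell_mask, pixel_size_um, area_fraction=area_fraction)
    f_cell = float(channel[cell_mask].sum())
    if f_cell <= 0:
        raise ValueError("whole-cell fluorescence is zero")
    n_center = int(center_mask.sum())
    if n_center == 0:
        raise ValueError("empty center region")
    dens_center = float(channel[center_mask].sum()) / n_center
    dens_cell = f_cell / int(cell_mask.sum())
    return dens_center / dens_cell - 1.0


def z_profile(
    stack: ImageStack,
    channel: int | str,
    cell_mask: np.ndarray,
    *,
    n_fractions: int = 10,
    frame: int = 0,
    upper_limit_rel: float = 0.05,
    z_top: int | None = None,
) -> ZProfile:
    """Mean in-mask intensity along Z, binned into fractions from the coverslip.

    Plane 0 is the coverslip.  The upper cell limit is ``z_top`` when given
    (e.g. from a cytosolic channel or known cell height); otherwise it is
    auto-detected as the last plane whose in-mask mean exceeds
    ``upper_limit_rel`` × the maximum plane mean of this channel.  The
    axis from coverslip to that limit is divided into ``n_fractions`` equal
    fractions (1-based, fraction 1 at the coverslip).  The peak fraction
    localizes the label in Z; a peak within fractions 1–2 (the synaptic Z
    area) flags the label as recruited to the synapse.
    """
    c = stack.channel_index(channel)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    n_z = stack.n_planes
    if not 2 <= n_fractions <= n_z:
        raise ValueError(f"need 2 <= n_fractions <= Z={n_z}")
    plane_means = np.array(
        [stack.pixels[frame, z, c][cell_mask].mean() for z in range(n_z)]
    )
    top = plane_means.max()
    if top <= 0:
        raise ValueError("no in-mask signal in any plane")
    if z_top is None:
        above = np.nonzero(plane_means > upper_limit_rel * top)[0]
        z_top = int(above[-1])
    elif not 0 < z_top < n_z:
        raise ValueError(f"z_top must lie in 1..{n_z - 1}")
    # normalized z in [0, 1] over coverslip..upper limit; plane centers
    if z_top == 0:
        raise ValueError("upper cell limit at the coverslip: profile degenerate")
    zn = np.arange(z_top + 1) / z_top
    bins = np.clip((zn * n_fractions).astype(int), 0, n_fractions - 1)
    means = np.zeros(n_fractions)
    for f in range(n_fractions):
        sel = bins == f
        means[f] = plane_means[: z_top + 1][sel].mean() if sel.any() else 0.0
    peak = int(np.argmax(means)) + 1
    return ZProfile(fraction_means=means, peak_fraction=peak, synaptic=peak <= 2)


def antigen_extraction(before: float, after: float) -> tuple[float, bool]:
    """Percent of bead fluorescence lost between two timepoints.

    Both values are total fluorescence over the same fixed bead region,
    measured on sum-of-planes Z projections.  Returns
    ``(100 × (1 − after/before), flagged)``; a gain (after > before, e.g.
    staining variability) is floored at 0% and flagged.
    """
    if before <= 0:
        raise ValueError("'before' fluorescence must be > 0")
    pct = 100.0 * (1.0 - after / before)
    if pct < 0:
        return 0.0, True
    return pct, False


def centrosome_nucleus_distance(
    centrosome_xy: tuple[float, float],
    nucleus_mask: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Euclidean distance (μm) from the centrosome to the nucleus boundary.

    Zero when the centrosome lies inside (or on) the nucleus.
    """
    if nucleus_mask is None or not nucleus_mask.any():
        raise ValueError("nucleus mask missing or empty")
    ci = int(centrosome_xy[1] / pixel_size_um)
    cj = int(centrosome_xy[0] / pixel_size_um)
    if 0 <= ci < nucleus_mask.shape[0] and 0 <= cj < nucleus_mask.shape[1]:
        if nucleus_mask[ci, cj]:
            return 0.0
    boundary = nucleus_mask & ~ndimage.binary_erosion(nucleus_mask)
    rows, cols = np.nonzero(boundary)
    bx = (cols + 0.5) * pixel_size_um
    by = (rows + 0.5) * pixel_size_um
    d = np.hypot(bx - centrosome_xy[0], by - centrosome_xy[1])
    return float(d.min())
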