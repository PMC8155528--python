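"""Independent brute-force oracles used to cross-check production code.

Everything here is deliberately written as plain Python loops over pixels and
explicit enumeration — no vectorized shortcuts and no calls into the package
internals being checked — so agreement with the production implementations is
a genuine dual-route verification.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_centroid_um(mask, px):
    xs, ys, n = 0.0, 0.0, 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                xs += (c + 0.5) * px
                ys += (r + 0.5) * px
                n += 1
    return xs / n, ys / n


def brute_polarity_index(cell_mask, bead_mask, cent_xy, px):
    cmx, cmy = brute_centroid_um(cell_mask, px)
    bmx, bmy = brute_centroid_um(bead_mask, px)
    ax, ay = bmx - cmx, bmy - cmy
    length = math.hypot(ax, ay)
    s = ((cent_xy[0] - cmx) * ax + (cent_xy[1] - cmy) * ay) / length
    return s / length


def brute_bead_recruitment(channel, region, cell_mask):
    num, den = [], []
    for r in range(channel.shape[0]):
        for c in range(channel.shape[1]):
            if region[r, c]:
                num.append(channel[r, c])
            if region[r, c] or cell_mask[r, c]:
                den.append(channel[r, c])
    return 100.0 * math.fsum(num) / math.fsum(den)


def brute_density_index(channel, cent_xy, cell_mask, px, radius_um=1.0):
    f_circ, n_circ, f_cell, n_cell = [], 0, [], 0
    for r in range(channel.shape[0]):
        for c in range(channel.shape[1]):
            x, y = (c + 0.5) * px, (r + 0.5) * px
            if (x - cent_xy[0]) ** 2 + (y - cent_xy[1]) ** 2 <= radius_um**2:
                f_circ.append(channel[r, c])
                n_circ += 1
            if cell_mask[r, c]:
                f_cell.append(channel[r, c])
                n_cell += 1
    d_cent = math.fsum(f_circ) / (n_circ * px * px)
    d_cell = math.fsum(f_cell) / (n_cell * px * px)
    return d_cent / d_cell


def brute_center_recruitment(channel, cell_mask, center_mask):
    f_ctr, n_ctr, f_cell, n_cell = [], 0, [], 0
    for r in range(channel.shape[0]):
        for c in range(channel.shape[1]):
            if center_mask[r, c]:
                f_ctr.append(channel[r, c])
                n_ctr += 1
            if cell_mask[r, c]:
                f_cell.append(channel[r, c])
                n_cell += 1
    return (math.fsum(f_ctr) / n_ctr) / (math.fsum(f_cell) / n_cell) - 1.0


def _bilinear(img, r, c):
    """Bilinear sample with zero outside the array (hand-rolled)."""
    h, w = img.shape
    r0, c0 = math.floor(r), math.floor(c)
    out = 0.0
    for dr in (0, 1):
        for dc in (0, 1):
            rr, cc = r0 + dr, c0 + dc
            wgt = (1 - abs(r - rr)) * (1 - abs(c - cc))
            if wgt > 0 and 0 <= rr < h and 0 <= cc < w:
                out += wgt * img[rr, cc]
    return out


def brute_radial_bins(mask, step_px=0.25):
    """Quartile bin per in-mask pixel by per-pixel ray casting from the centroid.

    Returns (bins dict keyed by (row, col), normalized radius dict).
    """
    maskf = mask.astype(float)
    rows, cols = np.nonzero(mask)
    rc, cc = rows.mean(), cols.mean()
    max_r = 0.0
    for r, c in zip(rows, cols):
        max_r = max(max_r, math.hypot(r - rc, c - cc))
    n_steps = int(math.ceil((max_r + 2.0) / step_px)) + 2
    bins, rnorms = {}, {}
    for r, c in zip(rows, cols):
        dr, dc = r - rc, c - cc
        rad = math.hypot(dr, dc)
        if rad == 0:
            bins[(r, c)] = 0
            rnorms[(r, c)] = 0.0
            continue
        ur, uc = dr / rad, dc / rad
        prev = 1.0
        boundary = None
        for k in range(1, n_steps):
            rho = k * step_px
            val = _bilinear(maskf, rc + ur * rho, cc + uc * rho)
            if prev >= 0.5 and val < 0.5:
                frac = (prev - 0.5) / (prev - val)
                boundary = (k - 1) * step_px + frac * step_px
                break
            prev = val
        if boundary is None:
            boundary = (n_steps - 1) * step_px
        rn = min(max(rad / boundary, 0.0), 1.0)
        bins[(r, c)] = min(int(rn * 4), 3)
        rnorms[(r, c)] = rn
    return bins, rnorms


def exhaustive_link(spots_per_frame, max_disp_um):
    """Frame-to-frame linking by exhaustive minimal-total-distance assignment.

    For each transition, enumerates every injective matching between active
    track ends and new spots whose links all respect ``max_disp_um``, and
    keeps the maximum-cardinality matching with minimal total distance.
    Returns tracks as tuples of (frame, xy) points.
    """
    tracks = []  # list of lists of (frame, xy)
    active = []
    for frame, spots in enumerate(spots_per_frame):
        spots = sorted(spots, key=lambda s: s.xy)
        if frame == 0:
            for s in spots:
                tracks.append([(0, s.xy)])
                active.append(tracks[-1])
            continue
        n_t, n_s = len(active), len(spots)
        dist = [
            [math.hypot(s.xy[0] - tr[-1][1][0], s.xy[1] - tr[-1][1][1]) for s in spots]
            for tr in active
        ]
        best = (0, 0.0, ())  # (-cardinality later), total, pairs
        best_card, best_total, best_pairs = -1, float("inf"), ()
        k_max = min(n_t, n_s)
        for k in range(k_max, -1, -1):
            if best_card > k:
                break
            for t_idx in itertools.combinations(range(n_t), k):
                for s_perm in itertools.permutations(range(n_s), k):
                    if any(dist[t][s] > max_disp_um for t, s in zip(t_idx, s_perm)):
                        continue
                    total = math.fsum(dist[t][s] for t, s in zip(t_idx, s_perm))
                    if k > best_card or (k == best_card and total < best_total):
                        best_card, best_total = k, total
                        best_pairs = tuple(zip(t_idx, s_perm))
            if best_card == k and best_card >= 0:
                break
        used_s = set()
        survivors = []
        for t, s in best_pairs:
            active[t].append((frame, spots[s].xy))
            survivors.append(active[t])
            used_s.add(s)
        for s_idx, s in enumerate(spots):
            if s_idx not in used_s:
                tracks.append([(frame, s.xy)])
                survivors.append(tracks[-1])
        active = survivors
    return tracks


def brute_quartiles_linear(values):
    """Q1/Q3 by linear interpolation on sorted data, written out longhand."""
    v = sorted(values)
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.75)
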