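"""Particle linking and track statistics: counts, durations, diffusion rates.

Spots detected per frame are linked into tracks by greedy nearest-neighbour
assignment: candidate (track, spot) pairs within ``max_disp_um`` are taken in
ascending order of distance, each track and spot used at most once per frame;
unmatched spots open new tracks and a track closes after ``max_gap_frames``
frames without a match.  Linking is deterministic and invariant to the order
spots are listed within a frame (ties are broken by distance, then by spot
position).

The per-track diffusion coefficient comes from the time-averaged mean squared
displacement: for Brownian motion in the synaptic plane ``MSD(τ) = 4 D τ``,
so D is a quarter of the through-origin slope of MSD against lag time, fit
over the first quarter of available lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import Spot

__all__ = [
    "Track",
    "DiffusionEstimate",
    "link_tracks",
    "track_stats",
    "msd_curve",
    "diffusion_coefficient",
]


@dataclass
class Track:
    """A time-ordered particle trajectory (positions in μm)."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    xy_um: list[tuple[float, float]] = field(default_factory=list)
    frame_interval_s: float = 1.0

    def __post_init__(self):
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        """(last − first frame) × Δt: an interval, not a point count."""
        if not self.frames:
            return 0.0
        return (self.frames[-1] - self.frames[0]) * self.frame_interval_s

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.xy_um, float)

    @property
    def total_displacement_um(self) -> float:
        p = self.positions
        return float(np.hypot(*(p[-1] - p[0]))) if len(p) >= 2 else 0.0

    @property
    def path_length_um(self) -> float:
        p = self.positions
        if len(p) < 2:
            return 0.0
        return float(np.hypot(*np.diff(p, axis=0).T).sum())


@dataclass(frozen=True)
class DiffusionEstimate:
    d_um2_s: float
    n_points_used: int  # MSD lags entering the fit
    fit_r2: float
    truncated: bool = False  # negative raw slope clipped to 0


def link_tracks(
    spots_per_frame: list[list[Spot]],
    *,
    max_disp_um: float,
    max_gap_frames: int = 0,
    frame_interval_s: float = 1.0,
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    ``spots_per_frame[i]`` holds the detections of frame ``i`` (contiguous
    frames).  Within each frame transition, candidate pairs are sorted by
    (distance, track id, spot position) and assigned greedily, so no link
    ever exceeds ``max_disp_um`` and the result does not depend on the input
    order of spots within a frame.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be > 0")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    tracks: list[Track] = []
    active: list[Track] = []

    def new_track(frame, spot):
        t = Track(
            track_id=len(tracks), frames=[frame], xy_um=[spot.xy],
            frame_interval_s=frame_interval_s,
        )
        tracks.append(t)
        active.append(t)

    for frame, spots in enumerate(spots_per_frame):
        spots = sorted(spots, key=lambda s: s.xy)  # input-order invariance
        if frame == 0:
            for s in spots:
                new_track(frame, s)
            continue
        candidates = []
        for ti, tr in enumerate(active):
            last = np.asarray(tr.xy_um[-1])
            for si, s in enumerate(spots):
                d = float(np.hypot(*(np.asarray(s.xy) - last)))
                if d <= max_disp_um:
                    candidates.append((d, tr.track_id, s.xy, ti, si))
        candidates.sort()
        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        for d, _, _, ti, si in candidates:
            if ti in used_tracks or si in used_spots:
                continue
            used_tracks.add(ti)
            used_spots.add(si)
            active[ti].frames.append(frame)
            active[ti].xy_um.append(spots[si].xy)
        for si, s in enumerate(spots):
            if si not in used_spots:
                new_track(frame, s)
        # retire tracks that have gone unmatched for longer than the gap allowance
        active = [tr for tr in active if frame - tr.frames[-1] <= max_gap_frames]
    return tracks


def track_stats(tracks: list[Track]) -> pd.DataFrame:
    """Per-track summary: duration, displacement, path length, diffusion rate.

    Tracks too short for a diffusion estimate get NaN in ``d_um2_s``.  An
    empty input yields an empty table.
    """
    rows = []
    for tr in tracks:
        try:
            d = diffusion_coefficient(tr).d_um2_s
        except ValueError:
            d = np.nan
        rows.append(
            {
                "track_id": tr.track_id,
                "n_points": tr.n_points,
                "duration_s": tr.duration_s,
                "total_displacement_um": tr.total_displacement_um,
                "path_length_um": tr.path_length_um,
                "d_um2_s": d,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "n_points", "duration_s", "total_displacement_um",
            "path_length_um", "d_um2_s",
        ],
    )


def msd_curve(track: Track, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD(τ) for lags 1..max_lag (τ in s, MSD in μm²)."""
    p = track.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.array(
        [np.mean(np.sum((p[lag:] - p[:-lag]) ** 2, axis=1)) for lag in lags]
    )
    return lags * track.frame_interval_s, msd


def diffusion_coefficient(track: Track, *, max_lag_fraction: float = 0.25) -> DiffusionEstimate:
    """D from a through-origin OLS fit of the time-averaged MSD.

    Lags up to ``max_lag_fraction`` of the track length are used (at least
    two), the standard bias/variance compromise for single-track estimates;
    ``MSD = 4 D τ`` for planar Brownian motion, so D = slope / 4.  A negative
    raw slope (possible for localization noise on a confined track) is
    truncated to 0 and flagged.
    """
    if track.n_points < 8:
        raise ValueError(f"track has {track.n_points} points; need >= 8")
    max_lag = max(2, int(np.floor(max_lag_fraction * (track.n_points - 1))))
    tau, msd = msd_curve(track, max_lag)
    slope = float((msd @ tau) / (tau @ tau))  # OLS through origin
    pred = slope * tau
    ss_tot = float(((msd - msd.mean()) ** 2).sum())
    ss_res = float(((msd - pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d = slope / 4.0
    if d < 0:
        return DiffusionEstimate(0.0, len(tau), r2, truncated=True)
    return DiffusionEstimate(d, len(tau), r2)
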