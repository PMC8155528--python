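"""Proteasome-like particle tracking and diffusion estimation.

Renders diffusing sub-resolution spots at the diffusion scale measured for
synaptic proteasome particles (D = 0.074 μm²/s), detects them frame by frame,
links them into tracks and estimates per-track diffusion coefficients from
the mean squared displacement.
"""

import numpy as np

from synq.segment import detect_spots
from synq.synthetic import make_brownian_movie
from synq.tracking import link_tracks, track_stats

D_TRUE = 0.074  # μm²/s
movie, truth_tracks = make_brownian_movie(
    diffusion_um2_s=D_TRUE, n_particles=12, n_frames=40, frame_interval_s=0.75, seed=1
)

spots = [
    detect_spots(movie.plane(t=t), movie.pixel_size_um, quality_threshold=5.0, frame=t)
    for t in range(movie.n_frames)
]
tracks = link_tracks(
    spots, max_disp_um=1.0, frame_interval_s=movie.frame_interval_s
)
stats = track_stats(tracks)
long = stats[stats.n_points >= 10]

print(f"{len(tracks)} tracks from {sum(map(len, spots))} detections")
print(f"median duration      {stats['duration_s'].median():.2f} s")
print(f"median displacement  {stats['total_displacement_um'].median():.2f} um")
print(f"median D             {long['d_um2_s'].median():.3f} um^2/s  (truth {D_TRUE})")
# Track number and duration report how persistently particles reside at the
# synaptic plane; D near 0.074 μm²/s reflects the limited mobility of
# proteasome particles there. Single-track MSD estimates scatter widely, so
# population medians over hundreds of tracks are what the tests validate.
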