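"""Colocalization with the rotation control, and radial quartile profiling.

Builds a two-channel scene whose channels share an off-axis punctate pattern,
verifies the correlation collapses under a 90° rotation of one channel, then
profiles a centrally clustered receptor-like label into radial quartiles
after IQR outlier filtering.
"""

import numpy as np

from synq.coloc import iqr_filter, radial_quartile_profile, rotation_control
from synq.synthetic import disk_mask

PX = 0.1
shape = (256, 256)
yy, xx = np.mgrid[0:256, 0:256]
x, y = (xx + 0.5) * PX, (yy + 0.5) * PX
mask = disk_mask(shape, (12.8, 12.8), 9.0, PX)

rng = np.random.default_rng(0)
puncta = sum(
    np.exp(-((x - px_) ** 2 + (y - py_) ** 2) / (2 * 0.3**2))
    for px_, py_ in rng.uniform(6, 20, (15, 2))
)
ch_a = puncta + rng.normal(0, 0.02, shape) ** 2
ch_b = 1.6 * puncta + rng.normal(0, 0.02, shape) ** 2

res = rotation_control(ch_a, ch_b, mask)
print(f"Pearson r          {res.r:.3f}")
print(f"after 90° rotation {res.r_rotated:.3f}  (n = {res.n_pixels} px)")
# r near 1 with a collapsed rotated control indicates genuine pixel-level
# colocalization rather than shared coarse geometry.

bcr = np.exp(-((x - 12.8) ** 2 + (y - 12.8) ** 2) / (2 * 2.5**2))
prof = radial_quartile_profile(bcr, mask)
for q, v in enumerate(prof.quartile_mfi, 1):
    print(f"quartile {q} MFI     {v:.3f}")
# Quartile 1 (center) dominating quartile 4 (periphery) is the signature of
# receptor clustering at the synapse center.

values = np.concatenate([rng.normal(1.0, 0.1, 30), [5.0]])
kept, rejected = iqr_filter(values)
print(f"IQR filter kept {len(kept)}/{len(values)} cells, rejected {rejected.round(2)}")
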