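"""Antigen extraction from a bead, scored on sum-of-planes Z projections.

Builds before/after Z-stacks of an OVA-coated bead, collapses them with the
sum projection, measures fluorescence over a fixed dilated bead region and
reports the percentage of antigen extracted.
"""

import numpy as np

from synq.io import ImageStack, sum_projection
from synq.polarity import antigen_extraction
from synq.segment import bead_region
from synq.synthetic import disk_mask

PX = 0.1
shape = (96, 96)
bead = disk_mask(shape, (4.8, 4.8), 1.5, PX)
region = bead_region(bead, PX, margin_um=0.25)  # fixed for both timepoints

def bead_stack(level, n_z=5):
    planes = np.stack([np.where(bead, level, 0.0) for _ in range(n_z)])
    return ImageStack.from_array(planes, "ZYX", pixel_size_um=PX, z_step_um=0.5)

before = sum_projection(bead_stack(100.0), 0)[region].sum()
after = sum_projection(bead_stack(42.0), 0)[region].sum()
pct, flagged = antigen_extraction(before, after)

print(f"bead fluorescence  before {before:.0f}, after {after:.0f} (a.u.)")
print(f"antigen extracted  {pct:.1f} %")
# 58% of the bead-bound antigen fluorescence was lost over the chase — the
# functional readout of successful extraction at the synapse.
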