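# synq — quantitative image analysis of the B-cell immune synapse

`synq` implements the fluorescence-microscopy measurements used to
characterize immune-synapse formation in B lymphocytes: organelle
polarization toward an antigen-coated bead or coverslip, recruitment of
labels to the synaptic interface, actin dynamics at the cell cortex, particle
mobility in the synaptic plane, and antigen extraction. It is aimed at cell
biologists who have calibrated TIFF stacks (or want ground-truthed synthetic
ones) and need these readouts as reproducible, tested code rather than ad hoc
macros.

## The measurements

**Centrosome polarity index.** With cell mass center CMC, bead mass center
BMC and centrosome position Cent, the centrosome is orthogonally projected
onto the CMC→BMC axis (CentProj) and

&nbsp;&nbsp;&nbsp;&nbsp;index = ⟨Cent − CMC, û⟩ / ‖BMC − CMC‖,&nbsp;&nbsp; û = (BMC − CMC)/‖BMC − CMC‖,

a signed quantity ranging from −1 (anti-polarized) through 0 (unpolarized) to
+1 (centrosome at the bead mass center).

**Recruitment and density indices.** Bead recruitment is
100 × F(bead region)/F(cell ∪ bead region); the centrosome density index is
(F_cent/A_cent)/(F_cell/A_cell) for a 1-μm-radius circle at the centrosome
(>1 = accumulation); center recruitment is the density ratio of the central
third-of-area ellipse to the whole cell, minus 1.

**FRAP kinetics.** Bleach-ROI intensity is normalized to an unbleached
control region, y-shifted to (0, 0) at the bleach event, and fit to
Y = plateau·(1 − e^(−k·t)) with Y₀ pinned to 0; half-life = ln 2/k.

**Retrograde flow.** A kymograph is resliced along a lamellipodium line; on
axes scaled to μm (space) and s (time) the flow-trace angle from the time
axis gives V (μm/s) = tan(angle in radians).

**Tracking and diffusion.** Spots of ~1 μm² are LoG-detected, linked by
greedy nearest-neighbour assignment, and each track's diffusion coefficient
comes from the through-origin fit MSD(τ) = 4Dτ over the first quarter of
lags.

**Colocalization and distribution.** Pearson's r over a mask with a
90°-rotation control; spot-wise two-channel correlation normalized per frame;
radial quartile (clock-scan) profiles with per-pixel normalized radii; Tukey
IQR outlier filtering.

Every metric is validated against the package's own synthetic-scene
generator (`synq.synthetic`), which renders disk cells, tangent 3-μm beads,
punctate centrosomes, cortical actin, diffusing spots, recovering FRAP
curves and translating flow edges with exact ground truth.

## Worked example

`examples/01_polarity_indices.py` renders a polarized cell (centrosome
displaced 70% of the way to the bead, bead-localized antigen channel,
centrin-like centrosome label) and prints:

```
polarity index           +0.609
bead recruitment          100.0 %
centrosome density index   99.1
center recruitment       +0.000
```

The index +0.609 says the centrosome has covered ~60% of the CMC→BMC axis;
100% bead recruitment means the antigen channel lies entirely in the bead
contact region; a density index ≫1 reports strong accumulation of the
centrin label in the 1-μm centrosome circle; and center recruitment 0 is the
expected value for a spatially uniform cytosolic channel. The other scripts
in `examples/` demonstrate FRAP fitting, flow velocimetry, tracking,
colocalization/radial profiling, spreading and antigen extraction the same
way.

A thin CLI mirrors the library for shell use, e.g.

```bash
synq simulate scene --out demo
synq segment demo.tif --centrosome-channel 1 --out seg
synq polarity demo.tif --labels demo_labels.tif --landmarks demo.json --out pol.csv
```

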