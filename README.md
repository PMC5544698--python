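# kymoflow

Kymograph motion analysis for growing neurons: a rotation-augmented optical
flow estimator with a ground-truth line benchmark, growth-cone-aligned
velocity profiles, and a microtubule transport mass budget.

## The problem

In a kymograph — a space-time image with one row per movie frame and one
column per position along a neurite — a moving object draws a streak whose
slope is its velocity in pixels per frame (p/f). Fluorescent speckle
microscopy of microtubules (MTs) in growing axons produces kymographs that
mix two very different motion regimes: slow bulk translocation of the MT
array (μm/h scale, well below 1 p/f) and fast motor-driven transport of
individual short MTs (μm/s scale, many p/f). Gradient-based optical flow
such as Lucas–Kanade (LK) is accurate only for sub-pixel displacements, so
neither regime alone covers a kymograph.

## The estimator

`kymoflow` exploits a geometric identity: swapping the time and distance
axes of a kymograph maps a streak of slope v to a streak of slope 1/v, so
fast motion (10 p/f) becomes slow motion (0.1 p/f). The same 1-D+time LK
kernel

    v(x, t) = − Σ_w I_x I_t / Σ_w I_x²

is run on the original and the axis-swapped image; the swapped branch is
back-transformed (v ← 1/v, coordinates mapped back) and the branches are
merged per pixel — the unrotated estimate for |v| below 1 p/f, the rotated
one above, their average in a hysteresis band around the 1 p/f symmetry
point. Accuracy is scored on a synthetic benchmark of 91 kymographs with a
single anti-aliased line rotated from 0° to −90° in 1° steps (velocity =
cot|angle|), using the average absolute angular error (AAE): per-pixel
velocities are converted to angles via θ = −arctan(1/v), averaged per
image, and compared with the known input angle.

Downstream, flow maps are calibrated to μm/h (v × pixel_size /
frame_interval × 3600), sheared row-by-row so the advancing growth cone
occupies a fixed column, averaged column-wise into velocity-vs-distance
profiles, and aligned at the T-zone — the retrograde→anterograde zero
crossing — so profiles from many cells can be averaged and regressed.
Fast transport is quantified separately from hand-style traces: the flux
Φ (MT/min) of fast speckles (|v| ≥ 0.05 μm/s) crossing the kymograph
centre per direction, and the mass budget

    Φ_net = Φ_antero − Φ_retro,   growth = 60 Φ_net · L_MT / N_cs

where L_MT is the mean transported MT length and N_cs the number of MTs
per axonal cross-section.

A `synthkymo` module simulates speckle kymographs of a growing neurite
(bulk anterograde flow along the axon, retrograde P-domain flow, a T-zone
advancing with the growth cone, Poisson fast-transport events) with full
ground truth, so every pipeline stage is testable without any external
data.

## Worked example

Mass budget from measured fluxes (0.5 and 0.38 MT/min), a 3.59 μm mean
transported MT length and 22 MTs per cross-section:

```python
>>> from kymoflow import mass_budget, net_flux_from_rate_fraction
>>> b = mass_budget(0.5, 0.38, mt_length=3.59, mt_per_cross_section=22)
>>> b.rounded()
{'antero_flux_mt_min': 0.5, 'retro_flux_mt_min': 0.38,
 'net_flux_mt_min': 0.12, 'net_flux_mt_h': 7.2, 'mt_length_um': 3.59,
 'transported_um_h': 26, 'mt_per_cross_section': 22,
 'net_axonal_growth_um_h': 1.2, 'mean_interval_min': 8.3}
>>> round(net_flux_from_rate_fraction(4.2, 0.87), 2)
0.18
```

Reading: a net flux of 0.12 MT/min (one net anterograde MT every 8.3 min)
delivers 26 μm of MT polymer per hour, equivalent to only 1.2 μm/h of
axon growth — far below typical elongation rates of ~24 μm/h, so rapid
transport of individual MTs cannot account for bulk MT advance.

The benchmark from the command line:

```
$ kymo benchmark --algo both --out bench.csv
lk: AAE full 0.040 deg, restricted 0.040 deg
kymoflow: AAE full 0.037 deg, restricted 0.038 deg
paired t-test p = 0.00013
```

Both estimators resolve noise-free lines well (an AAE below 2° is the
usual bar for motion trackers); the rotation-augmented estimator is
significantly more accurate, and under realistic noise the gap widens
sharply for fast angles, where the plain LK baseline collapses
(`kymo benchmark --noise-sd 0.1 ...`).

Other subcommands: `kymo build` (reslice a movie along an ROI polyline into
a kymograph), `kymo simulate` (synthetic neurite kymograph + ground truth),
`kymo flow` (velocity map TIFF), `kymo profile` (sheared, T-zone-aligned
velocity-vs-distance CSV), `kymo flux` (directional flux and mass budget
from a trace CSV).

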