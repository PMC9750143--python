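# tubesort

Quantitative analysis of membrane-curvature sensing and induction by
peripheral membrane proteins, built around two classic assays:

1. **GUV + nanotube pulling.** A membrane nanotube pulled from a giant
   unilamellar vesicle (GUV) by an optically trapped bead creates a
   contiguous membrane with a highly curved tube (radius tens of nm) next to
   an essentially flat reservoir. From two-channel confocal images
   (membrane dye + protein label) the package computes:

   - the **sorting ratio**
     `S = (I_prot,tube / I_mem,tube) / (I_prot,GUV / I_mem,GUV)`,
     the protein surface density on the tube relative to the GUV;
   - the **tube radius** from fluorescence,
     `R = k_tub · (I_mem,tube / I_mem,GUV)`, with `k_tub` calibrated from
     aspiration-pipette pulls via the tether relations
     `σ = ΔP·r_pip/2·(1 − r_pip/r_GUV)` and `R = F/(4πσ)`;
   - **protein surface densities** (per µm²) from dye-lipid standard-curve
     calibration (0.7 nm² per lipid, slope-ratio fluorophore correction);
   - **curvature-induction time courses**: tube density and radius against
     time, head/tail endpoint means and the Δφ/ΔR slope.

2. **Buckled-membrane curvature sampling.** For a simulated bilayer buckled
   into a sinusoidal fold, the package fits a periodic two-dimensional
   Fourier height field to lipid phosphate positions by least squares,
   evaluates local mean curvature `H` from the shape operator of the fitted
   profile (analytic derivatives; `H > 0` toward the binding leaflet),
   accumulates equilibration-gated histograms of `H` at a probe
   (e.g. an amphipathic helix centre of mass) versus random lipid
   positions, and measures the probe's **insertion depth** relative to the
   local phosphate level as a percentage of monolayer thickness.

A first-class synthetic-data module generates two-channel GUV+tube images,
calibration tables and buckled-membrane trajectories with known ground
truth, so every stage is testable end-to-end without any external data.

## Worked example

```python
import numpy as np
from tubesort import (
    ImagingGroundTruth, generate_tube_frame,
    segment_rois, measure_intensities,
    sorting_ratio, tube_radius_from_fluorescence,
)

gt = ImagingGroundTruth(tube_radius_nm=30.0, sorting=14.0, seed=1)
frame = generate_tube_frame(gt)                    # two-channel image + truth
m = measure_intensities(frame, segment_rois(frame))  # Otsu ROIs, bg-subtracted
S = sorting_ratio(m)
R = tube_radius_from_fluorescence(m, k_tub_nm=gt.k_tub_nm)
print(f"S = {S:.2f}   R = {R:.1f} nm")
```

prints

```
S = 14.02   R = 29.4 nm
```

i.e. the protein is ~14-fold enriched on a ~30 nm tube relative to the flat
GUV — the imposed ground truth recovered through segmentation, background
subtraction and the radius calibration. The buckled-membrane side:

```python
from tubesort import (BuckleGroundTruth, generate_buckled_membrane,
                      sample_probe_curvature)

traj = generate_buckled_membrane(BuckleGroundTruth(probe_bias_nm=80.0, seed=1))
cs = sample_probe_curvature(traj, equilibration_cut_ns=200.0, seed=2)
print(f"mean H at probe = {cs.mean_probe:+.4f} nm^-1  "
      f"(random lipids {cs.mean_random:+.4f}), KS p = {cs.ks_pvalue:.2g}")
```

```
mean H at probe = +0.0077 nm^-1  (random lipids -0.0006), KS p = 5e-07
```

— a curvature-seeking probe samples significantly more positive local mean
curvature than random lipids on the same frames.

The command-line interface mirrors the stages
(`tubesort simulate | quantify | calibrate-ktub | calibrate-density |
timecourse | fit-surface | sample-curvature | insertion-depth | report`).

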