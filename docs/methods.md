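# Methods

This note records the models, conventions and numerical choices behind
`tubesort`, and what the synthetic data do and do not emulate.

## Nanotube imaging model

### Measurement procedure

Tube and GUV are measured inside rectangular hint boxes (the analogue of
manually drawn ROIs on real images; `auto_hints` derives them from
generator geometry so tests need no interaction). Within each box the
**membrane-dye channel** is thresholded with Otsu's method; foreground
pixels define the structure, the remaining box pixels its local
background. Per channel the reported intensity is the **mean** over the
foreground minus the mean over the background, so adding a camera offset
to both channels changes nothing, and multiplying a channel by a gain
cancels wherever a ratio is formed. Segmentation never looks at the
protein channel. Two guards reject silent failures: a single-valued region
(Otsu undefined) and an Otsu split whose foreground/background separation
is below 5% of the baseline (a hint box containing no structure).

Pixels near the tube-GUV junction receive light bled from the bright rim;
the tube hint box therefore starts a configurable 5 PSF sigmas past the
junction. The GUV box sits on the rim on the side opposite the tube.

### Formulas

With the four background-subtracted means,

- sorting ratio `S = (I_prot,tube/I_mem,tube) / (I_prot,GUV/I_mem,GUV)`;
- tube radius `R = k_tub · (I_mem,tube/I_mem,GUV)`;
- aspiration tension `σ = ΔP·r_pip/2·(1 − r_pip/r_GUV)` (ΔP in Pa, radii
  in µm, σ in N/m; the geometry requires `r_pip < r_GUV`);
- force-derived radius `R = F/(4πσ)` (F in pN, R in nm).

Units are fixed at these boundaries with explicit conversion constants;
nothing downstream re-converts.

`k_tub` is calibrated by regressing the force-derived radius of
aspiration-pipette pulls on the measured fluorescence ratio. The default
regression fits an intercept and uses only the slope as `k_tub`; the
intercept is reported as a quality-control quantity (it should be ≈ 0) and
a through-origin option exists. 95% CIs come from the t distribution on
the slope standard error.

Surface densities use the standard two-step calibration: GUVs carrying
known dye-lipid mole fractions (0.01–1 mol%) give the slope of rim
intensity versus dye surface density, with density computed as
`leaflet_factor · fraction / 0.7 nm²` — 0.7 nm² per lipid, and
`leaflet_factor = 2` by default because both leaflets fluoresce in an
equatorial section. Bulk serial-dilution standard curves of the two
fluorophores correct for their brightness difference via the slope ratio.
Protein density is then `φ = I_prot,GUV / slope_dye · (s_lipid/s_protein)`,
optionally divided by 2 to count dimers of a two-protomer complex carrying
one label per protomer. Because the standards are measured through the
same segmentation pipeline as the protein frames, the mask-geometry factor
cancels exactly; the noise-free round trip is exact to machine precision.

### Time courses

A freshly pulled tube accumulates protein from the GUV reservoir toward
its equilibrium sorting value; at high surface density accumulation can
constrict the tube. `timecourse_analysis` reports initial/final values as
means over head/tail windows (default 3 frames) and the slope
`Δφ_tube/ΔR` between the windowed endpoints, flagging degenerate cases
(`flat`, `constant-radius`). `φ_tube = S·φ_GUV` by the definition of S.
The default synthetic induction schedule runs 40 frames over 78 s (a ~2 s
confocal frame interval), ramping tube density 600 → 1700 µm⁻² while the
radius falls 50 → 25 nm; because endpoints are windowed means over a ramp,
they sit slightly inside the nominal range (e.g. ~618 rather than 600 at
this sampling) — this is a property of the estimator's windowing, not
measurement error.

### Synthetic images

Frames emulate an equatorial confocal section: the GUV is a bright ring,
the tube a dim, slightly tilted (2°) line contiguous with it. Structures
are idealised as infinitely thin curves under an isotropic Gaussian PSF,
rendered analytically as `amplitude · exp(−d²/2σ_PSF²)` with `d` the
distance to the curve — the exact PSF image of a thin straight line, and
an O((σ/r)²) approximation for the ring. Defaults: 100 nm pixels, 120 nm
PSF sigma, GUV radius 10 µm, membrane rim peak 2000 counts, offset 100
counts, Poisson noise; all plausible confocal values, all configurable.
The tube's membrane amplitude is `R/k_tub` times the rim's (thin-tube
limit: projected membrane area per pixel scales with radius), and the
protein channel is the same geometry scaled by labelled-protein density
and, on the tube, by the imposed sorting ratio.

What this buys: the sorting ratio and the density round trip are *exact*
on noise-free frames, because every geometric factor cancels between
channels or between calibration and measurement. What it does not: the
tube/GUV membrane-intensity ratio carries one constant rendering factor
(≈ 0.997 at the defaults) from ring-curvature pixel weighting and Otsu
cutoff discretisation, so noise-free radius recovery is biased by ≈ −0.3%
uniformly across radii. In a real experiment the same kind of factor is
invisible because `k_tub` is calibrated through the same imaging pipeline.
The generator does not emulate polarisation effects, flat-field or
bleaching (the measurement applies no such corrections either), membrane
fluctuations, or out-of-focus light; passing tests therefore validate the
measurement chain, not microscope physics.

### Tilted tube

The tube is tilted a few degrees on purpose: a lattice-aligned horizontal
line samples its transverse profile at integer offsets only, which makes
the mask-mean factor sensitive to the Otsu cutoff in discrete jumps. The
tilt spreads sampled distances quasi-continuously, matching the ring's
sampling statistics and keeping the residual factor small and constant.

## Buckled-membrane curvature analysis

### Height field and shape operator

Phosphate positions of the binding leaflet are fitted with a periodic 2D
Fourier expansion `h(x,y) = Σ c_mn · trig(2πmx/Lx) · trig(2πny/Ly)` by
linear least squares (default truncation orders `(Nx, Ny) = (6, 2)`; the
nested-basis property guarantees residual RMS is non-increasing in the
order, and tests report convergence rather than asserting a magic
truncation). Each mode is stored as a phase-shifted cosine so first and
second derivatives are exact phase shifts — mean curvature needs no
grids or finite differences:

`H = −[(1+h_y²)h_xx − 2h_x h_y h_xy + (1+h_x²)h_yy] / (2(1+h_x²+h_y²)^{3/2})`,

the half-trace of the shape operator in Monge gauge. **Sign convention:**
`H > 0` where the surface bulges toward +z, the side the probe binds, so a
crest of `z = A sin(2πx/Lx)` has `H = +2π²A/Lx²` and "preference for
positive curvature" appears as a positive shift of the probe's sample
mean. The Monge gauge assumes a single-valued height field; overhangs are
out of scope.

Numerical notes: the fit is `numpy.linalg.lstsq` on an N×M design matrix
(M = (2Nx+1)(2Ny+1) = 65 at the default); underdetermined systems and
degenerate boxes are rejected, not regularised. With 0.3 nm height jitter
on ~4000 points per frame, the *pointwise* curvature of a single frame
carries roughly 10% noise (jitter leaks into high-order modes and
curvature amplifies mode m by (2πm/Lx)²); preference statistics therefore
always aggregate over frames, and exactness claims (machine-precision
recovery, closed-form crest value) hold for points lying on the surface.

### Preference sampling and insertion depth

Frames before the equilibration cut (and frames the generator flags as
pre-equilibration) are discarded; retained frames can be thinned to a
fixed sampling interval (default: the native 10 ns frame spacing). Per
frame, H is evaluated at the probe's (x, y) and at `n_random` phosphate
positions drawn per frame (not pooled); probe and random samples share
histogram binning and are normalised to unit mass. A two-sample
Kolmogorov-Smirnov test quantifies the probe-vs-random difference; under
the null (unbiased probe) its p-value is uniform, so a single run fails
at α = 0.05 with 5% probability by construction.

The binding leaflet is chosen per frame as the leaflet whose *local*
phosphate level — mean z within a periodic xy radius (default 5 nm) of
the probe — is nearer the probe height. (A global mean-z comparison
misassigns probes sitting in buckle troughs.) Insertion depth is the
probe height minus that local level, averaged over frames and expressed
as a percentage of the monolayer thickness; negative values mean
insertion below the phosphate level. Averaging the surface over a finite
window introduces a small curvature-coupling bias (≈ 0.1 nm at the
default 3 nm amplitude for a probe pinned to a crest); for unbiased
probes it cancels by symmetry.

### Synthetic trajectories

Frames carry two leaflets of phosphates scattered uniformly in-plane on
`z = A sin(2πx/Lx) ± t_mono` with Gaussian height jitter (0.3 nm) in a
periodic box (defaults 63 × 28 × 38 nm, A = 3 nm, 800 lipids per leaflet,
10 ns frame interval). The probe's x marginal is drawn with weight
`exp(bias · H_true(x))` — the simplest monotone curvature preference, with
`bias` in nm so the exponent is dimensionless; bias 0 reproduces the
random-lipid distribution exactly, and the tilted mean is strictly
increasing in the bias (its derivative is the tilted variance). The first
10% of frames are flagged pre-equilibration and carry an unbiased probe,
so tests exercise the gating. The generator prescribes positions
statistically; it does not simulate lipid or protein dynamics, in-plane
density modulation by curvature, or membrane undulation spectra beyond
the imposed jitter.

## Determinism

Every generator draws all randomness from a single integer seed via
`numpy.random.default_rng`; pipelines hash their analysis-relevant
configuration (excluding the output directory) and tag every output row
with it, and rerunning the same configuration and seed reproduces result
tables byte for byte.

## Known limitations

- No trap-force inference from bead tracking; F is an input.
- No thermodynamic sorting model (spontaneous-curvature fits); the package
  measures S, it does not interpret it.
- The GUV-density measurement uses the equatorial rim; pole-intensity
  protocols would need a different leaflet factor.
- Gaussian/overhanging geometries and closed vesicle surfaces are outside
  the Monge-gauge curvature machinery.
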