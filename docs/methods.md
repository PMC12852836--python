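# Methods

This note records the models behind `hexpam`, the parameter choices that
matter, and what the synthetic experiments do and do not establish.

## Steering geometry

The hexagon is modelled as six facet lines at apothem `R·cos 30°`, rotated
by the scan angle ω; at ω = 0 a facet squarely faces channel 1.  The two
excitation beams travel horizontally in opposite directions, both at
orthogonal distance `d` from the polygon centre (the two optical-acoustic
combiners face each other across the scanner).  Incidence angles are
measured from the facet normal, the standard optics convention.  Under this
convention — and only under it — the regime structure comes out exactly as
the instrument's design equations state: θ₁+θ₂ = 60° on
(60°−θ₀, θ₀) and 120° for ω ≥ θ₀, with θ₀ = arccos(d/R).  We verified
numerically that plausible alternatives (angles from the facet plane;
beams at symmetric heights ±d) produce either non-constant sums or regime
boundaries at arcsin-type angles instead of θ₀.  The residual band
[0, 60°−θ₀] is where a beam straddles a vertex at the band edges; it is
flagged `facet-transition` and excluded from the usable line, matching the
instrument's effective-range bookkeeping.  The regime labels are meaningful
for `R/2 < d < R·√3/2` (the shipped geometry has d/R = 5/7); outside that
band one beam can sit on a facet centre or miss transitions entirely.

`channel_angles` is itself an explicit mirror-reflection ray trace with
analytic facet selection; the test suite checks it against a deliberately
naive, independently written brute-force trace (all six facet lines,
nearest hit) to 1e-9 degrees on randomized geometries.

**Focal trajectory.**  The reflected-ray angle is twice the struck facet's
normal angle, hence linear in ω within a facet pass.  The focusing optics
are not prescribed, so the sweep is normalised: one facet pass maps
linearly onto one `channel_range_mm` (an ideal f-theta mapping).  Channel
2's range is placed at `channel_range − overlap` in global coordinates.

**Arc depth distortion.**  The focal spot of a rotating-mirror scan rides
an arc tangent to the flat focal plane at the pass centre.  We model the
extra acoustic path as the sagitta of an arc with radius equal to
`working_distance_mm` (default 30 mm, a plausible scan-head scale; with a
14-mm pass this injects up to ~0.8 mm of apparent-depth bowing).  The
forward model adds this path per A-line and `depth_correct` removes it —
the scheme is self-consistent by construction, and on a simulated flat slab
the post-correction surface spread is well below the 33-µm axial
resolution (sub-µm in practice), which is what the correction must achieve.

## Timing

All throughput identities are closed-form: `scan_time = (fov_slow /
slow_step) / bscan_rate`, `avg_fast_step = channel_range · bscan_rate /
prf`, `bscan_rate = rpm/60 · n_facets`, `overlap_pct = 100 · overlap /
channel_range`, and the echo separation `Δt·c` (0.675 mm for 450 ns at
1500 m/s) must exceed the 0.221-mm optical depth of focus — this is
enforced at configuration load, since gating correctness depends on it.

## Phantoms

Vessel networks are persistent random walks (step 2 voxels, azimuthal
diffusion 0.12 rad/step) confined to a shallow depth band (default
0.25–0.45 mm) so that each vessel's echo fits inside one demultiplexing
gate, as superficial vasculature does within the instrument's depth of
focus.  Tubes are rasterised by a distance transform with anti-aliased
edges but hard support (zero outside the radius), so interior total
haemoglobin is exactly uniform (default 2.3 mM, whole-blood scale) and the
HbO₂/HbR split per vessel is exactly its assigned sO₂ (defaults alternate
0.97 artery-like / 0.70 vein-like).  These values are synthetic
conventions, not measurements.  Extinction coefficients ship as an
approximate standard haemoglobin compilation over 500–600 nm (532 nm
near-isosbestic; HbR peak near 555 nm); they are configuration — replace
the CSV for quantitative work.  The ln 10 Beer–Lambert factor is applied
explicitly and cancels in all sO₂ ratios.

## Forward model

Fluence is uniform at the focal plane and the Grüneisen coefficient is a
global constant absorbed into amplitude units; amplitudes are therefore
relative, which suffices for ratiometric sO₂.  The transducer response is
a zero-phase Gaussian-modulated sinusoid at 30 MHz whose envelope FWHM maps
to the 33-µm axial resolution; the lateral aperture is a Gaussian with
7.5-µm FWHM, applied as a truncated-kernel blur of the absorption volume.
One-way travel time `t = z/c` is used (generation is at the absorber).

Two numerical choices matter for quantitative fidelity:

1. **Continuous-time echo placement.**  Each voxel's echo is the kernel
   evaluated at its exact (fractional-sample) arrival time.  Resampling
   voxel profiles onto the time grid by interpolation instead makes window
   energies phase-sensitive — vessel-edge profiles are near-impulses on the
   voxel grid — and biases the inter-wavelength amplitude ratio by up to a
   few percent.  With exact placement the 112.5-sample (450 ns × 250 MHz)
   delay of the 558-nm echo is rendered faithfully.
2. **Kernel truncation at six envelope sigmas** keeps echoes compactly
   supported (clean gating) at a truncation level (~e⁻¹⁸) far below the
   sO₂ round-trip tolerance.

Facet misalignment is injected as per-facet fast-axis offsets and gains
plus a sinusoidal within-B-scan wobble (water damping; amplitude
configurable, default 5 µm in the shipped config — the magnitude is not a
published number).  Noise is white Gaussian at a requested SNR; inside
`simulate_scan` the noise floor is derived from the combined two-channel
signal power, since both channels share identical detection electronics
and a channel looking at empty tissue still records noise.

## Demultiplexing and spectral amplitudes

Gates are surface-anchored: the 532-nm gate starts at the first envelope
sample above `surface_threshold_mads` scaled MADs (default 10; at 10 the
Rayleigh-tail false-trigger probability stays negligible over a full
raster of ~10⁷ samples, whereas 5 would false-trigger with near certainty
on noisy data), minus a guard of one kernel half-width so the leading
pulse energy stays inside its own gate.  The 558-nm gate is the same
window delayed by `round(Δt·fs)` samples; window length `floor(Δt·fs)`
guarantees the gates cannot overlap.  The raw signal is gated *first* and
enveloped per gate: a full-record analytic envelope has ~1/t² tails that
leak between gates and bias the amplitude ratio at the 10⁻² level.

The spectral amplitude per A-line is the gate's root-sum-square.  For a
band-limited echo fully inside its gate this is invariant to sub-sample
time shifts (Parseval), so the 532/558 ratio survives the half-sample
offset between gates exactly; an envelope-peak amplitude would err by ~2%.
This is why the noise-free simulate→demultiplex→unmix round trip returns
assigned sO₂ to ~10⁻⁷ rather than to a few percent.

## Assembly, stitching, registration, stabilisation

A-lines are assigned to half-open lattice bins `[k·pitch, (k+1)·pitch)`
(stable when positions fall exactly on bin edges) with mean-on-collision,
keeping the forward/inverse round trip linear; the mean true source
position per bin is kept in provenance so depth correction evaluates the
sagitta on the actual trajectory rather than at bin centres.  Stitching
blends the overlap band with a linear ramp (cosine available) and copies
everything else verbatim, so constants are preserved and mass outside the
band is conserved.

Facet registration is translation-only (the minimal model consistent with
displaced scan paths; affine extension would slot into the same
interface).  Facet stacks are 6-fold decimated along the slow axis, so
before correlation each stack is linearly stretched to full row density
and smoothed below the decimation Nyquist (vertical Gaussian, σ = one
facet period) — without this, the per-facet sampling phase biases the
correlation peak along image gradients by up to ~0.6 px.  The NCC peak is
refined with a full 2-D paraboloid fit (a separable parabola is biased by
tilted correlation ridges from diagonal vessels), the slow-axis search is
centred on the known acquisition row offset between stacks, and reported
shifts are misalignment-only, so aligned stacks estimate as the identity.
Because A-lines are assembled at nominal positions, a trajectory offset of
+δ makes the scene appear at −δ; estimators and reports use that sign
convention.  Frame stabilisation uses plain cross-correlation phase
registration on demeaned, Tukey-tapered frames (spectral whitening and
wrap-around artefacts otherwise dominate smooth, low-contrast frames),
with a confidence flag from the interior correlation after alignment.

Upsampling is an interpolating bivariate spline (exact at original sites,
exact on linear ramps); a learned upsampler could replace it behind the
same signature, and nothing downstream depends on which is used.

## Unmixing

Per pixel, `[a532; a558·k] = E·[c_HbO₂; c_HbR]` is solved with the 2×2
extinction matrix; `k` is a pulse-energy calibration scalar for the 558-nm
channel (default 1; the simulator is energy-balanced).  sO₂ is clipped to
[0, 1]; the validity mask requires both amplitudes above a threshold
(default 3 scaled MADs of each amplitude image, never admitting
zero-amplitude pixels) and positive unmixed total haemoglobin.

## Problem sizes and study conditions

The shipped desk-scale configuration keeps the full timing physics (450-ns
delay, 250-MHz sampling, 300-Hz B-scans) but scales the raster: 2-mm
channel ranges with 0.5-mm overlap, 80–160 A-lines per B-scan, 36–240
B-scans, ~350-sample records — a full simulate→reconstruct→unmix chain
runs in seconds.  The depth-correction experiment keeps the full 14-mm
pass (280 A-lines at 50-µm step) since the arc distortion scales with the
pass width.  Registration recovery is assessed over 100 seeded trials of
±10-px per-facet offsets on vessel images at 20-dB SNR (recovery ≤ 0.5 px
in 100/100 trials at these conditions); the full-scale in vivo raster
(4500 × 1667 A-lines) is exercised only through its closed-form timing
identities.

## What passing tests do not show

The phantoms are geometric stand-ins: no melanin or other chromophores, no
optical scattering or depth-dependent fluence, no acoustic attenuation,
dispersion, or full wave propagation, no motion of the imaged object
(stabilisation is tested on rigidly translated frames), ideal per-line
triggering, and a normalised rather than lens-derived angle-to-position
mapping.  Quantitative sO₂ accuracy on real tissue additionally depends on
wavelength-dependent fluence and calibration, which the simulator
deliberately leaves out of scope; results here establish the correctness
of the geometry, timing, gating, registration, and unmixing *software*,
not in vivo accuracy.
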