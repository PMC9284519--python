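# Methods

This note documents the models, estimators and numerical choices behind
`wrinklebio`, what the synthetic data generator does and does not
emulate, and the known limitations of each stage.

## Coordinate and angle conventions

Height maps are regular square-pixel grids in μm, row 0 at the north
edge, column 0 at the west edge. All in-plane directions are *axial*
angles in degrees from the N–S (vertical) axis, normalized to
[−90°, 90°); a line at angle α has direction (sin α, −cos α) in
(x-east, y-south) components. `SurfaceSpec.orientation` rotates the
primary *wavevector*, so grooves run at orientation + 90°. Maps are
leveled to zero mean at synthesis and plane-leveled (degree-1 least
squares) before thresholding metrics.

## Surface synthesis

The bilayer wrinkling relations are the canonical low-deformation
forms: λ = 2πh(E̅f/3E̅s)^(1/3), A = h√(ε/ε_c − 1),
ε_c = ¼(3E̅s/E̅f)^(2/3), with E̅ = E/(1 − ν²) and ν = 0.5 for an
incompressible elastomer. They are evaluated, not simulated: no
post-buckling wavelength compression or higher-order modes.

Patterns:

- **F** — zeros, optionally dressed with Gaussian white noise low-pass
  filtered at ≈4 px FWHM (emulating the finite lateral correlation of a
  real scan) and rescaled so its measured Ra equals the requested value
  exactly; default Ra 0.02 μm matches a bare elastomer replica.
- **1D** — A sin(2πu/λ + φ) along the wavevector coordinate u.
- **C** — sum of two orthogonal sinusoids. Sequential wrinkling
  attenuates the second generation: its effective amplitude is
  (A₂/A₁)·A₂, recovering A₂ when the generations match. Which
  generation carries the attenuation is not established; it is exposed
  as the `c_attenuation` override.
- **H** — a sinusoid whose phase coordinate is
  u cos δ + T(q) sin δ, where T is a continuous triangle wave of the
  groove-axis coordinate q with stripe width `arm_length` and
  δ = (180° − kink)/2. This alternates the wavevector by ±δ across
  chevron stripes with no phase jump; kink = 180° reduces exactly to
  the 1D pattern. Defaults: kink 90°, arm length 4λ, following typical
  equi-biaxial chevron geometry.

Default unit-test grids are 512² at 0.0391 μm/px (20 μm field);
pipeline runs use 20 μm fields at 256² — chosen so that a field holds
≥ 4 wavelengths per side and single cells span ≥ 8 px, while the full
4-pattern × 4-time × 3-replicate study completes in well under a
minute.

## Topography metrics

Ra and Rq are areal (whole-map) moments after mean subtraction; for a
pure sinusoid they converge to 2A/π and A/√2.

True 3D area splits every pixel quad into two triangles on the height
field and sums triangle areas; against the closed-form line integral of
a sinusoid (adaptive quadrature, `sine_arc_length`) the triangulated
area agrees to < 0.5% at 512² over 20 μm. Available surface area S_A
selects quads whose center height lies below the threshold (default
z = 0 after plane leveling) and reports their true area per unit
footprint; sub-pixel interface interpolation is deliberately omitted
(bias below one pixel row). The complementary above-threshold region
makes the partition exact: S_A(below) + S_A(above) = 100% + excess.

Two estimators are provided because they answer slightly different
questions: `available_surface_area` measures the below-threshold region
directly, while `sa_product_estimate` multiplies total relative area by
the valley fraction. They coincide for symmetric profiles and diverge
on asymmetric ones (real wrinkles at larger strains), which is why both
are reported.

Flat-surface convention: a map with Rq below `flat_eps` (default
0.05 μm) is the flat reference with S_A = 100% and valley fraction 1 —
the whole footprint is available, even though no pixel is strictly
below threshold. The epsilon sits between the residual roughness of a
noise-dressed flat replica (Rq ≈ 0.03 μm) and the shallowest patterned
surface (Rq ≈ 0.1 μm).

## Colonization simulator

The generator emulates scan data of early (monolayer) colonization with
the statistical structure the analysis assumes; it is a minimal
three-parameter adhesion model, not a mechanistic one:

- **Cell morphology.** Truncated-normal draws (floor 0.2 × mean) of
  cross-section a and length b per strain; rods resample until
  b ≥ a, spheroids swap instead to avoid biasing their nearly equal
  means. Means/SDs: S. aureus 0.8 ± 0.3 / 0.9 ± 0.3, P. aeruginosa
  0.7 ± 0.2 / 1.7 ± 0.2, E. coli K12 0.6 ± 0.2 / 1.9 ± 0.2,
  C. albicans 3.8 ± 1.5 / 4.1 ± 1.5 μm. A valley-resident cell whose
  relaxed cross-section exceeds the local valley width adopts the
  strain's confined dimensions (e.g. P. aeruginosa 0.7 × 2.5 μm on
  uniaxial wrinkles).
- **Placement.** Sequential random adsorption: centers uniform (with a
  half-length margin so every footprint lies inside the field and
  placed coverage is exactly the ellipse-area sum); candidates on hills
  accepted with odds reduced by `valley_affinity` (default 5; ∞ confines
  all cells to valleys); long-axis angle von Mises around the local
  groove direction with concentration `guidance_strength` (default 6),
  uniform where the structure tensor is isotropic; ellipse overlaps
  rejected (bounding-circle prefilter + boundary probing on a spatial
  hash). Placement stops at the target coverage or a stated attempt
  budget (with a warning). Jamming ceiling 55%, the saturation density
  of random sequential ellipse adsorption.
- **Groove direction.** Structure-tensor orientation over a window of
  about one wavelength; the minor eigenvector gives the groove axis,
  and a coherence below 0.2 returns the isotropic sentinel (`None`).
- **Coverage law.** coverage(t) = `rate_per_SA` · S_A-fraction ·
  max(0, t − lag), capped at the ceiling. Defaults: rate 5 %/h per unit
  S_A fraction (≈30% on flat at 6 h), lags {F: 0, 1D: 0, C: 2 h,
  H: 2 h} for the onset frustration of biaxial patterns. Measurement
  noise in `simulate_coverage_dataset` is Gaussian with sd equal to a
  *relative* fraction of the true coverage (default 1%).
- **Rendering.** Cells are half-ellipsoidal caps of height a_eff/2.
  The cap base rests at the highest surface point along the cell's long
  axis — a rigid-body contact rule, so a rod lying along a groove sinks
  to the valley floor while one bridging a pit rests on its rims —
  max-composited onto the substrate. Optional spherical-tip grayscale
  dilation models tip convolution; Gaussian height noise (default rms
  0.01 μm) models instrument noise.

Not emulated: motility, chemotaxis/quorum signalling, EPS mechanics,
multilayer stacking (real flat surfaces develop multilayered colonies,
where areal coverage of a monolayer is ill-defined), cell flexure into
pits, and tip-sample distortions beyond geometric dilation. Passing
tests therefore demonstrate that the *analysis chain* is consistent and
unbiased on data obeying the stated model — not that real colonies obey
it.

## Image analysis

**Background subtraction** (default `method="fit"`): the wrinkle
pattern concentrates its spectral energy in a handful of narrow peaks
around the fundamental and harmonics (annulus 0.5–3.5 × 1/λ), while
cells are sparse broadband objects. Peaks are detected on a
Hann-windowed spectrum, refined to sub-bin frequency accuracy by
log-parabolic interpolation (so non-integer field periods are captured
without leakage), and sinusoids at those frequencies are fitted to the
plane-leveled image by iteratively masked least squares: pixels with
residuals above median + 2.5 robust sd (cells) are excluded and the fit
repeated (3 iterations, tiny ridge regularization). This extrapolates
the pattern beneath the cells from their surround; on a flat image the
coefficients vanish and cells pass through unchanged, and a second pass
is a no-op on cell signal. Chevron patterns phase-modulate the carrier,
producing a sideband ladder spaced 1/(2·arm length) along the stripe
axis that is below FFT resolution on small fields; `stripe_period`
adds those sidebands to the basis (ladder axis inferred from the two
strongest arm peaks). Residuals on pure patterns are Rq ≈ 0.01 μm
(1D/C) and ≈ 0.008 μm (H with sidebands), far below the segmentation
threshold. A grayscale flat-disk opening (diameter 1.5λ) is kept as
`method="opening"` for near-flat substrates; on wrinkled ones a disk
wider than λ erodes the pattern itself, and no ball radius can both
follow λ ≈ 2 μm valleys and reject ≈1 μm-wide cells, which is why the
spectral fit is the default.

**Segmentation**: threshold on corrected height (default 0.15 μm,
between the pattern residual and the shortest cell cap of ≈0.3 μm),
8-connected components, minimum area 0.2 μm², moment-based ellipse
descriptors. Thresholding partway up a cap keeps only the fraction
1 − (t/h)² of its footprint, so each object also carries a
cap-corrected full footprint (used by coverage, default on); the
correction is skipped for marginal slivers with peak < 1.4 × threshold,
whose extrapolation would diverge. Mean coverage-recovery bias across
seeded fixtures at 5–25% coverage on all four patterns is < 1%
absolute; individual fixtures at 20%+ coverage can deviate by ≈2 points
through merged neighbors and valley burial.

**Orientation distributions**: the binary object mask is divided into
64-px subimages with 50% overlap, each Hann-windowed and Fourier
transformed; power is azimuthally *averaged* (sum per angular bin
divided by the bin's frequency-lattice occupancy — the sparse inner
radii would otherwise bias the histogram) over the radial band
[1/(2b), 1/a] cycles/μm derived from the median fitted axes, which
suppresses residual pattern harmonics. Spectral angles are rotated by
90° so reported angles are real-space cell orientations (an elongated
object concentrates power perpendicular to its long axis). Subimage
distributions are averaged (default) or pooled, then normalized to unit
sum over the declared window (0–90° by default, −45–45° for
herringbone); angles are mapped into the window by 180° shifts and
out-of-window mass is excluded. Bin width 5°. Subimage size, band
edges, bin width and normalization mode are engineering defaults, all
exposed as arguments. The fitted-ellipse angle histogram provides an
independent cross-check; modal bins of the two methods agree within one
bin on all patterned fixtures with ≥ 40 cells.

**Morphometrics**: line profiles through the cell center along its
axes; width of the central peak at half its height above a robust
baseline (profile 10th percentile). Peak *prominence* was rejected:
its reference saddles are raised by pattern walls beside
valley-confined cells, biasing widths ~19% low. The half-height width
of an ellipsoidal cap is √3/2 of the axis, so widths are rescaled by
2/√3 (`cap_corrected`).

## Scaling analysis

At fixed time, coverage vs S_A fraction is fit by least squares through
the origin; a pattern is flagged as deviating when its mean residual is
below −2 × the residual sd of the flat/uniaxial baseline (threshold
configurable). Note that under the lagged linear law a 2 h lag leaves a
permanent deficit, so biaxial patterns flag at every time once
proliferation starts; the flags are most informative at onset (t = 2 h,
where coverage is ≈0 against a finite prediction).

Per pattern, coverage = max(0, r·(t − lag)) is fit by profiling the lag
on a 0.01 h grid (r is closed-form at fixed lag; nonnegative); an
all-zero series is degenerate and reports lag = last observed time.
Bootstrap CIs (percentile, default 1000 resamples, fixed seed) resample
replicates. On the full synthetic design (4 patterns × 4 times × 3
replicates, 1% relative noise) rates are recovered within 10% and lags
within 0.5 h.

`reduction_summary` ranks patterns by fitted coverage at the reference
time (lags included) and reports reductions vs flat on the *post-lag
rates* — the lag-adjusted measure of how much a pattern slows
proliferation once started; a pattern with half the available area
shows a ≈50% rate reduction.

## Degenerate inputs and tie-breaks

Constant maps give Ra = Rq = 0 (not an error); an empty below-threshold
region returns S_A = 0 with a warning; zero placement targets return
empty lists; unknown pattern labels raise. The lag grid search keeps
the first strictly better optimum, so exact-fit plateaus resolve to the
smallest lag. GSF files are validated for magic line, mandatory
resolution keys and payload size (errors name the byte offset); heights
are converted to meters at the file boundary only.

## Limitations

- The checkerboard attenuation rule and the herringbone kink-angle
  variability of real specimens are idealized; measured S_A of real,
  asymmetric C/H surfaces differs from the ideal superpositions, so
  ideal-C S_A exceeds ideal-1D S_A even though measurements on real
  surfaces order them the other way. Rankings driven by lags are robust
  to this; S_A-only comparisons between C and 1D are not.
- The coverage law is phenomenological; the lag parameter stands in for
  any mechanism of onset frustration.
- Orientation windows of 90° necessarily fold the axial circle; masses
  outside the window are discarded rather than reflected.
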