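# Methods

`spectmcvar` compares two quantitative SPECT reconstruction pipelines for a
Lu-177-like isotope (single imaging line at 208 keV) on synthetic digital
phantoms: **conventional** ordered-subset EM with an analytic, scatter-free
system model and triple-energy-window (TEW) scatter correction, and
**hybrid Monte-Carlo** OSEM, whose forward projection is a Monte-Carlo
simulation that models patient scatter implicitly while the back projection
stays analytic. The package measures two things: the *bias* each pipeline
leaves in region-of-interest (ROI) activity (recovery coefficients), and the
*precision* of ROI totals across repeated noise realizations (variability,
its conventional-minus-MC difference, and the speed-up factor), with
delta-method uncertainties that respect the pairing of the two
reconstructions.

## Reconstruction model

The OSEM update per angle subset S is

    f <- f * H_S^T( g_S / (H_S f + a_S) ) / (H_S^T 1)

* Conventional: H is the analytic operator, `a` is the TEW estimate
  `a = (g_upper/w_upper + g_lower/w_lower) * w_peak/2` formed from the two
  flanking energy windows of the same acquisition.
* Hybrid-MC: `H f` is replaced by a Monte-Carlo estimate of the expected
  photopeak counts of `f` (scatter included), `a = 0`, and the transpose
  uses the analytic scatter-free operator. The update is then no longer a
  true EM iteration (unmatched adjoint); no monotonicity is claimed or
  tested for it, only nonnegativity, boundedness and seed reproducibility.

Defaults follow the clinical protocol under study: 10 iterations, 8
subsets, angle-interleaved subsets (angle i -> subset i mod 8), initial
estimate uniformly 1 inside the detector orbit radius and 0 outside. The
division in the update is floored at `1e-12 * max(g)`; voxels with zero
sensitivity stay frozen at zero.

### Analytic operator

Rotation-based projector: rotate the volume so the detector lies along +y
(bilinear in-plane interpolation, zero outside), multiply by per-voxel
attenuation factors `exp(-L)`, blur each constant-depth plane with a
Gaussian whose width grows linearly with the distance to the collimator,
and sum over depth. `L` is the cumulative mu along +y with a half-voxel
self-attenuation term. Two deliberate numerical choices:

* The adjoint is the mechanical transpose of every step (scatter-rotation
  with the same bilinear weights, self-adjoint zero-padded Gaussian,
  diagonal attenuation), so `<Hf, g> = <f, H^T g>` holds to rounding for
  every flag combination.
* The rotation weights are column-normalized (each voxel's weights over
  the rotated grid are rescaled to sum to one). Plain bilinear gather
  rotation conserves mass only approximately (and badly for a point source
  at the rotation fixed point); after normalization, total counts per angle
  equal total activity times time times sensitivity exactly when
  attenuation and PSF are off.

PSF: sigma(d) = sigma0 + slope*d with defaults sigma0 = 1.5 mm,
slope = 0.025 (medium-energy-collimator-like; the collimator is named in
the protocol but not parameterized, so the numbers live in configuration).
The sensitivity constant is 1; absolute scale cancels in every reported
metric because recovery coefficients and variability are count ratios.

### Monte-Carlo engine

The transport engine plays the role of a full simulation code at desk
scale. Photons are emitted in proportion to the activity map, tracked with
Woodcock (delta) tracking through the water/air medium, Compton-scattered
by rejection sampling of the Klein-Nishina cross-section up to a phantom
scatter order of 6, or photoelectrically absorbed. Detection uses
next-event estimation: at the emission point and at every scatter vertex,
the expected contribution to every detector head — phase-function weight,
attenuation along the exit ray, Gaussian energy-window acceptance — is
tallied at the projected detector pixel, then blurred with the same
depth-dependent PSF as the analytic model. Water cross sections are an
embedded table (50-250 keV): Klein-Nishina times the electron density of
water for the Compton part, an E^-3 power law anchored at a standard
100 keV value for the photoelectric part, normalized so the total at
208 keV equals the embedded mu(water, 208 keV) = 0.0137/mm. Energy
resolution is Gaussian with FWHM 9.5% at 208 keV scaling as 1/sqrt(E).

Two consistency-by-construction choices matter:

* Emission happens at voxel centers and the emission tally uses exactly
  the analytic projector's (column-normalized) rotation weights and
  attenuation tables. The MC expected projections are therefore an
  *unbiased stochastic estimator of the same discrete operator* the
  analytic model implements, plus scatter; with scattering disabled the
  two agree to MC noise at any history count. This is the key cross-model
  property the tests exercise.
* Scatter-vertex tallies interpolate the attenuation table trilinearly at
  the continuous vertex position and rescale the 208 keV path integral by
  mu(E)/mu(208) — exact for a water/air medium.

Simplifications relative to a full detector simulation, all deliberate:
no collimator septal penetration or scatter, no detector backscatter
compartment, no coherent (Rayleigh) scattering, single 208 keV emission
line (the 113 keV line lies outside every acquisition window). Photons
below ~150 keV can no longer reach any window and are dropped.

RNG: one seeded sequential stream per transport call (the grading-scale
runs are single-threaded); every call derives its seed deterministically
from (master seed, purpose, iteration, subset) with a SplitMix-style
mixer, so identical configuration and seed reproduce results bit for bit.

## Phantoms

* **Hot-sphere cylinder**: 20 cm water cylinder (16 cm tall), spheres of
  72/40/20 mm at 10:1 concentration against the warm background. Sphere
  positions are not prescribed by the protocol; the layout (72 mm at
  (-50,0,0), 40 mm at (45,35,0), 20 mm at (30,-50,0) mm) keeps every
  sphere clear of the wall and of its neighbors and is recorded in output
  metadata. Sphere ROIs use the strict interior rule (a voxel belongs only
  if all eight corners are inside the sphere). The warm-background ROI
  excludes a 25 mm guard band along the cylinder wall — about twice the
  PSF FWHM, the measured extent of edge ringing, since the calibration
  method assumes a background ROI free of resolution effects — and a
  15 mm guard around each sphere.
* **NEMA-IQ-like body**: six spheres (37-10 mm) at 9:1 on a 57.2 mm ring
  around a 50 mm cold water cylinder, inside a warm elliptical body
  (260 x 190 x 180 mm); background ROI of two 50 mm spheres in the warm
  region. The exact layout is an IEC-like fixture, not a claim. Sphere
  ROIs here use voxel-center masks (drawn-ROI convention): at the 4.8 mm
  desk-scale voxel size the strict interior rule would leave the 10-17 mm
  spheres empty.

Phantom bodies use voxel-center inclusion; phantoms are fully
deterministic. mu(water) at 208 keV is the embedded 0.0137/mm; air is 0.

## Experiments and problem sizes

Desk-scale defaults (chosen once as this package's study size): 64x64x48
grid at 4.8 mm, 48 projection angles on a 150 mm circular orbit, 15 s per
projection, 1e7 histories for the low-noise dataset, 2e6 histories per MC
forward call; the full-scale flag doubles matrix and angle count. The
count scale of the noise experiments is fixed by rescaling the expected
projections to 1.5e5 total photopeak counts — a realistic total for a
count-poor Lu-177 acquisition at this angle count.

* **Bias experiment** (cylinder): the engine generates low-noise
  triple-window projections (residual MC noise of the total photopeak
  ~1e-4, recorded in metadata); reconstructions are (a) conventional+TEW
  on the full data, (b) conventional with zero additive term on the
  primary-only provenance split, (c) hybrid-MC on the full data; recovery
  coefficients per sphere and iteration are tabulated.
* **Variance experiment** (NEMA-like): N paired Poisson realizations of
  the expected projections; each realization is reconstructed with both
  pipelines from the *same* sample, which is what makes the covariance
  terms in the uncertainty estimators meaningful. The acceptance-test run
  uses a reduced size (48x48x32 at 6.4 mm, 16 angles, N = 10) so the
  suite stays desk-scale; the library defaults are larger.
* **Thinning**: binomial subsampling of sampled projections (default
  fraction 4/25), emulating shorter acquisitions; ROI-count variability
  scales as 1/sqrt(fraction).

## Metrics

Counts `C = w * (f . mask)` with decay weight w (T1/2 = 6.647 d; all
synthetic realizations are simultaneous so w = 1 in practice).
Calibration factor CF = A_bkg / C_bkg; recovery coefficient
RC = (C_roi/C_bkg) / (A_roi/A_bkg) in percent. Variability sigma = 100 *
SD/mean of a count series (sample SD, N-1). For paired series,
Delta = sigma_conv - sigma_mc and SF = (sigma_conv/sigma_mc)^2, with

    u[Delta] = sqrt((s1^2 + s2^2 - 2 Cov^2/(s1 s2)) / (2(N-1)))
    u[SF]    = 2 SF sqrt((1 - rho^2)/(N-1))

where Cov is the covariance of mean-normalized counts (the only
dimensionally consistent reading) and rho the corresponding correlation.
Both forms were derived with the delta method assuming approximately
normal paired counts and validated against a replicate Monte-Carlo oracle
(within 10% of empirical SDs at rho in {0, 0.5, 0.9}); both vanish in the
perfectly correlated equal-sigma limit. The standard error of a mean RC
over N realizations is SD/sqrt(N). Equivalent scan time:
t2 = t1 (sigma1/sigma2)^2.

The RC-versus-radius curve uses a modified Gustafsson-Minguez model: the
closed-form mean RC of a uniform sphere of radius R convolved with an
isotropic Gaussian of per-axis width w — equivalently the expected overlap
volume of two spheres of radius R displaced by a Maxwell-distributed
distance — scaled by S, which absorbs scatter-correction bias:

    RC(R; S, w) = S [ erf(sqrt2 R/w)
                      - (w/R)  (3 - e^{-2R^2/w^2}) / sqrt(2 pi)
                      + (w/R)^3 (1 - e^{-2R^2/w^2}) / sqrt(2 pi) ]

The form was re-derived from the overlap construction and checked against
numerical integration; it is monotone in R, RC -> S as R/w -> inf (the
approach is linear in w/R) and RC -> 0 as R -> 0. Fitting uses
trust-region least squares with S0 = 1, w0 = half the smallest radius,
bounds S in (0, 3], w in (0, 5] cm; non-convergence is reported in the
result object, never silently.

## What the synthetic study does and does not show

The generator emulates the geometry, energy windows, count statistics and
physics *mechanism* of the comparison — TEW's spatially blurred scatter
estimate under-corrects hot regions (positive RC bias), and its reliance
on noisy scatter-window data inflates variability — but not a real
scanner: no septal penetration, detector backscatter, dead time, drift or
CT misregistration. Numbers that depend on those effects (the real-scanner
speed-up factors, the patient concentration ratios) are therefore treated
as sign/ordering predictions only; the desk-scale bias experiment
reproduces the matched-model recovery coefficients quantitatively.

Two observed desk-scale behaviors worth knowing:

* At 10 iterations the warm background reconstructs ~1% low (incomplete
  convergence: voxels outside the phantom, initialized uniform inside the
  orbit per the protocol, have not fully decayed, and ringing shells
  around the wall and spheres redistribute counts), while the 72 mm
  sphere interior overshoots by ~1.8% (edge ringing). Together these
  place the matched-model 72 mm RC near 103.5% rather than exactly 100%.
  The effect is a convergence/discretization property of the fixed
  iteration budget, affects all three pipelines alike, and is unrelated
  to scatter.
* The 20 mm sphere's interior ROI is ~8 voxels at the sphere center,
  where matched-PSF OSEM on noise-free data exhibits ringing
  (resolution-recovery overshoot): its RC exceeds 100% and is still
  rising at iteration 10. Engines whose data contain collimator/detector
  tails that the reconstruction PSF does not model show damped recovery
  and decreasing RC for small spheres instead. Consequently the
  smallest-sphere RC is not monotone in sphere size here, while the
  pipeline orderings (TEW above hybrid-MC, TEW above 100%) hold at every
  size.

## Known limitations

* Water/air media only; no CT-derived attenuation.
* The hybrid pipeline's MC forward refreshes its noise every subset;
  refresh-per-iteration is available in configuration but not the default.
* The variance comparison requires the MC forward noise to be well below
  the TEW-estimate noise (the premise of the method); at strongly reduced
  history counts per forward call the hybrid pipeline's own sampling noise
  can dominate and invert the comparison.
* Full-MC back projection is out of scope; the adjoint is always analytic.
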