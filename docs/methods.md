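# Methods

This note documents the models implemented in `lamellometer`, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions adopted where the underlying
physics leaves the design open.

## Axial scaling under refractive-index mismatch (`optics`)

A dry objective (index n₁, typically 1.0) focused into vitreous ice
(n₂ = 1.28 at cryogenic temperature) refracts every converging ray at the
interface, so the geometric focus of a beam nominally at depth z_N lands
at a larger actual depth z_A.  Within the linear regime — emitters no
deeper than `linear_limit_um` (default 9 μm for NA 0.85) — the two depths
are proportional, z_A = S·z_N.

The exact high-NA scaling factor depends on how aberrated ray bundles
are weighted, which a geometric model cannot settle uniquely.  We compute
S as the uniform mean over the aperture (sin θ₁ ∈ (0, NA/n₁]) of the
single-ray ratio

    tan θ₁ / tan θ₂ = sqrt((n₂² − sin²θ₁) / (n₁² − sin²θ₁)),

which interpolates between the paraxial bound n₂/n₁ = 1.28 and the
marginal-ray value ≈ 1.82 at NA 0.85; the mean is S ≈ 1.39.  Both
extreme conventions remain selectable (`averaging=` "paraxial" /
"marginal").  The resulting focal shift is (1 − 1/S) ≈ 0.28 μm per
micrometre of *actual* emitter depth, i.e. ≈ 2.5 μm at the 9 μm limit.

Depth-convention choice: stated per-micrometre shift rates in this field
can refer to actual or to nominal depth.  We default to per-actual-depth
(`depth_convention="actual"`), which is simultaneously consistent with a
~0.3 μm/μm rate and a ~2.7 μm maximum shift at 9 μm; the per-nominal
convention is available and documented because instrument software often
works in nominal coordinates.

Pattern placement: because the compression always puts the emitter
*deeper* than measured, the bottom rough-milling pattern needs only a
small safety margin below the coincident point (default 0.3 μm,
configurable), while the top pattern adds the worst-case shift
`max_nominal_depth · (S − 1)`.  The default targeting depth is the
nominal depth whose actual depth equals the linear limit.

## Geometric wedge thickness (`rlm`)

Milling at angle θ (default 10°) leaves wedge-shaped lamella ends.  The
foil-side wedge of axial extent w determines the plateau thickness
d = w·sin θ exactly.  The milling angle itself can be verified from the
defocus between the two lamella surfaces over the lamella length,
θ = arcsin(Δz/L).

Width criterion: the literature does not pin down where on a tapered
wedge w starts and ends, only the product w·sin θ.  We measure the
foil-side intensity peak of the x-averaged profile at half its height
above background, with sub-pixel linear interpolation at the two
crossings.  The half-height fraction is configurable.  Background and
noise are estimated robustly in two passes: pixels in the upper half of
the profile's dynamic range are excluded, then the background is the
median and the noise a MAD-based sigma of the remainder — this keeps the
estimate valid even when the bright wedge band covers most of the field
(wide wedges early in milling).  A peak must exceed background + 3σ
(configurable) or a no-wedge error is raised.

Validity: geometric estimates are reliable roughly between 2000 and
400 nm — above, the wedge leaves the optical depth of focus; below, the
band width approaches the optical resolution.  Estimates outside the
window are flagged `outside-validity`, never suppressed.

## Thin-film interference (`tfi`)

Reflectivity of an ice slab of thickness d at wavelength λ:

    r(d, λ, T) = r_mea + r_A · env(d) · cos(4π·d·n₂(λ,T)/λ + π)

with mean level r_mea, amplitude r_A, and an envelope env(d) with scale
L = 500 nm accounting for scattering and coherence loss.  The envelope's
printed functional form is ambiguous between exp(−d/L) and exp(−(d/L)²);
both are implemented, with the exponential as default (coherence-loss
reading).  All fitting uses min–max-normalized intensities, which are
insensitive to the envelope at d ≪ L and invariant under affine
intensity transforms a·I + b.  With the exponential envelope the extrema
spacing is exactly P = λ/(2n₂) ≈ 181 nm at λ = 463 nm; the Gaussian
envelope drifts the spacing by ~1 nm at L = 500 nm.

Refractive index: the packaged n₂(λ, T) grid is a **synthetic** Cauchy
dispersion n = A(T) + B/λ² (B = 3100 nm², dn/dT = −2·10⁻⁵ K⁻¹) anchored
to the one anchored measurement used throughout, n₂ = 1.28 at 109 K
mid-visible.  It is bilinearly interpolated over 400–700 nm × 100–140 K
and linearly extrapolated with a warning outside.  Substituting a
measured dispersion table is a one-line change.

Trace fitting (`fit_trace`): during constant-rate thinning the
timestamps fix the thickness *decrements* (rate × elapsed time), leaving
one unknown — the final-thickness offset.  The offset minimizing the
squared error between the normalized trace and the normalized model is
found by 1 nm grid scan with parabolic refinement.  Because the model is
near-periodic, the search window must be narrower than the ambiguity
allows: pass a window derived from the geometric estimate (the envelope
alone separates branches only in noiseless data).  Traces covering less
than one period, or with no modulation, raise an ambiguity error rather
than returning an arbitrary branch.

Per-pixel map fitting (`fit_thickness_map`): each pixel's intensity is
normalized by the per-pixel minimum/maximum observed over the milling
series, and compared with the model normalized over the thickness
interval that series covered (`norm_span_nm`, default two periods above
the current estimate).  The search is confined to ±P/2 around the
geometric initial estimate, which selects the interference order; an
initial estimate off by a full period aliases the result by exactly one
period — the documented failure mode of any single-wavelength fringe
method.  Ties between the rising and falling flank of a fringe (both
attain every normalized intensity) are broken toward the initial
estimate by a small quadratic penalty (weight 10⁻⁴ on (Δd/P)²).  Pixels
near a fringe extremum are intrinsically ill-conditioned: intensity noise
that falls outside the model's range snaps the estimate to the extremum,
which biases *individual* pixels by up to ~σ_I/|dm/dd| while the map
mean stays within a few nm.  Fitting is not attempted above 1.5 μm
(fringe contrast washes out) or on pixels lacking an initial estimate or
intensity dynamic range; those are flagged invalid.

Uniformity is reported as the population standard deviation of the
fitted thickness over a region of interest.

## Monte-Carlo electron transport (`mc`) and q4STEM (`q4stem`)

Transport model: single-scattering Monte Carlo of electrons through an
amorphous-H₂O slab at 0.94 g/cm³.  Elastic events use the
screened-Rutherford cross section with screening parameter
α = 3.4·10⁻³·Z^0.67/E (E in keV), sampled per collision from the H/O
partial cross sections; free paths are exponential (elastic mean free
path ≈ 105 nm at 30 keV).  Between collisions electrons lose energy
continuously by the Joy–Luo modified Bethe stopping power
(≈ 0.87 eV/nm at 30 keV), deposited along the flight segment in six
sub-steps into 1 nm annuli about the incident axis.  Electrons are
tracked until they exit (transmitted or backscattered) or fall below a
0.5 keV cutoff (residual energy deposited locally).  There is no
secondary-electron transport, energy straggling, inelastic deflection or
diffraction.  Energy is conserved exactly by construction and asserted
to 10⁻⁶ in tests; fixed seeds give bit-identical runs.

q4STEM measurement: patterns are integrated into equal-angle annuli
about the beam centre (angle = arctan(r/D)·1000 mrad with camera length
D = 300 μm; total counts inside the 218 mrad acceptance are conserved
exactly).  The virtual bright-field disc semi-angle defaults to 30 mrad
and can be measured from an empty-hole exposure as the angle containing
99% of the unscattered beam.  The DF/BF ratio is inverted by monotone
linear interpolation of a simulated lookup table (strictly increasing
ratio required; tables failing this from counting noise are rejected
with advice to raise `n_electrons`).  The ratio→thickness inversion
yields the beam *path length*; thickness along the lamella normal is
path·cos(incidence), with 52° as the reference SEM incidence.  The
most-common scattering angle (solid-angle-corrected profile peak with
parabolic refinement) is carried as a consistency check.  Profile
binning for inversion defaults to 256 bins: at 64 bins the ±half-bin
quantization of the BF cutoff biases the ratio several percent.

Beam-damage containment: `McResult.containment_radius_nm(0.95)` reports
the radius enclosing 95% of the deposited energy.  For 30 keV through
1000 nm of ice this model gives a median deposition radius of ~28 nm but
a 95% radius of ~280 nm: the tail is carried by the few electrons that
suffer a large-angle Rutherford deflection and then deposit along long
oblique paths.  The 95% quantile is therefore a conservative (tail-
sensitive) damage measure; the dense core that dominates dose *density*
is an order of magnitude tighter.  Classic beam-broadening estimates
(lateral spread ∝ t^{3/2}) give the same ~100–300 nm scale at the exit
surface, so the heavy tail is a property of the physics, not of the
sampling.

## EFTEM benchmark (`eftem`)

t = λ_inel·ln(I₀/I) per pixel with λ_inel = 320 nm (300 keV in vitreous
ice).  The mean apparent thickness over a vacuum region is subtracted,
which both zeroes holes and cancels any global exposure mismatch between
the two images.  The pre-tilt correction multiplies by cos(pre-tilt)
(default 10°) to convert beam-path thickness to lamella-normal
thickness — the same projection the q4STEM incidence correction applies.
Pixels with non-positive intensity are NaN and masked; negative
thicknesses from noise around zero stay in the array (so vacuum
statistics remain unbiased) but are excluded from the validity mask.

Map comparison block-averages the finer map to the coarser grid
(thickness is a local mean quantity) and reports the mean and SD of the
difference plus mean line profiles along both axes.  Registration is
assumed done upstream.

## Synthetic generators (`synth`)

The phantom is 2.5D — a thickness *field*, not a volume — with linear
wedges at both ends whose slope matches the milling angle (footprint
w = d/sin θ), a flat centre with an optional leading-to-trailing ramp
(emulating the ~50 nm thinning gradient from grazing ion flux), and a
platinum-mask band at the trailing edge.  Milling subtracts material
uniformly at the configured rate (default 2.4 nm/s), so truth stacks are
non-increasing by construction.

Rendering choices and their limits:

* **RLM** — plateau pixels carry the thin-film reflectivity of their
  local thickness; wedge footprints render as a constant bright band
  (standing in for specular foil-side reflection) and the Pt mask as a
  brighter constant.  Noise is additive Gaussian at 2% of the dynamic
  range.  Real wedges show Newton fringes and graded edges, so the
  sub-pixel bias of width extraction on real data may exceed the ≤1 px
  seen on synthetic bands; the d = w·sin θ conversion is unaffected.
* **Scattering** — exit angles are drawn from the same Monte-Carlo model
  the analysis tables use, with uniform azimuth, projected to the
  scintillator by r = D·tan θ and binned; counting statistics arise from
  the finite dose.  Because generator and analysis share the transport
  physics, round-trip tests validate the *inversion machinery*, not the
  cross sections; Pt-rich regions, crystalline diffraction and detector
  blur are not emulated.
* **EFTEM** — I = I₀·exp(−t/λ_inel) with independent 1% multiplicative
  Gaussian noise per image; plural-scattering deviations from the
  exponential law are not modelled.

Consequently, passing recovery tests demonstrate correctness of the
estimators under their own model assumptions and realistic noise, not
robustness to every instrumental artefact of real acquisitions.

## Problem sizes and determinism

Default desk-scale sizes keep every pipeline fast while leaving
counting errors well below the tolerances tested: lookup tables use
20 grid points × 20 000 electrons (≈ 2 s), pattern inversions 20 000
electrons per probe, RLM series ~20 frames of 400×80 px, TFI maps
64×64 px.  Every stochastic operation takes an explicit seed, child
seeds are derived deterministically per grid point / probe, and tables
embed seed and electron count for provenance.

## Known limitations

* The screened-Rutherford/Bethe model drifts for Z-heterogeneous
  material: Pt-rich GIS regions read thick (a documented interpretation
  aid, not corrected).
* Single-wavelength TFI cannot detect interference-order errors; the
  geometric initial estimate must be within half a period.
* The geometric method needs a resolvable wedge band (~> 400 nm).
* EFTEM assumes single-exponential zero-loss attenuation and
  pre-registered montages.
* The packaged ice dispersion is a synthetic stand-in anchored at one
  measured point (see above).
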