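# Methods note

Models, conventions, parameter defaults and limitations of the `fibremap`
package. Everything quantitative below refers to behaviour of this code on
its own synthetic data; no claims are made about any particular tissue
dataset.

## Angle conventions

* In-plane fibre orientation δ is measured anticlockwise from the
  horizontal image axis and reported modulo 180° in `[0, 180)`.
* Illumination/analysis azimuths ψ live on the full circle `[0, 360)`.
* Out-of-plane tilt α is in `[0, 90]`, 0 = in plane.
* Signed orientation differences are wrapped to `(−90°, 90°]` via
  `Δφ = 90 − mod(90 − (a − b), 180)`; the boundary case maps to +90°,
  never −90°. Orientation averages use the doubled-angle circular mean.
* Image transforms use a y-up coordinate frame about the image centre, so
  a positive rotation is anticlockwise both for the pixel grid and for the
  orientation values (which co-rotate: rotating an orientation image must
  rotate the orientations themselves, modulo 180°).

## Fibre phantoms

A phantom is a rectangular grid where each pixel holds up to three fibre
populations `(δ, α, amplitude)` plus one global susceptibility parameter
set `(R, Cmag, Δ)`. Phantoms are described as stacks of rectangular bands;
overlapping bands stack populations (a fourth population raises an error).
Optional per-pixel orientation jitter is Gaussian with a configurable
standard deviation and is deterministic for a fixed seed.

## Scattered-light forward model

Per pixel, the azimuthal line profile is a constant background (default
0.05 per unit amplitude) plus, for each population, a pair of
wrapped-Gaussian peaks (default standard deviation 8°) centred on
`δ + 180° ± s/2` with separation `s = 180° − k·α` (default slope
k = 0.5°/°). An in-plane fibre therefore peaks exactly at δ+90° and
δ+270° — scattering perpendicular to the fibre — and the pair mid-position
always recovers δ. Populations add linearly. Optional noise: additive
Gaussian or Poisson with a given photon budget, both seeded. The default
acquisition schedule is a full circle at 15° steps (24 images) at 45°
polar illumination angle.

The linear tilt law and the constant background are deliberate
simplifications: they reproduce the qualitative signatures (tilt narrows
the pair, background exercises the prominence filter) without modelling
diffuse scattering, absorption or the polar-angle dependence.

## Scattered-light analysis chain

Per pixel: circular peak detection → pairing → orientations.

* **Peaks**: local maxima of the profile treated circularly (the profile
  is tiled three times so every peak sees its full circular
  neighbourhood); a peak is kept when its circular prominence is at least
  8% of the profile amplitude (max − min). Constant profiles yield no
  peaks. Peak positions are refined with a 3-point parabolic
  (quadratic-vertex) interpolation, clipped to half a grid step; a 3-point
  intensity-weighted centroid and no refinement are available as options.
  The parabolic default is the package's own choice: the centroid variant
  is biased toward the discrete maximum by the background and by
  neighbouring peaks' tails, and on the pinned crossing-angle sweep it
  first resolves two bundles at 27° instead of 25°.
* **Pairing**: peak pairs separated by 180° ± 35° are accepted, greedily,
  closest-to-180° first, each peak used at most once.
* **Orientations**: a pair maps to its mid-position (mod 180°) with the
  circular distance between its peaks stored as the pair separation
  (≤ 180° by definition; values below 180° indicate tilt). A lone peak
  maps to `peak + 90°` with undefined separation. Candidates are ranked by
  prominence, orientations closer than 10° are merged by circular mean,
  and at most three are kept per pixel (an overflow flag records
  truncation).

At 15° sampling with 8°-wide peaks, off-grid orientations carry a
sub-grid interpolation bias of up to ≈2.5°; grid-aligned orientations are
exact. The smallest crossing angle resolved into two orientations under
the pinned noise-free sweep (first bundle at 0°, 3° truth tolerance) is
25°.

## Polarimetric SHG forward model

Both pSHG simulators work at field level from the fibre-frame second-order
susceptibility: `χ_zzz = R`, `χ_zxx = χ_xxz = 1`, and a chiral element
`C_eff = Cmag · e^{iΔ} · sin α` (fully in-plane fibres show no chirality).
The fibre frame is rotated by δ into the laboratory frame. Populations add
incoherently (intensities sum). Raw counts are scaled (default 1000) and
optional seeded noise is applied as for the scattered-light stack.

Two conventions are fixed by calibration, not by the equations themselves:
the handedness of the fibre-frame perpendicular axis and the sign of the
chiral term are chosen once so that the double-Stokes equations below
recover +δ and σ = +2C·cosΔ/(R+1) on simulated data.

The R parameter is used directly; no tilt projection of the achiral tensor
is applied (tilt enters the pSHG model only through the chiral term).

* **Double-Stokes stack**: 6 incident × 6 analyser states
  (HLP, VLP, +45°, −45°, RCP, LCP), intensities `(6, 6, H, W)`. The
  chiral contribution is linearised at intensity level,
  `I = |P_a|² + 2·Re(P_a*·P_c)` (clipped at zero): the full modulus square
  carries an O(C²) term that would break the printed closed form
  σ = 2C·cosΔ/(R+1) at the 10⁻³ level for Cmag ≈ 0.1. With the
  linearisation the closed form holds to ≤ 4·10⁻⁴ over
  R ∈ {1.5, 2, 3}, Cmag ∈ {0, 0.05, 0.1}, Δ ∈ {0, π/4}.
* **PIPO stack**: 8 incident × 8 analyser linear polarisation angles at
  22.5° steps, intensities `(8, 8, H, W)`, from the standard two-fibre
  field model (see below) with a real effective chiral ratio
  `C = Cmag · sin α`; the chiral phase Δ does not enter the PIPO model
  (off-resonance assumption).

## Double-Stokes analysis

Preprocessing masks pixels whose mean intensity over all stack images is
below 5 counts (boundary kept) and median-filters every image with a 3×3
window (reflect edges). Outgoing Stokes components per incident state are
`s0 = I_H + I_V`, `s1 = I_H − I_V`, `s2 = I_{+45} − I_{−45}`,
`s3 = I_R − I_L` from the analyser-side intensities.

From these:

* `A = [(s0^HLP − s0^VLP) − (s0^{+45} − s0^{−45})] / [(s0^HLP − s0^VLP) + (s0^{+45} − s0^{−45})]`
* `σ = (1/3)·(s2^HLP − s2^VLP − s1^{+45} + s1^{−45}) / (s1^HLP − s1^VLP + s2^{+45} − s2^{−45})`
  which equals `2C·cosΔ/(R+1)` on the forward model
* `SHG_LD = 2(s0^HLP − s0^VLP)/(s0^HLP + s0^VLP)`,
  `SHG_45 = 2(s0^{+45} − s0^{−45})/(s0^{+45} + s0^{−45})`
* `tan 2δ = [(A − 1) − (A + 1)σ] / [(A + 1) + (A − 1)σ]`

The ratios only pin |tan 2δ|; the quadrant is resolved as
`2δ = atan2(|num|·sign(SHG_45), |den|·sign(SHG_LD))`, using that
(SHG_LD, SHG_45) behaves as a positive multiple of (cos 2δ, sin 2δ). Near-
zero denominators are masked to NaN (tolerance 10⁻⁹ of the per-pixel s0
scale) rather than propagated.

Noise-free recovery is exact to well below 0.5° over
δ ∈ {0, 10, …, 170} × R ∈ {1.5, 2, 3}. For a pixel with two crossing
equal-amplitude bundles the chain returns one effective orientation — the
bisector of the pair — by construction of the incoherent sum; resolving
crossings requires the PIPO chain.

## PIPO analysis

Per pixel the measured 8×8 intensity grid is fitted with

`I(θ, φ) ∝ Σ_i |sin(φ−δ_i)·sin 2(θ−δ_i) + cos(φ−δ_i)·sin²(θ−δ_i) +
R·cos(φ−δ_i)·cos²(θ−δ_i) + 2C·cos(θ−δ_i)·sin(θ−φ)|²`

for one or two fibre orientations δ_i with shared R, C and amplitude.
Fitting is bounded multi-start least squares: a coarse 15° orientation
grid with the amplitude profiled out ranks starting points, the top three
are refined (`scipy.optimize.least_squares`, R ∈ [0.5, 4], C ∈ [−1, 1]).
The two-fibre model is selected only when it improves the single-fibre
residual by more than 20%, its orientations are more than 10° apart, and
the single-fibre residual is above a floor of 10⁻¹² of the signal energy —
otherwise the single-fibre fit is kept. At least 16 measurements are
required; all-zero pixels return an unconverged result. Image-level
fitting reuses the double-Stokes preprocessing (count threshold + median
filter).

On noise-free synthetic data the fitter recovers {δ1, δ2} to well under 1°
and R to under 0.05 for crossing angles from 30° to 90°; it cannot return
more than two orientations per pixel (three-layer pixels fit as at most
two).

## Cross-modality comparison

1. The scattered-light map is resampled to the pSHG pixel grid by
   nearest neighbour with factor `source/target` pixel size (reference
   values 2.87 µm → 2.37 µm).
2. An optional similarity transform (scale, rotation, translation)
   registers the moving map by inverse nearest-neighbour warping about the
   image centre; orientation values co-rotate by the rotation angle
   modulo 180°. Pixels mapped from outside become empty.
3. Both maps are cropped to their common extent and differenced per pixel:
   orientations are sorted ascending in both maps and differenced slot by
   slot, each Δφ wrapped to `(−90°, 90°]`, always as ComSLI − pSHG.
   Pixels where either map is empty, or where the two maps disagree on
   the number of orientations, are excluded with a reason code
   (1 = empty, 2 = count mismatch) and reported in the statistics.
4. The Δφ histogram uses bins centred on multiples of the bin width
   (default 1°), so a near-zero distribution reports mode 0°. The mode is
   the centre of the highest bin (ties resolved towards 0°); the FWHM is
   the distance between the outermost half-maximum crossings, linearly
   interpolated between bin centres and floored at one bin width.

## Rendering

Orientation maps render to HSV colour-wheel images (hue = δ/180°, full
saturation and value). Each source pixel becomes a 2×2 sub-pixel block:
one orientation fills all four sub-pixels; two occupy diagonal pairs (the
lower orientation on the main diagonal); three take three sub-pixels with
the fourth left black. Empty pixels are black.

## Limitations

* The simulators are idealised: no diffuse background scattering, no
  polar-angle dependence, a linear tilt law for the scattered-light pair
  separation, incoherent population addition, and a linearised chiral
  response in the double-Stokes stack. They are designed to close the
  loop against the analysis chains, not to reproduce raw microscope data.
* The double-Stokes chain reports a single effective orientation per
  pixel; crossing-fibre pixels are structurally excluded from
  cross-modality statistics unless the PIPO chain is used on the pSHG
  side.
* Sub-grid orientation accuracy of the scattered-light chain is limited
  by the azimuthal sampling (≈2.5° bias worst case at 15° steps).
* Registration is nearest-neighbour with a user-supplied similarity
  transform; no automatic registration is performed.
* The PIPO model is limited to two fibre orientations with shared R, C
  and amplitude, and a real chiral ratio.
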