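# Methods

`npfate` implements a correlative X-ray analysis chain for tracking the fate
of foliar-applied nanoparticles (NPs) in plant leaves, combining three
modalities: scanning small-angle X-ray scattering (SAXS) for nanoscale
particulate structure, micro-computed tomography (micro-CT) for 3D
densified-region morphology, and X-ray fluorescence (XRF) mapping for
elemental distributions. A synthetic phantom generator stands in for
beamline data so every stage is testable offline.

## SAXS reduction

Each detector pixel is assigned a scattering-vector magnitude
q = (4π/λ)·sin(½·atan(r/D)) with λ[Å] = 12.398/E[keV], r the in-plane
distance from the beam center and D the sample–detector distance, and an
azimuth θ measured counterclockwise from the detector +x axis (+y along
increasing row index), on [−π, π). Azimuthal regrouping is a plain
per-pixel rebin onto the polar (q, θ) grid: each cake cell stores the
*mean* of its unmasked pixels plus the contributing-pixel count, so

* windowed totals (mean × count) conserve the unmasked counts exactly,
* partially filled corner bins stay well defined,
* empty cells are NaN, never zero.

The beam-center pixel has undefined azimuth and is always excluded. The
implementation is validated cell-by-cell against a brute-force double-loop
binning oracle over random geometries and masks. No polarization,
solid-angle, flat-field or absolute-intensity corrections are applied;
intensities are relative throughout.

Radial and azimuthal integrations are pixel-count-weighted means over the
collapsed dimension, with Poisson counting errors
(σ(mean) = √(total counts)/n). Background subtraction interpolates the
background onto the sample grid, combines σ in quadrature, and retains
negative results with a warning count rather than clipping.

The default analysis q-window is 0.004–0.022 Å⁻¹, overridable in the run
configuration. A caveat on accuracy: the radial curve equals the
generating model to <1% only where the q-binning resolves the model's
curvature; when ln I varies by ≳0.2 within one bin (large particles on a
coarse grid) the bin-mean-versus-bin-center discrepancy alone exceeds 1%.

## Feature maps and the anisotropy statistic

Two per-point statistics assemble mesh-scan images:

* **Total scattering** — counts attributable to the q-window,
  Σ (cell mean × cell pixel count). Linear in frame intensity.
* **First moment of the azimuthal profile** — M1 = ∫ θ·I(θ) dθ by
  trapezoidal quadrature. The literal formula is origin-dependent on an
  uncentered grid (there it measures total intensity, not anisotropy), so
  the θ grid is centered about 0 and a normalized variant
  M1/∫I dθ — the intensity-weighted mean azimuth — is the default for
  maps. Isotropic scattering gives 0 in both modes; an oriented cos²
  modulation at θ₀ gives −(π/2)·sin 2θ₀ in literal mode on the full
  circle, which is what lets the map separate oriented cellulose from
  isotropic NP clusters of comparable total signal.

Invalid mesh points are NaN in exported maps, never zero, to avoid fake
low-signal pixels.

## Guinier analysis

In the Guinier regime I(q) ≈ I₀·exp(−q²Rg²/3). The fit is weighted linear
least squares of ln I on q², with delta-method weights (I/σ)²;
non-positive intensities are dropped and counted. Rg = √(−3·slope) and
I₀ = exp(intercept), with errors from the weight-model covariance. When no
window is supplied, the widest low-q window with q_max·Rg ≤ 1.3 (the
standard validity bound for globular scatterers; configurable) is found by
iterating fit ↔ window to a fixed point (≤50 iterations). A non-negative
slope flags the fit degenerate with Rg reported as 0.

Dilution series are summarized by the I₀ reduction ratio
I₀(baseline)/I₀(entry) — proportional to the dilution factor when
scattering is linear in concentration — and by the Rg spread
max|Rg − median|/median, called stable within 5% (size invariance under
dilution). Reported ratios are rounded to 2 decimals; internal values keep
full precision.

Closed-form radii of gyration: sphere Rg² = 3R²/5; cylinder
Rg² = L²/12 + R²/2; core–shell sphere the contrast-weighted second moment
(3/5)·[ρ_s(R_t⁵−R_c⁵)+ρ_c R_c⁵]/[ρ_s(R_t³−R_c³)+ρ_c R_c³]. Form factors
are orientation-averaged and normalized so I(0) = concentration ×
contrast²; the cylinder average uses a 128-point Gauss–Legendre rule. The
core–shell model needs two contrasts where the particle record carries
one, so an optional `shell_contrast` field defaults to half the core
contrast — enough to exercise the two-shell interference structure without
inventing material constants.

## CT quantification

"Semi-automated threshold segmentation" is operationalized as: leaf =
largest connected component above a global Otsu threshold after a
one-voxel binary closing; NP mask = voxels above an Otsu threshold
computed *within* the leaf (the automated part), overridable by a manual
threshold that is recorded in the segmentation record (the manual part).
The volume fraction is |NP mask|/|leaf mask| — leaf voxels, not a bounding
box, form the denominator. Otsu-based masks are invariant under global
gray shifts (the threshold shifts equally). NP-region histograms use
caller-supplied common bin edges across a time series so their leftward
shift under dispersion is directly comparable. Phase retrieval and
cone-beam reconstruction are upstream of this package; reconstructed
volumes are consumed as given.

## XRF maps

Registration is translation-only (integer pixel), estimated by normalized
cross-correlation of Otsu-binarized maps; a correlation peak below 0.2
raises an alignment error and requires a manual offset. Rotation and scale
are out of scope and left to the caller. Time-series histograms share bin
edges with the control map; the control map's literal maximum is the
reference marker, and each timepoint reports the fraction of pixels above
it — the signal attributable to the dosed NPs.

## The fate rule table

Per-modality region statistics (SAXS map mean over the infiltrated region,
CT NP-region mean gray, XRF region mean of the signature element) are
reduced to up/down/stable trends by the first-to-last relative change
r = (last−first)/first with an inclusive ±10% stability band (configurable;
first-to-last rather than a regression slope, matching day-0 vs day-3
comparisons). The rule table is

| process       | SAXS | CT     | XRF    |
|---------------|------|--------|--------|
| aggregation   | down | up     | stable |
| dispersion    | up   | down   | stable |
| dissolution   | down | stable | stable |
| translocation | down | down   | down   |

Classification returns *every* matching rule (the table is not claimed to
be a partition); an empty set is reported as "inconsistent with
framework". For dissolution the discriminating XRF tracer is the immobile
dopant (Ce-like): it stays in place while the mobile nutrient (P-like) is
exported, so the mobile element's decline is reported alongside but does
not veto the call.

## Dosimetry and geometry

Dose per exposure D = Φ·E·t/A·(µ/ρ) in gray, with keV→J via
1.602176634×10⁻¹⁶, µm²→m², cm²/g→m²/kg. This is a thin-sample surface
dose: no transmission, depth or fractionation factors. µ/ρ is a user
input; no internal attenuation tables. Cone-beam helpers: M = SDD/SOD,
effective voxel = pixel/M, effective propagation z = SOD·(SDD−SOD)/SDD;
values are kept at full precision with display rounding reproducing the
conventional printed figures (5.8×, 2.78 µm, 13 cm for 92 cm/16 cm/16 µm).

## The phantom's stated world

The generator emulates, at desk scale, the statistical structure the
analysis assumes:

* **Frames** — isotropic particle term (orientation-averaged form factor ×
  per-point concentration) plus an anisotropic cellulose-like background
  A·q^−p·[1−f+f·cos²(θ−θ₀)] with p = 2.5 by default. The background's
  q-exponent is a simulator parameter, not a claim about plant tissue: the
  power law is the minimal model whose anisotropy the first-moment
  statistic must detect. Poisson noise, when enabled, is applied after
  scaling by one count factor per scan anchored to the unit-concentration
  frame, so relative intensities across mesh points and days are
  preserved. All randomness flows from a single seed
  (`numpy.random.default_rng`); a fixed spec is bit-reproducible.
* **Time series** — per-fate day factors, fixed a priori so that every
  non-stable arrow of the rule table moves well outside the ±10% band by
  day 3: dissolution scales the particle concentration by e^−0.8d with CT
  and the immobile tracer flat and the mobile element e^−0.6d;
  aggregation e^−0.5d SAXS with CT amplitude 1+0.25d; translocation
  decays all three; dispersion raises SAXS by 1+0.3d while CT clusters
  loosen (amplitude e^−0.4d, width 1+0.4d), which is what drives the
  falling within-leaf Otsu threshold, the rising volume fraction and the
  leftward NP-histogram shift. In the freeze-dried regime the particle
  term dominates the cellulose background by roughly an order of magnitude
  inside the infiltrated region, mirroring the strong NP contrast that
  regime provides.
* **Scale** — defaults are mesh 8×8, frames 64×64, volumes 64³, maps
  64×64, versus beamline scales of 100×100 meshes of megapixel frames and
  multi-gigavoxel tomograms. Tests run down-scaled (CT trend checks at
  128³); this changes counting statistics, not the trend logic.

What a green phantom test does **not** establish: real leaves have
polydisperse, interacting particles (no structure factor or
polydispersity is modeled), spatially varying cellulose orientation,
reconstruction artifacts (rings, beam hardening), and imperfect
inter-modality registration. The phantom validates the pipeline's
statistics and decision logic, not instrument calibration.

## Numerical choices and degenerate inputs

* θ = π is folded to −π so the azimuthal edge bin is unambiguous.
* q at the beam-center pixel is clamped to the half-pixel q in the phantom
  renderer so the power-law background stays finite.
* Sphere amplitude uses a series expansion below |x| = 10⁻⁴.
* Guinier fits with fewer than 5 positive points raise instead of
  guessing; window iteration failure after 50 rounds raises.
* A segmentation threshold above the gray maximum yields an empty NP mask
  and fraction 0 — a valid result, not an error; an all-air volume raises.
* Stability-band boundary (|r| = band) counts as stable.

## Known limitations

* No absolute-intensity calibration; all intensities are arbitrary units.
* Translation-only XRF registration; rotation/scale must be handled
  upstream.
* The radial-curve accuracy caveat above (binning-resolved regime).
* The dose formula is a surface estimate and will overestimate mean dose
  for thick or strongly transmitting samples.
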