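# Methods

`kedgect` simulates a two-threshold photon-counting CT acquisition of a
cylindrical contrast-material phantom and measures how per-material image
contrast, image noise and pairwise material separability depend on the
upper energy threshold. This note records the model, its assumptions, the
parameters that matter, and the numerical choices, in enough detail to
reproduce or challenge any number the package prints.

## Phantom

A 30 cm diameter water cylinder holds 16 circular inserts: 15 elemental
solutions — Ca (50 mg/mL), Fe (30 mg/mL) and I, Ba, Sm, Eu, Gd, Tb, Yb,
Lu, Ta, W, Pt, Au, Bi at 4 mg/mL each — plus one pure-water control
insert. Concentrations of the contrast candidates are matched to the
clinical iodine level (4 mg/mL); Ca and Fe use typical
dual-energy-phantom levels. Insert radius (1.25 cm) and the layout (five
inserts on a 5 cm ring, eleven on a 10 cm ring, atomic-number order) are
conventions of this package chosen for clean ROI separation; the physics
studied here does not depend on them. The phantom is analytic
(circles), so projections are exact chord lengths with no voxelization
error.

Materials are grouped three ways for reporting: biological/clinical
(Ba, Ca, Gd, Fe, I), lanthanides (Sm, Eu, Gd, Tb, Yb, Lu) and candidate
agents/nanomaterials (Bi, Au, Pt, Ta, W, Yb); Gd and Yb each appear in
two groups.

## Attenuation physics

Per-element mass attenuation tables are bundled as plain text under
`kedgect/data` (1 keV grid over 15–140 keV, duplicated abscissae at each
K-edge). They are generated once by `scripts/make_attenuation_tables.py`
from the package's cross-section engine (`kedgect.crosssections`):
photoabsorption from Cromer–Liberman f″ (including all edges), incoherent
scattering from Klein–Nishina screened by a Waller–Hartree incoherent
function built from IT92 form factors, and coherent scattering from the
Thomson cross section with the same form factors, all driven by data
shipped with `gemmi`. Against the NIST standard tabulations this engine
is accurate to about 2% over the imaging band (verified for water in the
test suite); since solutes enter only as trace concentrations, that error
is second-order for every reported metric. Water and dry air use the NIST
standard-reference material tables directly, so the HU scale rests on
reference data. K-edge energies are the standard K-shell binding
energies; all 15 insert elements round to the published integer values
(I 33, Ba 37, Sm 47, Eu 49, Gd 50, Tb 52, Yb 61, Lu 63, Ta 67, W 70,
Pt 78, Au 81, Bi 91 keV).

Interpolation is linear in log E – log(μ/ρ). Edges are represented by two
table rows at the same energy (below-edge value first), so interpolation
never bridges a discontinuity; a query exactly at the edge returns the
above-edge branch. Solutions are ideal dilute mixtures:
μ(E) = μ_water(E) + c[g/cm³]·(μ/ρ)_solute(E), water density 1.0 g/cm³,
solute volume displacement neglected — exact affinity in concentration is
a tested invariant. Air uses dry-air composition at 1.205 mg/cm³.

## X-ray spectrum

The 120 kV tube output is a Kramers bremsstrahlung continuum (photon
fluence per 1 keV bin ∝ (kV−E)/E) filtered by aluminum, plus tungsten
characteristic lines at 59.3 keV (8% of output) and 67.2 keV (2%),
renormalized to a per-ray photon budget N0. The energy grid is 1 keV bin
left edges over [20, 120); thresholds at multiples of 5 keV align exactly
with bin boundaries, so two-bin partitions conserve photons to machine
precision.

Total filtration defaults to **6.0 mm Al equivalent**. A bare Kramers
continuum behind a thin (2–3 mm) filter has a mean energy near 51 keV,
unrealistically soft for a clinical CT system, whose inherent plus flat
filtration is ≥ 6 mm Al equivalent; at 6.0 mm the mean energy is
57.9 keV, inside the plausible clinical band (55–70 keV). The true
filtration of the scanner being emulated is not public, so all
spectrum-dependent quantities should be read as representative, not
vendor-exact.

N0 defaults to 4.5×10⁶ photons per ray. This is a calibration constant:
it is chosen so that, under the reduced geometry and the default 1-px
Gaussian denoising, the low-energy-image water-background noise at
threshold 50 keV is ≈ 16 HU, anchoring the noise scale to a realistic
clinical operating point. Absolute noise values scale as 1/√N0 (a tested
invariant); only trends in the threshold are physics.

## Acquisition and detector model

Geometry is 2-D parallel beam, single slice: `n_views` angles uniformly
covering 180°, `n_channels` detector elements spanning a 36 cm field of
view, detector pitch equal to the reconstruction pixel pitch. Presets:

| preset  | views | channels = grid | pixel   |
|---------|-------|-----------------|---------|
| paper   | 720   | 720             | 0.5 mm  |
| reduced | 180   | 256             | 1.41 mm |
| tiny    | 96    | 96              | 3.75 mm |

The 0.5 mm pixel of the `paper` preset matches the clinical
reconstruction; the grid is 720 px so the 36 cm field of view (and hence
the full 30 cm phantom) stays inside the reconstruction circle — a
512-px/0.5 mm grid would truncate the object in this geometry. The
`reduced` preset is the default for the analysis scripts and the
acceptance run; contrast argmax results are insensitive to this choice
because they compare noise-free means across thresholds within one fixed
geometry.

The detector is an **ideal** energy discriminator: every photon is
counted in the bin its true energy falls in ([20, T) and [T, 120]).
There is no charge sharing, no pulse pileup, no spectral distortion, and
no scatter is simulated. Consequences are discussed under Limitations.

Expected counts per ray and bin follow Beer–Lambert per energy bin, with
the spectrum defined as the air-scan fluence at the detector (so
materials act through their attenuation relative to air). Noisy
acquisitions Poisson-sample the expected counts. Sinograms are flat-field
normalized log line integrals −ln(N/N_air); zero counts are clamped to
0.5 counts before the log, and a photon-starvation warning is logged if
more than 1% of rays clamp.

Inside `run_sweep`, noise uses a Gaussian approximation to Poisson
(counts = μ + √μ·Z, rounded, clipped at zero) with the standard-normal
field Z shared across threshold settings — common random numbers. Each
noise estimate stays unbiased (expected counts exceed ~10³ everywhere at
the default budget), while threshold-to-threshold noise *comparisons* are
not swamped by estimator fluctuation; with 4 averaged realizations the
noise-vs-threshold curves are cleanly monotone. `simulate_sinogram` keeps
exact Poisson sampling for single acquisitions.

## Reconstruction and HU calibration

Filtered back projection uses the ramp (Ram–Lak) filter with linear
interpolation (scikit-image `iradon`), output in linear attenuation
(1/cm).

Before reconstruction each bin's sinogram passes a **water
beam-hardening linearization**: the analytic polychromatic water response
p(L) of that bin is inverted to the water-equivalent path L and rescaled
by the bin-effective water attenuation. Without it the water background
cups by ~18 HU between the center and the 10 cm ring at this phantom
size, which would alias into every contrast measurement; with it the
noise-free water phantom is flat to well under 5 HU in every bin and
threshold. This is the standard first-order water correction of clinical
CT and this package's reading of the scanner's "air/water corrections".

HU calibration is per bin and per threshold: a noise-free scan of a plain
water cylinder under the identical protocol yields the bin-effective
water attenuation μ_w; air is the flat-field reference and reconstructs
to zero, so HU = 1000·(μ − μ_w)/(μ_w − μ_air) with μ_air = 0 maps water
to 0 HU and air to −1000 HU.

Denoising is a 2-D Gaussian filter, the single-slice analog of the
volumetric smoothing used clinically; the kernel width is not public, so
σ = 1.0 px is the default and configurable. Noise metrics are quoted on
denoised images (matching how the clinical images are processed);
the 1/√N0 noise-scaling test bypasses denoising.

## Metrology

ROIs are circles on the reconstruction grid: per-insert ROIs at 60% of
the insert radius (avoiding rim ringing and partial volume), and a 2 cm
radius water-background ROI at the phantom center. Noise is the sample
standard deviation of HU in the background ROI. Contrast is
mean(insert ROI) − mean(background ROI), per bin image.

Separability uses per-voxel two-channel feature vectors — (low-bin HU,
high-bin HU) at spatially matched pixels. For materials A and B the
linear Hotelling observer template is w = S⁻¹(x̄_A − x̄_B) with
S = (Σ_A + Σ_B)/2 the unweighted average of the class sample covariances
plus a conditioning ridge of 1e−6·tr(S)/d·I; a covariance that stays
degenerate raises rather than silently returning zeros. Projecting every
voxel vector on w gives test statistics λ, and

s′ = (λ̄_A − λ̄_B) / √(½(σ²_{λA} + σ²_{λB}))

is reported as a magnitude (the sign only records which class was called
A). On Gaussian classes s′ estimates the Mahalanobis distance
√(Δμᵀ S⁻¹ Δμ); the tests verify < 2% bias at n = 10⁵ voxels, exact
symmetry and invariance under common invertible channel transforms.
Whether separability should be computed on raw or denoised images is not
dictated by the physics; the sweep uses the same denoised images as the
other metrics.

## Threshold sweep

`run_sweep` evaluates thresholds 50–90 keV in 5 keV steps. One
energy-resolved forward projection is accumulated into per-segment counts
(segments = intervals between consecutive thresholds), so every
(threshold, bin) sinogram is a partial sum — the full sweep costs one
projection pass plus 18 reconstructions (plus 18 water-calibration
reconstructions). Contrast argmax queries break ties toward the lower
threshold (more high-bin photons, less noise); the same rule applies to
the best-separating threshold per material pair. Noise-free mode is used
for contrast-argmax questions (no Monte Carlo flake); seeded noisy mode
for noise and separability. A rerun with the same configuration and seed
is bitwise identical.

## What the simulation does and does not emulate

The generator reproduces: polychromatic K-edge attenuation physics, the
photon economics of two-bin threshold detection (bin fluence partition),
beam hardening in a 30 cm water object, FBP noise texture, per-bin HU
calibration, and ROI-based contrast/noise/separability metrology.

It deliberately omits: detector charge sharing and pulse pileup, scatter,
helical/fan-beam 3-D geometry, bowtie filtration, tube-current
modulation, and dose accounting. Two consequences matter when comparing
with measurements on a real scanner:

* **Absolute HU noise values are calibration-dependent.** Only the
  direction of the noise trends (low bin quietens, high bin gets noisier
  as T rises, by factors the bin-fluence table explains) is a prediction.
* **Low-energy-image contrast is monotone decreasing in T for materials
  with K-edges below 50 keV.** Raising the threshold adds photons whose
  monoenergetic contrast for such a material is lower, so any fluence
  weighting lowers the low-bin mean — under an ideal detector this is a
  theorem, and the simulation confirms it (iodine peaks at the 50 keV
  end of the sweep). On real systems the low-energy image at low T is
  additionally diluted by scatter and by charge-sharing spill-down of
  high-energy photons, which suppresses contrast at low thresholds and
  can move the apparent peak up to ~70 keV. Reproducing that effect
  requires a non-ideal detector response model, which is out of scope
  here. High-energy-image argmax results do not suffer from this: they
  are driven by the K-edge position and survive the idealization — every
  material with an edge inside the sweep peaks at the threshold nearest
  its K-edge (Yb 60, Lu 65, Ta 65, W 70, Pt 80, Au 80; Gd and Tb at 50,
  their edges sitting at or just above it), and bismuth (edge 90.5 keV)
  keeps rising to the 90 keV end.

## Numerical choices

* Log–log interpolation on 1 keV tables; duplicated edge abscissae; edge
  evaluation points ±5 eV around the nominal edge.
* Energy bins evaluated at bin centers; a K-edge interior to a 1 keV bin
  is resolved only at bin resolution (≤ 1 keV smearing, small against the
  5 keV threshold step).
* Zero detected counts clamped to 0.5 before the log.
* FBP rotation center at pixel index n//2 on both axes (scikit-image
  convention); channel pitch equals pixel pitch.
* Hotelling ridge 1e−6·tr(S)/d; degeneracy surfaces as an error.
* Argmax ties break toward the lower threshold.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Limitations

Single 2-D slice; ideal detector; no scatter; Kramers continuum rather
than a measured tube spectrum; dilute-solution mixture rule without
density correction; insert geometry is a convention. The package answers
*comparative* questions about energy thresholds under ideal two-bin
detection; it does not predict vendor-exact HU, dose or noise magnitudes.
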