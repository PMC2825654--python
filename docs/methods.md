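# Methods

`darkscatter` simulates dark-field (small-angle scattering) X-ray imaging by
varying collimation: the same projection is acquired through anti-scatter
grids of different aspect ratios, and digital subtraction of the paired
images isolates the small-angle (mostly Rayleigh) scattered flux that the
low-aspect grid passes and the high-aspect grid rejects. The package
contains two independent engines — a Monte Carlo photon-transport simulator
and an analytic single-scattering forward model — plus the detection and
subtraction machinery that turns either into dark-field images.

## Interaction model

Photons are monoenergetic (50 keV by default) and each material is described
by exactly three parameters:

* `mu_t` (cm⁻¹) — photoelectric absorption coefficient,
* `mu_s` (cm⁻¹) — scattering coefficient (Rayleigh + Compton),
* `beta` — Rayleigh fraction: the probability that a scattering event is
  coherent.

Compton scattering energy loss is *not* tracked: a scattered photon keeps
interacting with the same coefficients. This is deliberate — the model is
defined by the `(mu_t, mu_s, beta)` triple, and at 50 keV with mostly
small-angle detection the energy change is a second-order effect.

### Angular densities

The Compton deflection density follows the Klein–Nishina differential
cross-section with `alpha = E/511 keV`. The Rayleigh density is the Thomson
cross-section `(1+cos²θ)/2` modulated by a squared analytic form factor

    F(θ) = c1 · θ^l · e^(−c2·θ),

replacing the tabulated atomic form factors that full-physics Monte Carlo
codes interpolate. `l = 2` by default (zero forward density, a smooth
unimodal small-angle peak); `c1` cancels under normalization; `c2` is
calibrated by bracketed root finding (`scipy.optimize.brentq`) so that the
mean polar deflection equals a target angle — 4.3° for water-like tissue at
50 keV. The calibration residual is verified below 1e−6 rad by independent
quadrature.

**Normalization convention.** All angular densities are normalized over
`θ ∈ [0, π]` under a plain `dθ` measure, *without* the `sin θ` solid-angle
Jacobian. This matches the bookkeeping by which the `beta` column of the
reference material table was defined and keeps `beta`, the mixture density
and the acceptance integrals mutually consistent. The conventional
`sin θ dθ` measure is available behind `weighting="solid_angle"` on every
density/sampler/calibration function for sensitivity checks; it is never
the default. Under the default convention the calibrated decay rate is
`c2 = 33.2666 rad⁻¹` for the 4.3° target at `l = 2`.

### Sampling

Deflection angles are drawn by rejection sampling against a constant
envelope set to the density maximum (coarse 4097-point grid + bounded local
refinement, with a 1e−9 head-room factor). A sampled density value above
the envelope raises an error rather than silently biasing. Acceptance rates
are ~1/π·max: ~0.5 for Klein–Nishina, ~1/80 for the sharply peaked
calibrated Rayleigh density; the samplers draw candidate batches sized from
the analytic acceptance rate, so a million Rayleigh draws cost a few
seconds. Azimuths are uniform on `[0, 2π)`.

## Phantom geometry and traversal

The phantom is a background box plus axis-aligned, pairwise-disjoint box
inclusions; outside is vacuum. Rays are intersected with each box by the
slab method; the sorted crossing parameters partition the chord into
material segments, and free paths are drawn by accumulating optical depth
`(mu_t+mu_s)·length` across segments until it reaches `−ln(ξ)` with
`ξ ∈ (0, 1]`. This multi-region rule is exact — no voxelization error — and
is implemented both per-ray (scalar API) and over flat arrays of rays (the
vectorized kernels the engine uses).

The reference phantom is a 10×10×5 cm³ water slab spanning
`[−5,5]×[−5,5]×[−2.5,2.5]` cm with four 1 cm³ cubes at the quadrant centres
`(±2.5, ±2.5, 0)`. The source text does not give cube coordinates or the
cube-number ↔ quadrant mapping; this package fixes cubes 1–4 in reading
order of the detector view (top-left, top-right, bottom-left, bottom-right)
with x right and y up, and the positions are config-overridable. All five
materials share `mu_t + mu_s = 0.21 cm⁻¹`, so the primary (attenuation)
image is flat and all contrast is scattering contrast.

## Monte Carlo transport

Histories follow launch → free path → (escape | absorb | scatter) → …, with
absorption probability `mu_t/(mu_t+mu_s)` at each interaction, the
Rayleigh/Compton branch decided by `beta`, and the direction updated by a
deterministic local-frame rotation (transverse basis built from the global
axis of smallest direction component). Escaping photons carry their scatter
history and are offered to *every* detector channel, so all channels score
one matched photon stream — subtraction images are then free of
independent-stream noise, and nested acceptance cones give `IL ≥ IH`
pixelwise deterministically.

The engine processes photons in fixed chunks of 2^19 flat numpy arrays;
each chunk owns a Philox substream keyed `(seed, chunk_index)`, so runs are
bit-reproducible for a configuration and independent of how many chunks
execute. A safety cap (10⁴ scatter events) guarantees termination; capped
histories are counted as absorbed and reported. Conservation
(`launched = absorbed + escaped`) is asserted on every run. Throughput is
roughly 1.4e5 histories/s/core on the reference phantom with four channels.

The source is a parallel beam along +z, uniform over the phantom's lateral
extent — the planar-detector geometry of the reference experiment; cone
beams are out of scope.

## Detection and collimator models

The detector is a pixel grid (reference: 600×600 at 0.02 cm pitch;
desk-scale: 60×60 at 0.2 cm) at `z = phantom exit + distance`. Escaping
photons propagate along straight exit rays; accepted photons are binned
into half-open pixels, tallied per scatter class (primary / Rayleigh-only /
Compton-involved), and images are stored as counts per launched photon.

Two collimator models are provided:

* **Angular gate** (default): accept iff the angle to the detector normal
  is ≤ `arctan(1/aspect_ratio)` — an idealized grid with no septal
  shadowing. Used for the IH/IL dark-field acquisitions.
* **Explicit septa** (`septa=True`): square collimator cells of height
  `H = aspect_ratio × pitch` sit on the pixel lattice; a photon is accepted
  iff its ray from the grid-top plane to the detector plane stays within
  one cell. This reproduces the partial transmission of a real grid
  (transmission falling roughly linearly to zero at `arctan(1/aspect)`),
  and is the geometry the single-scattering angular limits describe — so
  it is the model used whenever Monte Carlo is compared against the
  analytic single-scattering image.

The dark-field image is `IL − IH` (aspect 10 minus aspect 50 at 2.5 cm) or
`near − far` (aspect 10 at 2.5 cm minus 17.5 cm). Negative pixels are
noise and are retained. Region statistics are taken over the cubes'
parallel-beam shadows and a water reference region; for the distance
subtraction the water reference must sit ≥1.5 cm from the phantom edge and
the cube shadows, because the far image's scatter is laterally blurred by
≈ distance × tan(acceptance angle) ≈ 1.5 cm and edge pixels acquire a
systematic offset.

## Single-scattering forward model

The analytic estimator assumes each detected scattered photon scattered
exactly once:

    f(cell) = Σ_voxels I0 · w_in · w_out · mu_s · Δz · P(accept | voxel, cell)

with `w_in`/`w_out` Beer–Lambert factors along source→voxel and voxel→cell.
The acceptance probability of a cell at lateral offset `r` from the
scattering point's beam axis is `(φ2−φ1)/2π · ∫_{θ1}^{θ2} p(θ) dθ` with

    θ1 = arctan((r − D/2)/(R − H)),  θ2 = arctan((r + D/2)/R),
    φ2 = −φ1 = arctan(D/(2r)),

`D` the cell aperture, `H` the grid height, `R` the (vertical) distance to
the detector plane. Degenerate cases: `θ1` is clamped at 0 and the cell
subtends the full azimuth when `r < D/2`; an inverted window (`θ1 ≥ θ2`)
means the cell is shadowed and contributes 0; a scattering point below the
septa top (`R ≤ H`) sees nothing.

Acceptance is precomputed on a (depth × material × cell-offset) table —
250 depth levels at 0.02 cm through the 5 cm phantom, 5 materials, and
every geometrically reachable integer cell offset — and reused for all
voxels by the lateral translation invariance of the grid. Two table builds
exist:

* `method="quadrature"` — the factorized angular-limit windows above, with
  the θ-integral from a dense cumulative-trapezoid interpolant (verified
  against adaptive quadrature to 2e−6 and against 2-D `dblquad` to 1e−8).
* `method="mc"` — each entry statistically simulated: deflections drawn
  from the mixture density, azimuth uniform, scattering point uniform
  within the cell footprint, propagated through the *configured* collimator
  model. This makes the table exactly consistent with the transport
  engine's detection rule, including sub-cell geometry that the analytic
  windows approximate.

Attenuation uses vertical-path line integrals on the voxel grid with
half-voxel self terms (accepted angles are ≤ ~8°, so the oblique path
correction is < 1% and is neglected). `I0` defaults to
`pitch²/(source area)` per launched photon, matching the Monte Carlo
normalization.

**Model agreement.** At the desk-scale geometry the single-scatter image
built with the `mc` table matches the Monte Carlo image restricted to
exactly-one-scatter photons to within ~0.5%; the *full* Monte Carlo
small-angle image exceeds it by the multiple-scattering share, ≈6–7% here.
With the `quadrature` table the analytic windows under-cover when `H` is
comparable to `R` (as at 0.2 cm pitch, where `H = 2 cm` against
`R = 2.5–7.5 cm`) and the apparent excess rises to ~22%; at the full-scale
pitch (0.02 cm, `H = 0.2 cm`) the windows tile the acceptance cone far more
closely. Comparisons between the engines therefore always pair the septa
collimator with the `mc` table.

## Desk-scale study conditions

The full reference acquisition (2e10 photons, 600×600 pixels) is not a
desk-scale computation. The packaged `table1_reduced` fixture keeps the
identical phantom, physics, aspect ratios and distances but uses a 60×60
detector at 0.2 cm pitch and 10⁷ photons (the acceptance script's setting).
The shared test acquisition uses 5×10⁷ photons: the smallest region
contrast — cube1 vs cube2, Δmu_sr = 0.0035 cm⁻¹ over a 1 cm cube —
produces region-mean differences of only ~3% of the dark-field level, and
5×10⁷ histories put the worst pair ≥2.4 standard errors apart so the
rank-ordering checks are reproducible rather than coin flips. All
stochastic tests state their tolerance in standard errors of the quantity
they estimate.

## What the synthetic conditions do not capture

* Monoenergetic beam: no spectral hardening, no tube-voltage dimension.
* The analytic form factor mimics only the *mean* small-angle behaviour of
  coherent scattering; real form factors are material- and
  energy-dependent, so `beta` and the 4.3° mean enter as inputs, not
  predictions.
* Ideal detector: no energy response, PSF, or electronic noise; the
  collimator has absorbing, infinitely thin septa (no penetration,
  no focused grid).
* Parallel-beam source; the dual-height cone-beam acquisition and any
  tomographic reconstruction are out of scope.

Passing tests therefore demonstrate internal consistency of the transport,
detection and single-scattering models under these stated conditions — not
agreement with measured dark-field data.

## Numerical choices

* Quadratures: `scipy.integrate.quad` with `limit=200`, abs tol 1e−12 to
  1e−14 for normalizations; dense-grid cumulative trapezoid (32769 points)
  for acceptance windows.
* Calibration: brentq on `c2` to xtol 1e−12; residual checked < 1e−6 rad.
* `ξ ∈ (0, 1]` is realized as `1 − U[0, 1)`, so `−ln ξ` never overflows.
* Degenerate ray components are replaced by ±1e−300 in the slab method
  (yields ±inf crossings, never NaN).
* Pixel bins and collimator cells are half-open; a photon landing exactly
  on a cell wall belongs to the upper cell and, in septa mode, a ray
  whose grid-top and detector cells differ is rejected.
* Scatter-count cap 10⁴ per history; capped histories are reported in the
  tally (`cap_terminated`) and counted as absorbed.
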