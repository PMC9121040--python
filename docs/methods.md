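# Methods

This note documents the models, numerical choices and limitations behind
`mlcopt`.  Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## The two parameters

Rounded MLC leaf ends transmit extra fluence at every leaf tip.  Beam
models absorb this with the **dosimetric leaf gap** (DLG): during dose
calculation each leaf is shifted outward by half the entered DLG, widening
every open gap by exactly the DLG.  **Transmission** (T) is the fraction of
open-field dose leaking through fully closed leaves.  Both are physical
attributes of a machine/energy combination, but the values that make a
beam model *match measurement best* are an optimization target, not a
direct measurement — plan-dependent trade-offs between the two are
expected and are surfaced by this package rather than averaged away.

## Gamma engine

`compute_gamma` implements the standard composite metric: for each
reference (measured) pixel, the minimum over evaluated positions of the
root-sum-square of the distance term (normalized by the DTA) and the dose
term (normalized by dd × D_norm).  Choices the literature leaves open:

* **Normalization dose.**  Global mode uses an explicit `norm_dose` if
  given, else the maximum of the reference plane — measurement-anchored,
  matching common QA software.  Local mode (per-pixel normalization) is
  implemented but not the default.  The low-dose threshold is always
  referenced to the global dose and applied to the reference plane only.
* **Search.**  The evaluated plane is upsampled by an integer factor
  (default 10) with exact separable bilinear interpolation, and the
  minimum is searched within `search_factor × dta` (default 3×) of each
  reference pixel.  Reference pixels whose positions coincide with the
  upsampled lattice are processed in one vectorized gather; others fall
  back to per-pixel window searches.  Edge pixels use whatever evaluated
  points exist — no padding, no extrapolated dose.  A reference pixel whose
  entire search disc misses the evaluated plane falls back to the nearest
  evaluated point so its γ stays defined.
* **Boundary.**  γ = 1 exactly counts as passing.
* **Verification.**  The suite compares the radius-limited search against
  an independent exhaustive brute-force oracle (no radius cutoff, scipy's
  own interpolator) on ~100 random plane pairs; agreement is required to
  1e-6 wherever the exhaustive minimum lies inside the search radius.

## Dose simulator

The simulator stands in for the planning system, the delivery and the
detector.  It is a time-integrated fluence model: every delivery is a set
of piecewise-linear leaf-tip trajectories (bank A from −x, bank B from +x);
the open-time fraction of each point is computed exactly per linear
segment; closed time contributes the scalar T; the fluence is convolved
with a Gaussian penumbra kernel (default σ = 2 mm) and scaled by MU.  The
DLG enters exactly as in beam models: each bank is retracted by DLG/2.

* **Blur discretization.**  The Gaussian filter runs on an internal
  supersampled lattice (pixel ≤ σ/4) and is strided back down, so
  simulated dose is independent of the requested pixel pitch to machine
  precision — 1 mm "truth" planes and 2 mm "calculated export" planes are
  samples of the same continuous field.
* **Closed forms.**  A gap g swept over extent L at constant speed gives a
  central-axis dose of MU·[(g+DLG)/L + T·(1−(g+DLG)/L)]; the simulator
  reproduces it to machine precision pre-blur, which anchors the
  sweeping-gap DLG estimator.
* **Deliberately omitted:** tongue-and-groove, interleaf leakage,
  rounded-leaf-end spectral hardening, leaf-width variation across the
  field, FFF profile shape.  T is one scalar.

### Sweeping-gap DLG estimation

Readings at several gap widths are corrected for transmission and fitted
by least squares; the negated x-intercept is the gap offset (the DLG).
The correction used is the exact inversion of the sweep dose model,
`R_corr = (R − T·open)/(1−T) = open·(g+DLG)/L`, rather than the common
first-order subtraction `R − T·open·(1−g/L)`; the two differ by T·DLG
(~0.02 mm at clinical values), and the exact form makes the noise-free
round trip through the simulator exact.  T is the separately measured
value, as in practice, never fitted.  Negative estimates are returned with
a `suspect` flag instead of an error.

### Measurement model

A detector array with pitch `grid_spacing`, additive Gaussian noise
(`noise_sd`, as a fraction of the plane maximum) and a seed; every
stochastic output records its seed.  Matching pitch and zero noise is the
identity.  Non-commensurate pitches are resampled by block averaging
(area detectors); for the simulated plan sets the truth plane is instead
simulated finely (1 mm) and point-sampled on the detector lattice, because
diode arrays sample dose essentially at points.  Negative noisy readings
clip to zero, which slightly biases means in regions within ~2σ of zero
dose.

### Toy plan set

Three plans carry the desk-scale studies: sweeping gaps of 5 and 10 mm
(different gap-to-sweep ratios make the (DLG, T) → dose map injective) and
a three-region "chair": one region seen only through closed leaves
(transmission-dominated), one crossed by a narrow swept gap
(DLG-dominated), one briefly open.  The open region is exposed for only
~11% of the delivery, as in heavily modulated sliding-window fields; this
keeps the plane maximum low enough that the transmission region clears the
10% analysis threshold — otherwise its information content is discarded by
the mask and T is only weakly identifiable.  A 4 mm guard band separates
the swept and open regions so the DLG widening cannot overlap their
exposures.

Study conditions for the recovery experiments: truth (1.02 mm, 1.45%) —
deliberately off every grid node — 6×6 cm fields, 5 mm detector pitch,
2 mm calculated-plane pitch, 1% noise, MU 100.  Plane sizes stay at or
under 61×61 pixels so a full 561-point phase space over three plans
builds in tens of seconds on one CPU.

## Phase space

One record per plan per grid point, evaluated with the gamma engine;
records are independent of evaluation order, stored canonically, and the
CSV output is byte-reproducible for identical inputs.  Missing calculated
planes raise a completeness error that lists every gap; degenerate gamma
inputs are recorded as NaN and logged, never dropped silently.  The
transmission axis is {0.01%} ∪ {0.25%…2.5% step 0.25%}: the stated 11-value
count together with the stated endpoints admits only this reading.

## Optimizer

Per-plan surfaces are interpolated with bicubic tensor-product splines
(nodal-exact, no extrapolation — queries outside the grid box are errors).
The cost is the weighted plan sum of the interpolated metric: F2 (sum of
mean γ, minimized) by default, F1 (sum of pass rates, maximized)
available.  F2 is the default because pass rates saturate at 100% over
broad parameter regions and carry no gradient there; at desk scale the
sparse detector also quantizes pass rates in steps of 1/N_pixels, which
speckles the top of the F1 surface.

Minimization is multi-start L-BFGS-B in the normalized unit box (DLG and T
differ by two orders of magnitude; unnormalized steps condition badly along
the trade-off valley).  Start points are deterministic: the best raw grid
node, then a fixed 4×2 interior lattice — results are seed-free.  Each
start additionally runs a deterministic patch-scan refinement: bicubic
interpolation of V-shaped γ surfaces scallops along the DLG/T trade-off
valley, creating spurious local minima a few grid steps apart that trap a
pure quasi-Newton descent; scanning the spline on a fine lattice spanning
±6 grid steps and re-polishing lets every start escape to the same basin.
Ties between equal-cost converged points break to the smallest DLG, then
smallest T.

Reported flags:

* `stable` — all successful starts agree within 0.01 mm (DLG), 0.0005 (T)
  and 1e-6 relative cost (scaled by the tabulated cost range, so flat
  near-zero optima compare sanely).
* `nonunique` — the grid nodes within 1e-4 of the optimal cost span more
  than 3 grid steps on either axis: a flat valley where multiple (DLG, T)
  pairs describe the data equally well.  This is a real physical degeneracy
  of γ-based tuning (gap widening and leakage can compensate), and the
  package surfaces it rather than reporting a spuriously precise pair.

The returned cost is never worse than the best raw grid node (the node is
always a start).  The classical paired two-tailed t-test is provided for
comparing per-plan metrics between two parameter sets; zero-variance
differences are flagged degenerate, not silently assigned a p-value.

## What the synthetic studies do and do not show

Parameter recovery (noise-free to half a grid step; 1% noise to one grid
step in median over 20 seeds, with all starts stable) demonstrates that
the pipeline — simulator → measurement → γ phase space → spline → multi-start
optimizer — is self-consistent and identifiable under the stated
conditions.  It does not validate the simulator against a real planning
system or linac: real deliveries add tongue-and-groove, spectral and
detector-response effects the fluence model omits, and real measured
planes carry setup and calibration uncertainties beyond additive noise.
With noisy references the γ minimum-search relieves negative noise
excursions more easily than positive ones, which leaves a small systematic
pull of the optimum along the residual trade-off direction (visible as a
recovery bias of a fraction of a grid step); the same mechanism operates
on clinical data.

## Numerical conventions

Plane coordinates in mm, isocenter (0,0), leaf motion along x, y up; array
row 0 is the top row and `origin_*` is the centre of pixel (0,0).  Doses
in cGy; DICOM RT Dose files store Gy × a 32-bit scaling chosen so the
maximum maps to the top of the integer range (quantization ≤ half a
scaling step); file UIDs derive from content hashes, so writes are
byte-deterministic.  The ASCII grid dialect is documented in its file
header and round-trips at full float precision.  One seed governs all
stochastic steps; derived seeds stay below 2³¹.
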