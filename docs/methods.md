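# Methods

## Geometry and conventions

The laboratory frame is right-handed with *z* toward the X-ray source and
*y* vertical; the incident beam vector is **S**₀ = (0, 0, −1/λ), so the
Ewald sphere has radius 1/λ and is centered at −**S**₀ from the origin.
A reciprocal-lattice point is **x** = **R O h**, where **O** is the
upper-triangular (Busing–Levy) orthogonalization matrix built from the
reciprocal cell (first row `a*, b*·cos γ*, c*·cos β*`) and
**R** = R(θx)·R(θy)·R(θz) with the θz rotation applied first. The signed
Ewald offset is `r_h = |x + S₀| − 1/λ`: positive outside the sphere,
negative inside. Only `r_h²` enters the partiality model; the sign is kept
for diagnostics (offset histograms are expected to be symmetric about
zero, and the simulator's are).

A pure rotation about the beam axis preserves |**x**| and the *z*
component of **x**, hence every `r_h`; θz therefore has identically zero
gradient on the partiality target and is excluded from refinement (it is
also excluded from the spot-position pass, for parsimony). The detector is
modeled as a single flat panel normal to the beam — no tilt and no
multi-panel metrology, which this method does not refine. Angles are
stored in radians internally; constructors, file formats and reports use
degrees. The per-frame wavelength is a single scalar (the centroid of the
source spectrum); per-shot spectra are out of scope.

## Partiality model

The reflection is a sphere of radius
`r_s(θ, α) = γ₀ + γe·tan θ + √((γy cos α)² + (γx sin α)²)`, with α the
azimuth from the meridional (vertical) detector axis. A still samples an
infinitely thin slice at offset `r_h`. The geometric (area-ratio)
correction `Eoc_area = 1 − r_h²/r_s²` has an undefined derivative where it
reaches zero, so the refinement uses the smooth Lorentzian-derived form

    Eoc = r_s² / (2 r_h² + r_s²).

The two curves agree at `r_h = 0` (both 1) and `|r_h| = r_s/√2` (both ½);
inside the crossing the smooth form lies slightly below the area ratio and
beyond it dominates — its fat tails are what keep reflections near the
observation cutoff differentiable and usable. `Eoc_area` is retained as a
test oracle and diagnostic only. Conversion to the full-volume equivalent
multiplies by `Vc = (4/3) r_s` and divides by `Eoc · G`:

    I_full = Vc · I_obs / (Eoc · G),

with relative variance `(σ_obs/I_obs)² + (ΔG/G)² + (ΔEoc/Eoc)²`
(implemented in absolute form so that near-zero and negative measured
intensities stay well-defined). ΔG comes from the (ΔG₀, ΔB) errors; ΔEoc
sums squared products of the analytic ∂Eoc/∂p chain with the per-parameter
standard errors (diagonal-covariance approximation).

Observations with `Eoc` below a floor (default 0.10, configurable) are
excluded from full-intensity conversion: 1/Eoc amplifies noise without
bound. During refinement `r_s` is floored at 1e-9 Å⁻¹ to keep `Eoc` and
`Vc` finite.

## Polarization

For a beam with horizontal polarized fraction `fx` (default 1.0 —
XFEL beams are nearly fully horizontally polarized; configurable for
synchrotron-like input), a reflection whose plane makes angle ϕ with the
laboratory horizontal is attenuated by

    P = fx (sin²ϕ + cos²ϕ cos²2θ) + fy (cos²ϕ + sin²ϕ cos²2θ),  fy = 1 − fx.

Observed intensities and sigmas are divided by P once, before reference
generation and refinement; a per-frame flag prevents double correction. No
Lorentz factor applies to stills. Both α and ϕ are computed from the
lab-frame detector projection of **x** and folded into [0, π/2], since
only squared trigonometric functions of them appear.

## Refinement protocol

Each frame carries `G₀, B` (group SF), `θx, θy` (CO), `γ₀, γe, γx, γy`
(RR) and the unit cell (UC). Groups are refined one at a time in
*microcycles* (default order SF → CO → RR → UC, three microcycles per
frame) against the current reference set by minimizing the weighted
partiality target `T_pr` with a compact Levenberg–Marquardt solver:
damped normal equations with Marquardt (diagonal) scaling, damping ×10 on
a rejected step and ÷10 on acceptance (so the cost never increases), box
projection for positivity floors, stop after 50 iterations or when the
relative cost change falls below 1e-4, initial damping 1e-3. A singular
normal matrix skips the group for that frame with a diagnostic, leaving
parameters unchanged. Parameter standard errors are the square roots of
the diagonal of `(JᵀJ)⁻¹` scaled by the reduced chi-square at the optimum.

For the geometric groups (CO, UC) a subsequent LM pass minimizes the
spot-position target `T_xy` on the strong spots (I/σ ≥ 5 by default),
using a numerically differentiated Jacobian — the alternation of the two
targets avoids inventing a relative weight for a combined target, which
nothing in the model fixes.

Analytic T_pr gradients use the chain rule through `r_h` (orientation and
cell), `r_s` (the γ group, jointly through `Eoc·Vc⁻¹`), and the scale
function. **Within one LM pass the Bragg angle θ and azimuth α of every
observation are frozen at their values under the current geometry** and
recomputed between passes. This matches the dependency structure of the
analytic derivatives (which differentiate only through `r_h` and `r_s`)
and makes the Jacobian exact for the function actually minimized — the
finite-difference agreement is to ~1e-7 relative. At `γx = γy = 0` the
anisotropy term has a derivative kink; one-sided derivatives (|cos α|,
|sin α|) are used there so the parameters can move off their zero
starting values.

Unit-cell refinement is parametrized in the reciprocal-cell constants
(where the orthogonalization matrix is an explicit differentiable
function), with crystal-system constraint patterns applied in reciprocal
space: 6 free parameters (triclinic), 4 (monoclinic), 3 (orthorhombic),
2 (tetragonal, trigonal/hexagonal in hexagonal axes), 1 (cubic). Tied
parameters share one Jacobian column. Refined cells are converted back to
direct space for reporting, and a projection operator maps arbitrary
six-parameter sets to the nearest constrained cell.

### Macrocycles and convergence

The initial reference set is built by scaling each frame so the mean
intensity of a selected subset (resolution and I/σ cuts) is equal across
frames, Eoc-correcting with the starting parameters, and merging with
experimental-sigma weights; linear scaling only — B is left at zero at
this stage, where resolution-dependent scaling is not yet constrained.
Starting parameters per frame: G₀ = 1, B = 0, γ₀ = rms Ewald offset of the
frame's reflections, γe = 0.002 Å⁻¹ (configurable; stands in for a value
derived from the measured energy spread), γx = γy = 0; orientation and
cell from the frame header (i.e., the indexing result).

Each macrocycle refines every frame through its microcycles, converts to
full intensities, applies reflection selection (resolution, I/σ, Eoc
floor) and whole-frame rejection when the refined cell deviates from the
target cell by more than a configured fraction (default 5%), performs
iterative 3σ outlier rejection per unique reflection (groups of ≤2 are
never clipped), merges with inverse-variance weights, and installs the
merge as the new reference. The loop stops at convergence or after
`max_macrocycles` (default 5).

The stopping rule is deliberately conservative: |ΔCC1/2| < 1e-3 *and*
median per-frame |ΔT_pr|/T_pr < 1e-3 between macrocycles. In practice
CC1/2 stabilizes within three macrocycles while per-frame T_pr keeps
fluctuating at the percent level as the reference is re-merged, so runs
typically use all five macrocycles; the CC1/2 trace is the quantity to
inspect for convergence. Loosen `tpr_convergence` to stop earlier.

### Known degeneracies

γ₀ and γe are strongly correlated: over the Bragg-angle range of a typical
frame, `tan θ` spans a modest interval, so a change in γ₀ is nearly
compensable by γe. Joint refinement of the γ group therefore recovers the
*radius function* well but individual γ values only to ~10% even on
noiseless data. The per-frame B and the reference's overall falloff are
similarly coupled across macrocycles. Neither degeneracy affects merged
intensities; both show up as large parameter spreads, as expected.

## Merging and statistics

Reduced Miller indices come from the space group's reciprocal asymmetric
unit (Friedel mates merged by default; in anomalous mode the Friedel-
negative observations keep a negated index end-to-end and I⁺/I⁻ are
written as separate rows). Merged intensity per unique reflection is the
sigma-weighted mean `⟨I⟩ = Σ WᵢIᵢ/Σ Wᵢ`, `Wᵢ = 1/σᵢ²(I_full)`, with
`σ(⟨I⟩) = (Σ Wᵢ)^(-1/2)`. Merged intensities are left on an arbitrary
scale.

CC1/2 randomly partitions each reflection's observations into two halves
with a seeded RNG (odd counts put the extra observation in half 1),
rejects reflections with fewer than four observations, merges each half
with the same weighted mean, and reports the Pearson correlation of the
half-set means. On synthetic data with signal variance σ_T² and half-mean
noise variance σ_n², the measured CC1/2 matches σ_T²/(σ_T² + σ_n²) within
Monte-Carlo error.

Unique-reflection enumeration (for completeness) uses gemmi with inclusive
resolution bounds and systematic absences removed; an independently coded
brute-force enumeration over an index box with explicit symmetry reduction
agrees exactly across all seven crystal systems. Shell statistics use
equal reciprocal-volume bins (default 10): completeness = measured/possible
unique reflections, multiplicity = observations per measured unique index;
empty shells report zero with a flag.

Three processing schemes are runnable on the same input for paired
comparisons: *averaged* (plain per-index mean of polarization-corrected
partials — no Eoc, no scaling), *mean-scaled partiality corrected* (the
initial-reference procedure as the final merge), and *post-refined* (the
full protocol).

## Synthetic data generator

The generator emulates the pipeline's input contract with known ground
truth. Reference intensities are exponential (acentric Wilson statistics)
around a mean falling as `exp(−2·B_overall·(sinθ/λ)²)` with
B_overall = 15 Å². Orientations are Haar-uniform random rotations.
Per-frame truth: G₀ lognormal (σ = 0.3), B uniform on [0, 8] Å²,
γ₀ ~ N(1.3e-3, 2e-4) Å⁻¹, γe ~ N(2e-3, 3e-4) Å⁻¹, γx, γy half-normal
(8e-5 Å⁻¹) — centered on the values the refinement reports for real
XFEL data — plus 0.1% symmetric cell jitter. A reflection is observed when
`|r_h| ≤ 3·r_s` (at 3·r_s the partiality is 1/19, below any sensible
detection threshold). Observed intensity is `P·G·Eoc·Vc⁻¹·I_true` plus
Gaussian noise with counting-like variance `gain·I + background`
(gain 1, background 25); spot centroids get 0.03 mm Gaussian noise.
Starting models handed to the pipeline are the truth perturbed by seeded
Gaussian errors (defaults: 0.05° orientation, 0.2% cell, 20% scale and γ),
emulating indexing/integration inaccuracies.

Default study conditions are a myoglobin-like hexagonal form (P6,
a = b = 90.8 Å, c = 45.6 Å) at λ = 1.3 Å and 100 frames per data set,
truncated to 20–2.5 Å so that a frame carries ≈1600 spots (comparable to
the real myoglobin images) while the unique set stays at ≈7.6k reflections
with multiplicity ≈15–20 — small enough that the entire protocol, and
twenty seeded repeats of it, run on a laptop.

What the generator does *not* emulate: pixel-level images and integration
(input is already-integrated observations), rugged per-shot SASE spectra,
anisotropic or spherical-cap mosaicity, detector point-spread, and
non-Gaussian error sources. Passing tests therefore demonstrate that the
estimator recovers the parameters of its own forward model and improves
merging under realistic noise — not that the spherical-reflection model is
an adequate description of any particular real crystal.

## Numerical choices

* LM: damping 1e-3 initial, ×10 / ÷10, ≤50 iterations, relative-cost stop
  1e-4, ≤12 rejected sub-steps before giving up an iteration.
* Finite-difference checks use central differences with relative step
  1e-6; the T_xy Jacobian uses the same scheme at run time.
* Frames whose observations have no overlap with the reference (or fewer
  than n_params + 2 usable observations) are flagged unrefinable for that
  group and left unchanged.
* Degenerate cells (non-positive-definite metric) are rejected at
  construction with a diagnostic.
* Ties and degenerate groups: outlier rejection never clips groups of ≤2;
  sd = 0 groups stop iterating immediately.
* The CC1/2 partition, the simulator, and every stochastic step derive
  from explicit integer seeds; identical seeds reproduce outputs
  bit-identically.

## Limitations

* Single-panel, untilted detector; no metrology refinement.
* Wavelength fixed per frame (spectrum centroid); γe absorbs dispersion.
* The spherical-reflection partiality model is deliberately simple;
  anisotropic mosaicity and energy-resolved partiality are out of scope.
* Merged output is on an arbitrary scale; absolute (Wilson) scaling and
  amplitude truncation are left to downstream tools.
* R-factor families are not reported; CC1/2 is the quality metric.
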