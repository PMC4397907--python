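# stillpost

Post-refinement and merging of still-shot (serial / XFEL) crystallographic
diffraction data.

## The problem

An XFEL delivers femtosecond pulses to crystals in random orientations, so
every diffraction image is a *still*: each recorded Bragg spot is a thin
slice through its three-dimensional reflection volume, not a full
integration. Estimating full intensities by brute-force averaging of many
partial observations ("Monte Carlo" merging) needs thousands to millions of
images. `stillpost` instead *post-refines* the parameters that determine
each spot's partiality — per-image scale, crystal orientation, reciprocal
spot size, and unit cell — against an iteratively updated merged reference
set, then corrects every observation to its full-intensity equivalent
before merging. This yields accurate data sets from far fewer images.

## The model

A reflection is a sphere of reciprocal radius *r*<sub>s</sub> centered at
**x** = **R O h**; a still records it at signed normal distance
*r*<sub>h</sub> = |**x** + **S**<sub>0</sub>| − 1/λ from the Ewald sphere.
The observed partial intensity is modeled as

```
I_obs(h) ≈ G · Eoc(h) · Vc(h)⁻¹ · I_full(h)
```

with

* **Ewald-offset correction** `Eoc = r_s² / (2 r_h² + r_s²)` — a smooth
  (Lorentzian-derived) stand-in for the geometric area ratio
  `1 − r_h²/r_s²`, differentiable everywhere including `|r_h| = r_s`;
* **volume correction** `Vc = (4/3) r_s` (sphere volume over central disc);
* **spot radius** `r_s = γ₀ + γe·tanθ + √((γy cosα)² + (γx sinα)²)`
  (mosaicity, spectral dispersion, beam-divergence anisotropy);
* **scale** `G = G₀ · exp(−2B (sinθ/λ)²)`.

Each frame's parameters `G₀, B, θx, θy, γ₀, γe, γx, γy` and its
symmetry-constrained unit cell are refined by Levenberg–Marquardt least
squares with analytic gradients, minimizing

```
T_pr = Σ_h w_h (I_obs,h − G · Eoc_h · Vc_h⁻¹ · I_ref,h)²,   w_h = 1/σ_h²
```

in parameter-group *microcycles* (scale → orientation → spot radius →
cell), with a spot-position target `T_xy = Σ |x_obs − x_calc|²` minimized
in alternation for the geometric groups. After each *macrocycle* the
corrected full intensities are outlier-rejected, merged with
inverse-variance weights and error propagation, and become the new
reference. Data quality is assessed by CC<sub>1/2</sub> (half-data-set
correlation; reflections with fewer than four observations excluded).
Observed intensities are polarization-corrected for the nearly 100%
horizontally polarized beam; no Lorentz factor applies to stills.

A synthetic still-frame generator (Wilson-distributed ground-truth
intensities, uniform random orientations, realistic per-frame parameters,
counting-like noise) makes the whole pipeline testable without
experimental data.

## Worked example

```bash
stillpost simulate --n-frames 100 --seed 2 --out scratch/frames
stillpost postrefine scratch/frames --seed 2 --out scratch/run
stillpost merge-only scratch/frames --mode averaged --seed 2 --out scratch/avg
```

The post-refinement run prints its per-macrocycle trace:

```
 macrocycle  mean_t_pr_start  mean_t_pr_end  mean_t_xy_start  mean_t_xy_end  cc_half  n_frames_merged
          1     2.648414e+07   1.060219e+06         9.596649       7.987414 0.999510              100
          2     9.448273e+04   2.037050e+04         3.081816       2.950959 0.999968              100
          3     9.575919e+03   5.108151e+03         3.042959       2.950959 0.999982              100
          4     7.286478e+03   4.405739e+03         3.040892       2.950959 0.999984              100
          5     7.121555e+03   4.346819e+03         3.040636       2.950959 0.999984              100
```

`T_pr` (the partiality-model target) drops by four orders of magnitude as
the per-frame models converge; `T_xy` (mean spot-position residual, mm²)
settles at the simulated centroid-noise floor; CC<sub>1/2</sub> climbs to
0.9999 within three macrocycles. The same 100 frames merged by plain
averaging print `averaged: 7574 unique reflections, CC1/2 = 0.8759`, and
the acceptance script below reports the post-refined merge correlating
with the generator's ground-truth intensities at r ≈ 0.994 versus ≈ 0.945
for the averaged merge — the improvement post-refinement exists to
deliver.

Outputs: a merged reflection table (TSV and mmCIF `_refln` loop), a
per-shell statistics CSV (completeness, multiplicity, CC<sub>1/2</sub>), a
cycle-trace CSV, and a parameter summary (mean ± sd of the refined
per-frame parameters).

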