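# Methods

## Model

Two volume-fraction fields live on a regular anisotropic voxel grid
(defaults 0.25 × 0.25 × 1.0 mm, matching small-animal MRI): the tumor cell
volume fraction φ_T and the blood volume fraction φ_V, both in [0, 1].
Their coupled dynamics combine:

* **Cross-diffusion.** Each species' flux is reduced by the space the
  other occupies: the tumor flux is
  D_T[(1 − φ_V/θ_TV)∇(φ_T/θ_TV) + (φ_T/θ_TV)∇(φ_V/θ_TV)], and the
  vascular flux mirrors it with the roles swapped. θ_TV = θ_T + θ_V is the
  summed carrying capacity.
* **Vascularity-driven carrying capacity.** θ_T ramps linearly from θ_min
  (avascular) to θ_max as φ_V rises to a calibrated threshold φ_V,thresh,
  and saturates above it. θ_min, θ_max and the vascular capacity θ_V are
  assigned from the lowest/highest volume fractions observed in the
  calibration visits (θ_max is then refined as a calibrated parameter).
* **Distance-weighted angiogenesis.** The vascular logistic growth is
  multiplied by the normalized distance-to-rim d (1 at the tumor boundary,
  0 at maximal depth) and the untreated vascular death by (1 − d):
  vessels proliferate at the rim and regress in the core.
* **Mechanical coupling.** Tumor expansion loads the tissue through the
  linear-elastic equilibrium equation
  ∇·G∇u + ∇[G/(1−2ν)](∇·u) − λ₂∇φ_T = 0 with slip (zero normal
  displacement, free tangential motion) at the brain boundary; the von
  Mises stress of the solution damps both diffusivities,
  D = D₀ exp(−λ₁σ_vm). Defaults: G = 2.1 kPa (white matter), 2.6 kPa
  (gray), ν = 0.45, λ₁ = 0.25 kPa⁻¹, λ₂ = 1 kPa — G and ν are configurable
  because the underlying literature values depend on the tissue
  preparation; λ₁'s units make λ₁σ_vm dimensionless with stress in kPa.

## Radiotherapy response family

A delivered fraction at the start of a treatment day acts through one of
three mechanisms, each modulated voxelwise by a coupling field C ∈ (0, 1]:

| mechanism | effect |
|---|---|
| RTM1 | instantaneous kill: φ ← φ·(C·SF) |
| RTM2 | RTM1 kill + cumulative proliferation slowdown k_p = k_{p,0}·C·SF^n |
| RTM3 | slowdown + delayed death rate k_d = k_{d,0}(1 − C·SF^n), no instantaneous kill |

C1 = φ/θ (densely packed, slowly cycling regions are radioresistant),
C2 = exp(−α₁φ_V/θ_V) (well-perfused, oxygenated regions respond more),
C3 = 1. The same SF and formulas apply to the vasculature (C1's vascular
analog uses φ_V/θ_V; under RTM3 the vascular RT death rate reuses k_{d,V}
as its base rate — the family calibrates a single SF). Effective rates
apply only after the first delivered fraction; before any RT the untreated
rates hold. With the proliferation mode (global scalar vs voxel-node
field) this gives 18 members, ordered with the local-kp block first and
the response mechanism as the outer loop (members 7–9 of each block are
the delayed-death models).

## Numerics

Fully explicit forward-Euler integration (default dt = 0.01 days) with
conservative central differences: face-centered fluxes with
harmonic-mean diffusivity and arithmetic-mean occupancy coefficients, and
zero flux across faces leaving the brain mask, so the summed
cross-diffusion right-hand side telescopes to zero exactly (verified to
1e-10). A stability guard fails when 2·dt·D_max·Σ 1/h² > 1 and halves dt
until stable. Fields are clipped to [0, 1] after each step; overshoot
beyond 1e-6 emits one warning per run (at dt = 0.05 overshoots of order
1e-3 are routine and benign). Refresh cadences: carrying capacity every
step; distance field every 25 steps and at output/event boundaries, from
the thresholded model tumor extent (φ_T ≥ 0.5·θ_min by default); the
elasticity solve when max|Δφ_T| since the last solve exceeds 0.01 and at
least daily. The elasticity operator is assembled once per grid (7-point
stencil, harmonic G at tissue interfaces, antisymmetric ghosts for the
face-normal displacement component), LU-factorized, and reused; it is
skipped entirely when λ₁ = 0 since stress then has no observable effect.

On days where imaging and RT coincide the snapshot is taken before the
fraction (pre-fraction morning imaging). Dose magnitude never enters the
equations directly — its effect is absorbed by the calibrated SF.

## Calibration and uncertainty

The residual sum of squares compares the forward solve (initialized from
the first fitted visit's measured maps) with the measured φ_T and φ_V at
every later fitted visit, **over each visit's own measured tumor mask**.
Measured values only exist inside the imaging ROI, and restricting to it
keeps the residual noise homoscedastic, which the interval construction
assumes. Scenario 1 fits all visits; scenario 2 fits the first ⌈V/2⌉ and
forecasts the rest.

Optimization: simulated annealing over the bounded box (geometric cooling,
defaults T₀ = 1, ratio 0.95, 50 proposals per temperature, stop at
T < 1e-3; acceptance scaled by the initial RSS) followed by a bounded
trust-region least-squares polish with numerical Jacobian (relative RSS
tolerance 1e-6 by default). Bounds: rates 1e-3–10 /day, diffusivities
1e-4–0.2 mm²/day, SF 0.5–1, φ_V,thresh (0, θ_V), θ_max [θ_min, 1],
α₁ 0–10. Parameters a member does not use are excluded from the vector
and from k.

Local-kp members calibrate node values jointly with the global scalars:
each axial slice's tumor bounding box is tiled into 3×3 in-plane blocks
whose corners and center are nodes (≈5/9 of tumor voxels); every other
voxel takes its nearest node's value (mm metric, ties to the lowest linear
index), which doubles as a spatial regularizer.

95% intervals are Wald-type: estimate ± t(0.975, n−k)·SE with the
covariance (JᵀJ)⁻¹·RSS/(n−k). Two numerical choices matter here. First,
the trajectory depends on the parameters with small kinks (voxels crossing
the distance-refresh threshold, clipping), so the CI Jacobian is computed
by central differences at a relative step of 1e-3 — machine-scale steps
can land on a kink and corrupt a column. Second, the default least-squares
tolerance stops several SEs short of the optimum when n is large (tens of
thousands of residuals); workflows that consume the intervals
quantitatively should tighten `lm_ftol`/`lm_xtol`. Forecast ensembles draw
each parameter uniformly within its 95% interval (truncated to bounds);
the interval-sampling distribution is not specified more precisely by the
estimation theory, and uniform is the conservative choice.

Known limitation: when the noisy first-visit map initializes the forward
solve, its measurement error propagates through the dynamics
(errors-in-variables) and the Wald intervals — which model only the
fitted-visit noise — undercover. The coverage check in the acceptance
suite therefore initializes from the ground-truth day-0 state.

## Selection, ensemble, metrics

AICc = 2k + n·ln(RSS/n) + 2k(k+1)/(n−k−1); weights
w_i = exp(−δ_i/2)/Σ exp(−δ_j/2). The ensemble field averages the 100
parameter samples within each member and combines members by weight (the
per-sample sum is divided by the sample count; an unnormalized sum would
inflate the ensemble 100-fold and is inconsistent with forecasts plotted
on the measurement scale). The selected member is the lowest AICc, ties
broken by fewer parameters, then family order.

Metrics per parameter set and visit, then averaged over visits: percent
tumor-volume error (model volume = voxels with φ_T ≥ threshold, default
0.5·θ_min — a continuous field needs an explicit extent definition),
Dice overlap of model and measured masks, and Pearson/Lin-concordance
correlation of both fields over the union of measured and model masks.
Selected-vs-ensemble differences use the two-sided Wilcoxon rank-sum
(Mann–Whitney) test; the source analysis reports only "p < 0.05" without
naming a test, and the rank-sum test is the standard choice for paired
box-plot populations of this kind.

## Synthetic cohort

The animal MRI cohort behind the method is not publicly deposited, so the
generator manufactures datasets with the structure the analysis assumes:

* Gaussian-profile lesion, peak φ_T = 0.6, 2σ radius 1 mm, centered on a
  voxel; vascular background 0.02 with a rim elevation of 0.08 — a
  compact, well-circumscribed, peripherally vascularized lesion like the
  glioma line the experimental cohort used.
* Truth parameters near the reported selected-model estimates
  (k_{p,T} = 1.40/day, k_{d,T} = 0.11/day, D_T = 2.58e-2 mm²/day,
  D_V = 3.10e-2 mm²/day, k_{p,V} = 0.82/day, k_{d,V} = 0.29/day,
  φ_V,thresh = 0.03, θ_max = 0.94, α₁ = 4). Diffusivity scale note: the
  printed unit of the source estimates ("10⁴ m²/day") is physically
  impossible and is read as 10⁴ µm²/day = 1e-2 mm²/day.
* The seven cohort imaging/treatment schedules as presets
  (`animal1`..`animal7`); the daily dose maps onto SF presets 0.97 (2 Gy)
  and 0.90 (4 Gy), mirroring the observed dose dependence.
* Gaussian noise at SNR 20. The noise SD is acquisition-referenced: fixed
  once from the day-0 in-tumor mean (MRI thermal noise does not scale with
  tumor signal), and applied only inside the per-visit tumor ROI, where
  the volume-fraction maps are actually measured. Values are clipped to
  [0, 1]. Tumor masks are thresholded from the noiseless truth.

What a green test on this world does establish: the solver integrates the
stated equations correctly (oracle equivalence, conservation, analytic
limits), the measurement models invert their generators, the optimizer
recovers generating parameters, and AICc weighting identifies the
generating member. What it does not establish: behavior under registration
error, partial-volume and coil-bias effects, Rician (not Gaussian) MR
noise, infiltrative (non-circumscribed) tumor margins, or model
misspecification against real biology — the generating model and the
fitted model share the same equations by construction.

## Defaults worth knowing

| parameter | default | units | why |
|---|---|---|---|
| dt | 0.01 | day | explicit-scheme default; stability bound allows ~0.5 at the cohort diffusivities |
| voxel spacing | 0.25, 0.25, 1.0 | mm | small-animal MRI geometry |
| λ₁ | 0.25 | 1/kPa | assigned coupling constant |
| λ₂ | 1.0 | kPa | assigned coupling constant |
| G (white/gray) | 2.1 / 2.6 | kPa | literature-scale brain shear moduli, configurable |
| ν | 0.45 | – | nearly incompressible tissue |
| tumor-extent threshold | 0.5·θ_min | – | smallest observable cellularity, halved for margin |
| distance refresh | 25 steps | – | d varies on the tissue scale, not the step scale |
| SA schedule | T₀=1, ×0.95, 50/temp, stop 1e-3 | – | global phase default; tests use shortened schedules for budget |
| ensemble samples | 100 | – | CI-sampled forward runs per member |
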