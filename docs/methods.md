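# Methods

`hypersar` implements a two-stage learned surrogate for specific absorption
rate (SAR) prediction in phased-array brain hyperthermia, together with the
physics needed to generate and evaluate synthetic study data: path-difference
phase steering, an analytic electromagnetic forward model, a cross-attention
prediction network, a 1-D U-Net enhancement stage, and a point-cloud metric
suite including the gamma index. This note records the models, the defaults,
and the design decisions taken where the problem was genuinely open.

## Applicator and phase steering

The applicator is a cylindrical array of three rings of 24 half-wave dipole
antennas (72 total) of radius a = 13 cm, ring gap g = 4.2 cm, operating at
915 MHz. The two external rings share one phase set, so a steering
configuration has 48 independent phases.

Phases are set by the path-difference method. With antenna angles
θ_n = 2(n−1)π/N, the in-plane distance from central-ring antenna n to a
focus (x0, y0) is R_in[n], and the external-ring distance adds the ring gap
in quadrature, R_en² = R_in² + g². Phases are proportional to the extra
path relative to the closest central-ring antenna, in brain wavelengths:

    ψ_in[n] = (2π/λ_brain)(R_in[n] − min_m R_in[m])
    ψ_en[n] = (2π/λ_brain)(R_en[n] − min_m R_in[m])

All waves launched with these phase advances arrive in phase at the in-plane
focus. The formulas are two-dimensional: the focus z-coordinate does not
enter, and z-steering exists in the study design only through the dataset's
z ∈ {−2, 0, +2} cm planes. Phases are stored as unwrapped non-negative
radians (the minimum inner phase is exactly zero) and reduced modulo 2π only
where they enter a complex exponential.

Tissue wavelengths come from the lossy-dielectric dispersion relation

    β = (ω/c) sqrt(ε_r (sqrt(1 + tan²δ) + 1) / 2),  tan δ = σ/(ω ε0 ε_r),
    λ = 2π/β,

with c = 2.9979×10⁸ m/s and ε0 = 8.854×10⁻¹² F/m; the attenuation constant α
uses the same relation with (… − 1) under the root, so both wave parameters
share a single source of truth. The shipped registry (`data/tissues.tsv`)
holds density, relative permittivity and conductivity at 915 MHz for fat,
bone, muscle, white matter, gray matter, their average, air and deionised
water; λ is always derived, never stored.

## Head phantom

The phantom is a procedural stand-in for an anatomical model: a point cloud
sampled uniformly in nested ellipsoids — brain (default semi-axes 7, 7,
6 cm) wrapped in muscle (0.5 cm), bone (0.7 cm) and fat (0.5 cm) shells,
with a spherical intranasal-air pocket near the front. It makes no claim of
anatomical fidelity; its role is a stratified dielectric medium whose brain
compartment contains the steering grid. A homogeneous all-brain sphere
(radius 9 cm) is used where steering fidelity itself is under test, since it
removes shell refraction-free attenuation differences from the comparison.

Points are stored in Morton (Z-order) space-filling-curve order. This is the
package's canonical signal order: any treatment of a field as a 1-D array
(SSIM windows, the enhancement U-Net) then operates on spatially coherent
neighbourhoods. With a random order those operations would act on an
arbitrary permutation and carry no spatial meaning.

Each point's representative volume is (bounding-box volume)/N, which
conserves the total volume and makes the power normalisation reproducible.

## Forward surrogate

Ground-truth SAR is generated by coherent superposition of attenuated
spherical waves:

    E(r) = Σ_k A_k e^{−α(r) d_k} e^{−i(β(r) d_k − ψ_k)} / d_k,
    SAR(r) = σ(r) |E(r)|² / (2 ρ(r)),

with d_k the 3-D distance to antenna k, (α, β) evaluated from the tissue at
the observation point, uniform unit amplitudes, and distances floored at
0.1 cm to guard the antenna singularity (antennas lie outside any valid
phantom). The field is rescaled globally so the absorbed power
Σ_i ρ_i SAR_i V_i equals the stated input power (100 W by default),
interpreted as absorbed rather than port power.

This single-scatter model ignores reflection and refraction at layer
boundaries. It is not an electromagnetic solver and does not approximate
one quantitatively; what it preserves is the interference structure —
constructive focus at the steering target, bright periphery near the
antennas, dependence on tissue constants — which is what makes the learning
task meaningful. Steering fidelity is verified as a property: over the
36-point axial steering grid on the homogeneous phantom at N = 5000, the
located focus lies within 2 cm of the target.

### Focus locator

`focus_location` returns the SAR-weighted centroid of the top 5% of
brain-compartment points, restricted to within a 2.5 cm capture radius of
the hottest brain point. The restriction is load-bearing: steered fields
also carry a bright peripheral rim and secondary lobes, and a centroid over
a global top fraction mixes those clusters and can land between them
(measured errors up to ~4.8 cm for global fractions 0.001–0.05, while the
hottest brain point stays within ~1.3 cm of the target). Smoothed-anchor
variants were measured and rejected: under a ball kernel the rim integrates
more power than the focus.

## Study design and datasets

The steering grid places targets at 2 cm increments in [−4, 6] cm along x
and y, on planes z ∈ {−2, 0, +2} cm, crossed with three brain-tissue
variants (white matter, gray matter, their average) and filtered to targets
inside the brain compartment. The full product is 324 configurations before
filtering; a dataset draws `n_samples` of them (201 by default, matching
the study size it emulates — the selection rule behind that count is not
derivable, so the draw is seed-deterministic) and splits them 160/21/20
into train/validation/test. A 5-fold splitter is provided but the single
split is the default workflow.

Each sample holds the brain-mesh inputs ℬ (N_b × 6: coordinates plus ε_r,
σ, ρ), the 48 phases, and the surrogate field. The learning task is defined
on the brain compartment: the surrogate simulates the full stratified
phantom, but inputs and regression targets are the brain rows. Coordinates
are affinely normalised to [0, 1] per axis over the brain points.

## Prediction network

Two embedding streams produce point features F_p (N×128) and antenna
features F_a (48×128). Four chained cross-attention blocks compute

    Q = F_p W_Q,  K = F_a W_K,  V = F_a W_V,
    Att = softmax(Q Kᵀ / √d_k),  Z = Att V,  H = MLP(Norm(Z)) + F_p,

each block feeding H to the next as the new point stream while reusing F_a
(single-head, d_k = 128). Queries come from the point stream and keys/values
from the antenna stream; this is the only assignment under which the
residual with F_p is well-formed. After the last block a feature-wise max
over points yields a global descriptor, broadcast back and concatenated
with all four block outputs (640 features per point); three residual blocks
(512, 256, 128 — each three fully connected layers with layer
normalisation and a width-matching linear skip) and a linear head produce
scalar SAR per point. The max pool is the only cross-point coupling, so the
network is exactly equivariant under point permutations.

Design resolutions the architecture required:

* **Phase representation.** Phases enter as (cos ψ, sin ψ): the field
  depends on a phase only through e^{iψ}, and unwrapped path-difference
  values alias physically identical settings.
* **Per-antenna embedding weights.** A shared per-row embedding of phase
  features makes antennas with equal phases indistinguishable, yet which
  antenna carries a phase determines the field. Each of the 48 phase slots
  therefore owns its embedding weights; this is the embedding itself, not
  an added positional code.
* **Input/output scaling.** Property columns are scaled by fixed constants
  (ε_r/50, σ/1, ρ/1000) so every feature is O(1); the head output is
  multiplied by a characteristic 50 W/kg. Both are pure
  reparameterisations that let a fan-based initialisation start at the
  right magnitudes.
* **Sinusoidal point embedding.** The first point-embedding activation is
  sin with frequency scale 10 (configurable; relu available). SAR is an
  interference pattern — an oscillatory function of position with several
  periods across the head — and a sinusoidal first layer provides that
  spectral basis directly instead of asking a ReLU stack to assemble it.

## Enhancement network

A 1-D U-Net refines the predicted brain signal: four encoder blocks (two
same-padded width-3 convolutions, 2× max-pool) with channels 32→256, a
bottleneck, four decoder blocks with nearest-neighbour upsampling and skip
concatenation, and a 1×1 head. Signals are padded to a multiple of 16 and
cropped on output. The input is scaled by 1/100; the head is
zero-initialised and its output, in units of 30 W/kg (the magnitude of the
larger prediction errors), is added to the input. An untrained enhancer is
therefore exactly the identity, and training learns a correction.

## Losses

* **Prediction stage:** α₁·(1 − SSIM) + β₁·MSE with α₁ = β₁ = 1. MSE is the
  mean (not sum) of squared errors so the weights balance independently of
  N. SSIM treats the field as a 1-D signal in canonical order with a
  sliding Gaussian window (length 11, σ = 1.5), population statistics, and
  constants C1 = (0.01 L)², C2 = (0.03 L)² scaled to the data range L
  (truth max − min by default; signals shorter than the window fall back to
  one full-length uniform window). The same definition serves training
  (differentiable) and evaluation (numpy), and matches scikit-image's
  Gaussian-weighted SSIM to machine precision.
* **Enhancement stage:** a 30 W/kg threshold loss — mean of |P − P*| where
  the ground truth is below the threshold and (P − P*)² where it is at or
  above. The partition depends only on the truth, so the loss is continuous
  in the prediction.

## Training

Adam with a step schedule: the learning rate is reduced by 0.2 every 100
epochs over 500 epochs at the full scale (initial 1e-4); batch size 4.
Networks train in float32 (CPU training here is memory-bandwidth-bound and
single precision is ample for SAR regression); all physics, metrics and
tests run in float64. Every random element — phantom sampling, design draw,
split membership, initialisation, shuffling — derives from one experiment
seed, and runs are reproducible given the seed and thread configuration
(bit-exactness across BLAS thread counts is not guaranteed).

The best-validation checkpoint is restored after training. The selection
metric is the stage's own loss for the prediction stage and the validation
RMSE for the enhancement stage, with the initial state always a candidate.
For the zero-initialised residual enhancer the initial state is the
identity, which yields an artifact-level guarantee: the enhancement stage
never ships a model that degrades validated RMSE — if no epoch validates as
an improvement, enhancement is a no-op rather than a liability.

## Evaluation metrics

On a region mask (whole brain, or the target region — brain points within a
configurable 1.5 cm of the steering target): MAE, RMSE, relative RMSE
(RMSE / masked truth maximum), PSNR = 20 log10(max truth / RMSE) (+∞ for
identical fields), SSIM as above, and the gamma index

    γ(s) = min_{s'} sqrt( (|r_s − r_{s'}|/Δd_crit)² + (ΔD/ΔD_crit)² ),

with truth as the reference (the comparison is directional), the dose
difference normalised globally to the masked truth maximum, the spatial
search capped at 3 Δd_crit (points beyond it cannot yield γ ≤ 3), and
γ ≤ 1 passing with a 1e-9 tolerance absorbing round-off at exact criterion
boundaries. Evaluation is nearest-point only — no sub-point interpolation —
which is the honest choice on a point cloud but makes pass rates
resolution-dependent; reported criteria are 2%/2 mm, 3%/3 mm, 3%/5 mm,
whose pass rates are provably monotone in that order.

## Scaled-down study conditions

The default `ExperimentConfig` is the package's reduced-scale experiment,
sized for a single CPU: a 500-point layered phantom, the axial (z = 0)
steering grid crossed with the three tissue variants, 52 samples split
40/6/6, 50 epochs per stage, batch 4, learning rate 1e-3. The z = 0 grid is
used because the steering formulas are two-dimensional: for z ≠ 0 targets
the surrogate's true focus sits in the z = 0 plane by construction, and a
focus-distance measurement would measure the design rather than the model.
The learning rate is larger than the full-scale 1e-4 because the run takes
~500 optimiser steps rather than ~20,000.

What the reduced run demonstrates — and what it does not: training is
stable and reduces both stages' losses several-fold; the enhancement stage
correctly falls back to the identity when no validated improvement exists;
the full pipeline (generation → two-stage training → masked metrics and
gamma) runs end to end. It does **not** reach held-out steering
generalisation: with 40 training samples and ≤50 epochs the prediction
network learns the steering-independent structure (mean field and
peripheral rim) but not the target-dependent focus placement (held-out
residual correlation ≈ 0). Diagnostics locate the barrier on both axes:
at 40 samples, extending to 200 epochs overfits (validation loss rises);
at 120 samples and 50 epochs there is no overfitting but the model is
under-trained. Reaching focus generalisation requires roughly the
full-scale budget (160 samples, 500 epochs), which is orders of magnitude
beyond a desk-scale CPU run. The repository states this openly rather than
relaxing the check that encodes it.

## Known limitations

* The surrogate is single-scatter: no reflections, refraction, standing
  waves, antenna feed models, or water-bolus coupling. Networks trained on
  it are validated against it self-consistently, not against a field
  solver.
* The phantom is parametric, single-anatomy, and contains no CSF
  compartment.
* Amplitudes are uniform; only phases steer.
* SSIM and the U-Net depend on the canonical (Morton) point order; metrics
  on a different ordering are not comparable.
* The deionised-water wavelength printed in the source tissue table (3.6 cm)
  is not reproduced by the standard dispersion relation used here
  (≈3.7 cm); water is excluded from the wavelength oracle set.
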