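# Methods

## Mechanical model

A percussed tooth is reduced to three lumped degrees of freedom — enamel,
dentin, pulp/root — in a grounded spring–damper chain,

    M ẍ + C ẋ + K x = F(t),

with M = diag(m₁, m₂, m₃) and tridiagonal symmetric K and C. This is a
deliberate reduced-order abstraction: it captures how depth-dependent
changes in stiffness, mass and damping move the natural frequencies and
decay rates of the transient, and nothing else. Geometry, anisotropy,
the periodontal ligament, bone coupling and nonlinear contact are all
outside the model.

Baseline (healthy) parameters:

| layer | m (arb.) | k (N/m) | c (Ns/m) |
|---|---|---|---|
| enamel | 1.0 | 1.0e7 | 50 |
| dentin | 1.5 | 5.0e6 | 150 |
| pulp/root | 2.0 | 2.0e7 | 300 |

These are illustrative values chosen for a stable, lightly damped
response (enamel damping ratio ≈ 0.8%), not measured tissue constants.
Note the pulp/root stiffness exceeds enamel's even though real pulp is
compliant; the values are kept as listed because every experiment
perturbs them anyway and the study's question is about *relative*
depth-dependent degradation, not absolute biomechanics. Masses and
forces carry arbitrary units; nothing downstream depends on unit
conventions because the signal is amplitude-normalized.

The percussion input is a rectangular impulse on the enamel mass only:
F(t) = (F₀, 0, 0)ᵀ for 0 ≤ t ≤ τ (closed upper bound), with F₀ = 1 and
τ = 0.1 ms fixed. Excitation variability (operator force, contact time)
is intentionally not modeled.

## Solvers

Output is x₁(t) (enamel displacement) on the half-open uniform grid
t_n = n/44100 s, n = 0…2204 (50 ms, exactly 2205 samples). Velocities
are computed but internal.

Two integration paths exist and are cross-verified:

* **RK45** on the 6-state first-order form, split into a forced segment
  [0, τ] with max step τ/4 (an adaptive solver can otherwise step over a
  4.4-sample impulse) and a free-decay segment (τ, T]. Tolerances are
  rtol = 1e-10, atol = 1e-13: the system rings for ~30 periods in the
  window, and looser tolerances let phase error accumulate past the
  1e-6 relative agreement demanded of the solver pair.
* **Exact discretization**: the system is LTI with piecewise-constant
  forcing, so matrix-exponential propagation with τ inserted as a
  breakpoint reproduces the continuous solution at the sample instants
  to machine precision. Forced steps use the standard augmented-matrix
  zero-order-hold construction.

The two agree to ~1e-7 relative sup-norm across wide random parameter
draws. Bulk dataset generation defaults to the exact propagator (about
25× faster); the choice is configurable and has no measurable effect on
features or classification, since the solver discrepancy sits five
orders of magnitude below the measurement-noise floor.

## Caries model

Severity α scales the affected layer's parameters:
k → k(1 − β_k α), c → c(1 + β_c α), m → m(1 − β_m α). Enamel caries:
layer 1, β = (0.6, 0.8, 0.3), α ~ U(0.2, 0.5). Dentin caries: layer 2,
β = (0.8, 1.0, 0.3), α ~ U(0.4, 0.8). Healthy teeth receive no
modification. Unaffected layers are left unchanged. The uniform law for
α (the ranges are stated, the distribution was an open choice) is the
minimal-assumption option on a bounded range.

Inter-tooth variability multiplies each of the nine baseline parameters
by an independent U(1 − p, 1 + p) factor, p = 0.05 at baseline, 0.10 in
the robustness sweep. Uniform factors were chosen because "±p" phrasing
implies bounded support; the distributional test in the suite is stated
against exactly this law. Pipeline order is perturb-then-lesion:
variability represents the individual tooth's baseline, degradation acts
on that individual. Healthy samples are perturbed too.

A structural consequence worth knowing: stiffness loss outweighs mass
loss (β_k > β_m), so lesions lower the dominant response frequency —
dentin lesions by ~20% on average — which is the physical signal the
classifier exploits. Class separability is partly built in by the
shifted α ranges; the null-effect control (all β = 0 → chance accuracy)
confirms the classifier learns only what the degradation injects.

## Signal chain

s(t) = x₁(t) / max|x₁(t)| per sample, then additive i.i.d. N(0, σ²)
noise, σ = 0.01 baseline, with no renormalization. The normalization
denominator uses the *absolute* maximum (a signed max would make the
output polarity-dependent). Because the noisy signal can exceed [−1, 1],
WAVs are written as 32-bit IEEE float, which also makes the persisted
form lossless at float32 precision; features are computed from the
in-memory float64 arrays, with WAV as the equivalent persisted artifact.
Both operations are per-sample only — no dataset statistics are shared,
so train/test splits cannot leak through preprocessing.

## Features

13 MFCCs per frame: Hann window (512 samples = FFT size, hop 256, full
frames only → 7 frames per trace), power spectrum, 40 triangular mel
filters (HTK scale mel = 2595·log10(1 + f/700), fmin = 0,
fmax = Nyquist = 22.05 kHz, unit-peak triangles), natural log with floor
1e-10, orthonormal DCT-II, coefficients 0–12 retained, then the
arithmetic mean over frames. No pre-emphasis, liftering or deltas.
Window/hop/mel-variant were open choices; the ones above are the
simplest standard chain consistent with the stated sizes, and the
classification tolerances absorb the residual convention sensitivity.
Amplitude scaling of the signal shifts only coefficient 0 (by a
constant), so the feature vector is nearly amplitude-invariant on top of
the explicit normalization.

## Dataset generation

Default condition: 500 samples per class (1500 total), σ = 0.01, ±5%
variability. Each sample is an independent draw of everything —
per-sample RNG streams come from SeedSequence([master_seed, index]), so
generation is reproducible and stream-independent across samples, and no
parameter set is reused. Metadata (sample id, class, lesion type, α, σ,
variability, stream index, WAV path) and the feature table are persisted
as CSV next to the WAVs, with a YAML config snapshot. Healthy rows
record lesion type "none" and α = 0.

## Classification protocol

Random forest, 200 trees, Gini impurity, unlimited depth, bootstrap,
√13 ≈ 3 features per split — conventional defaults, fixed a priori, no
tuning. Stratified 80/20 split of the 1500 samples (300 test, 100 per
class). Each experimental condition is repeated with five master seeds;
each seed regenerates its dataset from scratch and drives the split and
forest initialization. Reported metrics: accuracy and macro-F1 as
mean ± SD (sample SD, ddof = 1) plus per-class precision/recall/F1,
confusion matrix and impurity-based feature importances.

Robustness grid: (σ, p) ∈ {0.01, 0.03} × {0.05, 0.10} minus the unused
corner — baseline, more-noise, more-variability, both.

## Numerical and degenerate-input choices

* Impulse boundary t = τ is inside the forced interval (closed bound).
* All-zero traces raise rather than normalize (division by zero).
* Mel log uses a 1e-10 floor, so silent frames produce a finite constant
  vector whose DCT has only a DC term.
* Dampings may be zero (undamped limit used by the energy-conservation
  oracle); masses and stiffnesses must be strictly positive.
* Sample SDs over seed repeats use ddof = 1; with a single seed the SD
  is reported as 0 and the CLI warns.

## What the synthetic data does and does not show

The generator *is* the study design: it emulates structured
depth-dependent mechanical degradation plus bounded parameter
variability and white measurement noise. It does not emulate sensor
transfer functions, acoustic radiation, nonstationary clinical noise,
excitation variability, restorations, cracks, periodontal support or any
other real-world confounder. Passing results therefore demonstrate that
the imposed structural perturbations are separable in MFCC space under
controlled conditions — an upper bound on, not an estimate of, clinical
performance.

## Problem sizes

The test suite runs most checks at reduced scale (5–100 samples per
class) to keep feedback fast, and the end-to-end checks plus
`scripts/acceptance.py` at the full scale above (1500-sample datasets,
five seeds, four conditions ≈ 30 000 simulations), which completes in a
few minutes thanks to the exact propagator.

## Known limitations

* Run-to-run accuracy SD over five seeds is dominated by binomial
  counting noise at 300 test samples (≈0.017 at 90% accuracy), and a
  five-run SD estimate itself carries ~35% relative uncertainty, so the
  stability summary fluctuates noticeably with the seed set.
* The three-class structure is partly encoded in the non-overlapping
  severity/coefficient design; results quantify separability of that
  imposed structure, not clinical detectability.
* Single tooth archetype: one baseline parameter set, perturbed, rather
  than a population of tooth types.
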