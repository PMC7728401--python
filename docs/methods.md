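# Methods

## Model

`cilva` models a population of N simultaneously imaged neurons whose
fluorescence traces f_n(t) (ΔF/F, frames t = 0..T−1) reflect a mixture of
stimulus-evoked activity and structured spontaneous activity shared across
sub-populations. The observation model is

    f_n(t) = α_n c_n(t) + β_n + ε_n(t),        ε_n(t) ~ N(0, σ_n²),

with the calcium concentration c_n the causal convolution of a
difference-of-exponentials indicator kernel with a non-negative intensity,

    c_n(t) = Σ_{τ≤t} k(t−τ) λ_n(τ),
    k(t)   = exp(−t/τ_d) − exp(−t/τ_r),          0 < τ_r < τ_d,
    λ_n(t) = w_nᵀ s(t) + b_nᵀ x(t).

s(t) ∈ {0,1}^K is a 1-of-K stimulus indicator (optionally expanded with
time-shifted copies for temporally extended responses), w_n ≥ 0 the neuron's
stimulus filter, x(t) ≥ 0 the activity of L shared latent factors and
b_n ≥ 0 the neuron's factor couplings. An exponential prior with mean γ,
p(x_l(t)) ∝ exp(−x_l(t)/γ), sparsifies the latent activity; because stimulus
times are fixed while factors are free, the prior is what makes the
evoked/spontaneous attribution identifiable in practice. All parameters and
latents are constrained non-negative, including the baselines β_n.

Assumptions worth keeping in mind: the kernel time constants are global and
stationary; evoked responses are additive impulses at onset frames (no
multiplicative trial-to-trial gain); latent factors have no temporal
dynamics prior — sparse independent events, not a smooth process; and the
noise is homoscedastic white Gaussian per neuron.

### Key parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| τ_r, τ_d | kernel rise/decay time constants | frames | 5.68, 11.5 (GCaMP6s-like; ÷fs for seconds) |
| L | number of latent factors | – | user-chosen via the correlation-vs-L elbow |
| γ | exponential prior mean on latent activity | intensity units | selected on held-out data over {0.2, …, 2.0} |
| σ_n² | imaging-noise variance | (ΔF/F)² | estimated from the PSD, then frozen |

## Inference

The exponential prior is non-conjugate, so instead of EM the fit alternates
two bounded MAP maximizations of the penalized log-joint ("pseudo-EM"):
over the latents X with parameters fixed, then over θ = (α, β, W, B) with X
fixed. Both subproblems are solved with L-BFGS-B under box constraints
≥ 0 using analytic gradients, warm-started from the previous iterate, which
makes the objective non-decreasing across alternations. Subproblems are
capped at 500 iterations with projected-gradient tolerance 1e−8; the outer
loop stops when the relative change of the penalized log-joint over one full
alternation falls below 1e−6, or at 100 alternations. The gradients are the
exact derivatives of the stated objective; in particular ∂ℓ/∂α_n =
(1/σ_n²) Σ_t E_n(t)(k∗λ_n)(t) with no leading α_n factor — every gradient
block is validated against central finite differences in the test suite.
The log-joint retains the γ-dependent prior normalizer (−ln γ per latent
entry): it is constant during a single fit but not across the γ grid, and
dropping it would corrupt model selection.

Initialization: stimulus filters from per-neuron non-negative least squares
(NNLS) of the trace onto kernel-convolved stimulus regressors; α_n ~
N(1, 10⁻²) clipped at 0; β_n = 0; couplings ~ U(0,1); latents ~ U(0, 1/5).
σ_n² is estimated once from the trace spectrum and held fixed — the noise
level is identified by the high-frequency floor, not by the EM loop.

Noise estimation uses Welch's method (Hann taper, 50%-overlap segments of
length min(256, T/4)) and averages the density over frequencies strictly
inside (fs/4, fs/2), scaled by fs/2 so the estimator is unbiased for white
noise. Calcium kinetics at typical imaging rates concentrate signal power
well below fs/4, which the test suite verifies by band-separation.

Time constants, when not supplied, are estimated by alternating penalized
regression: NNLS tuning curves given the current kernel, then L-BFGS-B over
(τ_r, Δ) with τ_d = τ_r + Δ, Δ > 0, minimizing the squared reconstruction
error plus η(τ_r + Δ). The kernel derivatives are the analytic ones
(∂k/∂τ_r = t/τ_d² e^{−t/τ_d} − t/τ_r² e^{−t/τ_r}, ∂k/∂Δ = t/τ_d² e^{−t/τ_d}),
checked against finite differences. τ_r is floored at 0.5 frames: a faster
rise is not resolvable at the imaging rate and the floor guards against
boundary divergence when η dominates.

### Identifiability

Fitted models are standardized: factors sorted by descending ‖x_l‖ (stable
sort, ties and zero-norm factors keep original relative order, zero-norm
last with a warning), each factor scaled to unit norm with its coupling
column absorbing the norm, then each neuron's (α_n, w_n, b_n) rescaled so
‖λ_n‖ = 1. The transform preserves the reconstruction exactly and is
idempotent.

### Model selection

The final round(test_seconds·fs) frames are held out (a contiguous terminal
block, so calcium autocorrelation is broken only once). For each (L, γ,
restart) the model is fit on the training block, fresh latents are inferred
on the test block at the fitted θ, and the held-out penalized log-joint is
scored; the maximizer wins and training latents are re-inferred under it.
Defaults follow the protocol Δγ = 0.2, d = 10 grid points, i_max = 5
restarts (restart i seeded base+i). L is user-guided by the elbow of the
correlation-vs-L curve rather than auto-selected; automatic selection tends
to absorb private transients into extra factors.

## Post-fit decomposition

Evoked and spontaneous trace components both carry the baseline,
f̂_evoked = α(k∗Wᵀs) + β and f̂_spont = α(k∗Bᵀx̂) + β, so each aligns with
the raw trace; consequently f̂_evoked + f̂_spont − β = f̂ and the sample
variance identity var[f̂] = var_e + var_s + 2 cov_es holds exactly (the
shared baseline cancels). The drive ratio d_n = (var_e − var_s)/(var_e +
var_s) is NaN-flagged when both components are constant. Private
variability is reported as var[f_n] − σ̂_n² − var[f̂_n]; it is an upper
bound (shared variance is itself a lower bound) and may be negative for
noisy neurons — negative values are reported with a flag, not clipped,
because they diagnose noise-estimate error. The factor contribution index
deletes one factor at a time from the reconstruction and reports the mean
proportional drop in fit correlation; neurons with |corr(f, f̂)| < 1e−6 are
excluded to avoid dividing by noise.

Averaging-based tuning curves take the mean ΔF/F over post-onset frames
4–7, counted 1-based after the onset frame, i.e. offsets {+4, +5, +6, +7}
— stated explicitly because off-by-one conventions differ. They are
compared against the model curves k_max·α_n·w_n, which are on the scale of
the evoked transient amplitude.

Shuffle nulls cyclically permute each trace by an independent uniform
offset, preserving each trace's temporal structure and exact moments, and
report the null distribution and its 95th percentile. Factor
cross-correlograms are Pearson-normalized at lags −max_lag..max_lag.

## Residual-NMF baseline

The two-stage comparison method: per-neuron NNLS onto kernel-convolved
stimulus regressors defines the evoked part; residuals are rectified at
zero and factorized by rank-L NMF (deterministic nndsvd-style
initialization, seeded, squared-error objective), whose per-neuron
projection defines the spontaneous part. Because NNLS sees the full trace,
spontaneous transients that overlap stimulus presentations inflate its
coefficients — the joint fit avoids this, and the suite reproduces the
inflation as a positive mean difference between the two filter estimates.
The calcium-basis diagnostic re-expresses an NMF spontaneous component in a
basis of kernel impulse responses, one per frame, by NNLS; its normalized
residual norm is ≈ 0 for genuine calcium-shaped components and large for
atypical ones (e.g. square pulses). The basis solve is the full T-column
NNLS; a windowed variant would be needed only for recordings far longer
than those used here.

## Synthetic data

The generator draws latent factor events x_l(t) and private events z_n(t)
from zero-inflated exponentials (probabilities ξ, π; magnitude means γ_x,
γ_z), Gaussian tuning curves over the stimulus axis (centres μ_n ~ U[0, K]),
block-structured couplings (neurons round-robin assigned to factors;
assigned entries ~ U[q, 1], others ~ U[0, 1−q], q = 0.85), integer scale
factors α_n ~ U{2..10}, β_n = 0, and white Gaussian noise of variance σ²;
λ_n = w_nᵀs + b_nᵀx + z_n. Everything is reproducible bit-for-bit from the
config and seed, and the true evoked/spontaneous component traces are
returned alongside the data.

Two regimes are provided. The spaced-spot regime (default N=50, T=2000,
K=9, L=3, fs=2.1646 Hz) presents one stimulus every 20 s cycling through a
fixed order that maximizes separation along the stimulus axis, with tuning
widths ν ~ U[0, K/2] — sparse visual stimulation of a larval zebrafish
optic tectum-like population. The rapid-grating regime (default N=60,
T=3000, K=24, L=5, fs=2.5 Hz) presents a uniformly random stimulus every
1–3 s with narrower tuning, ν ~ U[0, √K] by default — a mouse visual
cortex-like protocol. The √K width interval is a design choice: the regime
is defined by *more selective* receptive fields, and a width interval that
grows with K would instead broaden them; the interval is overridable via
`SimulationConfig.nu_interval`.

Event statistics default to ξ = 0.015 per frame per factor (≈ 2 shared
population events per minute per factor at 2.16 Hz, the few-per-minute rate
characteristic of tectal assemblies), γ_x = 1.0 (shared events comparable
in intensity to a strong stimulus response, matching recordings in which
spontaneous and evoked transients are similar in amplitude), π = 0.05 per
frame per neuron, and γ_z = 0.3 (private transients distinctly smaller than
shared events, so that population spontaneous activity is primarily
shared). These defaults describe a shared-SA-dominated population; raising
γ_z toward γ_x progressively degrades evoked-filter recovery because
frequent large private events near onset frames masquerade as stimulus
responses — the test suite measures exactly this degradation along the π
axis.

What the generator does not emulate: motion artifacts, neuropil
contamination, segmentation errors, bleaching or slow baseline drift,
heteroscedastic or autocorrelated noise, multiplicative trial-to-trial gain
on evoked responses, and temporally autocorrelated factor dynamics. Passing
recovery tests therefore demonstrate correctness of the inference under the
model's own assumptions plus private-event misspecification — not
robustness to every artifact of real imaging data.

## Numerical choices

- Kernel evaluated at integer frames; constants accepted in frames (or in
  seconds via `kernel_from_rates`, converted with fs). Tail truncated at
  the first post-peak frame below 1e−6 of the peak (truncation is a
  numerical device; no truncation level is part of the model).
- Convolution: direct per-row for kernels up to 64 frames, FFT-based
  beyond; both verified against an explicit double-loop oracle at 1e−10.
- Zero-norm factors and zero-norm intensities are left unscaled during
  standardization (warned); constant traces are excluded from correlation
  summaries (warned); all-zero stimulus regressors are dropped from NNLS
  (warned).
- Test problem sizes: recovery experiments use N=50, T=2000 (spaced-spot,
  5 seeds) and N=60, T=3000 (rapid-grating); elbow and monotonicity checks
  use N=30 populations. These sizes give stable population averages while
  keeping the full suite quick to run.

## Known limitations

- Private (per-neuron) spontaneous events are outside the model; they land
  in the residual or, when they coincide with onsets, partially in the
  stimulus filters. Recovery accuracy is therefore a decreasing function of
  the private event rate and amplitude.
- The pseudo-EM objective is non-convex; restarts mitigate but do not
  eliminate local optima. The restart with the best training objective is
  kept.
- σ_n² is estimated from the (fs/4, fs/2) band; signal power leaking above
  fs/4 (very fast kinetics or low imaging rates) biases it upward, which in
  turn biases the private-variance bound downward.
- The held-out score depends on latents re-inferred on the test block; with
  very short test segments the score is noisy and selection can be
  unstable.
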