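# Methods

## Model

`stpfit` models the per-spike efficacy of a synapse as a linear–nonlinear
cascade. A presynaptic spike train S(t) = Σⱼ δ(t − tⱼ) is convolved with a
causal *efficacy kernel* k_μ, shifted by a baseline b_μ, and passed through a
sigmoidal readout f. The efficacy of spike j, normalized to the first spike,
is

    μ_j = f(k_μ * S(t_j) + b_μ) / f(b_μ).

The readout is the logistic function f(x) = 1/(1+e⁻ˣ). The model only
requires "a sigmoid"; the logistic is chosen because it is strictly positive
(the gamma mean and SD below must be positive), smooth, and has the
convenient derivative f′ = f(1−f) used by the analytic likelihood gradient.
All qualitative claims in the tests are stated under this choice.

Kernels are linear combinations of integral-normalized basis functions with
a separate baseline coefficient:

* exponential bases h(t) = Θ(t)·e^(−t/τ)/τ — the workhorse for fitting; a
  default bank of τ = [15, 100, 650] ms tiles fast to slow STP timescales,
  overridable everywhere;
* Gaussian bases (normalized density, truncated to t > 0 without
  renormalization — the truncated mass is negligible for the second-scale
  delayed-facilitation kernels they are used for).

Causality is strict: h(0) counts as 0, so a spike affects the potential only
strictly after itself and the first pulse of any train sees the baseline
alone. This makes μ₁ = 1 an exact identity, not an approximation.

### Stochastic amplitudes

Observed amplitudes are modeled as independent gamma draws with mean μ_j and
standard deviation

    σ_j = σ₀ · f(k_σ * S(t_j) + b_σ)

(no 1/f(b_σ) normalization — only the mean is first-pulse-normalized). The
gamma is parameterized by shape γ = μ²/σ² and scale λ = σ²/μ. The first-pulse
coefficient of variation is CV₁ = σ₀·f(b_σ). Because the gamma support is
strictly positive, release failures are absorbed as small releases; no
zero-inflation or quantal mixture is modeled. Two reduced variance modes
recover GLM structure and fewer parameters: `proportional` (σ = σ₀·μ,
constant CV) and `constant` (σ = σ₀).

### Delayed facilitation kernel

The slow tri-Gaussian kernel used for post-burst facilitation has component
means {1.0, 2.5, 6.0} s and SDs {0.6, 1.3, 2.8} s. Its amplitudes are
specified on a millisecond basis-normalization scale, i.e. {0.125, 0.62,
1.30} when the Gaussian densities carry units of 1/s: this keeps the
potential within the dynamic range of the logistic readout (of order 0.3–2.5
for 1–8 burst spikes), so the test-spike efficacy grows smoothly with burst
length. On a literal 1/s reading of the amplitude figures ({125, 620, 1300})
the readout saturates to float-exact 1.0 after a single spike and the
phenomenon disappears; the millisecond convention is therefore the package's
unit choice for that kernel.

## Tsodyks–Markram benchmarks

The TM model tracks the recovered resource fraction R and utilization u,
releasing μ_n = R_n·u_n with pre-jump (left-limit) values at each spike;
between spikes both relax exponentially (τ_R, τ_u) toward 1 and U. The
classic facilitation jump is f(1−u); its affine update map makes successive
facilitation increments decay geometrically by (1−f)·e^(−Δt/τ_u), so classic
TM facilitation is always sublinear. The extended variant's jump u·f·(1−u)
is maximal at u = 1/2, giving supralinear facilitation when U is small.
Initial state is R₀ = 1, u₀ = U (no previous activation). All efficacy
computations use the exact integrated between-spike maps; a fixed-step
explicit ODE integrator with spike-triggered jumps on left limits exists
purely as an independent oracle (the maps agree with dt = 10⁻⁶ integration to
better than 10⁻⁴).

Since u + u·f·(1−u) ≤ 1 for u, f ∈ [0,1], no clipping is needed: the
extended-model state stays in the unit interval automatically (property-
tested over random parameters and trains).

## Inference

The SRP likelihood expands both kernels over a fixed basis bank and stores
the strictly causal filtered spike train in a design matrix X (one constant
row for the baseline, one row per basis, one column per spike; exponential
rows computed by the exact recursion z ← (z + 1/τ)·e^(−Δt/τ)). Potentials are
then matrix products, and the negative log-likelihood is the sum of gamma
NLL terms

    NLL = Σᵢ [ yᵢμᵢ/σᵢ² − (μᵢ²/σᵢ² − 1)·ln(yᵢμᵢ/σᵢ²) + ln(Γ(μᵢ²/σᵢ²)·σᵢ²/μᵢ) ]

over all trials, pulses and protocols. Missing observations (NaN) contribute
zero; non-positive amplitudes (possible in noisy real data, outside the gamma
support) are excluded with a warning.

Optimization is bounded L-BFGS-B from a multistart of seeded Latin-hypercube
points over the bound box (default 256 starts; the surrogate-data experiments
use 16–32 because their likelihood is convex over the region explored).
Default bounds keep the logistic out of flat saturation: baselines in
[−6, 6], amplitudes in [−10, 10], σ₀ in [10⁻³, 10]. Gradients are analytic —
derived through the gamma (shape, scale) partials (∂NLL/∂γ = ψ(γ) + ln λ −
ln y, ∂NLL/∂λ = γ/λ − y/λ²) and the logistic chain rule — because
finite-difference gradients are too noisy on the shallow ridge that couples
σ₀ and b_σ and cause premature termination there. Ties between equal-NLL
starts resolve to the lowest start index; the best converged start, its value
and the full per-start table are stored in the `FitResult`.

σ₀ is a free parameter by default (9 free parameters with three bases per
kernel and both baselines). A *standardized* mode (`fit_sigma_scale=False`)
fixes σ₀ = 1, the convention for amplitude-standardized data, leaving 8 free
parameters.

The TM benchmark is fitted by exhaustive grid search minimizing the MSE
between predicted and trial-averaged amplitudes: U and f linear in (0, 1),
τ_u and τ_R log-spaced over [1 ms, 10 s], default 10⁴ grid points
(configurable to 10⁶), ties broken in scan order, recursion vectorized across
the whole grid. Trial-averaged (not per-trial) MSE is used — the TM model is
deterministic, so the mean is what it predicts. Because the raw TM efficacy
R·u is bounded by 1, fitting first-pulse-normalized data uses an optional
normalized prediction (divide by R₁u₁ = U; still four parameters); the
hold-out comparison enables this by default.

## Surrogate data and evaluation experiments

The generator emulates the statistical structure the model assumes: gamma
amplitudes, independent across pulses and trials, with mean and SD given by
the two cascades. The reference surrogate synapse
(`poisson_surrogate_parameters`) is a facilitating mono-exponential pair of
kernels with known timescale τ = 100 ms (matched to the 10 Hz Poisson mean
inter-spike interval), amplitudes a = 0.2 and c = 0.15, baselines
b_μ = b_σ = −1.5, σ₀ = 1.5 (first-pulse CV ≈ 0.27) — a regime where every
parameter is identifiable from a single trial per spike.

* **Parameter recovery**: for training sizes of 100–2000 spikes and several
  seeds, simulate a Poisson train, sample amplitudes, fit, and record the
  relative error of each parameter plus the held-out MSE of the fitted and
  the true model on an independent 1000-spike test train (the true model's
  MSE is the irreducible sampling error). Median errors shrink with training
  size, to a few percent at 2000 spikes, and the held-out MSE ratio
  approaches 1.
* **Protocol hold-out bootstrap**: repeatedly drop a fraction of whole trials
  per protocol (default 20%, 20 iterations), hold out each protocol in turn,
  fit on the rest, and tabulate held-out MSE per model. The MSE averages
  uniformly over pulses — a metric that weights late, large-amplitude pulses
  more heavily.
* **Noise correlation**: Pearson correlation (two-sided t-approximation
  p-value) between successive amplitude deviations around trial means,
  pooled across trials and protocols — the check of the independence
  assumption.
* **Pulse statistics**: column-wise mean, unbiased (n−1) SD and CV of
  amplitude tables.

What passing these experiments shows — and does not. The generator produces
exactly the model's assumed noise (gamma, independent, unimodal); real
synaptic data have release failures, noise correlations, multimodal quantal
structure and non-stationarities the generator deliberately omits. Passing
recovery and dominance tests therefore demonstrates correctness of the
implementation and identifiability under the model's own assumptions, not
fidelity to any particular biological synapse.

## Numerical choices and degenerate inputs

* Event-driven kernel evaluation is the reference; the dense-grid convolution
  exists for plots and convergence oracles only.
* Potentials may drive f to underflow; μ and σ are floored at 10⁻¹² before
  entering the likelihood.
* Optimizer tolerances: objective change 10⁻¹⁰, projected-gradient norm
  10⁻⁸, max 1000 iterations per start.
* Empty spike trains are valid (duration 0); single-spike protocols are valid
  for prediction but fitting requires at least one protocol with ≥ 2 pulses.
* All randomness (Poisson trains, gamma sampling, multistart, bootstrap
  subsets) flows from explicit seeds; experiments derive per-run seeds from a
  master `numpy` Generator so every result is reproducible bit-for-bit
  (SRP fit objectives are reproducible to optimizer tolerance when trial
  order changes, since summation order perturbs the path at roundoff level).

## Known limitations

* Only exponential and Gaussian bases are provided (no raised-cosine or
  spline banks).
* No Bayesian posterior machinery; point estimates with multistart provenance
  only.
* No quantal/multimodal release-size mixtures and no biophysical mapping of
  kernels onto calcium or vesicle-pool mechanisms.
* Protocols with unspecified structure (e.g. a bare frequency with no pulse
  count, or unpublished in-vivo trains) cannot be reconstructed; the CLI
  accepts user-supplied spike-time files in their place.
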