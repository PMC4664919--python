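# Methods

## Generative model and objective

Observations are linear combinations of causes, μ = U r + ε, with
r ≥ 0 and ε i.i.d. Gaussian. The prior density of each intensity is
proportional to H(r)·exp(−α r − β r²/2): exponential for β = 0,
half-normal for α = 0, and a shifted truncated Gaussian in general
(sampled with `scipy.stats.truncnorm`). The likelihood noise scale is
fixed at σ = 1, so α and β are interpreted on that scale; the generator's
`noise_sd` defaults to 0 because every task input is a deterministic
combination of features.

MAP inference minimizes L(r) = ½‖μ − U r‖² + α Σ r + (β/2) Σ r² on r ≥ 0,
equivalently minimizes the energy E(r) = −gᵀr − ½ rᵀW r with
W = −UᵀU − βI, g = Uᵀμ − α𝟙. E(r) = L(r) − L(0) holds identically and is
tested. If the columns of U are linearly independent or β > 0, W is
negative definite and the minimizer is unique; otherwise the optimum can
be a flat set (the overcomplete bases used below are exactly this case),
and solvers report one minimizer of that set.

## Feature bases

* **Uniform bases** — entries i.i.d. uniform on [0, 1] (or [−0.5, 0.5]),
  each column normalized to unit length. Positive entries make the causes
  strongly overlapping: the mean pairwise dot product tends to
  E[x]²/E[x²] = 3/4, and at M = N = 100 is 0.75 ± 0.02 (tested).
  Symmetric entries give near-orthogonal causes.
* **Shifted-cosine basis** — M = 2, column j = (cos θⱼ, sin θⱼ) with
  θⱼ = 2πj/N, j = 1..N. Unit-norm, rank 2, highly overcomplete. The
  formula is isolated in `make_cosine_features` so the phase/frequency
  convention can be swapped; a half-circle variant (θⱼ = πj/N) was
  evaluated and rejected because it collapses activity onto one or two
  neurons and breaks decoding under delayed delta kernels. Note that the
  full-circle construction with even N contains exactly antipodal feature
  pairs (uᵢ·uⱼ = −1), which matters for the reset bookkeeping below.

## Rate network and solvers

The rate dynamics drᵢ/dt = [gᵢ + (W r)ᵢ + rᵢ]⁺ − rᵢ keeps r in the
non-negative orthant and descends the energy; the Euler integrator
(dt = 0.01 in the dynamics' intrinsic unit time constant) halves its step
when a step would raise the energy and raises an error if 30 halvings do
not restore monotonicity. Its fixpoints are the KKT points.

`solve_map_projected_gradient` is a projected gradient ascent with
Nesterov momentum and energy-based restarts; the default step is
1/λmax(−W). Plain projected steps crawl on badly conditioned Gram
matrices (uniform-[0,1] bases have one dominant eigenvalue), momentum
fixes that. `solve_map_active_set` enumerates all 2ᴺ supports (N ≤ 20),
solves the equality-constrained subproblem on each, keeps feasible KKT
points and returns the one with the lowest loss — an exact oracle used to
validate everything else (including against `scipy.optimize.nnls` for the
unregularized case). A coordinate with rᵢ = 0 and exactly zero net drive
is treated as inactive (consistent with H(0) = 0 in the prior's Heaviside
factor).

KKT residual: max over i of |(g + W r)ᵢ| on the support and of
[(g + W r)ᵢ]⁺ off it. Tolerances are absolute; callers solving problems
with O(10³) drives scale them by ‖g‖∞.

## Spiking network

Voltage dynamics (threshold units, time in seconds):

    dVᵢ/dt = gᵢ + Σⱼ≠ᵢ Jᵢⱼ Σₗ k(t − tⱼˡ)  [ − Vᵢ/τₘ ]

with J = −UᵀU − βI and g = Uᵀμ − α𝟙. Neuron i spikes at Vᵢ ≥ Θ and resets
to Hᵢ = Θ + Jᵢᵢ; the self-coupling is realized as this instantaneous
reset, never through the synaptic filter. L1 regularization is global
inhibition on the drive; L2 lowers every reset by β. For the non-leaky
network, integrating the dynamics over [0, T] shows that the time-averaged
rates nᵢ(T)/T satisfy the same KKT system as the rate network, so the
spike counts of a stable run converge to the MAP estimate; the KKT
residual of the rate estimate is monitored in tests and decays with T.

Integration is one-step Euler at dt = 0.01 ms. Synaptic kernels integrate
to one:

* **Exponential** (default, τs = 5 ms): one auxiliary current per neuron;
  per-step decay exp(−dt/τs) exactly, per-spike jump Jᵢⱼ(1 − ρ)/dt with
  ρ = exp(−dt/τs), so the discretized kernel mass telescopes to 1
  (tested to 1e-6).
* **Delta** (optional delay): the whole jump Jᵢⱼ is applied to the target
  voltage at the arrival step. Deliveries land on the first grid point at
  or after spike time + delay; zero-delay deltas land one step after the
  spike, which makes simultaneous mutual causation well defined. All
  threshold crossings within a step are registered; their consequences
  interact only at later steps.

**Reset bookkeeping.** By default the supra-threshold excess is discarded
at reset (Vᵢ ← Hᵢ); `SimConfig.carry_excess=True` keeps it
(Vᵢ ← Hᵢ + (Vᵢ − Θ)). Carrying the excess is the natural continuum rule
for delta jumps, but it is exactly lossless, and the full-circle cosine
basis contains antipodal pairs whose mutual excitation Jᵢⱼ = +1 equals the
threshold–reset gap: with carried excess two such neurons lock into a
self-sustaining loop that fires every other Euler step (50 kHz), an
undamped null-space mode of J that is invisible to the decoder and
recruits the whole population. Discarding the excess (at most one step's
drive for continuous kernels, one jump's overshoot for deltas) breaks the
loop while leaving the long-run rate balance unchanged. The discarded
excess is the only dissipation in the non-leaky network; it gives the
attractor wander of overcomplete networks a slow drift toward sparser
representations. The magnitude of spike-train irregularity (ISI CV) is
sensitive to exactly this bookkeeping: with the default the
population-averaged per-neuron CV of the overcomplete N = 100 network is
≈ 1.3–1.8 over 100–1000 s runs (≈ 2.4 at N = 500), while the CV of the
pooled ISI distribution is ≈ 2–4 and dominated by rare, very long
intervals. Decoding accuracy is insensitive to the choice.

Injected white noise is interpreted as per-unit-time variance: per-step
increments have sd √(variance·dt), so results are step-size invariant;
`noise_per_step=True` selects the per-step reading. Initial voltages are
uniform on [Hᵢ, Θ) unless fixed. Non-leaky silenced neurons may drift to
large negative voltages; no floor is applied (float64 is ample at the
durations used). The Euler core is numba-compiled; all randomness is
seeded and rasters are bit-reproducible.

**Mistuning.** `perturb_connectivity` adds i.i.d. uniform-[low, high]
noise to every entry of J (optionally sparing the diagonal) and recomputes
H from the perturbed diagonal. `stability_check` reports the spectrum of
the symmetrized J. For the rank-2 cosine network at N = 100, both a
zero-mean ±0.1 perturbation and the negatively biased [−0.2, 0] one push
the bulk spectral edge to ≈ +0.8 (the rank-one mean term only suppresses
the uniform direction), yet the dynamics differ sharply: the zero-mean
network runs away while the negative-mean network remains bounded and
decodes essentially like the tuned one (~1.2° with 500 ms windows). The
spectral flag is therefore treated as a warning; the experiment runner
aborts on it except in the mistuning task, whose purpose is to run
perturbed networks. The relative size of a perturbation is reported under
three conventions (mean entrywise |δ|/|J| with a 1e-8 floor,
mean|δ|/mean|J|, Frobenius ratio) since no single convention is canonical.

## Analysis definitions

* Rates: spike count in [t0, t0 + T) divided by T. Integration windows
  are anchored at t0 = 0; moving windows give time courses.
* Angular error: angle in degrees between μ and the reconstruction
  U r̂ — scale-invariant; undefined for all-silent windows, which are
  excluded from trial averages (and counted).
* Percentage error: 100·‖μ − U r̂‖/‖μ‖.
* ISI variability: per-neuron CV = std/mean of the inter-spike intervals;
  the population statistic averages neurons with ≥ 3 spikes (≥ 2 ISIs);
  excluded neurons are counted.
* Error-vs-window scaling: OLS of log error on log T; the 95% CI is
  1.96 × the OLS slope standard error. A deterministic rate code gives
  slope −1 (a missed spike costs 1/T); independent Poisson spiking gives
  −1/2. Windows at which the mean error is zero are dropped with a
  warning (log undefined).
* Shuffles: trial shuffling permutes whole-trial spike trains across
  trials independently per neuron (a joint permutation would not destroy
  cross-neuron coordination); bin shuffling permutes whole bins within a
  trial, independently per neuron, leaving a final partial bin in place.
  Both preserve the stated per-neuron marginals exactly (asserted on
  every run).

## Task suite and problem sizes

Defaults (overridable per task): N = 100 neurons, Θ = 1, H = 0,
exponential kernels τs = 5 ms, dt = 0.01 ms, α = β = 0, non-leaky.
Tasks: discrimination (M = 100 uniform-[0,1] basis, μ = 50·u₁₀); mixture
(adds a background of the remaining features with amplitudes uniform on
[0, 10]); approximation (μ = (1000, 0, …, 0), outside the conic hull, so
the error plateaus at the optimum instead of vanishing); regularization
(M = 10 symmetric-entry overcomplete basis; variants none / L1 α = 10 /
L2 β = 0.5 / leak τm = 50 ms; sparsity = fraction of neurons above a rate
threshold, default 0.5 Hz); variability, mistuning, noise robustness and
shuffle tasks on the cosine basis; and the network comparison (delta
kernels, mixture of features 10/20/30/40 at 50/50/5/1) between the tuned
non-leaky network (Θ = 1, H = 0) and a leaky signal-tracking variant
(τm = 20 ms, Θ = 0.5, H = −0.5 — only the threshold–reset gap matters,
so the variant differs from the tuned net only by its leak).

The regularized identification task drives the network with 50× the
stored feature rather than 1×: with α = 10 a unit-norm input would leave
every drive negative (g ≤ 1 − α < 0) and the network silent, so the
amplitude keeps the task non-trivial; the scale is exposed in the config.

Desk-scale sizes used by the test suite and the acceptance script:
20 s trials (50 of them for trial-averaged error curves), 1000 s single
runs for ISI statistics, 10 trials per arm for the network comparison.
Longer runs are config changes, not code changes.

## Known limitations

* The active-set oracle is exponential in N (enforced N ≤ 20); large
  problems rely on the accelerated projected gradient.
* With α = β = 0 and an overcomplete basis the optimum is a flat set;
  solvers and the spiking network may legitimately return different
  minimizers (they share the loss value to 1e-6 in tests). Uniqueness is
  flagged via the rank of the active-support Gram matrix.
* The magnitude (not the presence) of intrinsic spiking variability in
  overcomplete networks depends on the reset bookkeeping discussed above;
  the package exposes both conventions, and the pooled-versus-per-neuron
  CV readings are both reported by `isi_statistics`.
* Event-driven (exact) integration, conductance synapses, refractory
  periods, adaptive leaks and feature learning are out of scope.
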