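# Methods

## Model and decomposition

The neural state is a stationary multivariate Ornstein–Uhlenbeck process
`dx/dt = A x + w` with isotropic fluctuations `Cov(w) = σ²I` and a Hurwitz
stable drift `A` (every eigenvalue with real part below −1e−10; anything
closer to the imaginary axis is rejected because no stationary regime
exists). The stationary covariance `Σ` solves `AΣ + ΣAᵀ + σ²I = 0`, solved
with the Bartels–Stewart continuous-Lyapunov routine; an O(n⁶)-memory
Kronecker vectorized solve exists only as a test oracle.

The drift decomposes exactly as `A = (−(σ²/2)I + S)Σ⁻¹` with
`S = (AΣ − ΣAᵀ)/2` skew-symmetric — the steady-state differential
cross-covariance. The decomposition is a bijection between `(Σ, S)` and `A`
at fixed σ², so the package treats `(Σ, S)` as the canonical coordinates of
a fitted model: `Σ` carries zero-lag structure (its inverse, conditional
independence), `S` carries all time-lagged, directional structure. Two exact
consequences are used as invariants everywhere: the incoming strength
(row sum) of a node is a precision-weighted combination dominated by `Σ⁻¹`,
while the outgoing strength (column sum) inherits the column sums of `S` —
only outgoing strengths carry directional meaning.

Sign convention: `S_ij > 0` means column node `j` is the source and row node
`i` the target, so a positive column sum marks a net sender. Summing rows
instead negates the profile and flips the reading; both views lead to the
same conclusions and the tests pin this equivalence.

σ² is an input parameter (or an estimate, during inversion): the variance
rate of endogenous fluctuations is not separately observable from the state
scale, and the package fixes `Σ_w = σ²I` throughout. Correlated or
region-specific noise is out of scope — with non-diagonal `Σ_w` the
differential cross-covariance and `S` stop coinciding.

## Irreversibility metrics

* Entropy production rate `φ = −2 tr(Σ_w⁻¹AS)`, units 1/s, clipped at 0
  against rounding noise; the manifestly nonnegative equivalent
  `2 tr(Σ_w⁻¹SΣ⁻¹Sᵀ)` is kept as a cross-check, never as the implementation.
* Node irreversibility: absolute column sums of `S` (equal to absolute row
  sums by skewness).
* Power spectral density: diagonal of `(iωI − A)⁻¹Σ_w(iωI − A)⁻*` on an
  angular-frequency grid. Default grid: 400 log-spaced points over
  `[2π·10⁻⁴, 2π·1]` rad/s plus ω = 0 — the BOLD band with a wide margin;
  outputs state rad/s explicitly since Hz/rad conventions differ across
  tools. The peak is the grid argmax with ties broken toward the lowest
  frequency, so a monotone (reversible) spectrum reports exactly 0; a peak
  landing on the last grid point raises a coarse-grid flag.
* Autocorrelation: `diag(e^{Aτ}Σ)/diag(Σ)` via scaling-and-squaring matrix
  exponentials per lag — exact on arbitrary lag grids, unlike an inverse-FFT
  of the spectrum.

## Synthetic data

The generator emulates the statistical structure the inversion assumes:

* **Ground-truth EC.** `random_stable_ec` draws a correlation-like SPD `Σ`
  (Wishart-based, unit diagonal, +0.05 ridge), a random skew `S` rescaled so
  `max|S|` equals the requested asymmetry (default 0.5, i.e. solenoidal
  coupling comparable to the σ²/2 = 0.5 dissipative diagonal scale at the
  default σ² = 1), optionally zeroing a fraction of S-pairs symmetrically,
  and maps through the decomposition — stability is automatic because the
  constructed `A` satisfies a Lyapunov equation with an SPD solution.
  `random_sparse_stable_ec` instead places exact zeros in `A` itself
  (diagonally dominant rows), the right ground truth for sparsity-recovery
  experiments.
* **States.** Exact discretization `x_{k+1} = e^{AΔt}x_k + w_k`,
  `Cov(w_k) = Σ − e^{AΔt}Σe^{AΔt}ᵀ`, initial state from the stationary law:
  sample paths are stationary by construction and carry no time-step bias.
* **Hemodynamics.** A per-region FIR (length 18 at TR = 1 s) drawn from a
  Gaussian prior whose mean and covariance come from Monte-Carlo sampling of
  Balloon–Windkessel impulse responses. Nominal parameters are the standard
  DCM-for-fMRI set (signal decay 0.64 /s, autoregulation 0.32 /s, transit
  time 2.0 s, stiffness 0.32, resting extraction 0.32, V₀ = 0.02), jittered
  independently by 10% Gaussian s.d. These are implementation constants, in
  one config block; the nominal impulse response peaks at 4 s. All draws are
  integrated in a single batched RK45 solve.
* **Observation.** Causal per-region FIR convolution (each region sees only
  its own state history), burn-in of L−1 samples dropped, diagonal Gaussian
  noise with variance defaulting to 10% of the noiseless BOLD variance.

What the generator does **not** emulate: nonlinear neural dynamics and
multistability, nonlinear hemodynamic coupling in the forward loop (the
Balloon model enters only through FIR sampling), spatially correlated
observation noise, scanner drifts and motion artifacts, and non-stationarity.
Passing recovery tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to their violation on real
recordings.

## Inference

**Baseline (closed form, states observed).** Sample covariance `Σ̂₀` and
lag-1 cross-covariance `Σ̂₁` give the propagator `Â_d = Σ̂₁Σ̂₀⁻¹`; the
principal matrix log recovers `Â = logm(Â_d)/Δt`, and `Ŝ, σ̂²` follow from
the decomposition. Propagator eigenvalues on the closed negative real axis
(including the white-noise limit `Â_d ≈ 0`) are a hard domain error with the
remedy (shorter sampling period) in the message.

**Sparse DCM (EM with latent states).** The discrete model stacks L lags of
the state, `z_k = [x_k; …; x_{k−L+1}]`:

* transition: block-companion `F` with `A_d = I + TR·A` (first-order
  discretization, matching the linearized formulation; an exact
  `logm(A_d)/TR` readout is available as `discretization="exact"`, with its
  own domain error), process noise `q = σ²·TR` on the leading block;
* observation: `y_{k,i} = h_iᵀ[z_k]_{lags of i} + e_{k,i}`,
  `e ~ N(0, λ_i)`; FIR prior `h_i ~ N(μ_h, Σ_h)` from the Balloon–Windkessel
  calibration. The Monte-Carlo `Σ_h` is numerically low-rank (a 5-parameter
  family seen through 18 taps), so a ridge of 1e−4 of its mean variance is
  added before inversion;
* priors on couplings: `a_ij ~ N(0, γ_ij)` per entry (ARD).

The E-step is a Kalman filter/RTS smoother on the nL-dimensional augmented
state. The companion structure is exploited in the prediction step, and once
the predicted covariance stops changing (relative change < 1e−12) the
Riccati recursion is frozen and constant gains reused — means stay exact,
covariance perturbations sit at the freeze tolerance, and the cost per
sweep collapses to matrix-vector work. `freeze_tol=0` gives the dense
reference smoother, and a test pins the two against each other and against a
brute-force joint-Gaussian oracle. The initial augmented covariance is the
stationary block-Toeplitz covariance of the *initialization* propagator,
held fixed across EM so the objective never depends on parameters through
the initial condition.

M-steps are closed form: per-row Gaussian-prior updates of `A_d` (rows
decouple), symmetric-constrained updates via half-vectorized
(duplication-basis) normal equations when time-reversibility is imposed,
conjugate updates of each `h_i`, and residual-moment updates of `λ` and `q`.

**Sparsity and the evidence trace.** The fit runs in two phases. Phase one
(default 30 iterations) adapts `γ` by the MacKay fixed point
`γ ← m²/(1 − v/γ)`, pruning an entry when `γ < 1e−12` — the pruned coupling
becomes exactly zero and stays frozen. The plain posterior-second-moment
update `γ ← m² + v` is available (`ard_update="em"`) but shrinks only
harmonically and effectively never prunes; MacKay decays geometrically.
Because γ adaptation and pruning change the objective's prior terms
discontinuously, that phase carries no monotonicity guarantee and is logged
separately (`ard_trace_`). Phase two freezes `γ` and the support and runs
MAP-EM to convergence; its penalized log-likelihood per observation is the
`evidence_trace_`, non-decreasing by EM theory (up to the 1e−12 freeze
tolerance). Convergence: relative evidence change below 1e−6, or 500
iterations, whichever first; both recorded in the fit.

**Initialization.** Deterministic and data-driven: `A_d` from
ridge-regularized lag-1 regression on band-passed (0.01–0.1 Hz) BOLD,
spectral radius rescaled to 0.95 if it reaches 0.98; `h_i = μ_h`; `λ_i` = 10% of signal
variance; σ² = 1. Identical inputs give bitwise-identical fits — there is no
randomness anywhere in the inversion.

**Scale.** The data scale must be commensurate with the FIR prior scale:
`A` is invariant to a global state rescaling, but σ̂² and the fitted FIRs
absorb it. Data are mean-centered per region before fitting.

## Data-facing metrics

Band-pass: 2nd-order Butterworth applied forward–backward (zero phase),
mean removed first; default band 0.01–0.1 Hz. Static FC: Pearson
correlation, constant regions rejected by name. Dynamic FC: windows at
integer sample offsets (length `round(50 s/TR)`, step `round(25 s/TR)`);
the FCD matrix correlates the strict-upper-triangle FC vectors of window
pairs, and distributions of FCD triangles are compared with the two-sample
Kolmogorov–Smirnov statistic. Whether the comparison should use the FCD
matrix or pooled window-FC values is ambiguous in common usage; the FCD
matrix is the default here. Phases: analytic-signal argument after
band-passing, with ⌈5/TR⌉ samples trimmed per edge against Hilbert edge
artifacts; Kuramoto order parameter `R(t)`, synchronization = mean,
metastability = s.d. Zero-lag metrics are provably invariant under time
reversal — the package's own demonstration of why they cannot detect the
arrow of time.

## Pipeline

`run_subject_pipeline` chains band-pass → inversion (standard and,
optionally, symmetric) → stationary decomposition → irreversibility metrics
→ surrogate-based FC/dFC/Kuramoto validation (surrogates simulated from the
fitted model with its own FIRs and noise) → sender/receiver profiles and
network matrix → time-reversal experiment, writing TSV/JSON artifacts and a
sorted-key `summary.json` that is byte-identical across runs with the same
seed. Network-pair averages exclude the structurally zero diagonal of `S`;
the full signed network matrix is returned (masking negative entries is a
display choice left to the caller). Any stage failure is re-raised naming
the stage and its inputs.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which every property is comfortably resolved: algebraic identities
on 100 random systems up to n = 20 (residuals ~1e−14 against a 1e−9 bound);
the baseline estimator on 10⁶ exact steps of a 2-node system; EM benchmarks
on 5 nodes, T = 4000, TR = 1 s, FIR length 18, with 60–80 EM iterations;
surrogate FC checks at T = 10⁴; pipeline determinism on 4 nodes, T = 700.
Skew-symmetry is enforced exactly after every construction of `S`
(`(S − Sᵀ)/2`, zero diagonal) and inputs failing
`max|S + Sᵀ| ≤ 1e−8·max|S|` are rejected; quadruples failing the
decomposition identity at 1e−8 are rejected as inconsistent rather than
silently re-projected, and an unstable fitted drift raises on any stationary
analysis instead of being projected to stability.

## Known limitations

The linear model has a single fixed point: synchrony/metastability of rich
nonlinear regimes can only be approximated, and recovered `S` magnitudes are
biased toward zero by the first-order discretization and the sparsity prior
(the time-reversal slope, a ratio, is unaffected — observed ≈ −0.97). ARD
with MacKay updates can occasionally prune a weak true coupling along with
the spurious ones. The EM objective is non-convex; the deterministic warm
start makes results reproducible but not provably global. Empirical-data
concerns (preprocessing, parcellation, scan length at low TR) are outside
the package's scope.
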