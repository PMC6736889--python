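# Methods

## Scope and conventions

Time is measured in days with `t = 0` at the first primary-tumor (PT)
cell; 1 month = 30.4375 d and 1 year = 365.25 d are used only when
reporting.  Sizes are cell counts internally; diameters (mm) appear only
at I/O boundaries and convert through the spherical assumption
1 mm³ = 10⁶ cells, so a lesion of diameter d mm holds (π/6)·d³·10⁶
cells.  Measurement files anchor times at diagnosis; the conversion to
the internal clock happens in the readers.

## Primary-tumor growth

Pre-diagnosis growth is Gompertz from a single cell,
`S_p(t) = exp[(α₀/β)(1 − e^{−βt})]`, with carrying capacity
`K = e^{α₀/β}`.  Because no pre-diagnosis measurements exist in
practice, (α₀, β) are calibrated from (i) `K = 10¹²` cells (configurable)
and (ii) the histology doubling time at the diagnosis size S_d, using the
definitional doubling time `DT(s) = t(2s) − t(s)` with
`t(s) = −(1/β) ln(1 − (β/α₀) ln s)`.  The calibration solves
`DT(S_d; β, α₀ = β ln K) = DT_d` by Brent root finding on
β ∈ [10⁻⁶, 1] d⁻¹, where DT is monotone in β; the capacity constraint
then holds exactly by construction.  `t(s)` is evaluated with `log1p` so
the exponential limit β → 0 (DT → ln2/α₀) stays accurate.

The bundled doubling-time table is {adenocarcinoma: 201 d,
undifferentiated: 104 d, squamous: 104 d} and is user-extensible.  The
squamous entry equals the undifferentiated value because the calibration
chain (53.7 mm, 104 d, 10¹² cells) reproduces published squamous
parameter sets — α₀ = 0.0858 d⁻¹, β = 3.10e-3 d⁻¹, tumor age 2.1 y — to
their printed precision, so we treat 104 d as the operative value.

Post-diagnosis the PT follows the tumor-growth-inhibition law
`dS_p/dt = [α₁ − κ e^{−(t−T_d) ln2 / t_res}] S_p`, integrated in closed
form on the log scale.  Treatment acts only on the PT: brain metastases
are assumed not to respond to systemic therapy (consistent with their
unchecked growth under treatment in the clinical setting this models),
but PT shrinkage does reduce seeding through d(S_p(t)).

## Dissemination and colonization

Seeding follows `d(S) = μ S^γ` foundings per day, γ ∈ [0, 1].  For
primary-only seeding the size-structured lesion density is transported
along Gompertz characteristics, giving the closed forms
`N(t) = ∫₀ᵗ d(S_p) du` and `f(t, s) = N(t − t(s))`, with the delay
variant `f = max(N(t − t(s)) − N(t₀), 0)` (the raw expression can go
negative; counts cannot) and the dormancy variant
`f = N(t − t(s) − τ)`.  Dormant lesions sit exactly at S₀ during
[birth, birth + τ]; f(t, s) for s > S₀ excludes them and we define
f(t, S₀) := N(t) so the census includes them.  N is computed by adaptive
quadrature (relative tolerance 1e-8) with the integrand evaluated in log
space, since S_p spans twelve orders of magnitude; a breakpoint at T_d
handles the treatment kink.

Secondary dissemination (lesions seeding lesions with the same (μ, γ))
makes the birth flux b(t) solve the Volterra renewal equation
`b(t) = d(S_p(t)) + ∫₀ᵗ b(u) d(S_bm(t − u)) du`, where S_bm(a) is the
Gompertz size of a lesion of age a.  We march the trapezoid rule on a
uniform mesh (default 1 d; 2 d during fitting), implicit in the diagonal
term; an optional check re-solves at half the step and rejects meshes
whose final cumulative count moves by more than 0.5%.  The solver was
validated against an independent per-generation convolution cascade
(primary → secondary → tertiary) at parameters where the fourth
generation is negligible, agreeing to better than 1%.  The BM carrying
capacity defaults to the PT's K unless the different-growth variant
overrides it — a symmetric choice where nothing else is specified.

## Discrete per-lesion simulation

Clinical predictions concern a handful of lesions, so expectations are
realized lesion by lesion: the i-th lesion is born at
`T_i = inf{t : N(t) ≥ i}` (the census at t is floor(N(t)); no
rounding-to-nearest), then rests for τ (dormancy) and grows along the
closed-form Gompertz curve.  Birth times are found by bracketed root
solving on a cached monotone (PCHIP) interpolant of N tabulated on a
daily grid — thousands of solves stay cheap, and the grid agrees with
adaptive quadrature to ~1e-4 relative.  The expectation-mode simulator
excludes the secondary variant (its census is not floor of a single N);
the stochastic simulator covers it by generational thinning: candidate
births from a homogeneous Poisson process at the peak intensity are
accepted with probability d(source)/peak, and each accepted lesion
becomes a source itself (capped at 5 generations; a test-oriented
feature).

## Individual-level fitting

Scans are reduced to the empirical cumulative size distribution: sizes
sorted descending within each scan, rank i serving as the count
y = #{lesions ≥ x_i}; ties keep input order and receive sequential
ranks, and the objective compares f at each (x, rank) pair exactly as
constructed.  The SSE objective is minimized by Nelder–Mead (max 2000
iterations, x-tolerance 1e-8, f-tolerance 1e-10, one restart from the
incumbent) with positive parameters (μ, τ, t₀, α₁, κ, t_res) on log
scale, since μ alone spans ten orders of magnitude across the γ grid.
γ is never a continuous free parameter: it is profiled over
(0, 0.4, 0.5, 2/3, 1) with matched μ initializations
(10⁻³, 10⁻⁵, 10⁻⁸, 10⁻⁹, 10⁻¹²), crossed with lag initializations
τ ∈ {0, 50, 100, 350} or t₀ ∈ {0, 500, 1700, 2000} (floored at 10⁻³ d on
the log scale).  PT growth parameters stay fixed at their calibrated
values during BM fits; only the different-growth variant frees the BM
(α₀, β) pair, initialized at the PT values.  For primary-seeding
variants the objective exploits `N(t) = μ · B_γ(t)` with
`B_γ(t) = ∫ S_p^γ` precomputed once per (trajectory, γ) on a daily grid,
making each evaluation a few interpolant lookups.

Identifiability: `Cov = σ̂² (JᵀJ)⁻¹` with σ̂² = SSE/(N − P) (the residual
variance estimate) and J the central-finite-difference Jacobian
(relative step 1e-4) of the predictions in the free parameters; the
relative standard error is 100·sqrt(Cov_ii)/|θ̂_i|.  A rank-deficient JᵀJ
(condition > 1e12) switches to the pseudoinverse and names the offending
parameters instead of raising.

The TGI fit uses log-size residuals (imaging error is multiplicative)
with multi-start Nelder–Mead; a κ estimate collapsing to zero is flagged
as "no measurable response".

## Population-level risk

With γ = 1, a patient of diagnosis size S harbors ≥ 1 metastasis iff
`μ I(S) > 1`, `I(S) = ∫₀^{T_D(S)} S_p dt`, the growth law being
re-calibrated per S from the histology doubling time.  Under lognormal
heterogeneity `ln μ ~ N(ln μ_pop, σ_log²)` this gives the closed form
`Φ((ln I(S) + ln μ_pop)/σ_log)` (a step function at σ_log = 0; exactly ½
at the median crossing μ_pop·I = 1); we interpret the at-least-one-lesion
event operationally (the threshold criterion above).  Heterogeneity
reported as a natural-scale standard deviation of μ converts to σ_log
via the lognormal moment relations.  Bin probabilities over uniform
diameter intervals use 64-point Gauss–Legendre quadrature by default
(deterministic; ln I is cached per node), with a Monte-Carlo estimator
retained for cross-checks.  Cohort fits minimize the squared deviation
of bin probabilities from observed frequencies by Nelder–Mead on
(ln μ_pop, ln σ_log); a fit driven to vanishing μ_pop (e.g. all-zero
frequencies) is flagged as degenerate.

## Synthetic data

The virtual-patient generator emulates the measurement process the
analysis assumes: PT diameters at scan times with multiplicative
lognormal noise (default CV 0 for the bundled fixtures, 5% available),
and visible-BM diameters (≥ 3 mm by default) from either the
expectation-mode or the Poisson-mode lesion realization, with two noise
channels — multiplicative diameter noise (default CV 5%) and additive
count noise on the cumulative ranks (default σ = 0.5), matching the
fitting error model y = f + σε.  The bundled fixtures carry the two
reference parameter sets; their scan schedules (6 BM scans yielding 47
size measurements; 4 scans yielding 16) reproduce the structure of the
clinical series the model was built for, with the times themselves a
package choice.  What the generator does not emulate: inter-lesion
growth-rate variability, lesion coalescence or spatial effects, imaging
false positives, and irregular real-world scan scheduling — so passing
recovery tests demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to model misspecification.

Cohort generation draws each patient's diameter uniformly within its bin
and μ lognormally, marking BM-positivity by the same threshold criterion
as the closed form; ln I(d) is tabulated on a 201-point grid and
interpolated so large cohorts are cheap.

## Numerical and design notes

- Expected-count quadrature: `scipy.integrate.quad`, epsrel 1e-8, with
  the integrand in log space; grid interpolants use cumulative trapezoid
  + PCHIP (monotone, no overshoot).
- Birth-time roots: Brent to 1e-3 d on the cached N.
- The dormancy/delay lag enters tests and fits at a 10⁻³-d log-scale
  floor; estimates at the floor mean "no lag".
- Snapshot lesion sizes use the closed-form Gompertz, never an ODE
  stepper; the TGI closed form was validated against an adaptive
  Runge–Kutta integration to 1e-6 relative.
- T₂, the detection time of the first BM, is defined model-internally as
  the smallest t with f(t, S_vis) ≥ 1.  Derived snapshot quantities near
  integer boundaries (floor(N)) are sensitive to the 3-significant-figure
  precision of published parameter inputs; the test suite documents one
  such case.
- Reference problem sizes: per-patient simulations span the ~2,000-day
  pre-diagnosis history plus up to 48 months of follow-up on daily
  grids; recovery experiments use 20 noise seeds; the population
  recovery uses 5 diameter bins at up to 10⁴ patients per bin.

## Known limitations

- The expectation-mode census (floor of N) understates variance relative
  to the Poisson process it approximates; use the stochastic mode for
  uncertainty in small counts.
- Secondary-dissemination fitting re-solves the renewal equation per
  objective evaluation and is an order of magnitude slower than the
  closed-form variants.
- γ is only identifiable up to the profiled grid; μ estimates are
  conditional on the selected γ.
- Population fits assume a single histology-wide growth law; only μ is
  heterogeneous.
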