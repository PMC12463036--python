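# Methods

## Model abstraction

A `ModelSpec` is either a closed-form observable function h(t, θ) or an
ODE system φ̇ = f(φ, θ, t), φ(t₀) = φ₀(θ), observed through a map h(φ)
of dimension L. Time is the generic independent variable; for the Hill
model it is ligand concentration, treated identically in every interface.
ODE trajectories are integrated with LSODA (adaptive, automatic stiffness
switching) at rtol = 1e-8, atol = 1e-10 — tighter than typical because
sensitivities are differenced downstream of the solves and the quotient
amplifies solver error.

### Model zoo defaults

| model | equations | θ defaults | initial state | domain |
|---|---|---|---|---|
| polynomial | h = θ₁ + θ₂t² + θ₃(t−1)(t−2)(t−3) + 2 | (1, 1, 1) | — | t ∈ [0, 4] |
| hill | h = V·xⁿ/(xⁿ + Kⁿ) | V=2, K=1, n=4 | — | x ∈ [0, 4] |
| nn1 | Σ w2ⱼ·act(w1ⱼ t + b1ⱼ) + b2, act ∈ {relu, tanh} | user | — | t ∈ [0, 1] |
| lv | ẋ = αx − βxy, ẏ = δxy − γy | (0.55, 0.028, 0.024, 0.84) | (30, 4) | t ∈ [0, 20] |
| mm | mass action over (S, E, ES, P), rates (k₁, k₋₁, k₂) | (1.0, 0.5, 0.3) | (10, 1, 0, 0) | t ∈ [0, 40] |
| seir | Ṡ=−βSI, Ė=βSI−σE, İ=σE−γI, Ṙ=γI | (0.6, 0.2, 0.15) | (0.99, 0, 0.01, 0) | t ∈ [0, 100] |

These defaults are this package's reproducible reference conditions; all
tests are self-consistency checks against them, not digit-matching against
external datasets. Observable maps for ODE models are state subsets,
configurable per run: lv observes both states, mm observes [S, P] (or [P]
for the product-only readout), seir supports [I], [E, I], [I, R], and
[S, E, I, R], with [I] the default.

### Synthetic data

Observations are h(φ(tᵢ, θ*)) + εᵢ with εᵢ i.i.d. N(0, σ²) per observable
from a seeded generator. The default σ is 5% of each observable's
trajectory range, because observable scales differ (LV prey vs predator);
the polynomial and Hill protocols use σ = 0, since every identifiability
conclusion on them depends only on the sensitivity matrix at θ*, not on
the noise realization. The generator emulates homoscedastic additive
Gaussian measurement error only — no outliers, missing samples,
heteroscedastic counting noise, or model misspecification — so passing
tests demonstrate correctness of the identifiability machinery under the
stated noise model, not robustness of any particular biological
conclusion to real-data pathologies.

The packaged Hill protocol samples nine concentrations uniformly on
x ∈ [2, 4], the saturating arm of the curve (≥ 94% of Vmax at the default
parameters). This emulates a saturating-ligand assay in which the
plateau is well measured but the rising flank is not; it is the regime in
which the cooperativity n becomes practically non-identifiable and the
identifiability ordering Vmax > Kd > n emerges. A uniform grid over
[0, 4] instead makes Kd the best-determined parameter.

## Sensitivities

The sensitivity matrix s(θ*) stacks N blocks of size L×k, block n holding
∂h_l(φ(t_n, θ*))/∂θ_i. Two routes:

* **Forward sensitivity ODEs** (default for ODE models): the variational
  system Ż = J_f·Z + ∂f/∂θ, Z(0) = ∂φ₀/∂θ, is integrated jointly with
  the states; J_f and ∂f/∂θ come from central differences on f with step
  1e-7·max(1, |value|) unless the model registers analytic Jacobians.
  The observable chain rule ∂h/∂φ is applied per time point.
* **Central finite differences** (default for closed-form models, optional
  for ODE models): per-parameter step hᵢ = 1e-6·max(1, |θᵢ|). For ODE
  models all 2k perturbed trajectories are integrated as one joint system
  at rtol = 1e-10 so that the copies share the adaptive step sequence;
  discretization error is then strongly correlated across copies and
  largely cancels in the difference quotient. (Independent solves leave
  noise of order rtol/(2h), which at these scales would dominate the
  derivative.)

Sensitivities are raw (unnormalized) by default. An optional relative
scaling multiplies column i by |θᵢ*|; the flag travels with the matrix and
is recorded in reports, since it changes every downstream number.

## Identifiability analysis

**FIM and eigenstructure.** F = sᵀs, symmetrized as (F + Fᵀ)/2.
`eigendecompose_fim` sorts eigenvalues non-increasing, clips negatives at
zero, and counts r = #{λ > ε}. The threshold ε is configuration, not
inference: packaged values are 1e-4 (polynomial, Hill) and 1e-6 (MM,
SEIR, LV), and reports always carry the full spectrum so threshold
sensitivity is inspectable. Eigenvector signs follow a deterministic
convention (largest-magnitude component positive, ties to the lowest
index) so heatmaps and reports are reproducible; eigenvalue pairs with
relative gap < 1e-8 are flagged as near-degenerate because their
eigenvectors are only defined up to rotation.

**Coordinate metric.** For parameter i, A is s(θ*) with column i deleted
— range-equivalent to the column permutation formulation, which is all
the theory uses — and the metric is ‖sᵢ − A·A†sᵢ‖∞, computed via a
minimum-norm least-squares solve with relative SVD cutoff 1e-10. The
identifiability flag is metric > tol_coord with tol_coord defaulting to
1e-8 × the largest absolute entry of s(θ*): an exact-arithmetic rank
criterion, deliberately distinct from the thresholded eigenvalue
criterion (a parameter can be identifiable in exact arithmetic yet sit in
an eigendirection below ε, as Hill's n does).

**Profile likelihood.** PL(θᵢ) minimizes the loss over the other k−1
parameters on a 21-point grid spanning θᵢ*(1 ± 0.5). Grid points are
visited outward from the point nearest θᵢ*, each inner trust-region solve
warm-started from its inner neighbour — a strict left-to-right sweep can
drift into secondary minima and then reports a profile value above the
global minimum at θᵢ* itself. A profile is classified flat when
max(PL) − min(PL) ≤ 1e-6·(1 + min(PL)). Failed inner solves are marked
and skipped; more than 50% failures aborts. The profiler can include the
null-space penalty so the regularized objective's profiles can be
inspected directly.

**Structural rank test.** Numerical column rank (singular values above
1e-10 of the largest) of the sensitivity matrix on a dense uniform grid
(default 50 points) over the time domain. Full rank on a rich grid is the
practical surrogate for structural identifiability; the implied limit
grid → continuum is not taken.

**Contribution index.** ξ = σ_min/σ_max of the FIM with eigenvalues
clipped at zero; 0 when σ_max = 0 or σ_min < 1e-300. Note ξ is a ratio:
adding observables can raise every eigenvalue (it always does — Weyl) yet
still lower ξ when the dominant direction gains more than the weakest.
The SEIR fixture shows exactly this: ξ([I]) < ξ([E,I]) but
ξ([S,E,I,R]) < ξ([E,I]), making [E,I] the most *evenly* informative
readout even though [S,E,I,R] is pointwise richer.

## Fitting and regularization

The loss is the unweighted sum of squared residuals (unit noise weight; a
weighted variant is a config option). Fits use SciPy's trust-region
reflective least squares with the analytic sensitivity Jacobian,
tolerances 1e-12, iteration cap 500, and optional box bounds (rate-like
zoo parameters default to [0, ∞)). An optional seeded multi-start adds
log-uniform perturbations of the start (factors in [2/3, 3/2]) for rough
ODE loss surfaces.

The regularized refit appends residual rows √λ·U₀ᵀ(θ − θ*) so the same
least-squares machinery minimizes loss + λ‖U₀ᵀ(θ − θ*)‖². λ defaults
to 1.0 and is recorded in every report; it corresponds to a Gaussian
prior of variance τ² = 1/(2λ) on the null coordinates, and no principled
universal value exists — it sets how strongly flat directions are pinned
to the reference estimate, not how well the data are fit. The
information matrix of the refit, λU₀U₀ᵀ + sᵀs, has spectrum
{retained eigenvalues} ∪ {λ repeated k−r times} whenever U₀ comes from
the eigendecomposition of sᵀs, which is tested directly.

## Uncertainty quantification

Perturbations are restricted to the non-identifiable subspace:
Cov(θ̂) = τ²U₀U₀ᵀ, propagated to first order through the sensitivities,
Var(h_l(t)) = ∇θh_l·Cov·∇θh_lᵀ, and turned into mean ± z_{α/2}·√Var
bands (α defaults to 0.05). τ is a user input with default
0.1·max(1, ‖θ̃‖)/√k; band *magnitudes* therefore reflect the chosen τ and
only structural features — zero width at data points for models whose
null directions are exact, bulges between them — are meaningful without
committing to a τ. The default evaluation grid is 200 uniform points plus
all data times, so the pinch at the data is directly visible. A
Monte-Carlo band (seeded Gaussian draws, empirical quantiles, failed
draws dropped with a warning and > 10% failures an error) is available
for nonlinear models where the linearization is suspect; estimation error
along the *identifiable* directions is deliberately not propagated.

## Optimal design

Greedy forward selection: score every candidate time not yet in the
schedule by d(t) = diag(U₀ᵀS̃(t)ᵀS̃(t)U₀); choose the candidate maximizing
(count of entries > tol_design, then Σd(t), then smallest t); update
F ← F + S̃ᵀS̃ and re-decompose; stop at full rank or the iteration cap.
tol_design = 1e-10·(1 + largest current eigenvalue). The lexicographic
rule reconciles the two printed selection criteria (a count of nonzero
contributions vs a magnitude argmax) and makes the selection invariant to
candidate-grid ordering, which is tested. Candidates are a grid (default
201 uniform points) rather than a continuous optimization; duplicate
times are excluded from the pool. Since each update adds a PSD matrix, no
eigenvalue ever decreases (Weyl), asserted every iteration. If no
candidate scores above tolerance while rank is deficient, the run
terminates unsuccessfully with a structural-non-identifiability
diagnostic. Sensitivity blocks for the whole candidate grid are computed
once per run (θ is fixed throughout), so ODE models cost one sensitivity
solve per candidate, not per iteration.

## Problem sizes and determinism

Packaged protocols use 3 (polynomial), 9 (Hill), 25 (LV), 25 (MM), and
26 (SEIR) time points, 17–201-point design grids, 21-point profiles, and
200-matrix random sweeps for the metric oracle — sizes at which every
analysis is exact or converged while the full suite and the acceptance
script each run in seconds. All stochastic steps (noise, multi-start,
Monte-Carlo bands, random sweeps) take explicit integer seeds and are
bitwise reproducible.

## Known limitations

* First-order machinery throughout: the FIM, the coordinate metric, and
  the analytic bands all linearize around θ*; strongly curved null
  manifolds are only captured by the Monte-Carlo band.
* The eigenvalue threshold ε is context-dependent configuration; no
  automatic selection rule is provided.
* Finite-difference Jacobians limit accuracy to ~1e-6 relative on rough
  models; analytic Jacobians can be registered per model but are not
  required.
* PDE models and models with discontinuous right-hand sides are out of
  scope; user models enter through the same `ModelSpec` interface as the
  zoo, provided their dynamics are smooth enough for LSODA and central
  differences.
* The design algorithm is greedy and grid-based: it guarantees rank
  completion when information exists on the grid, not minimality of the
  selected schedule.
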