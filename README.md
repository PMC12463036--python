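# identifim

Practical parameter identifiability analysis for dynamic models in systems
biology — Fisher-information eigenanalysis, per-parameter identifiability
scoring, null-space regularization and uncertainty quantification, and
optimal measurement-time design.

## The problem

Fitting an ODE model (or any parametric curve) to time-series data often
leaves some parameter combinations essentially unconstrained: the loss
surface is flat along certain directions, so wildly different parameter
vectors fit the data equally well. This *practical non-identifiability* is
distinct from structural non-identifiability — it depends on *which* time
points were measured and *which* variables were observed, not only on the
model equations. `identifim` is for modellers who want to know, before
trusting a fit: which parameters does my data actually pin down, how should
I regularize the ones it does not, how much prediction uncertainty do the
flat directions cause, and when should I measure next to fix them.

## The method

Let φ(t, θ) be the model output with parameters θ ∈ ℝᵏ, observed through
h(·) ∈ ℝᴸ at times t₁…t_N. Everything derives from the stacked sensitivity
matrix

    s(θ*) ∈ ℝ^(N·L × k),   entry ∂h_l(φ(t_n, θ*))/∂θ_i,

computed by forward sensitivity ODEs or central finite differences.

* **Practical identifiability** — the Fisher Information Matrix
  F(θ*) = sᵀs is eigendecomposed, F = UΣUᵀ. Directions with eigenvalues
  above a threshold ε (the columns Ur) are practically identifiable
  combinations Urᵀθ; the near-null directions U₀ = U_{k−r} are not.
* **Coordinate identifiability** — for each parameter i, the metric
  ‖(I − AA†)sᵢ‖∞ measures how far its sensitivity column sᵢ sticks out of
  the span A of the other columns (A† is the Moore–Penrose pseudoinverse).
  It is zero exactly when sᵢ ∈ range(A), i.e. when the profile likelihood
  of θᵢ is locally flat — at a fraction of the profiling cost.
* **Regularized refit** — the MAP estimate
  θ̃ = argmin ‖h(φ(t,θ)) − ĥ‖² + λ‖U₀ᵀ(θ − θ*)‖² pins only the flat
  directions; its information matrix λU₀U₀ᵀ + sᵀs is full rank, with the
  null eigenvalues replaced by λ.
* **Uncertainty quantification** — parameter perturbations confined to the
  null space, θ̂ = θ̃ + U₀ε with ε ~ N(0, τ²I), propagate to prediction
  variance ∇h·(τ²U₀U₀ᵀ)·∇hᵀ and a normal confidence band (or a seeded
  Monte-Carlo band). The band is pinched to zero at the data points —
  exactly the uncertainty the data cannot see.
* **Optimal design** — a greedy algorithm scores each candidate time t by
  d(t) = diag(U₀ᵀ S̃(t)ᵀS̃(t) U₀) and appends the point activating the most
  null directions, until all k eigenvalues exceed ε.
* **Contribution index** — ξ = σ_min/σ_max of the FIM summarizes in one
  number how evenly a dataset informs all parameter directions.

A model zoo ships ready-made benchmarks: a degenerate cubic, the Hill
dose–response curve, a one-hidden-layer neural net, Lotka–Volterra,
Michaelis–Menten, and SEIR — each with a packaged YAML protocol.

## Worked example

Which Hill-curve parameters can a saturating-ligand assay identify?

```python
import numpy as np
import identifim as idf

model = idf.hill()                       # h(x) = Vmax x^n / (x^n + Kd^n)
theta = np.array([2.0, 1.0, 4.0])        # (Vmax, Kd, n)
x = np.linspace(2.0, 4.0, 9)             # concentrations on the saturating arm
data = idf.generate_synthetic(model, theta, x, sigma=0.0, seed=0)

S = idf.sensitivity_matrix(model, theta, data.times)
ana = idf.eigendecompose_fim(idf.fim(S), eps_eig=1e-4,
                             param_names=model.param_names)
print("eigenvalues:", np.round(ana.eigenvalues, 6))
print("identifiable directions r =", ana.r, "of k =", ana.k)
rep = idf.coordinate_metric(S)
for name, m, ok in zip(rep.param_names, rep.metric, rep.flags):
    print(f"  {name:<5} metric = {m:.4f}  identifiable = {ok}")
print("contribution index xi =", f"{idf.contribution_index(ana.F):.3e}")
des = idf.optimal_design(model, theta, [0.25], np.linspace(0, 4, 201),
                         eps_eig=1e-4)
print("design: added measurement points", des.added_times,
      "-> success =", des.success)
```

Output:

```
eigenvalues: [8.866549e+00 1.588910e-01 6.900000e-05]
identifiable directions r = 2 of k = 3
  Vmax  metric = 0.4686  identifiable = True
  Kd    metric = 0.0298  identifiable = True
  n     metric = 0.0041  identifiable = True
contribution index xi = 7.797e-06
design: added measurement points [4.   1.08] -> success = True
```

Reading it: the FIM has one eigenvalue below ε = 10⁻⁴, so one parameter
combination — dominated by the cooperativity n — is practically
non-identifiable from saturated measurements, while Vmax is pinned down
hardest (largest coordinate metric), then Kd, then n. In exact arithmetic
no column is linearly dependent (all flags true), which is why the tiny ξ
is the more honest summary: the dataset informs the weakest direction five
orders of magnitude less than the strongest. The design step fixes this by
prescribing two extra concentrations (x = 4 and x = 1.08, near the
inflection point), after which all three eigenvalues clear the threshold.

## Command line

The same pipeline is scriptable via YAML configs (packaged: `polynomial`,
`hill`, `lv`, `mm`, `seir`, or a path to your own):

```sh
identifim simulate --config hill --out hill.csv
identifim identify --config hill --data hill.csv --out report.json
identifim regfit   --config hill --data hill.csv --out refit.json
identifim uq       --config hill --data hill.csv --out band.csv
identifim design   --config hill --out design.json
```

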