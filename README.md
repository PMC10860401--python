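# pracident

Practical identifiability diagnostics for dynamic models in plant science
and epidemiology.

Mechanistic growth and epidemic models carry parameters with biological
meaning, so a fitted value is only useful if the data could actually pin it
down.  *Structural* identifiability asks whether the map from parameters to
noise-free trajectories is injective; *practical* identifiability asks the
harder, applied question: given a concrete observation protocol — which
variables, at which times, with how much noise — how accurately can each
parameter be estimated?  `pracident` quantifies this with three
complementary indices for any discrete- or continuous-time model
`ẋ = f(x, θ, u, t)`, `y = g(x, θ, u, t)`:

- **Collinearity indices.**  From the scaled sensitivity matrix
  `S_ij = (Δθ_j / SC_i) ∂η_i/∂θ_j` at a reference point θ*, the index of a
  parameter subset K is `γ_K = 1/√λ_min` of the unit-normalized Gram matrix
  of the columns in K.  A change caused by one parameter in K can be
  compensated up to `(1 − 1/γ_K)·100 %` by the others; γ = ∞ means exact
  local compensation.  Indices can be averaged over a prior on θ* to escape
  the purely local picture.
- **Profile-likelihood risk index.**  With the weighted least-squares
  objective `χ²(θ) = Σ_kl (y_kl − η_kl(θ))²/σ_kl²`, the profile
  `χ²_PL(θ_i) = min_{θ_j, j≠i} χ²(θ)` defines confidence intervals bounded
  by the crossings of `χ²_min + Δ_α` (Δ_α the α-quantile of χ²₁).  The risk
  index `r_i = 1 / sup{α : PLCI_i(α) finite}` turns the binary
  "practically unidentifiable" verdict into a number: r ≈ 1 means the
  interval stays finite at almost every confidence level.
- **Average relative error (ARE).**  Repeated synthetic-data estimation:
  `ARE_i = 100 · mean_k |θ*_i − θ̂_i^(k)|/|θ*_i|` over N noisy replicates,
  each fitted by a derivative-free simplex from a random initial guess.
  This measures the estimation *practice*, optimizer warts included.

Two case-study models are built in: **LNAS**, a discrete-time sugar-beet
growth model (Beer–Lambert light interception, log-normal allocation and
senescence, 8 parameters, daily weather inputs), and a continuous-time
**plant-population epidemics model** (SIR-type with a decaying force of
infection, 5 parameters).  A synthetic weather generator supplies LNAS
inputs; all datasets are simulated, so every analysis is fully
reproducible from a seed.

## Worked example

Which epidemics parameters can be estimated from counts of infected and
total stems every other day between days 2 and 12, with noise of 1.5 % of
each observable's time-mean?

```python
import numpy as np
from pracident import (
    ChiSquareObjective, NoiseSpec, ObservationProtocol,
    all_subset_indices, sensitivity_matrix, simulate_dataset,
)
from pracident.models import make_epidemics_model

model = make_epidemics_model()
protocol = ObservationProtocol(
    times=[2, 4, 6, 8, 10, 12],
    observed=["I", "N"],
    noise={"I": NoiseSpec("relative", 0.015),
           "N": NoiseSpec("relative", 0.015)},
)

# 1. collinearity: which parameter pairs compensate each other?
S = sensitivity_matrix(model, protocol)
table = all_subset_indices(S, min_size=2, max_size=2).to_frame()
print(table.head(3).to_string(index=False))

# 2. profile-likelihood risk index of the carrying capacity
dataset = simulate_dataset(model, protocol, seed=11)
fit = ChiSquareObjective.from_model(model, dataset).fit()
risk = fit.risk_index("kappa")
ci = fit.plci("kappa", 0.95)
print(f"kappa estimate {fit.params[1]:.3f}, risk index {risk.risk:.3f} "
      f"(sup alpha {risk.sup_alpha:.3f}), 95% PLCI [{ci.lower:.3f}, {ci.upper:.3f}]")
```

prints

```
    subset  size     gamma  compensation_percent
      mu+d     2 43.228114             97.686691
 lambda0+d     2  3.439672             70.927463
lambda0+mu     2  3.336104             70.024912
kappa estimate 4.833, risk index 1.005 (sup alpha 0.995), 95% PLCI [4.769, 4.897]
```

Reading: the decay rate of the infection force (μ) and the death rate of
infected stems (d) form a strongly compensating pair — a shift in one can
be offset up to ~98 % by the other, so estimating both from this protocol
is hazardous.  The carrying capacity κ, by contrast, is pinned by the
plateau of the total count: its profile-likelihood interval stays finite
up to the highest probed confidence level (risk index ≈ 1).

The same analyses run from the command line off a YAML config:

```sh
pracident run --config examples/epidemics.yaml
pracident collinearity --config examples/lnas.yaml
```

producing CSV tables, a JSON summary and the echoed effective
configuration in the output directory.

## Documentation

`docs/methods.md` describes the models, the index definitions, the
numerical choices (finite-difference scheme, profile marching, bisection
tolerances) and the known limitations, including where the package's
conventions can shift the absolute values of collinearity indices.
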