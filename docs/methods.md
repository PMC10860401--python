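# Methods

This note documents the models, index definitions, numerical choices and
limitations of `pracident`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Model formalism

A model is a parameterized dynamical system with state `x(t) ∈ ℝ^m`,
exogenous input `u(t)`, parameters `θ ∈ Θ ⊂ ℝ^p` and an observation map
`y = g(x, θ, u, t) ∈ ℝ^n`.  Continuous-time models define a vector field
`ẋ = f(x, θ, u, t)` integrated by an adaptive explicit Runge–Kutta scheme
(default relative tolerance 1e-8, absolute 1e-10); discrete-time models
apply the transition map exactly once per day.  Time is measured in days
throughout.  Continuous trajectories are evaluated exactly on the
requested grid (solver-internal dense output, never post-hoc
interpolation), and any non-finite state aborts the simulation with the
blow-up time rather than letting NaNs reach the indices.

An observation protocol fixes the observed components, the observation
times and a Gaussian noise model, either an absolute standard deviation
per component or a fraction of the component's time-mean over the protocol
(the epidemics case uses 1.5 % of the time-mean of each observable).  The
wording "σ² is 1.5 % of the typical value" in the field literature is read
as a standard deviation: a variance with those units would be
dimensionally inconsistent.  Flattened measurement vectors are ordered
time-major, component-minor; every index module relies on this ordering.
Noise is independent across records (diagonal covariance).

## Case-study models

### Plant-population epidemics

Stems are produced toward a carrying capacity and infected by a force of
infection that decays exponentially over the season:

    dS/dt = b (κ − N) − λ₀ e^{−μt} S
    dI/dt = λ₀ e^{−μt} S − d I
    dR/dt = d I,          N = S + I + R

with reference values b = 1.177 /day, κ = 4.876 stems, λ₀ = 0.051 /day,
μ = 0.096 /day, d = 0.246 /day.  Observables are I and N.

Two modeling decisions deserve comment:

- **The removal term.**  The default infected equation includes the
  standard SIR removal `−dI`.  A variant without it (where I accumulates
  and d only routes stems into R) is available via `removal_in_I=False`,
  but in that variant the death rate has no effect on the infected count
  at all, and the hallmark compensation between μ and d — clearly present
  in this system's published identifiability behavior, and reproduced
  here (pairwise index ≈ 43 at the reference) — cannot arise.  The
  removal form is therefore the default.
- **Initial condition.**  `(S, I, R)(0) = (0, 0, 0)`: a bare plot whose
  stems appear through the production term.  This is the only choice that
  introduces no extra constants; it is configurable, and the collinearity
  results are only mildly sensitive to it.

For profile-likelihood work the five rates are treated as real-valued
(confidence intervals may extend below zero); all are flagged
positive-by-nature, so a log reparameterization is available per
parameter.

### LNAS (sugar beet)

A discrete daily-step compartment model.  Thermal time
`τ(t+1) = τ(t) + max(0, T(t) − T_b)` drives phenology; daily production
follows Beer–Lambert interception,
`Q(t) = 0.95·RUE·PAR(t)·(1 − e^{−k_B·Q_g(t)·e_g})`, capped at 95 % of the
incident usable radiation; allocation to leaves slides from γ₀ to γ_f
along a log-normal CDF of thermal time, and green leaf mass is the
unsenesced fraction of leaf mass, also log-normal in thermal time.  The
eight free parameters are (RUE, e_g, μ_a, σ_a, μ_s, σ_s, γ₀, γ_f).
Allocation and senescence are evaluated with the pre-update thermal time,
and day-t production lands in the day-(t+1) compartments, following the
order of the update equations.  Growth bootstraps from the seed: day-0
production equals the seed mass while leaf and root masses start at zero.
Mass balance — leaves + roots = cumulated production — holds to machine
precision and is asserted to 1e-10 relative in the tests.

**Log-normal parameterization.**  The allocation/senescence laws are
quoted by median and standard deviation.  Two readings of the spread are
supported: the default takes it as the standard deviation of the
log-normal *variate* (same units and order of magnitude as the median,
which matches spreads of ~950 °C·day alongside medians of a few hundred);
the underlying log-scale sigma then solves
`median²·e^{s²}(e^{s²} − 1) = spread²` in closed form.  The alternative
(`mode="log-sd"`) reads the spread as the underlying normal's standard
deviation directly.

**Constants and reference values.**  The extinction coefficient
(k_B = 0.7), base temperature (T_b = 0 °C), senescence onset
(τ_sen = 450 °C·day), seed mass (0.3 g/m²) and the reference parameter
vector (RUE = 3.6 g/MJ, e_g = 0.06 m²/g, μ_a = 550, σ_a = 950,
μ_s = 2300, σ_s = 1600 °C·day, γ₀ = 0.85, γ_f = 0.15) are documented,
configurable choices producing a realistic sigmoidal yield curve over a
150-day season — green leaf biomass peaking mid-season near 650 g/m² and
declining through senescence, yield saturating near 2.4 kg/m².  They are
not a calibration to field data, so LNAS results here are qualitative:
the *structure* (all pairwise indices finite, some larger subsets an
order of magnitude more collinear than any pair) is reproducible, exact
index values are not.

**Weather generator.**  Daily temperature and PAR are an annual sinusoid
peaking mid-summer (season start at calendar day 100, i.e. spring sowing)
plus independent Gaussian noise, with PAR clipped at zero; defaults
T = 15 ± 7 °C (noise sd 1.5 °C), PAR = 5 ± 3 MJ/m² (noise sd 1).  Real
weather has autocorrelated, skewed day-to-day variation and
cloud-cover/temperature coupling that the generator does not emulate;
passing tests therefore demonstrate correctness of the indices under a
plausible driving signal, not robustness to real meteorology.

## Collinearity indices

The scaled sensitivity matrix at θ* is
`S_ij = (Δθ_j / SC_i) ∂η_i/∂θ_j`, with central finite differences
(per-parameter step `1e-4·max(|θ*_j|, 1)`), integrator tolerances
tightened 100× (1e-10/1e-12) so difference noise stays below truncation
error, and `SC_i` the time-mean of record i's component (records whose
component has a near-zero mean fall back to SC = 1 with a warning; a
per-record-value mode is available via `sc_mode="value"`).  Δθ defaults
to 100 % relative uncertainty; since columns are re-normalized the indices
are provably invariant to any positive rescaling of Δθ (asserted exactly
for power-of-two rescalings), so Δθ only matters for reporting S itself.

`γ_K = 1/√λ_min` of the normalized Gram matrix of the columns in K;
eigenvalues below 1e-12 of the Gram trace report γ = ∞, matching the
convention that a singular restriction is infinitely collinear.
Singletons give γ = 1 (a single normalized column has Gram [1]); a
parameter with no effect gives γ = ∞.  Full-subset enumeration is capped
at 2^16 subsets unless explicitly raised (the built-in models have 8 and
5 parameters, far below the cap).  Prior-averaged ("mean") indices draw
θ from a componentwise log-normal centered at θ* with log-sd 1 by
default, report the per-subset sample mean with a Monte-Carlo standard
error, and count draws with failed simulations or infinite indices
separately (excluded from the mean).  The log-normal prior is heavy-
tailed, so mean values at moderate sample sizes are indicative, not
converged; the tests assert ordering, not values.

**Convention sensitivity.**  The absolute size of γ for larger subsets
depends visibly on the row normalization: at the epidemics reference
point, time-mean normalization puts the maximum subset index at ≈ 52 and
the (μ, d) pair at ≈ 43.2, while per-record-value normalization gives
≈ 48 and ≈ 41.5.  At the alternate point (6.02, 162.19, 3.74, 0.40,
1.30) the two conventions diverge sharply (maximum subset index ≈ 2200
vs ≈ 53) because the infected count decays to near zero there, making
per-value rows explode.  Time-mean is the default because it is stable
when an observable crosses zero; users comparing against other tools
should check which convention those use.

## Profile likelihood and the risk index

The objective is `χ²(θ) = Σ (y_kl − η_kl(θ))²/σ_kl²`.  Fits use a
derivative-free simplex (Nelder–Mead), restarted from its own solution
until the improvement stalls; on simulation failure inside an optimizer
the objective returns a 1e12 penalty (and counts it) instead of raising.

Profiles are computed by outward marching from the fit: the profiled
parameter is stepped in both directions, each point's nuisance
minimization warm-started from its neighbor's minimizer, with the step
adapted to a target profile rise of ~1 χ² unit per point, a retry from
the fit-point nuisance values whenever a point jumps implausibly (guard
against simplex glitches), and a failure if more than 20 % of points do
not converge.  Marching stops at a configurable search box (default
radius 1e3·max(|θ̂_i|, 1) on the working scale).  PLCI endpoints are the
first crossings of `χ²_min + Δ_α`, refined by bisection between the
bracketing profile points (endpoint tolerance 1e-4 relative); a side is
flagged infinite when the box edge is reached below threshold.  On
linear-Gaussian problems, where the PLCI coincides with the Wald interval
`θ̂_i ± √Δ_α·se_i` exactly, the implementation agrees to better than
1e-3 relative — the core correctness oracle.

The risk index bisects the confidence level (tolerance 0.005 by default):
finiteness of the PLCI is monotone in α because the intervals are nested,
so `sup{α : PLCI finite}` is bracketed by repeatedly testing whether the
profile clears Δ_α on both sides before the box edge.  The profile is
marched once to the highest probed threshold and all probes reuse it.  A
parameter whose interval is already infinite at the lowest probe is
flagged unidentifiable with r = ∞.  Because finiteness is decided by the
maximum profile rise per side over the whole marched range, a bimodal
profile with a second valley beyond the first crossing is handled
correctly.  The reported sup α is capped at 1 − α_tol, so a fully
identifiable parameter reports r = 1/(1 − α_tol) ≈ 1.005 rather than
exactly 1.

Endpoint search by marching + bisection was chosen over a Newton-type
endpoint solver: it is simpler, robust to non-quadratic profiles, and
the risk index needs the whole-range march anyway.  Interval lengths of
different parameters live on different scales; reports rank parameters
by risk index only, never by interval length.

## Average relative error

For each of N replicates (default 100): generate a fresh noisy dataset at
θ* (independent child seed), draw an initial guess from a componentwise
log-normal centered at θ* with log-sd 1 (on the natural-log scale), fit
with a single-run simplex (scipy defaults; restarts configurable), and
accumulate `|θ*_i − θ̂_i|/|θ*_i|`.  Parameters with θ*_i = 0 are routed to
the expected absolute estimate (AE) instead, since the relative error is
undefined there.  Divergent replicates (estimate beyond 1e6× the
reference scale) are kept by default but counted; an exclusion switch
exists.  The full replicate table is stored so the reported ARE can be
recomputed exactly from it (asserted in the tests).  The globalized ARE
averages local AREs over a prior on θ* and reports a Monte-Carlo standard
error; it is expensive and intended for small draw counts.

ARE is deliberately procedure-dependent: a poor initial guess or a stalled
simplex inflates it, and that is information about the estimation
practice, not a bug.  The default evaluation budget is the simplex
default (200·p function evaluations), matching a plain single-run fit.

## Performance

Likelihood-heavy analyses (fits, profiles, ARE replicates) evaluate the
epidemics observables through a numba-compiled fixed-step RK4 integrator
(step 0.01 day, segment-wise so every observation time is hit exactly).
It agrees with the adaptive solver to ~1e-9 relative and is cross-checked
in the tests to 1e-6; the sensitivity matrix and all trajectory-level
outputs always use the adaptive solver.  The problem sizes used by the
bundled reproduction script — 20 noise seeds for the risk median, 100
replicates for ARE — run in a few minutes on one CPU.

## Known limitations

- Collinearity index magnitudes for subsets of size ≥ 3 carry a
  normalization-convention uncertainty of order 10 % (see above); the
  identified dominant pairs and the qualitative gap between pairs and
  larger subsets are robust.
- The profile machinery relies on a derivative-free simplex; on strongly
  compensated ridges the profiled objective can be overestimated if the
  warm-start chain is broken (mitigated by restarts and the jump guard,
  but not eliminated).  Profiles are therefore conservative: reported
  intervals can only be too narrow, not too wide, when the nuisance
  optimization is imperfect.
- Noise is Gaussian, independent, and fully specified; model-discrepancy
  error, autocorrelated residuals and missing data are out of scope.
- The LNAS constants are plausible defaults, not a calibration; only
  qualitative statements about LNAS identifiability are supported.
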