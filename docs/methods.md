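# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite demonstrates.  Everything quantitative stated here is
computed by the package's tests or by `scripts/acceptance.py`.

## State space and events

A GeoSSE state space over n regions contains all 2^n − 1 nonempty region
subsets, ordered canonically by range size then lexicographically; this
fixed ordering defines every vector, matrix and file column in the package.
Between-region speciation rates are keyed by the *unordered* split
{s}|{t} of a parent range into two disjoint covering daughter ranges, so
the two orientations of a split always carry the same rate.  For `{A,B,C}`
the admissible splits are A|B, A|C, B|C (for the two-region parents) and
A|BC, B|AC, C|AB (for the full range).

Per-state gain and loss totals are assembled from the four event classes:

* gains of state i: within-region speciation into an endemic `{ℓ}` from
  every species whose range contains ℓ; dispersal into i from each range
  one region smaller; between-region speciation of every strict superset j
  at rate b_{j\i|i}; extirpation from supersets exactly one region larger.
* losses of state i: dispersal out of i into regions *not yet in the
  range* (a full-range species cannot disperse anywhere new); between-
  region speciation of i, summed once per unordered split (equivalently,
  half the sum over ordered proper subsets); extirpation in each occupied
  region.  Within-region speciation never removes a species from its
  state.

The module's currency is rates (events per unit time), not per-Δt
probabilities, so the same code serves the diffusion stepper, the exact
jump simulator, and the deterministic limit.  Both totals are linear in the
count vector; the matrices behind them (`rate_matrices`,
`count_drift_matrix`) power the vectorized simulators and the stationary
theory.

## Diffusion approximation

The count process for each state is approximated by a diffusion with drift
μ_i = ℙ_i⁺ − ℙ_i⁻ and variance σ_i² = ℙ_i⁺ + ℙ_i⁻.  Cross-covariances
between state counts are assumed zero — a model assumption, not a
truncation; each state's Euler–Maruyama step draws its own independent
Wiener increment.  The frequency process Π_i = N_i/N inherits its drift and
variance from the multivariate Itô transform; the tests verify the closed
formulas against the transform evaluated with analytic partial derivatives
to 1e-10 relative, on random two- and three-region instances.  Frequencies
are undefined at N = 0; total extinction raises an error carrying the time
stamp.

**The two large-N drifts.** The canonical deterministic limit used by all
stationary computations is dΠ_i/dt = ℙ̂_i⁺ − ℙ̂_i⁻ (per-capita gain minus
loss).  The exact N → ∞ limit of the finite-N frequency drift, however,
carries an additional −Π_i · Σ_j (ℙ̂_j⁺ − ℙ̂_j⁻) term, the share correction
from overall clade growth; the two coincide exactly at a stationary point
(where every state's per-capita gain and loss balance) and differ
transiently whenever net growth is nonzero.  Both are exposed
(`large_N_frequency_drift(..., adjust_for_growth=True)`); the
growth-adjusted variant is the right reference for convergence checks
(the finite-N drift error against it halves when N doubles, as the tests
verify) and is also the flow that the renormalized frequency simulation
tracks at large N.  The unadjusted form remains the default because the
entire stationary theory — the closed form, the rate solver, and the
benchmark values — is built on it.

## Simulators

* **Count paths**: Euler–Maruyama with Δt = T/n_steps, drift and variance
  recomputed from the current counts each step, negative excursions
  clamped to exactly zero before the next step.  A warning is emitted when
  the largest per-state event rate times Δt exceeds 0.1 (the per-step
  event load is then large enough that the discretization deserves more
  steps).
* **Frequency paths**: per step, the latent count vector is advanced and
  clamped first; the frequency drift/variance are evaluated at the updated
  counts; the frequency vector is then advanced, truncated to [0, 1] and
  renormalized to sum 1.  The order (advance counts → advance frequencies
  → clamp → normalize) is fixed.
* **Jump process**: an exact continuous-time Markov chain over integer
  count vectors.  Every elementary event (one species, one event class,
  one region or split) is enumerated with its rate coefficient and count
  increment; waiting times are exponential in the aggregate rate and the
  event is chosen proportionally.  Dispersal and extirpation conserve the
  total count, speciation events add one.  Survival conditioning is
  rejection sampling (paths with N(T) = 0 are redrawn; the rejection count
  is reported).  This simulator is distribution-identical to tree-based
  forward simulation of the same model when only state counts are
  observed, which is why it serves as the package's reference process.

Initial counts for a frequency-specified scenario are realized by
largest-remainder rounding of N(0)·Π(0) (deterministic, totals exact), with
a seeded multinomial option.  One master seed deterministically spawns
per-replicate child seeds (`numpy.random.SeedSequence`); identical seeds
give bit-identical trajectories.

## Stationary theory

Substituting Π_last = 1 − Σ others into the linear per-capita dynamics
yields an affine system dx/dt = Jx + c in the remaining |S|−1 frequencies.
For two regions, J is 2×2 and the solution is written in closed form:
fixed point K = −J⁻¹c, eigenvalues λ₁ ≤ λ₂, eigenvectors ν₁, ν₂ and
integration constants C₁, C₂ from the initial frequencies.  The scalar
constants carried in the solution object satisfy

```
Π̂_A = numA/denomA,
numA   = (wA+bBA+eB)(eB+dBA−wB),
denomA = (eA+dAB+bBA+eB)(eB+dBA+bBA+eA) − (wB+bBA+eA)(wA+bBA+eB),
R      = sqrt(R1 + R2),   R2 = (dAB − dBA)²,
R1     = 4 (bBA+eA+wB)(bBA+eB+wA),
```

with λ = ½(−(2bBA+dAB+dBA+2eA+2eB) ∓ R).  A textbook-style variant of R1
in which most coefficients lack their factor of 4 is retained on the
solution object as `printed_R1` for reference; it enters no computation.
The closed form and the ODE integrator agree to 1e-7 (scale-aware) on 200
random strictly positive rate draws.

Three routes to stationary frequencies are provided:

1. `stationary_by_ode` — integrate the reduced system from an interior
   point, doubling the horizon until the terminal drift is < 1e-10;
2. `solve_stationary_2region` — evaluate the closed form (2 regions);
3. `stationary_by_eigen` — the projection-matrix route: dominant right
   eigenvector of the full count matrix A, normalized to sum 1 (the stable
   stage distribution).  A defective or complex dominant eigenspace is
   reported as an error, never silently repaired.

Routes 1–2 find the point where every state's per-capita gain and loss
balance; route 3 finds the asymptotic *composition* of a growing clade.
They coincide at zero net growth and differ by up to ~0.02 per state on
the shipped benchmarks.

**Stability caveat.** The reduced affine system is not guaranteed stable:
for strongly asymmetric growth (e.g. the three-region demonstration
scenarios) J has eigenvalues with positive real part, the trajectory
leaves the simplex, and neither a stationary point nor mixing times exist
along this flow.  The closed form's validity proviso (Π_A + Π_B ≤ 1) is
checkable via `Stationary2RegionSolution.simplex_violated`.

## Rate solving

At a fixed target Π̂ the stationarity conditions ℙ̂_i⁺ = ℙ̂_i⁻ and the flux
ordering side conditions (states with larger stationary frequency must
have larger total incoming-minus-outgoing rate-constant flux; equal
frequencies force equal fluxes) are all *linear* in the rate vector.  The
solver is therefore a linear program over the box [1e-4, 1] per rate
(strict positivity), solved with HiGHS under a random objective; restarts
with different objectives land on different vertices of the solution
polytope, which directly exhibits the many-to-one map from rates to
stationary frequencies.  Inequality orderings carry a 1e-8 margin so they
are checkable in floating point.  A verifier mode checks user-supplied
rates against the same conditions.

Findings worth knowing (all reproducible from the tests): for three
regions, the uniform target (1/7, …) and widespread-heavy targets admit
*no* strictly positive rate solution — the stationarity kernel meets the
positive orthant only on its boundary — while endemic-heavy targets are
comfortably feasible.  Targets containing equal frequency pairs are harder
because they force flux equalities.

Two closed-form rate families with stationary frequencies (1/3, 1/3, 1/3)
ship as samplers (`sample_equal_thirds_rates`): both share
wA = ½(−2bBA + 2dAB + dBA − 2eB), wB = ½(2eB − dAB),
eA = dAB + dBA − bBA − eB, and differ in the admissible free-rate region
(family 1: eB < dAB < 2eB, 0 < bBA ≤ dAB − eB; family 2: 0 < dAB ≤ eB,
dBA > 2(bBA − dAB + eB)).

## Mixing time

On a uniform grid of n_grid points over [0, T] (default 1000 points,
Δt = T/(n_grid − 1)), a state's mixing time t* is the first grid point
t_k (k ≥ 1) with |Π_i(t_k) − Π_i(t_{k−1})| < ε; default ε = 1e-9.  The
trajectory is evaluated with the exact closed form for two regions and by
ODE integration otherwise.  The criterion is grid-dependent by design: t*
is always a grid point, and rates known only to three decimals move t* by
a grid step or two.

## Statistical comparison protocol

Two ensembles (typically diffusion vs jump process) are compared state by
state at the terminal time: Welch's unequal-variances t-test on means
(Welch–Satterthwaite dof), an F-test on variances with the two-sided
p-value 2·min(P(F≤f), P(F≥f)), and the equal-tailed 95% CI for the
variance ratio s²_a/s²_b.  No multiple-testing correction is applied
across states; the overall verdict is "indistinguishable means" when every
state's Welch p exceeds α (default 0.05).  On the full-event three-region
scenario (N(0) = 40, T = 10, 1000 steps, 1000 replicates per simulator)
all seven Welch tests are non-significant at α = 0.01.  The diffusion
systematically *inflates variances* relative to the exact process (the
clamp-and-renormalize steps and the Gaussian increments are approximations
to a skewed discrete law), so variance-equality tests are expected to
reject; the framework's accuracy claim concerns means.

## What the scenarios do and do not emulate

The shipped fixtures are synthetic rate configurations — three-region
scenarios isolating each event class (speciation-only, dispersal,
extirpation, all events; N(0) = 40 over 10 time units) and two-region
configurations whose stationary behavior is known analytically.  They
exercise the full event algebra at realistic macroevolutionary rate
magnitudes (10⁻³–10⁻¹ per lineage per unit time) but idealize real data in
the usual ways: rates are time-homogeneous, regions are featureless
labels, there is no sampling error in the observed frequencies, and
simulations start from a standing clade rather than a single ancestor.
Passing tests therefore demonstrate internal correctness of the algebra,
the simulators and the stationary theory — not that any particular
empirical clade follows a GeoSSE model.

## Numerical choices

* ODE integration: LSODA with rtol 1e-12 / atol 1e-14 and the exact
  (constant) Jacobian; the system is linear, so this is effectively exact
  on the grid.
* Eigen route tie-breaks: dominant eigenvalue by largest real part;
  near-degenerate dominant eigenvalues are accepted only if the eigenspace
  has full rank; the eigenvector must be real and sign-definite.
* Closed-form eigenvalue ordering: λ₁ is the more negative (faster decay).
* LP margins: flux inequalities enforced at 1e-8; equal-target detection
  at 1e-12.
* Strict-positivity box for rate solving: [1e-4, 1] per rate by default.
* Problem sizes: test ensembles use 200–2000 replicates and 100–1000
  steps; the headline diffusion-vs-jump comparison uses the scenario's
  full 1000 replicates and 1000 steps.

## Known limitations

* No cross-covariance between state counts (model assumption inherited
  from treating the per-state birth–death processes as independent).
* The as-printed deterministic frequency drift is not the exact limit of
  the finite-N drift under nonzero net growth (see above); both variants
  are exposed and the discrepancy is documented rather than resolved.
* The reduced-system stationary analysis can be unstable for ≥3 regions
  under strong asymmetric growth; use the eigen route there.
* Survival conditioning exists for the jump process only (rejection
  sampling); no diffusion-side small-clade correction is implemented.
* Time-homogeneous rates only; no epoch models, no perturbation
  re-equilibration analysis, no tree topology output.
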