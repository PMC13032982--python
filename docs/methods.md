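# Methods

## Model and conventions

The model couples three ingredients: logistic competition between two
host types, a lytic virus epidemic (infection, recovery, lysis with burst
size `m`, virion degradation), and contact-mediated dormancy available
only to the mutant host type.  The state is the vector of abundances of
the six types (1a, 1i, 2a, 2d, 2i, 3); `K` is the carrying-capacity
scaling, with pairwise rates (competition `C`, contact `D`) entering the
stochastic chain as `C/K` and `D/K` per pair.

**Dormancy probability `q`.**  Throughout the package, `q` is the
probability that a virion contact with an active mutant ends in dormancy
(virion repelled, virion count unchanged) and `1 − q` the probability of
infection (virion internalised, virion count decremented).  This is the
convention under which the dormant class gains mass at rate
`q D n₃ n₂ₐ` in the limit ODEs and under which larger `q` favours the
dormancy trait in every invasion condition.  Descriptions of this model
class sometimes state the two probabilities the other way around in
prose; the equations are the authority followed here.

**Mechanistic conventions.**  Lysis is a single atomic event (+`m`
virions instantly).  Recovery destroys the internalised virion — the
virion balance has no recovery source term.  Infected and dormant hosts
exert competitive pressure on active hosts but do not feel it
themselves.  The standing ordering `0 < μ₁ < λ₂ < λ₁` is checked and
reported as warnings, not enforced: the reversed ordering `λ₂ > λ₁` is a
legitimate input that produces the virus-free-fixation and
founder-control regimes.

## Equilibria (module `equilibria`)

All equilibria are computed by exact algebraic reduction; generic root
finding appears only as an independent oracle in the test suite.

* Virus-free monocultures: `n̄₁ₐ = (λ₁−μ₁)/C`, `n̄₂ₐ = (λ₂−μ₁)/C`.
* Resident epidemic `n*`: `n1a*` has a closed form; substituting the
  infected-line stationarity `n1i* = D n1a* n3*/(r+v)` into the active
  line and dividing by `n1a*` leaves a linear equation,
  `n3* = (λ₁−μ₁−C n1a*)(r+v) / (D(C n1a* + v))`.
* Mutant epidemic `ñ`: same pattern, with the dormant and infected
  densities slaved to `ñ₃` through their linear lines.
* Coexistence `x`: `x₃` is in closed form; `x1i, x2d, x2i` are slaved to
  `(x1a, x2a, x₃)`; the remaining pair `(x1a, x2a)` solves the 2×2
  linear system formed by the active-density conservation
  `x1a + (1−q) x2a = n1a*` and the active-resident stationarity
  `C(x₁+x₂) = λ₁ − μ₁ − D x₃ v/(r+v)`.

Absence of an equilibrium is a value (`None`), not an exception, so
parameter scans can tabulate existence.  The degenerate surface
`r κ μ₁ = v σ` (where the closed form for `x₃` divides by zero) is
rejected with a dedicated error.  Every returned equilibrium is verified
in the tests to zero the corresponding vector field to 1e-8 or better,
and the coexistence solution is cross-checked against multi-start
numerical root finding of the full stationarity system.

## Deterministic dynamics (module `odes`)

`solve_ivp` with LSODA (stiff-capable, adaptive), `rtol = 1e-8`,
`atol = 1e-10`.  Trajectories started non-negative may undershoot zero by
numerical noise; undershoots within 1e-12 are clamped, anything larger
is reported via the `min_component` diagnostic rather than silently
clipped.  No convergence/stopping heuristic is applied by default; the
tests detect convergence by comparing the final state against the
candidate equilibrium after a fixed horizon.  When both the
resident-virus and mutant-virus sub-systems exhibit limit cycles (large
`m`), the six-dimensional system is numerically delicate; trajectories
are reported as computed but no accuracy guarantee is claimed there.

## Stochastic simulation (module `ssa`)

Direct-method Gillespie SSA over the 14 event channels; exact in
distribution.  Tau-leaping was deliberately not used: desk-scale runs
(`K ≤ 10⁴`) are tractable exactly, and exactness matters when validating
invasion probabilities of order 0.1 with binomial error bars.  Inner
loops are numba-compiled; the compiled RNG is seeded inside compiled
code, and identical `(seed, params, init)` reproduce trajectories
bit-identically.  The event cap defaults to 1e8 and overflow is a
distinct termination status.

Stopping times: `T_β` is the first time all six rescaled components
strictly exceed `β` (the strict/weak distinction is immaterial for a
continuous-time chain hitting at jump times, but strict is what is
implemented); extinction times track the first vanishing of the type-1
or type-2 host line.

**Invasion experiments** start from the rounded resident equilibrium
`round(K·n*)` plus exactly one active mutant, and declare success when
`T_β` precedes the extinction of the mutant line.  `β = 0.05` by
default: all coexistence-equilibrium coordinates in the study scenarios
exceed 0.08, so the threshold lies strictly inside the basin the theory
requires, while `βK ≥ 25` keeps the threshold macroscopic at the
smallest `K` used.

**Branching approximations** freeze the resident at its equilibrium
densities and simulate the linear three-type (2a, 2d, 2i) or two-type
(1a, 1i) process.  Monte Carlo survival declares a line immortal once it
reaches 1000 individuals (a supercritical line at this size dies out
with probability `s^1000`, far below Monte Carlo resolution); the
per-capita channel rates can be overridden for sensitivity checks.

## Invasion analysis (module `invasion`)

The mean matrices `J*` and `J̃` are the transposes of the corresponding
Jacobian sub-blocks at the resident equilibria; closed-form determinant
formulas provide independent cross-checks.  Extinction probabilities are
the coordinatewise smallest positive fixed points of the offspring
generating maps of the embedded jump chains, found by monotone iteration
from the zero vector (guaranteed monotone convergence for PGF maps,
tolerance 1e-12) followed by a Newton polish; a generic multi-root
solver is never used alone.  Values within 1e-9 of the all-ones vector
are snapped to exactly 1 (the sub-critical answer), consistent with the
hyperbolicity tolerance below.

The type-1 extinction system uses the full resident competition pressure
`C(ñ2a + ñ2d + ñ2i)`, matching the branching-process rate list; a
published variant of the fixed-point system omits the dormant term, and
`extinction_probability_type1(..., literal_printed_system=True)`
reproduces that variant for comparison.

**Regime classification** follows the invasion decision tree: with the
resident epidemic present, case (C)/(D) is decided by existence of the
mutant epidemic `ñ`; within a case, the two invasion booleans select
fixation of type 1, fixation of type 2, six-type coexistence (mutual
invasion), virus-free mutant fixation (`λ₂ > λ₁` with `ñ` absent), or
founder control (both non-invasion conditions, reachable only for
`λ₂ > λ₁` with `r κ μ₁ > v σ`).  Invasion booleans are theorem-backed;
the long-term outcome labels are conjecture-backed and marked as such.
Margins or leading eigenvalues within 1e-9 of zero are labelled
degenerate/non-hyperbolic and never classified, since linearisation is
uninformative there.

## Problem sizes used in the test suite

The stochastic checks use desk-scale versions of the asymptotic
statements: branching-process survival at 10⁴ replicates; full-chain
invasion probability at `K = 1000` with 2000 replicates (dark-green
scenario) and 500 replicates (purple scenario); the `T_β/log K`
timescale compared between `K = 500` (1000 replicates) and `K = 5000`
(700 replicates); and the law-of-large-numbers deviation of the mean
rescaled trajectory from the ODE solution between `K = 200` and
`K = 2000` (20 replicates each).  Monte Carlo agreement is asserted at
three binomial standard errors.  These sizes make the suite cheap while
keeping each check's expected discrepancy well below its assertion
threshold; they do not probe the true `K → ∞` limits, and the
finite-`K` bias of `T_β/log K` (of order `1/log K`) is visible in the
numbers — the corresponding test therefore asserts monotone approach to
`1/λ*`, not equality.

## What the simulations do and do not emulate

All inputs are model parameters; no empirical data enters.  The study
scenarios vary `(λ₂, q)` over a fixed base parameter set chosen so that
`r κ μ₁ < v σ` (dormancy can pay off) and the resident epidemic is
stable.  Passing tests demonstrate internal consistency of the three
routes (algebra, branching theory, exact simulation) at those parameter
sets and random sweeps around them — not robustness of the biological
conclusions to model extensions (spatial structure, multiple virus
strains, fluctuating environments are out of scope).

## Known limitations

* Stability of the coexistence equilibrium is assessed numerically
  (eigenvalues of the Jacobian), not proven; fixation outcomes are
  conjecture-level.
* Hopf-bifurcation loci of the sub-systems at large `m` are not
  continued; only pointwise eigenvalue reports are available.
* Uniqueness of the coordinatewise nonzero equilibrium is verified only
  numerically (multi-start root finding).
* Boundary equilibria beyond the named ones (e.g. mixed faces with some
  infected but no virions) are not enumerated.
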