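# phagedorm

Invasion analysis for the emergence of **contact-mediated host dormancy**
during a persistent lytic virus epidemic.

Many microbes can escape a virus attack by switching into a reversible,
protected dormant state upon mere *contact* with a virion — before any
infection takes place.  Such a defence trait typically carries a
reproductive cost.  `phagedorm` implements a minimal eco-evolutionary
model that asks: under which conditions can a single mutant host carrying
a costly dormancy trait invade a resident host population that is locked
in a stable ("persistent") epidemic with a lytic virus — and what happens
afterwards?

The package is aimed at researchers in theoretical population dynamics,
adaptive dynamics and mathematical epidemiology who want a reproducible,
scriptable implementation of the model: exact stochastic simulation,
the deterministic limit system, closed-form equilibria, branching-process
invasion probabilities and phase-diagram regime classification.

## The model

Six sub-populations are tracked: active and infected residents (1a, 1i),
active, dormant and infected mutants (2a, 2d, 2i) and free virions (3).
The stochastic model is a continuous-time Markov chain on ℕ₀⁶ with
carrying-capacity scaling `K` (pairwise interaction rates scale as 1/K):
birth at rates λ₁ (1a) and λ₂ (2a), natural death at μ₁, competitive
death at C/K per pair, host–virion contact at D/K per pair — leading to
infection for residents, and for mutants to dormancy with probability `q`
(virion repelled) or infection with probability 1−q — recovery at r,
lysis at v releasing a burst of `m` virions, resuscitation at σ, dormant
death at κμ₁, and virion degradation at μ₃.

Rescaling by `K` yields the limiting ODE system, e.g. for the active
mutants

    dn2a/dt = n2a (λ₂ − μ₁ − C(n₁+n₂) − D n₃) + r n2i + σ n2d .

Key analysis objects:

* the persistent-epidemic equilibrium `n* = (n1a*, n1i*, n3*)` with
  `n1a* = μ₃(r+v) / (D(mv−(r+v)))`, and its dormancy analogue
  `ñ = (ñ2a, ñ2d, ñ2i, ñ3)` with `(1−q) ñ2a = n1a*`;
* the unique coordinatewise nonzero coexistence equilibrium `x`, with
  `x₃ = (λ₂−λ₁)(κμ₁+σ)(r+v) / (qD (rκμ₁−vσ))`; it is positive exactly
  when both host types can invade each other's epidemic (`ñ₃ < x₃ < n₃*`);
* the invasion condition for the dormancy trait,

      λ₁ − λ₂ < q D n₃* (vσ − rκμ₁) / ((r+v)(κμ₁+σ)) ,

  equivalently positivity of the leading eigenvalue λ\* of the mean
  matrix `J*` of the branching process approximating the rare mutant;
* the invasion probability `1 − s2a` of a single mutant, where
  `(s2a, s2d, s2i)` is the smallest positive solution of the offspring
  generating fixed-point system, and the macroscopic-threshold time
  `T_β ≈ (log K)/λ*`.

## Worked example

The dark-green study scenario (λ₂ = 2.55, q = 0.6 over the base
parameters λ₁ = 3.15, μ₁ = 1, C = 1, D = 0.5, r = 1, v = 1, κ = 0.1,
σ = 2, m = 10, μ₃ = 0.5):

```
$ phagedorm equilibria --scenario fig2_darkgreen
{
  "nbar_1a": 2.15,
  "nbar_2a": 1.5499999999999998,
  "coex13": true,
  "coex23": true,
  "x_positive": true,
  "n1a_star": 0.25,
  "n1i_star": 0.38,
  "n3_star": 6.08,
  "n2a_tilde": 0.625,
  ...
  "n3_tilde": 3.4765100671140927,
  "x3": 4.421052631578949
}
```

The virion density ordering `ñ₃ = 3.477 < x₃ = 4.421 < n₃* = 6.08` places
the scenario in the mutual-invasion regime, so stable six-type
coexistence is expected:

```
$ phagedorm invade --scenario fig2_darkgreen
{
  "inv2_yes": true,
  "inv1_yes": true,
  "s2a": 0.9117086834733883,
  "lambda_star": 0.10850651388798571,
  "p_invade_type2": 0.08829131652661171,
  "t_beta_type2": 63.66212526294232,
  "regime": "coexistence_sixtype",
  "case": "C",
  "subcase": "(iii)",
  "color": "darkgreen"
}
```

A single dormancy-capable mutant arriving in the resident epidemic
therefore invades with probability ≈ 0.088, and a successful invasion
becomes macroscopic after about `(log K)/λ* ≈ 64` time units at
K = 1000.  The same number is recovered by exact simulation of the
individual-based model:

```python
>>> import phagedorm as pg
>>> exp = pg.invasion_experiment(pg.scenario("fig2_darkgreen"),
...                              K=1000, n_replicates=2000, seed=11001)
>>> exp.probability, exp.stderr
(0.083, 0.0062)
```

Other entry points: `phagedorm simulate` (SSA trajectories / replicated
invasion runs, CSV output with a reproducibility manifest),
`phagedorm ode` (deterministic trajectories), `phagedorm scan`
(phase-diagram classification over any two parameters, e.g.
`--axis1 lambda2:1.2:4 --axis2 q:0.01:0.99`), and
`phagedorm scenario-list`.

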