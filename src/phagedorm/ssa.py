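"""Exact event-driven simulation of the six-type Markov chain.

The chain jumps through 14 event channels derived from the model's
mechanisms: logistic birth/death of the two active host types, virion
contacts splitting into infection (the virion is consumed) and dormancy
(the virion is repelled), recovery, lysis with an instantaneous burst of
``m`` virions, resuscitation, dormant death and virion degradation.
Per-pair interaction rates carry the ``1/K`` scaling of the carrying
capacity.

Simulation uses the direct Gillespie method (exact in distribution); the
inner loops are numba-compiled.  Identical ``(seed, params, init)`` always
reproduce the identical trajectory.

Besides full-chain runs, the module simulates the two linear multi-type
branching processes that approximate a rare invader against a frozen
resident equilibrium, used for Monte Carlo validation of invasion
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .equilibria import host1_virus_equilibrium, host2_virus_equilibrium
from .params import ModelParams

__all__ = [
    "CHANNEL_LABELS", "channel_deltas", "total_rates", "PopulationCounts",
    "StoppingSpec", "StoppingRecord", "SimTrajectory", "gillespie_run",
    "InvasionExperiment", "invasion_experiment", "branching_run",
    "branching_survival", "mean_trajectory",
]

#: Event channels in simulation order.
CHANNEL_LABELS = (
    "birth-1a", "death-1a", "contact-infect-1", "recover-1i", "lysis-1i",
    "birth-2a", "death-2a", "contact-infect-2", "contact-dormancy-2",
    "recover-2i", "lysis-2i", "resuscitate-2d", "death-2d", "degrade-3",
)

STATUS_T_MAX = 0
STATUS_BETA = 1
STATUS_EXTINCT_2 = 2
STATUS_EXTINCT_1 = 3
STATUS_ABSORBED = 4
STATUS_EVENT_CAP = 5


def channel_deltas(m: int) -> np.ndarray:
    """Integer state changes of the 14 channels, rows in
    :data:`CHANNEL_LABELS` order, columns ``(n1a,n1i,n2a,n2d,n2i,n3)``.

    Infection consumes the virion (``n3 - 1``); dormancy repels it
    (``n3`` unchanged); lysis releases ``m`` virions atomically.
    """
    return np.array([
        [+1, 0, 0, 0, 0, 0],      # birth-1a
        [-1, 0, 0, 0, 0, 0],      # death-1a
        [-1, +1, 0, 0, 0, -1],    # contact-infect-1
        [+1, -1, 0, 0, 0, 0],     # recover-1i
        [0, -1, 0, 0, 0, m],      # lysis-1i
        [0, 0, +1, 0, 0, 0],      # birth-2a
        [0, 0, -1, 0, 0, 0],      # death-2a
        [0, 0, -1, 0, +1, -1],    # contact-infect-2
        [0, 0, -1, +1, 0, 0],     # contact-dormancy-2
        [0, 0, +1, 0, -1, 0],     # recover-2i
        [0, 0, 0, 0, -1, m],      # lysis-2i
        [0, 0, +1, -1, 0, 0],     # resuscitate-2d
        [0, 0, 0, -1, 0, 0],      # death-2d
        [0, 0, 0, 0, 0, -1],      # degrade-3
    ], dtype=np.int64)


@dataclass(frozen=True)
class PopulationCounts:
    """Integer abundances of the six types."""

    n1a: int
    n1i: int
    n2a: int
    n2d: int
    n2i: int
    n3: int

    def __post_init__(self):
        if min(self.n1a, self.n1i, self.n2a, self.n2d, self.n2i, self.n3) < 0:
            raise ValueError("population counts must be non-negative")

    @property
    def n1(self) -> int:
        return self.n1a + self.n1i

    @property
    def n2(self) -> int:
        return self.n2a + self.n2d + self.n2i

    def to_array(self) -> np.ndarray:
        return np.array([self.n1a, self.n1i, self.n2a, self.n2d,
                         self.n2i, self.n3], dtype=np.int64)

    @classmethod
    def from_array(cls, a) -> "PopulationCounts":
        return cls(*(int(x) for x in a))

    def rescaled(self, K: float) -> np.ndarray:
        return self.to_array() / K


def total_rates(state: PopulationCounts | np.ndarray,
                p: ModelParams) -> np.ndarray:
    """Per-channel jump rates at ``state`` (order: :data:`CHANNEL_LABELS`).

    Competition and contact are pairwise with ``1/K`` scaling:
    ``death-1a = (mu1 + (C/K)(n1+n2)) n1a``,
    ``contact-infect-2 + contact-dormancy-2 = (D/K) n2a n3`` split
    ``(1-q) : q`` between infection and dormancy.
    """
    if isinstance(state, PopulationCounts):
        state = state.to_array()
    n1a, n1i, n2a, n2d, n2i, n3 = (float(x) for x in state)
    comp = p.mu1 + (p.C / p.K) * (n1a + n1i + n2a + n2d + n2i)
    dk = p.D / p.K
    return np.array([
        p.lambda1 * n1a,
        comp * n1a,
        dk * n1a * n3,
        p.r * n1i,
        p.v * n1i,
        p.lambda2 * n2a,
        comp * n2a,
        (1 - p.q) * dk * n2a * n3,
        p.q * dk * n2a * n3,
        p.r * n2i,
        p.v * n2i,
        p.sigma * n2d,
        p.kappa * p.mu1 * n2d,
        p.mu3 * n3,
    ])


def rates_by_label(state, p: ModelParams) -> dict[str, float]:
    """Convenience mapping ``channel label -> rate``."""
    return dict(zip(CHANNEL_LABELS, total_rates(state, p)))


def _param_vector(p: ModelParams) -> np.ndarray:
    return np.array([p.lambda1, p.lambda2, p.mu1, p.C, p.D, p.q, p.r,
                     p.v, float(p.m), p.sigma, p.kappa, p.mu3, p.K])


@njit(cache=True)
def _rates_kernel(n, par, out):
    lam1, lam2, mu1, C, D, q, r, v, m, sig, kap, mu3, K = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6],
        par[7], par[8], par[9], par[10], par[11], par[12])
    n1a, n1i, n2a, n2d, n2i, n3 = (float(n[0]), float(n[1]), float(n[2]),
                                   float(n[3]), float(n[4]), float(n[5]))
    comp = mu1 + (C / K) * (n1a + n1i + n2a + n2d + n2i)
    dk = D / K
    out[0] = lam1 * n1a
    out[1] = comp * n1a
    out[2] = dk * n1a * n3
    out[3] = r * n1i
    out[4] = v * n1i
    out[5] = lam2 * n2a
    out[6] = comp * n2a
    out[7] = (1 - q) * dk * n2a * n3
    out[8] = q * dk * n2a * n3
    out[9] = r * n2i
    out[10] = v * n2i
    out[11] = sig * n2d
    out[12] = kap * mu1 * n2d
    out[13] = mu3 * n3


@njit(cache=True)
def _seed_numba(seed):
    # numba's compiled np.random keeps its own state; it must be seeded
    # from inside compiled code
    np.random.seed(seed)


@njit(cache=True)
def _sim_core(n, par, deltas, t_max, event_cap, beta_thr,
              stop_beta, stop_ext1, stop_ext2,
              rec_t, rec_s):
    """Direct-method SSA from state ``n`` (modified in place).

    Returns ``(status, t, n_events, n_recorded, t_beta, t_ext1, t_ext2)``;
    hit times are -1 when the stopping level was never reached.
    ``beta_thr`` is the count threshold ``beta*K`` (strict ``>`` on all
    six components).  Recording (if ``rec_t`` is non-empty) stores every
    event; overflowing the record buffer ends the run with the event-cap
    status.
    """
    rates = np.empty(14)
    t = 0.0
    events = 0
    nrec = 0
    t_beta = -1.0
    t_ext1 = -1.0
    t_ext2 = -1.0
    cap_rec = rec_t.shape[0]
    while True:
        _rates_kernel(n, par, rates)
        total = 0.0
        for i in range(14):
            total += rates[i]
        if total <= 0.0:
            return STATUS_ABSORBED, t, events, nrec, t_beta, t_ext1, t_ext2
        u = 1.0 - np.random.random()
        dt = -np.log(u) / total
        if t + dt > t_max:
            return STATUS_T_MAX, t_max, events, nrec, t_beta, t_ext1, t_ext2
        t += dt
        pick = np.random.random() * total
        acc = 0.0
        ch = 13
        for i in range(14):
            acc += rates[i]
            if pick < acc:
                ch = i
                break
        for j in range(6):
            n[j] += deltas[ch, j]
        events += 1
        if cap_rec > 0:
            if nrec >= cap_rec:
                return (STATUS_EVENT_CAP, t, events, nrec,
                        t_beta, t_ext1, t_ext2)
            rec_t[nrec] = t
            for j in range(6):
                rec_s[nrec, j] = n[j]
            nrec += 1
        if t_beta < 0.0:
            above = True
            for j in range(6):
                if not (n[j] > beta_thr):
                    above = False
                    break
            if above:
                t_beta = t
                if stop_beta:
                    return (STATUS_BETA, t, events, nrec,
                            t_beta, t_ext1, t_ext2)
        if t_ext2 < 0.0 and n[2] + n[3] + n[4] == 0:
            t_ext2 = t
            if stop_ext2:
                return (STATUS_EXTINCT_2, t, events, nrec,
                        t_beta, t_ext1, t_ext2)
        if t_ext1 < 0.0 and n[0] + n[1] == 0:
            t_ext1 = t
            if stop_ext1:
                return (STATUS_EXTINCT_1, t, events, nrec,
                        t_beta, t_ext1, t_ext2)
        if events >= event_cap:
            return (STATUS_EVENT_CAP, t, events, nrec,
                    t_beta, t_ext1, t_ext2)


@njit(cache=True)
def _sim_batch(n0, par, deltas, t_max, event_cap, beta_thr, n_rep, seed):
    """Replicated invasion runs stopping at T_beta or type-2 extinction.

    Returns per-replicate ``status``, stop time, ``t_beta`` and ``t_ext2``.
    """
    np.random.seed(seed)
    statuses = np.empty(n_rep, dtype=np.int64)
    t_stop = np.empty(n_rep)
    t_betas = np.empty(n_rep)
    t_exts = np.empty(n_rep)
    empty_t = np.empty(0)
    empty_s = np.empty((0, 6), dtype=np.int64)
    work = np.empty(6, dtype=np.int64)
    for k in range(n_rep):
        for j in range(6):
            work[j] = n0[j]
        status, t, _, _, tb, _, te2 = _sim_core(
            work, par, deltas, t_max, event_cap, beta_thr,
            True, False, True, empty_t, empty_s)
        statuses[k] = status
        t_stop[k] = t
        t_betas[k] = tb
        t_exts[k] = te2
    return statuses, t_stop, t_betas, t_exts


@njit(cache=True)
def _sim_grid(n0, par, deltas, grid, event_cap, seed):
    """One SSA run sampled on a fixed time grid (state held between jumps)."""
    np.random.seed(seed)
    n = n0.copy()
    rates = np.empty(14)
    out = np.empty((grid.shape[0], 6), dtype=np.int64)
    t = 0.0
    gi = 0
    events = 0
    t_end = grid[grid.shape[0] - 1]
    while gi < grid.shape[0]:
        _rates_kernel(n, par, rates)
        total = 0.0
        for i in range(14):
            total += rates[i]
        if total <= 0.0 or events >= event_cap:
            while gi < grid.shape[0]:
                for j in range(6):
                    out[gi, j] = n[j]
                gi += 1
            break
        u = 1.0 - np.random.random()
        t_next = t - np.log(u) / total
        while gi < grid.shape[0] and grid[gi] < t_next:
            for j in range(6):
                out[gi, j] = n[j]
            gi += 1
        if t_next > t_end:
            break
        t = t_next
        pick = np.random.random() * total
        acc = 0.0
        ch = 13
        for i in range(14):
            acc += rates[i]
            if pick < acc:
                ch = i
                break
        for j in range(6):
            n[j] += deltas[ch, j]
        events += 1
    return out


@dataclass(frozen=True)
class StoppingSpec:
    """What the simulation should stop on.

    ``beta``: threshold of the macroscopic hitting time ``T_beta`` (first
    time all six rescaled components strictly exceed ``beta``); ``None``
    disables it.  ``stop_on_type2_extinction`` / ``stop_on_type1_extinction``
    stop at the extinction times of the mutant / resident host lines.
    """

    beta: float | None = None
    stop_on_type2_extinction: bool = False
    stop_on_type1_extinction: bool = False


@dataclass
class StoppingRecord:
    """First-hit times of the tracked stopping levels (None = not hit)."""

    t_beta: float | None
    t_extinct_type1: float | None
    t_extinct_type2: float | None


@dataclass
class SimTrajectory:
    """Event-indexed stochastic trajectory."""

    times: np.ndarray          # event times, strictly increasing
    states: np.ndarray         # (n_events+1, 6) incl. initial state at t=0
    seed: int
    status: int                # STATUS_* code of the terminating condition
    t_end: float
    n_events: int
    stopping: StoppingRecord

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            self.states, index=pd.Index(self.times, name="time"),
            columns=["n1a", "n1i", "n2a", "n2d", "n2i", "n3"]).reset_index()


def gillespie_run(p: ModelParams, init: PopulationCounts,
                  stop: StoppingSpec | None = None,
                  t_max: float = 100.0, seed: int = 0,
                  event_cap: int = 10**8,
                  record_cap: int = 2 * 10**6) -> SimTrajectory:
    """Exact SSA realisation of the six-type chain.

    Terminates at the first of: a requested stopping time, ``t_max``, the
    event cap, or absorption (all rates zero).  Event-cap termination is
    reported distinctly via ``status == STATUS_EVENT_CAP``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    stop = stop or StoppingSpec()
    n = init.to_array()
    rec_t = np.empty(min(event_cap, record_cap))
    rec_s = np.empty((rec_t.shape[0], 6), dtype=np.int64)
    beta_thr = -1.0 if stop.beta is None else stop.beta * p.K
    _seed_numba(seed)
    status, t, events, nrec, tb, te1, te2 = _sim_core(
        n, _param_vector(p), channel_deltas(p.m), t_max, event_cap,
        beta_thr, stop.beta is not None, stop.stop_on_type1_extinction,
        stop.stop_on_type2_extinction, rec_t, rec_s)
    times = np.concatenate([[0.0], rec_t[:nrec]])
    states = np.vstack([init.to_array()[None, :], rec_s[:nrec]])
    record = StoppingRecord(
        t_beta=tb if tb >= 0 else None,
        t_extinct_type1=te1 if te1 >= 0 else None,
        t_extinct_type2=te2 if te2 >= 0 else None)
    return SimTrajectory(times=times, states=states, seed=seed,
                         status=status, t_end=t, n_events=events,
                         stopping=record)


@dataclass
class InvasionExperiment:
    """Monte Carlo estimate of the invasion probability of a single
    2a mutant arriving in the resident-plus-virus equilibrium."""

    n_replicates: int
    n_success: int
    probability: float
    stderr: float              # binomial standard error of the estimate
    ci95: tuple[float, float]
    t_beta: np.ndarray         # hit times, NaN where not hit
    t_extinct: np.ndarray      # type-2 extinction times, NaN where not hit
    statuses: np.ndarray
    beta: float
    seed: int

    @property
    def mean_t_beta_over_log_k(self) -> float:
        """Mean of ``T_beta / log K`` over successful replicates."""
        hits = self.t_beta[~np.isnan(self.t_beta)]
        return float(np.mean(hits)) / self._log_k if hits.size else np.nan

    _log_k: float = 0.0


def invasion_experiment(p: ModelParams, K: float | None = None,
                        beta: float = 0.05, n_replicates: int = 1000,
                        seed: int = 0, t_max: float = 400.0,
                        event_cap: int = 10**8) -> InvasionExperiment:
    """Estimate the probability that a single 2a invader reaches
    macroscopic size before its line dies out.

    Each replicate starts from the resident-plus-virus equilibrium
    (counts ``round(K n*)``) plus exactly one active mutant, and runs the
    full chain until ``T_beta`` (success) or type-2 extinction (failure).
    """
    if K is not None:
        p = p.replace(K=float(K))
    eq = host1_virus_equilibrium(p)
    if eq is None:
        raise ValueError("resident-plus-virus equilibrium does not exist "
                         "for these parameters")
    n1a, n1i, n3 = (int(round(c * p.K)) for c in eq)
    init = np.array([n1a, n1i, 1, 0, 0, n3], dtype=np.int64)
    statuses, t_stop, t_betas, t_exts = _sim_batch(
        init, _param_vector(p), channel_deltas(p.m), t_max, event_cap,
        beta * p.K, n_replicates, seed)
    success = statuses == STATUS_BETA
    n_succ = int(success.sum())
    phat = n_succ / n_replicates
    se = float(np.sqrt(phat * (1 - phat) / n_replicates))
    t_betas = np.where(t_betas < 0, np.nan, t_betas)
    t_exts = np.where(t_exts < 0, np.nan, t_exts)
    exp = InvasionExperiment(
        n_replicates=n_replicates, n_success=n_succ, probability=phat,
        stderr=se, ci95=(max(0.0, phat - 1.96 * se), min(1.0, phat + 1.96 * se)),
        t_beta=t_betas, t_extinct=t_exts, statuses=statuses,
        beta=beta, seed=seed)
    exp._log_k = float(np.log(p.K))
    return exp


# ---------------------------------------------------------------------------
# Approximating branching processes (frozen resident environment)
# ---------------------------------------------------------------------------

def _branching_rates(which: str, p: ModelParams) -> np.ndarray:
    """Linear per-individual rates of the invader branching process.

    ``which="2->13"``: three types (2a, 2d, 2i) against the frozen
    resident equilibrium ``(n1a*, n1i*, n3*)``; ``which="1->23"``: two
    types (1a, 1i) against the frozen ``ñ`` equilibrium.  Rates already
    use rescaled equilibrium densities, so no ``1/K`` factors appear.
    """
    if which == "2->13":
        eq = host1_virus_equilibrium(p)
        if eq is None:
            raise ValueError("resident-plus-virus equilibrium absent")
        n1a, n1i, n3 = eq
        death = p.mu1 + p.C * (n1a + n1i)
        return np.array([p.lambda2, death, (1 - p.q) * p.D * n3,
                         p.q * p.D * n3, p.sigma, p.kappa * p.mu1,
                         p.r, p.v])
    if which == "1->23":
        eq = host2_virus_equilibrium(p)
        if eq is None:
            raise ValueError("mutant-plus-virus equilibrium absent")
        n2a, n2d, n2i, n3 = eq
        death = p.mu1 + p.C * (n2a + n2d + n2i)
        return np.array([p.lambda1, death, p.D * n3, p.r, p.v])
    raise ValueError(f"unknown branching process {which!r}; "
                     "use '2->13' or '1->23'")


# (delta, rate-type-index) tables: type index 0/1/2 = active/dormant/infected
_B3_DELTAS = np.array([
    [+1, 0, 0],    # birth of 2a
    [-1, 0, 0],    # death of 2a
    [-1, 0, +1],   # contact -> infection
    [-1, +1, 0],   # contact -> dormancy
    [+1, -1, 0],   # resuscitation
    [0, -1, 0],    # dormant death
    [+1, 0, -1],   # recovery
    [0, 0, -1],    # lysis
], dtype=np.int64)
_B3_WEIGHT_TYPE = np.array([0, 0, 0, 0, 1, 1, 2, 2], dtype=np.int64)

_B2_DELTAS = np.array([
    [+1, 0],       # birth of 1a
    [-1, 0],       # death of 1a
    [-1, +1],      # contact -> infection
    [+1, -1],      # recovery
    [0, -1],       # lysis
], dtype=np.int64)
_B2_WEIGHT_TYPE = np.array([0, 0, 0, 1, 1], dtype=np.int64)


@njit(cache=True)
def _branch_once(rates, deltas, wtype, n, t_max, size_cap):
    """One linear branching run; returns (outcome, t, events).

    outcome 0 = extinct, 1 = reached size_cap, 2 = reached t_max.
    """
    n_chan = rates.shape[0]
    dim = deltas.shape[1]
    chan_rate = np.empty(n_chan)
    t = 0.0
    events = 0
    while True:
        total = 0.0
        alive = 0
        for j in range(dim):
            alive += n[j]
        if alive == 0:
            return 0, t, events
        if alive >= size_cap:
            return 1, t, events
        for c in range(n_chan):
            chan_rate[c] = rates[c] * n[wtype[c]]
            total += chan_rate[c]
        u = 1.0 - np.random.random()
        dt = -np.log(u) / total
        if t + dt > t_max:
            return 2, t_max, events
        t += dt
        pick = np.random.random() * total
        acc = 0.0
        ch = n_chan - 1
        for c in range(n_chan):
            acc += chan_rate[c]
            if pick < acc:
                ch = c
                break
        for j in range(dim):
            n[j] += deltas[ch, j]
        events += 1


@njit(cache=True)
def _branch_batch(rates, deltas, wtype, init, t_max, size_cap, n_rep, seed):
    np.random.seed(seed)
    outcomes = np.empty(n_rep, dtype=np.int64)
    dim = deltas.shape[1]
    work = np.empty(dim, dtype=np.int64)
    for k in range(n_rep):
        for j in range(dim):
            work[j] = init[j]
        out, _, _ = _branch_once(rates, deltas, wtype, work, t_max, size_cap)
        outcomes[k] = out
    return outcomes


def _branch_tables(which: str, p: ModelParams):
    rates = _branching_rates(which, p)
    if which == "2->13":
        return rates, _B3_DELTAS, _B3_WEIGHT_TYPE
    return rates, _B2_DELTAS, _B2_WEIGHT_TYPE


@dataclass
class BranchingRun:
    """One realisation of an invader branching process."""

    extinct: bool
    survived_to_cap: bool       # reached the escape size before t_max
    t_end: float
    n_events: int
    final_counts: np.ndarray
    seed: int


def branching_run(which: str, p: ModelParams, init=None,
                  t_max: float = 200.0, seed: int = 0,
                  size_cap: int = 10**6, rates=None) -> BranchingRun:
    """Simulate the invader branching process in the frozen resident
    environment (``which`` as in :func:`_branching_rates`).

    Default initial condition is a single active invader.  ``rates``
    optionally overrides the per-capita channel rates (channel order as
    in the frozen-environment rate tables), e.g. to probe the process
    with individual channels switched off.
    """
    table_rates, deltas, wtype = _branch_tables(which, p)
    if rates is None:
        rates = table_rates
    else:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != table_rates.shape or rates.min() < 0:
            raise ValueError("rates must be "
                             f"{table_rates.shape[0]} non-negative values")
    dim = deltas.shape[1]
    if init is None:
        n = np.zeros(dim, dtype=np.int64)
        n[0] = 1
    else:
        n = np.asarray(init, dtype=np.int64).copy()
        if n.shape != (dim,) or n.min() < 0:
            raise ValueError(f"init must be {dim} non-negative counts")
    _seed_numba(seed)
    out, t, events = _branch_once(rates, deltas, wtype, n, t_max, size_cap)
    return BranchingRun(extinct=(out == 0), survived_to_cap=(out == 1),
                        t_end=t, n_events=events, final_counts=n, seed=seed)


def branching_survival(which: str, p: ModelParams, n_replicates: int = 10**4,
                       t_max: float = 400.0, seed: int = 0,
                       size_cap: int = 1000) -> tuple[float, float]:
    """Monte Carlo long-run survival frequency of the invader branching
    process started from one active individual.

    A replicate counts as surviving when it reaches ``size_cap``
    individuals before ``t_max`` (a supercritical line that grows to this
    size is effectively immortal).  Returns ``(frequency, stderr)``.
    """
    rates, deltas, wtype = _branch_tables(which, p)
    init = np.zeros(deltas.shape[1], dtype=np.int64)
    init[0] = 1
    outcomes = _branch_batch(rates, deltas, wtype, init, t_max, size_cap,
                             n_replicates, seed)
    surv = float(np.mean(outcomes == 1))
    return surv, float(np.sqrt(surv * (1 - surv) / n_replicates))


def mean_trajectory(p: ModelParams, init: PopulationCounts, t_grid,
                    n_replicates: int, seed: int = 0,
                    event_cap: int = 10**8) -> np.ndarray:
    """Mean rescaled SSA trajectory over replicates, sampled on ``t_grid``.

    Used to verify the law-of-large-numbers convergence of the rescaled
    chain to the deterministic limit.
    """
    grid = np.asarray(t_grid, dtype=float)
    par = _param_vector(p)
    deltas = channel_deltas(p.m)
    acc = np.zeros((grid.shape[0], 6))
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(n_replicates) % (2**31 - 1)
    for k in range(n_replicates):
        acc += _sim_grid(init.to_array(), par, deltas, grid, event_cap,
                         int(seeds[k]))
    return acc / (n_replicates * p.K)
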