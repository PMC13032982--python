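"""Deterministic limit dynamics: right-hand sides and integration.

In the large-population limit the rescaled six-type Markov chain converges
to the solution of a six-dimensional ODE system.  Three invariant faces of
that system are of independent interest and are exposed as sub-system
right-hand sides:

* the virus-free two-type competitive Lotka--Volterra system,
* the resident-plus-virus system (types 1a, 1i, 3),
* the mutant-plus-virus system with dormancy (types 2a, 2d, 2i, 3).

State component order is always ``(n1a, n1i, n2a, n2d, n2i, n3)`` for the
full system, and the corresponding coordinate projection for sub-systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams

#: numerical positivity slack: components of trajectories started
#: non-negative may undershoot zero by at most this much before the
#: trajectory is flagged.
UNDERSHOOT_TOL = 1e-12


def rhs_full(n, p: ModelParams):
    """Time derivative of the full six-type system at state ``n``."""
    n1a, n1i, n2a, n2d, n2i, n3 = n
    host_total = n1a + n1i + n2a + n2d + n2i
    pressure1 = p.lambda1 - p.mu1 - p.C * host_total - p.D * n3
    pressure2 = p.lambda2 - p.mu1 - p.C * host_total - p.D * n3
    return np.array([
        n1a * pressure1 + p.r * n1i,
        p.D * n3 * n1a - (p.r + p.v) * n1i,
        n2a * pressure2 + p.r * n2i + p.sigma * n2d,
        p.q * p.D * n3 * n2a - (p.kappa * p.mu1 + p.sigma) * n2d,
        (1 - p.q) * p.D * n3 * n2a - (p.r + p.v) * n2i,
        (-p.D * n3 * n1a - (1 - p.q) * p.D * n3 * n2a
         + p.m * p.v * (n1i + n2i) - p.mu3 * n3),
    ])


def rhs_lv(n1a, n2a, p: ModelParams):
    """Virus-free Lotka--Volterra sub-system (types 1a, 2a)."""
    total = n1a + n2a
    return np.array([
        n1a * (p.lambda1 - p.mu1 - p.C * total),
        n2a * (p.lambda2 - p.mu1 - p.C * total),
    ])


def rhs_host1_virus(n1a, n1i, n3, p: ModelParams):
    """Resident-plus-virus sub-system (types 1a, 1i, 3)."""
    return np.array([
        n1a * (p.lambda1 - p.mu1 - p.C * (n1a + n1i) - p.D * n3) + p.r * n1i,
        p.D * n1a * n3 - (p.r + p.v) * n1i,
        p.m * p.v * n1i - p.D * n1a * n3 - p.mu3 * n3,
    ])


def rhs_host2_virus(n2a, n2d, n2i, n3, p: ModelParams):
    """Mutant-plus-virus sub-system with dormancy (types 2a, 2d, 2i, 3)."""
    host_total = n2a + n2d + n2i
    return np.array([
        (n2a * (p.lambda2 - p.mu1 - p.C * host_total - p.D * n3)
         + p.sigma * n2d + p.r * n2i),
        p.q * p.D * n2a * n3 - (p.kappa * p.mu1 + p.sigma) * n2d,
        (1 - p.q) * p.D * n2a * n3 - (p.r + p.v) * n2i,
        p.m * p.v * n2i - (1 - p.q) * p.D * n2a * n3 - p.mu3 * n3,
    ])


_SYSTEMS = {
    "full": (6, lambda n, p: rhs_full(n, p)),
    "lv": (2, lambda n, p: rhs_lv(n[0], n[1], p)),
    "host1_virus": (3, lambda n, p: rhs_host1_virus(n[0], n[1], n[2], p)),
    "host2_virus": (4, lambda n, p: rhs_host2_virus(n[0], n[1], n[2], n[3], p)),
}


@dataclass
class OdeTrajectory:
    """Grid-sampled deterministic trajectory with solver diagnostics."""

    t: np.ndarray
    y: np.ndarray                  # shape (len(t), dim)
    system: str
    success: bool
    rtol: float
    atol: float
    message: str = ""
    #: worst negative undershoot observed (0 if none); values below
    #: -UNDERSHOOT_TOL indicate a genuine solver positivity violation.
    min_component: float = 0.0

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]


def integrate(system: str, p: ModelParams, init, t_end: float,
              n_points: int = 500, rtol: float = 1e-8,
              atol: float = 1e-10) -> OdeTrajectory:
    """Integrate a (sub-)system with a stiff-capable adaptive solver.

    Parameters
    ----------
    system
        One of ``"full"``, ``"lv"``, ``"host1_virus"``, ``"host2_virus"``.
    init
        Non-negative initial state of the matching dimension.
    t_end, n_points
        Output grid ``linspace(0, t_end, n_points)``.
    """
    try:
        dim, fun = _SYSTEMS[system]
    except KeyError:
        raise ValueError(f"unknown system {system!r}; choose from "
                         f"{sorted(_SYSTEMS)}") from None
    init = np.asarray(init, dtype=float)
    if init.shape != (dim,):
        raise ValueError(f"system {system!r} needs a state of dimension {dim}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(lambda t, n: fun(n, p), (0.0, t_end), init,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    y = sol.y.T if sol.success else np.atleast_2d(sol.y.T)
    min_comp = float(y.min()) if y.size else 0.0
    # tiny undershoots are numerical noise; clamp them, report the rest
    if -UNDERSHOOT_TOL <= min_comp < 0:
        y = np.clip(y, 0.0, None)
    return OdeTrajectory(t=sol.t, y=y, system=system, success=sol.success,
                         rtol=rtol, atol=atol, message=sol.message,
                         min_component=min(min_comp, 0.0))
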