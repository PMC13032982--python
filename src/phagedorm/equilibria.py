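"""Closed-form equilibria of the full system and its sub-systems.

All equilibria are obtained by exact algebraic reduction (closed forms
plus linear solves); no generic root finding is involved.  Absence of an
equilibrium is an explicit value (``None`` inside :class:`EquilibriumSet`),
never an exception, so regime scans can tabulate existence.

Notation (matching the field's usage):

* ``nbar_1a``, ``nbar_2a`` -- monoculture carrying densities of the
  virus-free Lotka--Volterra faces.
* ``n* = (n1a*, n1i*, n3*)`` -- the persistent-epidemic equilibrium of the
  resident-plus-virus sub-system.
* ``ñ = (ñ2a, ñ2d, ñ2i, ñ3)`` -- the analogous equilibrium of the
  mutant-plus-virus sub-system with dormancy.
* ``x = (x1a, x1i, x2a, x2d, x2i, x3)`` -- the unique coordinatewise
  nonzero equilibrium of the full system (which may have negative
  coordinates; it is an admissible rest point only when positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams


class DegenerateParameterError(ValueError):
    """Raised when ``r*kappa*mu1 == v*sigma``: the coexistence virion
    density is undefined (its closed form divides by ``r*kappa*mu1 -
    v*sigma``) and the invasion analysis is non-hyperbolic."""


def lv_equilibria(p: ModelParams) -> tuple[float, float]:
    """Monoculture carrying densities ``(nbar_1a, nbar_2a)``.

    Negative values are returned as-is (the corresponding monoculture is
    not viable).
    """
    return (p.lambda1 - p.mu1) / p.C, (p.lambda2 - p.mu1) / p.C


def _epidemic_threshold(p: ModelParams) -> float | None:
    """``mu3 (r+v) / (D (mv - (r+v)))`` or None when ``mv <= r+v``."""
    surplus = p.m * p.v - (p.r + p.v)
    if surplus <= 0:
        return None
    return p.mu3 * (p.r + p.v) / (p.D * surplus)


def host1_virus_equilibrium(p: ModelParams) -> tuple[float, float, float] | None:
    """Persistent-epidemic equilibrium ``(n1a*, n1i*, n3*)`` or ``None``.

    Exists iff ``mv > r+v`` and ``nbar_1a > n1a* = mu3(r+v)/(D(mv-(r+v)))``.
    ``n1i*`` and ``n3*`` follow from stationarity: the infected line gives
    ``n1i* = D n1a* n3* / (r+v)``; substituting into the active line and
    dividing by ``n1a*`` leaves a linear equation in ``n3*``.
    """
    thr = _epidemic_threshold(p)
    if thr is None:
        return None
    nbar_1a, _ = lv_equilibria(p)
    if not nbar_1a > thr:
        return None
    n1a = thr
    # (lam1 - mu1 - C n1a) = n3 * D (C n1a + v) / (r+v)
    n3 = (p.lambda1 - p.mu1 - p.C * n1a) * (p.r + p.v) / (p.D * (p.C * n1a + p.v))
    n1i = p.D * n1a * n3 / (p.r + p.v)
    return n1a, n1i, n3


def host2_virus_equilibrium(
        p: ModelParams) -> tuple[float, float, float, float] | None:
    """Mutant-plus-virus equilibrium ``(ñ2a, ñ2d, ñ2i, ñ3)`` or ``None``.

    Exists iff ``mv > r+v`` and ``nbar_2a > ñ2a``, with
    ``ñ2a = mu3(r+v)/((1-q) D (mv-(r+v)))``.  The dormant and infected
    densities are slaved to ``ñ3`` by their own stationarity; the active
    line then becomes linear in ``ñ3``.
    """
    thr = _epidemic_threshold(p)
    if thr is None:
        return None
    n2a = thr / (1 - p.q)
    _, nbar_2a = lv_equilibria(p)
    if not nbar_2a > n2a:
        return None
    kd = p.kappa * p.mu1 + p.sigma
    rv = p.r + p.v
    denom = p.D * (p.q * p.C * n2a / kd + (1 - p.q) * p.C * n2a / rv
                   + 1 - p.q * p.sigma / kd - (1 - p.q) * p.r / rv)
    n3 = (p.lambda2 - p.mu1 - p.C * n2a) / denom
    n2d = p.q * p.D * n2a * n3 / kd
    n2i = (1 - p.q) * p.D * n2a * n3 / rv
    return n2a, n2d, n2i, n3


def coexistence_equilibrium(p: ModelParams) -> np.ndarray | None:
    """The unique coordinatewise nonzero equilibrium ``x`` of the full
    system, or ``None`` when the resident-plus-virus equilibrium ``n*``
    does not exist (then the full system has no such rest point).

    The virion density has the closed form
    ``x3 = (lambda2-lambda1)/(qD) * (kappa mu1 + sigma)(r+v) /
    (r kappa mu1 - v sigma)``; the infected/dormant coordinates are slaved
    to ``(x1a, x2a, x3)`` by their linear stationarity lines, and
    ``(x1a, x2a)`` solve the remaining linear pair (the virion balance and
    the active-resident line).

    Raises
    ------
    DegenerateParameterError
        If ``r kappa mu1 == v sigma``.
    """
    if p.r * p.kappa * p.mu1 == p.v * p.sigma:
        raise DegenerateParameterError(
            "r*kappa*mu1 == v*sigma: coexistence virion density undefined")
    if host1_virus_equilibrium(p) is None:
        return None
    kd = p.kappa * p.mu1 + p.sigma
    rv = p.r + p.v
    x3 = ((p.lambda2 - p.lambda1) / (p.q * p.D) * kd * rv
          / (p.r * p.kappa * p.mu1 - p.v * p.sigma))
    thr = _epidemic_threshold(p)
    # host totals per unit of active density
    w1 = 1 + p.D * x3 / rv
    w2 = 1 + p.q * p.D * x3 / kd + (1 - p.q) * p.D * x3 / rv
    # active-resident stationarity: C (x1 + x2) = lam1 - mu1 - D x3 v/(r+v)
    total = (p.lambda1 - p.mu1 - p.D * x3 * p.v / rv) / p.C
    mat = np.array([[w1, w2], [1.0, 1.0 - p.q]])
    vec = np.array([total, thr])
    x1a, x2a = np.linalg.solve(mat, vec)
    x1i = p.D * x1a * x3 / rv
    x2d = p.q * p.D * x2a * x3 / kd
    x2i = (1 - p.q) * p.D * x2a * x3 / rv
    return np.array([x1a, x1i, x2a, x2d, x2i, x3])


@dataclass
class EquilibriumSet:
    """All named equilibria of a parameter set, with existence and
    positivity annotations."""

    nbar_1a: float
    nbar_2a: float
    host1_virus: tuple[float, float, float] | None
    host2_virus: tuple[float, float, float, float] | None
    coexistence: np.ndarray | None
    coex13: bool          # resident-plus-virus equilibrium exists
    coex23: bool          # mutant-plus-virus equilibrium exists
    x_positive: bool      # coexistence equilibrium coordinatewise positive

    def to_record(self) -> dict:
        """Flat record for CSV/JSON serialisation."""
        rec: dict = {"nbar_1a": self.nbar_1a, "nbar_2a": self.nbar_2a,
                     "coex13": self.coex13, "coex23": self.coex23,
                     "x_positive": self.x_positive}
        names1 = ("n1a_star", "n1i_star", "n3_star")
        rec.update(zip(names1, self.host1_virus or (np.nan,) * 3))
        names2 = ("n2a_tilde", "n2d_tilde", "n2i_tilde", "n3_tilde")
        rec.update(zip(names2, self.host2_virus or (np.nan,) * 4))
        namesx = ("x1a", "x1i", "x2a", "x2d", "x2i", "x3")
        x = self.coexistence if self.coexistence is not None else (np.nan,) * 6
        rec.update(zip(namesx, x))
        return rec


def equilibrium_set(p: ModelParams) -> EquilibriumSet:
    """Compute every named equilibrium and its classification."""
    nbar_1a, nbar_2a = lv_equilibria(p)
    h1 = host1_virus_equilibrium(p)
    h2 = host2_virus_equilibrium(p)
    x = coexistence_equilibrium(p)
    return EquilibriumSet(
        nbar_1a=nbar_1a, nbar_2a=nbar_2a,
        host1_virus=h1, host2_virus=h2, coexistence=x,
        coex13=h1 is not None, coex23=h2 is not None,
        x_positive=x is not None and bool(np.all(x > 0)),
    )
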