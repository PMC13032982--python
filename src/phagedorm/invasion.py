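"""Invasion fitness, extinction probabilities, timescales and regimes.

The fate of a rare invader host in a resident-plus-virus equilibrium is
governed by the invader block of the Jacobian of the deterministic limit
system at that equilibrium -- equivalently by the mean matrix of the
linear branching process that approximates the invader while rare:

* ``J*`` (3x3, types 2a/2d/2i against the frozen ``n*`` equilibrium) is
  the transpose of the Jacobian sub-block ``A``; its leading eigenvalue
  ``lambda*`` is the invasion fitness of the dormancy trait.
* ``J̃`` (2x2, types 1a/1i against the frozen ``ñ`` equilibrium) is the
  transpose of the sub-block ``F``; its leading eigenvalue ``λ̃`` is the
  invasion fitness of the resident against an established mutant.

Sign conditions on closed-form determinants, extinction probabilities of
the branching processes (smallest positive fixed point of the offspring
generating system) and logarithmic invasion timescales all derive from
these matrices.  A decision tree over the invasion conditions assigns
each parameter set its long-term regime (fixation, six-type coexistence,
virus-free fixation or founder control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import equilibria as eq
from .params import ModelParams

#: margins / real parts closer to zero than this are treated as critical
#: (non-hyperbolic) and never classified.
HYPERBOLICITY_TOL = 1e-9


def jacobian_full(n, p: ModelParams) -> np.ndarray:
    """Analytic 6x6 Jacobian of the full deterministic system at ``n``."""
    n1a, n1i, n2a, n2d, n2i, n3 = n
    S = n1a + n1i + n2a + n2d + n2i
    kd = p.kappa * p.mu1 + p.sigma
    rv = p.r + p.v
    pres1 = p.lambda1 - p.mu1 - p.C * S - p.D * n3
    pres2 = p.lambda2 - p.mu1 - p.C * S - p.D * n3
    return np.array([
        [pres1 - p.C * n1a, p.r - p.C * n1a, -p.C * n1a, -p.C * n1a,
         -p.C * n1a, -p.D * n1a],
        [p.D * n3, -rv, 0.0, 0.0, 0.0, p.D * n1a],
        [-p.C * n2a, -p.C * n2a, pres2 - p.C * n2a, p.sigma - p.C * n2a,
         p.r - p.C * n2a, -p.D * n2a],
        [0.0, 0.0, p.q * p.D * n3, -kd, 0.0, p.q * p.D * n2a],
        [0.0, 0.0, (1 - p.q) * p.D * n3, 0.0, -rv, (1 - p.q) * p.D * n2a],
        [-p.D * n3, p.m * p.v, -(1 - p.q) * p.D * n3, 0.0, p.m * p.v,
         -p.D * n1a - (1 - p.q) * p.D * n2a - p.mu3],
    ])


def matrix_A(p: ModelParams) -> np.ndarray:
    """Invader sub-block of the Jacobian at the ``n*`` equilibrium: the
    (2a, 2d, 2i) rows/columns of ``jacobian_full`` at
    ``(n1a*, n1i*, 0, 0, 0, n3*)``."""
    h1 = eq.host1_virus_equilibrium(p)
    if h1 is None:
        raise ValueError("resident-plus-virus equilibrium absent")
    n1a, n1i, n3 = h1
    return np.array([
        [p.lambda2 - p.mu1 - p.C * (n1a + n1i) - p.D * n3, p.sigma, p.r],
        [p.q * p.D * n3, -(p.kappa * p.mu1 + p.sigma), 0.0],
        [(1 - p.q) * p.D * n3, 0.0, -(p.r + p.v)],
    ])


def matrix_F(p: ModelParams) -> np.ndarray:
    """Resident sub-block of the Jacobian at the ``ñ`` equilibrium: the
    (1a, 1i) rows/columns of ``jacobian_full`` at ``(0, 0, ñ)``."""
    h2 = eq.host2_virus_equilibrium(p)
    if h2 is None:
        raise ValueError("mutant-plus-virus equilibrium absent")
    n2a, n2d, n2i, n3 = h2
    return np.array([
        [p.lambda1 - p.mu1 - p.C * (n2a + n2d + n2i) - p.D * n3, p.r],
        [p.D * n3, -(p.r + p.v)],
    ])


def matrix_Jstar(p: ModelParams) -> np.ndarray:
    """Mean matrix of the (2a, 2d, 2i) invader branching process
    (= transpose of :func:`matrix_A`)."""
    return matrix_A(p).T


def matrix_Jtilde(p: ModelParams) -> np.ndarray:
    """Mean matrix of the (1a, 1i) invader branching process
    (= transpose of :func:`matrix_F`)."""
    return matrix_F(p).T


def det_A_closed_form(p: ModelParams) -> float:
    """``det A = (lambda2-lambda1)(r+v)(kappa mu1+sigma) + q D n3*
    (v sigma - r kappa mu1)`` -- cross-check for :func:`matrix_A`."""
    h1 = eq.host1_virus_equilibrium(p)
    if h1 is None:
        raise ValueError("resident-plus-virus equilibrium absent")
    n3 = h1[2]
    return ((p.lambda2 - p.lambda1) * (p.r + p.v)
            * (p.kappa * p.mu1 + p.sigma)
            + p.q * p.D * n3 * (p.v * p.sigma - p.r * p.kappa * p.mu1))


def det_F_closed_form(p: ModelParams) -> float:
    """``det F = (lambda2-lambda1)(r+v) + q D ñ3 (v sigma - r kappa mu1)
    / (kappa mu1 + sigma)`` -- cross-check for :func:`matrix_F`."""
    h2 = eq.host2_virus_equilibrium(p)
    if h2 is None:
        raise ValueError("mutant-plus-virus equilibrium absent")
    n3 = h2[3]
    return ((p.lambda2 - p.lambda1) * (p.r + p.v)
            + p.q * p.D * n3 * (p.v * p.sigma - p.r * p.kappa * p.mu1)
            / (p.kappa * p.mu1 + p.sigma))


def leading_eigenvalue(mat: np.ndarray) -> float:
    """Largest real part among the eigenvalues.  For the mean matrices
    here the leading eigenvalue is real (their off-diagonal entries are
    non-negative, so Perron--Frobenius applies to ``M + rho*I``)."""
    return float(np.linalg.eigvals(mat).real.max())


@dataclass
class InvasionConditions:
    """The four invasion inequalities with signed diagnostic margins.

    The shared pivot quantity is ``q D n3 (v sigma - r kappa mu1) /
    ((r+v)(kappa mu1 + sigma))`` evaluated at the resident's equilibrium
    virion density ``n3``.  The dormancy trait invades a resident
    epidemic iff its fitness cost ``lambda1 - lambda2`` is below the
    pivot at ``n3*``; the trait-free host invades an established mutant
    epidemic iff the cost is above the pivot at ``ñ3``.  Margins are
    left-minus-right of each inequality; ``None`` marks a condition whose
    reference equilibrium does not exist ("not applicable").
    """

    inv2_yes: bool | None       # type 2 can invade type 1 + virus
    inv2_no: bool | None
    inv1_yes: bool | None       # type 1 can invade type 2 + virus
    inv1_no: bool | None
    margin2: float | None       # pivot(n3*) - (lambda1 - lambda2)
    margin1: float | None       # (lambda1 - lambda2) - pivot(ñ3)
    critical: bool = False      # some applicable margin within tolerance of 0


def _pivot(p: ModelParams, n3: float) -> float:
    return (p.q * p.D * n3 * (p.v * p.sigma - p.r * p.kappa * p.mu1)
            / ((p.r + p.v) * (p.kappa * p.mu1 + p.sigma)))


def invasion_conditions(p: ModelParams,
                        tol: float = HYPERBOLICITY_TOL) -> InvasionConditions:
    """Evaluate both invasion inequalities with signed margins."""
    cost = p.lambda1 - p.lambda2
    h1 = eq.host1_virus_equilibrium(p)
    h2 = eq.host2_virus_equilibrium(p)
    m2 = _pivot(p, h1[2]) - cost if h1 is not None else None
    m1 = cost - _pivot(p, h2[3]) if h2 is not None else None
    critical = any(m is not None and abs(m) < tol for m in (m2, m1))
    return InvasionConditions(
        inv2_yes=None if m2 is None else m2 > 0,
        inv2_no=None if m2 is None else m2 < 0,
        inv1_yes=None if m1 is None else m1 > 0,
        inv1_no=None if m1 is None else m1 < 0,
        margin2=m2, margin1=m1, critical=critical)


# ---------------------------------------------------------------------------
# Branching-process extinction probabilities
# ---------------------------------------------------------------------------

def _smallest_fixed_point(pgf, dim: int, tol: float = 1e-12,
                          max_iter: int = 10**6) -> np.ndarray:
    """Coordinatewise smallest fixed point of a monotone offspring
    generating map, by iteration from the zero vector.

    The map is coordinatewise non-decreasing on [0,1]^dim, so the iterates
    increase monotonically to the smallest fixed point.  A Newton polish
    on the residual finishes the convergence.
    """
    s = np.zeros(dim)
    for _ in range(max_iter):
        s_next = pgf(s)
        if np.max(np.abs(s_next - s)) < tol:
            s = s_next
            break
        s = s_next
    else:
        raise RuntimeError("fixed-point iteration did not converge")

    def residual(sv):
        return pgf(sv) - sv

    # Newton polish on the residual (finite-difference Jacobian)
    for _ in range(50):
        res = residual(s)
        if np.max(np.abs(res)) < 1e-15:
            break
        jac = np.empty((dim, dim))
        h = 1e-8
        for j in range(dim):
            sp = s.copy()
            sp[j] += h
            jac[:, j] = (residual(sp) - res) / h
        try:
            step = np.linalg.solve(jac, -res)
        except np.linalg.LinAlgError:
            break
        s_new = s + step
        if not np.all((s_new > 0) & (s_new <= 1 + 1e-12)):
            break
        s = s_new
    s = np.minimum(s, 1.0)
    # sub-/critical case: the smallest positive solution is exactly 1
    if np.all(s > 1 - 1e-9):
        return np.ones(dim)
    return s


def extinction_probability_type2(p: ModelParams) -> tuple[float, float, float]:
    """Extinction probabilities ``(s2a, s2d, s2i)`` of the dormancy-trait
    invader branching process, one per starting type.

    They form the coordinatewise smallest positive solution of the
    first-step system; equivalently the smallest fixed point of the
    embedded-jump-chain offspring generating map, found by monotone
    iteration from zero.  ``(1, 1, 1)`` in the subcritical case.
    """
    h1 = eq.host1_virus_equilibrium(p)
    if h1 is None:
        raise ValueError("resident-plus-virus equilibrium absent")
    n1a, n1i, n3 = h1
    death = p.mu1 + p.C * (n1a + n1i)
    inf_r = (1 - p.q) * p.D * n3
    dorm_r = p.q * p.D * n3
    tot_a = p.lambda2 + death + inf_r + dorm_r
    kd = p.kappa * p.mu1 + p.sigma
    rv = p.r + p.v

    def pgf(s):
        s2a, s2d, s2i = s
        return np.array([
            (p.lambda2 * s2a ** 2 + death + inf_r * s2i + dorm_r * s2d) / tot_a,
            (p.kappa * p.mu1 + p.sigma * s2a) / kd,
            (p.r * s2a + p.v) / rv,
        ])

    s = _smallest_fixed_point(pgf, 3)
    return float(s[0]), float(s[1]), float(s[2])


def extinction_probability_type1(
        p: ModelParams, literal_printed_system: bool = False
) -> tuple[float, float]:
    """Extinction probabilities ``(s1a, s1i)`` of the trait-free invader
    branching process against an established mutant epidemic.

    The competition pressure on the 1a invader uses the full resident
    total ``ñ2a + ñ2d + ñ2i``.  With ``literal_printed_system=True`` the
    dormant component is dropped from the pressure term (a published
    variant of the system), for reproducibility of that variant.
    """
    h2 = eq.host2_virus_equilibrium(p)
    if h2 is None:
        raise ValueError("mutant-plus-virus equilibrium absent")
    n2a, n2d, n2i, n3 = h2
    total = n2a + n2i if literal_printed_system else n2a + n2d + n2i
    death = p.mu1 + p.C * total
    inf_r = p.D * n3
    tot_a = p.lambda1 + death + inf_r
    rv = p.r + p.v

    def pgf(s):
        s1a, s1i = s
        return np.array([
            (p.lambda1 * s1a ** 2 + death + inf_r * s1i) / tot_a,
            (p.r * s1a + p.v) / rv,
        ])

    s = _smallest_fixed_point(pgf, 2)
    return float(s[0]), float(s[1])


# ---------------------------------------------------------------------------
# Timescales
# ---------------------------------------------------------------------------

@dataclass
class TimescalePrediction:
    """Logarithmic-in-K durations of the invasion phases.

    ``t_beta`` (theorem-backed): expected time for a successful invader to
    become macroscopic, ``log(K) / lambda_leading``.  ``t_fixation``
    (conjecture-backed): total time to fixation when only one direction
    can invade, ``(1/lambda_other + 1/lambda_leading) * log(K)``.
    """

    lambda_star: float | None
    lambda_tilde: float | None
    t_beta_type2: float | None       # (log K)/lambda*  [theorem-backed]
    t_beta_type1: float | None       # (log K)/lambda~  [theorem-backed]
    t_fixation: float | None         # (1/l~ + 1/l*) log K  [conjecture-backed]
    K: float


def timescales(p: ModelParams, K: float | None = None) -> TimescalePrediction:
    """Predicted invasion/fixation durations at carrying capacity ``K``.

    Entries are ``None`` ("not applicable") when the corresponding
    process is not supercritical or its resident equilibrium is absent.
    """
    K = float(K if K is not None else p.K)
    logk = np.log(K)
    try:
        lam_star = leading_eigenvalue(matrix_Jstar(p))
    except ValueError:
        lam_star = None
    try:
        lam_tilde = leading_eigenvalue(matrix_Jtilde(p))
    except ValueError:
        lam_tilde = None
    tb2 = logk / lam_star if lam_star is not None and lam_star > 0 else None
    tb1 = logk / lam_tilde if lam_tilde is not None and lam_tilde > 0 else None
    t_fix = (tb1 + tb2) if tb1 is not None and tb2 is not None else None
    return TimescalePrediction(lambda_star=lam_star, lambda_tilde=lam_tilde,
                               t_beta_type2=tb2, t_beta_type1=tb1,
                               t_fixation=t_fix, K=K)


# ---------------------------------------------------------------------------
# Regime classification
# ---------------------------------------------------------------------------

REGIMES = (
    "fixation_type1_with_virus",
    "coexistence_sixtype",
    "fixation_type2_with_virus",
    "fixation_type2a_virus_free",
    "founder_control",
    "no_persistent_epidemic",
    "degenerate",
)


@dataclass
class RegimeLabel:
    """Long-term outcome of the six-type system for one parameter set."""

    regime: str                        # one of REGIMES
    case: str | None = None            # "C" (mutant-virus eq. exists) or "D"
    subcase: str | None = None         # "(i)", "(ii)", "(iii)"
    color: str | None = None           # phase-diagram colour convention
    theorem_backed: bool = False       # invasion booleans are proven;
    #                                   fixation/coexistence outcomes are
    #                                   conjecture-backed
    note: str = ""


_COLORS = {
    ("fixation_type1_with_virus", "C"): "purple",
    ("fixation_type1_with_virus", "D"): "red",
    ("coexistence_sixtype", "C"): "darkgreen",
    ("coexistence_sixtype", "D"): "lightgreen",
    ("fixation_type2_with_virus", "C"): "blue",
    ("fixation_type2a_virus_free", "D"): "orange",
}


def classify_regime(p: ModelParams,
                    tol: float = HYPERBOLICITY_TOL) -> RegimeLabel:
    """Assign the long-term regime by the invasion decision tree.

    Outcomes beyond the invasion booleans themselves (which are
    theorem-backed) are conjecture-backed: fixation of the sole invading
    type, or stable six-type coexistence under mutual invasion.
    """
    if abs(p.r * p.kappa * p.mu1 - p.v * p.sigma) < tol:
        return RegimeLabel(regime="degenerate",
                           note="r*kappa*mu1 == v*sigma (virion balance "
                                "degenerate)")
    h1 = eq.host1_virus_equilibrium(p)
    if h1 is None:
        return RegimeLabel(regime="no_persistent_epidemic",
                           note="resident-plus-virus equilibrium absent; "
                                "no coordinatewise positive equilibrium "
                                "exists")
    cond = invasion_conditions(p, tol=tol)
    if cond.critical:
        return RegimeLabel(regime="degenerate",
                           note="invasion margin within tolerance of zero "
                                "(non-hyperbolic)")
    case = "C" if eq.host2_virus_equilibrium(p) is not None else "D"
    inv2 = bool(cond.inv2_yes)
    if case == "C":
        inv1 = bool(cond.inv1_yes)
        if inv2 and inv1:
            lab = RegimeLabel("coexistence_sixtype", case, "(iii)")
        elif inv2:
            lab = RegimeLabel("fixation_type2_with_virus", case, "(ii)")
        elif inv1:
            lab = RegimeLabel("fixation_type1_with_virus", case, "(i)")
        else:
            # both non-invasion conditions: requires lambda2 > lambda1
            # and r*kappa*mu1 > v*sigma
            lab = RegimeLabel("founder_control", case, None,
                              note="neither host can invade the other's "
                                   "epidemic equilibrium")
    else:
        if inv2:
            if p.lambda2 > p.lambda1:
                lab = RegimeLabel("fixation_type2a_virus_free", case, "(ii)",
                                  note="mutant wins and the epidemic "
                                       "collapses (virus-free fixation)")
            else:
                lab = RegimeLabel("coexistence_sixtype", case, "(iii)")
        else:
            lab = RegimeLabel("fixation_type1_with_virus", case, "(i)")
    lab.color = _COLORS.get((lab.regime, lab.case))
    return lab


@dataclass
class InvasionReport:
    """Complete single-parameter-set invasion analysis."""

    conditions: InvasionConditions
    s2a: float | None
    s2d: float | None
    s2i: float | None
    s1a: float | None
    s1i: float | None
    lambda_star: float | None
    lambda_tilde: float | None
    invasion_probability_type2: float | None    # 1 - s2a
    invasion_probability_type1: float | None    # 1 - s1a
    timescale: TimescalePrediction
    regime: RegimeLabel
    hyperbolic: bool

    def to_record(self) -> dict:
        return {
            "inv2_yes": self.conditions.inv2_yes,
            "inv1_yes": self.conditions.inv1_yes,
            "margin2": self.conditions.margin2,
            "margin1": self.conditions.margin1,
            "s2a": self.s2a, "s2d": self.s2d, "s2i": self.s2i,
            "s1a": self.s1a, "s1i": self.s1i,
            "lambda_star": self.lambda_star,
            "lambda_tilde": self.lambda_tilde,
            "p_invade_type2": self.invasion_probability_type2,
            "p_invade_type1": self.invasion_probability_type1,
            "t_beta_type2": self.timescale.t_beta_type2,
            "t_beta_type1": self.timescale.t_beta_type1,
            "regime": self.regime.regime,
            "case": self.regime.case,
            "subcase": self.regime.subcase,
            "color": self.regime.color,
        }


def invasion_report(p: ModelParams, K: float | None = None) -> InvasionReport:
    """Run the full invasion analysis for one parameter set."""
    try:
        s2 = extinction_probability_type2(p)
    except ValueError:
        s2 = (None, None, None)
    try:
        s1 = extinction_probability_type1(p)
    except ValueError:
        s1 = (None, None)
    ts = timescales(p, K)
    cond = invasion_conditions(p)
    return InvasionReport(
        conditions=cond,
        s2a=s2[0], s2d=s2[1], s2i=s2[2], s1a=s1[0], s1i=s1[1],
        lambda_star=ts.lambda_star, lambda_tilde=ts.lambda_tilde,
        invasion_probability_type2=None if s2[0] is None else 1 - s2[0],
        invasion_probability_type1=None if s1[0] is None else 1 - s1[0],
        timescale=ts, regime=classify_regime(p),
        hyperbolic=not cond.critical)


# ---------------------------------------------------------------------------
# Phase-diagram scan
# ---------------------------------------------------------------------------

def boundary_coex23_lambda2(p: ModelParams, q: float) -> float:
    """The ``lambda2`` value where the mutant-plus-virus equilibrium
    appears (``nbar_2a = ñ2a``): ``mu1 + C mu3 (r+v) /
    ((1-q) D (mv - (r+v)))``.  Separates the case-C and case-D regimes in
    a ``(lambda2, q)`` phase diagram."""
    surplus = p.m * p.v - (p.r + p.v)
    if surplus <= 0:
        return np.inf
    return p.mu1 + p.C * p.mu3 * (p.r + p.v) / ((1 - q) * p.D * surplus)


def scan_phase_diagram(p_base: ModelParams, axis1: tuple[str, float, float],
                       axis2: tuple[str, float, float],
                       n1: int = 40, n2: int | None = None):
    """Classify the regime over a rectangular parameter grid.

    ``axis1``/``axis2`` are ``(field_name, low, high)``; the grid has
    ``n1 x n2`` cells.  Returns a pandas DataFrame with one classified
    row per grid point plus key scalars (x3, n3*, ñ3, s2a, s1a,
    eigenvalues).  Degenerate points are labelled, never dropped.
    """
    import pandas as pd
    n2 = n2 or n1
    name1, lo1, hi1 = axis1
    name2, lo2, hi2 = axis2
    rows = []
    for val1 in np.linspace(lo1, hi1, n1):
        for val2 in np.linspace(lo2, hi2, n2):
            kwargs = {name1: float(val1), name2: float(val2)}
            if "m" in kwargs:
                kwargs["m"] = int(round(kwargs["m"]))
            try:
                p = p_base.replace(**kwargs)
            except Exception as err:
                rows.append({name1: val1, name2: val2, "regime": "invalid",
                             "note": str(err)})
                continue
            row = {name1: val1, name2: val2}
            try:
                rep = invasion_report(p)
                row.update(rep.to_record())
                es = eq.equilibrium_set(p)
                row["n3_star"] = es.host1_virus[2] if es.coex13 else np.nan
                row["n3_tilde"] = es.host2_virus[3] if es.coex23 else np.nan
                row["x3"] = (es.coexistence[5]
                             if es.coexistence is not None else np.nan)
            except eq.DegenerateParameterError as err:
                row.update({"regime": "degenerate", "note": str(err)})
            rows.append(row)
    return pd.DataFrame(rows)
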