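"""Model parameters, scenario presets and plain-text configuration I/O.

The model tracks six sub-populations of a microbial host--virus system:
active residents (1a), infected residents (1i), active mutants carrying a
contact-mediated dormancy trait (2a), dormant mutants (2d), infected
mutants (2i) and free virions (3).  All dynamics are governed by the rate
constants collected in :class:`ModelParams`.

Convention for the dormancy probability ``q``: upon a virion contact with
an active type-2 host, the host escapes into dormancy with probability
``q`` (the virion is repelled) and becomes infected with probability
``1 - q`` (the virion is consumed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


class ParameterError(ValueError):
    """A hard violation of the model's parameter domain."""


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the host--virus--dormancy model.

    Parameters
    ----------
    lambda1, lambda2
        Birth rates of active residents (1a) and active mutants (2a),
        per unit time.  The dormancy trait is usually assumed costly,
        ``lambda2 < lambda1``, but the reverse ordering is representable
        (founder-control regime).
    mu1
        Natural death rate of active hosts.
    C
        Competition strength; each active host dies from competition at
        rate ``C/K`` per (host) competitor.
    D
        Host--virion contact rate; contacts occur at rate ``D/K`` per
        host--virion pair.
    q
        Probability in (0, 1) that a virion contact with a 2a host leads
        to dormancy rather than infection.
    r
        Recovery rate of infected hosts (the internalised virion is
        destroyed on recovery).
    v
        Lysis rate of infected hosts.
    m
        Burst size: number of virions released instantaneously at lysis.
    sigma
        Resuscitation rate of dormant hosts.
    kappa
        Non-negative factor scaling the dormant death rate
        (dormant hosts die at rate ``kappa * mu1``).
    mu3
        Degradation rate of free virions.
    K
        Carrying capacity: the scaling parameter of the stochastic model;
        population sizes are of order ``K``.
    """

    lambda1: float
    lambda2: float
    mu1: float
    C: float
    D: float
    q: float
    r: float
    v: float
    m: int
    sigma: float
    kappa: float
    mu3: float
    K: float = 1000.0

    def __post_init__(self) -> None:
        problems = _hard_errors(self)
        if problems:
            raise ParameterError("; ".join(problems))

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_RATE_FIELDS = ("lambda1", "lambda2", "mu1", "C", "D", "r", "v",
                "sigma", "kappa", "mu3")
_STRICTLY_POSITIVE = ("lambda1", "lambda2", "D", "C", "v", "sigma", "mu3")


def _hard_errors(p: ModelParams) -> list[str]:
    errs = []
    for name in _RATE_FIELDS:
        if getattr(p, name) < 0:
            errs.append(f"{name} must be non-negative, got {getattr(p, name)}")
    for name in _STRICTLY_POSITIVE:
        if getattr(p, name) <= 0:
            errs.append(f"{name} must be strictly positive, got {getattr(p, name)}")
    if not (0.0 < p.q < 1.0):
        errs.append(f"q must lie strictly inside (0, 1), got {p.q}")
    if not (isinstance(p.m, int) and not isinstance(p.m, bool)):
        errs.append(f"m must be an integer, got {p.m!r}")
    elif p.m < 1:
        errs.append(f"m must be a positive integer, got {p.m}")
    if p.K <= 0:
        errs.append(f"K must be positive, got {p.K}")
    return errs


def validate_params(p: ModelParams) -> list[str]:
    """Check the standing parameter ordering and return warnings.

    Hard domain violations are already rejected by the ``ModelParams``
    constructor.  The ordering ``0 < mu1 < lambda2 < lambda1`` assumed
    throughout the asymptotic analysis is *not* enforced: a reversed
    birth-rate ordering (``lambda2 > lambda1``) is a valid input that
    produces the founder-control and virus-free-fixation regimes.
    Violations are reported here as warnings.
    """
    warnings = []
    if p.mu1 >= p.lambda2:
        warnings.append(
            f"mu1 = {p.mu1} >= lambda2 = {p.lambda2}: the mutant host is "
            "not viable on its own")
    if p.lambda2 >= p.lambda1:
        warnings.append(
            f"lambda2 = {p.lambda2} >= lambda1 = {p.lambda1}: dormancy "
            "carries no reproductive cost (founder-control territory)")
    return warnings


# Base parameters shared by all study scenarios; lambda2 and q vary.
_BASE = dict(lambda1=3.15, mu1=1.0, C=1.0, D=0.5, r=1.0, v=1.0,
             kappa=0.1, sigma=2.0, m=10, mu3=0.5, K=1000.0)

#: (lambda2, q) pairs of the named study scenarios, each exemplifying one
#: long-term regime of the six-type system.
SCENARIOS: dict[str, tuple[float, float]] = {
    "fig2_darkgreen": (2.55, 0.6),   # stable six-type coexistence
    "fig3_blue": (3.0, 0.2),         # fixation of type 2 (with virus)
    "fig4_purple": (2.0, 0.4),       # fixation of type 1 (with virus)
    "fig5_lightgreen": (2.2, 0.9),   # coexistence without a 2-3 subsystem equilibrium
    "fig6_red": (1.2, 0.4),          # fixation of type 1; type 2 cannot host the virus
}


def scenario(name: str, lambda2: float | None = None,
             q: float | None = None) -> ModelParams:
    """Return the parameter set of a named scenario.

    ``fig1_base`` leaves ``lambda2`` and ``q`` free (both must then be
    supplied); the other names fix them to the study values.
    """
    if name == "fig1_base":
        if lambda2 is None or q is None:
            raise ValueError("fig1_base requires explicit lambda2 and q")
        return ModelParams(lambda2=lambda2, q=q, **_BASE)
    try:
        l2, qq = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from "
            f"{['fig1_base', *SCENARIOS]}") from None
    if lambda2 is not None or q is not None:
        raise ValueError(f"scenario {name!r} fixes lambda2 and q")
    return ModelParams(lambda2=l2, q=qq, **_BASE)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(ModelParams)}


def save_config(p: ModelParams, path: str | Path) -> None:
    """Write the parameters as a flat ``key = value`` text file."""
    lines = [f"{k} = {v!r}" for k, v in p.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> ModelParams:
    """Read a flat ``key = value`` config written by :func:`save_config`.

    Unknown keys are rejected; every field except ``K`` is required;
    ``m`` must parse as an integer.
    """
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, text = line.partition("=")
        key, text = key.strip(), text.strip()
        if key not in _FIELD_TYPES:
            raise ParameterError(f"line {lineno}: unknown parameter {key!r}")
        if key in values:
            raise ParameterError(f"line {lineno}: duplicate parameter {key!r}")
        if key == "m":
            try:
                values[key] = int(text)
            except ValueError:
                raise ParameterError(
                    f"m must be an integer, got {text!r}") from None
        else:
            try:
                values[key] = float(text)
            except ValueError:
                raise ParameterError(
                    f"{key} must be a number, got {text!r}") from None
    missing = [k for k in _FIELD_TYPES
               if k not in values and k != "K"]
    if missing:
        raise ParameterError(f"missing required parameter(s): {', '.join(missing)}")
    return ModelParams(**values)
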