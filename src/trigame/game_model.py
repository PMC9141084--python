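"""Core game model: parameters, payoffs, expected utilities and replicator rates.

Three populations interact over the adoption of environmentally friendly
masks (EFMs):

* **governments** choose to *regulate* or *deregulate* production and use,
* **enterprises** choose to *increase* EFM production or not,
* **institutions** (medical institutions) choose to *use EFMs* or regular
  masks.

The state of the system is the triple of adoption proportions
``(x, y, z)`` and the dynamics are standard replicator equations: each
proportion grows in proportion to the payoff advantage of its focal action
over the population mean.

Two algebraic variants of the enterprise replicator rate are provided (see
:data:`AS_PRINTED` and :data:`TABLE2_CONSISTENT`).  They differ by the term
``y*(1 - y)*(1 - z)*P*q``; :func:`check_payoff_replicator_consistency`
quantifies the discrepancy instead of hiding it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

__all__ = [
    "PARAM_FIELDS",
    "AS_PRINTED",
    "TABLE2_CONSISTENT",
    "VARIANTS",
    "GOVERNMENT",
    "ENTERPRISE",
    "INSTITUTION",
    "PLAYERS",
    "ParameterValidationError",
    "ParameterSet",
    "StrategyState",
    "Payoffs",
    "PayoffTable",
    "ExpectedUtilities",
    "ConsistencyRecord",
    "build_payoff_table",
    "expected_utilities",
    "replicator_rate_government",
    "replicator_rate_enterprise",
    "replicator_rate_institution",
    "replicator_field",
    "check_payoff_replicator_consistency",
    "load_parameters",
    "save_parameters",
]

#: Canonical field order of the exogenous model constants.
PARAM_FIELDS = (
    "R", "H", "GC", "GH", "P", "C", "CG", "CS",
    "d", "rc", "f1", "f2", "q", "alpha", "beta",
)

#: Enterprise replicator rate exactly as used for the reference eigenvalue
#: table (treats the opportunity-cost term ``P`` as state independent).
AS_PRINTED = "as_printed"
#: Enterprise replicator rate derived from the payoff table (the ``P`` term
#: is weighted by the consumer proportion ``z``).
TABLE2_CONSISTENT = "table2_consistent"
VARIANTS = (AS_PRINTED, TABLE2_CONSISTENT)

GOVERNMENT = "government"
ENTERPRISE = "enterprise"
INSTITUTION = "institution"
PLAYERS = (GOVERNMENT, ENTERPRISE, INSTITUTION)

# Pure strategy labels, adopt-action first.
GOV_STRATEGIES = ("regulate", "deregulate")
ENT_STRATEGIES = ("increase", "no_increase")
INST_STRATEGIES = ("efm", "regular")


class ParameterValidationError(ValueError):
    """A model constant violates its sign/positivity constraint.

    Attributes
    ----------
    field : str
        Name of the offending parameter.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"parameter {field!r}: {message}")


@dataclass(frozen=True)
class ParameterSet:
    """The 15 exogenous constants of the game (monetary values per mask).

    ``rc`` (the net cost benefit of reusing EFMs) is the only field that may
    be negative; every other monetary constant must be non-negative, the two
    coefficients ``alpha``/``beta`` and the volume ``q`` strictly positive.
    """

    R: float      #: environmental benefit of EFM use
    H: float      #: reputation damage from government inaction
    GC: float     #: subsidy for producing EFMs
    GH: float     #: subsidy for using EFMs
    P: float      #: average price of a regular mask
    C: float      #: average cost of a regular mask
    CG: float     #: government regulation cost
    CS: float     #: production machine transformation cost
    d: float      #: institution management cost
    rc: float     #: cost benefit of using EFMs (may be negative)
    f1: float     #: environmental penalty on institutions not using EFMs
    f2: float     #: liquidated damages for terminating regular-mask orders
    q: float = 1.0       #: number of EFMs used (> 0)
    alpha: float = 1.5   #: price increase coefficient of EFMs
    beta: float = 1.5    #: cost increase coefficient of EFMs

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ParameterValidationError(name, f"expected a number, got {value!r}")
            if not math.isfinite(value):
                raise ParameterValidationError(name, f"must be finite, got {value!r}")
            object.__setattr__(self, name, float(value))
        if self.q <= 0:
            raise ParameterValidationError("q", f"must be > 0, got {self.q}")
        for name in ("alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ParameterValidationError(name, f"must be > 0, got {getattr(self, name)}")
        for name in ("R", "H", "GC", "GH", "P", "C", "CG", "CS", "d", "f1", "f2"):
            if getattr(self, name) < 0:
                raise ParameterValidationError(name, f"must be >= 0, got {getattr(self, name)}")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ParameterSet":
        unknown = sorted(set(data) - set(PARAM_FIELDS))
        if unknown:
            raise ParameterValidationError(unknown[0], "unknown parameter key")
        missing = [name for name in PARAM_FIELDS if name not in data]
        if missing:
            raise ParameterValidationError(missing[0], "missing from parameter mapping")
        return cls(**{name: data[name] for name in PARAM_FIELDS})


@dataclass(frozen=True)
class StrategyState:
    """Adoption proportions ``(x, y, z)``, each in the closed unit interval.

    ``x``: share of regulating governments; ``y``: share of enterprises
    increasing EFM production; ``z``: share of institutions using EFMs.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            value = getattr(self, name)
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"proportion {name}={value!r} outside [0, 1]")
            object.__setattr__(self, name, float(value))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


class Payoffs(NamedTuple):
    """Per-run payoffs of one pure-strategy profile, in player order."""

    government: float
    enterprise: float
    institution: float


StrategyProfile = tuple[str, str, str]


@dataclass(frozen=True)
class PayoffTable:
    """Payoffs of all eight pure-strategy profiles.

    Keys are ``(government, enterprise, institution)`` action labels drawn
    from :data:`GOV_STRATEGIES`, :data:`ENT_STRATEGIES` and
    :data:`INST_STRATEGIES`.  Values are already multiplied by the mask
    volume ``q``.
    """

    entries: Mapping[StrategyProfile, Payoffs]

    def __post_init__(self) -> None:
        expected = {
            (g, e, i)
            for g in GOV_STRATEGIES
            for e in ENT_STRATEGIES
            for i in INST_STRATEGIES
        }
        if set(self.entries) != expected:
            raise ValueError("payoff table must contain exactly the 8 pure profiles")

    def __getitem__(self, profile: StrategyProfile) -> Payoffs:
        return self.entries[profile]


class ExpectedUtilities(NamedTuple):
    """Expected payoff of the focal action, of the alternative, and the mix."""

    u_adopt: float
    u_decline: float
    u_mean: float


def build_payoff_table(params: ParameterSet) -> PayoffTable:
    """Construct the 8-entry payoff table from the model constants.

    In the (regulate, no_increase, efm) cell the institution pays the
    liquidated damages ``f2`` (the term enters with a minus sign), matching
    the expected-utility expansion used by the replicator rates.
    """
    p = params
    q = p.q
    entries: dict[StrategyProfile, Payoffs] = {
        ("regulate", "increase", "efm"): Payoffs(
            (p.R - p.GC - p.GH - p.CG) * q,
            (p.alpha * p.P + p.GC - p.beta * p.C - p.CS) * q,
            (p.GH - p.alpha * p.P - p.d + p.rc) * q,
        ),
        ("regulate", "increase", "regular"): Payoffs(
            (p.f1 - p.GC - p.CG) * q,
            (p.GC - p.beta * p.C - p.CS) * q,
            -p.f1 * q,
        ),
        ("regulate", "no_increase", "efm"): Payoffs(
            (p.R - p.GH - p.CG) * q,
            (p.f2 - p.P) * q,
            (p.GH - p.alpha * p.P - p.d + p.rc - p.f2) * q,
        ),
        ("regulate", "no_increase", "regular"): Payoffs(
            (p.f1 - p.CG) * q,
            0.0,
            -p.f1 * q,
        ),
        ("deregulate", "increase", "efm"): Payoffs(
            (p.R - p.H) * q,
            (p.alpha * p.P - p.beta * p.C - p.CS) * q,
            (-p.alpha * p.P - p.d + p.rc) * q,
        ),
        ("deregulate", "increase", "regular"): Payoffs(
            -p.H * q,
            (-p.beta * p.C - p.CS) * q,
            0.0,
        ),
        ("deregulate", "no_increase", "efm"): Payoffs(
            (p.R - p.H) * q,
            (p.f2 - p.P) * q,
            (-p.alpha * p.P - p.d + p.rc - p.f2) * q,
        ),
        ("deregulate", "no_increase", "regular"): Payoffs(
            -p.H * q,
            0.0,
            0.0,
        ),
    }
    return PayoffTable(entries)


def expected_utilities(
    params: ParameterSet, state: StrategyState, player: str
) -> ExpectedUtilities:
    """Expected payoffs of the named player at the given mixed state.

    ``u_adopt`` is the expected payoff of the focal action (regulate /
    increase / use EFMs) against the other two populations, ``u_decline``
    that of the alternative, and ``u_mean`` the share-weighted mean using
    the player's own proportion.
    """
    if player not in PLAYERS:
        raise ValueError(f"unknown player {player!r}; expected one of {PLAYERS}")
    table = build_payoff_table(params)
    x, y, z = state.as_tuple()

    def mix(gov: str | None, ent: str | None, inst: str | None) -> float:
        """Expected payoff of a profile with one slot fixed, others mixed."""
        total = 0.0
        for g, wg in (("regulate", x), ("deregulate", 1.0 - x)):
            for e, we in (("increase", y), ("no_increase", 1.0 - y)):
                for i, wi in (("efm", z), ("regular", 1.0 - z)):
                    if gov is not None and g != gov:
                        continue
                    if ent is not None and e != ent:
                        continue
                    if inst is not None and i != inst:
                        continue
                    weight = 1.0
                    if gov is None:
                        weight *= wg
                    if ent is None:
                        weight *= we
                    if inst is None:
                        weight *= wi
                    payoff = table[(g, e, i)]
                    total += weight * getattr(payoff, player)
        return total

    if player == GOVERNMENT:
        u1, u2, share = mix("regulate", None, None), mix("deregulate", None, None), x
    elif player == ENTERPRISE:
        u1, u2, share = mix(None, "increase", None), mix(None, "no_increase", None), y
    else:
        u1, u2, share = mix(None, None, "efm"), mix(None, None, "regular"), z
    return ExpectedUtilities(u1, u2, share * u1 + (1.0 - share) * u2)


# ---------------------------------------------------------------------------
# Replicator rate factors (the "bracket" of each rate, per unit q)
# ---------------------------------------------------------------------------

def government_rate_factor(params: ParameterSet, y: float, z: float) -> float:
    p = params
    return p.H + p.f1 - p.CG - z * p.GH - z * p.f1 - y * p.GC


def enterprise_rate_factor(
    params: ParameterSet, x: float, z: float, variant: str = AS_PRINTED
) -> float:
    p = params
    base = x * p.GC + z * p.alpha * p.P - z * p.f2 - p.beta * p.C - p.CS
    if variant == AS_PRINTED:
        return base + p.P
    if variant == TABLE2_CONSISTENT:
        return base + z * p.P
    raise ValueError(f"unknown enterprise variant {variant!r}; expected one of {VARIANTS}")


def institution_rate_factor(params: ParameterSet, x: float, y: float) -> float:
    p = params
    return x * p.GH + x * p.f1 + y * p.f2 - p.alpha * p.P - p.d + p.rc - p.f2


def replicator_rate_government(params: ParameterSet, state: StrategyState) -> float:
    """dx/dt: growth rate of the regulating share."""
    x = state.x
    return x * (1.0 - x) * government_rate_factor(params, state.y, state.z) * params.q


def replicator_rate_enterprise(
    params: ParameterSet, state: StrategyState, variant: str = AS_PRINTED
) -> float:
    """dy/dt: growth rate of the EFM-producing share, under either variant."""
    y = state.y
    return (
        y * (1.0 - y)
        * enterprise_rate_factor(params, state.x, state.z, variant)
        * params.q
    )


def replicator_rate_institution(params: ParameterSet, state: StrategyState) -> float:
    """dz/dt: growth rate of the EFM-using share."""
    z = state.z
    return z * (1.0 - z) * institution_rate_factor(params, state.x, state.y) * params.q


def replicator_field(
    params: ParameterSet, state: StrategyState, variant: str = AS_PRINTED
) -> tuple[float, float, float]:
    """Right-hand side ``(dx/dt, dy/dt, dz/dt)`` of the replicator ODE."""
    return (
        replicator_rate_government(params, state),
        replicator_rate_enterprise(params, state, variant),
        replicator_rate_institution(params, state),
    )


class ConsistencyRecord(NamedTuple):
    """Residual of one (state, player) pair in the consistency check."""

    state: StrategyState
    player: str
    rate: float
    payoff_rate: float
    residual: float


def check_payoff_replicator_consistency(
    params: ParameterSet,
    states: Iterable[StrategyState],
    variant: str = AS_PRINTED,
) -> list[ConsistencyRecord]:
    """Compare the closed-form rates with ``share*(1-share)*(U1-U2)``.

    The expected utilities are always computed from the payoff table, so
    government and institution residuals vanish to numerical precision while
    the enterprise residual under :data:`AS_PRINTED` equals
    ``y*(1-y)*(1-z)*P*q`` exactly.
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one state")
    out: list[ConsistencyRecord] = []
    for state in states:
        for player in PLAYERS:
            u = expected_utilities(params, state, player)
            share = getattr(state, {"government": "x", "enterprise": "y", "institution": "z"}[player])
            payoff_rate = share * (1.0 - share) * (u.u_adopt - u.u_decline)
            if player == GOVERNMENT:
                rate = replicator_rate_government(params, state)
            elif player == ENTERPRISE:
                rate = replicator_rate_enterprise(params, state, variant)
            else:
                rate = replicator_rate_institution(params, state)
            out.append(ConsistencyRecord(state, player, rate, payoff_rate, rate - payoff_rate))
    return out


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------

def load_parameters(path: str | Path) -> ParameterSet:
    """Load a flat YAML/JSON parameter file with exactly the 15 model keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterValidationError("<file>", f"expected a mapping in {path}")
    return ParameterSet.from_dict(data)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the parameter set as a flat JSON document (valid YAML too)."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=2, sort_keys=False) + "\n")
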