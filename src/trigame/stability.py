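"""Equilibrium classification, regulation thresholds and sensitivity signs.

The replicator system has eight pure-strategy fixed points (the corners of
the unit cube).  At a corner the Jacobian of the field is diagonal, so its
eigenvalues are the three marginal stability derivatives and a corner is an
evolutionarily stable strategy (ESS) exactly when all three are negative.

The module also exposes the analytic indifference thresholds of each player
(the mixing proportion of one opponent at which the focal player is
indifferent), the critical reputation loss above which regulation dominates
for the government, the six midpoint "region proportion" summaries used for
comparative statics, and finite-difference sensitivity signs for those
summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .game_model import (
    AS_PRINTED,
    TABLE2_CONSISTENT,
    ENTERPRISE,
    GOVERNMENT,
    INSTITUTION,
    PLAYERS,
    ParameterSet,
    ParameterValidationError,
    StrategyState,
    enterprise_rate_factor,
    government_rate_factor,
    institution_rate_factor,
)

__all__ = [
    "CORNER_ORDER",
    "STABLE",
    "SADDLE",
    "NON_HYPERBOLIC",
    "ZERO_EIGENVALUE_TOL",
    "DegenerateThresholdError",
    "EquilibriumRecord",
    "ThresholdSet",
    "SensitivitySign",
    "EXPECTED_SENSITIVITY_SIGNS",
    "marginal_stability_derivative",
    "jacobian",
    "classify_pure_equilibria",
    "regulation_thresholds",
    "critical_reputation_loss",
    "regulation_dominates",
    "midpoint_region_proportions",
    "sensitivity_signs",
    "equilibria_to_json",
    "render_equilibria_table",
]

#: Corner enumeration order used in reports (O1..O8).
CORNER_ORDER: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1),
)

STABLE = "stable"
SADDLE = "saddle"
NON_HYPERBOLIC = "non-hyperbolic"

#: |eigenvalue| below this is treated as exactly zero (degenerate corner).
ZERO_EIGENVALUE_TOL = 1e-9


class DegenerateThresholdError(ZeroDivisionError):
    """A threshold formula degenerates (division by a vanishing constant)."""


@dataclass(frozen=True)
class EquilibriumRecord:
    """One corner fixed point with its eigenvalues and stability attribute."""

    corner: StrategyState
    eigenvalues: tuple[float, float, float]  # player order (gov, ent, inst)
    attribute: str

    def is_stable(self) -> bool:
        return self.attribute == STABLE


@dataclass(frozen=True)
class ThresholdSet:
    """Indifference thresholds and midpoint region proportions.

    ``lambda_y`` / ``lambda_z`` are the government indifference thresholds
    in the producer / consumer proportion; the ``v``/``w`` fields are the
    six midpoint region proportions (one minus the indifference root of a
    player, with the remaining opponent proportion fixed at one half).
    Fields not produced by the constructing operation are ``None``.  Values
    are reported unclipped; a value above 1 (below 0) means the favored
    regime holds for every admissible proportion.
    """

    lambda_y: float | None = None
    lambda_z: float | None = None
    v11: float | None = None
    v12: float | None = None
    w21: float | None = None
    w22: float | None = None
    w31: float | None = None
    w32: float | None = None

    def clipped(self) -> "ThresholdSet":
        """Copy with every non-None field clipped to [0, 1] (for plotting)."""
        changes = {
            f.name: min(1.0, max(0.0, getattr(self, f.name)))
            for f in dataclasses.fields(self)
            if getattr(self, f.name) is not None
        }
        return dataclasses.replace(self, **changes)


class SensitivitySign(NamedTuple):
    """Sign of a midpoint region proportion's partial derivative."""

    quantity: str
    parameter: str
    sign: str  # one of "+", "-", "0"
    derivative: float


#: Expected correlation signs of the region proportions at the baseline.
EXPECTED_SENSITIVITY_SIGNS: tuple[tuple[str, str, str], ...] = (
    ("v11", "H", "+"),
    ("v11", "CG", "-"),
    ("v11", "GC", "-"),
    ("v12", "GH", "-"),
    ("v12", "f1", "+"),
    ("w21", "f2", "-"),
    ("w21", "beta", "-"),
    ("w21", "CS", "-"),
    ("w21", "alpha", "+"),
    ("w21", "P", "+"),
    ("w22", "GC", "+"),
    ("w31", "alpha", "-"),
    ("w31", "d", "-"),
    ("w31", "rc", "+"),
    ("w31", "f2", "-"),
    ("w32", "GH", "+"),
    ("w32", "f1", "+"),
)

_SHARE_OF = {GOVERNMENT: "x", ENTERPRISE: "y", INSTITUTION: "z"}


def _rate_factor(
    params: ParameterSet, state: StrategyState, player: str, variant: str
) -> float:
    if player == GOVERNMENT:
        return government_rate_factor(params, state.y, state.z)
    if player == ENTERPRISE:
        return enterprise_rate_factor(params, state.x, state.z, variant)
    if player == INSTITUTION:
        return institution_rate_factor(params, state.x, state.y)
    raise ValueError(f"unknown player {player!r}; expected one of {PLAYERS}")


def marginal_stability_derivative(
    params: ParameterSet,
    state: StrategyState,
    player: str,
    variant: str = AS_PRINTED,
) -> float:
    """Diagonal Jacobian entry ``(1 - 2s) * factor * q`` for one player."""
    share = getattr(state, _SHARE_OF[player])
    return (1.0 - 2.0 * share) * _rate_factor(params, state, player, variant) * params.q


def jacobian(
    params: ParameterSet, state: StrategyState, variant: str = AS_PRINTED
) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at ``state``.

    Rows/columns follow (x, y, z).  At any corner the off-diagonal factors
    ``s*(1-s)`` vanish, leaving the marginal stability derivatives on the
    diagonal.
    """
    p = params
    x, y, z = state.as_tuple()
    q = p.q
    gx = x * (1.0 - x)
    gy = y * (1.0 - y)
    gz = z * (1.0 - z)
    dyz_coeff = p.alpha * p.P - p.f2
    if variant == TABLE2_CONSISTENT:
        dyz_coeff += p.P
    J = np.empty((3, 3))
    J[0, 0] = marginal_stability_derivative(p, state, GOVERNMENT, variant)
    J[0, 1] = -gx * p.GC * q
    J[0, 2] = -gx * (p.GH + p.f1) * q
    J[1, 0] = gy * p.GC * q
    J[1, 1] = marginal_stability_derivative(p, state, ENTERPRISE, variant)
    J[1, 2] = gy * dyz_coeff * q
    J[2, 0] = gz * (p.GH + p.f1) * q
    J[2, 1] = gz * p.f2 * q
    J[2, 2] = marginal_stability_derivative(p, state, INSTITUTION, variant)
    return J


def classify_pure_equilibria(
    params: ParameterSet, variant: str = AS_PRINTED
) -> list[EquilibriumRecord]:
    """Classify all eight corner fixed points.

    Eigenvalues are the diagonal Jacobian entries in player order.  A corner
    is ``stable`` when all three are negative, ``non-hyperbolic`` when any
    is zero within :data:`ZERO_EIGENVALUE_TOL`, otherwise ``saddle`` (the
    label covers sources and true saddles alike).
    """
    records = []
    for corner in CORNER_ORDER:
        state = StrategyState(*corner)
        eig = tuple(
            marginal_stability_derivative(params, state, player, variant)
            for player in PLAYERS
        )
        if any(abs(e) < ZERO_EIGENVALUE_TOL for e in eig):
            attribute = NON_HYPERBOLIC
        elif all(e < 0.0 for e in eig):
            attribute = STABLE
        else:
            attribute = SADDLE
        records.append(EquilibriumRecord(state, eig, attribute))
    return records


# ---------------------------------------------------------------------------
# Indifference thresholds
# ---------------------------------------------------------------------------

def regulation_thresholds(params: ParameterSet, y: float, z: float) -> ThresholdSet:
    """Government indifference thresholds.

    ``lambda_y`` is the producer proportion at which the government is
    indifferent given consumer proportion ``z`` (above it deregulation is
    favored); ``lambda_z`` is the analogous consumer threshold given ``y``.
    Values may leave [0, 1], in which case one regime holds everywhere.
    """
    p = params
    if p.GC == 0.0:
        raise DegenerateThresholdError("lambda_y undefined: GC is zero")
    if p.f1 + p.GH == 0.0:
        raise DegenerateThresholdError("lambda_z undefined: f1 + GH is zero")
    lambda_y = (p.H + p.f1 - p.CG - z * (p.GH + p.f1)) / p.GC
    lambda_z = (p.H + p.f1 - p.CG - y * p.GC) / (p.f1 + p.GH)
    return ThresholdSet(lambda_y=lambda_y, lambda_z=lambda_z)


def critical_reputation_loss(
    params: ParameterSet, mode: str, proportion: float
) -> float:
    """Reputation-damage level above which regulation dominates.

    ``mode="given_y"``: threshold ``CG + GC + GH - GC*(1-y)`` — above it the
    government regulates regardless of the consumers.  ``mode="given_z"``:
    threshold ``CG + GC + GH - (GH+f1)*(1-z)`` — above it the government
    regulates regardless of the producers.
    """
    p = params
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    if mode == "given_y":
        return p.CG + p.GC + p.GH - p.GC * (1.0 - proportion)
    if mode == "given_z":
        return p.CG + p.GC + p.GH - (p.GH + p.f1) * (1.0 - proportion)
    raise ValueError(f"unknown mode {mode!r}; expected 'given_y' or 'given_z'")


def regulation_dominates(params: ParameterSet, mode: str, proportion: float) -> bool:
    """True when the reputation damage H exceeds the critical loss."""
    return params.H > critical_reputation_loss(params, mode, proportion)


# ---------------------------------------------------------------------------
# Indifference roots of the other two players (used by the W summaries)
# ---------------------------------------------------------------------------

def _enterprise_root_x(p: ParameterSet, z: float) -> float:
    if p.GC == 0.0:
        raise DegenerateThresholdError("enterprise x-root undefined: GC is zero")
    return (p.beta * p.C + p.CS - p.P - z * (p.alpha * p.P - p.f2)) / p.GC


def _enterprise_root_z(p: ParameterSet, x: float) -> float:
    if p.alpha * p.P == p.f2:
        raise DegenerateThresholdError("enterprise z-root undefined: alpha*P equals f2")
    return (p.beta * p.C + p.CS - p.P - x * p.GC) / (p.alpha * p.P - p.f2)


def _institution_root_x(p: ParameterSet, y: float) -> float:
    if p.GH + p.f1 == 0.0:
        raise DegenerateThresholdError("institution x-root undefined: GH + f1 is zero")
    return (p.alpha * p.P + p.d - p.rc + p.f2 - y * p.f2) / (p.GH + p.f1)


def _institution_root_y(p: ParameterSet, x: float) -> float:
    if p.f2 == 0.0:
        raise DegenerateThresholdError("institution y-root undefined: f2 is zero")
    return (p.alpha * p.P + p.d - p.rc + p.f2 - x * (p.GH + p.f1)) / p.f2


def midpoint_region_proportions(
    params: ParameterSet, strict_print: bool = False
) -> ThresholdSet:
    """The six midpoint region-proportion summaries.

    Each summary evaluates a player's favored-regime proportion with the
    free opponent proportion at one half:

    * ``v11`` = ``lambda_z`` at ``y = 1/2``; ``v12`` = ``lambda_y`` at
      ``z = 1/2`` (government regulation proportions);
    * ``w21``/``w22`` = one minus the enterprise indifference root in ``x``
      (at ``z = 1/2``) / in ``z`` (at ``x = 1/2``);
    * ``w31``/``w32`` = one minus the institution indifference root in ``x``
      (at ``y = 1/2``) / in ``y`` (at ``x = 1/2``).

    With ``strict_print=True`` the historically published literal forms are
    returned instead for ``v12``, ``w31`` and ``w32``; these contradict the
    indifference derivation (a halved-``CG`` slip in ``v12`` and a flipped
    ``rc`` sign in ``w31``/``w32``) and are kept only for audit.
    """
    p = params
    thr = regulation_thresholds(p, y=0.5, z=0.5)
    v11 = thr.lambda_z
    if strict_print:
        v12 = (2.0 * p.H + p.f1 - p.CG - p.GH) / (2.0 * p.GC)
        w31 = 1.0 - (2.0 * p.alpha * p.P + 2.0 * p.d + 2.0 * p.rc + p.f2) / (
            2.0 * p.GH + 2.0 * p.f1
        )
        if p.f2 == 0.0:
            raise DegenerateThresholdError("w32 undefined: f2 is zero")
        w32 = 1.0 - (
            2.0 * p.alpha * p.P + 2.0 * p.d + 2.0 * p.rc + 2.0 * p.f2 - p.GH - p.f1
        ) / (2.0 * p.f2)
    else:
        v12 = thr.lambda_y
        w31 = 1.0 - _institution_root_x(p, y=0.5)
        w32 = 1.0 - _institution_root_y(p, x=0.5)
    w21 = 1.0 - _enterprise_root_x(p, z=0.5)
    w22 = 1.0 - _enterprise_root_z(p, x=0.5)
    return ThresholdSet(
        lambda_y=thr.lambda_y, lambda_z=thr.lambda_z,
        v11=v11, v12=v12, w21=w21, w22=w22, w31=w31, w32=w32,
    )


def sensitivity_signs(
    params: ParameterSet,
    step: float = 1e-6,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[SensitivitySign]:
    """Signs of central finite-difference partials of the region proportions.

    ``pairs`` defaults to the (quantity, parameter) pairs of
    :data:`EXPECTED_SENSITIVITY_SIGNS`.  A derivative smaller than ``1e-6``
    in absolute value reports sign ``"0"``.
    """
    if step <= 0.0:
        raise ValueError("step must be positive")
    if pairs is None:
        pairs = [(quantity, param) for quantity, param, _ in EXPECTED_SENSITIVITY_SIGNS]
    out: list[SensitivitySign] = []
    for quantity, param in pairs:
        base = getattr(params, param)
        h = step * max(abs(base), 1.0)

        def value(v: float) -> float:
            perturbed = params.replace(**{param: v})
            return getattr(midpoint_region_proportions(perturbed), quantity)

        try:
            deriv = (value(base + h) - value(base - h)) / (2.0 * h)
        except ParameterValidationError:
            # lower perturbation left the admissible region: forward difference
            deriv = (value(base + h) - value(base)) / h
        if abs(deriv) < 1e-6:
            sign = "0"
        else:
            sign = "+" if deriv > 0.0 else "-"
        out.append(SensitivitySign(quantity, param, sign, deriv))
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def equilibria_to_json(records: Sequence[EquilibriumRecord]) -> str:
    payload = [
        {
            "corner": [int(record.corner.x), int(record.corner.y), int(record.corner.z)],
            "eigenvalues": list(record.eigenvalues),
            "attribute": record.attribute,
        }
        for record in records
    ]
    return json.dumps(payload, indent=2) + "\n"


def render_equilibria_table(records: Sequence[EquilibriumRecord]) -> str:
    """Aligned text table: corner, three eigenvalues, attribute."""
    header = f"{'point':<12}{'e_gov':>10}{'e_ent':>10}{'e_inst':>10}  attribute"
    lines = [header, "-" * len(header)]
    for k, record in enumerate(records, start=1):
        corner = f"({record.corner.x:.0f}, {record.corner.y:.0f}, {record.corner.z:.0f})"
        e1, e2, e3 = record.eigenvalues
        lines.append(
            f"O{k} {corner:<9}{e1:>10.4g}{e2:>10.4g}{e3:>10.4g}  {record.attribute}"
        )
    return "\n".join(lines) + "\n"
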