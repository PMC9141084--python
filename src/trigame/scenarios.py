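"""Scenario construction: the baseline run, sweep presets, random parameters.

Only the baseline constants, the (0.1, 0.1, 0.1) start and the {0.1, 0.5}
initial-regulation comparison are fixed by the reference experiments; the
numeric levels of the other sweeps were never published and are artifact
choices, defaulting to {0.5x, 1x, 2x} of the baseline value (and a
symmetric positive/zero/negative ladder for the reuse cost benefit ``rc``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .game_model import (
    PARAM_FIELDS,
    ParameterSet,
    ParameterValidationError,
    StrategyState,
    load_parameters,
)
from .simulator import InterventionEvent, InterventionSchedule, SimulationSettings

__all__ = [
    "Scenario",
    "SweepSpec",
    "baseline_parameters",
    "baseline_scenario",
    "figure_presets",
    "preset_by_name",
    "random_parameters",
    "DEFAULT_RANGES",
]

#: Initial-state coordinates accepted by :class:`SweepSpec` besides parameters.
_STATE_COORDS = ("x", "y", "z")


@dataclass(frozen=True)
class Scenario:
    """A fully specified run: parameters, start state, settings, schedule."""

    name: str
    params: ParameterSet
    initial: StrategyState
    settings: SimulationSettings
    schedule: InterventionSchedule

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
            "initial": {"x": self.initial.x, "y": self.initial.y, "z": self.initial.z},
            "settings": {
                "t_initial": self.settings.t_initial,
                "t_final": self.settings.t_final,
                "dt": self.settings.dt,
                "method": self.settings.method,
                "variant": self.settings.variant,
            },
            "schedule": [list(ev) for ev in self.schedule.events],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Scenario":
        return cls(
            name=data["name"],
            params=ParameterSet.from_dict(data["params"]),
            initial=StrategyState(**data["initial"]),
            settings=SimulationSettings(**data["settings"]),
            schedule=InterventionSchedule(
                [InterventionEvent(*ev) for ev in data.get("schedule", [])]
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep around a base scenario.

    ``parameter`` is either a model-constant name or one of ``x``/``y``/``z``
    (an initial-state coordinate).
    """

    name: str
    parameter: str
    values: tuple[float, ...]
    base: Scenario

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("values must be nonempty")
        if self.parameter not in PARAM_FIELDS + _STATE_COORDS:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        self.scenarios()  # fail fast if any level is invalid

    def scenarios(self) -> list[Scenario]:
        out = []
        for value in self.values:
            label = f"{self.name}:{self.parameter}={value:g}"
            if self.parameter in _STATE_COORDS:
                initial = replace(self.base.initial, **{self.parameter: value})
                out.append(replace(self.base, name=label, initial=initial))
            else:
                params = self.base.params.replace(**{self.parameter: value})
                out.append(replace(self.base, name=label, params=params))
        return out


def baseline_parameters() -> ParameterSet:
    """The packaged baseline constants, loaded from the bundled YAML file."""
    source = importlib.resources.files("trigame") / "data" / "baseline.yaml"
    with importlib.resources.as_file(source) as path:
        return load_parameters(path)


def baseline_scenario() -> Scenario:
    """Baseline constants, start (0.1, 0.1, 0.1), default settings."""
    return Scenario(
        name="baseline",
        params=baseline_parameters(),
        initial=StrategyState(0.1, 0.1, 0.1),
        settings=SimulationSettings(),
        schedule=InterventionSchedule(),
    )


def figure_presets() -> list[SweepSpec]:
    """The sweep presets emulating the reference simulation experiments.

    Level values not fixed by the experiments are artifact choices (see the
    module docstring).
    """
    base = baseline_scenario()
    p = base.params
    negative_rc_base = replace(
        base, name="baseline_rc=-2", params=p.replace(rc=-2.0)
    )
    return [
        # regulation on/off comparison: start with essentially no vs strong regulation
        SweepSpec("regulation_comparison", "x", (0.0, 0.9), base),
        SweepSpec("initial_x", "x", (0.1, 0.5), base),
        SweepSpec("alpha_levels", "alpha", (0.75, 1.5, 3.0), base),
        SweepSpec("beta_levels", "beta", (0.75, 1.5, 3.0), base),
        SweepSpec("H_levels", "H", (0.9, 1.8, 3.6), base),
        # reuse cost benefit: large positive, baseline, zero, normal and large negative
        SweepSpec("rc_levels", "rc", (4.0, 2.0, 0.0, -2.0, -4.0), base),
        # use-subsidy ladder under a negative reuse cost benefit
        SweepSpec("negative_rc_GH", "GH", (0.2, 0.5, 1.0, 2.0), negative_rc_base),
        SweepSpec("f2_levels", "f2", (0.1, 0.2, 0.4), base),
    ]


def preset_by_name(name: str) -> SweepSpec:
    presets = {spec.name: spec for spec in figure_presets()}
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[name]


def _default_ranges() -> dict[str, tuple[float, float]]:
    base = baseline_parameters()
    ranges = {
        name: (0.5 * getattr(base, name), 1.5 * getattr(base, name))
        for name in PARAM_FIELDS
    }
    # the reuse cost benefit may additionally be negative, down to -baseline
    ranges["rc"] = (-base.rc, 1.5 * base.rc)
    return ranges


#: Default sampling intervals: +-50% of the baseline value per field
#: (``rc`` extended down to minus its baseline value).
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = _default_ranges()


def random_parameters(
    seed: int, ranges: Mapping[str, tuple[float, float]] | None = None
) -> ParameterSet:
    """Seeded uniform draw of a valid parameter set.

    The same seed always yields the same set.  Custom ``ranges`` override
    the defaults per field and must respect the sign rules (only ``rc`` may
    reach negative values).
    """
    merged = dict(DEFAULT_RANGES)
    if ranges:
        unknown = sorted(set(ranges) - set(PARAM_FIELDS))
        if unknown:
            raise ParameterValidationError(unknown[0], "unknown range key")
        merged.update({k: (float(lo), float(hi)) for k, (lo, hi) in ranges.items()})
    for name, (lo, hi) in merged.items():
        if lo > hi:
            raise ValueError(f"range for {name!r} has lower > upper")
        if name != "rc" and lo < 0:
            raise ValueError(f"range for {name!r} admits negative values")
        if name in ("q", "alpha", "beta") and lo <= 0:
            raise ValueError(f"range for {name!r} admits non-positive values")
    rng = np.random.default_rng(seed)
    draw = {name: float(rng.uniform(*merged[name])) for name in PARAM_FIELDS}
    return ParameterSet(**draw)
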