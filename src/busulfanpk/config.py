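"""YAML configuration for population parameters and study settings.

A config file may override any subset of the population parameters, the
positivity floor, cohort size, seed, schedules, and the dose/lag band
tables.  Example::

    params:
      cl: 10.7
      sigma_prop: 0.126
    study:
      n: 1000
      seed: 42
      schedules: [schedule1, schedule3]
    floor: 0.001
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .cohort import POSITIVITY_FLOOR
from .pk_core import TypicalParams

__all__ = ["StudyConfig", "load_config"]


@dataclass
class StudyConfig:
    params: TypicalParams = field(default_factory=TypicalParams)
    n: int = 1000
    seed: int = 0
    schedules: tuple[str, ...] = ("schedule1", "schedule2", "schedule3")
    floor: float = POSITIVITY_FLOOR
    lag_table: tuple | None = None  # ((upper_kg, minutes, edge_closed), ...)


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML file (missing keys keep defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = TypicalParams(**raw.get("params", {}))
    study = raw.get("study", {})
    lag = raw.get("lag_table")
    if lag is not None:
        lag = tuple(
            (math.inf if u in ("inf", None) else float(u), float(v), bool(c))
            for u, v, c in lag
        )
    return StudyConfig(
        params=params,
        n=int(study.get("n", 1000)),
        seed=int(study.get("seed", 0)),
        schedules=tuple(study.get("schedules", ("schedule1", "schedule2", "schedule3"))),
        floor=float(raw.get("floor", POSITIVITY_FLOOR)),
        lag_table=lag,
    )
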