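"""Configuration files, shipped scenario fixtures, and writers.

A model configuration is a YAML or JSON document::

    regions: [A, B]
    rates:
      w: {A: 0.01, B: 0.02}
      e: {A: 0.169, B: 0.008}
      d: {A>B: 0.002, B>A: 0.178}
      b: {A|B: 0.003}
    init:
      pi0: {A: 0.45, B: 0.45, AB: 0.1}   # or n0 with integer counts
    run:
      t_max: 10.0
      steps: 1000
      replicates: 1000
      seed: 42

Dispersal keys are ordered ``from>to``; between-region speciation keys are
unordered splits ``left|right`` with concatenated region labels.  Unknown
keys are rejected.  Trajectories are written as TSV with a ``time`` column
plus one column per state in canonical order; reports are JSON with
full-precision scalars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .simulate import EnsembleSummary, Trajectory, counts_from_frequencies
from .state_space import (
    GeoSSEParams,
    enumerate_range_states,
    split_key,
    validate_params,
)

_RUN_KEYS = {"t_max", "steps", "replicates", "seed"}


class ConfigError(ValueError):
    """Malformed model configuration document."""


def _rates_from_mapping(doc: dict, regions) -> GeoSSEParams:
    allowed = {"w", "e", "d", "b"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown rate classes: {sorted(unknown)}")
    w = {str(k): float(v) for k, v in (doc.get("w") or {}).items()}
    e = {str(k): float(v) for k, v in (doc.get("e") or {}).items()}
    d = {}
    for key, v in (doc.get("d") or {}).items():
        parts = str(key).split(">")
        if len(parts) != 2 or not all(parts):
            raise ConfigError(f"dispersal keys use 'from>to', got {key!r}")
        d[(parts[0], parts[1])] = float(v)
    b = {}
    for key, v in (doc.get("b") or {}).items():
        parts = str(key).split("|")
        if len(parts) != 2 or not all(parts):
            raise ConfigError(f"split keys use 'left|right', got {key!r}")
        b[split_key(tuple(parts[0]), tuple(parts[1]))] = float(v)
    return GeoSSEParams(w=w, e=e, d=d, b=b)


def _rates_to_mapping(params: GeoSSEParams) -> dict:
    return {
        "w": dict(params.w),
        "e": dict(params.e),
        "d": {f"{k}>{l}": v for (k, l), v in params.d.items()},
        "b": {f"{''.join(a)}|{''.join(b_)}": v for (a, b_), v in params.b.items()},
    }


def parse_config(doc: dict):
    """Validate a parsed configuration mapping.

    Returns (space, params, init, run) where ``init`` holds optional ``n0``
    or ``pi0`` vectors in canonical state order and ``run`` the run settings.
    """
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(doc) - {"regions", "rates", "init", "run", "name"}
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "regions" not in doc or "rates" not in doc:
        raise ConfigError("configuration needs 'regions' and 'rates'")
    space = enumerate_range_states([str(r) for r in doc["regions"]])
    params = validate_params(
        _rates_from_mapping(doc["rates"], space.regions), space
    )

    init: Dict[str, np.ndarray] = {}
    init_doc = doc.get("init") or {}
    unknown = set(init_doc) - {"n0", "pi0", "N0"}
    if unknown:
        raise ConfigError(f"unknown init keys: {sorted(unknown)}")
    for key in ("n0", "pi0"):
        if key in init_doc:
            mapping = init_doc[key]
            vec = np.zeros(space.n_states)
            unknown = set(mapping) - set(space.labels())
            if unknown:
                raise ConfigError(f"{key} references unknown states: {sorted(unknown)}")
            for label, v in mapping.items():
                vec[space.index(space.state_by_label(label))] = float(v)
            init[key] = vec
    if "N0" in init_doc:
        init["N0"] = int(init_doc["N0"])
    if "pi0" in init and abs(init["pi0"].sum() - 1.0) > 1e-9:
        raise ConfigError("pi0 must sum to 1")

    run = dict(doc.get("run") or {})
    unknown = set(run) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown run keys: {sorted(unknown)}")
    return space, params, init, run


def load_config(path):
    """Load and validate a YAML/JSON model configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return parse_config(doc)


def dump_config(space, params, init=None, run=None, name=None) -> dict:
    """Inverse of :func:`parse_config` (lossless round trip)."""
    doc = {
        "regions": list(space.regions),
        "rates": _rates_to_mapping(params),
    }
    if name:
        doc["name"] = name
    if init:
        init_doc = {}
        for key in ("n0", "pi0"):
            if key in init:
                init_doc[key] = {
                    label: float(v)
                    for label, v in zip(space.labels(), init[key])
                }
        if "N0" in init:
            init_doc["N0"] = int(init["N0"])
        doc["init"] = init_doc
    if run:
        doc["run"] = dict(run)
    return doc


# ---------------------------------------------------------------------------
# scenario fixtures


@dataclass
class ScenarioFixture:
    """A fully specified, ready-to-run simulation scenario."""

    name: str
    regions: Tuple[str, ...]
    rates: dict
    pi0: Optional[Dict[str, float]] = None
    N0: Optional[int] = None
    t_max: float = 10.0
    steps: int = 1000
    replicates: int = 1000
    seed: int = 42
    note: str = ""

    def to_config(self) -> dict:
        doc = {
            "name": self.name,
            "regions": list(self.regions),
            "rates": self.rates,
            "run": {
                "t_max": self.t_max,
                "steps": self.steps,
                "replicates": self.replicates,
                "seed": self.seed,
            },
        }
        init = {}
        if self.pi0 is not None:
            init["pi0"] = dict(self.pi0)
        if self.N0 is not None:
            init["N0"] = self.N0
        if init:
            doc["init"] = init
        return doc

    def load(self):
        space, params, init, run = parse_config(self.to_config())
        return space, params, init, run

    def initial_counts(self, method="largest_remainder", rng=None) -> np.ndarray:
        space, _, init, _ = self.load()
        if "pi0" in init and "N0" in init:
            return counts_from_frequencies(init["pi0"], init["N0"], method, rng)
        if "n0" in init:
            return init["n0"]
        raise ValueError(f"fixture {self.name} has no initial condition")


FIXTURES: Dict[str, ScenarioFixture] = {}


def _register(fx: ScenarioFixture) -> None:
    FIXTURES[fx.name] = fx


_register(
    ScenarioFixture(
        name="three_region_cladogenetic",
        regions=("A", "B", "C"),
        rates={
            "w": {"A": 0.03, "B": 0.03, "C": 0.03},
            "e": {"A": 0.0, "B": 0.0, "C": 0.0},
            "d": {
                "A>B": 0.0, "B>A": 0.0, "A>C": 0.0,
                "C>A": 0.0, "B>C": 0.0, "C>B": 0.0,
            },
            "b": {
                "A|B": 0.08, "A|C": 0.10, "B|C": 0.06,
                "A|BC": 0.04, "B|AC": 0.12, "C|AB": 0.06,
            },
        },
        pi0={lbl: 1 / 7 for lbl in ("A", "B", "C", "AB", "AC", "BC", "ABC")},
        N0=40,
        note="speciation-only dynamics: within- and between-region "
        "speciation, no dispersal or extinction",
    )
)

_register(
    ScenarioFixture(
        name="three_region_dispersal",
        regions=("A", "B", "C"),
        rates={
            "w": {"A": 0.03, "B": 0.03, "C": 0.03},
            "e": {"A": 0.0, "B": 0.0, "C": 0.0},
            "d": {
                "A>B": 0.03, "B>A": 0.03, "A>C": 0.04,
                "C>A": 0.04, "B>C": 0.05, "C>B": 0.05,
            },
            "b": {
                "A|B": 0.0, "A|C": 0.0, "B|C": 0.0,
                "A|BC": 0.0, "B|AC": 0.0, "C|AB": 0.0,
            },
        },
        pi0={
            "A": 1 / 6, "B": 1 / 6, "C": 1 / 6,
            "AB": 1 / 6, "AC": 1 / 6, "BC": 1 / 6, "ABC": 0.0,
        },
        N0=40,
        note="within-region speciation plus dispersal; ranges only grow",
    )
)

_register(
    ScenarioFixture(
        name="three_region_extinction",
        regions=("A", "B", "C"),
        rates={
            "w": {"A": 0.03, "B": 0.03, "C": 0.03},
            "e": {"A": 0.01, "B": 0.02, "C": 0.025},
            "d": {
                "A>B": 0.0, "B>A": 0.0, "A>C": 0.0,
                "C>A": 0.0, "B>C": 0.0, "C>B": 0.0,
            },
            "b": {
                "A|B": 0.0, "A|C": 0.0, "B|C": 0.0,
                "A|BC": 0.0, "B|AC": 0.0, "C|AB": 0.0,
            },
        },
        pi0={lbl: 1 / 7 for lbl in ("A", "B", "C", "AB", "AC", "BC", "ABC")},
        N0=40,
        note="within-region speciation plus local extinction",
    )
)

_register(
    ScenarioFixture(
        name="three_region_full",
        regions=("A", "B", "C"),
        rates={
            "w": {"A": 0.09, "B": 0.06, "C": 0.07},
            "e": {"A": 0.002, "B": 0.003, "C": 0.001},
            "d": {
                "A>B": 0.006, "B>A": 0.006, "A>C": 0.003,
                "C>A": 0.003, "B>C": 0.001, "C>B": 0.001,
            },
            "b": {
                "A|B": 0.04, "A|C": 0.04, "B|C": 0.04,
                "A|BC": 0.04, "B|AC": 0.04, "C|AB": 0.04,
            },
        },
        pi0={
            "A": 0.0, "B": 0.0, "C": 0.0,
            "AB": 0.25, "AC": 0.25, "BC": 0.25, "ABC": 0.25,
        },
        N0=40,
        note="all four event classes active; widespread-only start",
    )
)

# Two-region scenarios from the closed-form equal-thirds rate families.
# equal_thirds_f1_a's wB is stored at its exact family value
# (2*eB - dAB)/2 = 0.0005 rather than a rounded 0.
_register(
    ScenarioFixture(
        name="equal_thirds_f1_a",
        regions=("A", "B"),
        rates={
            "w": {"A": 0.090, "B": 0.0005},
            "e": {"A": 0.176, "B": 0.008},
            "d": {"A>B": 0.015, "B>A": 0.173},
            "b": {"A|B": 0.004},
        },
        pi0={"A": 0.45, "B": 0.45, "AB": 0.1},
        N0=100,
        t_max=250.0,
        replicates=100,
        note="family-1 member with stationary frequencies (1/3, 1/3, 1/3)",
    )
)

_register(
    ScenarioFixture(
        name="equal_thirds_f1_b",
        regions=("A", "B"),
        rates={
            "w": {"A": 0.160, "B": 0.002},
            "e": {"A": 0.315, "B": 0.009},
            "d": {"A>B": 0.014, "B>A": 0.310},
            "b": {"A|B": 0.001},
        },
        pi0={"A": 0.1, "B": 0.45, "AB": 0.45},
        N0=100,
        t_max=250.0,
        replicates=100,
        note="family-1 member with stationary frequencies (1/3, 1/3, 1/3)",
    )
)

_register(
    ScenarioFixture(
        name="equal_thirds_f2_a",
        regions=("A", "B"),
        rates={
            "w": {"A": 0.107, "B": 0.008},
            "e": {"A": 0.309, "B": 0.008},
            "d": {"A>B": 0.001, "B>A": 0.405},
            "b": {"A|B": 0.089},
        },
        pi0={"A": 0.45, "B": 0.45, "AB": 0.1},
        N0=100,
        t_max=60.0,
        replicates=100,
        note="family-2 member with stationary frequencies (1/3, 1/3, 1/3)",
    )
)

_register(
    ScenarioFixture(
        name="equal_thirds_f2_b",
        regions=("A", "B"),
        rates={
            "w": {"A": 0.049, "B": 0.005},
            "e": {"A": 0.470, "B": 0.008},
            "d": {"A>B": 0.006, "B>A": 0.843},
            "b": {"A|B": 0.371},
        },
        pi0={"A": 0.1, "B": 0.45, "AB": 0.45},
        N0=100,
        t_max=60.0,
        replicates=100,
        note="family-2 member with stationary frequencies (1/3, 1/3, 1/3)",
    )
)

_register(
    ScenarioFixture(
        name="two_region_benchmark1",
        regions=("A", "B"),
        rates={
            "w": {"A": 0.01, "B": 0.02},
            "e": {"A": 0.169, "B": 0.008},
            "d": {"A>B": 0.002, "B>A": 0.178},
            "b": {"A|B": 0.003},
        },
        t_max=250.0,
        note="asymmetric benchmark: strong A-side extirpation and B-to-A "
        "dispersal; stationary frequencies near (0.057, 0.506, 0.437)",
    )
)

_register(
    ScenarioFixture(
        name="two_region_benchmark2",
        regions=("A", "B"),
        rates={
            "w": {"A": 0.0006, "B": 0.0003},
            "e": {"A": 0.0048, "B": 0.0045},
            "d": {"A>B": 0.0370, "B>A": 0.03703},
            "b": {"A|B": 1e-9},
        },
        t_max=2000.0,
        note="near-symmetric, dispersal-dominated benchmark with a "
        "negligible between-region speciation rate; stationary "
        "frequencies near (0.0996, 0.0996, 0.8008)",
    )
)


# ---------------------------------------------------------------------------
# writers


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as TSV: a ``time`` column plus one canonical state
    column, full double precision."""
    df = pd.DataFrame(traj.values, columns=list(traj.labels))
    df.insert(0, "time", traj.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path, kind: str = "counts") -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ValueError(f"{path} is not a trajectory file (no 'time' column)")
    labels = tuple(c for c in df.columns if c != "time")
    return Trajectory(
        times=df["time"].to_numpy(),
        values=df[list(labels)].to_numpy(),
        kind=kind,
        labels=labels,
    )


def write_ensemble(summary: EnsembleSummary, path) -> None:
    """Terminal values of an ensemble as TSV (one row per replicate)."""
    df = pd.DataFrame(summary.terminal_values, columns=list(summary.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ensemble(path) -> EnsembleSummary:
    df = pd.read_csv(path, sep="\t")
    return EnsembleSummary(
        labels=tuple(df.columns), terminal_values=df.to_numpy(dtype=float)
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path) -> None:
    """JSON report writer; numpy scalars/arrays are converted losslessly."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
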