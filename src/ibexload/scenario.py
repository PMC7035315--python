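"""Demographic scenario configuration for the forward simulator.

A scenario is a structured program of patches (demes) with carrying
capacities, carrying-capacity changes over time, and founding events in
which offspring migrate from one or two extant source patches into an empty
patch.  Scenarios are read from YAML files with keys ``patches``, ``burn_in``,
``events``, and optional ``snapshots`` / ``end_generation``.

Carrying capacities of long-running natural populations are set to the
harmonic mean of their census record, which is the census summary that
governs drift over fluctuating sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml


def harmonic_mean(census) -> float:
    """Harmonic mean n / Σ(1/N_t) of a census vector (all entries > 0)."""
    census = np.asarray(census, dtype=float)
    if census.size == 0:
        raise ValueError("empty census vector")
    if np.any(census <= 0):
        raise ValueError("census values must be positive")
    return float(len(census) / np.sum(1.0 / census))


@dataclass
class SetK:
    """Change the carrying capacity of a patch at a generation."""

    generation: int
    patch: str
    k: int


@dataclass
class Founding:
    """Found (or re-found) a patch by migration of offspring.

    ``sources`` maps source patch name -> number of founder offspring drawn
    from that source's offspring pool (sex ratio forced to 1:1, extra
    individual female when odd).
    """

    generation: int
    patch: str
    sources: dict
    k: int | None = None

    @property
    def n_founders(self) -> int:
        return int(sum(self.sources.values()))


@dataclass
class Scenario:
    """Time-ordered demographic program for :func:`~ibexload.simulate.run_scenario`."""

    patches: dict = field(default_factory=dict)  # name -> initial K (0 = empty)
    burn_in_patch: str = "gp"
    burn_in_generations: int = 3000
    events: list = field(default_factory=list)
    end_generation: int | None = None
    snapshots: list = field(default_factory=list)  # generations to record counts
    report_every: int = 0

    def __post_init__(self):
        if self.burn_in_patch not in self.patches:
            raise ValueError(
                f"burn-in patch {self.burn_in_patch!r} not among patches"
            )
        gens = [e.generation for e in self.events]
        if gens != sorted(gens):
            raise ValueError("events must be time-ordered")
        extant = {p for p, k in self.patches.items() if k > 0}
        for ev in self.events:
            if ev.patch not in self.patches:
                raise ValueError(f"event references unknown patch {ev.patch!r}")
            if isinstance(ev, Founding):
                for src, n in ev.sources.items():
                    if src not in self.patches:
                        raise ValueError(
                            f"founding of {ev.patch!r} from unknown patch {src!r}"
                        )
                    if src not in extant:
                        raise ValueError(
                            f"founding of {ev.patch!r} from patch {src!r} "
                            "that is empty at event time"
                        )
                    if n < 2:
                        raise ValueError(
                            f"founding of {ev.patch!r}: founder count per "
                            f"source must be >= 2, got {n}"
                        )
                extant.add(ev.patch)
        if self.end_generation is None:
            last = max(gens, default=0)
            self.end_generation = max(self.burn_in_generations, last) + 10

    @property
    def generations(self) -> int:
        return int(self.end_generation)

    def events_at(self, generation: int) -> list:
        return [e for e in self.events if e.generation == generation]


def _parse_events(raw_events) -> list:
    events = []
    for raw in raw_events:
        kind = raw.get("type")
        if kind == "set_k":
            events.append(
                SetK(int(raw["generation"]), str(raw["patch"]), int(raw["k"]))
            )
        elif kind == "found":
            events.append(
                Founding(
                    int(raw["generation"]),
                    str(raw["patch"]),
                    {str(s): int(n) for s, n in raw["sources"].items()},
                    int(raw["k"]) if "k" in raw else None,
                )
            )
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return events


def scenario_from_dict(cfg: dict) -> Scenario:
    patches = {str(p["name"]): int(p.get("k", 0)) for p in cfg["patches"]}
    burn = cfg.get("burn_in", {})
    return Scenario(
        patches=patches,
        burn_in_patch=str(burn.get("patch", next(iter(patches)))),
        burn_in_generations=int(burn.get("generations", 0)),
        events=_parse_events(cfg.get("events", [])),
        end_generation=(
            int(cfg["end_generation"]) if "end_generation" in cfg else None
        ),
        snapshots=[int(g) for g in cfg.get("snapshots", [])],
        report_every=int(cfg.get("report_every", 0)),
    )


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scenario_from_dict(cfg)


def bundled_scenario(name: str) -> Scenario:
    """Load a scenario shipped with the package (e.g. ``ibex_reintroduction``)."""
    ref = resources.files("ibexload") / "scenarios" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_scenario(Path(path))
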