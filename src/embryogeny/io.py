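"""Configuration files, result serialisation, and deterministic fixtures.

Config files are YAML (or JSON, a YAML subset) mappings whose keys mirror
:class:`~embryogeny.config.GAConfig` field names exactly, plus a small set
of experiment-level keys (``experiment``, ``output_dir``, ``levels``,
``fractions``).  Unknown keys are rejected by name.

Results are written as UTF-8 CSV (one row per condition/repeat/generation)
plus a JSON summary; nothing time-stamped goes into data files, so
re-running with the same seed reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError, GAConfig
from .core import Embryo, Population, RunResult, count_inversions, init_population
from .experiments import (
    EvolvableSuiteResult,
    FixedSuiteResult,
    MixedSuiteResult,
    ScanResult,
)

__all__ = ["ExperimentSpec", "load_config", "write_results", "make_fixture"]

EXPERIMENT_NAMES = ("run", "fixed_suite", "mixed_suite", "evolvable", "baldwin", "scan")

_SPEC_KEYS = ("experiment", "output_dir", "levels", "fractions")


@dataclass
class ExperimentSpec:
    """A fully resolved experiment: base config plus suite-level parameters."""

    name: str = "run"
    base: GAConfig = field(default_factory=GAConfig)
    levels: Optional[Tuple[int, ...]] = None
    fractions: Optional[Tuple[float, ...]] = None
    output_dir: Path = Path("results")

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ConfigError(
                f"experiment must be one of {EXPERIMENT_NAMES}, got {self.name!r}"
            )
        self.output_dir = Path(self.output_dir)


def load_config(path: Union[str, Path]) -> ExperimentSpec:
    """Read and validate an experiment config file (YAML or JSON).

    An empty file resolves to an all-default hardwired single run.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = set(GAConfig.field_names()) | set(_SPEC_KEYS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    config_kwargs = {k: v for k, v in raw.items() if k in GAConfig.field_names()}
    base = GAConfig.from_dict(config_kwargs)
    return ExperimentSpec(
        name=raw.get("experiment", "run"),
        base=base,
        levels=tuple(raw["levels"]) if "levels" in raw else None,
        fractions=tuple(raw["fractions"]) if "fractions" in raw else None,
        output_dir=Path(raw.get("output_dir", "results")),
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _config_dict(config: GAConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(data: Mapping, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True, default=_json_default))


def runs_to_frame(runs: Sequence[RunResult], condition: str = "run") -> pd.DataFrame:
    """Long-format per-generation records over a set of repeats."""
    frames = []
    for run in runs:
        df = run.to_frame()
        df.insert(0, "repeat", run.repeat_index)
        df.insert(0, "condition", condition)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_results(result, out_dir: Union[str, Path]) -> List[Path]:
    """Serialise a run or suite result to CSV + JSON under ``out_dir``.

    Returns the list of files written.  Accepts a :class:`RunResult`, a list
    of them, or any suite result from :mod:`embryogeny.experiments`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    def save_json(data: Mapping, name: str) -> None:
        p = out / name
        _write_json(data, p)
        written.append(p)

    if isinstance(result, RunResult):
        result = [result]
    if isinstance(result, list) and result and isinstance(result[0], RunResult):
        save_csv(runs_to_frame(result), "records.csv")
        final = result[0].records[-1]
        save_json(
            {
                "config": _config_dict(result[0].config),
                "seeds": [r.seed for r in result],
                "repeats": len(result),
                "final_best_phenotypic_fitness": [
                    r.records[-1].best_phenotypic_fitness for r in result
                ],
                "final_best_genotypic_fitness": [
                    r.records[-1].best_genotypic_fitness for r in result
                ],
                "generations": final.generation + 1,
            },
            "summary.json",
        )
    elif isinstance(result, FixedSuiteResult):
        save_csv(result.to_long_frame(), "records.csv")
        save_json(
            {
                "breakthrough_thresholds": list(result.table.thresholds),
                "breakthrough_generations": result.table.rows,
            },
            "summary.json",
        )
    elif isinstance(result, MixedSuiteResult):
        rows = []
        for (level, fraction), prev in result.prevalence.items():
            for g, p in enumerate(prev):
                rows.append(
                    {
                        "competency_level": level,
                        "initial_fraction": fraction,
                        "generation": g,
                        "mean_competent_prevalence": p,
                    }
                )
        save_csv(pd.DataFrame(rows), "records.csv")
        save_json(
            {
                "dominance_generations": {
                    f"level_{lvl}@{frac:g}": gen
                    for (lvl, frac), gen in result.table.cells.items()
                },
                "min_dominating_level": {
                    f"{frac:g}": result.table.min_dominating_level(frac)
                    for frac in result.table.fractions
                },
            },
            "summary.json",
        )
    elif isinstance(result, EvolvableSuiteResult):
        save_csv(runs_to_frame(result.runs, condition="evolvable"), "records.csv")
        save_json(
            {
                "config": _config_dict(result.config),
                "mean_stable_competency": result.mean_stable_competency(),
                "saturation_generation": result.saturation_generation(),
                "windowed_correlation": result.windowed_correlation().tolist(),
            },
            "summary.json",
        )
    elif isinstance(result, ScanResult):
        save_csv(result.grid, "records.csv")
        save_json(
            {
                "mutation_correlation": result.mutation_correlation,
                "selection_correlation": result.selection_correlation,
                "cells": len(result.grid),
            },
            "summary.json",
        )
    else:
        raise TypeError(f"don't know how to serialise {type(result)}")
    return written


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0, length: int = 6, size: int = 6):
    """Small deterministic objects with analytically known properties.

    ``sorted`` / ``reversed``: embryos with 0 / C(L, 2) inversions;
    ``known_inversions``: a seeded random embryo returned together with its
    brute-force inversion count; ``tiny_population``: a seeded hardwired
    population (N = ``size``, L = ``length``).
    """
    rng = np.random.default_rng(seed)
    if kind == "sorted":
        return Embryo(np.arange(1, length + 1))
    if kind == "reversed":
        return Embryo(np.arange(length, 0, -1))
    if kind == "known_inversions":
        genes = rng.permutation(np.arange(1, length + 1))
        return Embryo(genes), count_inversions(genes)
    if kind == "tiny_population":
        config = GAConfig(population_size=size, genome_length=length)
        return init_population(config, rng)
    raise ValueError(f"unknown fixture kind {kind!r}")
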