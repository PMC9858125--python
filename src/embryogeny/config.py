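"""Run configuration for the embryogeny genetic algorithm.

A single :class:`GAConfig` carries every model and GA hyperparameter for one
evolutionary run: population geometry, the competency mode of the embryos,
mutation/selection settings, the fitness-counting variant, the competency
cost, and the RNG seed.  Configs are immutable; derive variants with
:func:`dataclasses.replace`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from typing import Any, Mapping, Tuple

__all__ = ["GAConfig", "ConfigError", "COMPETENCY_MODES", "FITNESS_VARIANTS"]

COMPETENCY_MODES = ("hardwired", "fixed", "evolvable", "mixed")
FITNESS_VARIANTS = ("all_pairs", "adjacent")


class ConfigError(ValueError):
    """Raised when a run configuration violates a model constraint."""


def _check_interval(name: str, iv: Tuple[int, int]) -> Tuple[int, int]:
    lo, hi = int(iv[0]), int(iv[1])
    if lo > hi:
        raise ConfigError(f"{name}: empty interval [{lo}, {hi}]")
    return lo, hi


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters for one evolutionary run.

    Parameters
    ----------
    population_size
        Number of embryos per generation (kept constant by repopulation).
        100 in single-type experiments, 200 in mixed populations.
    genome_length
        Number of cells along the 1-D embryonic axis; each cell carries one
        integer structural (positional-value) gene.
    gene_value_range
        Inclusive range a structural gene may take after mutation.  Initial
        genomes are always a permutation of ``1..genome_length``.
    mutation_probability
        Per-individual, per-generation probability of receiving exactly one
        point mutation.
    selection_fraction
        Fraction of the population (fittest first) kept at selection.
    competency_mode
        ``hardwired`` (no cell movement), ``fixed`` (every embryo gets the
        same swap budget ``competency_level``), ``evolvable`` (each embryo
        carries a heritable, mutable competency gene), or ``mixed``
        (a hardwired majority seeded with a competent minority).
    competency_level
        Swap budget in ``fixed`` mode.
    competency_init_range
        Inclusive range competency genes are initialised from in
        ``evolvable`` mode (deliberately low: [1, 15]).
    competency_gene_range
        Inclusive range a mutated competency gene may explore ([1, 500]).
    penalty_factor
        Competency cost λ.  Selection then acts on
        ``max(0, phenotypic_fitness − λ · competency)``.
    fitness_variant
        ``adjacent`` scores the fraction of ordered adjacent cell pairs;
        ``all_pairs`` scores the fraction of ordered pairs over all C(L, 2)
        pairs (1 − normalised Kendall inversion count).
    mixed_competent_fraction, mixed_competency_level
        Initial prevalence and (fixed) swap budget of the competent
        sub-population in ``mixed`` mode.
    generations, repeats, seed
        Run length, number of Monte-Carlo repeats, and the root RNG seed
        (repeat ``r`` runs with ``seed + r``).
    """

    population_size: int = 100
    genome_length: int = 50
    gene_value_range: Tuple[int, int] = (1, 50)
    mutation_probability: float = 0.6
    selection_fraction: float = 0.10
    competency_mode: str = "hardwired"
    competency_level: int = 0
    competency_init_range: Tuple[int, int] = (1, 15)
    competency_gene_range: Tuple[int, int] = (1, 500)
    penalty_factor: float = 0.0
    generations: int = 250
    repeats: int = 1
    seed: int = 0
    fitness_variant: str = "all_pairs"
    mixed_competent_fraction: float = 0.10
    mixed_competency_level: int = 75

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.genome_length < 2:
            raise ConfigError("genome_length must be >= 2")
        if not 0 < self.selection_fraction <= 1:
            raise ConfigError("selection_fraction must lie in (0, 1]")
        if not 0 <= self.mutation_probability <= 1:
            raise ConfigError("mutation_probability must lie in [0, 1]")
        if self.penalty_factor < 0:
            raise ConfigError("penalty_factor must be non-negative")
        if self.competency_mode not in COMPETENCY_MODES:
            raise ConfigError(
                f"competency_mode must be one of {COMPETENCY_MODES}, "
                f"got {self.competency_mode!r}"
            )
        if self.fitness_variant not in FITNESS_VARIANTS:
            raise ConfigError(
                f"fitness_variant must be one of {FITNESS_VARIANTS}, "
                f"got {self.fitness_variant!r}"
            )
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        object.__setattr__(
            self, "gene_value_range", _check_interval("gene_value_range", self.gene_value_range)
        )
        ginit = _check_interval("competency_init_range", self.competency_init_range)
        grange = _check_interval("competency_gene_range", self.competency_gene_range)
        object.__setattr__(self, "competency_init_range", ginit)
        object.__setattr__(self, "competency_gene_range", grange)
        if not (grange[0] <= ginit[0] and ginit[1] <= grange[1]):
            raise ConfigError("competency_init_range must lie within competency_gene_range")
        if self.competency_mode == "fixed" and self.competency_level < 0:
            raise ConfigError("competency_level must be non-negative")
        if self.competency_mode == "mixed":
            if not 0 < self.mixed_competent_fraction < 1:
                raise ConfigError("mixed_competent_fraction must lie in (0, 1)")
            if self.mixed_competency_level < 1:
                raise ConfigError("mixed_competency_level must be >= 1 in mixed mode")

    # -- convenience -------------------------------------------------------

    @property
    def pair_count(self) -> int:
        """Number of cell pairs C(L, 2); the all-pairs fitness denominator."""
        L = self.genome_length
        return L * (L - 1) // 2

    def with_(self, **changes: Any) -> "GAConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GAConfig":
        """Build a config from a plain mapping, rejecting unknown keys."""
        known = set(cls.field_names())
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        kwargs = dict(data)
        for key in ("gene_value_range", "competency_init_range", "competency_gene_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
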