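"""Core model types: embryos, populations, and the monotonicity fitness.

A virtual embryo is a 1-D array of integer "structural genes", one per cell,
encoding that cell's positional value along a single body axis.  Fitness is
the degree to which the array is in ascending order: 1.0 for a fully
ascending axis, 0.0 for a fully descending one, 0.5 in expectation for a
random arrangement.  Two counting variants are supported:

``all_pairs``
    1 − (number of inverted pairs) / C(L, 2), i.e. the fraction of ordered
    pairs among all pairs of positions (a rescaled Kendall tau distance to
    the sorted order).
``adjacent``
    Fraction of adjacent cell pairs that are in (weakly) ascending order.

Ties count as ordered in both variants: a tied pair cannot be improved by
any swap, so counting it against the embryo would make full fitness
unreachable after mutation introduces duplicate gene values.

Populations are stored densely as integer matrices (one row per embryo) so
that whole-population operations vectorise; :class:`Embryo` objects are
lightweight views constructed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .config import ConfigError, GAConfig

__all__ = [
    "Embryo",
    "Population",
    "GenerationRecord",
    "RunResult",
    "count_inversions",
    "fitness",
    "genotypic_fitness",
    "phenotypic_fitness",
    "init_population",
]

GENE_DTYPE = np.int64


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def count_inversions(seq: Sequence[int]) -> int:
    """Number of strictly inverted pairs ``(i < j, seq[i] > seq[j])``.

    Equals the minimum number of adjacent swaps needed to sort ``seq``;
    ties are not inversions.
    """
    a = np.asarray(seq)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("expected a non-empty 1-D sequence")
    gt = a[:, None] > a[None, :]
    return int(np.triu(gt, k=1).sum())


def _inversions_rows(genes: np.ndarray) -> np.ndarray:
    """Row-wise inversion counts for a population matrix ``(N, L)``."""
    gt = genes[:, :, None] > genes[:, None, :]
    iu = np.triu_indices(genes.shape[1], k=1)
    return gt[:, iu[0], iu[1]].sum(axis=1)


def fitness(seq: Sequence[int], variant: str = "all_pairs") -> float:
    """Monotonicity fitness of a cell array, in [0, 1].

    Ascending arrays score 1.0, descending arrays of distinct values score
    0.0, and a uniformly random permutation scores 0.5 in expectation under
    either variant.
    """
    a = np.asarray(seq)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("fitness needs a 1-D sequence of length >= 2")
    L = a.size
    if variant == "all_pairs":
        return 1.0 - count_inversions(a) / (L * (L - 1) / 2.0)
    if variant == "adjacent":
        return float(np.count_nonzero(np.diff(a) >= 0)) / (L - 1)
    raise ValueError(f"unknown fitness variant {variant!r}")


def _fitness_rows(genes: np.ndarray, variant: str) -> np.ndarray:
    """Row-wise fitness for a population matrix ``(N, L)``."""
    L = genes.shape[1]
    if variant == "all_pairs":
        return 1.0 - _inversions_rows(genes) / (L * (L - 1) / 2.0)
    if variant == "adjacent":
        ordered = np.count_nonzero(np.diff(genes, axis=1) >= 0, axis=1)
        return ordered / float(L - 1)
    raise ValueError(f"unknown fitness variant {variant!r}")


# ---------------------------------------------------------------------------
# embryos and populations
# ---------------------------------------------------------------------------

@dataclass
class Embryo:
    """One virtual embryo.

    ``structural_genes`` is the heritable cell array; ``competency_gene`` is
    the number of adjacent-cell swaps the embryo may execute during
    development (0 marks a hardwired embryo); ``phenotype`` is the developed
    cell arrangement, equal to the structural genes until development runs.
    """

    structural_genes: np.ndarray
    competency_gene: int = 0
    phenotype: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.structural_genes = np.asarray(self.structural_genes, dtype=GENE_DTYPE)
        if self.competency_gene < 0:
            raise ValueError("competency_gene must be non-negative")
        if self.phenotype is None:
            self.phenotype = self.structural_genes.copy()
        else:
            self.phenotype = np.asarray(self.phenotype, dtype=GENE_DTYPE)

    @property
    def is_hardwired(self) -> bool:
        return self.competency_gene == 0


def genotypic_fitness(e: Embryo, variant: str = "all_pairs") -> float:
    """Fitness of the heritable (pre-development) cell array."""
    return fitness(e.structural_genes, variant)


def phenotypic_fitness(e: Embryo, variant: str = "all_pairs") -> float:
    """Fitness of the developed cell array (what selection sees)."""
    return fitness(e.phenotype, variant)


@dataclass
class Population:
    """A generation of embryos, stored as dense matrices.

    ``genes`` is ``(N, L)`` structural genes, ``competency`` is ``(N,)``
    swap budgets, ``phenotypes`` is ``(N, L)`` developed arrangements
    (equal to ``genes`` until :func:`embryogeny.development.develop_population`
    runs for the current generation).
    """

    genes: np.ndarray
    competency: np.ndarray
    phenotypes: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=GENE_DTYPE)
        self.competency = np.asarray(self.competency, dtype=GENE_DTYPE)
        self.phenotypes = np.asarray(self.phenotypes, dtype=GENE_DTYPE)
        if self.genes.ndim != 2:
            raise ValueError("genes must be a 2-D (N, L) matrix")
        if self.phenotypes.shape != self.genes.shape:
            raise ValueError("phenotypes must match genes in shape")
        if self.competency.shape != (self.genes.shape[0],):
            raise ValueError("competency must be a length-N vector")

    @property
    def size(self) -> int:
        return self.genes.shape[0]

    @property
    def genome_length(self) -> int:
        return self.genes.shape[1]

    @property
    def competent_prevalence(self) -> float:
        """Fraction of embryos with a non-zero swap budget."""
        return float(np.count_nonzero(self.competency > 0)) / self.size

    @property
    def embryos(self) -> List[Embryo]:
        return [
            Embryo(self.genes[i].copy(), int(self.competency[i]), self.phenotypes[i].copy())
            for i in range(self.size)
        ]

    @classmethod
    def from_embryos(cls, embryos: Iterable[Embryo], generation: int = 0) -> "Population":
        embryos = list(embryos)
        genes = np.stack([e.structural_genes for e in embryos])
        comp = np.array([e.competency_gene for e in embryos], dtype=GENE_DTYPE)
        phen = np.stack([e.phenotype for e in embryos])
        return cls(genes, comp, phen, generation)


def init_population(config: GAConfig, rng: np.random.Generator) -> Population:
    """Create the founding population.

    Every embryo's structural genes are an independent uniform random
    permutation of ``1..genome_length``.  Competency genes follow the mode:
    all zero (hardwired), a shared constant (fixed), uniform draws from
    ``competency_init_range`` (evolvable), or ``round(fraction * N)``
    embryos at ``mixed_competency_level`` in random positions with the rest
    hardwired (mixed).
    """
    N, L = config.population_size, config.genome_length
    base = np.tile(np.arange(1, L + 1, dtype=GENE_DTYPE), (N, 1))
    genes = rng.permuted(base, axis=1)

    mode = config.competency_mode
    if mode == "hardwired":
        comp = np.zeros(N, dtype=GENE_DTYPE)
    elif mode == "fixed":
        comp = np.full(N, config.competency_level, dtype=GENE_DTYPE)
    elif mode == "evolvable":
        lo, hi = config.competency_init_range
        comp = rng.integers(lo, hi + 1, size=N, dtype=GENE_DTYPE)
    elif mode == "mixed":
        n_comp = int(round(config.mixed_competent_fraction * N))
        if n_comp < 1 or n_comp >= N:
            raise ConfigError(
                "mixed_competent_fraction leaves no competent or no hardwired embryos"
            )
        comp = np.zeros(N, dtype=GENE_DTYPE)
        comp[rng.permutation(N)[:n_comp]] = config.mixed_competency_level
    else:  # pragma: no cover - guarded by GAConfig validation
        raise ConfigError(f"unknown competency_mode {mode!r}")

    return Population(genes=genes, competency=comp, phenotypes=genes.copy(), generation=0)


# ---------------------------------------------------------------------------
# run bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class GenerationRecord:
    """Per-generation metrics, measured after development, before selection.

    "Best" metrics describe the single fittest individual by selection
    fitness (penalised phenotypic fitness when a competency cost applies,
    raw phenotypic fitness otherwise; ties go to the lowest population
    index).  ``best_genotypic_fitness`` is that same individual's
    pre-development fitness, i.e. what its fitness would have been had it
    not been allowed to enact its competency.
    """

    generation: int
    best_genotypic_fitness: float
    best_phenotypic_fitness: float
    max_genotypic_fitness: float
    mean_genotypic_fitness: float
    mean_phenotypic_fitness: float
    best_competency_gene: int
    competency_min: int
    competency_max: int
    competent_prevalence: float
    penalized_best_fitness: float
    mean_swaps_used: float
    geno_pheno_correlation: float
    per_gene_change_counts: Optional[np.ndarray] = field(default=None, repr=False)

    SCALAR_FIELDS = (
        "generation",
        "best_genotypic_fitness",
        "best_phenotypic_fitness",
        "max_genotypic_fitness",
        "mean_genotypic_fitness",
        "mean_phenotypic_fitness",
        "best_competency_gene",
        "competency_min",
        "competency_max",
        "competent_prevalence",
        "penalized_best_fitness",
        "mean_swaps_used",
        "geno_pheno_correlation",
    )

    def as_scalar_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.SCALAR_FIELDS}


@dataclass
class RunResult:
    """A completed evolutionary run: config, seed, and ordered records."""

    config: GAConfig
    seed: int
    records: List[GenerationRecord]
    repeat_index: int = 0

    def series(self, name: str) -> np.ndarray:
        """Per-generation array of one scalar record field."""
        return np.array([getattr(r, name) for r in self.records])

    def change_count_matrix(self) -> np.ndarray:
        """Cumulative per-gene change counts, shape ``(generations, L + 1)``.

        Column ``L`` (the last) tracks the competency gene.
        """
        return np.stack([r.per_gene_change_counts for r in self.records])

    def to_frame(self):
        """Scalar records as a pandas DataFrame (one row per generation)."""
        import pandas as pd

        return pd.DataFrame([r.as_scalar_dict() for r in self.records])
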