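"""The genetic algorithm: selection, cross-over, mutation, orchestration.

Each evolutionary cycle runs, in order:

1. record genotypic fitness (all embryos are "just born"),
2. develop every embryo (restricted bubble sort up to its swap budget),
3. record phenotypic — and, under a competency cost, penalised — fitness,
4. select the fittest ``selection_fraction`` by selection fitness,
5. repopulate to full strength by single-point cross-over of random
   survivor pairs,
6. apply point mutations to the repopulated population (survivors included).

All stochastic draws flow from one ``numpy`` Generator per run, in a fixed
order (initialisation, then per generation: parent pairing, split points,
mutation mask, mutation slots, mutation values), so a run is reproducible
bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import ConfigError, GAConfig
from .core import (
    GENE_DTYPE,
    Embryo,
    GenerationRecord,
    Population,
    RunResult,
    _fitness_rows,
    init_population,
)
from .development import develop_population, penalized_fitness

__all__ = [
    "SelectionResult",
    "select",
    "crossover_pair",
    "repopulate",
    "mutate",
    "step_generation",
    "run_evolution",
    "run_repeats",
]


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Survivors of one selection round, fittest first.

    Ties are broken by original population index, so when more embryos than
    the quota share the top fitness the first ones in population order win.
    """

    genes: np.ndarray
    competency: np.ndarray
    survivor_indices: np.ndarray

    @property
    def size(self) -> int:
        return self.genes.shape[0]

    @property
    def survivors(self) -> List[Embryo]:
        return [
            Embryo(self.genes[i].copy(), int(self.competency[i])) for i in range(self.size)
        ]


def _survivor_count(config: GAConfig) -> int:
    return max(2, math.floor(config.selection_fraction * config.population_size))


def _selection_fitness(pop: Population, config: GAConfig) -> np.ndarray:
    """Fitness selection acts on: phenotypic, minus the competency cost."""
    phen = _fitness_rows(pop.phenotypes, config.fitness_variant)
    if config.penalty_factor > 0:
        return penalized_fitness(phen, pop.competency, config.penalty_factor)
    return phen


def select(pop: Population, config: GAConfig) -> SelectionResult:
    """Keep the fittest ``floor(selection_fraction * N)`` individuals.

    Ranking uses the developed (phenotypic) fitness, penalised by the
    competency cost when one is configured.
    """
    if pop.size == 0:
        raise ValueError("cannot select from an empty population")
    return _select_by_fitness(pop, _selection_fitness(pop, config), _survivor_count(config))


def _select_by_fitness(pop: Population, fit: np.ndarray, k: int) -> SelectionResult:
    order = np.argsort(-fit, kind="stable")[:k]
    return SelectionResult(
        genes=pop.genes[order].copy(),
        competency=pop.competency[order].copy(),
        survivor_indices=order,
    )


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

def crossover_pair(
    p1: Embryo,
    p2: Embryo,
    split: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Embryo, Embryo]:
    """Single-point cross-over of two parents' structural genes.

    The genomes are cut at ``split`` (drawn uniformly from ``1..L-1`` when
    not given) and the right-hand segments are exchanged.  Each child
    inherits the competency gene of the parent donating its left segment.
    Children are born undeveloped: their phenotypes equal their structural
    genes.
    """
    L = p1.structural_genes.size
    if p2.structural_genes.size != L:
        raise ValueError("parents must share genome length")
    if split is None:
        if rng is None:
            raise ValueError("provide either a split position or an rng")
        split = int(rng.integers(1, L))
    if not 1 <= split <= L - 1:
        raise ValueError(f"split must lie in [1, {L - 1}], got {split}")
    g1, g2 = p1.structural_genes, p2.structural_genes
    c1 = np.concatenate([g1[:split], g2[split:]])
    c2 = np.concatenate([g2[:split], g1[split:]])
    return (
        Embryo(c1, p1.competency_gene),
        Embryo(c2, p2.competency_gene),
    )


def _same_type_partners(
    first: np.ndarray, is_competent: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Partner indices drawn uniformly among same-type survivors.

    The partner is a distinct survivor of the same type (competent or
    hardwired) as the first parent; a survivor whose type it alone
    represents is paired with itself (clonal reproduction).
    """
    pools = {
        True: np.nonzero(is_competent)[0],
        False: np.nonzero(~is_competent)[0],
    }
    raw = rng.integers(0, np.iinfo(np.int64).max, size=first.size)
    second = np.empty_like(first)
    for n, i in enumerate(first):
        pool = pools[bool(is_competent[i])]
        if pool.size == 1:
            second[n] = i
        else:
            pos = int(np.searchsorted(pool, i))
            second[n] = pool[(pos + 1 + raw[n] % (pool.size - 1)) % pool.size]
    return second


def repopulate(
    survivors: SelectionResult, config: GAConfig, rng: np.random.Generator
) -> Population:
    """Refill the population to full strength from the survivor pool.

    Survivors carry over unchanged; the deficit is filled with children from
    single-point cross-over of uniformly random *distinct* survivor pairs
    (each pairing yields two complementary children; one is discarded if the
    deficit is odd).  In ``mixed`` mode parents pair within their own type —
    competent with competent, hardwired with hardwired — so the competency
    gene cannot leak between the two lineages; the share of children each
    type receives still follows its share of the survivor pool.
    """
    k = survivors.size
    if k < 2:
        raise ValueError("repopulation needs at least 2 survivors")
    N, L = config.population_size, config.genome_length
    n_children = N - k
    genes_parts = [survivors.genes]
    comp_parts = [survivors.competency]
    if n_children > 0:
        n_pairs = (n_children + 1) // 2
        first = rng.integers(0, k, size=n_pairs)
        if config.competency_mode == "mixed":
            # the two embryo kinds are distinct lineages: partners come from
            # the same type, so competency never flows across types
            second = _same_type_partners(first, survivors.competency > 0, rng)
        else:
            offset = rng.integers(1, k, size=n_pairs)
            second = (first + offset) % k
        splits = rng.integers(1, L, size=n_pairs)
        left_of_split = splits[:, None] > np.arange(L)[None, :]
        ga, gb = survivors.genes[first], survivors.genes[second]
        child_a = np.where(left_of_split, ga, gb)
        child_b = np.where(left_of_split, gb, ga)
        children = np.empty((2 * n_pairs, L), dtype=GENE_DTYPE)
        children[0::2] = child_a
        children[1::2] = child_b
        child_comp = np.empty(2 * n_pairs, dtype=GENE_DTYPE)
        child_comp[0::2] = survivors.competency[first]
        child_comp[1::2] = survivors.competency[second]
        genes_parts.append(children[:n_children])
        comp_parts.append(child_comp[:n_children])
    genes = np.concatenate(genes_parts)[:N]
    comp = np.concatenate(comp_parts)[:N]
    return Population(genes=genes, competency=comp, phenotypes=genes.copy())


def mutate(pop: Population, config: GAConfig, rng: np.random.Generator) -> Population:
    """Apply point mutations to a repopulated population.

    Each embryo independently receives, with probability
    ``mutation_probability``, exactly one point mutation: a slot is chosen
    uniformly among the L structural genes — plus the competency gene as an
    (L+1)-th slot in ``evolvable`` mode — and resampled uniformly from its
    value range.  Outside evolvable mode the competency gene never mutates,
    so hardwired embryos can never gain competency and fixed/mixed levels
    stay put.
    """
    N, L = pop.size, pop.genome_length
    lo, hi = config.gene_value_range
    clo, chi = config.competency_gene_range
    n_slots = L + 1 if config.competency_mode == "evolvable" else L
    # fixed-size draws keep the stream layout independent of outcomes
    hit = rng.random(N) < config.mutation_probability
    slots = rng.integers(0, n_slots, size=N)
    gene_vals = rng.integers(lo, hi + 1, size=N, dtype=GENE_DTYPE)
    comp_vals = rng.integers(clo, chi + 1, size=N, dtype=GENE_DTYPE)

    genes = pop.genes.copy()
    comp = pop.competency.copy()
    struct_hit = hit & (slots < L)
    rows = np.nonzero(struct_hit)[0]
    genes[rows, slots[rows]] = gene_vals[rows]
    comp_rows = np.nonzero(hit & (slots == L))[0]
    comp[comp_rows] = comp_vals[comp_rows]
    return Population(
        genes=genes, competency=comp, phenotypes=genes.copy(), generation=pop.generation
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class _BestGenomeTracker:
    """Cumulative change counts of the best individual's genes over time."""

    def __init__(self, genome_length: int):
        self.counts = np.zeros(genome_length + 1, dtype=np.int64)
        self._prev: Optional[np.ndarray] = None

    def update(self, genes: np.ndarray, competency: int) -> np.ndarray:
        current = np.concatenate([genes, [competency]])
        if self._prev is not None:
            self.counts += current != self._prev
        self._prev = current
        return self.counts.copy()


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r across individuals; 0.0 when either side has no variance."""
    xs, ys = x - x.mean(), y - y.mean()
    vx, vy = float(xs @ xs), float(ys @ ys)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    return float((xs @ ys) / math.sqrt(vx * vy))


def step_generation(
    pop: Population,
    config: GAConfig,
    rng: np.random.Generator,
    tracker: Optional[_BestGenomeTracker] = None,
) -> Tuple[Population, GenerationRecord]:
    """Run one full evolutionary cycle; returns the next population and the
    record measured after development, before selection."""
    variant = config.fitness_variant
    geno_fit = _fitness_rows(pop.genes, variant)
    _, swaps = develop_population(pop)
    phen_fit = _fitness_rows(pop.phenotypes, variant)
    if config.penalty_factor > 0:
        sel_fit = penalized_fitness(phen_fit, pop.competency, config.penalty_factor)
    else:
        sel_fit = phen_fit

    best = int(np.argmax(sel_fit))  # first index on ties, per selection rule
    counts = tracker.update(pop.genes[best], int(pop.competency[best])) if tracker else None
    record = GenerationRecord(
        generation=pop.generation,
        best_genotypic_fitness=float(geno_fit[best]),
        best_phenotypic_fitness=float(phen_fit[best]),
        max_genotypic_fitness=float(geno_fit.max()),
        mean_genotypic_fitness=float(geno_fit.mean()),
        mean_phenotypic_fitness=float(phen_fit.mean()),
        best_competency_gene=int(pop.competency[best]),
        competency_min=int(pop.competency.min()),
        competency_max=int(pop.competency.max()),
        competent_prevalence=pop.competent_prevalence,
        penalized_best_fitness=float(sel_fit[best]),
        mean_swaps_used=float(swaps.mean()),
        geno_pheno_correlation=_pearson_rows(geno_fit, phen_fit),
        per_gene_change_counts=counts,
    )

    survivors = _select_by_fitness(pop, sel_fit, _survivor_count(config))
    nxt = repopulate(survivors, config, rng)
    nxt = mutate(nxt, config, rng)
    nxt.generation = pop.generation + 1
    return nxt, record


def run_evolution(
    config: GAConfig, repeat_index: int = 0, track_best_genome: bool = True
) -> RunResult:
    """Run one seeded evolutionary trajectory of ``config.generations`` cycles.

    The run seed is ``config.seed + repeat_index``; identical inputs yield
    bit-identical trajectories.
    """
    seed = config.seed + repeat_index
    rng = np.random.default_rng(seed)
    pop = init_population(config, rng)
    tracker = _BestGenomeTracker(config.genome_length) if track_best_genome else None
    records: List[GenerationRecord] = []
    for _ in range(config.generations):
        pop, record = step_generation(pop, config, rng, tracker)
        records.append(record)
    return RunResult(config=config, seed=seed, records=records, repeat_index=repeat_index)


def run_repeats(config: GAConfig, track_best_genome: bool = True) -> List[RunResult]:
    """Monte-Carlo repeats of a run; repeat ``r`` uses seed ``seed + r``."""
    return [
        run_evolution(config, repeat_index=r, track_best_genome=track_best_genome)
        for r in range(config.repeats)
    ]
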