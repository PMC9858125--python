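"""The developmental cycle: restricted bubble sort and the competency cost.

A competent embryo's cells can sense their neighbours and trade places
before fitness is evaluated.  This is modelled as a *restricted bubble
sort*: repeated left-to-right passes over adjacent cell pairs, swapping any
strictly out-of-order pair, with a hard budget on the number of executed
swaps (the embryo's competency level).  Comparisons are free; the sweep
halts as soon as the budget is spent or a full pass makes no swap.

Because every executed swap removes exactly one inversion, the developed
array has ``max(0, initial_inversions - budget)`` inversions left — the
swap–inversion lemma the test suite checks exhaustively.

Development acts on a working copy: the heritable structural genes are
never modified (no Lamarckian inheritance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .core import GENE_DTYPE, Embryo, Population

__all__ = [
    "DevelopmentOutcome",
    "restricted_bubble_sort",
    "develop",
    "develop_population",
    "penalized_fitness",
]

try:  # numba accelerates the per-cell swap loop ~100x; fall back to pure python
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _bubble_restricted(arr: np.ndarray, budget: int) -> int:
    """In-place restricted bubble sort; returns the number of swaps used."""
    n = arr.shape[0]
    used = 0
    if budget <= 0:
        return 0
    swapped = True
    while swapped:
        swapped = False
        for i in range(n - 1):
            if arr[i] > arr[i + 1]:
                tmp = arr[i]
                arr[i] = arr[i + 1]
                arr[i + 1] = tmp
                used += 1
                swapped = True
                if used >= budget:
                    return used
    return used


@njit(cache=False)
def _develop_rows(genes: np.ndarray, budgets: np.ndarray, out: np.ndarray) -> np.ndarray:
    n_rows = genes.shape[0]
    swaps = np.zeros(n_rows, dtype=np.int64)
    for r in range(n_rows):
        out[r, :] = genes[r, :]
        if budgets[r] > 0:
            swaps[r] = _bubble_restricted(out[r], budgets[r])
    return swaps


@dataclass
class DevelopmentOutcome:
    """Result of one embryo's developmental cycle."""

    phenotype: np.ndarray
    swaps_used: int


def restricted_bubble_sort(seq: Sequence[int], budget: int) -> DevelopmentOutcome:
    """Sort ``seq`` toward ascending order using at most ``budget`` swaps.

    Returns the rearranged copy and the number of swaps actually executed,
    which is ``min(budget, count_inversions(seq))``.
    """
    if budget < 0:
        raise ValueError("swap budget must be non-negative")
    arr = np.array(seq, dtype=GENE_DTYPE)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    used = int(_bubble_restricted(arr, int(budget)))
    return DevelopmentOutcome(phenotype=arr, swaps_used=used)


def develop(e: Embryo) -> Embryo:
    """Run one embryo's developmental cycle.

    Returns a new embryo whose phenotype is the (budget-limited) bubble-sorted
    arrangement of its structural genes; hardwired embryos (competency 0)
    develop into themselves.  Structural genes are inherited, phenotypes are
    not.
    """
    outcome = restricted_bubble_sort(e.structural_genes, e.competency_gene)
    return Embryo(
        structural_genes=e.structural_genes.copy(),
        competency_gene=e.competency_gene,
        phenotype=outcome.phenotype,
    )


def develop_population(pop: Population) -> Tuple[np.ndarray, np.ndarray]:
    """Develop every embryo in a population.

    Returns ``(phenotypes, swaps_used)`` and stores the phenotypes on the
    population in place.
    """
    out = np.empty_like(pop.genes)
    swaps = _develop_rows(pop.genes, pop.competency, out)
    pop.phenotypes = out
    return out, np.asarray(swaps)


def penalized_fitness(f_phen, competency, penalty_factor: float):
    """Selection fitness under a competency cost.

    ``max(0, f_phen − λ · competency)``: embryos pay linearly for the swap
    budget they carry, so a high competency gene is only worth keeping while
    the fitness it rescues exceeds its price.  Accepts scalars or arrays.
    """
    if penalty_factor < 0:
        raise ValueError("penalty factor must be non-negative")
    penalized = np.asarray(f_phen, dtype=float) - penalty_factor * np.asarray(
        competency, dtype=float
    )
    clipped = np.maximum(0.0, penalized)
    if np.isscalar(f_phen) or getattr(f_phen, "ndim", 0) == 0:
        return float(clipped)
    return clipped
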