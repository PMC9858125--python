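"""Scenario runners and summary statistics.

This module packages the study's standard experiments:

* fixed-competency comparison — hardwired vs. constant swap budgets,
  breakthrough-generation table, mean/CI fitness trajectories;
* mixed populations — competent minorities invading a hardwired majority,
  dominance-time table;
* evolvable competency — the competency gene as a heritable, mutable trait,
  its plateau, the genotype/phenotype fitness divergence and decorrelation,
  and per-gene change frequencies;
* Baldwin-effect runs — evolvable competency under a linear fitness cost;
* a hyperparameter scan of mutation probability x selection stringency.

Suites take a base :class:`~embryogeny.config.GAConfig` and derive one
config per experimental condition; repeat ``r`` of a condition runs with
seed ``condition_seed + r`` where condition seeds are spaced by a fixed
stride from the suite root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import GAConfig
from .core import RunResult
from .evolution import run_evolution

__all__ = [
    "breakthrough_generation",
    "dominance_time",
    "ci_band",
    "compare_best_fitness",
    "geno_pheno_correlation",
    "gene_change_frequencies",
    "stable_competency_value",
    "BreakthroughTable",
    "DominanceTable",
    "ScanResult",
    "FixedSuiteResult",
    "MixedSuiteResult",
    "EvolvableSuiteResult",
    "GeneChangeSummary",
    "run_fixed_competency_suite",
    "run_mixed_population_suite",
    "run_evolvable_competency",
    "run_baldwin",
    "hyperparameter_scan",
    "FITNESS_THRESHOLDS",
    "MIXED_LEVELS",
    "MIXED_FRACTIONS",
]

FITNESS_THRESHOLDS = (0.65, 0.75, 0.8, 0.9, 0.97, 1.0)
MIXED_LEVELS = (10, 25, 40, 75, 95)
MIXED_FRACTIONS = (0.025, 0.10, 0.20, 0.30)

_SEED_STRIDE = 100_003  # condition seeds spaced by a prime >> any repeat count
_EPS = 1e-9


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def breakthrough_generation(
    best_fitness_series: Sequence[float], threshold: float
) -> Optional[int]:
    """First generation (1-based) at which the series reaches ``threshold``.

    Intended for repeat-averaged best-fitness trajectories; returns ``None``
    if the threshold is never reached.
    """
    series = np.asarray(best_fitness_series, dtype=float)
    if series.size == 0:
        raise ValueError("empty fitness series")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    hits = np.nonzero(series >= threshold - _EPS)[0]
    return int(hits[0]) + 1 if hits.size else None


def dominance_time(prevalence_series: Sequence[float]) -> Optional[int]:
    """Generation (1-based) at which competent embryos take over for good.

    The smallest ``g`` with prevalence above 0.5 at ``g`` and never
    decreasing afterwards; ``None`` if no such point exists.
    """
    p = np.asarray(prevalence_series, dtype=float)
    if p.size == 0:
        raise ValueError("empty prevalence series")
    nondecreasing_tail = np.ones(p.size, dtype=bool)
    for t in range(p.size - 2, -1, -1):
        nondecreasing_tail[t] = nondecreasing_tail[t + 1] and (p[t + 1] >= p[t] - _EPS)
    hits = np.nonzero((p > 0.5) & nondecreasing_tail)[0]
    return int(hits[0]) + 1 if hits.size else None


def ci_band(
    series_matrix: np.ndarray, level: float = 0.95
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normal-approximation confidence band over Monte-Carlo repeats.

    ``series_matrix`` is ``(repeats, generations)``; returns
    ``(mean, lower, upper)`` with half-width ``z * SD / sqrt(n)``.
    """
    m = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    n = m.shape[0]
    mean = m.mean(axis=0)
    if n < 2:
        return mean, mean.copy(), mean.copy()
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * m.std(axis=0, ddof=1) / math.sqrt(n)
    return mean, mean - half, mean + half


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def compare_best_fitness(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample Student's t-test on per-repeat best fitness."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 repeats per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # zero pooled variance: identical constants => no evidence either way
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(math.inf if a.mean() > b.mean() else -math.inf, 0.0, True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p))


def geno_pheno_correlation(
    per_generation_correlation: Sequence[float], window: int = 10
) -> np.ndarray:
    """Average a per-generation correlation series over non-overlapping windows.

    The per-generation values are population Pearson correlations between
    individuals' genotypic and phenotypic fitness (0 by convention when
    either has no variance, e.g. once every phenotype saturates).  Trailing
    generations that do not fill a window are dropped.
    """
    series = np.asarray(per_generation_correlation, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n_windows = series.size // window
    if n_windows == 0:
        raise ValueError("series shorter than one window")
    return series[: n_windows * window].reshape(n_windows, window).mean(axis=1)


def stable_competency_value(run: RunResult) -> float:
    """Mean best-individual competency gene over the final 10% of generations."""
    comp = run.series("best_competency_gene").astype(float)
    if comp.size < 10:
        raise ValueError("run too short to define a stable value (need >= 10 generations)")
    tail = max(1, comp.size // 10)
    return float(comp[-tail:].mean())


@dataclass
class GeneChangeSummary:
    """Per-gene change frequencies of the best individual's genome.

    ``cumulative`` is ``(generations, L + 1)`` running change counts
    (column ``L`` is the competency gene); ``per_gene_frequency`` is the
    time-averaged change rate per gene.
    """

    cumulative: np.ndarray
    per_gene_frequency: np.ndarray

    @property
    def structural_mean_frequency(self) -> float:
        return float(self.per_gene_frequency[:-1].mean())

    @property
    def competency_frequency(self) -> float:
        return float(self.per_gene_frequency[-1])


def gene_change_frequencies(run: RunResult) -> GeneChangeSummary:
    """How often each gene of the per-generation best individual changed.

    Counts, between consecutive generations, every position at which the
    best individual's genome (50 structural genes + the competency gene)
    differs from the previous best, cumulatively over the run.
    """
    cumulative = run.change_count_matrix()
    n_gen = cumulative.shape[0]
    return GeneChangeSummary(
        cumulative=cumulative,
        per_gene_frequency=cumulative[-1].astype(float) / max(1, n_gen - 1),
    )


# ---------------------------------------------------------------------------
# suite plumbing
# ---------------------------------------------------------------------------

def _run_condition(
    config: GAConfig, repeats: int, track_best_genome: bool = False
) -> List[RunResult]:
    return [
        run_evolution(config, repeat_index=r, track_best_genome=track_best_genome)
        for r in range(repeats)
    ]


def _series_matrix(runs: Sequence[RunResult], name: str) -> np.ndarray:
    return np.stack([run.series(name) for run in runs])


@dataclass
class ConditionTrajectories:
    """Repeat matrices and mean trajectories for one experimental condition."""

    label: str
    config: GAConfig
    best_phenotypic: np.ndarray  # (repeats, generations)
    best_genotypic: np.ndarray
    founding_genotypic_best: np.ndarray  # (repeats,) max genotypic fitness at birth
    mean_best_phenotypic: np.ndarray = field(init=False)
    mean_best_genotypic: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_best_phenotypic = self.best_phenotypic.mean(axis=0)
        self.mean_best_genotypic = self.best_genotypic.mean(axis=0)

    @property
    def breakthrough_series(self) -> np.ndarray:
        """Repeat-averaged best-fitness trajectory for threshold timing.

        Generation 1 is the founding population recorded at birth — before
        its developmental phase, so its best fitness is genotypic — and each
        later generation is recorded after development.
        """
        return np.concatenate(
            [[self.founding_genotypic_best.mean()], self.mean_best_phenotypic]
        )


# ---------------------------------------------------------------------------
# fixed-competency suite
# ---------------------------------------------------------------------------

@dataclass
class BreakthroughTable:
    """Generations to first reach each fitness threshold, per condition."""

    thresholds: Tuple[float, ...]
    rows: Dict[str, List[Optional[int]]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            self.rows, orient="index", columns=[str(t) for t in self.thresholds]
        )


@dataclass
class FixedSuiteResult:
    table: BreakthroughTable
    trajectories: Dict[str, ConditionTrajectories]

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for label, traj in self.trajectories.items():
            n_rep, n_gen = traj.best_phenotypic.shape
            frames.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "repeat": np.repeat(np.arange(n_rep), n_gen),
                        "generation": np.tile(np.arange(n_gen), n_rep),
                        "best_phenotypic_fitness": traj.best_phenotypic.ravel(),
                        "best_genotypic_fitness": traj.best_genotypic.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def condition_label(level: int) -> str:
    return "hardwired" if level == 0 else f"level_{level}"


def run_fixed_competency_suite(
    base: Optional[GAConfig] = None,
    levels: Sequence[int] = (0, 20, 100, 400),
    generations: int = 250,
    repeats: int = 100,
    seed: int = 0,
    thresholds: Sequence[float] = FITNESS_THRESHOLDS,
) -> FixedSuiteResult:
    """Hardwired vs. fixed-competency populations (level 0 = hardwired).

    Returns the breakthrough table and the per-condition trajectory matrices
    for both phenotypic and genotypic best fitness.  Threshold crossings are
    timed on the repeat-averaged best-fitness trajectory whose first point is
    the founding population at birth (undeveloped, hence genotypic) and whose
    later points are post-development phenotypic bests.
    """
    base = base or GAConfig()
    trajectories: Dict[str, ConditionTrajectories] = {}
    rows: Dict[str, List[Optional[int]]] = {}
    for idx, level in enumerate(levels):
        mode = "hardwired" if level == 0 else "fixed"
        config = base.with_(
            competency_mode=mode,
            competency_level=level,
            generations=generations,
            seed=seed + idx * _SEED_STRIDE,
        )
        runs = _run_condition(config, repeats)
        label = condition_label(level)
        traj = ConditionTrajectories(
            label=label,
            config=config,
            best_phenotypic=_series_matrix(runs, "best_phenotypic_fitness"),
            best_genotypic=_series_matrix(runs, "best_genotypic_fitness"),
            founding_genotypic_best=np.array(
                [run.records[0].max_genotypic_fitness for run in runs]
            ),
        )
        trajectories[label] = traj
        rows[label] = [
            breakthrough_generation(traj.breakthrough_series, t) for t in thresholds
        ]
    return FixedSuiteResult(
        table=BreakthroughTable(tuple(thresholds), rows), trajectories=trajectories
    )


# ---------------------------------------------------------------------------
# mixed-population suite
# ---------------------------------------------------------------------------

@dataclass
class DominanceTable:
    """Generations for competent embryos to dominate, per (level, fraction)."""

    levels: Tuple[int, ...]
    fractions: Tuple[float, ...]
    cells: Dict[Tuple[int, float], Optional[int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(lvl, f)] for f in self.fractions] for lvl in self.levels],
            index=[f"level_{lvl}" for lvl in self.levels],
            columns=[f"{100 * f:g}%" for f in self.fractions],
        )

    def min_dominating_level(self, fraction: float) -> Optional[int]:
        """Smallest tested competency level that dominates at this fraction."""
        for lvl in sorted(self.levels):
            if self.cells[(lvl, fraction)] is not None:
                return lvl
        return None


@dataclass
class MixedSuiteResult:
    table: DominanceTable
    prevalence: Dict[Tuple[int, float], np.ndarray]  # mean prevalence per generation


def run_mixed_population_suite(
    base: Optional[GAConfig] = None,
    levels: Sequence[int] = MIXED_LEVELS,
    fractions: Sequence[float] = MIXED_FRACTIONS,
    generations: int = 30,
    repeats: int = 20,
    population_size: int = 200,
    seed: int = 0,
) -> MixedSuiteResult:
    """Competent minorities invading hardwired majorities.

    Each (competency level, initial fraction) cell runs ``repeats`` seeded
    trajectories; dominance is judged on the repeat-averaged prevalence
    series using the rule of :func:`dominance_time`.
    """
    base = base or GAConfig()
    cells: Dict[Tuple[int, float], Optional[int]] = {}
    prevalence: Dict[Tuple[int, float], np.ndarray] = {}
    for idx, (level, fraction) in enumerate(
        [(lvl, f) for lvl in levels for f in fractions]
    ):
        config = base.with_(
            population_size=population_size,
            competency_mode="mixed",
            mixed_competency_level=level,
            mixed_competent_fraction=fraction,
            generations=generations,
            seed=seed + idx * _SEED_STRIDE,
        )
        runs = _run_condition(config, repeats)
        mean_prev = _series_matrix(runs, "competent_prevalence").mean(axis=0)
        prevalence[(level, fraction)] = mean_prev
        cells[(level, fraction)] = dominance_time(mean_prev)
    return MixedSuiteResult(
        table=DominanceTable(tuple(levels), tuple(fractions), cells), prevalence=prevalence
    )


# ---------------------------------------------------------------------------
# evolvable competency and the Baldwin effect
# ---------------------------------------------------------------------------

@dataclass
class EvolvableSuiteResult:
    """Repeat matrices from evolvable-competency runs (optionally penalised)."""

    config: GAConfig
    runs: List[RunResult]
    best_competency: np.ndarray  # (repeats, generations)
    best_phenotypic: np.ndarray
    best_genotypic: np.ndarray
    correlation: np.ndarray  # per-generation population geno/pheno Pearson r

    @property
    def mean_best_competency(self) -> np.ndarray:
        return self.best_competency.mean(axis=0)

    @property
    def mean_best_phenotypic(self) -> np.ndarray:
        return self.best_phenotypic.mean(axis=0)

    @property
    def mean_best_genotypic(self) -> np.ndarray:
        return self.best_genotypic.mean(axis=0)

    @property
    def mean_correlation(self) -> np.ndarray:
        return self.correlation.mean(axis=0)

    def mean_stable_competency(self) -> float:
        return float(np.mean([stable_competency_value(run) for run in self.runs]))

    def windowed_correlation(self, window: int = 10) -> np.ndarray:
        return geno_pheno_correlation(self.mean_correlation, window=window)

    def saturation_generation(self, threshold: float = 1.0) -> Optional[int]:
        """First generation (1-based) where the repeat-averaged best
        phenotypic fitness reaches ``threshold``."""
        return breakthrough_generation(self.mean_best_phenotypic, threshold)


def run_evolvable_competency(
    base: Optional[GAConfig] = None,
    generations: int = 1000,
    repeats: int = 100,
    seed: int = 0,
    penalty_factor: float = 0.0,
) -> EvolvableSuiteResult:
    """Evolvable-competency runs: competency genes start low ([1, 15]) and
    mutate freely over [1, 500]."""
    base = base or GAConfig()
    config = base.with_(
        competency_mode="evolvable",
        generations=generations,
        penalty_factor=penalty_factor,
        seed=seed,
    )
    runs = _run_condition(config, repeats, track_best_genome=True)
    return EvolvableSuiteResult(
        config=config,
        runs=runs,
        best_competency=_series_matrix(runs, "best_competency_gene").astype(float),
        best_phenotypic=_series_matrix(runs, "best_phenotypic_fitness"),
        best_genotypic=_series_matrix(runs, "best_genotypic_fitness"),
        correlation=_series_matrix(runs, "geno_pheno_correlation"),
    )


def run_baldwin(
    base: Optional[GAConfig] = None,
    penalty_factor: float = 1e-4,
    generations: int = 3000,
    repeats: int = 100,
    seed: int = 0,
) -> EvolvableSuiteResult:
    """Evolvable competency under a linear competency cost.

    With a small positive cost, phenotypic fitness still saturates early but
    the structural genome keeps improving and the competency gene declines —
    the plastic gain is assimilated into the genome (Baldwin effect).
    Selection uses the penalised fitness; recorded phenotypic fitness stays
    unpenalised.
    """
    return run_evolvable_competency(
        base=base,
        generations=generations,
        repeats=repeats,
        seed=seed,
        penalty_factor=penalty_factor,
    )


# ---------------------------------------------------------------------------
# hyperparameter scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Stable competency values over a mutation x selection grid."""

    grid: pd.DataFrame  # columns: mutation_probability, selection_fraction, stable_competency
    mutation_correlation: float
    selection_correlation: float


def hyperparameter_scan(
    base: Optional[GAConfig] = None,
    mutation_probabilities: Optional[Sequence[float]] = None,
    selection_fractions: Optional[Sequence[float]] = None,
    generations: int = 300,
    repeats: int = 2,
    seed: int = 0,
    runner=None,
) -> ScanResult:
    """Sensitivity of the stable competency value to GA hyperparameters.

    The default grid is 12 mutation probabilities x 11 selection fractions,
    evenly spaced inclusive over [0.2, 0.8] (132 cells).  Each cell runs the
    evolvable-competency experiment (reduced generations/repeats) and
    reports the tail-mean best competency gene; the two Pearson
    correlations of that value against the grid axes summarise the scan.

    ``runner(config) -> float`` may replace the per-cell simulation (used
    for testing against hand-computed correlations).
    """
    base = base or GAConfig()
    if mutation_probabilities is None:
        mutation_probabilities = np.linspace(0.2, 0.8, 12)
    if selection_fractions is None:
        selection_fractions = np.linspace(0.2, 0.8, 11)

    def default_runner(config: GAConfig) -> float:
        runs = _run_condition(config, repeats)
        return float(np.mean([stable_competency_value(run) for run in runs]))

    runner = runner or default_runner
    records = []
    idx = 0
    for mp in mutation_probabilities:
        for sf in selection_fractions:
            config = base.with_(
                competency_mode="evolvable",
                mutation_probability=float(mp),
                selection_fraction=float(sf),
                generations=generations,
                seed=seed + idx * _SEED_STRIDE,
            )
            records.append(
                {
                    "mutation_probability": float(mp),
                    "selection_fraction": float(sf),
                    "stable_competency": runner(config),
                }
            )
            idx += 1
    grid = pd.DataFrame.from_records(records)

    def _corr(x: pd.Series, y: pd.Series) -> float:
        if x.std() == 0.0 or y.std() == 0.0:
            return 0.0
        return float(stats.pearsonr(x, y)[0])

    return ScanResult(
        grid=grid,
        mutation_correlation=_corr(grid["mutation_probability"], grid["stable_competency"]),
        selection_correlation=_corr(grid["selection_fraction"], grid["stable_competency"]),
    )
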