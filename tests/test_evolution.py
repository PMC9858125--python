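"""Genetic algorithm: selection, cross-over, repopulation, mutation, loop."""

import numpy as np
import pytest

from embryogeny import (
    Embryo,
    GAConfig,
    crossover_pair,
    init_population,
    mutate,
    repopulate,
    run_evolution,
    select,
    step_generation,
)
from embryogeny.development import develop_population
from embryogeny.evolution import _select_by_fitness


class TestSelect:
    def test_survivor_count(self, rng):
        cfg = GAConfig()
        pop = init_population(cfg, rng)
        develop_population(pop)
        sel = select(pop, cfg)
        assert sel.size == 10

    def test_ties_resolved_by_population_order(self, rng):
        cfg = GAConfig(population_size=10, genome_length=5, selection_fraction=0.3)
        pop = init_population(cfg, rng)
        fit = np.ones(10)  # everyone maximally fit
        sel = _select_by_fitness(pop, fit, 3)
        assert sel.survivor_indices.tolist() == [0, 1, 2]

    def test_full_fraction_keeps_everyone(self, rng):
        cfg = GAConfig(population_size=10, genome_length=5, selection_fraction=1.0)
        pop = init_population(cfg, rng)
        develop_population(pop)
        sel = select(pop, cfg)
        assert sorted(sel.survivor_indices.tolist()) == list(range(10))

    def test_penalty_changes_ranking(self, rng):
        """With a steep competency cost, a competent embryo at peak phenotypic
        fitness loses to an unpenalised mediocre one."""
        cfg = GAConfig(
            population_size=4,
            genome_length=4,
            gene_value_range=(1, 4),
            competency_mode="fixed",
            competency_level=0,
            penalty_factor=0.01,
            selection_fraction=0.5,
        )
        genes = np.array([[1, 2, 3, 4], [1, 2, 4, 3], [4, 3, 2, 1], [4, 3, 2, 1]])
        comp = np.array([90, 0, 0, 0])
        from embryogeny.core import Population

        pop = Population(genes=genes, competency=comp, phenotypes=genes.copy())
        develop_population(pop)
        sel = select(pop, cfg)
        # embryo 0 is perfect (1.0) but pays 0.9 penalty -> 0.1, below embryo 1
        assert sel.survivor_indices.tolist()[0] == 1


class TestCrossoverPair:
    def test_segment_exchange(self):
        p1 = Embryo([1, 2, 3, 4, 5, 6])
        p2 = Embryo([6, 5, 4, 3, 2, 1])
        c1, c2 = crossover_pair(p1, p2, split=3)
        assert c1.structural_genes.tolist() == [1, 2, 3, 3, 2, 1]
        assert c2.structural_genes.tolist() == [6, 5, 4, 4, 5, 6]

    def test_identical_parents_clone(self):
        p = Embryo([2, 4, 1, 3])
        c1, c2 = crossover_pair(p, p, split=2)
        assert c1.structural_genes.tolist() == p.structural_genes.tolist()
        assert c2.structural_genes.tolist() == p.structural_genes.tolist()

    def test_competency_follows_left_donor(self):
        p1 = Embryo([1, 2, 3, 4], competency_gene=0)
        p2 = Embryo([4, 3, 2, 1], competency_gene=9)
        c1, c2 = crossover_pair(p1, p2, split=3)
        assert c1.competency_gene == 0 and c1.is_hardwired
        assert c2.competency_gene == 9

    def test_children_born_undeveloped(self):
        p1 = Embryo([3, 1, 2], competency_gene=5)
        d = p1
        c1, _ = crossover_pair(d, d, split=1)
        np.testing.assert_array_equal(c1.phenotype, c1.structural_genes)

    def test_split_bounds(self):
        p = Embryo([1, 2, 3])
        with pytest.raises(ValueError):
            crossover_pair(p, p, split=0)
        with pytest.raises(ValueError):
            crossover_pair(p, p, split=3)


class TestRepopulate:
    def test_restores_population_size(self, rng, tiny_config):
        pop = init_population(tiny_config, rng)
        develop_population(pop)
        sel = select(pop, tiny_config)
        nxt = repopulate(sel, tiny_config, rng)
        assert nxt.size == tiny_config.population_size

    def test_survivors_carried_unchanged(self, rng, tiny_config):
        pop = init_population(tiny_config, rng)
        develop_population(pop)
        sel = select(pop, tiny_config)
        nxt = repopulate(sel, tiny_config, rng)
        np.testing.assert_array_equal(nxt.genes[: sel.size], sel.genes)

    def test_children_are_parent_segments(self, rng, tiny_config):
        """Each child's left and right segment occurs verbatim in a survivor."""
        pop = init_population(tiny_config, rng)
        develop_population(pop)
        sel = select(pop, tiny_config)
        nxt = repopulate(sel, tiny_config, rng)
        L = tiny_config.genome_length
        survivor_rows = [tuple(r) for r in sel.genes.tolist()]
        for child in nxt.genes[sel.size :]:
            child = child.tolist()
            ok = False
            for s in range(1, L):
                left_match = any(r[:s] == tuple(child[:s]) for r in survivor_rows)
                right_match = any(r[s:] == tuple(child[s:]) for r in survivor_rows)
                if left_match and right_match:
                    ok = True
                    break
            assert ok

    def test_two_survivors_minimum(self, rng):
        cfg = GAConfig(population_size=4, genome_length=4, gene_value_range=(1, 4),
                       selection_fraction=0.5)
        pop = init_population(cfg, rng)
        develop_population(pop)
        sel = select(pop, cfg)
        assert sel.size == 2
        nxt = repopulate(sel, cfg, rng)
        assert nxt.size == 4

    def test_mixed_mode_pairs_within_type(self, rng):
        """In mixed populations the competency gene never crosses between the
        competent and hardwired lineages during reproduction."""
        cfg = GAConfig(
            population_size=40,
            competency_mode="mixed",
            mixed_competent_fraction=0.25,
            mixed_competency_level=50,
        )
        pop = init_population(cfg, rng)
        develop_population(pop)
        sel = select(pop, cfg)
        nxt = repopulate(sel, cfg, rng)
        assert set(nxt.competency.tolist()) <= {0, 50}
        # type shares among children mirror survivor shares in expectation;
        # here we only require both types present iff both survived
        survivor_types = set((sel.competency > 0).tolist())
        child_types = set((nxt.competency[sel.size:] > 0).tolist())
        assert child_types <= survivor_types


class TestMutate:
    def test_zero_probability_is_identity(self, rng, tiny_config):
        cfg = tiny_config.with_(mutation_probability=0.0)
        pop = init_population(cfg, rng)
        nxt = mutate(pop, cfg, rng)
        np.testing.assert_array_equal(nxt.genes, pop.genes)
        np.testing.assert_array_equal(nxt.competency, pop.competency)

    def test_at_most_one_position_changes(self, rng):
        cfg = GAConfig(mutation_probability=1.0, competency_mode="fixed",
                       competency_level=20)
        pop = init_population(cfg, rng)
        nxt = mutate(pop, cfg, rng)
        diffs = (nxt.genes != pop.genes).sum(axis=1)
        assert diffs.max() <= 1
        np.testing.assert_array_equal(nxt.competency, pop.competency)

    def test_values_stay_in_range(self, rng):
        cfg = GAConfig(mutation_probability=1.0, competency_mode="evolvable")
        pop = init_population(cfg, rng)
        for _ in range(20):
            pop = mutate(pop, cfg, rng)
        lo, hi = cfg.gene_value_range
        assert pop.genes.min() >= lo and pop.genes.max() <= hi
        clo, chi = cfg.competency_gene_range
        assert pop.competency.min() >= clo and pop.competency.max() <= chi

    def test_hardwired_never_gain_competency(self, rng):
        cfg = GAConfig(mutation_probability=1.0)  # hardwired mode
        pop = init_population(cfg, rng)
        for _ in range(10):
            pop = mutate(pop, cfg, rng)
        assert (pop.competency == 0).all()

    def test_evolvable_competency_explores_full_range(self):
        """Over a long run, mutated competency genes span most of [1, 500]."""
        cfg = GAConfig(competency_mode="evolvable", generations=200, seed=4)
        run = run_evolution(cfg)
        assert max(r.competency_max for r in run.records) > 450


class TestStepAndRun:
    def test_elitism_without_mutation(self, rng):
        """With mutation off, the best phenotypic fitness never decreases."""
        cfg = GAConfig(mutation_probability=0.0, generations=30, seed=2)
        run = run_evolution(cfg)
        series = run.series("best_phenotypic_fitness")
        assert (np.diff(series) >= -1e-12).all()

    def test_saturated_budget_perfect_from_start(self, rng):
        cfg = GAConfig(competency_mode="fixed", competency_level=50 * 49 // 2,
                       generations=1, seed=0)
        run = run_evolution(cfg)
        assert run.records[0].best_phenotypic_fitness == 1.0

    def test_population_size_constant(self, rng, tiny_config):
        pop = init_population(tiny_config, rng)
        for _ in range(5):
            pop, _ = step_generation(pop, tiny_config, rng)
            assert pop.size == tiny_config.population_size

    def test_heredity_barrier(self, rng):
        """Children are built from structural genes, never from developed
        phenotypes: after a step, every genome is born undeveloped."""
        cfg = GAConfig(competency_mode="fixed", competency_level=100,
                       mutation_probability=0.0)
        pop = init_population(cfg, rng)
        nxt, _ = step_generation(pop, cfg, rng)
        np.testing.assert_array_equal(nxt.genes, nxt.phenotypes)

    def test_deterministic_trajectories(self):
        cfg = GAConfig(competency_mode="evolvable", generations=20, seed=42)
        a = run_evolution(cfg)
        b = run_evolution(cfg)
        for ra, rb in zip(a.records, b.records):
            assert ra.as_scalar_dict() == rb.as_scalar_dict()

    def test_repeats_use_distinct_seeds(self):
        cfg = GAConfig(generations=5, seed=42)
        a = run_evolution(cfg, repeat_index=0)
        b = run_evolution(cfg, repeat_index=1)
        assert a.seed == 42 and b.seed == 43
        assert a.series("best_phenotypic_fitness").tolist() != b.series(
            "best_phenotypic_fitness"
        ).tolist()

    def test_records_measured_before_selection(self):
        """Mean genotypic fitness at generation 0 reflects the random founding
        population (~0.5), not the post-selection elite."""
        cfg = GAConfig(generations=1, seed=8)
        run = run_evolution(cfg)
        assert abs(run.records[0].mean_genotypic_fitness - 0.5) < 0.05

    def test_competent_run_accelerates(self):
        """Higher fixed budgets reach high fitness sooner (acceleration)."""
        gens = {}
        for level in (0, 400):
            cfg = GAConfig(
                competency_mode="fixed" if level else "hardwired",
                competency_level=level,
                generations=40,
                seed=21,
            )
            series = run_evolution(cfg).series("best_phenotypic_fitness")
            hits = np.nonzero(series >= 0.97)[0]
            gens[level] = hits[0] if hits.size else np.inf
        assert gens[400] < gens[0]
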