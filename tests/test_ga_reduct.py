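from fractions import Fraction

import numpy as np
import pytest

from conftest import random_consistent_table
from roughsel.decision_table import SyntheticSpec, synthesize_table
from roughsel import ga_reduct as ga
from roughsel import rough_core as rc


def make_pool(fitnesses):
    members = tuple(
        ga.Chromosome((i,), Fraction(f).limit_denominator(1000))
        for i, f in enumerate(fitnesses)
    )
    return ga.GenePool(members)


class FakeRNG:
    """Queue-driven stand-in for the few Generator methods the operators use."""

    def __init__(self, integer_queue):
        self.queue = list(integer_queue)

    def integers(self, low, high=None, size=None):
        assert size is None
        return self.queue.pop(0)


class TestSelectionConfig:
    @pytest.mark.parametrize("triple", [(33, 34, 33), (100, 0, 0), (20, 50, 30)])
    def test_modified_accepts_triples_summing_to_100(self, triple):
        b, m, w = triple
        ga.SelectionConfig("artificial_modified", b, m, w)

    @pytest.mark.parametrize("triple", [(33, 33, 33), (50, 50, 50), (0, 0, 0)])
    def test_modified_rejects_other_sums(self, triple):
        b, m, w = triple
        with pytest.raises(ValueError, match="100"):
            ga.SelectionConfig("artificial_modified", b, m, w)

    def test_classical_best_worst_identity(self):
        ga.SelectionConfig("artificial_classical", 40, 0, 60)
        with pytest.raises(ValueError):
            ga.SelectionConfig("artificial_classical", 40, 0, 50)
        with pytest.raises(ValueError, match="middle"):
            ga.SelectionConfig("artificial_classical", 40, 10, 60)

    def test_negative_percentages_rejected(self):
        with pytest.raises(ValueError):
            ga.SelectionConfig("artificial_modified", -10, 60, 50)


class TestGAConfigValidation:
    def test_population_must_be_even_and_at_least_four(self):
        with pytest.raises(ValueError):
            ga.GAConfig(population_size=5)
        with pytest.raises(ValueError):
            ga.GAConfig(population_size=2)

    def test_rates_and_alpha_in_unit_interval(self):
        with pytest.raises(ValueError):
            ga.GAConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            ga.GAConfig(alpha=-0.1)


class TestInitPopulation:
    def test_deterministic_given_seed(self, table1):
        cfg = ga.GAConfig(seed=5, subset_size_range=(5, 5))
        a1, b1 = ga.init_population(table1, cfg, 5, np.random.default_rng(5))
        a2, b2 = ga.init_population(table1, cfg, 5, np.random.default_rng(5))
        assert [c.genes for c in a1] == [c.genes for c in a2]
        assert [c.genes for c in b1] == [c.genes for c in b2]

    def test_fixed_k_and_distinct_genes(self, table1):
        cfg = ga.GAConfig(subset_size_range=(5, 5))
        gen_a, gen_b = ga.init_population(table1, cfg, 5, np.random.default_rng(0))
        for ch in gen_a + gen_b:
            assert len(ch.genes) == 5 and len(set(ch.genes)) == 5
            assert ch.fitness is not None

    def test_cross_generation_duplicate_suppression(self, table1):
        cfg = ga.GAConfig(population_size=30, subset_size_range=(5, 5))
        gen_a, gen_b = ga.init_population(table1, cfg, 5, np.random.default_rng(1))
        sets = [ch.gene_set for ch in gen_a + gen_b]
        assert len(set(sets)) == len(sets)

    def test_oversized_k_rejected(self, table1):
        cfg = ga.GAConfig(subset_size_range=(5, 5))
        with pytest.raises(ValueError):
            ga.init_population(table1, cfg, 13, np.random.default_rng(0))


class TestRouletteSelect:
    def test_probabilities_proportional_to_fitness(self):
        pool = make_pool([1, 3])
        rng = np.random.default_rng(123)
        picks = ga.roulette_select(pool, 10_000, rng)
        # the fitness-3 member should be drawn with probability 3/4
        freq = sum(p.fitness == Fraction(3) for p in picks) / 10_000
        sigma = (0.75 * 0.25 / 10_000) ** 0.5
        assert abs(freq - 0.75) < 3 * sigma

    def test_single_member_pool(self):
        pool = make_pool([0.5])
        assert all(
            p is pool.members[0]
            for p in ga.roulette_select(pool, 10, np.random.default_rng(0))
        )

    def test_zero_fitness_falls_back_to_uniform(self):
        pool = make_pool([0, 0, 0])
        picks = ga.roulette_select(pool, 3000, np.random.default_rng(7))
        counts = [sum(p is m for p in picks) for m in pool.members]
        assert all(c > 800 for c in counts)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            ga.roulette_select(make_pool([1]), 0, np.random.default_rng(0))


class TestArtificialSelect:
    def test_modified_picks_best_median_and_worst_ranks(self):
        pool = make_pool([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        cfg = ga.SelectionConfig("artificial_modified", 33, 34, 33)
        picked = ga.artificial_select(pool, cfg, 3)
        assert sorted(float(c.fitness) for c in picked) == [0.4, 0.6, 0.9]

    def test_classical_40_60_split(self):
        pool = make_pool([round(1 - i * 0.1, 1) for i in range(10)])
        cfg = ga.SelectionConfig("artificial_classical", 40, 0, 60)
        picked = ga.artificial_select(pool, cfg, 5)
        fits = sorted(float(c.fitness) for c in picked)
        assert fits == [0.1, 0.2, 0.3, 0.9, 1.0]  # 2 best + 3 worst

    def test_modified_100_0_0_is_elitist_truncation(self):
        pool = make_pool([0.9, 0.8, 0.7, 0.6])
        cfg = ga.SelectionConfig("artificial_modified", 100, 0, 0)
        picked = ga.artificial_select(pool, cfg, 2)
        assert [float(c.fitness) for c in picked] == [0.9, 0.8]

    def test_overlapping_regions_never_double_pick(self):
        pool = make_pool([0.9, 0.5, 0.1])
        cfg = ga.SelectionConfig("artificial_modified", 33, 34, 33)
        picked = ga.artificial_select(pool, cfg, 3)
        assert sorted(float(c.fitness) for c in picked) == [0.1, 0.5, 0.9]

    def test_undersized_pool_refills_from_worst_region(self):
        pool = make_pool([0.9, 0.1])
        cfg = ga.SelectionConfig("artificial_modified", 33, 34, 33)
        picked = ga.artificial_select(pool, cfg, 6, rng=np.random.default_rng(0))
        assert len(picked) == 6


class TestLoxCrossover:
    def test_hand_traced_sublist_exchange(self):
        p1 = ga.Chromosome((0, 1, 2, 3))
        p2 = ga.Chromosome((2, 3, 4, 5))
        # length 2, both sublists cut at position 2 (0-based)
        rng = FakeRNG([2, 2, 2])
        c1, c2 = ga.lox_crossover(p1, p2, rng)
        assert c1.genes == (0, 1, 4, 5)
        assert c2.genes == (4, 5, 2, 3)

    def test_identical_parents_reproduce_themselves(self):
        p = ga.Chromosome((3, 1, 4))
        c1, c2 = ga.lox_crossover(p, p, np.random.default_rng(0))
        assert c1.genes == p.genes and c2.genes == p.genes

    def test_zero_length_sublist_copies_parents(self):
        p1, p2 = ga.Chromosome((0, 1)), ga.Chromosome((2, 3))
        c1, c2 = ga.lox_crossover(p1, p2, FakeRNG([0]))
        assert (c1.genes, c2.genes) == (p1.genes, p2.genes)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ga.lox_crossover(ga.Chromosome((0,)), ga.Chromosome((1, 2)), np.random.default_rng(0))

    @pytest.mark.parametrize("seed", range(20))
    def test_children_keep_length_distinctness_and_parent_genes(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        genes = rng.permutation(12)
        p1 = ga.Chromosome(tuple(int(g) for g in genes[:k]))
        p2 = ga.Chromosome(tuple(int(g) for g in rng.permutation(12)[:k]))
        c1, c2 = ga.lox_crossover(p1, p2, rng)
        union = p1.gene_set | p2.gene_set
        for c in (c1, c2):
            assert len(c.genes) == k
            assert len(set(c.genes)) == k
            assert c.gene_set <= union  # no gene from outside both parents


class TestMutate:
    def test_deterministic_given_seed(self):
        ch = ga.Chromosome((0, 1, 2))
        a = ga.mutate(ch, "swap2", 12, np.random.default_rng(3))
        b = ga.mutate(ch, "swap2", 12, np.random.default_rng(3))
        assert a.genes == b.genes

    def test_swap2_replaces_two_positions_with_outside_attrs(self):
        ch = ga.Chromosome((0, 1, 2))
        out = ga.mutate(ch, "swap2", 5, np.random.default_rng(1))
        assert len(set(out.genes)) == 3
        assert len(set(out.genes) - {0, 1, 2}) == 2
        assert out.fitness is None

    def test_full_width_chromosome_falls_back_to_permutation(self):
        ch = ga.Chromosome(tuple(range(5)))
        out = ga.mutate(ch, "swap3", 5, np.random.default_rng(2))
        assert set(out.genes) == set(range(5))

    def test_arity_exceeds_length(self):
        with pytest.raises(ValueError):
            ga.mutate(ga.Chromosome((0, 1)), "swap3", 5, np.random.default_rng(0))


class TestRunSearch:
    def test_sample_table_yields_full_dependency_reducts(self, table1):
        cfg = ga.GAConfig(
            population_size=30, alpha=1.0, max_generations=20,
            subset_size_range=(5, 5), seed=3,
        )
        res = ga.run_search(table1, cfg)
        assert res.accepted
        assert all(r.gamma == 1 for r in res.accepted)
        assert all(len(r.attrs) == 5 for r in res.accepted)

    def test_reproducible_from_seed(self, table1):
        cfg = ga.GAConfig(population_size=10, alpha=1.0, max_generations=5,
                          subset_size_range=(5, 5), seed=9)
        r1, r2 = ga.run_search(table1, cfg), ga.run_search(table1, cfg)
        assert r1 == r2

    def test_alpha_zero_accepts_whole_starting_pool(self, table1):
        cfg = ga.GAConfig(population_size=10, alpha=0.0, max_generations=5,
                          subset_size_range=(4, 4), seed=1, stop_on_first=True)
        res = ga.run_search(table1, cfg)
        assert len(res.accepted) >= cfg.population_size
        assert res.first_acceptance_generation == 1

    def test_accepted_sets_annotated_with_minimality(self, table1):
        cfg = ga.GAConfig(population_size=10, alpha=1.0, max_generations=5,
                          subset_size_range=(5, 5), seed=2)
        res = ga.run_search(table1, cfg)
        for r in res.accepted:
            assert r.minimal == rc.is_minimal_reduct(table1, r.attrs, 1.0)

    def test_roulette_strategy_runs(self, table1):
        cfg = ga.GAConfig(population_size=10, alpha=1.0, max_generations=10,
                          subset_size_range=(5, 5), seed=4,
                          selection=ga.SelectionConfig("roulette"))
        res = ga.run_search(table1, cfg)
        assert res.strategy == "roulette"
        assert all(r.gamma == 1 for r in res.accepted)

    def test_recovers_planted_minimal_reduct(self):
        spec = SyntheticSpec(n_rows=20, n_attrs=12, planted_reduct=(1, 4, 9),
                             ensure_minimal=True, seed=42)
        t = synthesize_table(spec)
        cfg = ga.GAConfig(population_size=30, alpha=1.0, max_generations=100,
                          subset_size_range=(3, 3), seed=0)
        res = ga.run_search(t, cfg)
        assert frozenset({1, 4, 9}) in {r.attrs for r in res.accepted}

    def test_size_range_sweep_collects_multiple_sizes(self, table1):
        cfg = ga.GAConfig(population_size=10, alpha=1.0, max_generations=5,
                          subset_size_range=(4, 5), seed=6)
        res = ga.run_search(table1, cfg)
        assert {len(r.attrs) for r in res.accepted} == {4, 5}
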