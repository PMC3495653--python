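"""GA machinery: domination, ranking, termination, CCO and MOCO solvers."""

import itertools

import numpy as np
import pytest

import codonopt as co
from codonopt.distributions import FitnessPair
from codonopt.evolution import GAConfig

from conftest import make_seq


def pareto_peel_rank0(fitness):
    """O(n²) peeling oracle: members not dominated by any other member."""
    front = []
    for i, fi in enumerate(fitness):
        dominated = any(
            (fj[0] >= fi[0] and fj[1] >= fi[1]) and (fj[0] > fi[0] or fj[1] > fi[1])
            for j, fj in enumerate(fitness)
            if j != i
        )
        if not dominated:
            front.append(i)
    return set(front)


class TestDomination:
    @pytest.mark.parametrize(
        "f1, f2, expected",
        [
            ((-0.1, -0.2), (-0.2, -0.2), 1),  # strict ICU, tied CC
            ((-0.2, -0.1), (-0.2, -0.2), 1),  # tied ICU, strict CC
            ((-0.2, -0.2), (-0.1, -0.2), 2),
            ((-0.1, -0.3), (-0.2, -0.2), 0),  # trade-off
            ((-0.1, -0.1), (-0.1, -0.1), 0),  # identical
        ],
    )
    def test_rules(self, f1, f2, expected):
        assert co.dominates(f1, f2) == expected
        assert co.dominates(FitnessPair(*f1), FitnessPair(*f2)) == expected

    def test_antisymmetry(self, rng):
        for _ in range(50):
            f1, f2 = -rng.random(2), -rng.random(2)
            a, b = co.dominates(f1, f2), co.dominates(f2, f1)
            assert (a, b) in {(0, 0), (1, 2), (2, 1)}


class TestNondominatedRank:
    def test_single_member(self):
        assert co.nondominated_rank([FitnessPair(-0.5, -0.5)]).tolist() == [0]

    def test_totally_ordered_chain(self):
        chain = [FitnessPair(-0.1 * k, -0.1 * k) for k in range(4)]
        assert co.nondominated_rank(chain).tolist() == [0, 1, 2, 3]

    def test_identical_members_all_rank0(self):
        same = [FitnessPair(-0.3, -0.4)] * 5
        assert co.nondominated_rank(same).tolist() == [0] * 5

    def test_rank0_matches_peeling_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            fit = -rng.random((n, 2))
            ranks = co.nondominated_rank(fit)
            assert set(np.flatnonzero(ranks == 0)) == pareto_peel_rank0(fit)


class TestTermination:
    def test_flat_window_terminates(self):
        cfg = GAConfig(termination_window=10)
        assert co.check_termination([-1.0] * 12, cfg)

    def test_improving_history_continues(self):
        cfg = GAConfig(termination_window=10)
        history = [-1.0 * 0.99**k for k in range(12)]  # 1%/generation
        assert not co.check_termination(history, cfg)

    def test_perfect_fitness_terminates_immediately(self):
        cfg = GAConfig(termination_window=100)
        assert co.check_termination([-0.5, 0.0], cfg)

    def test_generation_cap(self):
        cfg = GAConfig(max_generations=5, termination_window=100)
        assert co.check_termination([-1.0, -0.9, -0.8, -0.7, -0.6], cfg)


class TestGaStep:
    def test_zero_degeneracy_protein_is_fixed_point(self, small_refs):
        _, ref_cc = small_refs
        pop = [make_seq(["AUG", "UGG", "AUG", "UGG"]) for _ in range(4)]
        new = co.ga_step(pop, ref_cc, "CC", GAConfig(population_size=4, seed=0))
        assert all(s == pop[0] for s in new)

    def test_offspring_are_codon_boundary_recombinants(self, small_refs):
        _, ref_cc = small_refs
        parents = [make_seq(["AAA", "AAA"]), make_seq(["AAG", "AAG"])] * 2
        new = co.ga_step(
            parents, ref_cc, "CC",
            GAConfig(population_size=4, mutation_per_offspring=0, seed=1),
        )
        allowed = {("AAA", "AAA"), ("AAG", "AAG"), ("AAA", "AAG"), ("AAG", "AAA")}
        assert all(tuple(s.codons) in allowed for s in new)

    def test_population_protein_conserved(self, small_refs, rng):
        ref_icu, ref_cc = small_refs
        protein = "MKKLLVVNPQRSTWY*"
        pop = [co.rca_sequence(protein, seed=int(s)) for s in range(8)]
        for mode, refs in (("CC", ref_cc), ("multi", (ref_icu, ref_cc))):
            out = co.ga_step(pop, refs, mode, GAConfig(population_size=8, seed=2))
            assert len(out) == 8
            assert all(s.protein == protein for s in out)

    def test_mixed_proteins_rejected(self, small_refs):
        _, ref_cc = small_refs
        pop = [make_seq(["AAA", "AAA"]), make_seq(["AAA", "UUU"])] * 2
        with pytest.raises(co.UsageError):
            co.ga_step(pop, ref_cc, "CC", GAConfig(population_size=4))


class TestSolveCco:
    def test_self_recovery(self, small_host):
        """With a single-gene reference the GA reaches Ψ_CC = 0."""
        gene = small_host.genes[0]
        own_cc = co.cc_distribution([gene])
        best = co.solve_cco(gene.protein, own_cc, GAConfig(seed=0))
        assert co.cc_fitness(own_cc, co.cc_distribution([best])) == 0.0

    def test_elitist_monotonicity(self, small_refs, small_host):
        _, ref_cc = small_refs
        rows = []
        co.solve_cco(
            small_host.genes[1].protein, ref_cc,
            GAConfig(seed=3, max_generations=300), log=rows.append,
        )
        best = [r["best_psi_cc"] for r in rows]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_beats_random_control(self, small_refs, small_host):
        _, ref_cc = small_refs
        protein = small_host.genes[2].protein
        cco = co.solve_cco(protein, ref_cc, GAConfig(seed=4))
        rca = co.rca_sequence(protein, seed=4)
        psi = lambda s: co.cc_fitness(ref_cc, co.cc_distribution([s]))
        assert psi(cco) > psi(rca)

    def test_seeded_reproducibility(self, small_refs):
        _, ref_cc = small_refs
        cfg = GAConfig(seed=5, max_generations=120)
        a = co.solve_cco("MKKLLVVNPQ*", ref_cc, cfg)
        b = co.solve_cco("MKKLLVVNPQ*", ref_cc, cfg)
        assert a == b


class TestSolveMoco:
    def test_degenerate_protein_front_of_one(self, small_refs):
        ref_icu, ref_cc = small_refs
        front, x = co.solve_moco(
            "MWMW", ref_icu, ref_cc, GAConfig(population_size=8, seed=0)
        )
        assert len(front.members) == 1
        assert x == front.members[0][0]
        assert x.protein == "MWMW"

    def test_front_is_mutually_nondominated(self, small_refs, small_host):
        ref_icu, ref_cc = small_refs
        front, _ = co.solve_moco(
            small_host.genes[3].protein, ref_icu, ref_cc,
            GAConfig(seed=6, max_generations=200),
        )
        fit = front.fitness_array()
        for i, j in itertools.combinations(range(len(fit)), 2):
            assert co.dominates(fit[i], fit[j]) == 0

    def test_fitness_within_bounds_and_ideal_choice(self, small_refs):
        ref_icu, ref_cc = small_refs
        front, x = co.solve_moco(
            "MKKLLVVNPQRST*", ref_icu, ref_cc, GAConfig(seed=7,
                                                        max_generations=150),
        )
        for _, f in front.members:
            assert -2 * 21 / 64 <= f.psi_icu <= 0
            assert -2 * 420 / 3904 <= f.psi_cc <= 0
        assert any(x == m for m, _ in front.members)

    def test_seeded_reproducibility(self, small_refs):
        ref_icu, ref_cc = small_refs
        cfg = GAConfig(seed=8, max_generations=120)
        _, a = co.solve_moco("MKLVNPQ*", ref_icu, ref_cc, cfg)
        _, b = co.solve_moco("MKLVNPQ*", ref_icu, ref_cc, cfg)
        assert a == b


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 3},
            {"population_size": 5},
            {"termination_threshold": 0.0},
            {"max_generations": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(co.UsageError):
            GAConfig(**kwargs)
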