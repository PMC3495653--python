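"""Genetic-algorithm machinery for codon-context and multi-objective design.

CCO (codon-context optimization) evolves a population of synonymous coding
sequences toward the host's codon-pair usage: elitist selection keeps the
top half by Ψ_CC, offspring arise by one-point crossover at a random codon
boundary plus synonymous point mutation, and the run terminates when the
best fitness improves by less than a relative threshold across a window of
generations.

MOCO (multi-objective codon optimization) runs the same loop under
(Ψ_ICU, Ψ_CC) with nondominated ranking in place of scalar sorting.  The
ranking stores one domination count per member — the number of members that
dominate it — so rank 0 is exactly the population's Pareto set and only
O(n) storage is needed.  The reported solution x_MOCO is the front member
nearest the ideal point (the best attained value of each objective) after
min–max normalization of both objectives across the front.

Because individuals are codon lists, crossover at triplet boundaries and
hash-table synonymous mutation preserve the encoded protein by
construction, so every individual in every generation translates to the
target protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .distributions import CC, ICU, FitnessPair, UsageDistribution
from .errors import UsageError
from .genetic_code import (
    N_AA,
    N_CODONS,
    CodonSequence,
    GeneticCode,
)

_EPS = 1e-12
_MUTATION_ATTEMPTS = 10


@dataclass
class GAConfig:
    """Tunable parameters of the genetic algorithm.

    The procedure fixes the elitist fraction (top 50%) and the convergence
    rule (< 0.5% relative improvement of the best fitness over 100
    generations); population size and per-offspring mutation count are
    free parameters with pragmatic defaults.
    """

    population_size: int = 100
    max_generations: int = 5000
    termination_window: int = 100
    termination_threshold: float = 0.005
    mutation_per_offspring: int = 1
    seed: int = 0
    crowding: bool = False  # NSGA-II crowding distance in MOCO selection
    raw_scale_distance: bool = False  # ideal-point distance without min–max

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise UsageError("population_size must be an even integer ≥ 4")
        if self.termination_window <= 0 or self.termination_threshold <= 0:
            raise UsageError("termination window and threshold must be positive")
        if self.max_generations <= 0 or self.mutation_per_offspring < 0:
            raise UsageError("max_generations must be ≥ 1, mutation count ≥ 0")


@dataclass
class ParetoFront:
    """The nondominated set of a final MOCO population.

    ``rank`` carries the domination count of each member; all zero, since
    the front is by definition dominated by nobody.
    """

    members: list[tuple[CodonSequence, FitnessPair]]
    rank: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def fitness_array(self) -> np.ndarray:
        return np.array([f.astuple() for _, f in self.members])


# ---------------------------------------------------------------------- #
# fast fitness evaluation over whole populations


class PopulationEvaluator:
    """Vectorized Ψ_ICU / Ψ_CC over an integer-coded population.

    The conditional denominators (per-amino-acid and per-amino-acid-pair
    counts) depend only on the target protein, so they are precomputed once;
    per-generation work is two batched bincounts and an L1 difference.
    """

    def __init__(
        self,
        protein: str,
        code: GeneticCode,
        reference_icu: UsageDistribution | None = None,
        reference_cc: UsageDistribution | None = None,
    ):
        self.code = code
        self.aa_idx = code.encode_protein(protein)
        self.n = self.aa_idx.size
        if code.stop_index in self.aa_idx[:-1]:
            raise UsageError("internal stop symbol in target protein")
        if reference_icu is not None:
            if reference_icu.kind != ICU:
                raise UsageError("reference_icu must be an ICU distribution")
            aa_counts = np.bincount(self.aa_idx, minlength=N_AA)
            denom = aa_counts[code.codon_aa].astype(float)
            self._inv64 = np.where(denom > 0, 1.0 / np.maximum(denom, 1), 0.0)
            self._p0 = reference_icu.freq
        if reference_cc is not None:
            if reference_cc.kind != CC:
                raise UsageError("reference_cc must be a CC distribution")
            if self.n < 2:
                raise UsageError("CC fitness needs at least 2 codons")
            pair_full = self.aa_idx[:-1] * N_AA + self.aa_idx[1:]
            pair_counts = np.bincount(pair_full, minlength=N_AA * N_AA)
            c1 = np.arange(N_CODONS * N_CODONS) // N_CODONS
            c2 = np.arange(N_CODONS * N_CODONS) % N_CODONS
            slot_aa = code.codon_aa[c1] * N_AA + code.codon_aa[c2]
            denom = pair_counts[slot_aa].astype(float)
            self._inv4096 = np.where(denom > 0, 1.0 / np.maximum(denom, 1), 0.0)
            q0 = np.zeros(N_CODONS * N_CODONS)
            q0[code.codon_pair_compact_to_full] = reference_cc.freq
            self._q0 = q0

    def psi_icu(self, population: np.ndarray) -> np.ndarray:
        pop = np.atleast_2d(population)
        P = pop.shape[0]
        flat = (np.arange(P)[:, None] * N_CODONS + pop).ravel()
        counts = np.bincount(flat, minlength=P * N_CODONS).reshape(P, N_CODONS)
        p1 = counts * self._inv64
        return -np.abs(self._p0 - p1).sum(axis=1) / N_CODONS

    def psi_cc(self, population: np.ndarray) -> np.ndarray:
        pop = np.atleast_2d(population)
        P = pop.shape[0]
        pairs = pop[:, :-1] * N_CODONS + pop[:, 1:]
        flat = (np.arange(P)[:, None] * (N_CODONS * N_CODONS) + pairs).ravel()
        counts = np.bincount(flat, minlength=P * N_CODONS * N_CODONS)
        q1 = counts.reshape(P, -1) * self._inv4096
        return -np.abs(self._q0 - q1).sum(axis=1) / 3904


# ---------------------------------------------------------------------- #
# population primitives


def _syn_by_position(protein: str, code: GeneticCode) -> list[np.ndarray]:
    return [code.synonyms[j] for j in code.encode_protein(protein)]


def random_population(
    protein: str,
    size: int,
    rng: np.random.Generator,
    code: GeneticCode,
) -> np.ndarray:
    """Initialize *size* random synonymous encodings of *protein*."""
    syn = _syn_by_position(protein, code)
    pop = np.empty((size, len(syn)), dtype=np.int64)
    for i, s in enumerate(syn):
        pop[:, i] = s[rng.integers(0, s.size, size=size)]
    return pop


def _mutate(
    row: np.ndarray,
    syn: list[np.ndarray],
    rng: np.random.Generator,
    count: int,
) -> None:
    n = row.size
    for _ in range(count):
        for _ in range(_MUTATION_ATTEMPTS):
            i = int(rng.integers(n))
            s = syn[i]
            if s.size > 1:
                choices = s[s != row[i]]
                row[i] = choices[rng.integers(choices.size)]
                break
            # degeneracy 1: re-draw another residue, else accept the no-op


def _offspring(
    parents: np.ndarray,
    syn: list[np.ndarray],
    rng: np.random.Generator,
    needed: int,
    mutations: int,
) -> np.ndarray:
    """One-point codon-boundary crossover of randomly paired parents."""
    n = parents.shape[1]
    out = np.empty((needed, n), dtype=np.int64)
    made = 0
    while made < needed:
        order = rng.permutation(parents.shape[0])
        for a, b in zip(order[0::2], order[1::2]):
            if made >= needed:
                break
            if n >= 2:
                cut = int(rng.integers(1, n))
                out[made] = np.concatenate([parents[a, :cut], parents[b, cut:]])
                if made + 1 < needed:
                    out[made + 1] = np.concatenate(
                        [parents[b, :cut], parents[a, cut:]]
                    )
                    made += 2
                else:
                    made += 1
            else:
                out[made] = parents[a]
                made += 1
    for row in out:
        _mutate(row, syn, rng, mutations)
    return out


def _select_order_cc(psi_cc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    tie = rng.permutation(psi_cc.size)
    return np.lexsort((tie, -psi_cc))


def _crowding_distance(fit: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    dist = np.zeros(fit.shape[0])
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        for m in range(fit.shape[1]):
            order = idx[np.argsort(fit[idx, m])]
            span = fit[order[-1], m] - fit[order[0], m]
            dist[order[0]] = dist[order[-1]] = np.inf
            if span > 0 and order.size > 2:
                gaps = (fit[order[2:], m] - fit[order[:-2], m]) / span
                dist[order[1:-1]] += gaps
    return dist


def _select_order_multi(
    fit: np.ndarray,
    ranks: np.ndarray,
    rng: np.random.Generator,
    crowding: bool,
) -> np.ndarray:
    tie = rng.permutation(ranks.size)
    if crowding:
        return np.lexsort((tie, -_crowding_distance(fit, ranks), ranks))
    return np.lexsort((tie, ranks))


# ---------------------------------------------------------------------- #
# domination


def dominates(f1: FitnessPair | Sequence[float], f2: FitnessPair | Sequence[float]):
    """Evaluate the pairwise domination rules on two (Ψ_ICU, Ψ_CC) pairs.

    Returns 1 if the first dominates, 2 if the second dominates, 0 if
    neither (trade-off or identical values).
    """
    a1, c1 = f1.astuple() if isinstance(f1, FitnessPair) else tuple(f1)
    a2, c2 = f2.astuple() if isinstance(f2, FitnessPair) else tuple(f2)
    if (a1 > a2 and c1 >= c2) or (a1 >= a2 and c1 > c2):
        return 1
    if (a2 > a1 and c2 >= c1) or (a2 >= a1 and c2 > c1):
        return 2
    return 0


def nondominated_rank(fitness: Sequence[FitnessPair] | np.ndarray) -> np.ndarray:
    """Domination count per member: how many others dominate it.

    Rank 0 is exactly the Pareto-optimal subset of the population.  Unlike
    the original NSGA-II bookkeeping, which stores each member's dominated
    set, a single counter per member suffices (O(n) storage; the pairwise
    comparison itself remains O(mn²)).
    """
    if isinstance(fitness, np.ndarray):
        fit = np.atleast_2d(np.asarray(fitness, dtype=float))
    else:
        fit = np.array([f.astuple() for f in fitness], dtype=float)
    icu, cc = fit[:, 0], fit[:, 1]
    ge = (icu[:, None] >= icu[None, :]) & (cc[:, None] >= cc[None, :])
    strict = (icu[:, None] > icu[None, :]) | (cc[:, None] > cc[None, :])
    dominates_matrix = ge & strict  # [i, j] — i dominates j
    return dominates_matrix.sum(axis=0).astype(np.int64)


# ---------------------------------------------------------------------- #
# termination


def check_termination(best_fitness_history: Sequence[float], config: GAConfig):
    """True when the best fitness has converged or the budget is exhausted.

    Convergence: the relative improvement of the best fitness across the
    termination window falls below the threshold,
    |Ψ(r+W) − Ψ(r)| / max(|Ψ(r)|, ε) < threshold.  A best fitness of exactly
    0 is the global maximum and terminates immediately.
    """
    history = list(best_fitness_history)
    if not history:
        return False
    if history[-1] == 0.0:
        return True
    if len(history) >= config.max_generations:
        return True
    window = config.termination_window
    if len(history) <= window:
        return False
    prev, cur = history[-1 - window], history[-1]
    return abs(cur - prev) / max(abs(prev), _EPS) < config.termination_threshold


# ---------------------------------------------------------------------- #
# public GA surface


def _common_protein(population: Sequence[CodonSequence]) -> tuple[str, GeneticCode]:
    if not population:
        raise UsageError("population must be nonempty")
    code = population[0].code
    protein = population[0].protein
    for member in population[1:]:
        if member.code is not code or member.protein != protein:
            raise UsageError("population members encode different proteins")
    return protein, code


def ga_step(
    population: Sequence[CodonSequence],
    references: UsageDistribution | tuple[UsageDistribution, UsageDistribution],
    objective_mode: str,
    config: GAConfig,
    rng: np.random.Generator | None = None,
) -> list[CodonSequence]:
    """Advance one generation (select parents, breed, recombine).

    ``objective_mode`` is ``"CC"`` (scalar Ψ_CC elitism, takes a CC
    reference) or ``"multi"`` (domination-rank elitism, takes an
    (ICU, CC) reference tuple).
    """
    protein, code = _common_protein(population)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop = np.stack([m.codon_indices for m in population])
    syn = _syn_by_position(protein, code)
    if objective_mode == "CC":
        evaluator = PopulationEvaluator(protein, code, reference_cc=references)
        order = _select_order_cc(evaluator.psi_cc(pop), rng)
    elif objective_mode == "multi":
        ref_icu, ref_cc = references
        evaluator = PopulationEvaluator(protein, code, ref_icu, ref_cc)
        fit = np.column_stack([evaluator.psi_icu(pop), evaluator.psi_cc(pop)])
        order = _select_order_multi(fit, nondominated_rank(fit), rng, config.crowding)
    else:
        raise UsageError(f"unknown objective mode {objective_mode!r}")
    parents = pop[order[: pop.shape[0] // 2]]
    children = _offspring(
        parents, syn, rng, pop.shape[0] - parents.shape[0],
        config.mutation_per_offspring,
    )
    new_pop = np.vstack([parents, children])
    return [CodonSequence(row, code) for row in new_pop]


def solve_cco(
    protein: str,
    reference_cc: UsageDistribution,
    config: GAConfig | None = None,
    log: Callable[[dict], None] | None = None,
) -> CodonSequence:
    """Design a CDS maximizing Ψ_CC against the host codon-pair reference."""
    config = config or GAConfig()
    code = reference_cc.code
    rng = np.random.default_rng(config.seed)
    evaluator = PopulationEvaluator(protein, code, reference_cc=reference_cc)
    syn = _syn_by_position(protein, code)
    pop = random_population(protein, config.population_size, rng, code)
    history: list[float] = []
    while True:
        psi = evaluator.psi_cc(pop)
        best = int(np.argmax(psi))
        history.append(float(psi[best]))
        if log is not None:
            log(
                {
                    "generation": len(history),
                    "best_psi_cc": float(psi[best]),
                    "mean_psi_cc": float(psi.mean()),
                }
            )
        if check_termination(history, config):
            return CodonSequence(pop[best].copy(), code)
        order = _select_order_cc(psi, rng)
        parents = pop[order[: config.population_size // 2]]
        children = _offspring(
            parents, syn, rng, config.population_size - parents.shape[0],
            config.mutation_per_offspring,
        )
        pop = np.vstack([parents, children])


def solve_moco(
    protein: str,
    reference_icu: UsageDistribution,
    reference_cc: UsageDistribution,
    config: GAConfig | None = None,
    log: Callable[[dict], None] | None = None,
) -> tuple[ParetoFront, CodonSequence]:
    """Design a CDS balancing Ψ_ICU and Ψ_CC (nondominated-sorting GA).

    Returns the final rank-0 front and the member nearest the ideal point.
    Termination requires the window criterion to hold for the best value of
    *both* objectives.
    """
    config = config or GAConfig()
    if reference_icu.code is not reference_cc.code:
        raise UsageError("references use different genetic codes")
    code = reference_cc.code
    rng = np.random.default_rng(config.seed)
    evaluator = PopulationEvaluator(protein, code, reference_icu, reference_cc)
    syn = _syn_by_position(protein, code)
    pop = random_population(protein, config.population_size, rng, code)
    hist_icu: list[float] = []
    hist_cc: list[float] = []
    while True:
        fit = np.column_stack([evaluator.psi_icu(pop), evaluator.psi_cc(pop)])
        ranks = nondominated_rank(fit)
        hist_icu.append(float(fit[:, 0].max()))
        hist_cc.append(float(fit[:, 1].max()))
        if log is not None:
            log(
                {
                    "generation": len(hist_icu),
                    "best_psi_icu": hist_icu[-1],
                    "best_psi_cc": hist_cc[-1],
                    "front_size": int((ranks == 0).sum()),
                }
            )
        done = check_termination(hist_icu, config) and check_termination(
            hist_cc, config
        )
        if len(hist_icu) >= config.max_generations:
            done = True
        if done:
            break
        order = _select_order_multi(fit, ranks, rng, config.crowding)
        parents = pop[order[: config.population_size // 2]]
        children = _offspring(
            parents, syn, rng, config.population_size - parents.shape[0],
            config.mutation_per_offspring,
        )
        pop = np.vstack([parents, children])

    front_idx = np.flatnonzero(ranks == 0)
    # deduplicate identical chromosomes on the front
    seen: dict[bytes, int] = {}
    for i in front_idx:
        seen.setdefault(pop[i].tobytes(), int(i))
    keep = np.array(sorted(seen.values()), dtype=np.int64)
    members = [
        (CodonSequence(pop[i].copy(), code), FitnessPair(*map(float, fit[i])))
        for i in keep
    ]
    front = ParetoFront(members, rank=np.zeros(keep.size, dtype=np.int64))
    x_moco = members[_ideal_point_choice(fit[keep], config.raw_scale_distance)][0]
    return front, x_moco


def _ideal_point_choice(front_fit: np.ndarray, raw_scale: bool) -> int:
    """Index of the front member nearest the ideal point.

    The ideal point pairs the best attained value of each objective over
    the front.  By default each objective is min–max normalized across the
    front first (a degenerate objective with zero range contributes 0).
    """
    fit = np.atleast_2d(front_fit).astype(float)
    if raw_scale:
        scaled = fit
    else:
        lo, hi = fit.min(axis=0), fit.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        scaled = (fit - lo) / span
    ideal = scaled.max(axis=0)
    return int(np.argmin(np.linalg.norm(scaled - ideal, axis=1)))
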