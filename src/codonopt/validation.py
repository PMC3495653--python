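"""Leave-one-out cross-validation of the optimizers against native genes.

Each high-expression gene is held out in turn; the remaining genes form the
training set from which the reference ICU and CC distributions are built.
Every method then back-translates the held-out gene's protein, and the
design is scored by P_M — the percentage of codon positions that match the
native coding sequence.  A pairwise tournament then counts, for each
ordered method pair, the genes on which the row method's P_M strictly
exceeds the column method's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import cc_distribution, icu_distribution
from .errors import UsageError
from .evolution import GAConfig, solve_cco, solve_moco
from .genetic_code import CodonSequence
from .ico import rca_sequence, solve_ico

logger = logging.getLogger(__name__)

METHODS = ("ICO", "CCO", "MOCO", "RCA")


@dataclass
class CrossValReport:
    """Per-gene P_M values per method, plus derived summaries."""

    per_gene: dict[str, dict[str, float]]
    methods: tuple[str, ...]
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(self.per_gene, orient="index")
        frame.index.name = "gene"
        return frame.reindex(columns=list(self.methods))

    def mean_pm(self) -> pd.Series:
        return self.to_frame().mean(axis=0)


def percent_match(native: CodonSequence, designed: CodonSequence) -> float:
    """Percentage of codon positions where the design matches the native CDS."""
    if len(native) != len(designed):
        raise UsageError("sequences differ in length")
    if native.protein != designed.protein:
        raise UsageError("sequences encode different proteins")
    if len(native) == 0:
        raise UsageError("empty sequences")
    matches = int((native.codon_indices == designed.codon_indices).sum())
    return 100.0 * matches / len(native)


def _design(
    method: str,
    protein: str,
    train: Sequence[CodonSequence],
    config: GAConfig,
    seed: int,
    uniform_fallback: bool,
) -> CodonSequence:
    if method == "ICO":
        return solve_ico(
            protein, icu_distribution(train), seed=seed,
            uniform_fallback=uniform_fallback,
        )
    if method == "RCA":
        return rca_sequence(protein, seed=seed, code=train[0].code)
    ga = GAConfig(
        population_size=config.population_size,
        max_generations=config.max_generations,
        termination_window=config.termination_window,
        termination_threshold=config.termination_threshold,
        mutation_per_offspring=config.mutation_per_offspring,
        seed=seed,
        crowding=config.crowding,
        raw_scale_distance=config.raw_scale_distance,
    )
    if method == "CCO":
        return solve_cco(protein, cc_distribution(train), ga)
    if method == "MOCO":
        _, x_moco = solve_moco(
            protein, icu_distribution(train), cc_distribution(train), ga
        )
        return x_moco
    raise UsageError(f"unknown method {method!r}; choose from {METHODS}")


def _needs_fallback(protein: str, train: Sequence[CodonSequence]) -> bool:
    trained = set("".join(g.protein for g in train))
    return not set(protein) <= trained


def loocv(
    genes: Sequence[CodonSequence],
    methods: Sequence[str] = METHODS,
    config: GAConfig | None = None,
    seed: int = 0,
    include_stop: bool = True,
) -> CrossValReport:
    """Leave-one-out cross-validation over a high-expression gene set.

    For each gene, reference distributions are trained on the remaining
    genes and every method designs a sequence for the held-out protein;
    P_M is recorded against the native CDS.  ``include_stop=False`` trims
    a terminal stop codon from the comparison.  Genes shorter than two
    codons are skipped with a logged warning; rare residues absent from a
    training fold automatically fall back to uniform synonymous
    frequencies in ICO (logged).
    """
    config = config or GAConfig()
    methods = tuple(methods)
    for m in methods:
        if m not in METHODS:
            raise UsageError(f"unknown method {m!r}; choose from {METHODS}")
    if len(genes) < 3:
        raise UsageError("need at least 3 genes for cross-validation")
    names = [g.id or f"gene_{i + 1}" for i, g in enumerate(genes)]
    if len(set(names)) != len(names):
        raise UsageError("gene ids must be unique")

    seed_seq = np.random.SeedSequence(seed)
    fold_seeds = seed_seq.generate_state(len(genes) * len(methods)) >> 1

    per_gene: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for gi, (name, gene) in enumerate(zip(names, genes)):
        if len(gene) < 2:
            logger.warning("skipping gene %s: fewer than 2 codons", name)
            skipped.append(name)
            continue
        train = [g for g in genes if g is not gene]
        native = gene
        protein = gene.protein
        if not include_stop and protein.endswith("*"):
            native = CodonSequence(gene.codon_indices[:-1], gene.code, id=gene.id)
            protein = protein[:-1]
        fallback = _needs_fallback(protein, train)
        if fallback:
            logger.info(
                "gene %s: residues absent from training fold; "
                "uniform synonymous fallback enabled",
                name,
            )
        row: dict[str, float] = {}
        for mi, method in enumerate(methods):
            designed = _design(
                method,
                protein,
                train,
                config,
                seed=int(fold_seeds[gi * len(methods) + mi]),
                uniform_fallback=fallback,
            )
            row[method] = percent_match(native, designed)
        per_gene[name] = row
    return CrossValReport(per_gene=per_gene, methods=methods, skipped=skipped)


def tournament(report: CrossValReport) -> pd.DataFrame:
    """Win matrix: cell [row, col] = genes where row's P_M > col's P_M.

    Wins and losses of a method pair sum with draws to the number of genes,
    so the matrix is antisymmetric up to draws.
    """
    frame = report.to_frame()
    if frame.isna().any().any():
        raise UsageError("missing method entries in cross-validation report")
    methods = list(report.methods)
    wins = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    for a in methods:
        for b in methods:
            if a != b:
                wins.loc[a, b] = int((frame[a] > frame[b]).sum())
    return wins
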