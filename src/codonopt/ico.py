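"""Non-iterative individual-codon-usage optimization (ICO) and the RCA control.

ICO back-translates a protein so that the realized codon counts are the
integer vector closest (per amino acid, in L1) to the host's ICU reference
frequencies scaled by the protein's amino-acid counts:

1. compute the reference frequencies p0^k;
2. count each amino acid in the subject protein, θ_A^j;
3. form the real-valued optimal counts p0^k · θ_A^j and round them to a
   codon budget by largest-remainder apportionment within each amino acid;
4. place each amino acid's budgeted codons uniformly at random over its
   positions.

Because the ICU fitness depends on the sequence only through its codon
counts, step 3 already fixes the attainable optimum and no search is
needed.  RCA (random codon assignment) is the negative control: every
residue receives a synonymous codon uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import ICU, UsageDistribution
from .errors import UsageError
from .genetic_code import N_CODONS, STANDARD_CODE, CodonSequence, GeneticCode


@dataclass
class CodonBudget:
    """Integer per-codon counts for one protein; sums match per-aa totals."""

    counts: np.ndarray  # length 64, nonnegative ints
    code: GeneticCode

    def __post_init__(self) -> None:
        if self.counts.shape != (N_CODONS,) or (self.counts < 0).any():
            raise UsageError("budget must be 64 nonnegative integers")


def _reference_syn_freq(
    reference: UsageDistribution,
    aa_j: int,
    uniform_fallback: bool,
) -> np.ndarray:
    """Synonymous frequencies of amino acid *aa_j* from an ICU reference."""
    code = reference.code
    syn = code.synonyms[aa_j]
    if reference.aa_counts[aa_j] > 0:
        return reference.freq[syn]
    if uniform_fallback:
        return np.full(syn.size, 1.0 / syn.size)
    raise UsageError(
        f"amino acid {code.amino_acids[aa_j]!r} is absent from the reference "
        "gene set; pass uniform_fallback=True to assign its codons uniformly"
    )


def largest_remainder(quota: np.ndarray, total: int, rng: np.random.Generator):
    """Round nonnegative quotas to integers summing to *total* (Hamilton).

    Floors each quota, then hands the remaining units to the largest
    fractional remainders; exact remainder ties are broken by a seeded
    random permutation.  Among all integer vectors with the given sum this
    minimizes the L1 distance to the quota vector.
    """
    floors = np.floor(quota).astype(np.int64)
    short = int(total - floors.sum())
    if short:
        remainder = quota - floors
        perm = rng.permutation(quota.size)
        order = perm[np.argsort(-remainder[perm], kind="stable")]
        floors[order[:short]] += 1
    return floors


def optimal_codon_counts(
    protein: str,
    reference: UsageDistribution,
    rng: np.random.Generator | int | None = None,
    uniform_fallback: bool = False,
) -> CodonBudget:
    """Per-codon optimal integer counts for *protein* under a reference ICU."""
    if reference.kind != ICU:
        raise UsageError("ICO needs an ICU reference distribution")
    rng = np.random.default_rng(rng)
    code = reference.code
    aa_idx = code.encode_protein(protein)
    aa_counts = np.bincount(aa_idx, minlength=len(code.amino_acids))
    counts = np.zeros(N_CODONS, dtype=np.int64)
    for j in np.flatnonzero(aa_counts):
        syn = code.synonyms[j]
        freq = _reference_syn_freq(reference, j, uniform_fallback)
        counts[syn] = largest_remainder(freq * aa_counts[j], int(aa_counts[j]), rng)
    return CodonBudget(counts, code)


def solve_ico(
    protein: str,
    reference: UsageDistribution,
    seed: int | np.random.Generator | None = None,
    uniform_fallback: bool = False,
) -> CodonSequence:
    """Design a CDS whose codon counts match the optimal budget exactly.

    The budgeted synonymous codons of each amino acid are shuffled uniformly
    over that amino acid's positions, per the random-assignment step of the
    non-iterative procedure.
    """
    rng = np.random.default_rng(seed)
    budget = optimal_codon_counts(protein, reference, rng, uniform_fallback)
    code = reference.code
    aa_idx = code.encode_protein(protein)
    out = np.empty(aa_idx.size, dtype=np.int64)
    for j in np.unique(aa_idx):
        positions = np.flatnonzero(aa_idx == j)
        codons = np.repeat(code.synonyms[j], budget.counts[code.synonyms[j]])
        rng.shuffle(codons)
        out[positions] = codons
    return CodonSequence(out, code)


def rca_sequence(
    protein: str,
    seed: int | np.random.Generator | None = None,
    code: GeneticCode = STANDARD_CODE,
    weights: UsageDistribution | None = None,
) -> CodonSequence:
    """Random codon assignment: independent synonymous draw per residue.

    By default each residue's codon is uniform over its synonyms.  Passing
    an ICU distribution as ``weights`` draws from those frequencies instead
    (e.g. the all-genes usage), for users who prefer a usage-matched
    control.
    """
    rng = np.random.default_rng(seed)
    aa_idx = code.encode_protein(protein)
    out = np.empty(aa_idx.size, dtype=np.int64)
    for i, j in enumerate(aa_idx):
        syn = code.synonyms[j]
        if weights is None:
            out[i] = rng.choice(syn)
        else:
            p = weights.freq[syn]
            total = p.sum()
            p = p / total if total > 0 else np.full(syn.size, 1.0 / syn.size)
            out[i] = rng.choice(syn, p=p)
    return CodonSequence(out, code)
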