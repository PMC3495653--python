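"""Codon-usage distributions and the ICU / CC fitness measures.

Two usage statistics are estimated from a gene set:

* **ICU** (individual codon usage): for each amino acid, the conditional
  frequency of each synonymous codon, ``p^k = θ_C^k / θ_A^{f(κ^k)}``.
* **CC** (codon context): for each ordered amino-acid pair, the conditional
  frequency of each of its synonymous codon pairs, taken over the n−1
  overlapping adjacent pairs of each gene.

Counts are pooled across all genes of the set before normalizing, i.e. the
distribution of a concatenation equals the distribution of the set.

The fitness of a subject sequence against a host reference is the negative
mean absolute difference between the two frequency vectors,

    Ψ_ICU = −(1/64)   Σ_k |p0^k − p1^k|
    Ψ_CC  = −(1/3904) Σ_k |q0^k − q1^k|

so Ψ ≤ 0 with 0 attained exactly when the distributions coincide.  When an
amino acid (pair) never occurs in a gene set its synonymous frequencies are
defined as 0; the corresponding |p_other − 0| terms are constant in the
design variables, so optimizer rankings are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .genetic_code import (
    N_AA,
    N_AA_PAIRS,
    N_CODON_PAIRS,
    N_CODONS,
    STANDARD_CODE,
    CodonSequence,
    GeneticCode,
)

ICU = "ICU"
CC = "CC"


@dataclass(frozen=True)
class FitnessPair:
    """(Ψ_ICU, Ψ_CC) of a candidate sequence against a reference."""

    psi_icu: float
    psi_cc: float

    def astuple(self) -> tuple[float, float]:
        return (self.psi_icu, self.psi_cc)


@dataclass
class UsageDistribution:
    """Conditional codon (pair) frequencies of a gene set.

    Attributes
    ----------
    kind
        ``"ICU"`` (length-64 vectors over codons) or ``"CC"`` (length-3904
        vectors over codon pairs whose first codon is sense).
    freq
        Conditional frequency of each unit given its amino acid (pair);
        entries of absent amino acids (pairs) are 0.
    aa_counts
        Occurrences of each of the 21 amino acids (ICU) or 420 ordered
        amino-acid pairs (CC), pooled over the gene set.
    codon_counts
        Occurrences of each codon (pair), pooled over the gene set.
    """

    kind: str
    freq: np.ndarray
    aa_counts: np.ndarray
    codon_counts: np.ndarray
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self) -> None:
        n_units = N_CODONS if self.kind == ICU else N_CODON_PAIRS
        n_aa = N_AA if self.kind == ICU else N_AA_PAIRS
        if self.kind not in (ICU, CC):
            raise UsageError(f"unknown distribution kind {self.kind!r}")
        if self.freq.shape != (n_units,) or self.codon_counts.shape != (n_units,):
            raise UsageError(f"{self.kind} distribution must have {n_units} units")
        if self.aa_counts.shape != (n_aa,):
            raise UsageError(f"{self.kind} distribution must have {n_aa} aa counts")

    # ------------------------------------------------------------------ #

    @property
    def unit_aa(self) -> np.ndarray:
        """Amino-acid (pair) index of each unit."""
        if self.kind == ICU:
            return self.code.codon_aa
        return self.code.codon_pair_aa_pair

    def unit_labels(self) -> list[str]:
        K, A, B, P = self.code.enumerate_units()
        return list(K if self.kind == ICU else P)

    def aa_labels(self) -> list[str]:
        K, A, B, P = self.code.enumerate_units()
        return list(A if self.kind == ICU else B)

    # ------------------------------------------------------------------ #
    # serialization

    def to_frame(self) -> pd.DataFrame:
        aa_labels = self.aa_labels()
        return pd.DataFrame(
            {
                "unit": self.unit_labels(),
                "amino_acid": [aa_labels[j] for j in self.unit_aa],
                "count": self.codon_counts.astype(int),
                "frequency": self.freq,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path, kind: str, code: GeneticCode = STANDARD_CODE
    ) -> "UsageDistribution":
        frame = pd.read_csv(path, sep="\t", dtype={"unit": str})
        n_units = N_CODONS if kind == ICU else N_CODON_PAIRS
        if len(frame) != n_units:
            raise UsageError(
                f"expected {n_units} rows for a {kind} distribution, got {len(frame)}"
            )
        ref = _empty(kind, code)
        index = {u: i for i, u in enumerate(ref.unit_labels())}
        counts = np.zeros(n_units)
        freq = np.zeros(n_units)
        for _, row in frame.iterrows():
            i = index[row["unit"]]
            counts[i] = row["count"]
            freq[i] = row["frequency"]
        aa_counts = np.zeros_like(ref.aa_counts, dtype=float)
        np.add.at(aa_counts, ref.unit_aa, counts)
        return cls(kind, freq, aa_counts, counts, code)


def _empty(kind: str, code: GeneticCode) -> UsageDistribution:
    n_units = N_CODONS if kind == ICU else N_CODON_PAIRS
    n_aa = N_AA if kind == ICU else N_AA_PAIRS
    return UsageDistribution(
        kind, np.zeros(n_units), np.zeros(n_aa), np.zeros(n_units), code
    )


def _check_genes(genes: Sequence[CodonSequence], min_len: int) -> GeneticCode:
    if not genes:
        raise UsageError("gene set must be nonempty")
    code = genes[0].code
    for g in genes:
        if g.code is not code:
            raise UsageError("all genes must share one genetic code")
        if len(g) < min_len:
            raise UsageError(
                f"gene {g.id or '<unnamed>'} has {len(g)} codons; need ≥ {min_len}"
            )
    return code


def _conditional(counts: np.ndarray, aa_counts: np.ndarray, unit_aa: np.ndarray):
    denom = aa_counts[unit_aa]
    freq = np.zeros_like(counts, dtype=float)
    nz = denom > 0
    freq[nz] = counts[nz] / denom[nz]
    return freq


def icu_distribution(genes: Sequence[CodonSequence]) -> UsageDistribution:
    """Pooled per-amino-acid synonymous codon frequencies of a gene set."""
    code = _check_genes(genes, min_len=1)
    codon_counts = np.zeros(N_CODONS)
    for g in genes:
        codon_counts += np.bincount(g.codon_indices, minlength=N_CODONS)
    aa_counts = np.zeros(N_AA)
    np.add.at(aa_counts, code.codon_aa, codon_counts)
    freq = _conditional(codon_counts, aa_counts, code.codon_aa)
    return UsageDistribution(ICU, freq, aa_counts, codon_counts, code)


def cc_distribution(genes: Sequence[CodonSequence]) -> UsageDistribution:
    """Pooled per-amino-acid-pair codon-pair frequencies of a gene set.

    Each gene of n codons contributes its n−1 overlapping adjacent pairs;
    pairs led by a stop codon cannot occur in a well-formed CDS and are
    rejected if present.
    """
    code = _check_genes(genes, min_len=2)
    full_counts = np.zeros(N_CODONS * N_CODONS)
    for g in genes:
        full_counts += np.bincount(g.pair_indices(), minlength=N_CODONS * N_CODONS)
    if full_counts[~code.codon_pair_valid].any():
        raise UsageError("gene set contains a codon pair led by a stop codon")
    codon_counts = full_counts[code.codon_pair_compact_to_full]
    aa_counts = np.zeros(N_AA_PAIRS)
    np.add.at(aa_counts, code.codon_pair_aa_pair, codon_counts)
    freq = _conditional(codon_counts, aa_counts, code.codon_pair_aa_pair)
    return UsageDistribution(CC, freq, aa_counts, codon_counts, code)


def _fitness(reference: UsageDistribution, subject: UsageDistribution, kind: str):
    for d in (reference, subject):
        if d.kind != kind:
            raise UsageError(f"expected a {kind} distribution, got {d.kind}")
    if reference.code is not subject.code:
        raise UsageError("distributions use different genetic codes")
    n = N_CODONS if kind == ICU else N_CODON_PAIRS
    return float(-np.abs(reference.freq - subject.freq).sum() / n)


def icu_fitness(reference: UsageDistribution, subject: UsageDistribution) -> float:
    """Ψ_ICU = −(1/64) Σ_k |p0^k − p1^k|; 0 iff the distributions agree."""
    return _fitness(reference, subject, ICU)


def cc_fitness(reference: UsageDistribution, subject: UsageDistribution) -> float:
    """Ψ_CC = −(1/3904) Σ_k |q0^k − q1^k|; 0 iff the distributions agree."""
    return _fitness(reference, subject, CC)


def fitness_pair(
    reference_icu: UsageDistribution,
    reference_cc: UsageDistribution,
    sequence: CodonSequence,
) -> FitnessPair:
    """Evaluate both fitness measures of one sequence against references."""
    return FitnessPair(
        psi_icu=icu_fitness(reference_icu, icu_distribution([sequence])),
        psi_cc=cc_fitness(reference_cc, cc_distribution([sequence])),
    )


def pooled(distributions: Iterable[UsageDistribution]) -> UsageDistribution:
    """Pool several same-kind distributions by summing their counts."""
    dists = list(distributions)
    if not dists:
        raise UsageError("nothing to pool")
    kind, code = dists[0].kind, dists[0].code
    codon_counts = np.sum([d.codon_counts for d in dists], axis=0)
    aa_counts = np.sum([d.aa_counts for d in dists], axis=0)
    unit_aa = dists[0].unit_aa
    freq = _conditional(codon_counts, aa_counts, unit_aa)
    return UsageDistribution(kind, freq, aa_counts, codon_counts, code)
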