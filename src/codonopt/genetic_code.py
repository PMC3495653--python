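"""Genetic-code tables, alphabets and translation primitives.

The package works on RNA codons internally (AUG, not ATG); DNA input is
converted on read.  A coding sequence is represented as an ordered list of
codon triplets — the unit that both the usage statistics and the genetic
algorithm manipulate — rather than as a nucleotide string.

Enumeration conventions
-----------------------
* 64 codons, sorted alphabetically (AAA … UUU).
* 21 amino-acid symbols: the 20 standard residues in alphabetical order
  followed by the stop symbol ``*``.
* 420 amino-acid pairs: ordered pairs whose first element is not stop
  (nothing can follow a stop codon), i.e. 20 × 21.
* 3904 codon pairs: ordered pairs whose first codon is a sense codon,
  i.e. 61 × 64.
"""

from __future__ import annotations

import math
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .errors import AlphabetError, UsageError

STOP = "*"

N_CODONS = 64
N_AA = 21
N_AA_PAIRS = 420
N_CODON_PAIRS = 3904


class GeneticCode:
    """A codon ↔ amino-acid mapping plus derived enumerations.

    Parameters
    ----------
    table_id
        NCBI translation-table identifier.  The default (1) is the standard
        nuclear code used by the common expression hosts (E. coli,
        L. lactis, P. pastoris, S. cerevisiae).  Any unambiguous RNA table
        known to Biopython can be plugged in instead.
    """

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_rna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop_codon in table.stop_codons:
            mapping[stop_codon] = STOP
        if len(mapping) != N_CODONS:
            raise UsageError(
                f"translation table {table_id} defines {len(mapping)} codons; "
                f"expected {N_CODONS}"
            )
        self.table_id = table_id
        self.codons: tuple[str, ...] = tuple(sorted(mapping))
        self.codon_index: dict[str, int] = {c: i for i, c in enumerate(self.codons)}

        sense_aas = sorted(set(mapping.values()) - {STOP})
        self.amino_acids: tuple[str, ...] = tuple(sense_aas) + (STOP,)
        if len(self.amino_acids) != N_AA:
            raise UsageError(
                f"translation table {table_id} encodes {len(self.amino_acids)} "
                f"symbols; expected {N_AA}"
            )
        self.aa_index: dict[str, int] = {a: j for j, a in enumerate(self.amino_acids)}
        self.stop_index = self.aa_index[STOP]

        # codon index -> amino-acid index
        self.codon_aa = np.array(
            [self.aa_index[mapping[c]] for c in self.codons], dtype=np.int64
        )
        # amino-acid index -> sorted codon indices of its synonyms
        self.synonyms: tuple[np.ndarray, ...] = tuple(
            np.flatnonzero(self.codon_aa == j) for j in range(N_AA)
        )
        self.degeneracy = np.array([len(s) for s in self.synonyms], dtype=np.int64)

    # ------------------------------------------------------------------ #
    # pair enumerations

    @cached_property
    def sense_codon_indices(self) -> np.ndarray:
        return np.flatnonzero(self.codon_aa != self.stop_index)

    @cached_property
    def aa_pair_valid(self) -> np.ndarray:
        """Boolean mask over the 441 full aa-pair slots (first ≠ stop)."""
        mask = np.ones((N_AA, N_AA), dtype=bool)
        mask[self.stop_index, :] = False
        return mask.ravel()

    @cached_property
    def aa_pair_full_to_compact(self) -> np.ndarray:
        """Full index a1*21+a2 → compact index in [0, 420), or −1."""
        out = np.full(N_AA * N_AA, -1, dtype=np.int64)
        out[np.flatnonzero(self.aa_pair_valid)] = np.arange(N_AA_PAIRS)
        return out

    @cached_property
    def codon_pair_valid(self) -> np.ndarray:
        """Boolean mask over the 4096 full codon-pair slots (first = sense)."""
        mask = np.ones((N_CODONS, N_CODONS), dtype=bool)
        mask[self.codon_aa == self.stop_index, :] = False
        return mask.ravel()

    @cached_property
    def codon_pair_full_to_compact(self) -> np.ndarray:
        out = np.full(N_CODONS * N_CODONS, -1, dtype=np.int64)
        out[np.flatnonzero(self.codon_pair_valid)] = np.arange(N_CODON_PAIRS)
        return out

    @cached_property
    def codon_pair_compact_to_full(self) -> np.ndarray:
        return np.flatnonzero(self.codon_pair_valid)

    @cached_property
    def codon_pair_aa_pair(self) -> np.ndarray:
        """Compact codon-pair index → compact aa-pair index (length 3904)."""
        full = self.codon_pair_compact_to_full
        c1, c2 = full // N_CODONS, full % N_CODONS
        aa_full = self.codon_aa[c1] * N_AA + self.codon_aa[c2]
        return self.aa_pair_full_to_compact[aa_full]

    def enumerate_units(
        self,
    ) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
        """Return (codons K, amino acids A, amino-acid pairs B, codon pairs P).

        Sizes are 64, 21, 420 and 3904 under any 64-codon table with a
        stop-excluding first pair position.
        """
        aa_pairs = tuple(
            self.amino_acids[f // N_AA] + self.amino_acids[f % N_AA]
            for f in np.flatnonzero(self.aa_pair_valid)
        )
        codon_pairs = tuple(
            self.codons[f // N_CODONS] + self.codons[f % N_CODONS]
            for f in self.codon_pair_compact_to_full
        )
        return self.codons, self.amino_acids, aa_pairs, codon_pairs

    # ------------------------------------------------------------------ #
    # translation

    def translate_indices(self, codon_indices: np.ndarray) -> np.ndarray:
        return self.codon_aa[codon_indices]

    def translate(self, seq: "CodonSequence | Iterable[str]") -> str:
        """Translate a codon sequence into its amino-acid string."""
        if isinstance(seq, CodonSequence):
            idx = seq.codon_indices
        else:
            idx = self.encode_codons(seq)
        return "".join(self.amino_acids[j] for j in self.codon_aa[idx])

    def encode_codons(self, codons: Iterable[str]) -> np.ndarray:
        """Map codon strings (RNA or DNA, any case) to codon indices."""
        out = []
        for pos, codon in enumerate(codons):
            c = codon.upper().replace("T", "U")
            try:
                out.append(self.codon_index[c])
            except KeyError:
                raise AlphabetError(
                    f"invalid codon {codon!r} at codon position {pos + 1}"
                ) from None
        return np.asarray(out, dtype=np.int64)

    def encode_protein(self, protein: str) -> np.ndarray:
        out = []
        for pos, aa in enumerate(protein):
            try:
                out.append(self.aa_index[aa.upper() if aa != STOP else aa])
            except KeyError:
                raise AlphabetError(
                    f"invalid amino-acid symbol {aa!r} at position {pos + 1}"
                ) from None
        return np.asarray(out, dtype=np.int64)


#: module-level standard code, shared by default everywhere
STANDARD_CODE = GeneticCode(1)


class CodonSequence:
    """A protein-coding sequence stored as an ordered list of codons.

    This is the chromosome of the genetic algorithm: crossover happens at
    codon boundaries and mutation swaps synonymous codons, so the encoded
    protein is invariant by construction.
    """

    __slots__ = ("codon_indices", "code", "id")

    def __init__(
        self,
        codon_indices: np.ndarray,
        code: GeneticCode = STANDARD_CODE,
        id: str | None = None,
    ):
        self.codon_indices = np.asarray(codon_indices, dtype=np.int64)
        if self.codon_indices.ndim != 1:
            raise UsageError("codon_indices must be one-dimensional")
        if self.codon_indices.size and not (
            (self.codon_indices >= 0) & (self.codon_indices < N_CODONS)
        ).all():
            raise AlphabetError("codon index out of range [0, 64)")
        self.code = code
        self.id = id

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_codons(
        cls,
        codons: Sequence[str],
        code: GeneticCode = STANDARD_CODE,
        id: str | None = None,
    ) -> "CodonSequence":
        return cls(code.encode_codons(codons), code, id=id)

    @classmethod
    def from_nucleotides(
        cls,
        seq: str,
        code: GeneticCode = STANDARD_CODE,
        id: str | None = None,
    ) -> "CodonSequence":
        """Build from a DNA or RNA string; length must be a multiple of 3."""
        seq = str(seq).strip()
        if len(seq) % 3 != 0:
            raise UsageError(
                f"sequence length {len(seq)} is not a multiple of 3"
                + (f" (record {id!r})" if id else "")
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        return cls.from_codons(codons, code, id=id)

    # ------------------------------------------------------------------ #

    @property
    def codons(self) -> list[str]:
        return [self.code.codons[i] for i in self.codon_indices]

    @property
    def protein(self) -> str:
        return self.code.translate(self)

    @property
    def protein_indices(self) -> np.ndarray:
        return self.code.translate_indices(self.codon_indices)

    def pair_indices(self) -> np.ndarray:
        """Full (4096-slot) indices of the n−1 overlapping adjacent pairs."""
        idx = self.codon_indices
        return idx[:-1] * N_CODONS + idx[1:]

    def to_rna(self) -> str:
        return "".join(self.codons)

    def to_dna(self) -> str:
        return self.to_rna().replace("U", "T")

    def __len__(self) -> int:
        return int(self.codon_indices.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonSequence):
            return NotImplemented
        return (
            self.code is other.code
            and self.codon_indices.shape == other.codon_indices.shape
            and bool((self.codon_indices == other.codon_indices).all())
        )

    def __hash__(self) -> int:
        return hash((self.code.table_id, self.codon_indices.tobytes()))

    def __repr__(self) -> str:
        head = "-".join(self.codons[:4])
        tail = "…" if len(self) > 4 else ""
        name = f" id={self.id!r}" if self.id else ""
        return f"<CodonSequence{name} n={len(self)} {head}{tail}>"


def count_coding_sequences_log10(
    protein: str, code: GeneticCode = STANDARD_CODE
) -> float:
    """log10 of the number of synonymous coding sequences of a protein.

    The count itself overflows for realistic proteins (a 300-residue protein
    has on the order of 1e100 codon paths), hence the log scale.  An
    all-Met/Trp protein has exactly one coding sequence, giving 0.
    """
    if not protein:
        raise UsageError("protein must be nonempty")
    aa_idx = code.encode_protein(protein)
    return float(np.log10(code.degeneracy[aa_idx].astype(float)).sum())


def back_translation_choices(protein: str, code: GeneticCode = STANDARD_CODE):
    """Yield the synonym codon-index array for each residue of *protein*."""
    for j in code.encode_protein(protein):
        yield code.synonyms[j]


def _math_guard() -> None:  # pragma: no cover - import-time sanity
    assert math.isclose(sum(STANDARD_CODE.degeneracy), 64)


_math_guard()
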