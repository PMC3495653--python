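"""FASTA / TSV readers and writers and expression-based gene selection."""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, UsageError
from .genetic_code import STANDARD_CODE, CodonSequence, GeneticCode

_VALID_NT = set("ACGTU")


def read_cds_fasta(
    path,
    code: GeneticCode = STANDARD_CODE,
    internal_stop: str = "warn",  # "warn" | "error" | "ignore"
) -> list[CodonSequence]:
    """Read coding sequences from FASTA (DNA or RNA, any case).

    Each record must be a whole number of codons; T is normalized to U.
    Ambiguity codes are rejected.  A stop codon before the final position
    usually indicates a frame problem and triggers a warning (or an error
    with ``internal_stop="error"``).
    """
    out: list[CodonSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_NT
        if bad:
            raise AlphabetError(
                f"record {record.id!r}: invalid nucleotide(s) {sorted(bad)} "
                "(ambiguity codes are not supported)"
            )
        cds = CodonSequence.from_nucleotides(seq, code, id=record.id)
        protein = cds.protein
        if "*" in protein[:-1]:
            msg = f"record {record.id!r} contains an internal stop codon"
            if internal_stop == "error":
                raise UsageError(msg)
            if internal_stop == "warn":
                warnings.warn(msg, stacklevel=2)
        out.append(cds)
    if not out:
        raise UsageError(f"no FASTA records found in {path}")
    return out


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """Read (id, amino-acid sequence) pairs from a protein FASTA."""
    out = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise UsageError(f"no FASTA records found in {path}")
    return out


def write_fasta(
    sequences: Iterable[CodonSequence],
    path,
    alphabet: str = "dna",
) -> None:
    """Write codon sequences as FASTA, DNA by default (``alphabet="rna"``)."""
    if alphabet not in ("dna", "rna"):
        raise UsageError("alphabet must be 'dna' or 'rna'")
    records = [
        SeqRecord(
            Seq(s.to_dna() if alphabet == "dna" else s.to_rna()),
            id=s.id or f"seq_{i + 1}",
            description="",
        )
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression_tsv(path, agg: str = "mean") -> pd.DataFrame:
    """Read an expression table: gene id column plus ≥1 numeric column(s).

    Multi-condition tables are collapsed to one value per gene by the mean
    across condition columns (``agg="median"`` for the median).  Returns a
    two-column frame (gene_id, expression) with unique ids and finite
    values.
    """
    if agg not in ("mean", "median"):
        raise UsageError("agg must be 'mean' or 'median'")
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise UsageError("expression table needs an id column and ≥1 value column")
    ids = table.iloc[:, 0].astype(str)
    values = table.iloc[:, 1:].apply(pd.to_numeric, errors="raise")
    collapsed = values.mean(axis=1) if agg == "mean" else values.median(axis=1)
    frame = pd.DataFrame({"gene_id": ids, "expression": collapsed})
    return validate_expression_table(frame)


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise UsageError("expression table is empty")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()[:3]
        raise UsageError(f"duplicate gene ids in expression table, e.g. {dupes}")
    if not np.isfinite(table["expression"]).all():
        raise UsageError("expression values must be finite")
    return table


def select_extreme_genes(
    table: pd.DataFrame, fraction: float = 0.05, tail: str = "top"
) -> list[str]:
    """Ids of the ceil(fraction·n) most (least) expressed genes.

    Ties in expression break deterministically by gene id (ascending), so
    the selection is reproducible across runs and platforms.
    """
    table = validate_expression_table(table)
    if not 0 < fraction < 1:
        raise UsageError("fraction must be in (0, 1)")
    if tail not in ("top", "bottom"):
        raise UsageError("tail must be 'top' or 'bottom'")
    k = math.ceil(fraction * len(table))
    ascending = tail == "bottom"
    ranked = table.sort_values(
        ["expression", "gene_id"], ascending=[ascending, True], kind="mergesort"
    )
    return ranked["gene_id"].head(k).tolist()


def subset_by_ids(
    genes: Sequence[CodonSequence], ids: Iterable[str]
) -> list[CodonSequence]:
    by_id = {g.id: g for g in genes}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise UsageError(f"gene ids not found in FASTA: {missing[:5]}")
    return [by_id[i] for i in ids]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
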