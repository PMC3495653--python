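"""Pearson chi-squared tests for codon (pair) usage bias.

Two tests are run per amino acid (pair) unit:

* ``uniform`` — H0: the synonymous codon (pair) usage of the high-expression
  genes is uniform/unbiased.  Expected counts are N_j / n_j where n_j is the
  unit's degeneracy.
* ``vs_all`` — H0: the usage in high-expression genes equals that of all
  genes in the genome.  Expected counts are scaled from the all-genes
  observations, Ẽ_ij = O_ij^A · N_j^H / N_j^A.

Both statistics use n_j − 1 degrees of freedom (the observed counts are
constrained to sum to N_j).  Units with a single synonymous codon (pair) —
Met, Trp and the four pairs composed of them — are *singular* and carry no
test; units with any expected count below 5 are *unevaluated*, the standard
validity screen for Pearson's chi-squared.  Otherwise a unit is *biased*
when p < 0.05 and *unbiased* when p ≥ 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import UsageDistribution
from .errors import UsageError

BIASED = "biased"
UNBIASED = "unbiased"
SINGULAR = "singular"
UNEVALUATED = "unevaluated"

ALPHA = 0.05
MIN_EXPECTED = 5.0


@dataclass(frozen=True)
class BiasTestResult:
    unit: str
    test: str  # "uniform" | "vs_all"
    chi2: float | None
    df: int | None
    p_value: float | None
    category: str


def _result(unit, test, chi2=None, df=None, p=None, category=UNEVALUATED):
    return BiasTestResult(unit, test, chi2, df, p, category)


def _pearson(observed: np.ndarray, expected: np.ndarray, unit: str, test: str):
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = observed.size - 1
    p = float(stats.chi2.sf(chi2, df))
    category = BIASED if p < ALPHA else UNBIASED
    return BiasTestResult(unit, test, chi2, df, p, category)


def chi2_uniform(observed: Sequence[float], unit: str = "") -> BiasTestResult:
    """Test one unit's synonymous counts against the uniform null."""
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0 or (obs < 0).any() or not np.isfinite(obs).all():
        raise UsageError("observed counts must be nonnegative and finite")
    if obs.size == 1:
        return _result(unit, "uniform", category=SINGULAR)
    total = obs.sum()
    if total == 0:
        return _result(unit, "uniform")
    expected = np.full(obs.size, total / obs.size)
    if (expected < MIN_EXPECTED).any():
        return _result(unit, "uniform")
    return _pearson(obs, expected, unit, "uniform")


def chi2_vs_all(
    observed_high: Sequence[float],
    observed_all: Sequence[float],
    unit: str = "",
) -> BiasTestResult:
    """Test high-expression counts against expectations scaled from all genes."""
    high = np.asarray(observed_high, dtype=float)
    allg = np.asarray(observed_all, dtype=float)
    if high.shape != allg.shape:
        raise UsageError("high and all-genes counts must cover the same unit")
    if high.size == 0 or (high < 0).any() or (allg < 0).any():
        raise UsageError("observed counts must be nonnegative")
    if high.size == 1:
        return _result(unit, "vs_all", category=SINGULAR)
    n_high, n_all = high.sum(), allg.sum()
    if n_high == 0 or n_all == 0:
        return _result(unit, "vs_all")
    expected = allg * n_high / n_all
    if (expected < MIN_EXPECTED).any():
        return _result(unit, "vs_all")
    return _pearson(high, expected, unit, "vs_all")


def _unit_counts(dist: UsageDistribution):
    """Yield (label, synonymous counts) for every amino acid (pair) unit."""
    unit_aa = dist.unit_aa
    labels = dist.aa_labels()
    for j, label in enumerate(labels):
        yield label, dist.codon_counts[unit_aa == j]


def bias_tests(
    high: UsageDistribution,
    all_genes: UsageDistribution | None = None,
    bonferroni: bool = False,
) -> list[BiasTestResult]:
    """Run the bias test for every unit of a distribution.

    With ``all_genes`` given, runs the high-vs-all test; otherwise the
    uniformity test.  ``bonferroni`` divides the 0.05 cutoff by the number
    of evaluated units (off by default: the raw per-unit cutoff is the
    convention this analysis follows).
    """
    if all_genes is not None:
        if all_genes.kind != high.kind:
            raise UsageError("high and all-genes distributions differ in kind")
        results = [
            chi2_vs_all(h_counts, a_counts, unit=label)
            for (label, h_counts), (_, a_counts) in zip(
                _unit_counts(high), _unit_counts(all_genes)
            )
        ]
    else:
        results = [
            chi2_uniform(counts, unit=label) for label, counts in _unit_counts(high)
        ]
    if bonferroni:
        evaluated = [r for r in results if r.p_value is not None]
        cutoff = ALPHA / max(len(evaluated), 1)
        results = [
            BiasTestResult(
                r.unit,
                r.test,
                r.chi2,
                r.df,
                r.p_value,
                (BIASED if r.p_value < cutoff else UNBIASED)
                if r.p_value is not None
                else r.category,
            )
            for r in results
        ]
    return results


def summarize_bias(results: Iterable[BiasTestResult]) -> dict[str, int]:
    """Count categories over a complete set of per-unit results.

    The categories partition the units, so the counts sum to the number of
    units (21 for ICU, 420 for CC).
    """
    results = list(results)
    units = [r.unit for r in results]
    if len(set(units)) != len(units):
        raise UsageError("duplicate units in bias results")
    summary = {BIASED: 0, UNBIASED: 0, SINGULAR: 0, UNEVALUATED: 0}
    for r in results:
        if r.category not in summary:
            raise UsageError(f"unknown category {r.category!r}")
        summary[r.category] += 1
    summary["total"] = len(results)
    return summary


def results_frame(results: Iterable[BiasTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [r.unit for r in results],
            "test": [r.test for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "category": [r.category for r in results],
        }
    )
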