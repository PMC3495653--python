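# Methods

## Usage distributions and fitness

A coding sequence is an ordered list of codon triplets over the RNA
alphabet; DNA input is converted on read and written back as DNA by
default. The standard genetic code (translation table 1) is the default,
with any unambiguous Biopython table pluggable. The stop symbol `*` is a
first-class amino-acid symbol, giving 21 symbols; ordered pairs whose
first element is a stop are excluded (nothing follows a stop), giving
420 amino-acid pairs and 61 × 64 = 3904 codon pairs.

The ICU distribution of a gene set conditions codon counts on amino-acid
counts, pooled across all genes before normalizing (so a set and its
concatenation give identical distributions). The CC distribution does the
same for the n−1 overlapping adjacent codon pairs of each gene,
conditioned on amino-acid-pair counts. Fitness of a subject against a
reference is the negative mean absolute difference of the two frequency
vectors over all 64 (3904) units.

**Absent units.** When an amino acid (pair) never occurs in a gene set,
its synonymous frequencies are defined as 0 and contribute
|p_other − 0| to the fitness sum. This makes the measure total; the
contribution is constant in the design variables, so optimizer rankings
are unaffected. Consequently Ψ_ICU ∈ [−2·21/64, 0] and
Ψ_CC ∈ [−2·420/3904, 0]: each conditional block contributes at most total
variation 2.

## Bias tests

Per amino acid (pair): Pearson chi-squared against (1) the uniform null,
expected N_j/n_j, and (2) the all-genes usage, expected
O_ij^A·N_j^H/N_j^A. Both use n_j − 1 degrees of freedom (counts are
constrained to sum to N_j; the second test's df is chosen to match the
first, as the same sum constraint applies). Units with one synonymous
codon (pair) — Met, Trp, and the four Met/Trp pairs — are *singular*;
units with any expected count < 5 are *unevaluated* (standard validity
screen); otherwise *biased* iff p < 0.05, uncorrected. A Bonferroni
option exists but is off by default: the per-unit raw cutoff is the
convention this analysis follows.

## ICO

Ψ_ICU depends on a design only through its codon counts, so optimization
reduces to rounding the real-valued targets p₀ᵏ × (protein's amino-acid
count) to integers. Largest-remainder (Hamilton) apportionment within
each amino acid preserves per-amino-acid totals and minimizes the L1
deviation from the real-valued optimum, hence attains the true integer
optimum; exact remainder ties are broken by a seeded permutation. The
budgeted codons are then placed uniformly at random over each amino
acid's positions. If the protein contains a residue absent from the
reference, the error suggests an explicit uniform-synonym fallback flag
rather than guessing (cross-validation enables it automatically for rare
residues, with a log notice). RCA, the control, assigns each residue a
synonymous codon uniformly at random; an option draws from a supplied
usage distribution instead; uniform is the default and is documented as
such.

## CCO and MOCO

Population of synonymous encodings; elitist selection keeps the top 50%
(by Ψ_CC, or by domination rank in MOCO); random parent pairing;
one-point crossover at a uniformly random codon boundary; each offspring
then receives one synonymous point substitution (count configurable). A
residue with degeneracy 1 makes the mutation a no-op after a bounded
number of re-draws. Protein identity is invariant by construction and
asserted in tests every generation.

**Termination.** Convergence means less than 0.5% improvement of the
best fitness across 100 generations. A literal ratio test
Ψ(r+100)/Ψ(r) < 0.005 would be ill-behaved for negative fitness values,
so the relative-improvement form |Ψ(r+W) − Ψ(r)|/max(|Ψ(r)|, 1e-12) <
threshold is implemented. A best fitness of exactly 0 (perfect match)
terminates immediately; `max_generations` (default 5000) is a safety
cap. MOCO terminates when the criterion holds for both objectives' best
values.

**Ranking.** Domination uses the standard two-objective rules (strict
improvement in one objective, no loss in the other). Each member stores only the
count of members dominating it — O(n) storage — and rank 0 provably
equals the Pareto set of the population (verified against an O(n²)
peeling oracle). Within equal ranks, selection ties are broken by a
seeded shuffle; NSGA-II crowding distance is available behind a flag but
off by default, keeping the reduced-storage variant as the baseline. The
reported MOCO solution is the front member nearest the ideal point
(best attained value per objective) after per-objective min–max
normalization over the front; raw-scale distance is available by flag.

**Defaults.** Population 100, window 100 generations, threshold 0.005,
one mutation per offspring. Population size and mutation count are free
parameters of the procedure; these defaults converge well at the gene
lengths used here (a 300-codon CCO run takes seconds).

## Cross-validation

Leave-one-out over a high-expression gene set (≥ 3 genes): references are
built from the remaining genes, every method designs the held-out
protein, and P_M = 100 × (matching codon positions)/n is scored against
the native CDS, including the stop codon by default (flag to exclude).
The tournament counts strict P_M wins per ordered method pair; wins +
losses + draws = number of genes. Genes shorter than 2 codons are skipped
with a warning. Per-fold, per-method seeds derive from one root seed.

## Synthetic hosts

The generator emulates the only external inputs the pipeline needs — a
host's high-expression gene set and an expression table — with two
controllable structures:

* **ICU target:** per amino acid, a Dirichlet draw with concentration
  `icu_concentration` (default 0.5: strongly biased but non-degenerate
  synonymous usage; → ∞ approaches uniform, → 0 approaches
  one-amino-acid-one-codon).
* **CC target:** per ordered amino-acid pair, a *coupling* — a joint
  distribution over the pair's codon pairs whose row and column marginals
  both equal the ICU target — obtained by Sinkhorn-scaling a random
  Gamma(shape = `cc_concentration`) matrix to those marginals (default
  0.15: strong pair structure; → ∞ recovers the independence product,
  the null under which CCO has no edge over ICO).

Genes are sampled as proteins (Met start, stop end, i.i.d. interior
residues, uniform composition by default) and back-translated by the
first-order codon chain induced by the couplings (or independently from
the ICU target in `independent` mode). Because every coupling preserves
the ICU marginals, the chain's codon marginals equal the ICU target at
every position and its adjacent-pair law equals the CC target exactly —
both advertised targets are simultaneously realizable, which is what
makes the estimator-consistency tests exact rather than approximate.

Gene lengths vary geometrically *around* the mean: a two-sided geometric
(discrete Laplace) jitter at 10% scale, so a 300-codon host yields
~300-codon genes. (A one-sided geometric with the same mean has mode 1
and spreads lengths over 1–5× the mean, which is not "around" the mean
and produces degenerate few-codon genes.)

The expression table assigns generated genes values near 1000–3000 and
pads 19 decoys per gene (uniform-codon-usage sequences) below 100, so
top-5% selection recovers exactly the generated genes and bottom-5%
selection yields decoys. Multi-condition expression tables read from disk
are collapsed by the mean across condition columns (median by flag).

**What the synthetic benchmark does not show.** The generator makes no
attempt at organism-realistic composition: no GC-content structure, no
expression-level noise model, no length/composition correlation, and its
pair structure is exactly first-order Markov. Passing the benchmark shows
the estimators, optimizers and validation protocol are correct and that
context optimization wins *when pair structure is real*; it does not by
itself establish effect sizes for any particular organism, which require
that organism's genome and expression data.

## Problem sizes used in the checks

Exhaustive oracles are feasible only at small n: ICO optimality is
verified against full enumeration on 50 peptides of length ≤ 6, CCO
against enumeration on 20 four-residue peptides (population 200), and the
domination ranking against peeling on 100 random populations of ≤ 50.
The end-to-end cross-validation runs on the default host — 30 genes of
~300 codons with strong pair structure — where the expected ordering is
mean P_M: CCO > ICO > RCA, with every optimized method beating the random
control on ≥ 95% of genes. At this scale the full LOOCV takes about four
minutes on one CPU.

## Known limitations

* The CC measure is first-order only; longer-range context is invisible
  to both the generator and the optimizers.
* The GA is heuristic: on long proteins CCO returns a converged, not
  certified-optimal, design (small-instance checks bound the gap).
* Chi-squared results on very small gene sets are dominated by the
  expected-count screen (most pair units end up unevaluated); the 420
  pair units need large gene sets to be well-populated.
* No design post-processing (restriction sites, repeats, mRNA secondary
  structure, oligo assembly) — deliberately out of scope.
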