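"""ICU / CC usage distributions and the Ψ fitness measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonopt as co
from codonopt.distributions import pooled

from conftest import make_seq


def naive_icu_fitness(ref_genes, subj_genes, code):
    """Independent re-count of Ψ_ICU from raw codon strings (dict based)."""

    def freq(genes):
        codon_counts, aa_counts = {}, {}
        for g in genes:
            for c in g.codons:
                codon_counts[c] = codon_counts.get(c, 0) + 1
                aa = code.translate([c])
                aa_counts[aa] = aa_counts.get(aa, 0) + 1
        return {
            c: codon_counts.get(c, 0) / aa_counts[code.translate([c])]
            if code.translate([c]) in aa_counts
            else 0.0
            for c in code.codons
        }

    p0, p1 = freq(ref_genes), freq(subj_genes)
    return -sum(abs(p0[c] - p1[c]) for c in code.codons) / 64


class TestIcuDistribution:
    def test_hand_counted_single_gene(self, code):
        gene = make_seq(["AUG", "AAA", "AAA", "AAG", "UGG"])
        dist = co.icu_distribution([gene])
        idx = code.codon_index
        assert dist.freq[idx["AAA"]] == pytest.approx(2 / 3)
        assert dist.freq[idx["AAG"]] == pytest.approx(1 / 3)
        assert dist.freq[idx["AUG"]] == 1.0
        assert dist.freq[idx["UGG"]] == 1.0
        assert dist.freq[idx["AAU"]] == 0.0  # Asn absent

    def test_degenerate_one_codon_per_aa(self):
        genes = [make_seq(["AAA", "GAA", "AAA"])]
        dist = co.icu_distribution(genes)
        assert set(np.unique(dist.freq)) <= {0.0, 1.0}

    def test_pooling_equals_concatenation(self, rng):
        g1 = co.rca_sequence("MKLVNP", seed=1)
        g2 = co.rca_sequence("KKLWPE", seed=2)
        cat = make_seq(g1.codons + g2.codons)
        assert np.allclose(
            co.icu_distribution([g1, g2]).freq, co.icu_distribution([cat]).freq
        )

    def test_empty_set_rejected(self):
        with pytest.raises(co.UsageError):
            co.icu_distribution([])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conditional_normalization(self, code, seed):
        """Synonymous frequencies of every present amino acid sum to 1."""
        genes = [
            co.rca_sequence("MKLVNPQRSTWYF", seed=seed),
            co.rca_sequence("ACDEFGHIKLMN", seed=seed + 1),
        ]
        dist = co.icu_distribution(genes)
        for j, syn in enumerate(code.synonyms):
            block = dist.freq[syn].sum()
            if dist.aa_counts[j] > 0:
                assert block == pytest.approx(1.0, abs=1e-12)
            else:
                assert block == 0.0


class TestCcDistribution:
    def test_singular_residue_pairs(self, code):
        gene = make_seq(["AUG", "UGG", "AUG"])
        dist = co.cc_distribution([gene])
        full = code.codon_pair_full_to_compact
        idx = code.codon_index
        mw = full[idx["AUG"] * 64 + idx["UGG"]]
        wm = full[idx["UGG"] * 64 + idx["AUG"]]
        assert dist.freq[mw] == 1.0
        assert dist.freq[wm] == 1.0

    def test_gene_contributes_n_minus_1_pairs(self):
        gene = co.rca_sequence("MKLVNPQ", seed=0)
        dist = co.cc_distribution([gene])
        assert dist.codon_counts.sum() == len(gene) - 1

    def test_unobserved_pair_has_zero_frequency(self, code):
        gene = make_seq(["AAA", "AAA"])
        dist = co.cc_distribution([gene])
        assert dist.codon_counts.sum() == 1
        assert (dist.freq > 0).sum() == 1

    def test_length_one_gene_rejected(self):
        with pytest.raises(co.UsageError):
            co.cc_distribution([make_seq(["AUG"])])

    def test_pair_conditional_normalization(self, code, small_host):
        dist = co.cc_distribution(small_host.genes)
        pair_aa = code.codon_pair_aa_pair
        for j in np.flatnonzero(dist.aa_counts):
            assert dist.freq[pair_aa == j].sum() == pytest.approx(1.0, abs=1e-12)


class TestFitness:
    def test_identity_is_zero(self, small_refs):
        ref_icu, ref_cc = small_refs
        assert co.icu_fitness(ref_icu, ref_icu) == 0.0
        assert co.cc_fitness(ref_cc, ref_cc) == 0.0

    def test_lysine_example(self):
        # reference 3:1 AAA:AAG vs all-AAA subject: |0.75-1| + |0.25-0| = 0.5
        ref = co.icu_distribution([make_seq(["AAA", "AAA", "AAA", "AAG"])])
        subj = co.icu_distribution([make_seq(["AAA"])])
        assert co.icu_fitness(ref, subj) == pytest.approx(-0.0078125)

    def test_symmetry(self, small_refs):
        ref_icu, _ = small_refs
        subj = co.icu_distribution([co.rca_sequence("MKLV", seed=5)])
        assert co.icu_fitness(ref_icu, subj) == co.icu_fitness(subj, ref_icu)

    def test_disjoint_pair_support(self):
        # same aa-pair (KK), disjoint codon pairs: block contributes 2/3904
        ref = co.cc_distribution([make_seq(["AAA", "AAA"])])
        subj = co.cc_distribution([make_seq(["AAG", "AAG"])])
        assert co.cc_fitness(ref, subj) == pytest.approx(-2 / 3904)

    def test_kind_mismatch_rejected(self, small_refs):
        ref_icu, ref_cc = small_refs
        with pytest.raises(co.UsageError):
            co.icu_fitness(ref_icu, ref_cc)
        with pytest.raises(co.UsageError):
            co.cc_fitness(ref_cc, ref_icu)

    def test_fitness_bounds(self, small_refs, rng):
        """Each amino-acid (pair) block contributes at most total variation 2."""
        ref_icu, ref_cc = small_refs
        for seed in range(5):
            seq = co.rca_sequence("MACDEFGHIKLNPQRSTVWY", seed=seed)
            f = co.fitness_pair(ref_icu, ref_cc, seq)
            assert -2 * 21 / 64 <= f.psi_icu <= 0
            assert -2 * 420 / 3904 <= f.psi_cc <= 0

    def test_matches_naive_recount_oracle(self, code, small_host):
        subj = [co.rca_sequence("MKKLVVNPQRST", seed=9)]
        expected = naive_icu_fitness(small_host.genes, subj, code)
        got = co.icu_fitness(
            co.icu_distribution(small_host.genes), co.icu_distribution(subj)
        )
        assert got == pytest.approx(expected, abs=1e-12)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, small_refs):
        for dist, kind in zip(small_refs, ("ICU", "CC")):
            path = tmp_path / f"{kind}.tsv"
            dist.to_tsv(path)
            back = co.UsageDistribution.from_tsv(path, kind)
            assert np.allclose(back.freq, dist.freq)
            assert np.allclose(back.codon_counts, dist.codon_counts)
            assert np.allclose(back.aa_counts, dist.aa_counts)

    def test_pooled_counts_add(self, small_host):
        d1 = co.icu_distribution(small_host.genes[:5])
        d2 = co.icu_distribution(small_host.genes[5:])
        both = pooled([d1, d2])
        direct = co.icu_distribution(small_host.genes)
        assert np.allclose(both.freq, direct.freq)
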