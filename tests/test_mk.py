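"""Tests for MK classification, exact tests, BH and Nei-Gojobori Ka/Ks."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mimicrylab.codon import CODON_AA, CodonSequence
from mimicrylab.mk import (
    MKTable,
    benjamini_hochberg,
    classify_sites,
    compare_observed_vs_simulated,
    fisher_exact_2x2,
    fisher_exact_rxc,
    ka_ks,
    omega_summary,
)

BASES = "ACGT"


def brute_force_classify(sample, ancestor, maf):
    """Independent site-by-site recount used as the oracle for classify_sites."""
    counts = dict(fixed_syn=0, fixed_nonsyn=0, poly_syn=0, poly_nonsyn=0)
    for site in range(len(ancestor)):
        calls = [s[site] for s in sample if s[site] in BASES]
        if not calls:
            continue
        for base in BASES:
            if base == ancestor[site]:
                continue
            freq = calls.count(base) / len(calls)
            if freq < maf:
                continue
            start = 3 * (site // 3)
            codon = list(ancestor[start : start + 3])
            mutant = codon.copy()
            mutant[site - start] = base
            aa_old = _translate("".join(codon))
            aa_new = _translate("".join(mutant))
            kind = "syn" if aa_old == aa_new else "nonsyn"
            bin_ = "fixed" if freq >= 1 - maf else "poly"
            counts[f"{bin_}_{kind}"] += 1
    return counts


def _translate(codon):
    idx = 16 * BASES.index(codon[0]) + 4 * BASES.index(codon[1]) + BASES.index(codon[2])
    return CODON_AA[idx]


class TestClassifySites:
    def test_no_variation(self):
        anc = "ATGGAA"
        t = classify_sites([anc, anc, anc], anc)
        assert t.as_vector().sum() == 0

    def test_fourfold_fixed_synonymous(self):
        anc = "GGAATG"
        sample = ["GGGATG"] * 20
        t = classify_sites(sample, anc)
        assert (t.fixed_syn, t.fixed_nonsyn, t.poly_syn, t.poly_nonsyn) == (1, 0, 0, 0)

    def test_toy_polymorphic_nonsynonymous(self):
        anc = "ATGGAA"
        sample = ["ATGGAA", "ATGGAA", "ATGAAA", "ATGAAA"]
        t = classify_sites(sample, anc, maf_cutoff=0.05)
        assert (t.fixed_syn, t.fixed_nonsyn, t.poly_syn, t.poly_nonsyn) == (0, 0, 0, 1)

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(77)
        sense = [
            "".join(c)
            for c in itertools.product(BASES, repeat=3)
            if _translate("".join(c)) != "*"
        ]
        for _ in range(100):
            n_codons = rng.integers(2, 6)
            anc = "".join(rng.choice(sense) for _ in range(n_codons))
            n_hap = int(rng.integers(2, 12))
            sample = []
            for _ in range(n_hap):
                seq = list(anc)
                for site in range(len(seq)):
                    r = rng.random()
                    if r < 0.15:
                        seq[site] = BASES[rng.integers(4)]
                    elif r < 0.2:
                        seq[site] = "N"
                sample.append("".join(seq))
            maf = float(rng.choice([0.0, 0.05, 0.1]))
            t = classify_sites(sample, anc, maf_cutoff=maf)
            expected = brute_force_classify(sample, anc, maf)
            assert {
                "fixed_syn": t.fixed_syn,
                "fixed_nonsyn": t.fixed_nonsyn,
                "poly_syn": t.poly_syn,
                "poly_nonsyn": t.poly_nonsyn,
            } == expected

    def test_maf_zero_never_decreases_counts(self):
        rng = np.random.default_rng(8)
        anc = "ATGGAAGGCTTA"
        sample = []
        for _ in range(10):
            seq = list(anc)
            for site in range(len(seq)):
                if rng.random() < 0.2:
                    seq[site] = BASES[rng.integers(4)]
            sample.append("".join(seq))
        t05 = classify_sites(sample, anc, maf_cutoff=0.05).as_vector()
        t0 = classify_sites(sample, anc, maf_cutoff=0.0).as_vector()
        assert (t0 >= t05).all()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            classify_sites(["ATG", "ATG"], "ATGGAA")


class TestFisher2x2:
    def test_enumerated_examples(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / 184756, abs=1e-15
        )

    def test_degenerate_margin(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 5]]) == 1.0

    def test_pmf_sums_to_one(self):
        table = np.array([[3, 7], [6, 2]])
        n = table.sum()
        r1 = table[0].sum()
        c1 = table[:, 0].sum()
        dist = sps.hypergeom(n, r1, c1)
        k = np.arange(max(0, c1 - table[1].sum()), min(r1, c1) + 1)
        assert dist.pmf(k).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            ours = fisher_exact_2x2(t)
            theirs = sps.fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestFisherRxC:
    def test_agrees_with_2x2(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 10, size=(2, 2))
            assert fisher_exact_rxc(t).p == pytest.approx(
                fisher_exact_2x2(t), abs=1e-12
            )

    def test_most_probable_table_p_one(self):
        assert fisher_exact_rxc([[1, 1], [1, 1]]).p == pytest.approx(1.0, abs=1e-12)

    def test_zero_total(self):
        assert fisher_exact_rxc([[0, 0], [0, 0]]).p == 1.0

    def test_enumeration_vs_monte_carlo(self):
        table = [[3, 0], [0, 3], [3, 0], [0, 3]]
        enum = fisher_exact_rxc(table)
        assert enum.method == "enumeration"
        mc = fisher_exact_rxc(table, max_tables=1, n_mc=100_000, seed=9)
        assert mc.method == "monte_carlo"
        assert abs(mc.p - enum.p) < 3 * mc.mc_se + 2 / 100_000

    def test_4x2_perfectly_structured(self):
        r = fisher_exact_rxc([[3, 0], [0, 3], [3, 0], [0, 3]])
        assert 0 < r.p < 0.05


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_matches_statsmodels_exactly(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            q_ours = benjamini_hochberg(p)
            q_ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q_ours, q_ref, atol=1e-15)

    def test_invariants(self):
        rng = np.random.default_rng(7)
        p = rng.random(25)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestKaKs:
    def test_identical_sequences(self):
        r = ka_ks("ATGGAA", "ATGGAA")
        assert r.ka == 0.0 and r.ks == 0.0 and r.omega is None

    def test_known_synonymous_change(self):
        r = ka_ks("TTCAAAGGAGGAGGA", "TTTAAAGGAGGAGGA")
        assert r.ka == 0.0
        assert r.ks > 0.0

    def test_hand_computed_pair(self):
        """ATG TTT vs ATG CTT: S = 2/3 sites, N = 16/3; one nonsynonymous
        difference; Ka = -3/4 ln(1 - 4*(3/16)/3), Ks = 0."""
        r = ka_ks("ATGCTT", "ATGTTT")
        assert r.syn_sites == pytest.approx(2 / 3, abs=1e-9)
        assert r.nonsyn_sites == pytest.approx(16 / 3, abs=1e-9)
        assert r.syn_diffs == 0.0 and r.nonsyn_diffs == 1.0
        assert r.ks == 0.0
        assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * (3 / 16) / 3), abs=1e-9)
        assert r.omega is None  # Ks = 0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(11)
        sense = [
            c
            for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
            if _translate(c) != "*"
        ]
        for _ in range(25):
            a = "".join(rng.choice(sense) for _ in range(8))
            b = "".join(rng.choice(sense) for _ in range(8))
            r1, r2 = ka_ks(a, b), ka_ks(b, a)
            for attr in ("ka", "ks", "syn_sites", "syn_diffs"):
                v1, v2 = getattr(r1, attr), getattr(r2, attr)
                if v1 is None or v2 is None:
                    assert v1 == v2
                else:
                    assert v1 == pytest.approx(v2, abs=1e-12)

    def test_jukes_cantor_undefined_reported_missing(self):
        # saturate: every codon maximally different, proportions >= 3/4
        r = ka_ks("AAA" * 5, "GGG" * 5)
        assert r.omega is None


class TestOmegaSummary:
    def test_identical_haplotypes_zero_se(self):
        anc = "ATGTTTGGA"
        hap = "ATGCTTGGG"  # one nonsyn + one syn change
        s = omega_summary([hap, hap, hap], anc)
        assert s.se == 0.0
        assert len(s.per_haplotype) == 3

    def test_mean_and_se_are_plain_statistics(self):
        anc = "ATGTTTGGAGGAGGAGGAGAA"
        haps = [
            "ATGCTTGGGGGAGGAGGAGAA",  # one nonsyn + one syn
            "ATGTTCGGGGGAGGAGGAGAA",  # two syn
            "ATGCTTGGGGGGGGAGGAGAA",  # one nonsyn + two syn
        ]
        values = [ka_ks(h, anc).omega for h in haps]
        values = [v for v in values if v is not None]
        s = omega_summary(haps, anc)
        assert s.mean == pytest.approx(np.mean(values))
        expected_se = np.std(values, ddof=1) / math.sqrt(len(values))
        assert s.se == pytest.approx(expected_se)

    def test_all_undefined_raises(self):
        anc = "ATGGAA"
        with pytest.raises(ValueError):
            omega_summary([anc, anc], anc)  # identical: omega undefined


class TestScenarioComparison:
    def test_identical_table_p_one(self):
        obs = MKTable(5, 2, 10, 3)
        res = compare_observed_vs_simulated(obs, [obs])
        assert res.p_values[0] == pytest.approx(1.0, abs=1e-9)
        assert res.fraction_nonsignificant == 1.0

    def test_divergent_tables_significant(self):
        obs = MKTable(20, 1, 5, 1)
        sims = [MKTable(1, 20, 1, 5)] * 5
        res = compare_observed_vs_simulated(obs, sims)
        assert res.fraction_nonsignificant == 0.0
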