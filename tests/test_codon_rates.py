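import itertools
import math

import numpy as np
import pytest

from paralogdiverge.codon_rates import (
    RateError,
    count_differences,
    count_sites,
    pairwise_ng86,
    per_codon_profile,
    rate_contrast,
    rate_summary,
)
from paralogdiverge.distances import jc69
from paralogdiverge.seqcore import sense_codons
from tests.conftest import make_alignment
from tests.oracles import ng86_pair_oracle, path_differences_oracle, site_counts_oracle


class TestCountSites:
    def test_phe_has_one_third_synonymous(self):
        cs = count_sites("TTT")
        assert cs.syn_sites == pytest.approx(1 / 3)
        assert cs.nonsyn_sites == pytest.approx(8 / 3)

    def test_met_fully_nonsynonymous(self):
        cs = count_sites("ATG")
        assert cs.syn_sites == 0.0
        assert cs.nonsyn_sites == 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(RateError, match="stop"):
            count_sites("TAA")

    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in sense_codons():
            cs = count_sites(codon)
            assert cs.syn_sites + cs.nonsyn_sites == pytest.approx(3.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        for codon in sense_codons():
            syn, nonsyn = site_counts_oracle(codon)
            cs = count_sites(codon)
            assert cs.syn_sites == pytest.approx(syn, abs=1e-12)
            assert cs.nonsyn_sites == pytest.approx(nonsyn, abs=1e-12)


class TestCountDifferences:
    def test_identical_codons(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_single_synonymous_step(self):
        assert count_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        # frozen from the exhaustive 2!-pathway oracle
        assert path_differences_oracle("TTT", "GTA") == (0.5, 1.5)
        assert count_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_symmetric_in_arguments(self, rng):
        codons = sense_codons()
        for _ in range(50):
            a, b = rng.choice(codons, size=2)
            assert count_differences(a, b) == count_differences(b, a)

    def test_stop_blocked_pathways_renormalized(self):
        # TTA -> TGA (stop) blocks one of the two orderings to TGG: the
        # average must be over the single remaining pathway
        assert count_differences("TTA", "TGG") == pytest.approx((1.0, 1.0))
        for a, b in [("TCA", "ACT"), ("TGG", "TAT"), ("TAT", "TGG"), ("AGA", "ACA")]:
            expected = path_differences_oracle(a, b)
            got = count_differences(a, b)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_sum_equals_number_of_differences(self, rng):
        codons = sense_codons()
        for _ in range(200):
            a, b = rng.choice(codons, size=2)
            d = count_differences(a, b)
            if d is None:
                continue
            k = sum(x != y for x, y in zip(a, b))
            assert d[0] + d[1] == pytest.approx(k, abs=1e-12)


class TestPairwiseNG86:
    def test_identical_rows(self):
        aln = make_alignment([("a", "ATGTTTGGC"), ("b", "ATGTTTGGC")])
        pr = pairwise_ng86(aln, "a", "b")
        assert pr.Ka == 0 and pr.Ks == 0 and pr.ratio is None
        assert pr.codons_compared == 3

    def test_hand_built_alignment_matches_oracle(self):
        rows = [("a", "TTTATGGGA"), ("b", "TTCATGGGG")]
        aln = make_alignment(rows)
        pr = pairwise_ng86(aln, "a", "b")
        S, N, Sd, Nd = ng86_pair_oracle(
            ["TTT", "ATG", "GGA"], ["TTC", "ATG", "GGG"])
        assert pr.S == pytest.approx(S, abs=1e-12)
        assert pr.N == pytest.approx(N, abs=1e-12)
        assert pr.Sd == pytest.approx(Sd, abs=1e-12)
        assert pr.Nd == pytest.approx(Nd, abs=1e-12)
        assert pr.Ks == pytest.approx(jc69(Sd / S), abs=1e-12)

    def test_gap_and_n_columns_skipped(self):
        aln = make_alignment([("a", "TTT---GGA"), ("b", "TTCATNGGG")])
        pr = pairwise_ng86(aln, "a", "b")
        assert pr.codons_compared == 2

    def test_symmetry(self, small_family):
        aln = small_family.alignment
        a, b = aln.ids[0], aln.ids[1]
        ab, ba = pairwise_ng86(aln, a, b), pairwise_ng86(aln, b, a)
        assert (ab.S, ab.N, ab.Sd, ab.Nd) == (ba.S, ba.N, ba.Sd, ba.Nd)

    def test_no_comparable_codons_raises(self):
        aln = make_alignment([("a", "---"), ("b", "ATG")])
        with pytest.raises(RateError):
            pairwise_ng86(aln, "a", "b")

    def test_random_pairs_match_oracle(self, rng):
        """The fast implementation equals the exhaustive enumerator on
        whole random sequences."""
        codons = sense_codons()
        for _ in range(5):
            ca = list(rng.choice(codons, size=30))
            cb = list(rng.choice(codons, size=30))
            aln = make_alignment([("a", "".join(ca)), ("b", "".join(cb))])
            pr = pairwise_ng86(aln, "a", "b")
            S, N, Sd, Nd = ng86_pair_oracle(ca, cb)
            assert (pr.S, pr.N) == pytest.approx((S, N), abs=1e-12)
            assert (pr.Sd, pr.Nd) == pytest.approx((Sd, Nd), abs=1e-12)

    def test_matches_biopython_ng86(self):
        """Independent cross-check against Biopython's NG86 estimator on a
        divergent gap-free pair."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(7)
        codons = sense_codons()
        ca = list(rng.choice(codons, size=80))
        cb = ca.copy()
        # mutate ~20 codons, rejecting stops
        stops = {"TAA", "TAG", "TGA"}
        idx = rng.choice(80, size=20, replace=False)
        for i in idx:
            while True:
                cand = str(rng.choice(codons))
                if cand not in stops:
                    cb[i] = cand
                    break
        aln = make_alignment([("a", "".join(ca)), ("b", "".join(cb))])
        pr = pairwise_ng86(aln, "a", "b")
        dn, ds = cal_dn_ds(CodonSeq("".join(ca)), CodonSeq("".join(cb)), method="NG86")
        # small systematic gap expected: Biopython keeps stop-crossing
        # pathways in the average whereas this package excludes them
        assert pr.Ka == pytest.approx(dn, rel=0.08)
        assert pr.Ks == pytest.approx(ds, rel=0.08)


class TestRateSummary:
    def test_two_sequence_group_equals_single_pair(self):
        rows = [("a", "TTTATGGGATGC"), ("b", "TTCATGGGGTGT")]
        aln = make_alignment(rows)
        s = rate_summary(aln, ["a", "b"], label="g")
        pr = pairwise_ng86(aln, "a", "b")
        assert s.mean_ka == pytest.approx(pr.Ka)
        assert s.mean_ks == pytest.approx(pr.Ks)
        assert s.mean_kaks == pytest.approx(pr.ratio)
        assert s.n_pairs == 1

    def test_mean_of_ratios_not_ratio_of_means(self):
        """Three sequences chosen so the two aggregations differ by > 5%;
        the mean-of-pairwise-ratios value must be the one reported."""
        pad = "GGTACTCTTGAAGCTCCAATT"
        rows = [
            ("a", "ATGAAATTT" + pad + pad),
            # a-b: a single synonymous difference (tiny Ks, ratio 0)
            ("b", "ATGAAGTTT" + pad + pad),
            # c: one nonsynonymous (TTT->TTA) plus several synonymous changes,
            # so the a-c and b-c pairs have a much larger Ks than a-b
            ("c", "ATGAAATTA" + "GGCACCCTGGAGGCTCCAATT" + pad),
        ]
        aln = make_alignment(rows)
        ratios, kas, kss = [], [], []
        for x, y in itertools.combinations("abc", 2):
            pr = pairwise_ng86(aln, x, y)
            kas.append(pr.Ka), kss.append(pr.Ks)
            if pr.ratio is not None:
                ratios.append(pr.ratio)
        mean_of_ratios = np.mean(ratios)
        ratio_of_means = np.mean(kas) / np.mean(kss)
        assert abs(mean_of_ratios - ratio_of_means) / ratio_of_means > 0.05
        s = rate_summary(aln, ["a", "b", "c"], label="g")
        assert s.mean_kaks == pytest.approx(mean_of_ratios)

    def test_undefined_ratios_counted_and_excluded(self):
        base = "ATGAAACCTGGTTCAGATCGT"
        rows = [("a", base), ("b", base), ("c", base[:-3] + "CGA")]  # CGT->CGA synonymous
        aln = make_alignment(rows)
        s = rate_summary(aln, ["a", "b", "c"], label="g")
        # a-b identical -> undefined ratio; a-c and b-c purely synonymous -> ratio 0
        assert s.n_undefined_ratios == 1
        assert s.mean_kaks == pytest.approx(0.0)

    def test_needs_two_sequences(self, small_family):
        with pytest.raises(RateError):
            rate_summary(small_family.alignment, [small_family.alignment.ids[0]])


class TestRateContrast:
    def test_identical_groups_give_one(self, small_family):
        aln = small_family.alignment
        ids = aln.ids_by(paralog="P1")
        s = rate_summary(aln, ids, label="P1")
        assert rate_contrast(s, s) == pytest.approx(1.0)

    def test_simulated_two_to_one_recovered(self):
        """omega ratio 2 recovered within 25% (averaged over replicates)."""
        from paralogdiverge import SimulationConfig, simulate_paralog_family

        vals = []
        for seed in range(5):
            c1 = SimulationConfig(n_taxa=10, n_codons=300, omega=0.2, seed=seed)
            c2 = SimulationConfig(n_taxa=10, n_codons=300, omega=0.1, seed=seed)
            fam = simulate_paralog_family(c1, c2)
            s1 = rate_summary(fam.alignment, fam.alignment.ids_by(paralog="P1"), "P1")
            s2 = rate_summary(fam.alignment, fam.alignment.ids_by(paralog="P2"), "P2")
            vals.append(rate_contrast(s1, s2))
        assert np.mean(vals) == pytest.approx(2.0, rel=0.25)


class TestPerCodonProfile:
    def test_invariant_alignment_all_undefined(self):
        aln = make_alignment([("a", "ATGTTTGGC"), ("b", "ATGTTTGGC")])
        prof = per_codon_profile(aln, [("a", "b")])
        assert all(r is None for r in prof.ratio)
        assert prof.Sd.sum() == 0 and prof.Nd.sum() == 0

    def test_pure_synonymous_column_is_zero_not_undefined(self):
        aln = make_alignment([("a", "TTTATG"), ("b", "TTCATG")])
        prof = per_codon_profile(aln, [("a", "b")])
        assert prof.ratio[0] == 0.0
        assert prof.ratio[1] is None

    def test_window_pooling(self):
        aln = make_alignment([("a", "TTTATGAAA"), ("b", "TTCATGAAG")])
        prof = per_codon_profile(aln, [("a", "b")], window=3)
        # middle column pools its synonymous neighbours -> defined, 0
        assert prof.ratio[1] == 0.0

    def test_even_window_rejected(self):
        aln = make_alignment([("a", "ATG"), ("b", "ATG")])
        with pytest.raises(RateError):
            per_codon_profile(aln, [("a", "b")], window=2)

    def test_low_omega_clade_profile_lower(self, small_family):
        aln = small_family.alignment
        p1 = aln.ids_by(paralog="P1")
        p2 = aln.ids_by(paralog="P2")
        prof1 = per_codon_profile(aln, list(itertools.combinations(p1, 2)))
        prof2 = per_codon_profile(aln, list(itertools.combinations(p2, 2)))
        mean1 = np.mean([r for r in prof1.ratio if r is not None])
        mean2 = np.mean([r for r in prof2.ratio if r is not None])
        # omega 0.08 clade shows a higher per-codon profile than omega 0.03
        assert mean1 > mean2

    def test_counts_match_pairwise_totals(self, small_family):
        aln = small_family.alignment
        ids = aln.ids_by(paralog="P1")[:4]
        pairs = list(itertools.combinations(ids, 2))
        prof = per_codon_profile(aln, pairs)
        total_sd = sum(pairwise_ng86(aln, a, b).Sd for a, b in pairs)
        total_nd = sum(pairwise_ng86(aln, a, b).Nd for a, b in pairs)
        assert prof.Sd.sum() == pytest.approx(total_sd, abs=1e-9)
        assert prof.Nd.sum() == pytest.approx(total_nd, abs=1e-9)
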