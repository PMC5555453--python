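"""Codon-bias suite: counting, Wright's Nc, CAI, GC partitions."""

import math

import numpy as np
import pytest

from domainscape.codons import (CAI_CODONS, CodonCounts, CodonWeights, FAMILIES,
                                SENSE_CODONS, codon_adaptation_index,
                                codon_frequency, count_codons, effective_number_of_codons,
                                equal_usage_cai, extract_cds, gc_partition,
                                relative_adaptiveness)
from domainscape.genes import IsoformModel


class TestCountCodons:
    def test_simple_tally_with_stop(self):
        cc = count_codons("ATGAAATAA")
        assert cc.counts["ATG"] == 1 and cc.counts["AAA"] == 1 and cc.counts["TAA"] == 1
        assert cc.total_sense == 2  # stop excluded

    def test_ambiguous_codon_skipped_and_counted(self):
        cc = count_codons("ATGNNNAAA")
        assert cc.counts["ATG"] == 1 and cc.counts["AAA"] == 1
        assert cc.ambiguous == 1

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            count_codons("ATGA")

    def test_empty_sequence_all_zero(self):
        assert count_codons("").total_sense == 0

    def test_reverse_strand_extraction_equals_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        genome = {"c": seq}
        minus = IsoformModel("g", "t", "c", "-", [(120, 240), (0, 60)])
        direct = seq[0:60] + seq[120:240]
        rc = direct[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert extract_cds(genome, minus) == rc


def uniform_counts(per_codon=12):
    return CodonCounts({c: per_codon for c in SENSE_CODONS})


def single_codon_counts(per_codon=12):
    return CodonCounts({cods[0]: per_codon for cods in FAMILIES.values()})


class TestEffectiveNumberOfCodons:
    def test_uniform_usage_is_61(self):
        assert effective_number_of_codons(uniform_counts(), "proportions") == pytest.approx(61.0)

    def test_single_codon_per_family_is_20(self):
        assert effective_number_of_codons(single_codon_counts(), "proportions") \
            == pytest.approx(20.0)

    def test_toy_gene_matches_hand_evaluated_formula(self):
        # 30-codon toy gene: Lys 6xAAA+2xAAG, Ile 3xATT+1xATC, Ala 4xGCT+4xGCC,
        # Leu 6xCTG+2xCTA, Met 2xATG (single-codon family, excluded)
        counts = CodonCounts({"AAA": 6, "AAG": 2, "ATT": 3, "ATC": 1,
                              "GCT": 4, "GCC": 4, "CTG": 6, "CTA": 2, "ATG": 2})
        # hand evaluation of Wright's estimator per family
        def f_hat(ns):
            n = sum(ns)
            sp2 = sum((x / n) ** 2 for x in ns)
            return (n * sp2 - 1) / (n - 1)
        f2 = f_hat([6, 2])            # Lys: only observed twofold family
        f3 = f_hat([3, 1, 0])         # Ile
        f4 = f_hat([4, 4, 0, 0])      # Ala
        f6 = f_hat([6, 2, 0, 0, 0, 0])  # Leu
        expected = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
        got = effective_number_of_codons(counts, "finite_sample")
        assert got == pytest.approx(expected, abs=1e-9)

    def test_absent_class_imputed_at_no_bias_value(self):
        # only one twofold family observed, uniform within it
        counts = CodonCounts({"AAA": 5, "AAG": 5})
        nc = effective_number_of_codons(counts, "proportions")
        # F2 = 0.5 -> 18; F3=1/3 -> 3; F4=1/4 -> 20; F6=1/6 -> 18; +2
        assert nc == pytest.approx(61.0)

    def test_all_families_absent_rejected(self):
        with pytest.raises(ValueError):
            effective_number_of_codons(CodonCounts(), "proportions")

    def test_monotone_along_bias_interpolation(self):
        # interpolate from uniform usage to one-codon-per-family
        prev = np.inf
        for step in range(11):
            t = step / 10
            counts = {}
            for cods in FAMILIES.values():
                mass = 1000
                lead = int(mass * (1 / len(cods) + t * (1 - 1 / len(cods))))
                rest = (mass - lead) // max(len(cods) - 1, 1)
                counts[cods[0]] = counts.get(cods[0], 0) + lead
                for c in cods[1:]:
                    counts[c] = rest
            nc = effective_number_of_codons(CodonCounts(counts), "proportions")
            assert nc <= prev + 1e-9
            prev = nc


class TestRelativeAdaptiveness:
    def test_family_ratio(self):
        ref = CodonCounts({"AAA": 30, "AAG": 10})
        w = relative_adaptiveness(ref)
        assert w.w["AAA"] == 1.0 and w.w["AAG"] == pytest.approx(1 / 3)

    def test_uniform_reference_all_ones(self):
        w = relative_adaptiveness(uniform_counts())
        assert set(w.w.values()) == {1.0}

    def test_zero_count_codon_floored(self):
        ref = CodonCounts({"CAT": 50, "CAC": 0})
        assert relative_adaptiveness(ref).w["CAC"] == 0.01

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_adaptiveness(CodonCounts())


class TestCai:
    def test_all_optimal_codons_give_one(self):
        w = relative_adaptiveness(uniform_counts())
        gene = CodonCounts({c: 3 for c in CAI_CODONS})
        assert codon_adaptation_index(gene, w) == pytest.approx(1.0)

    def test_all_floored_codons_give_floor(self):
        w = CodonWeights({c: 0.01 for c in CAI_CODONS})
        gene = CodonCounts({c: 2 for c in CAI_CODONS})
        assert codon_adaptation_index(gene, w) == pytest.approx(0.01)

    def test_mixed_gene_matches_log_sum_oracle(self, rng):
        ref = CodonCounts({c: int(n) for c, n in
                           zip(SENSE_CODONS, rng.integers(1, 100, len(SENSE_CODONS)))})
        w = relative_adaptiveness(ref)
        gene_counts = {c: int(n) for c, n in
                       zip(CAI_CODONS, rng.integers(0, 20, len(CAI_CODONS)))}
        gene = CodonCounts(gene_counts)
        log_sum = sum(n * math.log(w.w[c]) for c, n in gene_counts.items())
        L = sum(gene_counts.values())
        assert codon_adaptation_index(gene, w) == pytest.approx(
            math.exp(log_sum / L), abs=1e-12)

    def test_met_trp_stops_excluded(self):
        w = relative_adaptiveness(uniform_counts())
        gene = CodonCounts({"ATG": 10, "TGG": 10, "TAA": 2, "AAA": 5})
        # only AAA contributes
        assert codon_adaptation_index(gene, w) == pytest.approx(w.w["AAA"])

    def test_concatenation_is_weighted_geometric_mean(self, rng):
        ref = CodonCounts({c: int(n) for c, n in
                           zip(SENSE_CODONS, rng.integers(1, 100, len(SENSE_CODONS)))})
        w = relative_adaptiveness(ref)
        a = CodonCounts({"AAA": 4, "CAT": 2})
        b = CodonCounts({"GGC": 3, "AAG": 3})
        cai_ab = codon_adaptation_index(a + b, w)
        la, lb = 6, 6
        expected = math.exp((la * math.log(codon_adaptation_index(a, w))
                             + lb * math.log(codon_adaptation_index(b, w))) / (la + lb))
        assert cai_ab == pytest.approx(expected, abs=1e-12)


class TestEqualUsageCai:
    def test_all_ones_threshold_is_one(self):
        w = relative_adaptiveness(uniform_counts())
        assert equal_usage_cai(w) == pytest.approx(1.0)

    def test_two_codon_family_sqrt(self):
        w = CodonWeights({"AAA": 1.0, "AAG": 0.5})
        assert equal_usage_cai(w) == pytest.approx(math.sqrt(0.5))

    def test_bounds(self, rng):
        vals = rng.uniform(0.01, 1.0, len(CAI_CODONS))
        # force one 1.0 per family as the definition requires
        w_map = dict(zip(CAI_CODONS, vals))
        for cods in FAMILIES.values():
            if len(cods) > 1:
                w_map[cods[0]] = 1.0
        w = CodonWeights(w_map)
        thr = equal_usage_cai(w)
        assert min(w_map.values()) <= thr <= 1.0


class TestGcPartition:
    def test_two_codon_example(self):
        gc = gc_partition(CodonCounts({"GGG": 1, "AAA": 1}))
        assert gc["GC1"] == gc["GC2"] == gc["GC3"] == 0.5
        assert gc["GC_4D"] == 1.0  # only GGG (Gly) is fourfold

    def test_all_at_is_zero(self):
        gc = gc_partition(CodonCounts({"AAA": 5, "TTT": 5}))
        assert gc["GC_coding"] == 0 and gc["GC3"] == 0

    def test_planted_gc3_recovered(self, codon_geneset):
        truth = codon_geneset["truth"]
        seqs = codon_geneset["seqs"]
        for group, target in (("mutational", 0.30),):
            ids = truth[truth.group == group].gene_id
            cc = count_codons("".join(seqs[g] for g in ids))
            assert gc_partition(cc)["GC3"] == pytest.approx(target, abs=0.02)


class TestCodonFrequency:
    def test_family_fractions(self):
        df = codon_frequency(CodonCounts({"CAT": 7, "CAC": 3}))
        his = df[df.aa == "H"].set_index("codon")
        assert his.loc["CAT", "fraction"] == pytest.approx(0.7)
        assert his.loc["CAC", "fraction"] == pytest.approx(0.3)

    def test_absent_family_reported_missing(self):
        df = codon_frequency(CodonCounts({"AAA": 1}))
        assert df[df.aa == "H"].fraction.isna().all()

    def test_fractions_sum_to_one_per_observed_family(self, rng):
        counts = CodonCounts({c: int(n) for c, n in
                              zip(SENSE_CODONS, rng.integers(0, 30, len(SENSE_CODONS)))})
        df = codon_frequency(counts)
        sums = df.dropna().groupby("aa").fraction.sum()
        assert np.allclose(sums, 1.0)


class TestBiasRegimes:
    def test_selection_raises_cai_and_mutational_lowers_it(self, codon_geneset):
        seqs, truth = codon_geneset["seqs"], codon_geneset["truth"]
        w = relative_adaptiveness(codon_geneset["reference"])
        cai = {}
        for group in ("mutational", "selected"):
            ids = truth[truth.group == group].gene_id
            cai[group] = np.mean([
                codon_adaptation_index(count_codons(seqs[g]), w) for g in ids])
        assert cai["selected"] > cai["mutational"]

    def test_uniform_genes_near_maximal_nc(self, codon_geneset):
        seqs, truth = codon_geneset["seqs"], codon_geneset["truth"]
        ids = truth[truth.group == "uniform"].gene_id
        nc = [effective_number_of_codons(count_codons(seqs[g]), "finite_sample")
              for g in ids]
        assert np.mean(nc) == pytest.approx(61.0, abs=1.0)
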