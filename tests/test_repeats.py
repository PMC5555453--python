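"""Repeat ledger: parsing, class-aware merging, densities, attribution,
coverage — exact examples plus per-base brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domainscape.io import write_repeatmasker_out
from domainscape.repeats import (AnalysisRegion, RepeatFeature, class_density,
                                 coverage_track, merge_by_class,
                                 normalize_repeat_class, overlap_attribution,
                                 parse_repeatmasker_out, score_filter,
                                 top_repeat_table)

from conftest import classes_per_base


def feat(start, end, cls="LINE", name="el", seq="chr", score=300.0, strand="+"):
    return RepeatFeature(seq, start, end, strand, name, cls,
                         normalize_repeat_class(cls), score)


@pytest.mark.parametrize("raw,expected", [
    ("LINE/CR1", "LINE"),
    ("LTR/Gypsy", "LTR"),
    ("DNA/hAT-hobo", "DNA"),
    ("RC/Helitron", "RC_Helitron"),
    ("Helitron", "RC_Helitron"),
    ("Satellite/acro", "Satellite"),
    ("Simple_repeat", "Simple_LowComplexity"),
    ("Low_complexity", "Simple_LowComplexity"),
    ("ARTEFACT", "Other"),
    ("Unknown", "Other"),
])
def test_normalize_repeat_class(raw, expected):
    assert normalize_repeat_class(raw) == expected


class TestParseOut:
    def test_coordinates_converted_to_half_open(self, tmp_path):
        p = tmp_path / "r.out"
        write_repeatmasker_out(p, [(310.0, "chr", 100, 200, "+", "DNAREP1_DM", "LINE/CR1")])
        feats = parse_repeatmasker_out(p)
        assert len(feats) == 1
        f = feats[0]
        assert (f.start, f.end, f.length) == (100, 200, 100)
        assert f.repeat_name == "DNAREP1_DM"
        assert f.raw_class == "LINE/CR1" and f.canonical_class == "LINE"

    def test_minus_strand_and_helitron_class(self, tmp_path):
        p = tmp_path / "r.out"
        write_repeatmasker_out(p, [(99.5, "s", 0, 50, "-", "Hel", "RC/Helitron")])
        f = parse_repeatmasker_out(p)[0]
        assert f.strand == "-" and f.canonical_class == "RC_Helitron"

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "r.out"
        write_repeatmasker_out(p, [])
        assert parse_repeatmasker_out(p) == []

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "r.out"
        write_repeatmasker_out(p, [(310.0, "chr", 100, 200, "+", "x", "LINE")])
        with open(p, "a") as fh:
            fh.write("not a valid row\n")
        with pytest.raises(ValueError, match="line 5"):
            parse_repeatmasker_out(p)


class TestMergeByClass:
    def test_same_class_overlap_merges(self):
        segs = merge_by_class([feat(0, 100), feat(80, 150)])
        assert [(s.start, s.end, s.canonical_class) for s in segs] == [(0, 150, "LINE")]

    def test_cross_class_overlap_reclassified(self):
        segs = merge_by_class([feat(0, 100, "LINE"), feat(80, 150, "LTR")])
        assert [(s.start, s.end, s.canonical_class) for s in segs] == [
            (0, 80, "LINE"), (80, 100, "Overlapping"), (100, 150, "LTR")]

    def test_disjoint_features_unchanged(self):
        segs = merge_by_class([feat(0, 50, "LINE"), feat(60, 90, "DNA")])
        assert [(s.start, s.end, s.canonical_class) for s in segs] == [
            (0, 50, "LINE"), (60, 90, "DNA")]

    def test_never_merges_across_sequences(self):
        segs = merge_by_class([feat(0, 100, seq="a"), feat(50, 150, seq="b")])
        assert {(s.seq_id, s.start, s.end) for s in segs} == {("a", 0, 100), ("b", 50, 150)}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 120),
                              st.sampled_from(["LINE", "LTR", "DNA", "Other"])),
                    min_size=1, max_size=12))
    def test_partition_matches_per_base_oracle(self, raw):
        feats = [feat(s, s + l, cls) for s, l, cls in raw]
        segs = merge_by_class(feats)
        length = max(f.end for f in feats)
        oracle = classes_per_base(feats, length)
        got = [None] * length
        for seg in segs:
            for b in range(seg.start, seg.end):
                assert got[b] is None, "segments overlap"
                got[b] = seg.canonical_class
        for b in range(length):
            if not oracle[b]:
                assert got[b] is None
            elif len(oracle[b]) == 1:
                assert got[b] == next(iter(oracle[b]))
            else:
                assert got[b] == "Overlapping"


class TestClassDensity:
    region = AnalysisRegion("r", [("chr", 0, 1000)])

    def test_simple_fraction(self):
        segs = merge_by_class([feat(100, 350)])
        rep = class_density(segs, self.region)
        assert rep.per_class["LINE"] == pytest.approx(0.25)
        assert rep.total == pytest.approx(0.25)

    def test_no_segments_zero(self):
        rep = class_density([], self.region)
        assert rep.per_class == {} and rep.total == 0

    def test_invariant_under_fragment_order_and_splitting(self):
        a = [feat(0, 100), feat(300, 500, "LTR")]
        b = [feat(300, 500, "LTR"), feat(0, 40), feat(40, 100)]
        da = class_density(merge_by_class(a), self.region).per_class
        db = class_density(merge_by_class(b), self.region).per_class
        assert da == db

    def test_planted_density_recovered(self, sim_region):
        cfg = sim_region.config
        region = AnalysisRegion("sim", [("sim_region", 0, cfg.region_length)])
        rep = class_density(merge_by_class(sim_region.visible_fragments), region)
        for cls, target in cfg.class_densities.items():
            assert rep.per_class[cls] == pytest.approx(target, abs=0.02)


class TestTopRepeatTable:
    def test_ranking_and_percentages(self):
        region = AnalysisRegion("r", [("chr", 0, 1000)])
        feats = [feat(0, 200, name="beta"), feat(300, 500, name="alpha"),
                 feat(600, 700, name="alpha")]
        df = top_repeat_table(feats, region, 10)
        assert list(df.repeat_name) == ["alpha", "beta"]
        assert list(df.total_size) == [300, 200]
        assert list(df.fragments) == [2, 1]
        assert df.pct_region.tolist() == pytest.approx([30.0, 20.0])
        assert df.pct_all_repeats.tolist() == pytest.approx([60.0, 40.0])

    def test_ties_break_lexicographically_and_n_capped(self):
        region = AnalysisRegion("r", [("chr", 0, 1000)])
        feats = [feat(0, 100, name="zz"), feat(200, 300, name="aa")]
        df = top_repeat_table(feats, region, 5)
        assert list(df.repeat_name) == ["aa", "zz"]

    def test_fragment_count_matches_planted_fragments(self, sim_region):
        cfg = sim_region.config
        region = AnalysisRegion("sim", [("sim_region", 0, cfg.region_length)])
        df = top_repeat_table(sim_region.visible_fragments, region, 100)
        by_name = {}
        for f in sim_region.visible_fragments:
            by_name[f.repeat_name] = by_name.get(f.repeat_name, 0) + 1
        for row in df.itertuples():
            assert row.fragments == by_name[row.repeat_name]


class TestScoreFilter:
    def test_cutoff(self):
        feats = [feat(0, 10, score=100), feat(20, 30, score=300)]
        assert [f.score for f in score_filter(feats, 255.6)] == [300]

    def test_minus_infinity_is_identity(self):
        feats = [feat(0, 10, score=1), feat(20, 30, score=2)]
        assert score_filter(feats, float("-inf")) == feats

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1000), min_size=0, max_size=20),
           st.floats(0, 1000), st.floats(0, 1000))
    def test_monotone_in_threshold(self, scores, s1, s2):
        lo, hi = min(s1, s2), max(s1, s2)
        feats = [feat(i * 10, i * 10 + 5, score=sc) for i, sc in enumerate(scores)]
        kept_lo = {id(f) for f in score_filter(feats, lo)}
        kept_hi = {id(f) for f in score_filter(feats, hi)}
        assert kept_hi <= kept_lo

    def test_planted_spurious_matches_removed(self):
        from domainscape.simulate import SimulationConfig, simulate_region
        sim = simulate_region(SimulationConfig(
            seed=9, region_length=30_000, gene_count=2,
            class_densities={"LINE": 0.2}, spurious_matches=5, spurious_score=50.0))
        kept = score_filter(sim.visible_fragments, 60.0)
        removed = [f for f in sim.visible_fragments if f not in kept]
        assert all(f.repeat_name == "SpuriousHit" for f in removed)
        assert len(removed) == 5


class TestOverlapAttribution:
    def test_half_overlap(self):
        res = overlap_attribution([feat(0, 100, name="q")], [feat(50, 150, name="a")])
        assert res.fraction == pytest.approx(0.5)

    def test_identical_sets_full_overlap(self):
        q = [feat(10, 60, name="q")]
        res = overlap_attribution(q, [feat(10, 60, name="x")])
        assert res.fraction == 1.0
        assert res.per_name.iloc[0].repeat_name == "x"

    def test_no_matches_is_explicit_status(self):
        res = overlap_attribution([], [feat(0, 10)])
        assert res.status == "no matches" and res.fraction is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 80)), min_size=1, max_size=8),
           st.lists(st.tuples(st.integers(0, 300), st.integers(1, 80),
                              st.sampled_from(["a", "b"])), min_size=0, max_size=8))
    def test_fraction_matches_boolean_mask_oracle(self, qs, anns):
        q = [feat(s, s + l, name="q") for s, l in qs]
        a = [feat(s, s + l, name=n) for s, l, n in anns]
        res = overlap_attribution(q, a)
        L = 400
        qm = np.zeros(L, bool)
        am = np.zeros(L, bool)
        for f in q:
            qm[f.start:f.end] = True
        for f in a:
            am[f.start:f.end] = True
        assert res.fraction == pytest.approx((qm & am).sum() / qm.sum())


class TestCoverageTrack:
    def test_two_interval_example(self):
        tracks = coverage_track([("t", 0, 10), ("t", 5, 15)], {"t": 20})
        dense = tracks["t"].to_dense(20)
        assert tracks["t"].max_coverage == 2
        assert list(dense[:5]) == [1] * 5 and list(dense[5:10]) == [2] * 5
        assert list(dense[10:15]) == [1] * 5 and list(dense[15:]) == [0] * 5

    def test_no_matches_all_zero(self):
        tracks = coverage_track([], {"t": 10})
        assert tracks["t"].max_coverage == 0
        assert not tracks["t"].to_dense(10).any()

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="exceeds declared length"):
            coverage_track([("t", 5, 25)], {"t": 20})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 190), st.integers(1, 60)),
                    min_size=0, max_size=15))
    def test_matches_per_base_counting_oracle(self, ivs):
        ivs = [(s, min(s + l, 200)) for s, l in ivs]
        tracks = coverage_track([("t", s, e) for s, e in ivs], {"t": 200})
        oracle = np.zeros(200, int)
        for s, e in ivs:
            oracle[s:e] += 1
        assert np.array_equal(tracks["t"].to_dense(200), oracle)
        assert tracks["t"].max_coverage == oracle.max()
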