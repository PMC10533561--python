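"""Star scoring: mAb IDs, replicate counting, formulas, census."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybseq import score


class TestMabId:
    @pytest.mark.parametrize("text,expected", [
        ("K89/34.1", ("K89", "34", "1")),
        ("L113/13.5", ("L113", "13", "5")),
        ("N468/37", ("N468", "37", None)),
    ])
    def test_parse(self, text, expected):
        mid = score.parse_mab_id(text)
        assert (mid.project, mid.parent, mid.subclone) == expected
        assert str(mid) == text

    @pytest.mark.parametrize("bad", ["K89-34", "K89", "a/b/c", ""])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            score.parse_mab_id(bad)


def _entry(mab_id, seq="AAA", chain="light", plate="P1", well="A1",
           rps=90, rppw=100):
    return score.ScoredEntry(
        mab_id=score.parse_mab_id(mab_id), plate=plate, well=well,
        chain=chain, trimmed_nt=seq, read_per_sequence=rps,
        reads_per_primer_well=rppw)


class TestCountReplicates:
    def test_three_subclones_one_sample_each(self):
        cohort = [_entry("K1/1.1", well="A1"), _entry("K1/1.2", well="A2"),
                  _entry("K1/1.3", well="A3")]
        br, tr, total = score.count_replicates(cohort[0], cohort)
        assert (br, tr, total) == (2, 0, 3)

    def test_sequence_unique_to_focal(self):
        cohort = [_entry("K1/1.1", seq="AAA", well="A1"),
                  _entry("K1/1.2", seq="CCC", well="A2"),
                  _entry("K1/1.3", seq="GGG", well="A3"),
                  _entry("K1/1.4", seq="TTT", well="A4")]
        assert score.count_replicates(cohort[0], cohort) == (0, 0, 4)

    def test_same_subclone_on_two_plates_is_technical(self):
        cohort = [_entry("K1/1.1", plate="P1", well="A1"),
                  _entry("K1/1.1", plate="P2", well="A1")]
        assert score.count_replicates(cohort[0], cohort) == (0, 1, 2)

    def test_other_parents_and_chains_ignored(self):
        cohort = [_entry("K1/1.1", well="A1"), _entry("K1/2.1", well="A2"),
                  _entry("K1/1.2", chain="heavy", well="A3")]
        assert score.count_replicates(cohort[0], cohort) == (0, 0, 1)


class TestFormulas:
    @pytest.mark.parametrize("rps,rppw,expected", [
        (450, 500, 0.9), (0, 500, 0.0), (500, 500, 1.0),
    ])
    def test_asv_score(self, rps, rppw, expected):
        assert score.asv_score(rps, rppw) == pytest.approx(expected)

    def test_asv_score_zero_denominator_warns(self):
        with pytest.warns(UserWarning):
            assert score.asv_score(0, 0) == 0.0

    @pytest.mark.parametrize("br,tr,total,expected", [
        (2, 1, 3, 2.75), (0, 0, 1, -1.0), (4, 0, 5, 3.8),
    ])
    def test_match_score(self, br, tr, total, expected):
        assert score.match_score(br, tr, total) == pytest.approx(expected)

    def test_match_score_requires_samples(self):
        with pytest.raises(ValueError):
            score.match_score(1, 1, 0)

    @pytest.mark.parametrize("ms,asv,expected", [
        (2.75, 0.9, 4.8),       # 3*ln(2.75) = 3.035 caps at 3
        (-1.0, 0.5, 1.0),       # non-positive match -> component 0
        (math.e, 1.0, 5.0),     # both components at cap
        (1.0, 0.0, 0.0),
    ])
    def test_total_score(self, ms, asv, expected):
        assert score.total_score(ms, asv) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("s,kept", [(2.99, False), (3.0, True), (4.8, True)])
    def test_quality_filter_boundary(self, s, kept):
        e = _entry("K1/1.1")
        e.total_score = s
        assert (e in score.quality_filter([e])) is kept


class TestScoreProperties:
    @given(br=st.integers(0, 10), tr=st.integers(0, 10),
           total=st.integers(1, 20),
           asv=st.floats(0, 1, allow_nan=False))
    @settings(max_examples=200, deadline=None, database=None)
    def test_total_score_bounded(self, br, tr, total, asv):
        ms = score.match_score(br, tr, total)
        t = score.total_score(ms, asv)
        assert 0.0 <= t <= 5.0
        assert 0.0 <= score.match_component(ms) <= 3.0

    @given(br=st.integers(0, 9), tr=st.integers(0, 9), total=st.integers(1, 20),
           asv=st.floats(0, 0.9, allow_nan=False))
    @settings(max_examples=200, deadline=None, database=None)
    def test_monotonic_in_br_tr_and_fraction(self, br, tr, total, asv):
        base = score.total_score(score.match_score(br, tr, total), asv)
        assert score.total_score(score.match_score(br + 1, tr, total), asv) >= base
        assert score.total_score(score.match_score(br, tr + 1, total), asv) >= base
        assert score.total_score(score.match_score(br, tr, total), asv + 0.1) >= base


class TestMultiplicityAndCensus:
    def _group(self, counts):
        entries = []
        for i, n in enumerate(counts):
            for j in range(n):
                entries.append(_entry(f"K1/1.{i + 1}", seq=f"SEQ{j}",
                                      well=f"A{i + 1}"))
        return entries

    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 2], 1),   # mean 1.33
        ([2, 2, 2], 2),
        ([1, 2], 2),      # mean 1.5 rounds away from zero
    ])
    def test_chain_multiplicity(self, counts, expected):
        assert score.chain_multiplicity(self._group(counts), "light") == expected

    def test_empty_group(self):
        assert score.chain_multiplicity([], "light") == 0

    def test_census_extra_vl(self):
        df = pd.DataFrame({
            "mab_id": [f"K1/{i}" for i in range(10)],
            "n_vl": [2] + [1] * 9, "n_vh": [1] * 10,
        })
        out = score.summarize_cohort(df).set_index("category")
        assert out.loc["one_additional_vl_only", "count"] == 1
        assert out.loc["one_additional_vl_only", "percent"] == 10.0

    def test_census_all_single_pairs(self):
        df = pd.DataFrame({"mab_id": ["A/1", "A/2"], "n_vl": 1, "n_vh": 1})
        out = score.summarize_cohort(df).set_index("category")
        assert out.loc["no_additional_chain", "percent"] == 100.0

    def test_census_partitions_cohort(self):
        df = pd.DataFrame({
            "mab_id": [f"P/{i}" for i in range(8)],
            "n_vl": [0, 1, 1, 2, 2, 1, 3, 1],
            "n_vh": [1, 0, 1, 1, 2, 2, 1, 1],
        })
        out = score.summarize_cohort(df).set_index("category")
        assert (out.loc["vl_or_vh_zero", "count"]
                + out.loc["both_present", "count"]) == len(df)

    def test_census_stratified(self):
        df = pd.DataFrame({
            "mab_id": ["A/1", "A/2", "B/1", "B/2"],
            "n_vl": [1, 2, 1, 1], "n_vh": [1, 1, 1, 1],
            "fusion": ["chemical", "chemical", "electro", "electro"],
        })
        out = score.summarize_cohort(df, stratify="fusion").set_index("category")
        assert out.loc["one_additional_vl_only", "count_chemical"] == 1
        assert out.loc["one_additional_vl_only", "percent_electro"] == 0.0
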