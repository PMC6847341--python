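"""Pileup grammar resolution and mpileup file parsing."""

import io
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m7gmap.pileup_io import (
    DELETION,
    INSERTION,
    MATCH,
    SUBSTITUTION,
    PileupParseError,
    parse_mpileup,
    tokenize_bases,
    tokenize_to_arrays,
)


def kinds_of(bases, quals, ref):
    return [o.kind for o in tokenize_bases(bases, quals, ref)]


class TestTokenizer:
    @pytest.mark.parametrize(
        "bases,quals,ref,expected",
        [
            ("..A", "III", "G", [MATCH, MATCH, SUBSTITUTION]),
            ("^].+2AG,", "II", "G", [INSERTION, MATCH]),
            (".*>,", "IIII", "G", [MATCH, DELETION, MATCH]),
            (",$", "I", "G", [MATCH]),
            (".-2nn,", "II", "G", [MATCH, MATCH]),
            ("*-2nn,", "II", "G", [DELETION, MATCH]),
            ("Gg..", "IIII", "G", [MATCH, MATCH, MATCH, MATCH]),
            ("**#", "III", "G", [DELETION, DELETION, DELETION]),
            ("N.n", "III", "G", [MATCH]),
            ("><", "II", "G", []),
            ("aA", "II", "G", [SUBSTITUTION, SUBSTITUTION]),
        ],
    )
    def test_grammar_cases(self, bases, quals, ref, expected):
        assert kinds_of(bases, quals, ref) == expected

    def test_phred_error_probability_attached(self):
        obs = tokenize_bases("..A", "III", "G")
        assert all(o.error_prob == pytest.approx(1e-4) for o in obs)

    def test_strand_assignment(self):
        obs = tokenize_bases(".,aA", "IIII", "G")
        assert [o.reverse_strand for o in obs] == [False, True, True, False]

    def test_observed_bases(self):
        obs = tokenize_bases(".Ta*", "IIII", "G")
        assert [o.observed_base for o in obs] == ["G", "T", "A", "*"]

    def test_insertion_upgrades_anchor_only(self):
        obs = tokenize_bases(".+1A.", "II", "G")
        assert [o.kind for o in obs] == [INSERTION, MATCH]

    def test_dangling_indel_raises(self):
        with pytest.raises(PileupParseError):
            tokenize_bases("+2AG.", "I", "G")

    def test_quality_too_short_raises(self):
        with pytest.raises(PileupParseError):
            tokenize_bases("...", "II", "G")

    def test_quality_too_long_raises(self):
        with pytest.raises(PileupParseError):
            tokenize_bases("..", "III", "G")

    def test_unexpected_character_raises(self):
        with pytest.raises(PileupParseError):
            tokenize_bases(".!.", "III", "G")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.sampled_from(list(".,ACGTacgt*")), min_size=0, max_size=40),
        st.sampled_from(list("ACGT")),
    )
    def test_case_symmetry(self, chars, ref):
        """Flipping case (and ./,) changes strand but never the kind counts."""
        bases = "".join(chars)
        flip = bases.swapcase().replace(".", "\0").replace(",", ".").replace("\0", ",")
        quals = "I" * len([c for c in bases])
        k1 = sorted(kinds_of(bases, quals, ref))
        k2 = sorted(kinds_of(flip, quals, ref))
        assert k1 == k2

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from(list(".,ACGTacgt*><Nn")), max_size=50))
    def test_observation_count_bounded_by_depth(self, chars):
        bases = "".join(chars)
        kinds, _, _, _ = tokenize_to_arrays(bases, "I" * len(chars), "G")
        assert len(kinds) <= len(chars)
        if all(c not in "><Nn" for c in chars):
            assert len(kinds) == len(chars)

    def test_fast_and_scan_paths_agree(self):
        # '$' forces the scanning path without changing the observations
        bases = ".,AcG*t,."
        quals = "IIIIIIIII"
        fast = tokenize_to_arrays(bases, quals, "G")
        slow = tokenize_to_arrays(bases + "$", quals, "G")
        for a, b in zip(fast, slow):
            assert np.array_equal(a, b)


class TestParseMpileup:
    def test_single_sample_line(self):
        line = "SSU\t527\tG\t5\t..AA,\tIIIII\n"
        (site,) = parse_mpileup(io.StringIO(line))
        assert site.reference_name == "SSU"
        assert site.position == 527
        assert site.reference_base == "G"
        assert site.samples[0].reported_depth == 5
        assert site.samples[0].base_string == "..AA,"
        kinds = [o.kind for o in site.sample_observations(0)]
        assert kinds == [MATCH, MATCH, SUBSTITUTION, SUBSTITUTION, MATCH]

    def test_zero_depth_column(self):
        line = "ref\t10\tG\t3\t...\tIII\t0\t*\t*\n"
        (site,) = parse_mpileup(io.StringIO(line), n_samples=2)
        assert site.samples[1].reported_depth == 0
        assert site.sample_observations(1) == []

    def test_wrong_field_count_names_line(self):
        text = "ref\t1\tG\t1\t.\tI\nref\t2\tG\t1\t.\n"
        with pytest.raises(PileupParseError, match="line 2"):
            list(parse_mpileup(io.StringIO(text), n_samples=1))

    def test_non_monotone_position_warns(self):
        text = "ref\t5\tG\t1\t.\tI\nref\t4\tG\t1\t.\tI\n"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sites = list(parse_mpileup(io.StringIO(text), n_samples=1))
        assert len(sites) == 2
        assert any("non-monotone" in str(w.message) for w in caught)

    def test_sample_count_inference(self):
        text = "ref\t1\tG\t1\t.\tI\t2\t..\tII\n"
        (site,) = parse_mpileup(io.StringIO(text))
        assert len(site.samples) == 2


class TestSamtoolsOracle:
    def test_parser_matches_samtools_counts(self, samtools_pileup):
        """Counts parsed from real samtools output equal the alignment truth."""
        text, truth = samtools_pileup
        seen = {}
        for site in parse_mpileup(io.StringIO(text), n_samples=1):
            obs = site.sample_observations(0)
            seen[site.position] = {
                "match": sum(o.kind == MATCH for o in obs),
                "sub": sum(o.kind == SUBSTITUTION for o in obs),
                "ins": sum(o.kind == INSERTION for o in obs),
                "del": sum(o.kind == DELETION for o in obs),
            }
        assert seen == truth
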