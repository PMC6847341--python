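"""Per-position analysis, filters, candidate calling and table output."""

import io
import math

import pytest

from m7gmap.calling import (
    CallingThresholds,
    FLAG_HIGH_CONTROL_RATE,
    FLAG_LOW_DEPTH,
    FLAG_REPLICATE_INCONSISTENT,
    FLAG_UNTESTABLE,
    SampleDesign,
    SiteResult,
    analyze_position,
    apply_filters,
    call_candidates,
    is_called,
    run_calling,
    write_bed6,
    write_results_tsv,
)
from m7gmap.pileup_io import PileupSite, SampleColumn


def make_site(sample_strings, position=100, ref="G"):
    samples = [
        SampleColumn(len(q), b, q) if q else SampleColumn(0, "*", "*")
        for b, q in sample_strings
    ]
    return PileupSite("ref", position, ref, samples)


def make_result(**overrides):
    base = dict(
        reference_name="ref",
        position=50,
        reference_base="G",
        depth_treated=2000,
        depth_control=2000,
        f_treated=0.05,
        f_control=0.001,
        delta=0.049,
        p_between=1e-80,
        neg10log10_p=800.0,
        p_within_treated=0.5,
        p_within_control=0.5,
        control_rate_mean=0.001,
    )
    base.update(overrides)
    return SiteResult(**base)


class TestAnalyzePosition:
    def test_clear_signal(self):
        treated = ("." * 90 + "A" * 10, "I" * 100)
        control = ("." * 100, "I" * 100)
        site = make_site([treated, control])
        res = analyze_position(site, SampleDesign((0,), (1,)))
        assert res.delta == pytest.approx(0.10, abs=0.01)
        # closed-form binomial LRT oracle: stat 14.39, p = 1.50e-4
        assert res.p_between == pytest.approx(1.502e-4, rel=0.01)
        assert not res.filter_flags

    def test_identical_strings_give_null(self):
        col = ("." * 50 + "A", "I" * 51)
        site = make_site([col, col])
        res = analyze_position(site, SampleDesign((0,), (1,)))
        assert res.delta == pytest.approx(0.0, abs=1e-9)
        assert res.p_between == pytest.approx(1.0)

    def test_zero_depth_condition_untestable(self):
        site = make_site([("." * 10, "I" * 10), ("", "")])
        res = analyze_position(site, SampleDesign((0,), (1,)))
        assert FLAG_UNTESTABLE in res.filter_flags
        assert math.isnan(res.p_between)

    def test_within_p_values_need_replicates(self):
        cols = [("." * 20, "I" * 20)] * 4
        site = make_site(cols)
        res = analyze_position(site, SampleDesign((0, 1), (2, 3)))
        assert not math.isnan(res.p_within_treated)
        res1 = analyze_position(site, SampleDesign((0,), (1,)))
        assert math.isnan(res1.p_within_treated)


class TestFilters:
    @pytest.mark.parametrize(
        "dt,dc,flagged",
        [(700, 799, True), (750, 750, True), (750, 751, False), (2000, 2000, False)],
    )
    def test_depth_filter_is_strict(self, dt, dc, flagged):
        """Combined depth must strictly exceed 1500 to pass."""
        (res,) = apply_filters([make_result(depth_treated=dt, depth_control=dc)])
        assert (FLAG_LOW_DEPTH in res.filter_flags) is flagged

    @pytest.mark.parametrize("rate,flagged", [(0.012, True), (0.01, True), (0.0099, False)])
    def test_control_rate_filter(self, rate, flagged):
        (res,) = apply_filters([make_result(control_rate_mean=rate)])
        assert (FLAG_HIGH_CONTROL_RATE in res.filter_flags) is flagged

    @pytest.mark.parametrize("p,flagged", [(1e-6, True), (1e-5, False), (0.2, False)])
    def test_replicate_consistency_filter(self, p, flagged):
        (res,) = apply_filters([make_result(p_within_control=p)])
        assert (FLAG_REPLICATE_INCONSISTENT in res.filter_flags) is flagged

    def test_single_replicate_mode_uses_lower_depth(self):
        (res,) = apply_filters(
            [make_result(depth_treated=300, depth_control=300)], single_replicate=True
        )
        assert FLAG_LOW_DEPTH not in res.filter_flags

    def test_flags_are_independent(self):
        (res,) = apply_filters(
            [make_result(depth_treated=100, depth_control=100, control_rate_mean=0.05,
                         p_within_treated=1e-9)]
        )
        assert res.filter_flags == {
            FLAG_LOW_DEPTH,
            FLAG_HIGH_CONTROL_RATE,
            FLAG_REPLICATE_INCONSISTENT,
        }


class TestCalling:
    @pytest.mark.parametrize(
        "delta,p,called",
        [
            (0.006, 1e-60, True),
            (0.006, 1e-10, False),
            (0.004, 1e-200, False),
            (0.005, 1e-60, True),  # delta cutoff is inclusive
        ],
    )
    def test_thresholds(self, delta, p, called):
        res = make_result(delta=delta, p_between=p)
        assert is_called(res) is called

    def test_flagged_positions_never_called(self):
        res = make_result()
        res.filter_flags.add(FLAG_LOW_DEPTH)
        assert call_candidates([res]) == []

    def test_g_restriction_default_and_override(self):
        res = make_result(reference_base="A")
        assert not is_called(res)
        assert is_called(res, CallingThresholds(g_only=False))


class TestPipeline:
    PILEUP = (
        "ref\t1\tG\t4\t....\tIIII\t4\t....\tIIII\n"
        "ref\t2\tA\t4\t..TT\tIIII\t4\t....\tIIII\n"
        "ref\t3\tG\t0\t*\t*\t4\t....\tIIII\n"
    )

    def test_run_calling_output_shape(self):
        frame = run_calling(io.StringIO(self.PILEUP), SampleDesign((0,), (1,)))
        assert list(frame["position"]) == [1, 2, 3]
        assert frame.loc[2, "filters"].startswith("low_depth") or "untestable" in frame.loc[2, "filters"]

    def test_determinism_byte_identical(self):
        outs = []
        for _ in range(2):
            frame = run_calling(io.StringIO(self.PILEUP), SampleDesign((0,), (1,)))
            buf = io.StringIO()
            write_results_tsv(frame, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_bed_export_is_zero_based_half_open(self):
        frame = run_calling(io.StringIO(self.PILEUP), SampleDesign((0,), (1,)))
        frame.loc[0, "called"] = True
        buf = io.StringIO()
        write_bed6(frame, buf)
        fields = buf.getvalue().strip().split("\t")
        assert (fields[1], fields[2]) == ("0", "1")

    def test_one_based_design_helper(self):
        d = SampleDesign.from_one_based([1, 2], [3])
        assert d.treated == (0, 1)
        assert d.control == (2,)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SampleDesign((), (0,))
        with pytest.raises(ValueError):
            SampleDesign((0,), (0,))
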