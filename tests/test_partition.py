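"""Channel ratios, redox-state partitioning, uncertainty and flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import redoxquant as rq
from redoxquant.flags import Flag, IncompleteChannelsError, RedoxQuantError

DESIGN4 = rq.read_channel_design("itraq4")

areas = st.floats(min_value=1e-3, max_value=1e9, allow_nan=False, allow_infinity=False)
ratios01 = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)


def record_from_areas(ct, tt, cr, tr, errors=None, sequence="ACDK"):
    areas_map = {"114": ct, "116": tt, "118": cr, "121": tr}
    return rq.PeptideQuant("P", sequence, channel_areas=areas_map,
                           channel_area_errors=errors or {})


class TestComputeChannelRatios:
    def test_worked_division_example(self, design4):
        rec = record_from_areas(500.0, 239.0, 233.5, 129.0)
        rs = rq.compute_channel_ratios(rec, design4)
        assert (rs.r_total_test, rs.r_revox_control, rs.r_revox_test) == \
            pytest.approx((0.478, 0.467, 0.258))

    def test_equal_areas_give_unit_ratios(self, design4):
        rs = rq.compute_channel_ratios(record_from_areas(42.0, 42.0, 42.0, 42.0), design4)
        assert (rs.r_total_test, rs.r_revox_control, rs.r_revox_test) == (1.0, 1.0, 1.0)

    @given(ct=areas, tt=areas, cr=areas, tr=areas)
    @settings(max_examples=100, deadline=None)
    def test_ratios_match_elementwise_division(self, ct, tt, cr, tr):
        rs = rq.compute_channel_ratios(record_from_areas(ct, tt, cr, tr), DESIGN4)
        assert rs.r_total_test == pytest.approx(tt / ct, rel=1e-12)
        assert rs.r_revox_control == pytest.approx(cr / ct, rel=1e-12)
        assert rs.r_revox_test == pytest.approx(tr / ct, rel=1e-12)

    def test_area_errors_propagate_to_ratio_sds(self, design4):
        rec = record_from_areas(
            1000.0, 478.0, 467.0, 258.0,
            errors={"114": 0.0, "116": 143.0, "118": 180.0, "121": 195.0})
        rs = rq.compute_channel_ratios(rec, design4)
        assert rs.sd_total_test == pytest.approx(0.143, abs=1e-12)
        assert rs.sd_revox_control == pytest.approx(0.180, abs=1e-12)
        assert rs.sd_revox_test == pytest.approx(0.195, abs=1e-12)
        assert Flag.NO_ERROR_ESTIMATE not in rs.flags

    def test_no_error_columns_flagged(self, design4):
        rs = rq.compute_channel_ratios(record_from_areas(10.0, 10.0, 10.0, 10.0), design4)
        assert Flag.NO_ERROR_ESTIMATE in rs.flags
        assert rs.sd_total_test == 0.0

    def test_zero_reference_refuses_division(self, design4):
        with pytest.raises(IncompleteChannelsError):
            rq.compute_channel_ratios(record_from_areas(0.0, 1.0, 1.0, 1.0), design4)

    def test_missing_channel_refuses_division(self, design4):
        rec = rq.PeptideQuant("P", "ACDK", channel_areas={"114": 10.0, "116": 5.0})
        with pytest.raises(IncompleteChannelsError):
            rq.compute_channel_ratios(rec, design4)


class TestPartitionControl:
    def test_half_oxidized_worked_example(self):
        state = rq.partition_control(rq.RatioSet(0.478, 0.467, 0.258))
        assert state.revox == pytest.approx(0.467)
        assert state.free == pytest.approx(0.533)
        assert state.overox is None

    def test_fully_reduced_limit(self):
        state = rq.partition_control(rq.RatioSet(1.0, 0.0, 0.0))
        assert (state.revox, state.free) == (0.0, 1.0)

    def test_over_unity_ratio_goes_negative_and_is_flagged(self):
        state = rq.partition_control(rq.RatioSet(0.91, 1.17, 0.91))
        assert state.revox == pytest.approx(1.17)
        assert state.free == pytest.approx(-0.17)
        assert Flag.OVER_UNITY_RATIO in state.flags


class TestPartitionTest:
    def test_strong_oxidation_worked_example(self):
        state = rq.partition_test(rq.RatioSet(0.478, 0.467, 0.258))
        assert state.revox == pytest.approx(0.258)
        assert state.free == pytest.approx(0.220)
        assert state.overox == pytest.approx(0.522)
        assert not state.flags

    def test_unoxidized_test_sample(self):
        state = rq.partition_test(rq.RatioSet(1.0, 0.0, 0.0))
        assert (state.revox, state.free, state.overox) == (0.0, 1.0, 0.0)

    def test_negative_free_reported_unclamped_and_flagged(self):
        state = rq.partition_test(rq.RatioSet(0.245, 0.95, 0.300))
        assert state.revox == pytest.approx(0.300)
        assert state.free == pytest.approx(-0.055)
        assert state.overox == pytest.approx(0.755)
        assert Flag.NEGATIVE_FREE in state.flags


class TestPartitionProperties:
    @given(r_tt=ratios01, r_rc=ratios01, r_rt=ratios01)
    @settings(max_examples=200, deadline=None)
    def test_fractions_sum_to_one_for_all_inputs(self, r_tt, r_rc, r_rt):
        rs = rq.RatioSet(r_tt, r_rc, r_rt)
        control = rq.partition_control(rs)
        test = rq.partition_test(rs)
        assert abs(control.revox + control.free - 1.0) <= 1e-12
        assert abs(test.revox + test.free + test.overox - 1.0) <= 1e-12

    @given(ct=areas, tt=areas, cr=areas, tr=areas,
           scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_of_fractions(self, ct, tt, cr, tr, scale):
        def fractions(factor):
            rec = record_from_areas(ct * factor, tt * factor, cr * factor, tr * factor)
            rs = rq.compute_channel_ratios(rec, DESIGN4)
            c, t = rq.partition_control(rs), rq.partition_test(rs)
            return (c.revox, c.free, t.revox, t.free, t.overox)

        assert fractions(scale) == pytest.approx(fractions(1.0), rel=1e-9)

    @given(r_rt=st.floats(0.0, 1.0), r_tt=st.floats(0.01, 2.0),
           bump=st.floats(1e-6, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_total_ratio_monotonicity(self, r_rt, r_tt, bump):
        lo = rq.partition_test(rq.RatioSet(r_tt, 0.5, r_rt))
        hi = rq.partition_test(rq.RatioSet(r_tt + bump, 0.5, r_rt))
        assert hi.overox < lo.overox
        assert hi.free > lo.free


class TestUncertainty:
    def test_difference_sd_combines_in_quadrature(self):
        sds = rq.propagate_uncertainty(
            rq.RatioSet(0.478, 0.467, 0.258, sd_total_test=0.143,
                        sd_revox_control=0.18, sd_revox_test=0.195))
        assert sds["test_free"] == pytest.approx(0.2418, abs=5e-5)
        assert sds["test_revox"] == 0.195
        assert sds["test_overox"] == 0.143

    def test_zero_in_zero_out(self):
        sds = rq.propagate_uncertainty(rq.RatioSet(0.5, 0.5, 0.5))
        assert all(v == 0.0 for v in sds.values())

    def test_control_free_sd_is_linear_passthrough(self):
        sds = rq.propagate_uncertainty(rq.RatioSet(0.5, 0.5, 0.5, sd_revox_control=0.18))
        assert sds["control_free"] == 0.18

    @pytest.mark.parametrize("sd_tt,sd_rt", [(0.143, 0.195), (0.05, 0.3), (0.25, 0.01)])
    def test_agrees_with_monte_carlo_oracle(self, sd_tt, sd_rt):
        rng = np.random.default_rng(20120715)
        n = 100_000
        tt = 0.478 + sd_tt * rng.standard_normal(n)
        rt = 0.258 + sd_rt * rng.standard_normal(n)
        empirical = float(np.std(tt - rt, ddof=1))
        sds = rq.propagate_uncertainty(
            rq.RatioSet(0.478, 0.467, 0.258, sd_total_test=sd_tt, sd_revox_test=sd_rt))
        assert sds["test_free"] == pytest.approx(empirical, rel=0.02)


class TestAggregateReplicates:
    def test_two_point_mean_and_sample_sd(self):
        agg = rq.aggregate_replicates(
            [rq.RatioSet(0.4, 0.4, 0.4), rq.RatioSet(0.6, 0.6, 0.6)])
        assert agg.r_total_test == pytest.approx(0.5)
        assert agg.sd_total_test == pytest.approx(0.1414, abs=5e-5)
        assert agg.n_replicates == 2

    def test_single_group_passes_through(self):
        single = rq.RatioSet(0.478, 0.467, 0.258, sd_total_test=0.143)
        agg = rq.aggregate_replicates([single])
        assert agg.r_total_test == single.r_total_test
        assert agg.sd_total_test == single.sd_total_test
        assert agg.n_replicates == 1

    def test_empty_list_rejected(self):
        with pytest.raises(RedoxQuantError):
            rq.aggregate_replicates([])

    def test_matches_streaming_statistics_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0.1, 1.5, size=5)
        groups = [rq.RatioSet(v, v, v) for v in values]
        # Welford's online mean/variance as an independent oracle
        mean, m2 = 0.0, 0.0
        for k, v in enumerate(values, start=1):
            delta = v - mean
            mean += delta / k
            m2 += delta * (v - mean)
        sd = math.sqrt(m2 / (len(values) - 1))
        agg = rq.aggregate_replicates(groups)
        assert agg.r_total_test == pytest.approx(mean, rel=1e-12)
        assert agg.sd_total_test == pytest.approx(sd, rel=1e-12)


class TestFlags:
    def test_two_cysteines_flag_ambiguous(self):
        rec = rq.PeptideQuant("P", "CCSDVFNQVVK")
        assert Flag.MULTI_CYS_AMBIGUOUS in rq.flag_peptide(rec)

    def test_single_cysteine_not_flagged(self):
        rec = rq.PeptideQuant("P", "YSGVCHTDLHAWHGDWPLPTK")
        assert Flag.MULTI_CYS_AMBIGUOUS not in rq.flag_peptide(rec)

    def test_partition_flags_are_merged(self):
        rec = rq.PeptideQuant("P", "ACDK")
        state = rq.partition_test(rq.RatioSet(0.245, 0.95, 0.300))
        assert Flag.NEGATIVE_FREE in rq.flag_peptide(rec, state)

    def test_flags_do_not_alter_numbers(self, design4):
        rec = record_from_areas(1000.0, 245.0, 950.0, 300.0, sequence="CCSDVFNQVVK")
        row = rq.quantify_peptide(rec, design4)
        assert Flag.MULTI_CYS_AMBIGUOUS in row.flags
        assert Flag.NEGATIVE_FREE in row.flags
        assert row.test_free_pct == pytest.approx(-5.5)


class TestQuantifyPipeline:
    def test_published_table_row_reproduced_to_integer_percent(self, design4, adh_records_5mm):
        rows = rq.quantify(adh_records_5mm, design4)
        row = next(r for r in rows if r.start_pos == 40)
        rounded = [rq.round_half_away(v) for v in (
            row.control_revox_pct, row.control_free_pct,
            row.test_revox_pct, row.test_free_pct, row.test_overox_pct)]
        assert rounded == [47, 53, 26, 22, 52]

    def test_incomplete_record_row_is_flagged_not_dropped(self, design4):
        rec = rq.PeptideQuant("P", "ACDK", channel_areas={"114": 10.0})
        rows = rq.quantify([rec], design4, min_confidence=0.0)
        assert len(rows) == 1
        assert Flag.INCOMPLETE_CHANNELS in rows[0].flags
        assert rows[0].n_replicates == 0
        assert math.isnan(rows[0].test_revox_pct)

    def test_clamp_truncates_display_but_keeps_flags(self, design4):
        rec = record_from_areas(1000.0, 245.0, 950.0, 300.0)
        clamped = rq.quantify_peptide(rec, design4, clamp=True)
        assert clamped.test_free_pct == 0.0
        assert Flag.NEGATIVE_FREE in clamped.flags

    def test_duplex_design_aggregates_two_groups(self, design8):
        areas = {"114": 1000.0, "116": 400.0, "118": 450.0, "121": 250.0,
                 "113": 2000.0, "115": 1000.0, "117": 950.0, "119": 550.0}
        rec = rq.PeptideQuant("P", "ACDK", channel_areas=areas)
        row = rq.quantify_peptide(rec, design8)
        assert row.n_replicates == 2
        assert row.test_revox_pct == pytest.approx(100 * (0.25 + 0.275) / 2)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (0.5, 1.0), (-5.5, -6.0), (2.4, 2.0), (-2.4, -2.0), (46.7, 47.0), (52.2, 52.0)])
    def test_ties_round_away_from_zero(self, x, expected):
        assert rq.round_half_away(x) == expected
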