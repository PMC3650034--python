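"""The two-stage FNT/RPT calling decision and its aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amds.assay_model import FluorescenceTrace, MutationTarget, ThresholdSet, WellAssay
from amds.genotyper import (
    CallReason,
    CallStatus,
    ChannelCall,
    GenotypingError,
    MutationStatus,
    OverallStatus,
    call_channel,
    call_chip,
    call_well,
    compute_sr,
)
from conftest import make_trace


def flat_ep_trace(f_jp, f_ep, ep=600.0, jp=300.0):
    """Piecewise-linear corrected trace hitting F(JP) and F(EP) exactly."""
    return FluorescenceTrace(
        1, "F1", np.array([0.0, jp, ep]), np.array([0.0, f_jp, f_ep]), True
    )


def make_test_well(gene="KRAS", change="G13D", well_id=1):
    return WellAssay(
        well_id=well_id,
        target=MutationTarget(gene, change),
        channel_allele_map={"F1": "mutant", "F2": "wild_type"},
    )


def channel_call(status, reason, well_id=1, channel="F1", sr=None, f_ep=500.0):
    return ChannelCall(well_id, channel, f_ep, 400.0, sr, status, reason)


POS = lambda well_id=1, ch="F1": channel_call(CallStatus.POSITIVE, CallReason.SR_ABOVE_RPT, well_id, ch, sr=0.9)
NEG_RATIO = lambda well_id=1, ch="F1": channel_call(CallStatus.NEGATIVE, CallReason.SR_BELOW_RPT, well_id, ch, sr=0.4)
NEG_FNT = lambda well_id=1, ch="F1": channel_call(CallStatus.NEGATIVE, CallReason.BELOW_FNT, well_id, ch, f_ep=10.0)


class TestComputeSR:
    def test_direct_ratio(self, thresholds):
        assert compute_sr(flat_ep_trace(80.0, 100.0), thresholds) == pytest.approx(0.8)

    def test_plateau_before_judging_point_gives_unity(self, thresholds):
        t = np.arange(0.0, 601.0)
        vals = np.where(t < 100, 5.0 * t, 500.0)
        vals -= vals[0]
        tr = make_trace(vals, times=t, corrected=True)
        assert compute_sr(tr, thresholds) == pytest.approx(1.0)

    def test_saturating_beats_linear_drift_at_equal_endpoint(
        self, thresholds, saturating_trace, drifting_trace
    ):
        # both shapes end near 500/300 units; the reaction reaches most of its
        # endpoint signal by JP, the drift only half
        sr_sat = compute_sr(saturating_trace, thresholds)
        sr_lin = compute_sr(drifting_trace, thresholds)
        assert sr_sat > sr_lin
        assert sr_lin == pytest.approx(0.5, abs=1e-6)

    def test_degenerate_endpoint_rejected(self, thresholds):
        with pytest.raises(GenotypingError, match="degenerate"):
            compute_sr(flat_ep_trace(0.0, 0.0), thresholds)

    def test_requires_baseline_correction(self, thresholds):
        with pytest.raises(GenotypingError, match="baseline-corrected"):
            compute_sr(make_trace([50.0, 60.0], times=[0.0, 600.0]), thresholds)

    def test_alternative_definition_inverts_ordering(self, thresholds, saturating_trace, drifting_trace):
        alt_sat = compute_sr(saturating_trace, thresholds, definition="rise_over_jp")
        alt_lin = compute_sr(drifting_trace, thresholds, definition="rise_over_jp")
        assert alt_sat < alt_lin  # late-phase rise is small for a saturated reaction


class TestCallChannel:
    """Decision-chart cases: A/B positive, C ratio-negative, D below threshold."""

    def test_sample_d_below_fnt_is_negative(self, thresholds):
        call = call_channel(flat_ep_trace(8.0, 10.0), thresholds)
        assert call.status is CallStatus.NEGATIVE
        assert call.reason is CallReason.BELOW_FNT
        assert call.sr is None

    def test_samples_a_b_high_ratio_positive(self, thresholds):
        call = call_channel(flat_ep_trace(450.0, 500.0), thresholds)  # SR = 0.9
        assert call.status is CallStatus.POSITIVE
        assert call.reason is CallReason.SR_ABOVE_RPT
        assert call.sr == pytest.approx(0.9)

    def test_sample_c_low_ratio_negative(self, thresholds):
        call = call_channel(flat_ep_trace(250.0, 500.0), thresholds)  # SR = 0.5
        assert call.status is CallStatus.NEGATIVE
        assert call.reason is CallReason.SR_BELOW_RPT

    def test_endpoint_equal_to_fnt_proceeds_to_ratio_stage(self, thresholds):
        call = call_channel(flat_ep_trace(90.0, 100.0), thresholds)  # F(EP) == FNT
        assert call.reason is not CallReason.BELOW_FNT
        assert call.sr == pytest.approx(0.9)

    def test_sr_equal_to_rpt_is_negative(self, thresholds):
        call = call_channel(flat_ep_trace(300.0, 500.0), thresholds)  # SR == RPT == 0.6
        assert call.status is CallStatus.NEGATIVE

    def test_trace_must_span_decision_times(self, thresholds):
        short = make_trace([0.0, 50.0], times=[0.0, 400.0], corrected=True)
        with pytest.raises(GenotypingError, match="does not span"):
            call_channel(short, thresholds)

    @given(st.floats(0.1, 1000.0))
    def test_scale_invariance_of_the_ratio(self, scale):
        # scaling a trace scales F(JP) and F(EP) together; SR and the call
        # at fixed RPT are unchanged (as long as FNT stays crossed)
        thresholds = ThresholdSet(FNT=1e-6, RPT=0.6)
        base = flat_ep_trace(450.0, 500.0)
        scaled = FluorescenceTrace(1, "F1", base.times, base.values * scale, True)
        assert compute_sr(scaled, thresholds) == pytest.approx(0.9)
        assert call_channel(scaled, thresholds).status is CallStatus.POSITIVE

    @pytest.mark.parametrize("f_jp,f_ep", [(450.0, 500.0), (250.0, 500.0), (8.0, 10.0)])
    def test_raising_thresholds_never_creates_positives(self, f_jp, f_ep):
        tr = flat_ep_trace(f_jp, f_ep)
        lo = call_channel(tr, ThresholdSet(FNT=50.0, RPT=0.4))
        for fnt, rpt in [(50.0, 0.7), (200.0, 0.4), (600.0, 0.95)]:
            hi = call_channel(tr, ThresholdSet(FNT=fnt, RPT=rpt))
            if lo.status is CallStatus.NEGATIVE:
                assert hi.status is CallStatus.NEGATIVE


class TestCallWell:
    def test_mutant_positive_wins(self):
        wc = call_well(make_test_well(), POS(), POS(ch="F2"))
        assert wc.mutation_status is MutationStatus.POSITIVE

    def test_mutant_negative_wildtype_positive_is_negative(self):
        wc = call_well(make_test_well(), NEG_FNT(), POS(ch="F2"))
        assert wc.mutation_status is MutationStatus.NEGATIVE

    def test_both_below_fnt_is_invalid(self):
        wc = call_well(make_test_well(), NEG_FNT(), NEG_FNT(ch="F2"))
        assert wc.mutation_status is MutationStatus.INVALID

    def test_gating_disabled_reports_negative(self):
        wc = call_well(make_test_well(), NEG_FNT(), NEG_FNT(ch="F2"), validity_gating=False)
        assert wc.mutation_status is MutationStatus.NEGATIVE

    def test_mismatched_wells_rejected(self):
        with pytest.raises(GenotypingError, match="different wells"):
            call_well(make_test_well(), POS(well_id=1), POS(well_id=2, ch="F2"))


class TestCallChip:
    def layout(self):
        return [
            make_test_well("KRAS", "G13D", 1),
            make_test_well("PIK3CA", "E542K", 2),
            make_test_well("PIK3CA", "E545K", 3),
        ]

    def wc(self, well, status):
        assay = {1: ("KRAS", "G13D"), 2: ("PIK3CA", "E542K"), 3: ("PIK3CA", "E545K")}[well]
        mutant = {
            MutationStatus.POSITIVE: POS(well),
            MutationStatus.NEGATIVE: NEG_RATIO(well),
            MutationStatus.INVALID: NEG_FNT(well),
        }[status]
        wt = NEG_FNT(well, "F2") if status is MutationStatus.INVALID else POS(well, "F2")
        return call_well(make_test_well(*assay, well), mutant, wt)

    def test_co_occurring_mutations_reported_together(self):
        calls = [
            self.wc(1, MutationStatus.POSITIVE),
            self.wc(2, MutationStatus.NEGATIVE),
            self.wc(3, MutationStatus.POSITIVE),
        ]
        g = call_chip(self.layout(), calls, "41949")
        assert g.overall is OverallStatus.MUTANT
        assert g.detected_mutations == frozenset(
            {MutationTarget("KRAS", "G13D"), MutationTarget("PIK3CA", "E545K")}
        )

    def test_same_gene_double_mutation_kept(self):
        calls = [
            self.wc(1, MutationStatus.POSITIVE),
            self.wc(2, MutationStatus.POSITIVE),
            self.wc(3, MutationStatus.POSITIVE),
        ]
        g = call_chip(self.layout(), calls, "41950")
        assert {str(m) for m in g.detected_mutations} == {
            "KRAS G13D", "PIK3CA E542K", "PIK3CA E545K"
        }

    def test_all_negative_is_wild_type(self):
        calls = [self.wc(w, MutationStatus.NEGATIVE) for w in (1, 2, 3)]
        assert call_chip(self.layout(), calls).overall is OverallStatus.WILD_TYPE

    def test_invalid_well_without_positives_invalidates_sample(self):
        calls = [
            self.wc(1, MutationStatus.INVALID),
            self.wc(2, MutationStatus.NEGATIVE),
            self.wc(3, MutationStatus.NEGATIVE),
        ]
        assert call_chip(self.layout(), calls).overall is OverallStatus.INVALID

    def test_positive_overrides_invalid_elsewhere(self):
        calls = [
            self.wc(1, MutationStatus.INVALID),
            self.wc(2, MutationStatus.NEGATIVE),
            self.wc(3, MutationStatus.POSITIVE),
        ]
        assert call_chip(self.layout(), calls).overall is OverallStatus.MUTANT

    def test_missing_well_rejected(self):
        calls = [self.wc(1, MutationStatus.NEGATIVE)]
        with pytest.raises(GenotypingError, match="missing calls"):
            call_chip(self.layout(), calls)
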