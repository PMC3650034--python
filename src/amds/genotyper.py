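"""Threshold-based genotype calling from real-time fluorescence traces.

The decision per well-channel follows the instrument's two-stage rule:

1. If the baseline-corrected end-point fluorescence F(EP) is *less than* the
   negative threshold FNT, the channel is negative outright (no reaction).
2. Otherwise the signal ratio SR = F(JP)/F(EP) is computed.  A genuine
   invasive-cleavage reaction saturates early, so it has reached most of its
   end-point signal by the judging point and SR is close to 1; slow nonspecific
   drift accrues linearly and gives SR near JP/EP.  The channel is positive iff
   SR is *strictly greater than* the positive ratio threshold RPT.

Boundary semantics are deliberate: F(EP) == FNT proceeds to the ratio stage,
SR == RPT is negative.

Per well, the mutant-allele channel decides mutation status; a test well in
which *both* channels fail the FNT stage indicates no amplifiable template and
is flagged invalid (this wild-type-channel validity gate can be disabled for a
strict two-threshold mode).  Per chip, positive wells are aggregated into a
sample genotype; co-occurring mutations across genes are reported together.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .assay_model import (
    AssayModelError,
    FluorescenceTrace,
    MutationTarget,
    ThresholdSet,
    WellAssay,
    signal_at,
)


class CallStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class CallReason(str, enum.Enum):
    BELOW_FNT = "below_FNT"
    SR_BELOW_RPT = "SR_below_RPT"
    SR_ABOVE_RPT = "SR_above_RPT"


class MutationStatus(str, enum.Enum):
    POSITIVE = "mutation_positive"
    NEGATIVE = "mutation_negative"
    INVALID = "invalid"


class OverallStatus(str, enum.Enum):
    WILD_TYPE = "wild_type"
    MUTANT = "mutant"
    INVALID = "invalid"


#: Signal-ratio definitions selectable in :func:`compute_sr`.
SR_DEFINITIONS = ("jp_over_ep", "rise_over_jp")


class GenotypingError(ValueError):
    """Trace or threshold unusable for calling."""


@dataclass(frozen=True)
class ChannelCall:
    """Decision for one well-channel with its intermediate quantities.

    ``sr`` is None when the FNT stage already decided (SR is then undefined).
    """

    well_id: int
    channel: str
    f_ep: float
    f_jp: float
    sr: float | None
    status: CallStatus
    reason: CallReason

    def __post_init__(self) -> None:
        if self.reason is CallReason.BELOW_FNT:
            if self.status is not CallStatus.NEGATIVE or self.sr is not None:
                raise GenotypingError("below-FNT call must be negative with undefined SR")
        elif self.sr is None:
            raise GenotypingError("SR must be defined when F(EP) passed the FNT stage")


@dataclass(frozen=True)
class WellCall:
    well_id: int
    target: MutationTarget | None
    mutant_channel_call: ChannelCall
    wildtype_channel_call: ChannelCall
    mutation_status: MutationStatus


@dataclass(frozen=True)
class SampleGenotype:
    """Chip-level mutation profile for one sample."""

    sample_id: str
    calls: tuple[WellCall, ...]
    detected_mutations: frozenset[MutationTarget]
    overall: OverallStatus


def compute_sr(
    trace: FluorescenceTrace, thresholds: ThresholdSet, definition: str = "jp_over_ep"
) -> float:
    """Signal ratio of a baseline-corrected trace.

    Default definition: SR = F(JP)/F(EP).  The alternative ``rise_over_jp``,
    (F(EP)-F(JP))/F(JP), measures late-phase rise instead and inverts the
    ordering of saturating vs. drifting traces; it is provided as a switch, not
    used by the caller.
    """
    if not trace.baseline_corrected:
        raise GenotypingError("compute_sr requires a baseline-corrected trace")
    if definition not in SR_DEFINITIONS:
        raise GenotypingError(f"unknown SR definition {definition!r}; options: {SR_DEFINITIONS}")
    f_ep = signal_at(trace, thresholds.EP)
    f_jp = signal_at(trace, thresholds.JP)
    if definition == "jp_over_ep":
        if f_ep <= 0:
            raise GenotypingError(f"degenerate trace: F(EP)={f_ep} <= 0 after baseline correction")
        return f_jp / f_ep
    if f_jp <= 0:
        raise GenotypingError(f"degenerate trace: F(JP)={f_jp} <= 0 after baseline correction")
    return (f_ep - f_jp) / f_jp


def call_channel(trace: FluorescenceTrace, thresholds: ThresholdSet) -> ChannelCall:
    """Apply the two-stage FNT/RPT decision to one channel."""
    if not trace.baseline_corrected:
        raise GenotypingError("call_channel requires a baseline-corrected trace")
    t0, t1 = trace.span()
    if not (t0 <= thresholds.JP and thresholds.EP <= t1):
        raise GenotypingError(
            f"trace [{t0}, {t1}] does not span JP={thresholds.JP}..EP={thresholds.EP}"
        )
    f_ep = signal_at(trace, thresholds.EP)
    f_jp = signal_at(trace, thresholds.JP)
    if f_ep < thresholds.FNT:
        return ChannelCall(
            trace.well_id, trace.channel, f_ep, f_jp, None, CallStatus.NEGATIVE, CallReason.BELOW_FNT
        )
    sr = compute_sr(trace, thresholds)
    if sr > thresholds.RPT:
        return ChannelCall(
            trace.well_id, trace.channel, f_ep, f_jp, sr, CallStatus.POSITIVE, CallReason.SR_ABOVE_RPT
        )
    return ChannelCall(
        trace.well_id, trace.channel, f_ep, f_jp, sr, CallStatus.NEGATIVE, CallReason.SR_BELOW_RPT
    )


def call_well(
    assay: WellAssay,
    mutant: ChannelCall,
    wildtype: ChannelCall,
    validity_gating: bool = True,
) -> WellCall:
    """Combine the two channel calls of a test well into a mutation status.

    With ``validity_gating`` (default), a well whose channels *both* fell below
    FNT is invalid: nothing amplified, so a negative mutant channel carries no
    information.  With gating off the well is simply mutation-negative, the
    strict two-threshold reading of the decision chart.
    """
    if mutant.well_id != wildtype.well_id:
        raise GenotypingError(
            f"channel calls from different wells: {mutant.well_id} vs {wildtype.well_id}"
        )
    if mutant.status is CallStatus.POSITIVE:
        status = MutationStatus.POSITIVE
    elif (
        validity_gating
        and assay.role == "test"
        and mutant.reason is CallReason.BELOW_FNT
        and wildtype.reason is CallReason.BELOW_FNT
    ):
        status = MutationStatus.INVALID
    else:
        status = MutationStatus.NEGATIVE
    return WellCall(assay.well_id, assay.target, mutant, wildtype, status)


def call_chip(
    layout: Sequence[WellAssay], calls: Sequence[WellCall], sample_id: str = ""
) -> SampleGenotype:
    """Aggregate per-well calls into a sample genotype.

    Every test well of the layout must have exactly one call.  Detected
    mutations are the targets of mutation-positive wells (co-occurring
    mutations are all kept); the sample is invalid only when at least one test
    well is invalid and no well at all is positive.
    """
    by_well = {c.well_id: c for c in calls}
    if len(by_well) != len(calls):
        raise GenotypingError("more than one call for the same well")
    test_wells = [w for w in layout if w.role == "test"]
    missing = [w.well_id for w in test_wells if w.well_id not in by_well]
    if missing:
        raise GenotypingError(f"missing calls for test wells {missing}")
    relevant = [by_well[w.well_id] for w in test_wells]
    detected = frozenset(
        c.target for c in relevant if c.mutation_status is MutationStatus.POSITIVE and c.target
    )
    if detected:
        overall = OverallStatus.MUTANT
    elif any(c.mutation_status is MutationStatus.INVALID for c in relevant):
        overall = OverallStatus.INVALID
    else:
        overall = OverallStatus.WILD_TYPE
    return SampleGenotype(sample_id, tuple(relevant), detected, overall)


def genotype_sample(
    traces: Iterable[FluorescenceTrace],
    layout: Sequence[WellAssay],
    thresholds: Mapping[tuple[int, str], ThresholdSet],
    sample_id: str = "",
    validity_gating: bool = True,
) -> SampleGenotype:
    """End-to-end pipeline: raw traces -> channel calls -> well calls -> genotype.

    ``thresholds`` maps (well_id, channel) to a :class:`ThresholdSet`.  Raw
    traces are baseline-corrected here; pre-corrected traces are used as-is.
    """
    from .assay_model import baseline_correct

    by_key: dict[tuple[int, str], FluorescenceTrace] = {}
    for tr in traces:
        key = (tr.well_id, tr.channel)
        if key in by_key:
            raise GenotypingError(f"duplicate trace for well {key[0]} channel {key[1]}")
        by_key[key] = tr if tr.baseline_corrected else baseline_correct(tr)

    well_calls = []
    for assay in layout:
        if assay.role != "test":
            continue
        mt_ch = assay.channel_for("mutant")
        wt_ch = assay.channel_for("wild_type")
        try:
            mt_trace = by_key[(assay.well_id, mt_ch)]
            wt_trace = by_key[(assay.well_id, wt_ch)]
        except KeyError as exc:
            raise GenotypingError(f"no trace for well {assay.well_id} channel {exc.args[0][1]}")
        mt_call = call_channel(mt_trace, thresholds[(assay.well_id, mt_ch)])
        wt_call = call_channel(wt_trace, thresholds[(assay.well_id, wt_ch)])
        well_calls.append(call_well(assay, mt_call, wt_call, validity_gating=validity_gating))
    return call_chip(layout, well_calls, sample_id=sample_id)
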