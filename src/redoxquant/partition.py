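"""Partition reporter-ion areas into cysteine redox-state fractions.

The experiment splits each sample in two: one half has its free thiols
irreversibly blocked with NEM before the DTT reduction / biotin-HPDP
switch, so its captured signal reflects only reversibly oxidized
cysteines; the unblocked half reflects reduced + reversibly oxidized
("total detectable") thiols.  Overoxidized cysteines (sulfinic/sulfonic)
are never captured and are inferred by difference.

Taking the control total-detectable channel as the 100% reference, with
ratios r_tt = test-total : control-total, r_rc = control-revox :
control-total and r_rt = test-revox : control-total:

    control:  revox = r_rc          free = 1 - r_rc
    test:     revox = r_rt          free = r_tt - r_rt    overox = 1 - r_tt

Fractions are reported unclamped: negative free or over-unity revox are
diagnostics of an underestimated reference (e.g. thiols overoxidized
during cell lysis before the NEM block could protect them) and are
flagged, never silently truncated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .flags import Flag, IncompleteChannelsError, RedoxQuantError
from .quant_io import ChannelDesign, PeptideQuant, RedoxReportRow

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (so 0.5 -> 1, -5.5 -> -6).

    The scaled value is pre-rounded at 12 decimals to absorb binary
    representation dust (0.245 - 0.300 scales to -5.4999...99, which is
    the decimal tie -5.5).
    """
    scale = 10.0 ** ndigits
    scaled = round(x * scale, 12)
    return math.copysign(math.floor(abs(scaled) + 0.5), x) / scale


@dataclass
class RatioSet:
    """Channel ratios relative to the control-total reference channel."""

    r_total_test: float
    r_revox_control: float
    r_revox_test: float
    sd_total_test: float = 0.0
    sd_revox_control: float = 0.0
    sd_revox_test: float = 0.0
    n_replicates: int = 1
    flags: frozenset[Flag] = frozenset()

    def __post_init__(self) -> None:
        for name in ("r_total_test", "r_revox_control", "r_revox_test",
                     "sd_total_test", "sd_revox_control", "sd_revox_test"):
            if getattr(self, name) < 0:
                raise RedoxQuantError(f"{name} must be nonnegative")


@dataclass
class RedoxState:
    """Partitioned fractions for one condition, with uncertainties and flags.

    Fractions are on the 0-1 scale of the control reference; ``overox`` is
    None for the control condition, where it is structurally not
    detectable.
    """

    condition: str
    revox: float
    free: float
    overox: float | None
    sd_revox: float = 0.0
    sd_free: float = 0.0
    sd_overox: float | None = None
    flags: frozenset[Flag] = frozenset()


def compute_channel_ratios(
    record: PeptideQuant, design: ChannelDesign, group: int = 0
) -> RatioSet:
    """Form the three reference ratios for one replicate group.

    Area errors, when present, are carried into ratio standard deviations
    by first-order propagation of the quotient a/b:
    sd(a/b) = (a/b) * sqrt((sd_a/a)^2 + (sd_b/b)^2).
    """
    labels = {role: design.label_for(group, *role)
              for role in (("control", "total"), ("test", "total"),
                           ("control", "revox"), ("test", "revox"))}
    missing = [lbl for lbl in labels.values() if lbl not in record.channel_areas]
    if missing:
        raise IncompleteChannelsError(
            f"{record.peptide_sequence}: missing channel(s) {missing} in group {group}")
    ref_label = labels[("control", "total")]
    ref = record.channel_areas[ref_label]
    if ref <= 0:
        raise IncompleteChannelsError(
            f"{record.peptide_sequence}: reference channel {ref_label} area is zero")
    ref_err = record.channel_area_errors.get(ref_label, 0.0)

    def ratio_and_sd(role: tuple[str, str]) -> tuple[float, float]:
        label = labels[role]
        a = record.channel_areas[label]
        r = a / ref
        sa = record.channel_area_errors.get(label, 0.0)
        rel_a = (sa / a) if a > 0 else 0.0
        sd = r * math.hypot(rel_a, ref_err / ref) if a > 0 else sa / ref
        return r, sd

    r_tt, sd_tt = ratio_and_sd(("test", "total"))
    r_rc, sd_rc = ratio_and_sd(("control", "revox"))
    r_rt, sd_rt = ratio_and_sd(("test", "revox"))
    flags = set()
    group_labels = list(labels.values())
    if not any(lbl in record.channel_area_errors for lbl in group_labels):
        flags.add(Flag.NO_ERROR_ESTIMATE)
    return RatioSet(r_total_test=r_tt, r_revox_control=r_rc, r_revox_test=r_rt,
                    sd_total_test=sd_tt, sd_revox_control=sd_rc, sd_revox_test=sd_rt,
                    n_replicates=1, flags=frozenset(flags))


def aggregate_replicates(groups: Sequence[RatioSet]) -> RatioSet:
    """Average ratios across replicate plex groups.

    With several groups each ratio is the arithmetic mean and its
    uncertainty the sample standard deviation (n-1 denominator) across
    groups; a single group passes through with its propagated sd.
    Averaging happens at the ratio level, not the raw-area level, so
    per-group loading differences cancel against each group's own
    reference channel.
    """
    if not groups:
        raise RedoxQuantError("aggregate_replicates needs at least one RatioSet")
    if len(groups) == 1:
        return replace(groups[0], n_replicates=1)
    n = len(groups)

    def mean_sd(values: Sequence[float]) -> tuple[float, float]:
        m = sum(values) / n
        var = sum((v - m) ** 2 for v in values) / (n - 1)
        return m, math.sqrt(var)

    r_tt, sd_tt = mean_sd([g.r_total_test for g in groups])
    r_rc, sd_rc = mean_sd([g.r_revox_control for g in groups])
    r_rt, sd_rt = mean_sd([g.r_revox_test for g in groups])
    # with >1 replicate the sd is estimated empirically, so a missing
    # per-area error estimate no longer matters
    flags = frozenset().union(*(g.flags for g in groups)) - {Flag.NO_ERROR_ESTIMATE}
    return RatioSet(r_total_test=r_tt, r_revox_control=r_rc, r_revox_test=r_rt,
                    sd_total_test=sd_tt, sd_revox_control=sd_rc, sd_revox_test=sd_rt,
                    n_replicates=n, flags=flags)


def propagate_uncertainty(ratios: RatioSet) -> dict[str, float]:
    """First-order standard deviations of the partitioned fractions.

    revox and overox are linear in a single ratio, so their sds pass
    through; the test free fraction is a difference of two ratios treated
    as independent, sd = sqrt(sd_tt^2 + sd_rt^2).  Correlation through the
    shared reference denominator is ignored at this order.
    """
    return {
        "control_revox": ratios.sd_revox_control,
        "control_free": ratios.sd_revox_control,
        "test_revox": ratios.sd_revox_test,
        "test_free": math.hypot(ratios.sd_total_test, ratios.sd_revox_test),
        "test_overox": ratios.sd_total_test,
    }


def partition_control(ratios: RatioSet) -> RedoxState:
    """Control condition: revox = r_rc, free = 1 - r_rc, overox not detectable."""
    sds = propagate_uncertainty(ratios)
    r = ratios.r_revox_control
    flags = set(ratios.flags)
    if r > 1.0:
        flags.add(Flag.OVER_UNITY_RATIO)
    return RedoxState(condition="control", revox=r, free=1.0 - r, overox=None,
                      sd_revox=sds["control_revox"], sd_free=sds["control_free"],
                      sd_overox=None, flags=frozenset(flags))


def partition_test(ratios: RatioSet) -> RedoxState:
    """Test condition: revox = r_rt, free = r_tt - r_rt, overox = 1 - r_tt."""
    sds = propagate_uncertainty(ratios)
    r_tt, r_rt = ratios.r_total_test, ratios.r_revox_test
    free = r_tt - r_rt
    flags = set(ratios.flags)
    if free < 0:
        flags.add(Flag.NEGATIVE_FREE)
    if r_tt > 1.0 or r_rt > 1.0:
        flags.add(Flag.OVER_UNITY_RATIO)
    return RedoxState(condition="test", revox=r_rt, free=free, overox=1.0 - r_tt,
                      sd_revox=sds["test_revox"], sd_free=sds["test_free"],
                      sd_overox=sds["test_overox"], flags=frozenset(flags))


def flag_peptide(record: PeptideQuant, *states: RedoxState) -> frozenset[Flag]:
    """Merge partition flags with peptide-level ambiguity flags.

    A peptide with two or more cysteines cannot attribute its redox state
    to an individual residue (the reporter signal averages over the
    combinatorial mixture of site states), so it is flagged ambiguous.
    Flags never alter the numeric values.
    """
    flags: set[Flag] = set()
    if record.n_cys >= 2:
        flags.add(Flag.MULTI_CYS_AMBIGUOUS)
    for state in states:
        flags |= state.flags
    return frozenset(flags)


def _clamp_pct(x: float) -> float:
    return min(max(x, 0.0), 100.0)


def quantify_peptide(
    record: PeptideQuant, design: ChannelDesign, clamp: bool = False
) -> RedoxReportRow:
    """Full partition of one peptide: ratios per group, replicate
    aggregation, both condition partitions, flags.

    Groups with missing channels are skipped (flagged INCOMPLETE_CHANNELS);
    if no group is complete the row carries NaN fractions and the flag.
    ``clamp`` truncates displayed percentages to [0, 100] without touching
    flags — a display convenience only.
    """
    group_ratios: list[RatioSet] = []
    flags: set[Flag] = set()
    for gi in range(design.n_groups):
        try:
            group_ratios.append(compute_channel_ratios(record, design, gi))
        except IncompleteChannelsError:
            flags.add(Flag.INCOMPLETE_CHANNELS)
    if not group_ratios:
        nan = math.nan
        flags |= flag_peptide(record)
        return RedoxReportRow(
            protein_accession=record.protein_accession,
            peptide_sequence=record.peptide_sequence,
            start_pos=record.start_pos, end_pos=record.end_pos,
            control_revox_pct=nan, control_revox_sd_pct=nan,
            control_free_pct=nan, control_free_sd_pct=nan,
            test_revox_pct=nan, test_revox_sd_pct=nan,
            test_free_pct=nan, test_free_sd_pct=nan,
            test_overox_pct=nan, test_overox_sd_pct=nan,
            flags=frozenset(flags), n_replicates=0)
    ratios = aggregate_replicates(group_ratios)
    control = partition_control(ratios)
    test = partition_test(ratios)
    flags |= flag_peptide(record, control, test)
    pct = (lambda x: _clamp_pct(100.0 * x)) if clamp else (lambda x: 100.0 * x)
    return RedoxReportRow(
        protein_accession=record.protein_accession,
        peptide_sequence=record.peptide_sequence,
        start_pos=record.start_pos, end_pos=record.end_pos,
        control_revox_pct=pct(control.revox), control_revox_sd_pct=100.0 * control.sd_revox,
        control_free_pct=pct(control.free), control_free_sd_pct=100.0 * control.sd_free,
        test_revox_pct=pct(test.revox), test_revox_sd_pct=100.0 * test.sd_revox,
        test_free_pct=pct(test.free), test_free_sd_pct=100.0 * test.sd_free,
        test_overox_pct=pct(test.overox), test_overox_sd_pct=100.0 * (test.sd_overox or 0.0),
        flags=frozenset(flags), n_replicates=ratios.n_replicates)


def quantify(
    records: Sequence[PeptideQuant],
    design: ChannelDesign,
    min_confidence: float = 0.95,
    clamp: bool = False,
) -> list[RedoxReportRow]:
    """Confidence-filter a batch of records and partition each peptide."""
    from .quant_io import filter_confidence

    confident = filter_confidence(records, min_confidence)
    rows = [quantify_peptide(r, design, clamp=clamp) for r in confident]
    complete = sum(r.n_replicates > 0 for r in rows)
    flagged = sum(bool(r.flags) for r in rows)
    logger.info("quantified %d peptides (%d with complete channels, %d flagged)",
                len(rows), complete, flagged)
    return rows
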