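"""Tabular interfaces: peptide quantification tables, channel designs,
FASTA sequences and redox-state reports.

All tables are tab-separated UTF-8 with a header row.  Reporter-area
columns are named ``area_<label>`` and their errors ``err_<label>``, so a
single schema covers any plex design.  Coordinates are 1-based inclusive,
matching the residue numbering conventions of the proteomics literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .flags import Flag, FormatError, ValidationError, format_flags, parse_flags

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

CONDITIONS = ("control", "test")
CAPTURES = ("total", "revox")

#: The four experimental roles of a replicate group.  ``capture`` records
#: which thiol population the channel's sample presents for streptavidin
#: capture: ``total`` = reduced + reversibly oxidized (no NEM pre-block),
#: ``revox`` = reversibly oxidized only (free thiols blocked with NEM
#: before the DTT reduction / biotin-HPDP switch).
ROLES = tuple((c, k) for c in CONDITIONS for k in CAPTURES)

#: The 100% reference of the partition: the control sample without NEM.
REFERENCE_ROLE = ("control", "total")


@dataclass(frozen=True)
class ChannelDesign:
    """Maps reporter labels to experimental roles and replicate groups.

    Parameters
    ----------
    assignments
        Reporter label -> ``(condition, capture)`` with condition in
        {"control", "test"} and capture in {"total", "revox"}.
    replicate_groups
        Ordered list of label tuples; each group contains exactly one
        label per role and represents one plex of the experiment.
    """

    assignments: Mapping[str, tuple[str, str]]
    replicate_groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.replicate_groups:
            roles = []
            for label in group:
                if label not in self.assignments:
                    raise ValidationError(f"label {label!r} in a group has no role assignment")
                if label in seen:
                    raise ValidationError(f"reporter label {label!r} appears in two groups")
                seen.add(label)
                roles.append(self.assignments[label])
            for role in ROLES:
                if roles.count(role) != 1:
                    raise ValidationError(
                        f"group {group} must assign role {role} exactly once, got {roles.count(role)}"
                    )
        for label, role in self.assignments.items():
            if role[0] not in CONDITIONS or role[1] not in CAPTURES:
                raise ValidationError(f"label {label!r} has unknown role {role!r}")
            if label not in seen:
                raise ValidationError(f"label {label!r} assigned a role but absent from all groups")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for group in self.replicate_groups for lbl in group)

    @property
    def n_groups(self) -> int:
        return len(self.replicate_groups)

    def label_for(self, group: int, condition: str, capture: str) -> str:
        """Reporter label filling a role within a replicate group."""
        for label in self.replicate_groups[group]:
            if self.assignments[label] == (condition, capture):
                return label
        raise KeyError((group, condition, capture))

    def to_file(self, path: str | Path) -> None:
        rows = [
            {"label": lbl, "condition": self.assignments[lbl][0],
             "capture": self.assignments[lbl][1], "group": gi + 1}
            for gi, group in enumerate(self.replicate_groups)
            for lbl in group
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: Channel layout of the original 8-plex experiment: one 4-channel group
#: 114/116/118/121 plus a replicate group 113/115/117/119 filling the
#: same roles in the same order.
DEFAULT_DUPLEX = ChannelDesign(
    assignments={
        "114": ("control", "total"), "118": ("control", "revox"),
        "116": ("test", "total"), "121": ("test", "revox"),
        "113": ("control", "total"), "117": ("control", "revox"),
        "115": ("test", "total"), "119": ("test", "revox"),
    },
    replicate_groups=(("114", "116", "118", "121"), ("113", "115", "117", "119")),
)

#: Single-group 4-channel subset of the same layout.
DEFAULT_SINGLE = ChannelDesign(
    assignments={
        "114": ("control", "total"), "118": ("control", "revox"),
        "116": ("test", "total"), "121": ("test", "revox"),
    },
    replicate_groups=(("114", "116", "118", "121"),),
)

BUILTIN_DESIGNS: dict[str, ChannelDesign] = {
    "itraq8-duplex": DEFAULT_DUPLEX,
    "itraq4": DEFAULT_SINGLE,
}


def read_channel_design(source: str | Path) -> ChannelDesign:
    """Load a channel design from a built-in name or a TSV declaration.

    The declaration is a flat table with columns ``label``, ``condition``,
    ``capture``, ``group``; groups are formed in order of first appearance.
    """
    if isinstance(source, str) and source in BUILTIN_DESIGNS:
        return BUILTIN_DESIGNS[source]
    path = Path(source)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"label", "condition", "capture", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"channel design {path} is missing column(s): {sorted(missing)}")
    assignments: dict[str, tuple[str, str]] = {}
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        if label in assignments:
            raise ValidationError(f"duplicate reporter label {label!r} in {path}")
        condition, capture = str(row["condition"]).strip(), str(row["capture"]).strip()
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r} for label {label!r}")
        if capture not in CAPTURES:
            raise ValidationError(f"unknown capture {capture!r} for label {label!r}")
        assignments[label] = (condition, capture)
        groups.setdefault(str(row["group"]).strip(), []).append(label)
    return ChannelDesign(assignments=assignments,
                         replicate_groups=tuple(tuple(g) for g in groups.values()))


@dataclass
class PeptideQuant:
    """One identified peptide with per-channel reporter areas.

    ``channel_areas`` holds nonnegative reporter-ion peak areas in
    arbitrary intensity units; ``channel_area_errors`` optional matching
    peak-area errors as exported by the search engine.
    """

    protein_accession: str
    peptide_sequence: str
    start_pos: int | None = None
    end_pos: int | None = None
    confidence: float = 1.0
    channel_areas: dict[str, float] = field(default_factory=dict)
    channel_area_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.peptide_sequence) - STANDARD_RESIDUES
        if bad:
            raise ValidationError(
                f"peptide {self.peptide_sequence!r} contains non-standard residue(s) {sorted(bad)}"
            )
        if self.start_pos is not None and self.end_pos is not None:
            if self.end_pos - self.start_pos + 1 != len(self.peptide_sequence):
                raise ValidationError(
                    f"coordinates {self.start_pos}-{self.end_pos} inconsistent with "
                    f"sequence length {len(self.peptide_sequence)}"
                )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")
        stray = set(self.channel_area_errors) - set(self.channel_areas)
        if stray:
            raise ValidationError(f"error values for unknown channel(s) {sorted(stray)}")
        for label, area in self.channel_areas.items():
            if area < 0:
                raise ValidationError(f"negative area {area} for channel {label}")

    def is_complete(self, design: ChannelDesign, group: int | None = None) -> bool:
        """True when every channel of the design (or of one group) has an area."""
        labels = design.replicate_groups[group] if group is not None else design.labels
        return all(lbl in self.channel_areas for lbl in labels)

    @property
    def n_cys(self) -> int:
        return self.peptide_sequence.count("C")


_MANDATORY_COLUMNS = ("accession", "sequence", "start", "end", "confidence")


def _parse_confidence(raw) -> float:
    """Confidence as a fraction; '%'-suffixed or (1, 100] values are percentages."""
    if isinstance(raw, str) and raw.strip().endswith("%"):
        return float(raw.strip().rstrip("%")) / 100.0
    value = float(raw)
    if 1.0 < value <= 100.0:
        return value / 100.0
    return value


def read_peptide_quant(
    path: str | Path,
    design: ChannelDesign,
    on_error: str = "raise",
) -> list[PeptideQuant] | tuple[list[PeptideQuant], list[str]]:
    """Read a peptide quantification table against a channel design.

    Every design label must have an ``area_<label>`` column; ``err_<label>``
    columns are optional.  Rows with empty area cells are returned but are
    incomplete (``is_complete`` is False); rows with unparseable numbers
    raise a :class:`FormatError` carrying the 1-based file line number, or,
    with ``on_error="collect"``, are reported in a second return value so
    that ``len(records) + len(errors)`` always equals the input row count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    for label in design.labels:
        if f"area_{label}" not in df.columns:
            missing.append(f"area_{label}")
    if missing:
        raise FormatError(f"{path} is missing mandatory column(s): {missing}")

    records: list[PeptideQuant] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            areas: dict[str, float] = {}
            errs: dict[str, float] = {}
            for label in design.labels:
                cell = row[f"area_{label}"].strip()
                if cell == "":
                    continue
                areas[label] = float(cell)
                err_col = f"err_{label}"
                if err_col in df.columns and row[err_col].strip() != "":
                    errs[label] = float(row[err_col].strip())
            start = int(row["start"]) if row["start"].strip() else None
            end = int(row["end"]) if row["end"].strip() else None
            records.append(PeptideQuant(
                protein_accession=row["accession"].strip(),
                peptide_sequence=row["sequence"].strip().upper(),
                start_pos=start,
                end_pos=end,
                confidence=_parse_confidence(row["confidence"]),
                channel_areas=areas,
                channel_area_errors=errs,
            ))
        except (ValueError, ValidationError) as exc:
            message = f"{path} line {line_no}: {exc}"
            if on_error == "collect":
                errors.append(message)
            else:
                raise FormatError(message) from exc
    incomplete = sum(not r.is_complete(design) for r in records)
    logger.info("parsed %d records from %s (%d incomplete, %d rejected)",
                len(records), path, incomplete, len(errors))
    if on_error == "collect":
        return records, errors
    return records


def write_peptide_quant(
    records: Sequence[PeptideQuant], design: ChannelDesign, path: str | Path
) -> None:
    """Write a peptide quantification table in the schema read_peptide_quant expects."""
    columns = list(_MANDATORY_COLUMNS)
    has_errors = any(r.channel_area_errors for r in records)
    for label in design.labels:
        columns.append(f"area_{label}")
        if has_errors:
            columns.append(f"err_{label}")
    rows = []
    for r in records:
        row: dict[str, object] = {
            "accession": r.protein_accession,
            "sequence": r.peptide_sequence,
            "start": "" if r.start_pos is None else r.start_pos,
            "end": "" if r.end_pos is None else r.end_pos,
            "confidence": f"{r.confidence:.4f}",
        }
        for label in design.labels:
            area = r.channel_areas.get(label)
            row[f"area_{label}"] = "" if area is None else f"{area:.6f}"
            if has_errors:
                err = r.channel_area_errors.get(label)
                row[f"err_{label}"] = "" if err is None else f"{err:.6f}"
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def filter_confidence(
    records: Sequence[PeptideQuant], min_confidence: float = 0.95
) -> list[PeptideQuant]:
    """Retain records identified at or above a confidence threshold."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValidationError(f"min_confidence {min_confidence} outside [0, 1]")
    kept = [r for r in records if r.confidence >= min_confidence]
    logger.info("confidence filter >= %.2f: kept %d of %d records (discarded %d)",
                min_confidence, len(kept), len(records), len(records) - len(kept))
    return kept


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by FASTA record id (first token of header)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Redox report rows

#: Printed marker for quantities the capture chemistry cannot observe
#: (overoxidized thiols are never biotinylated, hence invisible in the
#: control where no test-total channel exists to infer them by difference).
NOT_DETECTABLE = "ND"


@dataclass
class RedoxReportRow:
    """One peptide's partitioned redox state, aggregated over replicates.

    All fractions are percentages of the control total-detectable-thiol
    reference.  The control overoxidized fraction is structurally not
    detectable and is rendered as the literal ``ND`` marker, never a number.
    """

    protein_accession: str
    peptide_sequence: str
    start_pos: int | None
    end_pos: int | None
    control_revox_pct: float
    control_revox_sd_pct: float
    control_free_pct: float
    control_free_sd_pct: float
    test_revox_pct: float
    test_revox_sd_pct: float
    test_free_pct: float
    test_free_sd_pct: float
    test_overox_pct: float
    test_overox_sd_pct: float
    flags: frozenset[Flag] = frozenset()
    n_replicates: int = 1


_REPORT_COLUMNS = [
    "accession", "sequence", "start", "end", "n_replicates",
    "control_revox_pct", "control_revox_sd", "control_free_pct", "control_free_sd",
    "control_overox_pct",
    "test_revox_pct", "test_revox_sd", "test_free_pct", "test_free_sd",
    "test_overox_pct", "test_overox_sd", "flags",
]


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.1f}"


def write_redox_report(rows: Iterable[RedoxReportRow], path: str | Path) -> None:
    """Write a redox report TSV (percentages to one decimal, flags joined)."""
    out = []
    for r in rows:
        out.append({
            "accession": r.protein_accession,
            "sequence": r.peptide_sequence,
            "start": "" if r.start_pos is None else r.start_pos,
            "end": "" if r.end_pos is None else r.end_pos,
            "n_replicates": r.n_replicates,
            "control_revox_pct": _fmt(r.control_revox_pct),
            "control_revox_sd": _fmt(r.control_revox_sd_pct),
            "control_free_pct": _fmt(r.control_free_pct),
            "control_free_sd": _fmt(r.control_free_sd_pct),
            "control_overox_pct": NOT_DETECTABLE,
            "test_revox_pct": _fmt(r.test_revox_pct),
            "test_revox_sd": _fmt(r.test_revox_sd_pct),
            "test_free_pct": _fmt(r.test_free_pct),
            "test_free_sd": _fmt(r.test_free_sd_pct),
            "test_overox_pct": _fmt(r.test_overox_pct),
            "test_overox_sd": _fmt(r.test_overox_sd_pct),
            "flags": format_flags(r.flags),
        })
    pd.DataFrame(out, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_redox_report(path: str | Path) -> list[RedoxReportRow]:
    """Read back a redox report written by :func:`write_redox_report`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing report column(s): {missing}")
    rows = []
    for _, r in df.iterrows():
        num = lambda c: float(r[c]) if r[c].strip() != "" else math.nan
        rows.append(RedoxReportRow(
            protein_accession=r["accession"],
            peptide_sequence=r["sequence"],
            start_pos=int(r["start"]) if r["start"].strip() else None,
            end_pos=int(r["end"]) if r["end"].strip() else None,
            control_revox_pct=num("control_revox_pct"),
            control_revox_sd_pct=num("control_revox_sd"),
            control_free_pct=num("control_free_pct"),
            control_free_sd_pct=num("control_free_sd"),
            test_revox_pct=num("test_revox_pct"),
            test_revox_sd_pct=num("test_revox_sd"),
            test_free_pct=num("test_free_pct"),
            test_free_sd_pct=num("test_free_sd"),
            test_overox_pct=num("test_overox_pct"),
            test_overox_sd_pct=num("test_overox_sd"),
            flags=parse_flags(r["flags"]),
            n_replicates=int(r["n_replicates"]),
        ))
    return rows
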