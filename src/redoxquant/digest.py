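"""In-silico tryptic digestion, modified peptide masses, and the
MS-amenability screen for cysteine-containing peptides.

A cysteine is observable by the reporter-ion workflow only if it sits in
a tryptic peptide whose (modified, singly protonated) m/z falls inside
the instrument acquisition window — by default 800-4000, the reflector
window of a MALDI TOF/TOF, at charge 1+ since MALDI predominantly yields
singly charged ions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _pmass
from pyteomics.parser import icleave

from .flags import ValidationError
from .quant_io import STANDARD_RESIDUES, read_fasta

PROTON_MASS = 1.007276466879  # Da

#: Unimod monoisotopic deltas for the fixed modifications of the workflow.
NEM_DELTA = 125.047679       # N-ethylmaleimide on Cys
ITRAQ8_DELTA = 304.205360    # 8-plex isobaric tag on Lys / peptide N-terminus

N_TERM = "n-term"
C_TERM = "c-term"

_TRYPSIN_PROLINE = r"[KR](?!P)"
_TRYPSIN_NO_PROLINE = r"[KR]"


@dataclass(frozen=True)
class ModificationSet:
    """Fixed monoisotopic mass deltas applied per residue and per terminus."""

    residue_deltas: Mapping[str, float] = field(default_factory=dict)
    n_term_delta: float = 0.0
    c_term_delta: float = 0.0

    def __post_init__(self) -> None:
        for target, delta in self.residue_deltas.items():
            if target not in STANDARD_RESIDUES:
                raise ValidationError(f"modification target {target!r} is not a residue letter")
            if not _finite(delta):
                raise ValidationError(f"non-finite delta for {target!r}")
        if not (_finite(self.n_term_delta) and _finite(self.c_term_delta)):
            raise ValidationError("non-finite terminal delta")

    def mass_shift(self, sequence: str) -> float:
        """Total delta the set adds to a peptide of this sequence."""
        shift = self.n_term_delta + self.c_term_delta
        for residue, delta in self.residue_deltas.items():
            shift += sequence.count(residue) * delta
        return shift

    @classmethod
    def itraq8_labeled(cls, nem_on_cys: bool = False) -> "ModificationSet":
        """Peptides after 8-plex labeling: tag on every Lys and the N-terminus.

        Analyzed cysteines default to free thiol — the biotin-HPDP handle is
        cleaved off by DTT at elution, and captured cysteines were never
        NEM-alkylated.  ``nem_on_cys`` models the blocked (non-captured)
        population instead.
        """
        deltas = {"K": ITRAQ8_DELTA}
        if nem_on_cys:
            deltas["C"] = NEM_DELTA
        return cls(residue_deltas=deltas, n_term_delta=ITRAQ8_DELTA)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValidationError(f"non-standard residue {aa!r} at position {i + 1}")


def digest_trypsin(
    sequence: str,
    max_missed: int = 0,
    proline_rule: bool = True,
) -> list[tuple[str, int, int, int]]:
    """Tryptic digestion products with coordinates and missed-cleavage counts.

    Cleaves C-terminal to K or R, by default not before proline.  Returns
    ``(peptide, start, end, missed)`` tuples with 1-based inclusive
    coordinates, exhaustive over all products with at most ``max_missed``
    retained internal sites and duplicate-free by coordinate.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    _check_sequence(sequence)
    rule = _TRYPSIN_PROLINE if proline_rule else _TRYPSIN_NO_PROLINE
    internal = re.compile(rule)
    products: dict[tuple[int, int], tuple[str, int, int, int]] = {}
    for start0, pep in icleave(sequence, rule, missed_cleavages=max_missed):
        start, end = start0 + 1, start0 + len(pep)
        # retained sites are cleavable positions strictly inside the peptide
        missed = sum(1 for m in internal.finditer(pep) if m.start() < len(pep) - 1)
        products[(start, end)] = (pep, start, end, missed)
    return sorted(products.values(), key=lambda t: (t[1], t[2]))


def peptide_mass(sequence: str, mods: ModificationSet | None = None) -> float:
    """Neutral monoisotopic peptide mass in Da, including fixed modifications."""
    _check_sequence(sequence)
    if not sequence:
        raise ValidationError("empty sequence")
    mass = _pmass.fast_mass(sequence)
    if mods is not None:
        mass += mods.mass_shift(sequence)
    return mass


def mz_from_mass(neutral_mass: float, charge: int = 1) -> float:
    if charge < 1:
        raise ValidationError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


@dataclass
class CysPeptide:
    """An in-silico tryptic peptide with its cysteine content and m/z."""

    parent_accession: str
    sequence: str
    start_pos: int
    end_pos: int
    cys_positions: list[int]          # 1-based protein coordinates
    missed_cleavages: int
    neutral_mass: float               # Da, fixed mods included
    charge: int
    mz: float
    amenable: bool = False


def cys_peptides(
    accession: str,
    sequence: str,
    mods: ModificationSet | None = None,
    max_missed: int = 0,
    charge: int = 1,
    proline_rule: bool = True,
) -> list[CysPeptide]:
    """Digest a protein and compute the modified mass of every product.

    All products are returned (cysteine-free ones included) so that the
    amenability screen can report what was excluded and why.
    """
    if mods is None:
        mods = ModificationSet.itraq8_labeled()
    out = []
    for pep, start, end, missed in digest_trypsin(sequence, max_missed, proline_rule):
        m = peptide_mass(pep, mods)
        out.append(CysPeptide(
            parent_accession=accession,
            sequence=pep,
            start_pos=start,
            end_pos=end,
            cys_positions=[start + i for i, aa in enumerate(pep) if aa == "C"],
            missed_cleavages=missed,
            neutral_mass=m,
            charge=charge,
            mz=mz_from_mass(m, charge),
        ))
    return out


def select_amenable(
    peptides: Iterable[CysPeptide],
    mz_window: tuple[float, float] = (800.0, 4000.0),
    require_cys: bool = True,
) -> list[CysPeptide]:
    """Mark and return peptides observable in the acquisition window.

    A peptide is amenable when its m/z lies inside ``mz_window`` and (by
    default) it contains at least one cysteine.  Every input peptide gets
    its ``amenable`` verdict set; the amenable subset is returned.
    """
    low, high = mz_window
    if not low < high:
        raise ValidationError(f"invalid m/z window {mz_window}")
    amenable = []
    for pep in peptides:
        pep.amenable = (low <= pep.mz <= high) and (pep.cys_positions != [] or not require_cys)
        if pep.amenable:
            amenable.append(pep)
    return amenable


def amenable_cys_positions(peptides: Iterable[CysPeptide]) -> list[int]:
    """Sorted protein coordinates of cysteines inside amenable peptides."""
    return sorted({pos for p in peptides if p.amenable for pos in p.cys_positions})


def digest_fasta(
    fasta_path: str | Path,
    mods: ModificationSet | None = None,
    max_missed: int = 0,
    mz_window: tuple[float, float] = (800.0, 4000.0),
    charge: int = 1,
    proline_rule: bool = True,
) -> list[CysPeptide]:
    """Digest every protein in a FASTA file and run the amenability screen."""
    peptides: list[CysPeptide] = []
    for accession, sequence in read_fasta(fasta_path).items():
        peptides.extend(cys_peptides(accession, sequence, mods, max_missed, charge, proline_rule))
    select_amenable(peptides, mz_window)
    return peptides


def write_digest_report(peptides: Sequence[CysPeptide], path: str | Path) -> None:
    rows = [{
        "accession": p.parent_accession,
        "peptide": p.sequence,
        "start": p.start_pos,
        "end": p.end_pos,
        "missed": p.missed_cleavages,
        "mass": f"{p.neutral_mass:.4f}",
        "mz": f"{p.mz:.4f}",
        "charge": p.charge,
        "cys_positions": ";".join(str(c) for c in p.cys_positions),
        "amenable": int(p.amenable),
    } for p in peptides]
    pd.DataFrame(rows, columns=["accession", "peptide", "start", "end", "missed",
                                "mass", "mz", "charge", "cys_positions", "amenable"]
                 ).to_csv(path, sep="\t", index=False)
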