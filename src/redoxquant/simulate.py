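"""Generative model of the differential-alkylation reporter-ion workflow.

Each simulated cysteine site has true state fractions (reduced,
reversibly oxidized, overoxidized) in control and test conditions.  The
capture chemistry determines the noiseless expected reporter areas of a
replicate group with per-site abundance scale I:

    control total  = I * (reduced_c + revox_c)      (no NEM block)
    control revox  = I * revox_c                    (NEM blocks free thiols)
    test total     = I * (reduced_t + revox_t)
    test revox     = I * revox_t

Overoxidized molecules carry no reducible thiol, are never biotinylated
and are invisible in every channel — they enter the data only through
the deficit of the test total channel.  A nonzero control overoxidized
fraction therefore shrinks the 100% reference and inflates every
recovered fraction by exactly 1 / (1 - overox_c), the mechanism behind
over-unity ratios seen in harshly lysed samples.

Reporter-area noise is multiplicative lognormal per channel (mean 1,
coefficient of variation ``multiplicative_cv``) plus an additive
background floor; replicate groups receive independent draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flags import ValidationError
from .quant_io import ChannelDesign, DEFAULT_DUPLEX, PeptideQuant

Fractions = tuple[float, float, float]  # (reduced, revox, overox)

#: Named scenarios: (control fractions, test fractions).  "adh-like"
#: mirrors a catalytic-site cysteine after a strong peroxide challenge:
#: half oxidized at baseline, half of the population pushed past the
#: reversible states by the treatment.  "random" draws each site's
#: fractions uniformly on the simplex.
SCENARIOS: dict[str, tuple[Fractions, Fractions] | None] = {
    "adh-like": ((0.53, 0.47, 0.0), (0.22, 0.26, 0.52)),
    "all-reduced": ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    "random": None,
}

_RESIDUES_NO_KRC = "ADEFGHILMNPQSTVWY"


@dataclass
class SiteTruth:
    """Ground truth for one simulated cysteine-containing peptide."""

    protein_accession: str
    peptide_sequence: str
    start_pos: int
    end_pos: int
    control: Fractions
    test: Fractions
    base_intensity: float = 1000.0

    def __post_init__(self) -> None:
        for name, frac in (("control", self.control), ("test", self.test)):
            if len(frac) != 3 or any(f < 0 for f in frac):
                raise ValidationError(f"{name} fractions must be three nonnegative values")
            if abs(sum(frac) - 1.0) > 1e-6:
                raise ValidationError(f"{name} fractions must sum to 1, got {sum(frac)}")
        if self.base_intensity <= 0:
            raise ValidationError("base_intensity must be positive")


@dataclass
class NoiseModel:
    """Per-channel reporter-area noise: lognormal CV plus additive floor."""

    multiplicative_cv: float = 0.05
    additive_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValidationError("multiplicative_cv must be >= 0")
        if self.additive_floor < 0:
            raise ValidationError("additive_floor must be >= 0")


def _validate_fractions(name: str, frac: Fractions) -> None:
    if len(frac) != 3 or any(f < 0 for f in frac):
        raise ValidationError(f"{name} fractions must be three nonnegative values")
    if abs(sum(frac) - 1.0) > 1e-6:
        raise ValidationError(f"{name} fractions must sum to 1, got {sum(frac)}")


def _with_control_overox(control: Fractions, overox: float) -> Fractions:
    """Impose a pre-lysis overoxidized fraction on the control state.

    The reduced:revox balance is preserved; the overoxidized pool is
    carved proportionally out of both, modeling indiscriminate oxidative
    damage during lysis before NEM can protect free thiols.
    """
    if not 0.0 <= overox < 1.0:
        raise ValidationError("control_overox must be in [0, 1)")
    red, rev, _ = control
    scale = (1.0 - overox) / (red + rev) if red + rev > 0 else 0.0
    return (red * scale, rev * scale, overox)


def _random_peptide(rng: np.random.Generator, index: int) -> str:
    length = int(rng.integers(7, 14))
    body = "".join(rng.choice(list(_RESIDUES_NO_KRC), size=length))
    cys_at = int(rng.integers(0, length))
    return body[:cys_at] + "C" + body[cys_at:] + "K"


def simulate_truth(
    n_peptides: int,
    scenario: str | tuple[Fractions, Fractions] = "adh-like",
    control_overox: float = 0.0,
    seed: int = 0,
    base_intensity: float = 1000.0,
    intensity_sigma: float = 0.5,
) -> list[SiteTruth]:
    """Sample ground-truth redox states for a cohort of cysteine peptides.

    ``scenario`` is a named preset or an explicit (control, test) fraction
    pair applied to every site; the "random" scenario draws each site's
    fractions uniformly on the probability simplex.  Per-site abundances
    are lognormal around ``base_intensity``.  Reproducible given ``seed``.
    """
    if n_peptides < 1:
        raise ValidationError("n_peptides must be >= 1")
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {scenario!r}; pick from {sorted(SCENARIOS)}")
        preset = SCENARIOS[scenario]
    else:
        preset = scenario
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_peptides):
        if preset is None:  # "random"
            red_c, rev_c = rng.dirichlet((1.0, 1.0))
            control: Fractions = (float(red_c), float(rev_c), 0.0)
            t = rng.dirichlet((1.0, 1.0, 1.0))
            test: Fractions = (float(t[0]), float(t[1]), float(t[2]))
        else:
            control, test = preset
        _validate_fractions("control", control)
        _validate_fractions("test", test)
        control = _with_control_overox(control, control_overox)
        sequence = _random_peptide(rng, i)
        intensity = float(base_intensity * rng.lognormal(0.0, intensity_sigma))
        truths.append(SiteTruth(
            protein_accession=f"SIM{i:04d}",
            peptide_sequence=sequence,
            start_pos=1,
            end_pos=len(sequence),
            control=control,
            test=test,
            base_intensity=intensity,
        ))
    return truths


def expected_areas(truth: SiteTruth, efficiency: Mapping[tuple[str, str], float] | None = None
                   ) -> dict[tuple[str, str], float]:
    """Noiseless expected reporter areas per role from the capture logic."""
    red_c, rev_c, _ = truth.control
    red_t, rev_t, _ = truth.test
    eff = efficiency or {}
    base = {
        ("control", "total"): truth.base_intensity * (red_c + rev_c),
        ("control", "revox"): truth.base_intensity * rev_c,
        ("test", "total"): truth.base_intensity * (red_t + rev_t),
        ("test", "revox"): truth.base_intensity * rev_t,
    }
    return {role: area * eff.get(role, 1.0) for role, area in base.items()}


def simulate_quant_table(
    truth: Sequence[SiteTruth],
    noise: NoiseModel | None = None,
    design: ChannelDesign = DEFAULT_DUPLEX,
    efficiency: Mapping[tuple[str, str], float] | None = None,
) -> list[PeptideQuant]:
    """Turn ground truth into a noisy peptide quantification table.

    One replicate group of channels per design group, with independent
    noise draws per channel and group.  When the noise model has a
    nonzero CV, nominal per-area errors of ``cv * area`` are emitted,
    mimicking search-engine error columns.  ``efficiency`` optionally
    scales each role's signal to stress the equal-labeling assumption.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    cv = noise.multiplicative_cv
    sigma = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0
    records = []
    for site in truth:
        exp = expected_areas(site, efficiency)
        areas: dict[str, float] = {}
        errs: dict[str, float] = {}
        for gi in range(design.n_groups):
            for role, expected in exp.items():
                label = design.label_for(gi, *role)
                area = expected
                if sigma > 0:
                    area *= float(rng.lognormal(-0.5 * sigma * sigma, sigma))
                area += noise.additive_floor
                areas[label] = area
                if cv > 0:
                    errs[label] = cv * area
        records.append(PeptideQuant(
            protein_accession=site.protein_accession,
            peptide_sequence=site.peptide_sequence,
            start_pos=site.start_pos,
            end_pos=site.end_pos,
            confidence=0.99,
            channel_areas=areas,
            channel_area_errors=errs,
        ))
    return records


_TRUTH_COLUMNS = ["accession", "sequence", "start", "end",
                  "control_reduced", "control_revox", "control_overox",
                  "test_reduced", "test_revox", "test_overox", "base_intensity"]


def write_truth(truth: Sequence[SiteTruth], path: str | Path) -> None:
    """Ground-truth sidecar TSV for parameter-recovery analysis."""
    rows = [{
        "accession": t.protein_accession, "sequence": t.peptide_sequence,
        "start": t.start_pos, "end": t.end_pos,
        "control_reduced": f"{t.control[0]:.9f}", "control_revox": f"{t.control[1]:.9f}",
        "control_overox": f"{t.control[2]:.9f}",
        "test_reduced": f"{t.test[0]:.9f}", "test_revox": f"{t.test[1]:.9f}",
        "test_overox": f"{t.test[2]:.9f}",
        "base_intensity": f"{t.base_intensity:.6f}",
    } for t in truth]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[SiteTruth]:
    df = pd.read_csv(path, sep="\t")
    return [SiteTruth(
        protein_accession=str(r["accession"]), peptide_sequence=str(r["sequence"]),
        start_pos=int(r["start"]), end_pos=int(r["end"]),
        control=(r["control_reduced"], r["control_revox"], r["control_overox"]),
        test=(r["test_reduced"], r["test_revox"], r["test_overox"]),
        base_intensity=float(r["base_intensity"]),
    ) for _, r in df.iterrows()]
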