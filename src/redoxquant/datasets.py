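"""Bundled example data.

``adh1_fasta_path`` points to a synthetic reconstruction of yeast
alcohol dehydrogenase 1 (348 residues, 8 cysteines) used by the worked
examples and tests; it is not a database export.  The quantification
tables encode the published reporter-ion ratio measurements for the two
MS-amenable ADH-1 cysteine peptides after in-vitro peroxide exposure,
expressed as areas against a reference channel fixed at 1000 (ratio
0.478 -> area 478, ratio sd 0.143 -> area error 143), for a single
4-channel replicate group.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

_DOSES = ("1mm", "5mm")


def _data(name: str) -> Path:
    with resources.as_file(resources.files("redoxquant") / "data" / name) as p:
        return Path(p)


def adh1_fasta_path() -> Path:
    """Synthetic ADH-1 protein sequence (FASTA)."""
    return _data("adh1_synthetic.fasta")


def adh1_quant_path(dose: str = "5mm") -> Path:
    """ADH-1 reporter-area table for a peroxide dose ("1mm" or "5mm")."""
    if dose not in _DOSES:
        raise ValueError(f"dose must be one of {_DOSES}")
    return _data(f"adh1_quant_{dose}.tsv")
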