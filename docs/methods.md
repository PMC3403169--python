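# Methods

## The measurement model

Each biological sample is split before lysis workup into a −NEM half and a
+NEM half. NEM alkylates free thiols irreversibly; DTT then reduces all
reversibly oxidized thiols; biotin-HPDP labels whatever is free at that
point. Consequently the captured (streptavidin-enriched) population of a
cysteine peptide is

- −NEM half: molecules whose cysteine was reduced **or** reversibly
  oxidized ("total detectable thiols"),
- +NEM half: molecules whose cysteine was reversibly oxidized only.

Overoxidized (–SO₂H/–SO₃H) molecules are refractory to DTT, never
biotinylated, and invisible in every channel. All four halves (two
conditions × two capture states) are labeled with amine-reactive isobaric
tags and quantified together; the per-channel reporter-ion areas are the
data this package consumes.

Writing the channel ratios against the control-total reference
(r_tt = test-total/control-total, r_rc = control-revox/control-total,
r_rt = test-revox/control-total), the partition is

```
control: revox = r_rc,  free = 1 − r_rc
test:    revox = r_rt,  free = r_tt − r_rt,  overox = 1 − r_tt
```

Both partitions sum to 1 algebraically. In floating point the identity
holds to ~1 ulp; tests assert |sum − 1| ≤ 1e−12.

### Assumptions

1. Equal protein input and equal labeling/capture efficiency across the
   four channels of a replicate group (the bench protocol normalizes
   protein content before labeling). The simulator exposes per-role
   efficiency multipliers to stress this assumption.
2. The control sample contains no overoxidized thiols. When it does
   (harsh lysis), the reference is underestimated and every fraction is
   inflated by 1/(1 − o_c), where o_c is the control overoxidized
   fraction — see the bias law below. Results then show over-unity revox
   or negative free values, which are flagged
   (`OVER_UNITY_RATIO`, `NEGATIVE_FREE`) and reported unclamped; an
   optional clamp mode truncates display values to [0, 100] only.
3. Peptides with a single cysteine. Multi-cysteine peptides are computed
   but flagged `MULTI_CYS_AMBIGUOUS`: at least one thiol must be free or
   reversibly oxidized for capture, and the reporter signal pools all
   combinatorial site states, so a per-residue partition is undefined.

## Uncertainty

Search-engine exports carry per-channel area errors. These propagate to
ratio standard deviations by the first-order quotient rule
sd(a/b) = (a/b)·√((sd_a/a)² + (sd_b/b)²), and to fractions linearly:
revox and overox inherit their ratio's sd, the test free fraction (a
difference of two ratios) gets √(sd_tt² + sd_rt²) under an independence
assumption. Correlation through the shared reference denominator is
ignored at first order; this is a known (mild, conservative) limitation.
Replicate plex groups are aggregated at the ratio level — each group is
normalized by its own reference channel, so per-group loading differences
cancel — with arithmetic means and sample standard deviations (n−1).
With several replicates the empirical sd supersedes the propagated one.
Records with no error columns and a single replicate are flagged
`NO_ERROR_ESTIMATE` and carry zero sds.

## Rounding and report conventions

Report TSVs print percentages to one decimal; comparisons against
integer-percent tables use round-half-away-from-zero (the scaled value is
pre-rounded at 12 decimals so decimal ties represented inexactly in
binary, e.g. −5.4999…99 for −5.5, round as the tie they are). The control
overoxidized fraction is printed as the literal `ND`, never 0 — it is
structurally undetectable, not zero.

## Digestion and the amenability screen

Trypsin cleavage is C-terminal to K/R, by default suppressed before
proline (configurable off), with a missed-cleavage budget; cleavage and
monoisotopic masses are computed via pyteomics and cross-checked in the
test suite against an independent brute-force cut-site enumeration and a
Biopython residue-sum oracle. Default fixed modifications (Unimod
monoisotopic values): +304.20536 Da per lysine and per peptide N-terminus
(8-plex isobaric tag); analyzed cysteines are treated as free thiols
because the biotin-HPDP handle is a disulfide cleaved by DTT at elution;
an NEM-on-Cys variant (+125.04767 Da) models the blocked population. A
cysteine is *amenable* when its peptide's singly protonated monoisotopic
m/z falls inside the acquisition window, default 800–4000 at charge 1+
(MALDI yields predominantly 1+ ions, so the instrument's Da range is
treated as an m/z window).

The bundled ADH-1 sequence (`data/adh1_synthetic.fasta`) is a synthetic
reconstruction of yeast alcohol dehydrogenase 1 used by examples and
tests: 348 residues, 8 cysteines, and exactly the cysteines 44, 277 and
278 inside amenable tryptic peptides.

## The simulator

`simulate_truth` draws per-site true state fractions — named scenarios
("adh-like": control (0.53, 0.47, 0), test (0.22, 0.26, 0.52);
"all-reduced"; "random": uniform on the simplex) — plus lognormal per-site
abundances (σ = 0.5 around a base intensity of 1000, a typical spread of
reporter-level peptide intensities). `simulate_quant_table` applies the
capture logic exactly: expected areas are I·(reduced + revox) for total
channels, I·revox for +NEM channels; overoxidized molecules contribute
nothing. Noise is multiplicative lognormal per channel with mean 1 and CV
0.05 by default (a typical reporter-ion repeatability for well-behaved
spots), plus an optional additive background floor; each replicate group
receives independent draws, producing realistic between-replicate spreads.
Emitted error columns are the nominal cv·area.

The `control_overox` parameter carves a pre-lysis overoxidized pool
proportionally out of the control's reduced and revox states. Closed
form in the noiseless case: estimated revox and free equal truth/(1 − o_c),
and the estimated overox fraction satisfies est·(1 − o_c) = o_t − o_c.
Tests verify this algebra numerically and the recovery of the generating
fractions (200 random-scenario peptides at CV 0.05 recover test fractions
with median absolute error well under 2 percentage points; errors shrink
as CV → 0).

What the simulator does **not** emulate: spectral interference and
isotope-impurity cross-talk between reporter channels, ratio compression
from co-isolation, missing channels, retention-time effects, or the
mixed oxidation states of multi-cysteine peptides. Passing recovery tests
therefore validates the partition arithmetic and the error model, not
robustness to those instrument artifacts.

## Design choices

- **Unclamped reporting.** Negative/over-unity fractions carry real
  information about reference underestimation and are printed as computed
  with flags; clamping is display-only and opt-in.
- **Ratio-level replicate averaging.** Invariant to per-group loading;
  averaging raw areas across groups would mix references.
- **Table schema.** Tab-separated UTF-8 with `area_<label>` /
  `err_<label>` columns maps any plex design unambiguously. Confidence
  accepts fractions, `%`-suffixed values, and bare values in (1, 100]
  (divided by 100), since search engines disagree on scale.
- **Missing error columns** are zero-uncertainty, flagged
  `NO_ERROR_ESTIMATE` rather than guessed.
- **Row accounting.** Parsing never silently drops a row: records +
  reported row errors = input rows; incomplete rows are returned and
  flagged, not discarded.

## Known limitations

- The partition is per-peptide, not per-protein; no roll-up is attempted.
- The modification type behind "reversibly oxidized" (disulfide vs
  S-nitrosylation vs glutathionylation) is indistinguishable by design.
- One printed row of the original bacterial survey (elongation factor G
  peptide 595–605: 75 / −10 / 25) cannot be produced by any ratio pair —
  the partition sums to 100 by construction — and is treated as a probable
  transcription erratum; it is excluded from quantitative checks.
- Problem sizes in the validation suite (10⁴ random partitions, 10⁵
  Monte-Carlo draws, 200-peptide recovery cohorts, 300 random digests)
  were chosen to give stable statistics at interactive runtimes.
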