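# redoxquant

Relative quantification of cysteine redox states from differential-alkylation
isobaric-tag (iTRAQ-style) reporter-ion data.

## The problem

A protein's abundance says little about its activity when that activity is
gated by a redox-sensitive cysteine ("thiol switch"). The workflow this
package supports measures, per cysteine-containing peptide, how the thiol
population is split between three states:

- **free** (reduced, –SH),
- **reversibly oxidized** (disulfide, S-glutathionylation, S-nitrosylation —
  anything DTT can reduce back),
- **overoxidized** (sulfinic/sulfonic acid, irreversible).

Each sample (control and test) is split in two. One half has its free thiols
irreversibly blocked with NEM; then all halves are DTT-reduced, labeled on
cysteine with biotin-HPDP, trypsin-digested, amine-labeled with isobaric
reporter tags, pooled, streptavidin-enriched and quantified by MS/MS. The
NEM-blocked halves therefore contribute only reversibly oxidized cysteines to
the captured signal; the unblocked halves contribute reduced + reversibly
oxidized ("total detectable") thiols. Overoxidized cysteines are never
captured and appear only as a deficit.

## The partition

With the control total-detectable channel as the 100% reference and channel
ratios r_tt (test-total : control-total), r_rc (control-revox :
control-total), r_rt (test-revox : control-total):

```
control:  revox = r_rc        free = 1 − r_rc
test:     revox = r_rt        free = r_tt − r_rt       overox = 1 − r_tt
```

Fractions sum to 1 by construction and are reported **unclamped**: negative
free or over-unity revox values are flagged (`NEGATIVE_FREE`,
`OVER_UNITY_RATIO`) rather than truncated, because they diagnose an
underestimated reference — typically thiols overoxidized during cell lysis
before NEM could protect them. Peptides with ≥ 2 cysteines are flagged
`MULTI_CYS_AMBIGUOUS`: the reporter signal averages over the combinatorial
mixture of site states and cannot be attributed to one residue.

Uncertainties propagate to first order (quotient rule for ratios, quadrature
for the test free fraction); replicate plex groups are averaged at the ratio
level with sample standard deviations.

The package also ships an in-silico trypsin digestion and **amenability
screen** (which cysteines sit in peptides inside the instrument's m/z
acquisition window, default 800–4000 at 1+), and a generative simulator of
the capture chemistry for validation and power analysis.

## Worked example

The bundled table `adh1_quant_5mm.tsv` encodes the measured reporter-ion
ratios for the two MS-amenable cysteine peptides of yeast alcohol
dehydrogenase 1 after 5 mM H₂O₂ (reference channel fixed at 1000, so ratio
0.478 → area 478):

```
$ redoxquant --quiet quantify --table src/redoxquant/data/adh1_quant_5mm.tsv \
      --design itraq4 --out adh_report.tsv
$ redoxquant --quiet report --report adh_report.tsv
Protein/peptide                  Sample     RevOx%    Free%  OverOx%  Flags
---------------------------------------------------------------------------
ADH1_SYN (40-60)                 Control      46.7     53.3       ND
                                 Test         25.8     22.0     52.2
ADH1_SYN (277-287)               Control      39.7     60.3       ND
                                 Test         34.6    194.7   -129.3  MULTI_CYS_AMBIGUOUS;OVER_UNITY_RATIO
```

Peptide 40–60 carries the catalytic-site Cys44: at baseline about half its
thiols are reversibly oxidized (46.7%) and half free (53.3%); after the
peroxide challenge the reversibly oxidized pool drops to 25.8%, free thiols
to 22.0%, and 52.2% of the population is pushed into irreversible
overoxidation — rounding to the 47/53 and 26/22/52 percent split of the
original experiment. The control overoxidized fraction is structurally not
detectable and prints as `ND`. Peptide 277–287 contains two adjacent
cysteines and an over-unity test-total ratio; its numbers are reported
as computed but flagged uninterpretable.

The amenability screen on the bundled synthetic ADH-1 sequence:

```
$ redoxquant digest --fasta src/redoxquant/data/adh1_synthetic.fasta --out digest.tsv
INFO redoxquant: digested 38 peptides, 2 amenable Cys peptides covering 3 cysteine(s): [44, 277, 278]
```

Of the protein's eight cysteines, only Cys44, Cys277 and Cys278 lie in
tryptic peptides inside the 800–4000 m/z window — the other five sit in a
69-residue product far above it.

Simulation round trip:

```
$ redoxquant simulate --n 200 --scenario random --cv 0.05 --seed 7 \
      --out sim.tsv --truth truth.tsv
$ redoxquant quantify --table sim.tsv --design itraq8-duplex --out sim_report.tsv
```

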