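# rhizochron

Quantification of root system architecture from traced seedling roots, built
around the **rhizochron index** *m*: a per-plant allometric slope describing
how lateral-root length declines with distance from the shoot along the
primary root.

## The problem and the model

In *Arabidopsis thaliana* (and other taprooted species such as soybean or
oilseed rape), lateral roots (LRs) near the shoot are older and therefore
longer than the younger laterals near the primary-root (PR) tip.  For a
plant whose laterals sit at positions *x₁ … xₙ* along the PR (measured from
the root–shoot junction) with lengths *y₁ … yₙ*, the pattern is summarised
by an ordinary-least-squares fit

  *y = m·x + b*

where the slope *m* — the rhizochron index — is typically negative and
captures, in one number, both how often elongated laterals emerge and how
their lengths are graded along the axis.  A plant needs at least two
elongated laterals to be fitted; anything else is *discarded* with an
explicit, logged reason rather than an error, matching how such individuals
are excluded from cohort analyses.

Alongside *m* the package computes the conventional trait panel: TRL (total
root length), PRL (primary root length), TLRL (total lateral root length),
RD = n_LR/PRL (root density), TLr = TLRL/TRL, PLr = TLRL/PRL, and the
branching-zone partition preBZ + BZ + postBZ = PRL, where the BZ spans the
first to the last elongated lateral.

It also ships:

* readers for two input dialects — a **measurement-table CSV** (the direct
  transcription of manual tracing: PR inter-branch segments, PR tip, LR
  lengths, shoot-to-tip order) and a subset of **RSML** (Root System Markup
  Language XML, polyline geometry);
* a **synthetic root generator** with known ground-truth slopes per
  accession × day × treatment cell, for validating every downstream stage;
* the **statistics battery** used to compare such cohorts: two-way ANOVA
  with interaction (Type II sums of squares), one-way ANOVA with
  Tukey–Kramer HSD and a compact letter display, Welch's two-sample
  *t*-test, and two-tailed Pearson correlations of *m* against the trait
  panel (reported as r²).

All lengths are millimetres throughout.

## Worked example

Simulate a three-accession experiment, fit every plant, and compare
accessions:

```sh
rhizochron simulate --design design.json --seed 7 --out roots.csv --truth truth.csv
rhizochron fit --input roots.csv --out traits.csv --discard-log discards.csv
rhizochron analyze --traits traits.csv --design accession,day --tukey --correlate --out report.json
```

with `design.json` declaring true slopes m₀ = −0.25 (Col-0), −0.10 (C24)
and −0.18 (Shahdara), days 8/10/12, eight replicates, and LR-length noise
σ = 0.3 mm.  The first fitted plant in `traits.csv` reads (columns
abbreviated):

```
plant_id          PRL  TLRL           m                b              r2
Col-0_d8_ctrl_r1  40   99.9481150653  -0.267598971283  12.3066680431  0.979630998992
```

i.e. a 40 mm primary root bearing ~100 mm of laterals whose lengths fall by
0.268 mm per mm of rootward position — close to the simulated −0.25.  The
`report.json` two-way ANOVA on *m* detects the accession effect but, as
simulated, no developmental-stage effect:

```
accession      F = 1161.9   p = 1.9e-50
day            F = 0.39     p = 0.676
accession:day  F = 0.94     p = 0.445
```

and the Tukey letter display separates all three accessions
(`Col-0: a, Shahdara: b, C24: c` with means −0.247, −0.183, −0.103).

The same `fit`/`analyze` commands run unchanged on real tracings supplied as
a measurement-table CSV or RSML files (`--rsml dir/`).

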