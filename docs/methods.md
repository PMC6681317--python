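# Methods

## The rhizochron fit

For each plant, the positions of lateral roots (LRs) along the primary root
(PR) are the cumulative sums of the traced inter-branch PR segments, measured
from the root–shoot junction and increasing rootward.  The rhizochron index
*m* is the ordinary-least-squares slope of LR length on LR position; the
intercept *b* is reported in mm and the coefficient of determination
r² = 1 − SS_res/SS_tot.

Estimator choices:

* **OLS of y on x**, not major-axis or robust regression.  Position is the
  natural predictor (it proxies the lateral's age) and OLS is the standard
  reading of a fitted `lm()`-style regression on these coordinates.
* **Duplicate positions** (two laterals at one branch point, possible when a
  traced inter-branch segment is 0 mm) are kept as distinct observations;
  OLS is well defined and no merging rule is imposed.
* *m* is reported **signed and untruncated**; positive slopes occur and are
  meaningful.
* r² is clipped to [0, 1] against floating-point round-off.  With exactly
  two points at distinct positions the line interpolates and r² is reported
  as exactly 1, including the measure-zero case of two equal lengths; with
  ≥3 points and a constant response SS_tot = 0 and r² is reported missing.

Plants that cannot be fitted are never errors: fewer than two elongated
laterals → discarded with reason "fewer than two elongated lateral roots";
all laterals at one position → "degenerate positions".  `batch_fit`
guarantees `fitted + discarded == cohort size` and logs every discard with
plant id, accession, day and reason.

## Trait panel and the elongation filter

PRL = Σ segments + tip; TLRL = Σ LR lengths; TRL = PRL + TLRL;
RD = n_LR/PRL; TLr = TLRL/TRL; PLr = TLRL/PRL; preBZ = first segment;
BZ = last − first LR position; postBZ = tip.  For an unbranched plant
preBZ = BZ = 0 and postBZ = PRL, which keeps the partition
PRL = preBZ + BZ + postBZ exact in the limit; ratios are 0 when TLRL = 0,
and RD is undefined (missing) only for a zero-length trace.

"Elongated" is a threshold in mm (`min_lr_length`), **default 0**: tracing
a lateral at all is taken as the visibility/elongation judgement, and the
knob exists for sensitivity analyses.  Filtering removes a short lateral
and merges its flanking PR segments (trailing merges are absorbed into the
tip), so PRL is conserved exactly.  All traits and the fit are computed
from the *same* filtered root, so one definition of "elongated" underlies
the whole record.

## Input formats

The measurement-table CSV mirrors how roots are traced by hand: PR lengths
between successive laterals first, then each LR length, shoot-to-tip, one
row per measured length.  Units are millimetres; readers never rescale,
since calibration belongs to the tracing tool.

The RSML reader consumes `rootsystem/scene/plant/root` elements with
`geometry/polyline/point` coordinates; first-order child `root` elements
are laterals.  A lateral's insertion point (the first vertex of its
polyline) is **projected perpendicularly onto the PR polyline segments**
and converted to an arc-length position.  True segment projection is used
rather than snapping to the nearest vertex because traced polylines may be
sparse (a straight PR needs only two vertices) and projection is exact in
that case too.  An insertion point whose residual distance from the PR
exceeds a tolerance (default 0.5 mm, configurable) — e.g. a child placed
beyond the PR apex — is a format error.  Laterals are ordered by arc-length
position, with a warning when that disagrees with document order.
Second-order laterals are out of scope and skipped with a warning.

Tables are written with 12-significant-digit floats, making write→read
round trips lossless at that precision; simulation outputs carry their seed
in a leading `#` comment line.

## Synthetic generator

One plant is drawn as: LR count ~ Poisson(λ·BZ); positions uniform on the
branching zone, sorted; LR length = max(0, m₀·(x − c) + b₀ + N(0, σ)) with
*c* the BZ midpoint.  Anchoring the intercept at the **BZ midpoint** makes
b₀ the plant's expected mean LR length and keeps the line positive over the
whole zone whenever b₀ > |m₀|·BZ/2, so truncation at zero is rare at
realistic noise levels; because the OLS slope is invariant to shifting the
predictor, the anchoring does not affect what the fit estimates.  Truncated
draws are kept (not resampled), a documented small-σ bias.

Defaults emulate an Arabidopsis plate assay: PR growth 5 mm/day (so 40–60 mm
over days 8–12), pre-BZ 20% and BZ 60% of PRL, λ = 0.5 LRs/mm,
σ = 0.5 mm, b₀ ≈ 6–7 mm, m₀ ≈ −0.2.  Factorial experiments derive one
`numpy` substream per plant deterministically from
(seed, accession, day, treatment, replicate), so designs reproduce
bit-identically.  A developmental-stage effect is an additive slope change
per day after the first observation day; a treatment adds to the slope and
may scale all LR lengths, so a cell's true slope is
(m₀ + stage·Δday + Δm)·scale.

What the generator does **not** emulate: longitudinal coupling between
observation days (each day is drawn independently, as re-scanned plants
are re-measured, not jointly modelled), non-uniform branching (no renewal
process between laterals), basal-vs-lateral root distinction, curvature of
the allometry, and measurement error on positions.  Tests passing on these
simulations therefore validate the estimator and pipeline mechanics, not
the biological adequacy of a linear model for any particular dataset.

## Statistics

* **Two-way ANOVA with interaction** via `statsmodels` OLS with Type II
  sums of squares.  Balanced designs are type-invariant; Type II removes
  the factor-order dependence of sequential (Type I) sums of squares in the
  unbalanced tables that discards produce.  A constant response
  short-circuits to F = 0, p = 1 for every term; an effect with zero
  residual variance reports F = ∞, p = 0.
* **Tukey HSD**: adjusted p for pair (i, j) is the upper tail of the
  studentized range distribution at q = |ȳᵢ − ȳⱼ| / √(MSE/2·(1/nᵢ + 1/nⱼ))
  with k groups and N − k error df (Tukey–Kramer for unequal n).  With
  k = 2 this reduces exactly to the pooled-variance t-test.  The compact
  letter display uses the insert-and-absorb algorithm: start with one
  column holding all levels; each significant pair splits every column
  containing both; columns contained in another are absorbed; letters are
  assigned by ascending group mean.  Two levels share a letter iff their
  adjusted p ≥ α (default α = 0.05).
* **Welch's t** with Satterthwaite df (via scipy); both-variances-zero
  degenerates to p = 1 (equal means) or p = 0 by convention.
* **Pearson correlations** of *m* against each conventional trait, reported
  as two-tailed p and r².  Missing values are pairwise-deleted; a trait
  with fewer than three complete pairs, or a constant column, is reported
  missing rather than raising.

Days are treated as a crossed fixed factor (no repeated-measures
correction) and no multiple-testing correction is applied across the
correlation rows; both match common practice for this kind of trait table
and are stated limitations.

## Validation problem sizes

The acceptance-style checks use: 500 random roots against an independent
normal-equation solver (1e-10 relative); 1000 simulated plants at σ = 0.1,
λ = 0.5/mm, BZ = 40 mm for slope recovery (mean within 0.01 of truth,
empirical SE within 20% of the OLS sampling-theory SE); 1000 Monte-Carlo
replicates of a 15-accession × 3-day × 20-replicate null-stage design for
the type-I error of the stage effect ([0.03, 0.07] at α = 0.05); 200
replicates with a ±0.15 slope spread for accession power (>95%); 200 random
unbalanced panels for the letter-display invariant; and 1000 random roots
for trait algebra (1e-9).  `scripts/acceptance.py` re-runs the same
computations (with 400 and 100 Monte-Carlo replicates for the two rate
estimates) and writes the measured values as JSON.

## Known limitations

* The linear model ignores the post-BZ by construction: the index carries
  no information about the unbranched apical PR.
* Basal roots are not distinguished from laterals; at early stages they are
  hard to tell apart in images, so they enter the fit like any lateral.
* Zero-truncation of simulated LR lengths slightly biases recovery at high
  σ relative to b₀.
* The letter display is one valid minimal representation; letter identity
  (not the sharing pattern) can depend on tie-breaking when means are equal.
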