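# Methods notes

## Scope and unit of analysis

The unit is one pulmonary nodule ≤ 30 mm with a complete imaging
description; patient-level grouping is not modelled because the target
statistics (sensitivity, specificity, agreement rate per density stratum)
are nodule-level. Records outside the valid domain (diameter > 30 mm, a
part-solid nodule without a solid-component diameter, unknown vocabulary
tokens) are rejected at validation with machine-readable reason codes, and
every record that passes validation classifies in both engines without
error (a property the tests enforce).

## PNI-GARS engine

Rule precedence: definitely-benign morphology → stability/course → base
size grade → sign upgrades → benign downgrade → endobronchial floor. The
ordering is a design choice where the published grade tables leave it
implicit; it encodes the management intent that a calcified or long-stable
nodule can never be argued upward by signs, and an endobronchial nodule
never below grade III.

Size tiers use half-open intervals, lower bound exclusive, upper bound
inclusive: ≤ 5.0 mm → I, (5, 8] → II, (8, 10] → IIIa, (10, 20] → IIIb,
(20, 30] → IIIc. The micronodule bound is inclusive because it is stated
as "≤ 5 mm"; making the upper bounds inclusive keeps 8.0 in II, 10.0 in
IIIa, 20.0 in IIIb and 30.0 in IIIc. The 5–8 mm tier's "partial edge
smooth" descriptor is treated as descriptive, not a gate: any 5–8 mm nodule
without signs receives II regardless of the margin token, because no
alternative assignment exists for non-smooth 5–8 mm nodules.

Sign handling: the special signs (vacuole, vascular convergence, a solid
component within a GGN) and the other suspicious signs (pleural
indentation, lobulation, GGN doubling within a year, GGN density above
−600 HU, enlarged lymph nodes, shrinkage with increasing density) each
count one sub-level on the ladder II → IIIa → IIIb → IIIc → IV; two or more
signs, or spiculation on its own, force grade IV. Grades below II are never
upgraded by signs. Margin tokens are carried but only act through the sign
vocabulary (lobulation as a sign, spiculation as the force-IV sign); the
engine does not let margin alone override the size tier, since the
interaction of margin scores with size tiers is otherwise unspecified.

Benign adjustment: satellite lesions — or an inflammation picture requiring
*both* the clinical and the CT indicator — downgrade one level with a floor
at I; grade 0 is reserved for the four definitely-benign morphologies.

Stability: solid nodules unchanged ≥ 24 months and sub-solid nodules
unchanged ≥ 60 months become grade I, as does any nodule whose course is
`decreased` or `disappeared`. A sub-solid nodule stable between 2 and 5
years keeps its grade — which is why a part-solid nodule stable for 16
months remains IIIa (and screen-positive) while Lung-RADS has long since
downgraded it to category 2.

A 14.9 mm solid nodule stable ~5 months grades IIIb under these rules; the
source material scores one such case IIIc, presumably via an unstated
sign. The engine reproduces IIIc only when a sign is supplied, so that
case's grade is excluded from exact-match tests (its Lung-RADS category 3
does reproduce).

Every classification returns a `GradingTrace` (base grade, ordered applied
rules, final grade); replaying the trace reproduces the final grade, which
makes the engine auditable and gives the determinism tests a concrete
object to compare.

## Lung-RADS 2022 engine

Only the size-based pathway exercised by baseline screening is
implemented: no S modifier, no volumetric thresholds, no prior-exam logic
beyond the stability downgrade. The 4X promotion applies only to baseline
category-3/4 nodules; the trigger set defaults to {spiculation, enlarged
lymph nodes, GGN doubling within a year} and is configurable, reflecting
how loosely "additional suspicious findings" is specified in practice.
Perifissural nodules map to category 2 unless completely calcified.
Ground-glass nodules are category 2 throughout the valid domain; behaviour
at exactly 30.0 mm follows the same rule (the domain excludes anything
larger, so the bound is unexercised by construction). The stability
downgrade spends the documented stable interval sequentially: 4A needs 3
months to reach 3 and 6 further months to reach 2. A course of `increased`
blocks the downgrade; growth-driven upgrades are out of scope for a
single-baseline cohort.

## Statistics

Sensitivity, specificity and agreement rate carry Wald 95% intervals
(z = Φ⁻¹(0.975) ≈ 1.959964), clipped to [0, 1] and degenerate at 0 and 1.
The Wald choice reproduces the published intervals at one-decimal rendering
in the spot-checked cells, with one known divergence: the part-solid
Lung-RADS specificity lower bound prints 1.2 where Wald gives 1.3, so that
single bound is only asserted to within 0.1 percentage point.

Percent rendering is two-stage: the exact proportion (kept as an integer
fraction) is rounded half-up to four decimal places, then the percentage to
one decimal. Single-stage rounding reproduces 23 of the 24 published
percentages but renders one agreement rate 81.0 where 81.1 is printed
(2446/3018 = 81.047%); the two-stage convention reproduces all 24 and
matches how mainstream statistics software displays proportions rounded
before percent conversion.

Test selection for a fourfold table follows the sample-size rule: Fisher's
exact probability when n < 40 or the smallest theoretical frequency
T = (row margin × column margin)/n is below 1; Yates' correction when
n ≥ 40 and T < 5; Pearson's χ² otherwise. T exactly 1 falls to Yates and T
exactly 5 to Pearson (the rule as stated leaves the boundary points open;
this closure leaves no gaps). The Yates statistic clamps |O−E|−0.5 at zero
so near-homogeneous tables score exactly 0 — the reason it is computed
in-package rather than delegated (scipy's correction shifts observed toward
expected without clamping). Fisher uses the two-sided probability method
(sum of all tables with the observed margins no more probable than the
observed one). McNemar on paired screens uses the exact two-sided binomial
when the discordant total is under 25 and the uncorrected χ² (b−c)²/(b+c)
otherwise; the variant is selectable because published analyses rarely say
which was used.

`compare_systems` reports, per stratum: both systems' contingency tables
and rate summaries, McNemar tests for sensitivity (malignant pairs) and
specificity (benign pairs) from the per-nodule cross-classification, and a
size-selected test on the per-system agreement indicator. The published
evaluation's own χ² statistics for agreement contrasts are not reproducible
from its printed margins (the exact tables tested were not printed), so no
test asserts them; the machinery is instead validated against enumeration
and closed-form oracles.

## Synthetic cohorts

`generate_cohort` materializes a block recipe (count × density × truth ×
feature template, sizes uniform on a stated range, rounded to the
one-decimal millimetre grid) under `numpy.random.default_rng(seed)`; output
is deterministic given the seed, down to byte-identical CSV.

`reconstruct_evaluation_cohort` is fully deterministic (no randomness at all):
sixteen homogeneous blocks whose sizes, signs and benign features steer
each engine into the required screening cell — e.g. a 5.5 mm nodule with a
vacuole sign is PNI-positive (II + one sign → IIIa) yet Lung-RADS-negative
(< 6 mm), while a 9 mm nodule with satellite lesions is the reverse. The
per-nodule joint classification of the two systems is not published; the
reconstruction fixes the maximum-concordance joint per stratum
(`RECONSTRUCTION_PLAN` documents it), and any feasible joint yields the
same per-system margins, which is all downstream statistics consume.
Malignant ground-glass nodules carry the published AIS/MIA/IAC subtype
split (979/946/560) with the 3-record remainder labelled `other`; subtype
labels never affect classification.

What the synthetic data does *not* emulate: realistic size distributions
within cells (steering sizes are a few fixed values), correlations among
imaging signs, margin morphology, patient-level clustering (6,511 patients
over 7,781 nodules), and centre effects. Passing the reconstruction tests
therefore demonstrates that the engines and tabulation reproduce the
published screening margins from a feasible cohort — not that the engines
were validated against the original images.

## Numerical and interface conventions

Diameters are millimetres to one decimal; comparisons are plain float
comparisons on that grid (the grid keeps boundary cases exact). Stability
is recorded in months (2 years = 24, 5 years = 60). CSV I/O is fixed
(UTF-8, comma, header, semicolon-joined sets) rather than sniffed, and a
write→read round trip preserves all fields exactly. The pipeline writes a
manifest (package and pandas versions, seed, config digest) so reruns can
be checked for byte-identity.

## Problem sizes in the test suite

The reconstruction tests classify the full 7,781-record cohort (a few
seconds). The Fisher-vs-enumeration check covers every 2×2 table with
total ≤ 60 up to the row/column/transpose symmetry of the two-sided p
(~80k canonical tables against an exact-fraction oracle), with the symmetry
invariance verified on a seeded subsample; the Pearson shortcut identity is
checked on 1,000 random tables. Property sweeps use a 0.1 mm grid to 30 mm
and seeded or derandomized generators throughout, so the suite is
deterministic end to end.
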