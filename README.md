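# pnigars

Deterministic rule engines for classifying screening-detected pulmonary
nodules with **PNI-GARS** (Pulmonary Node Imaging-Grading And Reporting
System, grades 0–IV) and **Lung-RADS 2022** (ACR categories 1–4X), plus the
diagnostic-accuracy machinery needed to compare the two systems on a cohort
with a pathology reference standard, and synthetic-cohort generators for
benchmarking.

## Who this is for

Radiologists and biostatisticians evaluating CT nodule-management schemes.
Both systems map a nodule's imaging description to an ordered risk score
that dichotomizes into a negative or positive screen:

* **Lung-RADS 2022** is size-driven: solid nodules cross into a positive
  screen at 6 mm (category 3), 4A at 8 mm, 4B at 15 mm; part-solid nodules
  are driven by the solid-component diameter (3 below 6 mm, 4A at 6 mm, 4B
  at 8 mm); nonsolid (ground-glass) nodules under 30 mm are category 2
  regardless of size or signs. Category 3 / 4A nodules stable for 6 / 3
  months are downgraded one step. Categories 1–2 are negative screens,
  3–4X positive.
* **PNI-GARS** grades by size tiers (≤ 5 mm → I, 5–8 mm → II, 8–10 mm →
  IIIa, 10–20 mm → IIIb, 20–30 mm → IIIc) in any density class, upgrades
  one sub-level per sign of early malignancy (vacuole, vascular
  convergence, a solid component in a GGN, pleural indentation, …) with two
  signs or spiculation forcing grade IV, downgrades one level for benign
  context (satellite lesions, an inflammation picture), floors
  endobronchial nodules at grade III, and sends definitely-benign
  morphologies (pure calcification, fat, spherical atelectasis,
  perifissural) to grade 0. Long stability (2 years solid, 5 years
  sub-solid) or regression is grade I. Grades 0/I/II are negative screens,
  III/IV positive.

Screening performance against pathology is summarized per density stratum
by sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP) and agreement
rate AR = (TP+TN)/N, each with a Wald 95% CI; paired system differences use
McNemar's test, and agreement-rate contrasts use Pearson's χ², Yates'
correction or Fisher's exact probability, selected by sample size and the
smallest expected cell count (n < 40 or T < 1 → Fisher; T < 5 → Yates).

## Worked example

```python
from pnigars import *

# a 9.5 mm ground-glass nodule with a vascular convergence sign
rec = NoduleRecord("case-1", DensityType.GGN, 9.5,
                   malignant_signs=frozenset({"vascular_convergence"}))

grade, trace = classify_pnigars(rec)
print(grade.value, trace.rule_ids(), dichotomize_pni(grade).value)
# IIIb ('signs_one_sublevel',) positive

cat = classify_lungrads(rec)
print(cat.value, dichotomize_lungrads(cat).value)
# 2 negative
```

The 9.5 mm size puts the nodule in PNI-GARS tier IIIa; the single special
sign lifts it one sub-level to IIIb, a positive screen. Lung-RADS keeps
every sub-30 mm ground-glass nodule in category 2, a negative screen — the
central disagreement between the two systems on nonsolid lesions.

Cohort-level comparison on the built-in 7,781-nodule reconstruction:

```python
df = classify_cohort(reconstruct_evaluation_cohort())
res = compare_systems(df)
print(res.to_frame().head(4).to_string(index=False))
# stratum   system   tp  fn  fp  tn     sensitivity     specificity  agreement_rate
#      SN lungrads 1839  12 757 410 99.4(99.0-99.7) 35.1(32.4-37.9) 74.5(73.0-76.1)
#      SN  pnigars 1848   3 569 598  99.8(99.7-100) 51.2(48.4-54.1) 81.1(79.7-82.5)
#     PSN lungrads 1578  26  99   6 98.4(97.8-99.0)   5.7(1.3-10.2) 92.7(91.5-93.9)
#     PSN  pnigars 1602   2  91  14  99.9(99.7-100)  13.3(6.8-19.8) 94.6(93.5-95.6)
```

Each row is one system on one density stratum: the screening contingency
cells against pathology and the three rates as `percent(95% CI)`.
`res["SN"].agreement_test` holds the solid-nodule agreement-rate contrast
(Pearson χ² = 37.2, p ≈ 1.1e-9 on this cohort).

The same chain is available from a shell:

```
pnigars reconstruct --out cohort.csv
pnigars classify -i cohort.csv -o classified.csv
pnigars compare -i classified.csv -o report
pnigars synthesize --spec myspec.yaml --seed 7 --out synthetic.csv
pnigars pipeline --reconstruct -o run/        # full chain + manifest
```

## Layout

| module | contents |
| --- | --- |
| `pnigars.records` | `NoduleRecord`, grade/category scales, validation |
| `pnigars.grading` | PNI-GARS engine with audit traces |
| `pnigars.lungrads` | Lung-RADS 2022 engine |
| `pnigars.stats` | rates, CIs, χ²/Fisher/McNemar, system comparison |
| `pnigars.synth` | recipe-driven generator + cohort reconstruction |
| `pnigars.io` / `pnigars.pipeline` / `pnigars.cli` | CSV I/O, pipeline, CLI |

See `docs/methods.md` for the modelling notes, rounding conventions and
known limitations.
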