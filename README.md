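# srseval

Dosimetric evaluation and paired comparison of **single-isocenter
multi-target (SIMT) stereotactic radiosurgery plans** for multiple brain
metastases.

When one linac isocenter serves 2–25 small intracranial targets at once,
plan quality hinges on how steeply dose falls off around each lesion and
how much healthy brain is bathed in intermediate dose.  `srseval`
implements the standard plan-evaluation currency of this field and the
cohort statistics used to compare two planning techniques (e.g. a dynamic
conformal arc technique against an inverse-optimized VMAT technique):

* **Paddick conformity index** — with `V_PI` the volume covered by 100%
  of the prescription dose (PD), `V_PTV` the planning target volume and
  `V_PI,PTV` their overlap:

  `CI = (V_PI,PTV / V_PTV) · (V_PI,PTV / V_PI)`,   ideal value 1.

* **Gradient index** — `GI = V_50% / V_PI`, the ratio of the
  half-prescription isodose volume to the prescription isodose volume;
  lower is steeper, 1 is the idealized limit.

* **Healthy-brain dose burden** — `V_5Gy, V_8Gy, V_10Gy, V_12Gy`
  (absolute cm³ of brain − GTV receiving ≥ x Gy; `V_12Gy` is the standard
  radionecrosis-risk surrogate), mean brain dose, per-lesion 12 Gy
  *cluster* analysis that merges bridged isodose shells of adjacent
  lesions, and hippocampal / organ-at-risk doses.

* **Plan-acceptance policy** — per-PTV coverage ≥ 98% at PD, a two-tier
  hotspot rule (per-PTV D2% < 130% PD warns; cumulative-PTV D2% > 135% PD
  rejects), and OAR maxima (brainstem 12 Gy, optic apparatus 8 Gy,
  lens 2 Gy).

* **Paired cohort statistics** — a two-tailed Wilcoxon signed-rank test
  (exact by sign-assignment enumeration for small effective n, normal
  approximation with tie and continuity correction otherwise), per-arm
  mean/SD/median/range summaries, median percent differences, and
  stratification by lesion count (≤10 vs >10) or total tumor volume.

Because clinical dose grids are not distributable, the package ships a
**synthetic paired-cohort generator**: an analytic head phantom
(≈1400 cm³ brain ellipsoid with OAR surrogates), 2–25 spherical lesions
per patient with clinically calibrated volumes and prescriptions
(18/20 Gy single fraction, 1 mm GTV→PTV margin), and per-lesion radial
dose kernels whose isodose volumes have closed forms — an isolated
target's GI is exactly `2^(3/k)` for falloff exponent `k`, so the two
technique arms are calibrated analytically (k ≈ 1.383 → GI ≈ 4.5 steep
arm; k ≈ 1.207 → GI ≈ 5.6 shallow arm, plus a larger low-dose bath).
Kernels superpose by summation, reproducing the *dose bridging* between
nearby lesions that drives healthy-brain V12 growth in multi-target
plans.

## Worked example

```python
import srseval as sv
from srseval.stats import CohortRecord, summarize_cohort, render_table

spec = sv.CohortSpec(n_patients=8, seed=1)
records = []
for patient in sv.iter_cohort(spec):
    pair = {tech: sv.evaluate_plan(dose, patient.structures, patient.prescriptions)
            for tech, dose in patient.doses.items()}
    m = pair["DCAT-like"]
    print(f"{patient.patient_id}: {patient.lesion_count:2d} lesions, "
          f"total GTV {patient.total_gtv_cm3:.2f} cm3 | DCAT-like: "
          f"coverage {m.coverage_percent:.1f}%, CI {m.ci:.2f}, GI {m.gi:.2f}, "
          f"V12 {m.v12_cm3:.1f} cm3, policy {m.policy_result.status}")
    records.append(CohortRecord(patient.patient_id, patient.lesion_count,
                                patient.total_gtv_cm3,
                                sum(p.volume_cm3 for p in patient.structures.ptvs),
                                pair["DCAT-like"], pair["VMAT-like"]))
report = summarize_cohort(records, metrics=(("v12_cm3", "v12_cm3"),
                                            ("v5_cm3", "v5_cm3"), ("gi", "gi")))
print(render_table(report, "DCAT-like", "VMAT-like"))
```

prints (seed 1):

```
P001: 18 lesions, total GTV 3.57 cm3 | DCAT-like: coverage 100.0%, CI 0.45, GI 4.60, V12 48.0 cm3, policy fail
P002:  2 lesions, total GTV 0.42 cm3 | DCAT-like: coverage 100.0%, CI 0.43, GI 5.39, V12 6.2 cm3, policy warn
...
P008: 16 lesions, total GTV 4.04 cm3 | DCAT-like: coverage 100.0%, CI 0.50, GI 4.94, V12 50.7 cm3, policy fail

=== all ===
metric                     DCAT-like mean(SD)/median   VMAT-like mean(SD)/median         p   %diff
v12_cm3                        30.55 (32.27) / 14.27       55.48 (61.11) / 25.10    0.0078    43.5
v5_cm3                       143.48 (128.37) / 87.30    249.65 (227.77) / 151.30    0.0078    42.3
gi                                5.07 (0.41) / 4.93          6.66 (1.00) / 6.47    0.0078    21.7
```

Reading: every patient's steep-gradient plan covers all targets at the
prescription; healthy-brain V12 grows superlinearly with lesion count
(dose bridging); across the paired cohort the steep arm's V12 is ~44%
lower (Wilcoxon p = 0.0078, the exact minimum for n = 8 all-one-sided);
`policy fail` flags plans violating the acceptance rules (here mostly
hotspots from closely spaced lesions, which the un-optimized synthetic
dose model does not suppress).

The same pipeline is scriptable from the shell:

```bash
srseval simulate --n 36 --seed 1 --out cohort/
srseval evaluate cohort/P001 --out metrics/P001     # (per patient)
srseval compare metrics/ --out comparison/
srseval report comparison/
```

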