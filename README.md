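# imprintscore

Quantitative analysis of loss of imprinting at multi-DMR imprinted loci,
built around the osteosarcoma 14q32 (mouse 12qF) locus: scoring, cohort
statistics, bisulfite clone calling, expression/ChIP normalization and
index-stratified survival, exercised end to end on a synthetic-cohort
generator.

## The problem and the statistic

Imprinted differentially methylated regions (DMRs) are methylated on one
parental allele, so normal tissue shows ~50% bulk methylation. In
osteosarcoma — particularly early-onset disease (<30 y) — the three DMRs
controlling the 14q32 *DLK1–DIO3* cluster lose (or occasionally gain)
methylation far beyond the genome-wide drift measured at LINE-1 repeats.
Since both directions disturb imprinted-gene expression, the defect extent
is the absolute deviation from 50%, and the per-sample **14q-index** is

```
14q-index = (|m_DMR-1 − 50| + |m_DMR-2 − 50| + |m_DMR-3 − 50|) / 3
```

with `index > 8.5` called defect-positive, 14q-I(+). The package computes
this score, derives normal reference ranges (t-CI of the mean or z
reference interval), classifies defect direction (hypo/hyper), contrasts
locus-specific vs genome-wide demethylation (Welch/Student t, one-way
ANOVA, Pearson r — implemented from their formulas), calls per-CpG
methylation from bisulfite TA-clone sequences with conversion QC and
two-allele pattern detection, normalizes qPCR (2^−ΔΔCt) and ChIP-qPCR
signals (IgG / percent-input / H3 modes), and compares Kaplan–Meier
survival between index strata with a from-first-principles log-rank test.

The synthetic-data module generates cohorts with the statistical structure
this analysis assumes (group shifts −19/−6 points at 14q32 vs −5 at LINE-1,
H19 coupling r = 0.78, triad correlations 0.5/0.63, two-allele clone
matrices, index-dependent expression decay and hazard), so every stage is
testable without any external data. See `docs/methods.md` for models,
assumptions and calibrations.

## Worked example

```python
from imprintscore import SimulationConfig, score_cohort
from imprintscore.synthetic_data import simulate_cohort

meth = simulate_cohort(SimulationConfig(seed=20))   # 8 normal / 23 early / 9 late
scores = score_cohort(meth)
print(scores.groupby("group")["fourteen_q_index"].mean().round(2))
```

```
group
early_onset    18.45
late_onset      8.88
normal          5.03
Name: fourteen_q_index, dtype: float64
```

Normal bone sits near the ~7-point noise floor of the index, early-onset
tumors near 19 (22/23 defect-positive at the 8.5 threshold in this draw),
late-onset in between — the separation the index is designed to expose.
The same workflow is available from the shell:

```
imprintscore simulate --outdir data --seed 20
imprintscore score --input data/methylation.tsv --out scores.tsv
imprintscore survive --scores scores.tsv --survival data/survival.tsv --outdir surv
# -> log-rank chi2=4.06 p=0.044  (14q-I(+) median 19.6 mo vs 43.4 mo)
```

The numbered scripts under `analysis/` run the full study narrative —
simulation, clone calling, scoring, cohort contrasts, expression/ChIP,
survival — writing tables under `results/`.

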