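# Methods

## The quantity being scored

An imprinted differentially methylated region (DMR) is methylated on exactly
one parental allele, so bulk methylation of intact tissue sits near 50%.
Both gains and losses of methylation disturb imprinted-gene expression, so
the extent of an imprinting defect in sample *s* at DMR *d* is the absolute
deviation `e_sd = |m_sd − 50|` (percentage points). For a locus governed by
three DMRs (two intergenic DMRs plus a promoter DMR, as at human 14q32 /
mouse 12qF), the per-sample **14q-index** is the mean of the three
deviations:

    index_s = (|m_s,DMR1 − 50| + |m_s,DMR2 − 50| + |m_s,DMR3 − 50|) / 3

A sample is called defect-positive when `index_s > 8.5` — strictly greater,
because the definition is phrased as an exclusive bound; an inclusive
comparator is exposed for sensitivity analyses. The expected level is
configurable per tissue and per DMR (`ScoringConfig.expected_overrides`):
aged buccal epithelium runs higher (means near 53% at DMR-1 and 64% at
DMR-2), and mouse IG-DMR normals sit near 64% or 72–76% depending on the
model, while bone uses 50% everywhere. Percentages are on the 0–100 scale
throughout; the index lives in [0, 50] and equals 0 only when all three
DMRs are exactly at the expected level. Missing DMRs are averaged over
(with a completeness flag) rather than refused, because single-DMR designs
(e.g. the mouse IG-DMR) are legitimate.

Reference ranges for normals are computed in two modes: `mean_ci` (t
interval of the mean, the default) and `reference_interval` (mean ± z·sd).
The default is `mean_ci` because the narrow published normal bands (e.g.
51–55% around a 53% mean) are consistent with a CI of the mean at modest n,
not with an SD-based population interval. Zero-variance normals degenerate
to [mean, mean] with a warning. Defect direction per DMR is hypo / normal /
hyper by strict comparison against the range bounds.

## Synthetic cohorts: what they emulate

`SimulationConfig` defaults encode the study conditions the analysis is
designed around:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 8 / 23 / 9 | normal bone, early-onset (<30 y), late-onset (>30 y) |
| `dmr_baseline_mean` | 50% | imprinted DMR level in normal tissue |
| `dmr_baseline_sd` | 8.8 | within-group SD; calibration, see below |
| `shift_14q_early` | −19 | mean 14q32 DMR shift in early-onset tumors |
| `shift_14q_late` | −6 | mean 14q32 DMR shift in late-onset tumors |
| `shift_line1` | −5 | LINE-1 (genome-wide surrogate) shift in tumors |
| `line1_baseline` / `line1_sd` | 70% / 2.5 | normal LINE-1 level; calibration |
| `h19_coupling_r` | 0.78 | target corr(14q-index, H19 defect extent) |
| `h19_extent_mean` / `sd` | 12 / 5 | H19 extent scale; calibration |
| `triad_r_father_dmr1` | 0.50 | child–father corr at DMR-1 (buccal) |
| `triad_r_mother_dmr2` | 0.63 | child–mother corr at DMR-2 (buccal) |
| `p_meth_dense` / `p_meth_sparse` | 0.9 / 0.1 | per-CpG rates of the two alleles |
| `conversion_efficiency` | 0.99 | bisulfite conversion probability per C |
| `gamma` | 1.0 | expression decay: fold = exp(−γ·index/10) |
| `h0`, `beta` | ln2/60 /mo, 1.0 | hazard h0·exp(β·(index−8.5)/10) |
| `censor_max` | 120 mo | uniform censoring horizon |

No within-group variances are published for any cohort, so every SD is an
implementer calibration surfaced in the config. The baseline SD of 8.8 is
chosen so the expected index of normals is `8.8·√(2/π) ≈ 7.0`, matching the
reported normal-bone index; it also places the late-onset folded mean at
≈8.6 and the early-onset at ≈19.1, close to the reported 8.5 and 18.6
without any further tuning. The 70% LINE-1 baseline is a typical
pyrosequencing LINE-1 level (no normal value is printed for it).

Noise is normal, clipped to [0, 100]; at the default means and SDs the
clipped mass is negligible, so means are effectively preserved.

**H19 coupling.** The H19 defect extent is generated from the sample's
realized 14q32 deviations: the per-sample index is standardized across the
cohort and mixed with independent noise at weight r (extent = 12 + 5·(r·z +
√(1−r²)·η), clipped at 0), then given a random sign around 50%, so H19
shows both gain and loss of methylation. A pre-implementation clamping
analysis fixed the extent scale at mean 12 / SD 5 so that sub-zero extents
are rare (≈1–2% in the normal tail) and the realized correlation attenuates
by well under 0.01 from the 0.78 target. MEST and PEG3 are drawn
independently of everything (SD 5 around 50%): undisturbed bystander loci.

**Triads.** Child buccal values are `μ + r·(parent − μ) + σ√(1−r²)·ε` with
the father driving DMR-1 and the mother DMR-2, giving the target population
correlations exactly; the other parent is independent at each DMR. Family
means (60% / 70%, SD 5) reflect the hypermethylated buccal values seen in
patients and parents; they are calibrations. `r = ±1` with zero noise is
allowed and degenerates to an exact copy.

**Clones.** Each clone draws an allele with probability ½, then per-CpG
Bernoulli methylation at the allele's rate. Failed conversion leaves an
unmethylated C reading as C (apparent methylation) with probability
1 − efficiency, identically at CpG and non-CpG cytosines — which is exactly
what the conversion-QC statistic (fraction of non-CpG Cs read as T) is
designed to catch. Sequences are emitted on the converted top strand only,
over a programmatically built amplicon whose unit structure guarantees no
CpG forms across junctions and that ≥5 QC cytosines exist.

**Outcomes.** Expression is encoded as Ct values: ΔCt of each imprinted
gene grows by `(γ/ln2)·index/10` cycles plus N(0, 0.3) noise over a
gene-specific baseline, so the ΔΔCt pipeline recovers fold ≈
exp(−γ·index/10); the housekeeping gene is flat. Survival times are
exponential with the hazard above and independent uniform censoring.

What the generator does **not** emulate: per-CpG heterogeneity within a
DMR, assay noise differences between pyrosequencing and cloning, age as a
continuous covariate, correlated multi-locus defects beyond H19, PCR/clone
selection bias, or non-exponential hazards. Passing tests therefore show
that the pipeline's arithmetic and inference behave correctly under the
stated statistical structure — not that real cohorts satisfy that
structure.

## Bisulfite calling and pattern classification

Calls are C→methylated, T→unmethylated, anything else (incl. N) →missing at
each CpG of a gapless, length-matched clone; alignment is explicitly
upstream (the protocol sequences fixed amplicons). Conversion rate =
(#non-CpG C read as T)/(#read as C or T); clones under 0.95 are flagged and
excluded from summaries by default (field convention — the protocol states
no threshold). The overall level is the mean of per-clone means over
non-missing calls, matching "average over sequenced molecules" reporting,
and is invariant to clone/CpG order.

Pattern classification: clones with per-clone methylation ≥0.7 are dense,
≤0.3 sparse; *imprinted* requires both classes at frequency ≥0.2 **and**
overall methylation in [40, 60]%; otherwise *hypermethylated* (≥80%),
*hypomethylated* (≤20%), or *mixed*. Cutoffs are exposed configuration,
chosen to reproduce the visual dichotomy of clone diagrams (dense ~90%
rows vs empty rows).

Known limitation: with alleles drawn i.i.d. Bernoulli(½), the probability
that 10 clones land 4–6 dense — required for the overall level to fall in
[40, 60] under (0.9, 0.1) allele rates — is 656/1024 ≈ 0.64. Detection of
the imprinted pattern at the protocol's 6–10 clone depth is therefore
limited by allele-sampling variance, not by the caller; ≥95% detection
would need ~60 clones or a balanced allele draw. The acceptance suite
keeps the strict ≥95% check at 10 clones and it fails honestly.

## Cohort statistics

Pearson r, pooled (Student) and Welch t, and one-way ANOVA F are computed
from their textbook formulas (only the t/F/χ² distribution functions come
from scipy); the test suite cross-checks them against scipy to 1e-10. The
demethylation contrast (locus vs LINE-1) uses per-sample deltas
`normal_mean − sample_mean` and a two-sided Welch t across samples — Welch
by default because group variances are not assumed equal; pooled t is one
flag away and the result object names which ran. No multiple-testing
correction is applied by default (none is applied in this style of
analysis); a Benjamini–Hochberg helper is provided. Correlations use
pairwise-complete observations with n reported. Classification percentages
keep full precision internally and round for display (nearest integer by
default, one decimal where that is how such cohorts are reported).

## Survival

Kaplan–Meier and the two-sample log-rank test are implemented directly (see
module docstring for the estimators). Ties: events precede censorings.
When no observation is censored the product telescopes, and the
implementation uses the telescoped form `(n − cum events)/n` so S(t) equals
1 − ECDF(t) exactly, not merely to machine rounding. Median survival is the
first event time with S ≤ 0.5, reported as "not reached" (NaN) when the
curve never crosses it. Exactly two strata are supported (pairwise tests
cover three-group designs); strata come from the defect call, a custom
threshold, or index tertiles. Operating characteristics are verified by
simulation: type-I error 5% ± 2% over 1000 null replicates (n = 200 each)
and power ≥95% at β = 1 with n = 2000 — replicate counts and sizes chosen
to keep Monte-Carlo error well below the margins being checked.

## Numerical and interface choices

- Single global seed; every component draws from a deterministic substream
  (`SeedSequence(seed, spawn_key=(k,))`), so identical configs are
  byte-identical across runs.
- Coordinates 0-based internally, 1-based in reports. Ambiguous bases are
  missing, never imputed.
- Tables are long (tidy) TSV with sniffed delimiters on read; floats are
  written with 6 decimals so write→read round-trips are lossless at that
  precision. Validation rejects out-of-range percentages, duplicate
  (sample, locus, DMR) measurements and malformed survival flags, naming
  the offending rows.
- The pipeline manifest records the package version, seed, a config hash
  and SHA-256 digests of every input, making reruns verifiable.

## Problem sizes used in checks

Parameter-recovery checks run at n = 1000/group (methylation), 5000 triads,
10,000 clones; these sizes put Monte-Carlo standard errors an order of
magnitude below the tolerances being asserted (e.g. SE of r ≈ 0.02 at
n = 1000 against a ±0.05 band). The study-sized default (8/23/9) is used
wherever the point is the end-to-end workflow rather than estimator
accuracy.
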