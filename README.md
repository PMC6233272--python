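# cardiosig

Etiology-specific transcriptome signatures of end-stage heart failure.

Bulk RNA-seq of explanted left ventricles can separate heart failure with
reduced ejection fraction into its two dominant clinical etiologies —
dilated cardiomyopathy (DCM) and ischemic cardiomyopathy (ICM) — and both
from non-failing donor hearts (NF). `cardiosig` implements that
multi-analytic workflow as a tested, reusable pipeline for anyone doing
covariate-adjusted differential expression with an absolute-abundance
criterion: cardiovascular genomics groups re-analyzing their own RPKM
matrices, and methodologists who need a ground-truthed synthetic testbed.

## The method

Expression is analyzed on the `log2(RPKM + 1)` scale. For a two-group
comparison, *expressed* genes have mean RPKM ≥ 5 in both groups, and a
differentially expressed gene (DEG) must jointly satisfy

```
|mean₁ − mean₂| ≥ 5 RPKM   and   q ≤ 0.05,
```

where `q` is the Benjamini–Hochberg-adjusted p-value of a pooled-variance
linear-model test over the expressed set. Age and sex effects are removed
before DEG calling by per-gene ordinary least squares
(`y_g = β₀ + β_DCM·I_DCM + β_ICM·I_ICM + β_sex·I_male + β_age·(age − āge) + ε`,
NF as reference level), subtracting the mean-centered covariate terms so
disease structure and per-gene grand means are preserved. The two vs-NF
DEG lists are partitioned into the HF-shared signature (intersection),
DCM-specific and ICM-specific sets (set differences), alongside the direct
ICM-vs-DCM list. Three validation devices surround the calls:

- **Label permutation** — group labels are reshuffled at the original
  cohort sizes and the full DEG criterion re-run (default 1000 replicates);
  the observed count is compared to the null by a one-sample t test.
- **Concordance diagnostics** — direction agreement and the R² of log10
  group-mean expression across the HF-shared set.
- **Signature classification** — independent cohorts (RNA-seq or
  microarray) are clustered with average linkage on `1 − Spearman ρ` over
  the disease-specific signature genes; each cluster takes its majority
  phenotype and per-phenotype segregation counts are reported. Spearman
  distances make the procedure invariant to monotone per-sample platform
  distortions.

A synthetic-cohort generator (`SimConfig`, `generate_cohort`,
`generate_external_dataset`) plants HF-shared, disease-specific,
sex-linked and age-linked genes with known log2 effects in a 37/13/14
cohort, so every stage is testable against ground truth without any
download.

## Worked example

```python
import cardiosig as cs

config = cs.SimConfig(seed=1)                      # 5000 genes, 37 DCM / 13 ICM / 14 NF
matrix, samples, truth = cs.generate_cohort(config)
adjusted = cs.adjust_expression(cs.log_transform(matrix), samples)

dcm = cs.call_degs(adjusted.rpkm, samples, ("DCM", "NF"))
icm = cs.call_degs(adjusted.rpkm, samples, ("ICM", "NF"))
direct = cs.call_degs(adjusted.rpkm, samples, ("ICM", "DCM"))
sets = cs.partition_signatures(dcm, icm, direct)
print("DEGs:", int(dcm["is_deg"].sum()), int(icm["is_deg"].sum()), int(direct["is_deg"].sum()))
print("signatures:", sets.summary())
print("concordance:", cs.concordance_diagnostics(sets, dcm, icm))

dist = cs.permutation_null(adjusted.rpkm, samples, ("DCM", "NF"), n_reps=200, seed=2)
s = dist.summary()
print(f"permutation: observed {s['observed']} vs null M={s['mean']:.2f} "
      f"SD={s['sd']:.2f} max={s['max']}, p {s['p_report']}")

external, labels, probe_map = cs.generate_external_dataset(truth, "microarray", distortion_seed=3)
report = cs.classify_by_signature(external, sets, labels, probe_map=probe_map)
print("classification accuracy:", report.accuracy)
```

prints

```
DEGs: 397 497 295
signatures: {'hf': {'n': 297, 'up': 149, 'down': 148}, 'dcm_specific': {'n': 100, 'up': 52, 'down': 48},
             'icm_specific': {'n': 200, 'up': 90, 'down': 110}, 'direct': {'n': 295, 'up': 136, 'down': 159}}
concordance: {'direction_concordance': 0.9966329966329966, 'log_mean_r2': 0.9656216246832978}
permutation: observed 397 vs null M=0.00 SD=0.00 max=0, p < 2.2e-16
classification accuracy: 1.0
```

The 297-gene HF-shared signature recovers nearly all 300 planted shared
genes plus a couple of false intersections (hence concordance 0.997
rather than 1.0 on the empirical set); the disease-specific sets recover
the planted 100 and 200; no random relabeling of 200 produces a single
DEG against the observed 397; and the disease-specific signature
classifies every sample of a distorted microarray replication cohort
correctly.

The same stages are scriptable from a shell via the `cardiosig` CLI
(`simulate`, `filter`, `adjust`, `deg`, `signatures`, `permute`,
`cluster`, `classify`, `cohort-stats`, `report`).

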