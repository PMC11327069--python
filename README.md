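# epilnc

Identification of **epigenetically dysregulated lncRNAs and protein-coding
genes** ("epi genes") from tumor-vs-normal multi-omics data, with
single-sample enrichment scoring and a Cox proportional-hazards risk
signature.  Built for desk-scale methodological work: a synthetic-cohort
generator with planted ground truth makes every stage testable without any
external download.

## What it computes

Given a gene annotation (GTF), an enhancer catalogue with enhancer→gene
associations, per-condition histone peak sets (H3K27ac / H3K4me1 /
H3K4me3), a CpG beta-value matrix, count/TPM expression matrices and a
clinical survival table, the pipeline:

1. builds strand-aware promoters (TSS − 2 kb, TSS + 0.5 kb) and
   enhancer regions;
2. calls differential expression with a negative-binomial Wald test
   (median-of-ratios normalization, BH FDR; significant iff FDR < 0.05 and
   |log2FC| > 1);
3. finds **condition-specific peaks** per mark (zero overlap with the other
   condition, per-peak p < 0.05) and **DMRs** by bump hunting (running-mean
   smoothed beta differences, permutation p < 0.01, after KNN imputation);
4. labels a gene **epi** iff it is differentially expressed *and* its
   promoter or enhancer carries ≥1 peak/DMR evidence region, and summarizes
   the 4-source × 2-element evidence landscape;
5. scores epi-lncRNA sets per sample with **ssGSEA** (rank-weighted running
   sum, α = 0.25) and compares tumor vs normal;
6. screens epi-lncRNAs by univariate Cox, fits a multivariate **risk
   signature** (Breslow partial likelihood, Newton–Raphson), stratifies by
   the training-median risk score, and evaluates with Kaplan–Meier,
   log-rank and IPCW time-dependent ROC AUC.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Generate a synthetic cohort (300 genes, 20 tumor / 20 normal, 10% of genes
planted as epi-dysregulated) and run the full pipeline:

```sh
epilnc simulate --seed 1 --out demo
# {"out": "demo", "n_files": 17}

python - <<'PY'
import yaml
from epilnc import pipeline
cfg = pipeline.config_for_bundle("demo", "demo_out", seed=1)
open("demo.yaml", "w").write(yaml.safe_dump(cfg.model_dump()))
PY

epilnc run-all --config demo.yaml
# {"epi_lncRNA": 14, "non_epi_lncRNA": 136, "epi_PCG": 16, "non_epi_PCG": 134}
```

The final line is the four-way partition: 14 of 150 lncRNAs and 16 of 150
PCGs are called epi-dysregulated (this cohort planted 30 epi genes; the
calls match the planted truth exactly — `demo/ground_truth.json` holds the
answer key).  `demo_out/` then contains, per stage:

- `de_results.tsv`, `diff_peaks.tsv`, `dmrs.tsv` — the differential calls;
- `epi_annotations.tsv`, `landscape.json` — per-gene epi labels and the
  promoter/enhancer evidence split;
- `ssgsea_scores.tsv`, `ssgsea_group_tests.tsv` — per-sample set scores and
  tumor-vs-normal tests (e.g. the H3K4me1-promoter epi-lncRNA score is
  higher in tumors, BH-adjusted p ≈ 8e-6 in this run);
- `univariate_screen.tsv`, `risk_model.json`, `risk_scores.tsv` — the
  prognostic layer.  In this run the screen keeps a 3-gene panel; the
  median-split groups separate survival (log-rank p ≈ 0.023) with
  1-year AUC 0.84 on the training cohort.

Every stage is also available as a subcommand (`epilnc de`, `epilnc dmr`,
…) against the same YAML config, and as plain library functions
(`epilnc.diffexpr.test_de`, `epilnc.dmr.find_bumps`,
`epilnc.survival.cox_fit`, …).

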