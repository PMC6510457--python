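# imds

Signature-based molecular disease-activity scoring for inflammatory bowel
disease expression cohorts.

The package turns a log2 gene-by-sample expression matrix plus a library of
gene signatures (GMT) into:

1. an **enrichment-score (ES) matrix** — one single-sample score per
   signature per sample (Gaussian kernel-CDF ranks + weighted
   Kolmogorov–Smirnov-like walk; all scores in [−1, 1]);
2. **differential-enrichment selections** — per-signature two-group t
   contrasts with BH-FDR adjustment and the dual threshold
   |ΔES| ≥ 0.2 AND adjusted p ≤ 0.05;
3. a per-sample **molecular activity score** — the sum of ES over the
   selected disease-shared upregulated signatures, centered so healthy
   volunteers average zero — with responder / non-responder classification
   at a configurable cutoff and sensitivity/specificity reporting;
4. **hierarchical clustering** of samples on ES rows and
   signature–signature Pearson correlation tables.

A synthetic-cohort generator (`imds.simulate`) emits expression data with
the structure the analysis assumes — two diseases sharing truly
dysregulated signatures, non-responders more dysregulated than responders
at baseline, responders reverting to healthy post-treatment — and serves
as ground truth for every recovery test.

## Library quick start

```python
import imds

expr, lib, truth = imds.simulate_cohort(imds.default_design(seed=1))
es = imds.gsva_scores(expr, lib)                       # signatures x samples

labels = expr.annotations["group"]                     # NHV / R / NR
res = imds.compare_groups(es.scores, labels, "NR", "NHV")
selected = imds.select_enriched(res, imds.SelectionCriteria(direction="up"))

cfg = imds.ScoreConfig(signature_ids=tuple(selected),
                       nhv_ids=tuple(expr.samples_where(group="NHV")))
result = imds.compute_imds(es, cfg)                    # NHV mean == 0
```

## CLI

```bash
imds simulate --seed 1 --out sim/                    # synthetic cohort on disk
imds score-es --expression sim/expression.tsv \
              --annotations sim/annotations.tsv \
              --gmt sim/signatures.gmt --out es.tsv
imds run-all  --config config.yaml                   # full workflow + manifest
```

`config.yaml` holds the input paths, selection thresholds, score settings
and a declarative list of group comparisons (annotation filters for the
two sides); see `imds.cli.RunConfig` for the schema and defaults. Every
run writes a manifest with a config hash so outputs are regenerable.

## Notes

- ES values are cohort-relative: the kernel CDF is fit across the samples
  in the call. Score train and comparison samples jointly, or score a
  validation cohort separately as its own universe (both are supported).
- Synthetic cohorts use `numpy.random.default_rng` (PCG64); the RNG
  algorithm is part of the reproducibility contract.
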