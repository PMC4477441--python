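# cilioprior

Candidate-gene prioritization from a high-content siRNA screen, with an
exome-variant intersection stage. The pipeline:

1. **Curate training labels** (`cilioprior.labels`): positive and negative
   gene partitions are cross-filtered against a per-gene evidence-count
   table (a positive-source gene needs at least one supporting study; a
   negative-source gene needs none), with a benchmark candidate list held
   out of training.
2. **Fuse features** (`cilioprior.features`): screen replicate matrices are
   quantile-normalized per batch; per-reagent knockdown scores collapse to
   one gene-level value by a consistency-weighted median; a tissue
   expression matrix yields per-tissue medians plus the gene loadings of
   the leading principal components covering 95% of each tissue's
   variance. The three sources inner-join on gene identifier (no
   imputation; losses are reported).
3. **Score genes** (`cilioprior.prioritizer`): a class-balanced random
   forest (per tree: positives bootstrapped, an equal number of negatives
   drawn without replacement) with hand-rolled bagging so out-of-bag
   bookkeeping is exact. A score-threshold FDR is estimated from training
   labels, monotonized, and used to select the high-confidence set
   (default FDR < 0.1).
4. **Validate** (`cilioprior.screen_stats`): ROC/PR, one-tailed Wilcoxon
   rank-sum, the Jonckheere–Terpstra ordinal trend test over
   evidence-count bins (exact for small n, tie-corrected normal otherwise),
   benchmark flagging fraction, and hypergeometric gene-set enrichment
   with Benjamini–Hochberg control.
5. **Intersect with family exomes** (`cilioprior.variants`): allele
   frequency / CADD / GERP filter cascade (frameshifts are exempt from the
   CADD rule but need GERP ≥ 4), trio segregation checks, compound-het
   pairing with phase-by-descent, control-database subtraction,
   intersection with the high-confidence gene list, and a per-gene
   family-recurrence tally.
6. **Cohort statistics** (`cilioprior.cohort`): allele frequencies, the
   two-sided Fisher exact test and allele-level odds ratio for
   replication cohorts.

`cilioprior.synthetic` generates seeded synthetic inputs with the
statistical structure each stage assumes (class-shifted screen features,
class-correlated evidence counts, tissue-structured expression, and family
variant tables with a planted recurrently mutated gene), so the whole
pipeline is testable offline.

## CLI

```sh
cilioprior simulate --config config.yaml --out data/          # synthetic bundle
cilioprior features --rep data/screen_rep1.tsv --rep data/screen_rep2.tsv \
    --reagents reagents.tsv --expression data/expression.tsv \
    --samples data/expression_samples.tsv --out features.tsv
cilioprior train --features features.tsv --positives pos.txt \
    --negatives neg.txt --ntree 5000 --seed 0 --out scores.tsv
cilioprior validate --scores scores.tsv --evidence data/evidence.tsv \
    --positives pos.txt --negatives neg.txt --out stats.json
cilioprior variants --table data/family_variants.tsv \
    --controls data/control_db.tsv --genes high_confidence.txt --out summary.json
cilioprior cohort-stats --case-alt 17 --case-total 326 \
    --control-alt 2 --control-total 536
```

All tables are plain TSV with the gene identifier in the first column;
reports are JSON. Fixed seeds reproduce byte-identical outputs.

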