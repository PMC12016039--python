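# msirna

Microsatellite instability (MSI) classification from gene expression.

MSI — hypermutability at microsatellite loci caused by deficient DNA
mismatch repair — is a pan-cancer biomarker for immune-checkpoint therapy.
`msirna` calls MSI vs MSS status directly from expression matrices (bulk
microarray, FPKM/TPM/RSEM RNA-seq, or single-cell RNA-seq), for anyone who
has transcriptome data but no matched DNA-based MSI assay.

## Method

1. **Normalization** — every value becomes log2(x+1), then each sample (or
   cell) is standardized to mean 0, sd 1 across genes, making heterogeneous
   platforms comparable and each sample's representation independent of the
   rest of the batch.
2. **Informative-gene selection** — a four-stage filter on a labeled
   cohort: blacklist (ribosomal/mitochondrial/low-expression genes), then
   two-sided Wilcoxon rank-sum P < 0.01, then absolute log2 fold change of
   group means F_i = |log2(mean_MSI/mean_MSS)| > 0.5, then single-gene rank
   AUC > 0.65; surviving candidates are ranked by single-gene SVM and
   random-forest 10-fold CV accuracy, and the genes in the top 25% of both
   rankings form the panel.
3. **Classifier** — SMOTE oversamples the minority class to parity, an
   RBF-kernel SVM with Platt-scaled probabilities is trained on the
   balanced data, and the MSI/MSS cutoff is the Youden-index
   (max sensitivity + specificity − 1) point on the original training
   samples.
4. **Single cell** — cells with ≥ 20% of genes detected are kept (top-20
   fallback otherwise), dropout zeros are imputed with the cell's mean
   detected expression, each cell is scored, and the sample's MSI score is
   the mean cell score.

Models serialize to plain JSON (support vectors, kernel width, Platt
sigmoid, threshold, preprocessing recipe) and round-trip bit-stably.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

A fully synthetic end-to-end run (no external data needed — the bundled
simulator plants 10 informative genes among 200, 40 MSI / 60 MSS samples):

```sh
msi-rna simulate --mode bulk --out sim --n-genes 200 --n-informative 10 \
    --n-msi 40 --n-mss 60 --seed 11
msi-rna select-genes --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --out genes.tsv --stats stats.tsv --seed 11
msi-rna train --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --genes genes.tsv --out model.json --seed 11
msi-rna predict --matrix sim/matrix.tsv --model model.json --out predictions.tsv
msi-rna evaluate --predictions predictions.tsv --labels sim/labels.tsv \
    --out metrics.json
```

The run prints (to stderr):

```
selected 2 informative genes (m=100, n=40)
trained on 100 samples (40 MSI); Youden threshold 0.4213; wrote model.json
scored 100 samples (44 MSI); wrote predictions.tsv
AUC 0.9858 accuracy 0.9400 F1 0.9286
```

`genes.tsv` holds the selected panel (here `G0026` and `G0071`, both
planted informative genes —
`stats.tsv` records every gene's p-value, fold change, AUC, CV scores, and
the stage at which it left the pipeline). `predictions.tsv` has one line
per sample with its MSI probability and the thresholded MSI/MSS call;
`metrics.json` reports AUC, accuracy, F1, precision, sensitivity, and
specificity against the true labels. Single-cell cohorts go through
`msi-rna predict-sc`, which adds per-cell scores and per-sample mean-score
calls.

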