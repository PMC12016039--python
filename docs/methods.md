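# Methods

## Problem and model

`msirna` classifies tumor samples as microsatellite instable (MSI) or
microsatellite stable (MSS) from gene-expression profiles alone — bulk
microarray/RNA-seq matrices (FPKM, TPM, RSEM counts, or array intensities)
or single-cell RNA-seq. MSI is a consequence of mismatch-repair deficiency
and an actionable immunotherapy biomarker; expression-based calling makes it
available from transcriptome data that many studies already have.

The method has three parts: (1) a per-sample normalization chain that makes
heterogeneous expression units comparable, (2) a four-stage statistical
filter that reduces the transcriptome to a small panel of MSI-informative
genes, and (3) a probability-emitting support vector machine trained on
class-balanced data, with an operating point chosen by the Youden index.

## Preprocessing

Every value x becomes log2(x + 1); each observation (sample or cell) is then
standardized to mean 0 and standard deviation 1 across genes. The population
standard deviation (divisor = number of genes) is used so the unit-variance
postcondition is exact. Normalizing per observation — never per gene —
makes a sample's representation independent of whatever else is in the
batch, which is what lets one trained model score microarray, RNA-seq, and
single-cell inputs alike. A zero-variance observation maps to all-zero
z-scores with a warning rather than erroring; it carries no signal, and
this degenerate case only arises on tiny fixtures.

A consequence worth knowing: per-sample z-scores depend on the full gene
panel present in the input. Scoring the same sample through two different
panels gives (slightly) different model inputs. At predict time up to 10% of
model genes may be absent (their z-scores are imputed as 0, the
cohort-neutral value, with a warning); more than 10% is treated as a panel
mismatch and fails loudly.

### Single-cell rules

Cells detecting at least 20% of genes (value > 0) count as high quality. If
at least 20 such cells exist, exactly they are kept; otherwise all cells are
ranked by detected fraction (descending; ties keep input order) and the top
min(20, n_cells) are kept, so a sample always retains at least one cell.
Remaining zeros are treated as dropout and imputed by the mean of the cell's
detected (nonzero) values. "Average expression in the sample" is ambiguous
between three readings, all implemented behind `impute_mode`:
`cell_nonzero` (default — a mean including the zeros being replaced would be
self-referential), `cell_all`, and `gene_nonzero` (the gene's mean across
the sample's cells). Imputation happens on the raw scale, before the log2
transform, so bulk and single-cell data share one downstream chain.

## Informative-gene selection

Run on a labeled cohort of m samples, n of them MSI:

1. **Blacklist.** Ribosomal (`RPL/RPS/MRPL/MRPS`) and mitochondrial (`MT-`)
   symbols are removed (prefix match, user-extensible), plus genes with mean
   raw expression < 1.0 — the conventional expressed/not-expressed FPKM
   boundary, flag-overridable.
2. **Rank-sum filter.** Two-sided Wilcoxon rank-sum test on the z-scored
   values of each gene, MSI vs MSS; keep P < 0.01. Exact null distribution
   when both groups have ≤ 8 tie-free values, normal approximation with
   midrank tie correction otherwise.
3. **Fold change.** F_i = |log2(mean_MSI / mean_MSS)| > 0.5. Group means are
   taken on the log2(x+1) scale, not on z-scores: standardization routinely
   produces negative group means, for which the log-ratio is undefined. This
   is the one stage where the value scale is a genuine design decision.
4. **AUC filter.** Single-gene rank AUC (Mann–Whitney pair counting,
   ties = ½), folded as max(a, 1−a) so down-regulated genes score
   symmetrically; keep AUC > 0.65. Survivors are the *candidate* genes.
5. **Cross-validation ranking.** For each candidate, a single-feature RBF
   SVM and a 100-tree random forest are scored by mean accuracy over
   stratified 10-fold CV (folds shuffled by the selection seed; fold count
   clamped to the minority class size). Candidates are ranked by each score
   (descending, gene-id tiebreak) and the final informative set is the
   intersection of the top ⌈0.25 · n_candidates⌉ of both rankings, ordered
   by gene id.

The top-quantile intersection is a *generalization* filter on the candidate
list: with a quantile of 0.25 the final panel can never exceed a quarter of
the candidates. On simulated cohorts where essentially only the planted
genes become candidates, the selected panel is therefore a small, pure
subset of the planted set (we observe 2–5 genes from ~19 candidates, zero
false positives) rather than the full planted set; real cohorts, with
hundreds of correlated candidates, yield proportionally larger panels. An
empty intersection raises an error advising threshold relaxation rather
than silently returning nothing.

## Classifier

Class imbalance (MSI is usually the minority) is corrected by SMOTE:
each synthetic minority point is x + u·(x_nn − x) with x a uniformly chosen
minority sample, x_nn one of its k = 5 nearest minority neighbors
(Euclidean, k clamped to minority−1), and u ~ Uniform(0,1). Original rows
are passed through bit-exactly.

The classifier is an RBF-kernel SVM (C = 1, kernel width by the standard
`scale` heuristic) with Platt-scaled probabilities fitted on internally
cross-validated decision values (`CalibratedClassifierCV(..., ensemble=False)`).
The MSI probability is sigmoid(a·f(x) + b) of the SVM decision function, and
all learned constants — support vectors, dual coefficients, intercept,
kernel width, sigmoid (a, b) — are inlined in a versioned JSON model file,
so persistence is diffable, cross-language, and bit-stable: retraining with
the same seed reproduces the file byte for byte.

The status threshold maximizes Youden's J = sensitivity + specificity − 1
over all cutpoints (midpoints of adjacent distinct scores plus the 0/1
boundaries), evaluated on the *original pre-SMOTE* training samples —
synthetic points would distort the operating-point estimate. Ties in J
resolve to the larger threshold (higher specificity); a score exactly at
the threshold is called MSI. Calibrating the threshold on training rather
than test data avoids label leakage.

### Single-cell scoring

Each retained, imputed, transformed cell is scored independently; the
sample's MSI score is the arithmetic mean of its cell scores and the status
call uses the bulk model's Youden threshold — no separate single-cell
threshold exists. An optional cell→group map (e.g. epithelial / stromal /
immune) adds per-group mean scores. One corrupt sample is reported and
skipped without aborting a cohort run.

## Synthetic cohorts

The simulator generates the labeled data every pipeline stage is tested on.
Gene g in observation s takes the value exp(N(μ_g + shift, σ_g)) − 1
clamped at 0, with μ_g ~ N(2, 1) and σ_g = 0.5 — a log-normal baseline
matching the continuous FPKM/TPM-like inputs the pipeline consumes and the
log2 transform chain. Planted informative genes (default 20 of 500) add
±δ·σ_g to the MSI mean with δ = 2; half are down-regulated so direction
folding is always exercised. Planted genes are drawn among genes with
μ_g ≥ 1, i.e. among expressed genes — real MSI-informative markers are by
construction detectable, and this keeps the planted truth orthogonal to the
low-expression blacklist. Default cohort sizes are 60 MSI / 90 MSS for
training-scale runs and 40/60 for held-out sets.

Single-cell samples reuse the identical seed-derived gene universe (so a
bulk-trained model can score them) and draw each cell as MSI-like with the
sample's cell fraction (MSI-type samples 70–95%, MSS-type 0–10%; the label
is MSI iff the fraction exceeds 0.5). Dropout zeroes entries independently
at 30% by default; ~10% of cells get 97% dropout to land below the
detected-fraction QC bar. The gene universe comes from the config seed
alone, while an optional `sample_seed` redraws only the sample/cell noise —
that is how independent train/test replicates over the same planted truth
are produced.

What the simulator does *not* model: gene–gene correlation structure, batch
effects, library-size variation, or count noise (negative binomial). Passing
tests therefore demonstrate the statistical machinery — filter behavior,
balance, calibration, aggregation — under clean planted signal, not
performance on real tumor cohorts.

## Reference problem sizes

Tests and the acceptance script run at: selection fixture 500 genes ×
150 samples; end-to-end 20 replicates of train-150 / test-100; single-cell
20 samples × 200 cells × 500 genes at 30% dropout. Measured under these
conditions (seed 1): mean held-out AUC 0.98, mean accuracy at the Youden
threshold 0.93, null (δ = 0) AUC 0.48, single-cell sample-level AUC 1.0,
and sample scores strictly increasing in the MSI-like cell fraction.

## Known limitations

- The informative-gene panel size is bounded by a quarter of the candidate
  count; sparse-candidate cohorts yield very small panels (see above).
- Per-sample z-scoring ties a prediction to the input's gene panel;
  panel-mismatch behavior beyond the 10% missing-gene tolerance is a hard
  error by design.
- Probe-to-symbol mapping for microarrays is out of scope: input matrices
  must already be gene-symbol keyed (duplicate symbols collapse to the
  highest-mean row).
- No batch correction, no model-based imputation, no alternative
  classifiers at train time (the random forest participates only in gene
  ranking).
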