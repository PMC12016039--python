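"""Four-stage informative-gene selection.

Stage 0 (blacklist): drop ribosomal/mitochondrial genes and genes with low
mean raw expression.  Stage 1: two-sided Wilcoxon rank-sum test, keep
P < 0.01.  Stage 2: absolute log2 fold change of group means > 0.5,
computed on the log2(x+1) scale (per-sample z-scores can produce negative
group means, for which a log-ratio is undefined).  Stage 3: single-gene
rank-based AUC > 0.65, folded as max(a, 1-a) so down-regulated genes score
symmetrically.  Stage 4: per-gene SVM and random-forest 10-fold CV accuracy;
candidates appearing in the top quarter of BOTH rankings form the final
informative set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import ValidationError
from .io_matrix import LabeledCohort
from .preprocess import log2_shift, zscore_per_observation

#: prefix blacklist for ribosomal and mitochondrial human gene symbols
DEFAULT_BLACKLIST_PREFIXES = ("RPL", "RPS", "MRPL", "MRPS", "MT-")

#: stage names in pipeline order; a record's stage_passed is the point at
#: which the gene left the pipeline ("candidate" = survived all filters but
#: missed the CV top-quantile intersection; "informative" = final set)
STAGES = ("blacklist", "ranksum", "fold_change", "auc", "candidate", "informative")


@dataclass
class SelectionThresholds:
    """Cutoffs for the selection pipeline (defaults are the published ones)."""

    p_max: float = 0.01
    fc_min: float = 0.5
    auc_min: float = 0.65
    top_quantile: float = 0.25
    cv_folds: int = 10
    low_expr_min_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValidationError("p_max must be in (0, 1)")
        if self.fc_min < 0:
            raise ValidationError("fc_min must be >= 0")
        if not 0.5 <= self.auc_min < 1:
            raise ValidationError("auc_min must be in [0.5, 1)")
        if not 0 < self.top_quantile <= 1:
            raise ValidationError("top_quantile must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


@dataclass
class GeneStatRecord:
    """Per-gene statistics accumulated across selection stages.

    Later-stage fields stay ``None`` for genes eliminated earlier; only
    survivors of all filters receive CV scores.
    """

    gene_id: str
    p_value: float | None = None
    fold_change: float | None = None
    auc: float | None = None
    svm_cv: float | None = None
    rf_cv: float | None = None
    stage_passed: str = "blacklist"


@dataclass
class InformativeGeneSet:
    """Final informative genes plus the provenance needed to reproduce them."""

    gene_ids: list[str]
    thresholds: SelectionThresholds
    m: int = 0
    n: int = 0


def ranksum_pvalue(msi_values: Sequence[float], mss_values: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have <= 8 values and there are
    no ties; normal approximation with midrank tie correction otherwise.
    """
    x = np.asarray(msi_values, dtype=np.float64)
    y = np.asarray(mss_values, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires both groups non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def fold_change(msi_values: Sequence[float], mss_values: Sequence[float]) -> float:
    """Absolute log2 ratio of MSI to MSS group means."""
    x = np.asarray(msi_values, dtype=np.float64)
    y = np.asarray(mss_values, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("fold change requires both groups non-empty")
    mx, my = x.mean(), y.mean()
    if mx <= 0 or my <= 0:
        raise ValidationError(
            f"fold change needs strictly positive group means (got {mx:.4g}, {my:.4g}); "
            "compute it on the log2(x+1) scale, not on z-scores"
        )
    return abs(math.log2(mx / my))


def gene_auc(msi_values: Sequence[float], mss_values: Sequence[float]) -> float:
    """Single-gene rank AUC folded into [0.5, 1].

    The unfolded value is the Mann-Whitney U statistic over n_msi * n_mss
    pairs with ties counting one half; folding max(a, 1-a) treats up- and
    down-regulated genes symmetrically.
    """
    x = np.asarray(msi_values, dtype=np.float64)
    y = np.asarray(mss_values, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("AUC requires both groups non-empty")
    u = float(mannwhitneyu(x, y, alternative="two-sided").statistic)
    a = u / (x.size * y.size)
    return max(a, 1.0 - a)


def blacklist_filter(
    cohort: LabeledCohort,
    thresholds: SelectionThresholds,
    prefixes: Sequence[str] = DEFAULT_BLACKLIST_PREFIXES,
) -> LabeledCohort:
    """Drop ribosomal/mitochondrial symbols and low-expression genes."""
    keep = _blacklist_keep_mask(cohort, thresholds, prefixes)
    if not keep.any():
        raise ValidationError("blacklist filter removed every gene")
    kept_ids = [g for g, k in zip(cohort.matrix.gene_ids, keep) if k]
    return LabeledCohort(cohort.matrix.subset_genes(kept_ids), dict(cohort.labels))


def _blacklist_keep_mask(
    cohort: LabeledCohort,
    thresholds: SelectionThresholds,
    prefixes: Sequence[str],
) -> np.ndarray:
    if cohort.matrix.value_kind != "raw":
        raise ValidationError("blacklist filter needs the raw-scale matrix")
    prefixes = tuple(p.upper() for p in prefixes)
    symbol_ok = np.array(
        [not g.upper().startswith(prefixes) for g in cohort.matrix.gene_ids]
    )
    expressed = cohort.matrix.values.mean(axis=1) >= thresholds.low_expr_min_mean
    return symbol_ok & expressed


def gene_cv_scores(
    cohort: LabeledCohort,
    gene_id: str,
    thresholds: SelectionThresholds,
) -> tuple[float, float]:
    """Mean stratified k-fold CV accuracy of single-gene SVM and RF models.

    The cohort matrix should hold the per-sample z-scored values.  Folds are
    shuffled with ``thresholds.seed``; fold count is clamped to the minority
    class size.
    """
    idx = cohort.matrix.gene_index()
    if gene_id not in idx:
        raise ValidationError(f"gene {gene_id!r} not in cohort")
    y = cohort.label_array()
    minority = min(int(y.sum()), int((1 - y).sum()))
    if minority < 2:
        raise ValidationError("cross-validation requires >= 2 samples per class")
    X = cohort.matrix.values[idx[gene_id], :].reshape(-1, 1)
    return _cv_pair(X, y, thresholds, minority)


def _cv_pair(
    X: np.ndarray, y: np.ndarray, thresholds: SelectionThresholds, minority: int
) -> tuple[float, float]:
    folds = min(thresholds.cv_folds, minority)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=thresholds.seed)
    svm = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=thresholds.seed)
    rf = RandomForestClassifier(n_estimators=100, random_state=thresholds.seed, n_jobs=1)
    svm_cv = cross_val_score(svm, X, y, cv=skf, scoring="accuracy").mean()
    rf_cv = cross_val_score(rf, X, y, cv=skf, scoring="accuracy").mean()
    return float(svm_cv), float(rf_cv)


def select_informative_genes(
    cohort: LabeledCohort,
    thresholds: SelectionThresholds | None = None,
    prefixes: Sequence[str] = DEFAULT_BLACKLIST_PREFIXES,
) -> tuple[InformativeGeneSet, list[GeneStatRecord]]:
    """Run the full selection pipeline on a raw-scale labeled cohort.

    Returns the final gene set (ordered by gene id) and one
    :class:`GeneStatRecord` per input gene.  Raises if the top-quantile
    intersection of the SVM and RF rankings is empty.
    """
    thresholds = thresholds or SelectionThresholds()
    cohort.require_both_classes()

    records = {g: GeneStatRecord(gene_id=g) for g in cohort.matrix.gene_ids}
    keep = _blacklist_keep_mask(cohort, thresholds, prefixes)
    if not keep.any():
        raise ValidationError("blacklist filter removed every gene")
    kept_ids = [g for g, k in zip(cohort.matrix.gene_ids, keep) if k]

    raw = cohort.matrix.subset_genes(kept_ids)
    logm = log2_shift(raw)
    z = zscore_per_observation(logm)
    is_msi = cohort.label_array().astype(bool)

    log_idx = logm.gene_index()
    candidates: list[str] = []
    for i, g in enumerate(kept_ids):
        rec = records[g]
        zv = z.values[i, :]
        rec.p_value = ranksum_pvalue(zv[is_msi], zv[~is_msi])
        rec.stage_passed = "ranksum"
        if not rec.p_value < thresholds.p_max:
            continue
        lv = logm.values[log_idx[g], :]
        rec.fold_change = fold_change(lv[is_msi], lv[~is_msi])
        rec.stage_passed = "fold_change"
        if not rec.fold_change > thresholds.fc_min:
            continue
        rec.auc = gene_auc(zv[is_msi], zv[~is_msi])
        rec.stage_passed = "auc"
        if not rec.auc > thresholds.auc_min:
            continue
        rec.stage_passed = "candidate"
        candidates.append(g)

    if not candidates:
        raise ValidationError(
            "no genes survived the rank-sum/fold-change/AUC filters; "
            "consider relaxing the selection thresholds"
        )

    z_cohort = LabeledCohort(z, dict(cohort.labels))
    y = z_cohort.label_array()
    minority = min(int(y.sum()), int((1 - y).sum()))
    gi = z.gene_index()
    for g in candidates:
        X = z.values[gi[g], :].reshape(-1, 1)
        records[g].svm_cv, records[g].rf_cv = _cv_pair(X, y, thresholds, minority)

    k = math.ceil(thresholds.top_quantile * len(candidates))
    top_svm = set(
        sorted(candidates, key=lambda g: (-records[g].svm_cv, g))[:k]
    )
    top_rf = set(
        sorted(candidates, key=lambda g: (-records[g].rf_cv, g))[:k]
    )
    final = sorted(top_svm & top_rf)
    if not final:
        raise ValidationError(
            "the top-quantile SVM and RF rankings do not intersect; "
            "consider raising --top-quantile or relaxing earlier thresholds"
        )
    for g in final:
        records[g].stage_passed = "informative"

    gene_set = InformativeGeneSet(
        gene_ids=final, thresholds=thresholds, m=cohort.m, n=cohort.n
    )
    ordered_records = [records[g] for g in cohort.matrix.gene_ids]
    return gene_set, ordered_records
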