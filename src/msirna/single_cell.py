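"""Single-cell MSI scoring: QC, imputation, per-cell scoring with a trained
bulk model, and mean-score aggregation to one call per biological sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classifier import MSIModel, score_matrix
from .errors import MsirnaError, ValidationError
from .io_matrix import ExpressionMatrix
from .preprocess import PreprocessRecipe, cell_qc_filter, impute_dropouts

logger = logging.getLogger(__name__)


@dataclass
class SampleCellResult:
    """Per-sample result: retained cells, their scores, and the mean-score call."""

    sample_id: str
    cell_ids: list[str]
    cell_scores: np.ndarray
    sample_score: float
    status: str
    n_cells_input: int
    n_cells_retained: int
    group_scores: dict[str, float] = field(default_factory=dict)


def score_sample_cells(
    model: MSIModel,
    cells: ExpressionMatrix,
    recipe: PreprocessRecipe | None = None,
    sample_id: str = "sample",
    groups: Mapping[str, str] | None = None,
) -> SampleCellResult:
    """Score one sample's cells and call MSI status from the mean cell score.

    Pipeline: cell QC → dropout imputation → log2 → per-cell z-score →
    SVM probability per cell; the sample score is the arithmetic mean of the
    retained cells' scores and the status uses the bulk model's Youden
    threshold.  ``groups`` (cell id → group label) optionally adds per-group
    mean scores, e.g. for epithelial/stromal/immune strata.
    """
    recipe = recipe or model.recipe
    n_input = cells.n_obs
    kept = cell_qc_filter(cells, recipe)
    imputed = impute_dropouts(kept, mode=recipe.impute_mode)
    scores = score_matrix(model, imputed)
    sample_score = float(scores.mean())
    group_scores: dict[str, float] = {}
    if groups:
        by_group: dict[str, list[float]] = {}
        for cid, s in zip(imputed.obs_ids, scores):
            g = groups.get(cid)
            if g is not None:
                by_group.setdefault(g, []).append(float(s))
        group_scores = {g: float(np.mean(v)) for g, v in sorted(by_group.items())}
    return SampleCellResult(
        sample_id=sample_id,
        cell_ids=list(imputed.obs_ids),
        cell_scores=scores,
        sample_score=sample_score,
        status="MSI" if sample_score >= model.threshold else "MSS",
        n_cells_input=n_input,
        n_cells_retained=imputed.n_obs,
        group_scores=group_scores,
    )


def score_cohort(
    model: MSIModel,
    samples: Sequence[tuple[str, ExpressionMatrix]],
    recipe: PreprocessRecipe | None = None,
    groups: Mapping[str, str] | None = None,
) -> tuple[list[SampleCellResult], list[tuple[str, str]]]:
    """Score many single-cell samples independently.

    A failing sample is reported in the returned ``failures`` list
    (sample id, error message) without aborting the cohort run.
    """
    if not samples:
        raise ValidationError("single-cell cohort is empty")
    results: list[SampleCellResult] = []
    failures: list[tuple[str, str]] = []
    for sample_id, cells in samples:
        try:
            results.append(
                score_sample_cells(model, cells, recipe, sample_id=sample_id, groups=groups)
            )
        except MsirnaError as exc:
            logger.error("sample %s failed: %s", sample_id, exc)
            failures.append((sample_id, str(exc)))
    return results, failures
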