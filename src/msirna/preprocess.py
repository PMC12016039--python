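"""Expression preprocessing: log2(x+1), per-observation z-scoring, and the
single-cell quality-control / dropout-imputation rules.

Bulk chain: ``log2_shift`` → ``zscore_per_observation``.
Single-cell chain: ``cell_qc_filter`` → ``impute_dropouts`` → ``log2_shift``
→ ``zscore_per_observation``.  Imputation runs on the raw scale so bulk and
single-cell share one transformation chain downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import StateError, ValidationError
from .io_matrix import ExpressionMatrix

#: supported dropout-imputation interpretations of "the average of the gene
#: expression values in the given sample"
IMPUTE_MODES = ("cell_nonzero", "cell_all", "gene_nonzero")


@dataclass
class PreprocessRecipe:
    """Preprocessing parameters carried inside a trained model.

    ``sc_min_detected_fraction`` is the minimum fraction of genes a cell must
    detect (value > 0) to count as high quality; ``sc_min_cells`` is the
    fallback count kept when fewer cells pass.
    """

    do_log2: bool = True
    do_zscore: bool = True
    sc_min_detected_fraction: float = 0.20
    sc_min_cells: int = 20
    impute_mode: str = "cell_nonzero"

    def __post_init__(self) -> None:
        if not 0.0 <= self.sc_min_detected_fraction <= 1.0:
            raise ValidationError("sc_min_detected_fraction must be in [0, 1]")
        if self.sc_min_cells < 1:
            raise ValidationError("sc_min_cells must be >= 1")
        if self.impute_mode not in IMPUTE_MODES:
            raise ValidationError(
                f"impute_mode must be one of {IMPUTE_MODES}, got {self.impute_mode!r}"
            )

    def to_dict(self) -> dict:
        return {
            "do_log2": self.do_log2,
            "do_zscore": self.do_zscore,
            "sc_min_detected_fraction": self.sc_min_detected_fraction,
            "sc_min_cells": self.sc_min_cells,
            "impute_mode": self.impute_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        return cls(**d)


def log2_shift(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1) to a raw matrix."""
    if matrix.value_kind != "raw":
        raise StateError(f"log2_shift expects raw values, got {matrix.value_kind!r}")
    return matrix.with_values(np.log2(matrix.values + 1.0), "log2")


def zscore_per_observation(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each observation (column) to mean 0, population sd 1.

    Zero-variance columns map to all-zeros with a warning; they carry no
    rankable signal and zero is the mean-centered limit.
    """
    if matrix.value_kind != "log2":
        raise StateError(
            f"zscore_per_observation expects log2 values, got {matrix.value_kind!r}"
        )
    if matrix.n_genes < 2:
        raise ValidationError("z-scoring requires at least 2 genes")
    mean = matrix.values.mean(axis=0, keepdims=True)
    sd = matrix.values.std(axis=0, ddof=0, keepdims=True)
    flat = sd.ravel() == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} observation(s) have zero variance; z-scores set to 0",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (matrix.values - mean) / safe_sd
    z[:, flat] = 0.0
    return matrix.with_values(z, "zscore")


def detected_fraction(cells: ExpressionMatrix) -> np.ndarray:
    """Per-cell fraction of genes with value > 0."""
    return (cells.values > 0).mean(axis=0)


def cell_qc_filter(cells: ExpressionMatrix, recipe: PreprocessRecipe) -> ExpressionMatrix:
    """Keep high-quality cells of one sample.

    Cells detecting at least ``sc_min_detected_fraction`` of genes pass.  If
    fewer than ``sc_min_cells`` pass, all cells are ranked by detected
    fraction (descending, original order on ties) and the top
    ``min(sc_min_cells, n_cells)`` are kept.  The kept set retains its
    original column order.
    """
    if cells.n_obs == 0:
        raise ValidationError("cell QC requires at least one cell")
    frac = detected_fraction(cells)
    passing = np.flatnonzero(frac >= recipe.sc_min_detected_fraction)
    if len(passing) >= recipe.sc_min_cells:
        keep = passing
    else:
        order = np.argsort(-frac, kind="stable")  # stable: ties keep input order
        keep = np.sort(order[: min(recipe.sc_min_cells, cells.n_obs)])
    return cells.subset_obs([cells.obs_ids[j] for j in keep])


def impute_dropouts(
    cells: ExpressionMatrix, mode: str = "cell_nonzero"
) -> ExpressionMatrix:
    """Replace scRNA-seq dropout zeros by an average expression value.

    Modes (the wording "average of the gene expression values in the given
    sample" admits several readings):

    - ``cell_nonzero`` (default): zeros in a cell become the mean of that
      cell's detected (nonzero) values.
    - ``cell_all``: zeros become the mean over all of the cell's values,
      zeros included.
    - ``gene_nonzero``: a zero for gene g becomes the mean of gene g's
      nonzero values across the sample's cells.

    Nonzero entries are never touched; an all-zero cell (or gene, for
    ``gene_nonzero``) is left unchanged with a warning.
    """
    if cells.value_kind != "raw":
        raise StateError(f"impute_dropouts expects raw values, got {cells.value_kind!r}")
    if mode not in IMPUTE_MODES:
        raise ValidationError(f"unknown impute mode {mode!r}")
    v = cells.values.copy()
    zero = v == 0.0
    if mode in ("cell_nonzero", "cell_all"):
        nz_count = (~zero).sum(axis=0)
        empty = nz_count == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} cell(s) have no detected genes; left unimputed",
                stacklevel=2,
            )
        denom = np.where(empty, 1, nz_count if mode == "cell_nonzero" else v.shape[0])
        fill = v.sum(axis=0) / denom
        fill = np.where(empty, 0.0, fill)
        v = np.where(zero, fill[np.newaxis, :], v)
    else:  # gene_nonzero
        nz_count = (~zero).sum(axis=1)
        empty = nz_count == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} gene(s) are undetected in every cell; left unimputed",
                stacklevel=2,
            )
        fill = v.sum(axis=1) / np.where(empty, 1, nz_count)
        fill = np.where(empty, 0.0, fill)
        v = np.where(zero, fill[:, np.newaxis], v)
    return cells.with_values(v, "raw")


def bulk_transform(matrix: ExpressionMatrix, recipe: PreprocessRecipe | None = None) -> ExpressionMatrix:
    """log2(x+1) then per-observation z-score, as configured by the recipe."""
    recipe = recipe or PreprocessRecipe()
    out = matrix
    if recipe.do_log2:
        out = log2_shift(out)
    if recipe.do_zscore:
        out = zscore_per_observation(out)
    return out


def single_cell_transform(
    cells: ExpressionMatrix, recipe: PreprocessRecipe | None = None
) -> ExpressionMatrix:
    """Full single-cell chain: QC → imputation → log2 → z-score."""
    recipe = recipe or PreprocessRecipe()
    kept = cell_qc_filter(cells, recipe)
    imputed = impute_dropouts(kept, mode=recipe.impute_mode)
    return bulk_transform(imputed, recipe)
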