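"""Synthetic labeled cohorts with planted MSI-informative genes.

The generator emulates FPKM/TPM-like continuous expression: gene g's raw
value in sample s is ``exp(N(mu_g + shift, sigma_g)) - 1`` clamped at 0,
with baseline log-mean ``mu_g ~ N(base_log_mean, 1)`` and log-sd
``sigma_g = base_log_sd``.  Planted informative genes add a mean shift of
``effect_size * sigma_g`` in MSI samples; half of them are down-regulated
(negative shift) so direction folding in the selection stages is exercised.
Informative genes are planted among genes with ``mu_g >= 1`` — real MSI
biomarkers are detectably expressed genes, and this keeps the planted truth
orthogonal to the low-expression blacklist stage.

Single-cell samples reuse the same seed-derived gene parameters as the bulk
generator, so a model trained on a simulated bulk cohort can score simulated
cells over a shared gene universe.  Dropout is independent per entry; a
configurable fraction of cells is forced to very high dropout to exercise
the detected-fraction QC rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_matrix import ExpressionMatrix, LabeledCohort


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the package's reference conditions."""

    n_genes: int = 500
    n_informative: int = 20
    n_msi: int = 60
    n_mss: int = 90
    effect_size: float = 2.0  # mean shift in units of log-scale sd
    base_log_mean: float = 2.0
    base_log_sd: float = 0.5
    sc_cells_per_sample: int = 200
    sc_dropout_rate: float = 0.30
    sc_msi_fraction_range: tuple[float, float] = (0.70, 0.95)
    sc_mss_fraction_range: tuple[float, float] = (0.00, 0.10)
    sc_low_quality_fraction: float = 0.10
    sc_low_quality_dropout: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValidationError("n_informative cannot exceed n_genes")
        if min(self.n_genes, self.n_msi, self.n_mss, self.sc_cells_per_sample) < 1:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.sc_dropout_rate < 1.0:
            raise ValidationError("sc_dropout_rate must be in [0, 1)")
        if self.base_log_sd <= 0:
            raise ValidationError("base_log_sd must be positive")
        for lo, hi in (self.sc_msi_fraction_range, self.sc_mss_fraction_range):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValidationError("cell-fraction ranges must satisfy 0 <= lo <= hi <= 1")


def _gene_params(config: SimulationConfig):
    """Seed-derived gene universe shared by the bulk and single-cell modes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    mu = rng.normal(config.base_log_mean, 1.0, size=config.n_genes)
    sigma = np.full(config.n_genes, config.base_log_sd)
    expressed = np.flatnonzero(mu >= 1.0)
    if expressed.size < config.n_informative:
        raise ValidationError(
            "too few expressed genes to plant informative genes; "
            "raise base_log_mean or n_genes"
        )
    informative = np.sort(rng.choice(expressed, size=config.n_informative, replace=False))
    # half the planted genes are down-regulated in MSI samples
    signs = np.ones(config.n_informative)
    down = rng.choice(
        config.n_informative, size=config.n_informative // 2, replace=False
    )
    signs[down] = -1.0
    shift = np.zeros(config.n_genes)
    shift[informative] = signs * config.effect_size * sigma[informative]
    return gene_ids, mu, sigma, informative, shift


def _sample_rng(config: SimulationConfig, sample_seed: int | None, mode_tag: int):
    """Noise stream for sample/cell draws, independent of the gene universe.

    ``sample_seed`` lets callers draw replicate cohorts (e.g. a held-out test
    set) over the SAME gene universe; the mode tag keeps bulk and
    single-cell noise streams distinct.
    """
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 + mode_tag, sample_seed or 0])
    )


def _draw_profiles(
    rng: np.random.Generator,
    mu: np.ndarray,
    sigma: np.ndarray,
    shift: np.ndarray,
    is_msi_like: np.ndarray,
) -> np.ndarray:
    """Raw genes-by-observations values for a vector of MSI-like flags."""
    n_obs = is_msi_like.size
    means = mu[:, None] + shift[:, None] * is_msi_like[None, :].astype(float)
    logv = rng.normal(means, sigma[:, None], size=(mu.size, n_obs))
    return np.maximum(np.exp(logv) - 1.0, 0.0)


def simulate_bulk(
    config: SimulationConfig, sample_seed: int | None = None
) -> tuple[LabeledCohort, list[str]]:
    """Generate a labeled bulk cohort; returns (cohort, planted gene ids).

    ``sample_seed`` draws an independent replicate cohort (fresh sample
    noise) over the same seed-derived gene universe — use it for held-out
    test sets.
    """
    gene_ids, mu, sigma, informative, shift = _gene_params(config)
    rng = _sample_rng(config, sample_seed, mode_tag=0)
    m = config.n_msi + config.n_mss
    obs_ids = [f"S{j:04d}" for j in range(m)]
    is_msi = np.zeros(m, dtype=bool)
    is_msi[rng.choice(m, size=config.n_msi, replace=False)] = True
    values = _draw_profiles(rng, mu, sigma, shift, is_msi)
    matrix = ExpressionMatrix(gene_ids, obs_ids, values, value_kind="raw")
    labels = {o: ("MSI" if f else "MSS") for o, f in zip(obs_ids, is_msi)}
    truth = [gene_ids[i] for i in informative]
    return LabeledCohort(matrix, labels), truth


def simulate_single_cell(
    config: SimulationConfig,
    fractions: Sequence[float] | None = None,
    n_msi_samples: int = 10,
    n_mss_samples: int = 10,
    sample_seed: int | None = None,
) -> tuple[list[tuple[str, ExpressionMatrix, str]], list[str]]:
    """Generate single-cell samples; returns ([(id, cells, label)], truth).

    Each sample's cells are bulk-style profiles that are MSI-like with the
    sample's cell fraction; the fraction is drawn from the config's MSI or
    MSS range unless ``fractions`` overrides it (then the sample label is
    MSI iff fraction > 0.5).  Per-entry dropout zeros values with
    probability ``sc_dropout_rate``; a ``sc_low_quality_fraction`` of cells
    gets ``sc_low_quality_dropout`` instead, pushing them under the
    detected-fraction QC bar.
    """
    gene_ids, mu, sigma, informative, shift = _gene_params(config)
    rng = _sample_rng(config, sample_seed, mode_tag=1)
    truth = [gene_ids[i] for i in informative]

    if fractions is None:
        fracs = np.concatenate(
            [
                rng.uniform(*config.sc_msi_fraction_range, size=n_msi_samples),
                rng.uniform(*config.sc_mss_fraction_range, size=n_mss_samples),
            ]
        )
    else:
        fracs = np.asarray(fractions, dtype=np.float64)
        if np.any((fracs < 0) | (fracs > 1)):
            raise ValidationError("cell fractions must lie in [0, 1]")

    samples: list[tuple[str, ExpressionMatrix, str]] = []
    n_cells = config.sc_cells_per_sample
    for si, frac in enumerate(fracs):
        label = "MSI" if frac > 0.5 else "MSS"
        sample_id = f"SC{si:03d}"
        cell_ids = [f"{sample_id}_C{c:04d}" for c in range(n_cells)]
        msi_like = rng.uniform(size=n_cells) < frac
        values = _draw_profiles(rng, mu, sigma, shift, msi_like)
        dropout = np.full(n_cells, config.sc_dropout_rate)
        low_q = rng.uniform(size=n_cells) < config.sc_low_quality_fraction
        dropout[low_q] = config.sc_low_quality_dropout
        drop_mask = rng.uniform(size=values.shape) < dropout[None, :]
        values = np.where(drop_mask, 0.0, values)
        cells = ExpressionMatrix(gene_ids, cell_ids, values, value_kind="raw")
        samples.append((sample_id, cells, label))
    return samples, truth
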