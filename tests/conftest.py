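import numpy as np
import pytest

from msirna.io_matrix import ExpressionMatrix, LabeledCohort
from msirna.gene_select import SelectionThresholds, select_informative_genes
from msirna.preprocess import bulk_transform
from msirna.classifier import train
from msirna.simulate import SimulationConfig, simulate_bulk


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
    return ExpressionMatrix(["g1", "g2", "g3"], ["S1", "S2"], values)


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference simulated bulk cohort: 500 genes, 20 planted at 2 sd."""
    config = SimulationConfig(seed=1)
    cohort, truth = simulate_bulk(config)
    return cohort, truth, config


@pytest.fixture(scope="session")
def reference_selection(reference_cohort):
    cohort, truth, config = reference_cohort
    gene_set, records = select_informative_genes(cohort, SelectionThresholds(seed=1))
    return gene_set, records


@pytest.fixture(scope="session")
def reference_model(reference_cohort, reference_selection):
    cohort, truth, config = reference_cohort
    gene_set, _ = reference_selection
    z = bulk_transform(cohort.matrix).subset_genes(gene_set.gene_ids)
    return train(LabeledCohort(z, cohort.labels), seed=1)
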