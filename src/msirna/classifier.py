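"""MSI classification: SMOTE balancing, a Platt-calibrated RBF SVM, Youden
threshold calibration, JSON model persistence, and bulk prediction.

The trained artifact stores every learned constant (support vectors, dual
coefficients, intercept, kernel width, Platt sigmoid) in plain JSON, so a
model predicts identically after a save/load round-trip and the file can be
consumed from any language.  The MSI probability of a sample x is

    p(x) = 1 / (1 + exp(a * f(x) + b)),   f(x) = sum_i c_i K(s_i, x) + rho

with K the RBF kernel; ``a`` and ``b`` come from Platt scaling fitted on
internally cross-validated decision values.  The classification threshold
maximizes the Youden index J = sensitivity + specificity - 1 on the
original (pre-SMOTE) training samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from . import __version__
from .errors import ModelFormatError, ValidationError
from .io_matrix import ExpressionMatrix, LabeledCohort
from .preprocess import PreprocessRecipe, bulk_transform

MODEL_FORMAT_VERSION = 1

#: fraction of model genes that may be absent at predict time before failing
MISSING_GENE_TOLERANCE = 0.10


@dataclass
class PredictionResult:
    obs_id: str
    msi_score: float
    status: str  # MSI iff msi_score >= threshold


@dataclass
class MSIModel:
    """Trained MSI classifier with inlined learned constants."""

    genes: list[str]
    kernel: str
    gamma: float
    C: float
    support_vectors: np.ndarray  # (n_sv, n_genes)
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    platt_a: float
    platt_b: float
    threshold: float
    recipe: PreprocessRecipe = field(default_factory=PreprocessRecipe)
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes or len(set(self.genes)) != len(self.genes):
            raise ValidationError("model genes must be non-empty and unique")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.kernel != "rbf":
            raise ValidationError(f"unsupported kernel {self.kernel!r}")
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.dual_coef = np.asarray(self.dual_coef, dtype=np.float64).ravel()
        if self.support_vectors.shape != (self.dual_coef.size, len(self.genes)):
            raise ValidationError("support vector / dual coefficient shape mismatch")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """RBF decision values for samples-by-genes features ``X``."""
        X = np.asarray(X, dtype=np.float64)
        sq = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def score_features(self, X: np.ndarray) -> np.ndarray:
        """MSI probabilities for samples-by-genes features ``X``."""
        f = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(self.platt_a * f + self.platt_b))


def smote_balance(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity with SMOTE interpolation.

    Each synthetic point is ``x + u * (x_nn - x)`` for a uniformly chosen
    minority sample ``x``, one of its ``k`` nearest minority neighbors
    ``x_nn`` (Euclidean), and ``u ~ Uniform(0, 1)``.  Majority rows and the
    original minority rows are returned untouched, in their input order,
    followed by the synthetic rows.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if k < 1:
        raise ValidationError("SMOTE requires k >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"SMOTE requires exactly 2 classes, got {classes.size}")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    min_idx = np.flatnonzero(y == minority)
    if min_idx.size < 2:
        raise ValidationError("SMOTE needs >= 2 minority samples to interpolate")
    if k > min_idx.size - 1:
        warnings.warn(
            f"SMOTE k={k} exceeds minority size - 1; clamped to {min_idx.size - 1}",
            stacklevel=2,
        )
        k = min_idx.size - 1
    Xmin = X[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neighbors = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, Xmin.shape[0], size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    anchors = Xmin[base]
    partners = Xmin[neighbors[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def youden_threshold(scores, labels) -> float:
    """Cutpoint maximizing J(t) = sensitivity(t) + specificity(t) - 1.

    Candidates are the midpoints of adjacent distinct sorted scores plus the
    0 and 1 boundaries; a sample is called MSI when its score >= t.  Ties in
    J resolve toward the larger threshold (higher specificity).  Emits a
    warning when no cutpoint achieves J > 0.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = _as_binary_labels(labels)
    if s.size != y.size:
        raise ValidationError("scores and labels must align")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("Youden threshold requires both classes present")
    distinct = np.unique(s)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    best_t, best_j = 0.5, -np.inf
    for t in candidates:
        called = s >= t
        sens = (called & (y == 1)).sum() / n_pos
        spec = (~called & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = float(t), float(j)
    if best_j <= 0:
        warnings.warn(
            f"no cutpoint separates the classes (best Youden J = {best_j:.3f})",
            stacklevel=2,
        )
    return best_t


def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        return np.array([1 if v == "MSI" else 0 for v in arr], dtype=np.int64)
    return arr.astype(np.int64)


def train(
    cohort: LabeledCohort,
    seed: int = 0,
    smote_k: int = 5,
    recipe: PreprocessRecipe | None = None,
) -> MSIModel:
    """Train the MSI classifier on a z-scored, gene-restricted cohort.

    The cohort matrix must already be per-sample z-scored and restricted to
    (and ordered by) the informative gene list.  Training data is SMOTE
    balanced; the Youden threshold is calibrated on the original, unbalanced
    samples so synthetic points cannot distort the operating point.
    """
    cohort.require_both_classes()
    if cohort.matrix.value_kind != "zscore":
        raise ValidationError(
            f"train expects z-scored values, got {cohort.matrix.value_kind!r}"
        )
    X = cohort.matrix.values.T  # samples x genes
    y = cohort.label_array()
    Xb, yb = smote_balance(X, y, k=smote_k, seed=seed)

    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        method="sigmoid",
        ensemble=False,
    )
    clf.fit(Xb, yb)
    cal = clf.calibrated_classifiers_[0]
    svc: SVC = cal.estimator
    sigmoid = cal.calibrators[0]

    model = MSIModel(
        genes=list(cohort.matrix.gene_ids),
        kernel="rbf",
        gamma=float(svc._gamma),
        C=float(svc.C),
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        intercept=float(svc.intercept_[0]),
        platt_a=float(sigmoid.a_),
        platt_b=float(sigmoid.b_),
        threshold=0.5,  # placeholder until calibrated below
        recipe=recipe or PreprocessRecipe(),
        training_summary={
            "m": cohort.m,
            "n": cohort.n,
            "seed": seed,
            "smote_k": smote_k,
            "software_version": __version__,
        },
    )
    # calibrate on the ORIGINAL samples, not the SMOTE-augmented set
    scores = model.score_features(X)
    t = youden_threshold(scores, y)
    model.threshold = float(np.clip(t, 1e-9, 1.0 - 1e-9))
    return model


def score_matrix(model: MSIModel, matrix: ExpressionMatrix) -> np.ndarray:
    """MSI probabilities for a raw genes-by-observations matrix.

    The model's preprocessing recipe is applied over ALL genes present in
    the input (per-observation z-scores depend on the full panel), then the
    matrix is restricted to the model genes in model order.  Up to 10% of
    model genes may be absent; their z-scores are imputed as 0 (the
    cohort-neutral value) with a warning.
    """
    if matrix.value_kind != "raw":
        raise ValidationError(f"prediction expects raw values, got {matrix.value_kind!r}")
    transformed = bulk_transform(matrix, model.recipe)
    present = set(transformed.gene_ids)
    missing = [g for g in model.genes if g not in present]
    if len(missing) > MISSING_GENE_TOLERANCE * len(model.genes):
        raise ValidationError(
            f"{len(missing)} of {len(model.genes)} model genes absent from input "
            f"(> {MISSING_GENE_TOLERANCE:.0%} tolerance): {missing}"
        )
    gi = transformed.gene_index()
    X = np.zeros((matrix.n_obs, len(model.genes)))
    for j, g in enumerate(model.genes):
        if g in gi:
            X[:, j] = transformed.values[gi[g], :]
    if missing:
        warnings.warn(
            f"{len(missing)} model gene(s) absent; z-scores imputed as 0: {missing}",
            stacklevel=2,
        )
    return model.score_features(X)


def predict(model: MSIModel, matrix: ExpressionMatrix) -> list[PredictionResult]:
    """Score a raw bulk matrix and call MSI/MSS status per sample."""
    scores = score_matrix(model, matrix)
    return [
        PredictionResult(
            obs_id=o,
            msi_score=float(s),
            status="MSI" if s >= model.threshold else "MSS",
        )
        for o, s in zip(matrix.obs_ids, scores)
    ]


def save_model(model: MSIModel, path: str | Path) -> None:
    """Serialize to versioned JSON with all learned constants inlined."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "genes": model.genes,
        "kernel": model.kernel,
        "gamma": model.gamma,
        "C": model.C,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "platt_a": model.platt_a,
        "platt_b": model.platt_b,
        "threshold": model.threshold,
        "recipe": model.recipe.to_dict(),
        "training_summary": model.training_summary,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> MSIModel:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{Path(path).name}: not valid model JSON ({exc})") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ModelFormatError(f"{Path(path).name}: missing format_version")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{Path(path).name}: format version {doc['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    try:
        return MSIModel(
            genes=list(doc["genes"]),
            kernel=doc["kernel"],
            gamma=doc["gamma"],
            C=doc["C"],
            support_vectors=np.array(doc["support_vectors"], dtype=np.float64),
            dual_coef=np.array(doc["dual_coef"], dtype=np.float64),
            intercept=doc["intercept"],
            platt_a=doc["platt_a"],
            platt_b=doc["platt_b"],
            threshold=doc["threshold"],
            recipe=PreprocessRecipe.from_dict(doc["recipe"]),
            training_summary=dict(doc.get("training_summary", {})),
        )
    except KeyError as exc:
        raise ModelFormatError(f"{Path(path).name}: missing field {exc}") from exc
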