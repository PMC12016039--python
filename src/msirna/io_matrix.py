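"""Expression-matrix, label, and sidecar-file I/O.

The universal in-memory currency is :class:`ExpressionMatrix`: a dense
genes × observations grid with unique row and column identifiers.  Matrices
round-trip through TSV/CSV (first column = gene symbol, first row =
observation ids) and MatrixMarket coordinate files with ``genes.tsv`` /
``barcodes.tsv`` sidecars (the dominant single-cell convention).  Values are
written with 12 significant digits so a round-trip is stable to well below
1e-9 relative error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

VALUE_KINDS = ("raw", "log2", "zscore")

#: status strings accepted in label files; MSI-H is the clinical synonym for MSI
_LABEL_ALIASES = {"MSI": "MSI", "MSI-H": "MSI", "MSS": "MSS"}


@dataclass
class ExpressionMatrix:
    """Dense genes × observations expression grid.

    Parameters
    ----------
    gene_ids
        Ordered unique gene symbols (rows).
    obs_ids
        Ordered unique sample or cell identifiers (columns).
    values
        Float array of shape ``(len(gene_ids), len(obs_ids))``.  Must be
        non-negative and finite while ``value_kind == "raw"``.
    value_kind
        Transformation state: ``raw``, ``log2`` (after log2(x+1)) or
        ``zscore`` (after per-observation standardization).
    """

    gene_ids: list[str]
    obs_ids: list[str]
    values: np.ndarray
    value_kind: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array (genes x observations)")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id {dup!r}")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            dup = _first_duplicate(self.obs_ids)
            raise ValidationError(f"duplicate observation id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if self.value_kind == "raw" and np.any(self.values < 0):
            g, o = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[g, o]} at gene {self.gene_ids[g]!r}, "
                f"observation {self.obs_ids[o]!r} (raw matrices must be non-negative)"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row subset/reorder by gene id; missing ids raise."""
        idx = self.gene_index()
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.obs_ids), self.values[rows, :], self.value_kind
        )

    def subset_obs(self, obs_ids: list[str]) -> "ExpressionMatrix":
        idx = {o: j for j, o in enumerate(self.obs_ids)}
        missing = [o for o in obs_ids if o not in idx]
        if missing:
            raise ValidationError(f"observations absent from matrix: {missing[:10]}")
        cols = [idx[o] for o in obs_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(obs_ids), self.values[:, cols], self.value_kind
        )

    def with_values(self, values: np.ndarray, value_kind: str) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.obs_ids), values, value_kind)


@dataclass
class LabeledCohort:
    """An expression matrix plus one MSI/MSS label per observation.

    ``m`` is the total sample count and ``n`` the MSI count; informative-gene
    selection and training require ``0 < n < m``.
    """

    matrix: ExpressionMatrix
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [o for o in self.matrix.obs_ids if o not in self.labels]
        if missing:
            raise ValidationError(f"observations without a label: {missing[:10]}")
        bad = {s for s in self.labels.values() if s not in ("MSI", "MSS")}
        if bad:
            raise ValidationError(f"labels must be MSI or MSS, got {sorted(bad)}")

    @property
    def m(self) -> int:
        """Total number of labeled samples in the matrix."""
        return self.matrix.n_obs

    @property
    def n(self) -> int:
        """Number of MSI samples in the matrix."""
        return sum(1 for o in self.matrix.obs_ids if self.labels[o] == "MSI")

    def label_array(self) -> np.ndarray:
        """Labels aligned to matrix column order, 1 = MSI, 0 = MSS."""
        return np.array(
            [1 if self.labels[o] == "MSI" else 0 for o in self.matrix.obs_ids],
            dtype=np.int64,
        )

    def require_both_classes(self) -> None:
        if not 0 < self.n < self.m:
            raise ValidationError(
                f"both classes required: cohort has {self.n} MSI of {self.m} samples"
            )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    if Path(path).is_dir():
        return "mtx"
    raise ValidationError(f"cannot infer matrix format from path {path!s}")


def _collapse_duplicate_genes(
    gene_ids: list[str], values: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Keep, for each duplicated symbol, the row with the highest mean."""
    if len(set(gene_ids)) == len(gene_ids):
        return gene_ids, values
    means = values.mean(axis=1)
    best: dict[str, int] = {}
    for i, g in enumerate(gene_ids):
        if g not in best or means[i] > means[best[g]]:
            best[g] = i
    keep = sorted(best.values())
    n_dropped = len(gene_ids) - len(keep)
    logger.warning(
        "collapsed %d duplicate gene rows (kept highest-mean row per symbol)", n_dropped
    )
    return [gene_ids[i] for i in keep], values[keep, :]


def read_matrix(
    path: str | Path,
    format: str | None = None,
    orientation: str = "genes_by_obs",
) -> ExpressionMatrix:
    """Read a raw expression matrix from TSV/CSV or MatrixMarket files.

    For dense text the first column holds gene symbols and the first
    non-comment row holds observation ids.  For ``mtx``, ``path`` is either
    the ``.mtx`` file or a directory containing ``matrix.mtx``; sidecar files
    ``genes.tsv`` and ``barcodes.tsv`` must sit alongside it.  With
    ``orientation="obs_by_genes"`` the file is transposed on read.
    Duplicate gene rows are collapsed to the highest-mean row.
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format not in ("tsv", "csv", "mtx"):
        raise ValidationError(f"unknown matrix format {format!r}")
    if orientation not in ("genes_by_obs", "obs_by_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")

    if format == "mtx":
        gene_ids, obs_ids, values = _read_mtx(path)
    else:
        gene_ids, obs_ids, values = _read_dense(path, sep="\t" if format == "tsv" else ",")

    if orientation == "obs_by_genes":
        gene_ids, obs_ids = obs_ids, gene_ids
        values = values.T

    if len(set(obs_ids)) != len(obs_ids):
        raise ValidationError(
            f"duplicate observation id {_first_duplicate(obs_ids)!r} in {path.name}"
        )
    gene_ids, values = _collapse_duplicate_genes(gene_ids, values)
    return ExpressionMatrix(gene_ids, obs_ids, values, value_kind="raw")


def _read_dense(path: Path, sep: str) -> tuple[list[str], list[str], np.ndarray]:
    if not path.exists():
        raise ValidationError(f"matrix file not found: {path}")
    # header parsed by hand: pandas silently renames duplicate column names,
    # which would mask a duplicate-observation error
    header: list[str] | None = None
    header_lineno = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split(sep)
            header_lineno = lineno
            break
    if header is None:
        raise ParseError(f"{path.name}: no header line found")
    if len(header) < 2:
        raise ParseError(
            f"{path.name}: malformed header at line {header_lineno} "
            f"(expected gene column plus at least one observation)"
        )
    obs_ids = [h.strip() for h in header[1:]]
    try:
        df = pd.read_csv(
            path, sep=sep, comment="#", index_col=0, header=0, dtype=str
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.shape[1] != len(obs_ids):
        raise ParseError(
            f"{path.name}: ragged rows (header has {len(obs_ids)} observations, "
            f"data has {df.shape[1]} columns)"
        )
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ParseError(f"{path.name}: non-numeric value in matrix body ({exc})") from exc
    return [str(g) for g in df.index], obs_ids, values


def _read_mtx(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    if path.is_dir():
        mtx_path = path / "matrix.mtx"
    else:
        mtx_path = path
    base = mtx_path.parent
    genes_path = base / "genes.tsv"
    barcodes_path = base / "barcodes.tsv"
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise ValidationError(f"required MTX component not found: {p}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise ParseError(f"{mtx_path.name}: {exc}") from exc
    values = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
    )
    gene_ids = _read_sidecar(genes_path)
    obs_ids = _read_sidecar(barcodes_path)
    if values.shape != (len(gene_ids), len(obs_ids)):
        raise ParseError(
            f"{mtx_path.name}: matrix is {values.shape} but sidecars list "
            f"{len(gene_ids)} genes and {len(obs_ids)} barcodes"
        )
    return gene_ids, obs_ids, values


def _read_sidecar(path: Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0])
    if not out:
        raise ParseError(f"{path.name}: empty sidecar file")
    return out


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """Write a matrix; ``read_matrix`` recovers it to ≥10 significant digits.

    ``header_lines`` are emitted as ``#``-prefixed provenance comments.
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "mtx":
        _write_mtx(matrix, path)
        return
    sep = "\t" if format == "tsv" else ","
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("gene" + sep + sep.join(matrix.obs_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + sep + sep.join(f"{v:.12g}" for v in row) + "\n")


def _write_mtx(matrix: ExpressionMatrix, path: Path) -> None:
    if path.suffix.lower() == ".mtx":
        base = path.parent
        mtx_path = path
    else:
        base = path
        base.mkdir(parents=True, exist_ok=True)
        mtx_path = base / "matrix.mtx"
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(mtx_path), sparse, precision=12)
    (base / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
    (base / "barcodes.tsv").write_text("\n".join(matrix.obs_ids) + "\n", encoding="utf-8")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample id, status) file; MSI-H normalizes to MSI."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"label file not found: {path}")
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split(",")
            if len(fields) < 2:
                raise ParseError(
                    f"{path.name}: line {lineno}: expected two delimited columns"
                )
            sample, status = fields[0].strip(), fields[1].strip()
            if sample in labels:
                raise ValidationError(f"{path.name}: duplicate sample id {sample!r}")
            if status.upper() not in _LABEL_ALIASES:
                raise ValidationError(
                    f"{path.name}: line {lineno}: unknown status {status!r} "
                    f"(expected MSI, MSI-H, or MSS)"
                )
            labels[sample] = _LABEL_ALIASES[status.upper()]
    if not labels:
        raise ValidationError(f"{path.name}: no labels found")
    return labels


def write_labels(
    labels: Mapping[str, str], path: str | Path, header_lines: list[str] | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for sample, status in labels.items():
            fh.write(f"{sample}\t{status}\n")
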