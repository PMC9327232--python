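"""Reading, writing and summarising expression data and prior networks.

On-disk conventions
-------------------
Expression matrices are TSV/CSV with probes (features) as rows: the first
column is ``probe_id`` and the remaining column headers are sample ids
(GEO series-matrix style).  Internally samples index rows.  The loader
auto-detects a transposed file by matching ids against the label file.

Labels are two-column TSV ``sample_id<TAB>label`` with ``label`` in
``{0, 1}``.  Prior networks are three-column TSV
``feature_a<TAB>feature_b<TAB>weight`` with nonnegative weights,
GeneMANIA-style.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from graphsel.errors import (
    DuplicateFeatureError,
    NegativeWeightError,
    NonNumericValueError,
    SampleAlignmentError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SIGNIFICANCE_CATEGORIES = ("ns", "*", "**", "***")


@dataclass
class ExpressionDataset:
    """A samples x features expression matrix with binary class labels.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_features)
        Expression levels; no missing values.
    labels : ndarray of shape (n_samples,)
        Per-sample class in {0, 1}.
    feature_ids : list of str
        Unique probe identifiers, one per column of ``values``.
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        m, n = self.values.shape
        if len(self.labels) != m or len(self.sample_ids) != m:
            raise ValidationError("labels/sample_ids length does not match matrix rows")
        if len(self.feature_ids) != n:
            raise ValidationError("feature_ids length does not match matrix columns")
        if len(set(self.feature_ids)) != n:
            raise ValidationError("feature ids are not unique")
        if len(set(self.sample_ids)) != m:
            raise ValidationError("sample ids are not unique")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be in {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids: list[str]) -> "ExpressionDataset":
        """Return a copy restricted to ``feature_ids``, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return ExpressionDataset(
            values=self.values[:, cols].copy(),
            labels=self.labels.copy(),
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PriorNetwork:
    """Sparse symmetric nonnegative feature-feature weights.

    ``weights`` maps sorted id pairs to a weight > 0; symmetry is implied
    by the unordered key.  ``n_self_edges``/``n_unmapped`` count rows that
    were dropped during loading.
    """

    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    n_self_edges: int = 0
    n_unmapped: int = 0

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.weights.get(self._key(a, b), default)

    def n_edges(self) -> int:
        return len(self.weights)

    def restrict(self, universe: set[str]) -> "PriorNetwork":
        """Keep only edges with both endpoints in ``universe``."""
        kept = {k: w for k, w in self.weights.items() if k[0] in universe and k[1] in universe}
        return PriorNetwork(weights=kept)


@dataclass
class DatasetSummary:
    n_samples: int
    n_pos: int
    n_neg: int
    n_features: int
    imbalance_ratio: float


def _read_table(path, index_col=0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col, dtype=str)


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a two-column sample_id/label TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise SampleAlignmentError(f"label file {path} needs two columns")
    # tolerate a header row
    if df.iloc[0, 1] not in ("0", "1"):
        df = df.iloc[1:]
    sample_ids = df.iloc[:, 0].tolist()
    try:
        labels = df.iloc[:, 1].astype(int).to_numpy()
    except ValueError as exc:
        raise SampleAlignmentError(f"non-binary label in {path}: {exc}") from exc
    if not set(labels) <= {0, 1}:
        raise SampleAlignmentError("labels must be 0 or 1")
    return sample_ids, labels


def read_expression(matrix_path, labels_path) -> ExpressionDataset:
    """Load an expression matrix and its label file into a dataset.

    The matrix is expected with features as rows and sample ids as the
    header, but a transposed file is detected and fixed by matching ids
    against the label file.  Samples follow label-file order.

    Raises
    ------
    SampleAlignmentError
        If sample ids cannot be matched between the two files.
    NonNumericValueError
        If a cell does not parse as a float.
    DuplicateFeatureError
        If a probe id occurs twice.
    """
    sample_ids, labels = read_labels(labels_path)
    df = _read_table(matrix_path)
    sample_set = set(sample_ids)
    if sample_set <= set(df.columns):
        pass  # features are rows, as documented
    elif sample_set <= set(df.index):
        df = df.T  # transposed file: samples were rows
    else:
        missing = sorted(sample_set - set(df.columns))[:5]
        raise SampleAlignmentError(
            f"sample ids {missing} from {labels_path} not found in {matrix_path}"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DuplicateFeatureError(f"duplicate probe ids: {dupes}")
    try:
        values = df[sample_ids].astype(float).to_numpy().T  # samples x features
    except ValueError as exc:
        raise NonNumericValueError(f"non-numeric expression cell: {exc}") from exc
    return ExpressionDataset(
        values=values,
        labels=labels,
        feature_ids=df.index.tolist(),
        sample_ids=list(sample_ids),
    )


def write_expression(ds: ExpressionDataset, matrix_path, labels_path=None) -> None:
    """Write a dataset back to disk (features as rows, full float precision)."""
    df = pd.DataFrame(ds.values.T, index=ds.feature_ids, columns=ds.sample_ids)
    df.index.name = "probe_id"
    sep = "," if str(matrix_path).endswith(".csv") else "\t"
    df.to_csv(matrix_path, sep=sep)
    if labels_path is not None:
        pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels}).to_csv(
            labels_path, sep="\t", header=False, index=False
        )


def read_prior_network(path, feature_universe=None, strict: bool = False) -> PriorNetwork:
    """Read a three-column edge list into a symmetric prior network.

    Duplicate (a, b)/(b, a) rows are averaged, self-edges dropped and
    counted, and rows with an endpoint outside ``feature_universe``
    (when given) counted as unmapped.  Negative weights raise in strict
    mode and are skipped with a warning otherwise.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"prior network {path} needs three columns")
    if not _is_float(df.iloc[0, 2]):
        df = df.iloc[1:]  # header row
    universe = set(feature_universe) if feature_universe is not None else None
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    n_self = n_unmapped = 0
    for a, b, w_str in df.itertuples(index=False):
        try:
            w = float(w_str)
        except ValueError as exc:
            raise ValidationError(f"unparseable weight {w_str!r} in {path}") from exc
        if w < 0:
            if strict:
                raise NegativeWeightError(f"negative weight {w} for edge ({a}, {b})")
            warnings.warn(f"dropping negative-weight edge ({a}, {b}, {w})")
            continue
        if a == b:
            n_self += 1
            continue
        if universe is not None and (a not in universe or b not in universe):
            n_unmapped += 1
            continue
        key = PriorNetwork._key(a, b)
        sums[key] = sums.get(key, 0.0) + w
        counts[key] = counts.get(key, 0) + 1
    weights = {k: sums[k] / counts[k] for k in sums}
    if n_self or n_unmapped:
        logger.info("prior network: dropped %d self-edges, %d unmapped rows", n_self, n_unmapped)
    return PriorNetwork(weights=weights, n_self_edges=n_self, n_unmapped=n_unmapped)


def write_prior_network(net: PriorNetwork, path) -> None:
    rows = sorted(net.weights.items())
    with open(path, "w") as fh:
        for (a, b), w in rows:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def summarize_dataset(ds: ExpressionDataset) -> DatasetSummary:
    """Count samples per class and compute the imbalance ratio n_pos/n_neg.

    The ratio is truncated (not rounded) to 2 decimals, matching how
    unbalance rates are conventionally printed in the microarray cohort
    tables this mirrors (e.g. 26/67 -> 0.38).
    """
    n_pos = int((ds.labels == 1).sum())
    n_neg = int((ds.labels == 0).sum())
    if n_neg == 0:
        raise ValidationError("imbalance ratio undefined: no negative samples")
    return DatasetSummary(
        n_samples=ds.n_samples,
        n_pos=n_pos,
        n_neg=n_neg,
        n_features=ds.n_features,
        imbalance_ratio=math.floor(100.0 * n_pos / n_neg) / 100.0,
    )


def welch_pvalues(ds: ExpressionDataset) -> np.ndarray:
    """Per-feature Welch two-sample t-test p-values (class 1 vs class 0).

    Features with zero variance in both classes get p = 1 when the class
    means are equal and p = 0 when they differ.
    """
    pos = ds.values[ds.labels == 1]
    neg = ds.values[ds.labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("Welch t-test needs at least 2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    both_const = (pos.var(axis=0) == 0) & (neg.var(axis=0) == 0)
    means_equal = pos.mean(axis=0) == neg.mean(axis=0)
    p = np.where(both_const & means_equal, 1.0, p)
    p = np.where(both_const & ~means_equal, 0.0, p)
    return np.nan_to_num(p, nan=1.0)


def ttest_prefilter(ds: ExpressionDataset, keep: int = 100) -> ExpressionDataset:
    """Keep the ``keep`` features with smallest Welch t-test p-values.

    The returned feature order is ascending p-value with lexicographic
    probe-id tie-break; the original column order is not preserved.
    """
    if keep < 1:
        raise ValidationError("keep must be >= 1")
    p = welch_pvalues(ds)
    order = sorted(range(ds.n_features), key=lambda i: (p[i], ds.feature_ids[i]))
    chosen = [ds.feature_ids[i] for i in order[: min(keep, ds.n_features)]]
    return ds.subset_features(chosen)


def categorize_pvalue(p: float) -> str:
    """Map a p-value to a star category with strict thresholds.

    p < 0.001 -> '***', p < 0.01 -> '**', p < 0.05 -> '*', else 'ns'.
    """
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_significance(categories) -> float:
    """Percent of entries in the highest ('***') category, 2 decimals.

    Accepts either star categories or raw p-values (mapped through
    :func:`categorize_pvalue` first).
    """
    items = list(categories)
    if not items:
        raise ValidationError("empty significance list")
    cats = [categorize_pvalue(c) if isinstance(c, (int, float)) else c for c in items]
    bad = [c for c in cats if c not in SIGNIFICANCE_CATEGORIES]
    if bad:
        raise ValidationError(f"unknown significance categories: {bad[:5]}")
    return round(100.0 * cats.count("***") / len(cats), 2)
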