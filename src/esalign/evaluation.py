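"""All-vs-all evaluation: distance matrices, similarity, clustering metrics.

The geodesic distances θ from pairwise comparison are assembled into an
N×N matrix, optionally converted to similarities in (0, 1] by the sigmoid
s(x) = 2 / (1 + exp(αx)), and scored against known class labels by
clustering (k-means, fuzzy c-means, spectral) followed by confusion-matrix
statistics.  The headline statistics are per-class precision, recall and
F-measure plus two Rand-index readings: the accuracy form Σᵢ Mᵢᵢ / Σᵢⱼ Mᵢⱼ
and the standard pair-counting Rand index, both reported because the two
are frequently conflated in the clustering literature.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, SpectralClustering

from .elastic_align import CompareConfig, compare_chains
from .errors import ContractError, RunError
from .structure_io import ChainModel, parse_pdb, select_chain, validate_chain

logger = logging.getLogger(__name__)

CLUSTER_METHODS = ("kmeans", "fuzzy-cmeans", "spectral")


@dataclass
class DistanceMatrix:
    """Symmetric θ matrix with a zero diagonal; NaN marks failed pairs."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ContractError("distance matrix shape must match labels")

    @property
    def n_missing(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = "\t") -> "DistanceMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))


def _as_chain(item: Any) -> tuple[str, ChainModel]:
    if isinstance(item, ChainModel):
        return item.pdb_id, item
    if isinstance(item, tuple) and len(item) == 2 and isinstance(item[1], ChainModel):
        return str(item[0]), item[1]
    # a path to a PDB file
    chain = validate_chain(select_chain(parse_pdb(item)))
    return chain.pdb_id, chain


def distance_matrix(
    structures: Sequence[Any],
    criterion: str = "ESA-CA",
    feature_set: Sequence[str] = (),
    config: CompareConfig | None = None,
    both_directions: bool = False,
    max_missing_fraction: float = 0.2,
) -> DistanceMatrix:
    """θ for every unordered pair of structures (chains, (id, chain) pairs
    or PDB paths).

    By default each pair is compared once and mirrored; with
    ``both_directions`` both orders are computed and averaged.  Failing
    pairs are recorded as NaN; more than ``max_missing_fraction`` missing
    raises :class:`RunError`.
    """
    if len(structures) < 2:
        raise ContractError("need at least 2 structures for a distance matrix")
    named = [_as_chain(s) for s in structures]
    labels = [name for name, _ in named]
    n = len(named)
    values = np.zeros((n, n))
    n_failed = 0
    n_pairs = n * (n - 1) // 2
    for a in range(n):
        for b in range(a + 1, n):
            try:
                theta = compare_chains(
                    named[a][1], named[b][1], criterion=criterion,
                    feature_set=feature_set, config=config,
                ).theta
                if both_directions:
                    theta_ba = compare_chains(
                        named[b][1], named[a][1], criterion=criterion,
                        feature_set=feature_set, config=config,
                    ).theta
                    theta = (theta + theta_ba) / 2.0
            except Exception as exc:
                logger.error("pair (%s, %s) failed: %s", labels[a], labels[b], exc)
                theta = float("nan")
                n_failed += 1
            values[a, b] = values[b, a] = theta
    if n_failed > max_missing_fraction * n_pairs:
        raise RunError(f"{n_failed}/{n_pairs} pairs failed (> {max_missing_fraction:.0%})")
    return DistanceMatrix(labels=labels, values=values)


def sigmoid_similarity(x: float | np.ndarray, alpha: float = 1.0) -> float | np.ndarray:
    """s = 2 / (1 + exp(αx)): maps distance 0 to similarity 1, decreasing to 0."""
    if alpha <= 0:
        raise ContractError("alpha must be > 0")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ContractError("distances must be non-negative")
    out = 2.0 / (1.0 + np.exp(alpha * arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class ConfusionMatrix:
    """Class-level counts: rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ContractError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ContractError("confusion matrix counts must be non-negative")


@dataclass
class MetricsReport:
    """Per-class and aggregate clustering-agreement statistics, all in [0, 1]."""

    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f_measure: float
    ri_accuracy: float
    ri_pairs: float
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f_measure": self.macro_f_measure,
            "ri_accuracy": self.ri_accuracy,
            "ri_pairs": self.ri_pairs,
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.counts.tolist()
            out["class_labels"] = self.confusion.class_labels
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_table(self) -> pd.DataFrame:
        rows = {c: dict(v) for c, v in self.per_class.items()}
        df = pd.DataFrame(rows).T
        df.loc["macro"] = [self.macro_precision, self.macro_recall, self.macro_f_measure]
        return df


def _comb2(x: np.ndarray | float) -> float:
    arr = np.asarray(x, dtype=float)
    return float((arr * (arr - 1) / 2.0).sum())


def pair_counting_rand_index(counts: np.ndarray) -> float:
    """Standard Rand index from a class-by-cluster contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        return 1.0
    total_pairs = n * (n - 1) / 2.0
    agree = total_pairs + 2.0 * _comb2(counts) - _comb2(counts.sum(axis=1)) - _comb2(counts.sum(axis=0))
    return agree / total_pairs


def confusion_metrics(M: ConfusionMatrix | np.ndarray, class_labels: Sequence[str] | None = None) -> MetricsReport:
    """Precision, recall, F per class plus both Rand-index readings.

    precisionᵢ = Mᵢᵢ / (column-i sum), recallᵢ = Mᵢᵢ / (row-i sum),
    Fᵢ = 2PR/(P+R); the accuracy-form RI is Σᵢ Mᵢᵢ / Σᵢⱼ Mᵢⱼ.  Classes
    with an empty row or column get NaN metrics and are excluded from the
    macro averages.
    """
    if not isinstance(M, ConfusionMatrix):
        counts = np.asarray(M)
        labels = list(class_labels) if class_labels else [str(i + 1) for i in range(counts.shape[0])]
        M = ConfusionMatrix(counts=counts, class_labels=labels)
    counts = M.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ContractError("empty confusion matrix")
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    per_class: dict[str, dict[str, float]] = {}
    for i, label in enumerate(M.class_labels):
        precision = counts[i, i] / col[i] if col[i] > 0 else float("nan")
        recall = counts[i, i] / row[i] if row[i] > 0 else float("nan")
        if math.isnan(precision) or math.isnan(recall):
            logger.warning("class %s has an empty row/column; metrics undefined", label)
            f = float("nan")
        elif precision + recall == 0:
            f = 0.0
        else:
            f = 2.0 * precision * recall / (precision + recall)
        per_class[label] = {"precision": precision, "recall": recall, "f_measure": f}
    macro = {
        key: float(np.nanmean([v[key] for v in per_class.values()]))
        for key in ("precision", "recall", "f_measure")
    }
    return MetricsReport(
        per_class=per_class,
        macro_precision=macro["precision"],
        macro_recall=macro["recall"],
        macro_f_measure=macro["f_measure"],
        ri_accuracy=float(np.trace(counts) / total),
        ri_pairs=pair_counting_rand_index(counts),
        confusion=M,
    )


# --- clustering harness ------------------------------------------------------


def classical_mds(D: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson metric MDS: embed a distance matrix in Euclidean space."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_components]
    keep = order[evals[order] > 1e-12]
    if keep.size == 0:  # all points coincide
        return np.zeros((n, max(1, n_components)))
    return evecs[:, keep] * np.sqrt(evals[keep])


def fuzzy_cmeans(
    X: np.ndarray, n_clusters: int, seed: int, m: float = 2.0,
    max_iter: int = 300, tol: float = 1e-6,
) -> np.ndarray:
    """Bezdek fuzzy c-means on an embedded point set; returns hard labels."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    U = rng.random((n, n_clusters))
    U /= U.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = np.maximum(cdist(X, centers, "sqeuclidean"), 1e-12)
        U_new = d2 ** (-1.0 / (m - 1.0))
        U_new /= U_new.sum(axis=1, keepdims=True)
        shift = np.abs(U_new - U).max()
        U = U_new
        if shift < tol:
            break
    return np.argmax(U, axis=1)


def map_clusters_to_classes(
    true_labels: Sequence[Any], cluster_labels: np.ndarray, class_order: Sequence[Any]
) -> ConfusionMatrix:
    """Hungarian maximum-agreement assignment of clusters to classes.

    Builds the class-by-cluster contingency table, permutes the cluster
    columns by the optimal one-to-one assignment, and returns the resulting
    class-by-predicted-class confusion matrix.
    """
    class_index = {c: i for i, c in enumerate(class_order)}
    n_classes = len(class_order)
    n_clusters = int(np.max(cluster_labels)) + 1
    size = max(n_classes, n_clusters)
    contingency = np.zeros((size, size), dtype=int)
    for t, c in zip(true_labels, cluster_labels):
        contingency[class_index[t], int(c)] += 1
    _, col_ind = linear_sum_assignment(-contingency)
    mapped = contingency[:, col_ind]
    return ConfusionMatrix(
        counts=mapped[:n_classes, :n_classes],
        class_labels=[str(c) for c in class_order],
    )


def cluster_and_score(
    D: DistanceMatrix,
    true_labels: Mapping[str, Any] | Sequence[Any],
    method: str = "spectral",
    n_clusters: int | None = None,
    seed: int = 0,
    alpha: float = 1.0,
) -> MetricsReport:
    """Cluster a distance matrix and score against known classes.

    ``spectral`` clusters the sigmoid similarity matrix directly;
    ``kmeans`` and ``fuzzy-cmeans`` run on a classical-MDS embedding of
    the distances (min(N−1, 10) dimensions).  Clusters are mapped to
    classes by Hungarian assignment before computing the metrics.
    Deterministic for a fixed seed.
    """
    if method not in CLUSTER_METHODS:
        raise ContractError(f"unknown clustering method {method!r}; valid: {CLUSTER_METHODS}")
    if D.n_missing:
        raise RunError(f"distance matrix has {D.n_missing} missing entries")
    labels = (
        [true_labels[name] for name in D.labels]
        if isinstance(true_labels, Mapping)
        else list(true_labels)
    )
    if len(labels) != len(D.labels):
        raise ContractError("one true label per structure required")
    class_order = sorted(set(labels), key=str)
    k = n_clusters or len(class_order)

    if method == "spectral":
        S = sigmoid_similarity(D.values, alpha=alpha)
        np.fill_diagonal(S, 1.0)
        if k == 1:
            assignment = np.zeros(len(labels), dtype=int)
        else:
            assignment = SpectralClustering(
                n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans",
            ).fit_predict(S)
    else:
        X = classical_mds(D.values, n_components=min(len(labels) - 1, 10))
        if method == "kmeans":
            assignment = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
        else:
            assignment = fuzzy_cmeans(X, n_clusters=k, seed=seed)

    confusion = map_clusters_to_classes(labels, assignment, class_order)
    return confusion_metrics(confusion)
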