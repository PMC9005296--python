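"""Rank-and-truncate feature selection.

A pluggable stand-in for external feature-selection toolchains: a trio of
base rankers — class-separation F statistic, mutual information on
quantile-discretized features, and variance — each produce a full ranking of
the feature columns, and the rankings are merged by Borda count (ties broken
by column order). ``select_top`` then truncates the matrix to the best k
columns (791 is the canonical choice for the 11,045-dimensional DACC matrix).

An externally produced ranking (e.g. from a dedicated selector) can be
ingested verbatim via ``read_ranking_tsv``, keeping the pipeline decoupled
from any particular ranking engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.metrics import mutual_info_score

from .sequence_io import ConfigError

logger = logging.getLogger(__name__)

Ranker = Callable[[np.ndarray, np.ndarray], np.ndarray]


def f_statistic_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per column; constant columns score -inf."""
    with np.errstate(divide="ignore", invalid="ignore"):
        scores, _ = f_classif(x, y)
    scores = np.asarray(scores, dtype=float)
    scores[~np.isfinite(scores)] = -np.inf
    return scores


def mutual_information_scores(
    x: np.ndarray, y: np.ndarray, bins: int = 8
) -> np.ndarray:
    """Mutual information between each quantile-discretized column and y."""
    scores = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
        disc = np.searchsorted(edges, col, side="right")
        scores[j] = mutual_info_score(disc, y)
    return scores


def variance_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Variance of each min-max scaled column.

    Scaling to [0, 1] first makes the criterion favor columns whose mass sits
    far from the column center (e.g. bimodal, class-separated columns) rather
    than columns that merely have large units.
    """
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0] = 1.0
    return ((x - lo) / span).var(axis=0)


DEFAULT_RANKERS: dict[str, Ranker] = {
    "f_statistic": f_statistic_scores,
    "mutual_information": mutual_information_scores,
    "variance": variance_scores,
}


@dataclass
class FeatureRanking:
    """Columns ordered best first, with per-ranker raw scores for audit."""

    ordered: list[str]
    scores: pd.DataFrame  # index = column labels, one column per ranker

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"{i + 1}\t{label}" for i, label in enumerate(self.ordered)]
        Path(path).write_text("\n".join(lines) + "\n")


def read_ranking_tsv(path: str | Path) -> FeatureRanking:
    """Ingest an external (rank, column-label) TSV verbatim."""
    ordered = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigError(f"{path}:{lineno}: expected 2 tab-separated columns")
        ordered.append(parts[1])
    return FeatureRanking(ordered, pd.DataFrame(index=ordered))


def rank_features(
    matrix: pd.DataFrame,
    labels: Sequence[str] | np.ndarray,
    rankers: Mapping[str, Ranker] | None = None,
) -> FeatureRanking:
    """Borda-aggregate the base rankers into one full column ranking.

    Each ranker scores every column; scores are converted to a ranking
    (stable, ties kept in column order) and each column earns
    ``n_columns - rank`` Borda points per ranker. Totals decide the final
    order; Borda ties break on the raw scores themselves and only fully tied
    columns fall back to input column order, so the result is deterministic,
    invariant to row shuffling, and (for columns with distinct scores)
    invariant to column order.
    """
    if matrix.shape[1] < 2:
        raise ConfigError("ranking requires at least 2 feature columns")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ConfigError("both classes must be present to rank features")
    if len(y) != len(matrix):
        raise ConfigError("labels and matrix rows misaligned")
    if rankers is None:
        rankers = DEFAULT_RANKERS
    x = matrix.to_numpy(dtype=float)
    n_cols = x.shape[1]

    constant = x.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "%d constant feature column(s) ranked last: %s",
            constant.sum(),
            list(matrix.columns[constant][:5]),
        )

    score_table = pd.DataFrame(index=matrix.columns)
    borda = np.zeros(n_cols)
    for name, ranker in rankers.items():
        scores = np.asarray(ranker(x, y), dtype=float)
        scores = np.where(constant, -np.inf, scores)
        score_table[name] = scores
        # stable argsort on descending score; ties stay in column order
        order = np.argsort(-scores, kind="stable")
        ranks = np.empty(n_cols, dtype=int)
        ranks[order] = np.arange(n_cols)
        borda += n_cols - ranks
    # final order: Borda total, then raw scores (so columns with genuinely
    # different scores sort the same way regardless of input column order),
    # then column order as the last resort for fully tied columns
    score_matrix = score_table.to_numpy()
    final_order = sorted(
        range(n_cols),
        key=lambda i: (-borda[i], tuple(-score_matrix[i]), i),
    )
    ordered = [matrix.columns[i] for i in final_order]
    return FeatureRanking(ordered, score_table)


def select_top(matrix: pd.DataFrame, ranking: FeatureRanking, k: int) -> pd.DataFrame:
    """Restrict the matrix to the top-k ranked columns.

    Row order and the matrix's own column order are preserved (only
    membership is decided by the ranking), so selecting all columns is the
    identity and top-k sets are nested in k.
    """
    if not 1 <= k <= matrix.shape[1]:
        raise ConfigError(
            f"k must be between 1 and {matrix.shape[1]} columns, got {k}"
        )
    keep = set(ranking.ordered[:k])
    unknown = keep - set(matrix.columns)
    if unknown:
        raise ConfigError(f"ranking names unknown columns: {sorted(unknown)[:5]}")
    return matrix[[c for c in matrix.columns if c in keep]]
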