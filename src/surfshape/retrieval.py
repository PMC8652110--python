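"""Retrieval statistics over a dissimilarity matrix and a class hierarchy.

Given an N x N pairwise dissimilarity matrix and class labels at one or
more hierarchical levels, this module computes the standard shape
retrieval statistics: Nearest Neighbor (NN), First Tier (FT), Second
Tier (ST), Mean Average Precision (MAP) and the interpolated
precision-recall curve, plus the conformer-tracking count (number of
same-class members within the top-k ranked targets of each query).

Conventions (all switchable where noted):

* a query is always excluded from its own ranking;
* ties in dissimilarity are broken by ascending original index;
* FT considers the first ``|C| - 1`` targets, ST the first
  ``2|C| - 1`` (the literal second-tier window; ``st_window="2(|C|-1)"``
  selects the alternative convention);
* FT/ST denominators are ``|C| - 1`` (relevant targets excluding the query);
* classes of size 1 are excluded from the averages with a warning;
* precision-recall uses max-precision-at-recall >= r interpolation on an
  evenly spaced recall grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "ClassHierarchy",
    "RetrievalStats",
    "rank_targets",
    "nn_ft_st",
    "mean_average_precision",
    "precision_recall_curve",
    "top_k_class_count",
    "evaluate_level",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative N x N dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dissimilarities must be finite")
        if np.abs(self.values - self.values.T).max() > 1e-9:
            raise ValueError("dissimilarity matrix must be symmetric (tol 1e-9)")
        if np.abs(np.diag(self.values)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, mesh_id: str) -> int:
        try:
            return self._index[mesh_id]
        except KeyError:
            raise KeyError(f"unknown id {mesh_id!r}") from None

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "DissimilarityMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))


@dataclass
class ClassHierarchy:
    """Per-level mapping of shape id to class label.

    Levels are ordered coarse to fine (e.g. protein > species > domain);
    finer levels must nest within coarser ones.
    """

    levels: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        names = list(self.levels)
        ids = set(self.levels[names[0]])
        for name in names[1:]:
            if set(self.levels[name]) != ids:
                raise ValueError(f"level {name!r} labels a different id set")
        # nesting: members of a finer class share the coarser class
        for coarse, fine in zip(names, names[1:]):
            seen: dict[str, str] = {}
            for i in ids:
                f = self.levels[fine][i]
                c = self.levels[coarse][i]
                if f in seen and seen[f] != c:
                    raise ValueError(
                        f"class {f!r} at level {fine!r} spans multiple "
                        f"{coarse!r} classes")
                seen[f] = c

    @property
    def level_names(self) -> list[str]:
        return list(self.levels)

    def labels_for(self, level: str, ids: list[str]) -> np.ndarray:
        mapping = self.levels[level]
        return np.asarray([mapping[i] for i in ids])

    @classmethod
    def from_tsv(cls, path) -> "ClassHierarchy":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", dtype=str)
        id_col = df.columns[0]
        levels = {c: dict(zip(df[id_col], df[c])) for c in df.columns[1:]}
        return cls(levels=levels)


@dataclass
class RetrievalStats:
    """NN/FT/ST/MAP plus an interpolated PR curve for one level."""

    level: str
    nn: float
    ft: float
    st: float
    map: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"level": self.level, "NN": self.nn, "FT": self.ft,
                "ST": self.st, "MAP": self.map,
                "PR": [[r, p] for r, p in self.pr_curve]}


def _ranked_indices(values: np.ndarray, qi: int) -> np.ndarray:
    """Indices of all targets except the query, ascending distance, stable."""
    order = np.argsort(values[qi], kind="stable")
    return order[order != qi]


def rank_targets(matrix: DissimilarityMatrix, query_id: str) -> list[str]:
    """All ids except the query sorted by ascending dissimilarity; ties by
    ascending original index."""
    qi = matrix.index_of(query_id)
    return [matrix.ids[j] for j in _ranked_indices(matrix.values, qi)]


def _usable_queries(matrix: DissimilarityMatrix, labels: np.ndarray) -> list[int]:
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    singles = [c for c, s in sizes.items() if s < 2]
    if singles:
        logger.warning("excluding %d singleton classes from retrieval averages",
                       len(singles))
    return [q for q in range(matrix.n) if sizes[labels[q]] >= 2]


def nn_ft_st(matrix: DissimilarityMatrix, hierarchy: ClassHierarchy, level: str,
             st_window: str = "2|C|-1") -> tuple[float, float, float]:
    """Mean Nearest-Neighbor, First-Tier and Second-Tier rates at ``level``.

    Per query of class C: NN is 1 when the top target is in C; FT is the
    fraction of the |C|-1 relevant targets found in the first |C|-1 ranks;
    ST likewise within the first 2|C|-1 ranks (capped at N-1).
    """
    labels = hierarchy.labels_for(level, matrix.ids)
    queries = _usable_queries(matrix, labels)
    if not queries:
        raise ValueError("no class has >= 2 members at this level")
    nn = ft = st = 0.0
    for q in queries:
        ranked = _ranked_indices(matrix.values, q)
        rel = labels[ranked] == labels[q]
        n_rel = int(rel.sum())            # |C| - 1
        size_c = n_rel + 1
        nn += float(rel[0])
        ft += rel[:n_rel].sum() / n_rel
        if st_window == "2|C|-1":
            w = min(2 * size_c - 1, len(ranked))
        elif st_window == "2(|C|-1)":
            w = min(2 * n_rel, len(ranked))
        else:
            raise ValueError(f"unknown st_window {st_window!r}")
        st += rel[:w].sum() / n_rel
    k = len(queries)
    return nn / k, ft / k, st / k


def mean_average_precision(matrix: DissimilarityMatrix, hierarchy: ClassHierarchy,
                           level: str) -> float:
    """MAP: mean over queries of the average precision at the ranks where
    each relevant target is retrieved."""
    labels = hierarchy.labels_for(level, matrix.ids)
    queries = _usable_queries(matrix, labels)
    if not queries:
        raise ValueError("no class has >= 2 members at this level")
    total = 0.0
    for q in queries:
        ranked = _ranked_indices(matrix.values, q)
        rel = labels[ranked] == labels[q]
        ranks = np.flatnonzero(rel) + 1
        precisions = np.arange(1, len(ranks) + 1) / ranks
        total += precisions.mean()
    return total / len(queries)


def precision_recall_curve(matrix: DissimilarityMatrix, hierarchy: ClassHierarchy,
                           level: str, n_recall_points: int = 20
                           ) -> list[tuple[float, float]]:
    """Mean interpolated PR curve: per query, precision at recall level r is
    the maximum precision at any rank achieving recall >= r."""
    labels = hierarchy.labels_for(level, matrix.ids)
    queries = _usable_queries(matrix, labels)
    if not queries:
        raise ValueError("no class has >= 2 members at this level")
    grid = np.arange(1, n_recall_points + 1) / n_recall_points
    acc = np.zeros(n_recall_points)
    for q in queries:
        ranked = _ranked_indices(matrix.values, q)
        rel = (labels[ranked] == labels[q]).astype(float)
        n_rel = rel.sum()
        cum = np.cumsum(rel)
        precision = cum / np.arange(1, len(rel) + 1)
        recall = cum / n_rel
        # max precision over ranks achieving recall >= r
        run_max = np.maximum.accumulate(precision[::-1])[::-1]
        idx = np.searchsorted(recall, grid, side="left")
        acc += run_max[np.minimum(idx, len(rel) - 1)]
    curve = acc / len(queries)
    return list(zip(grid.tolist(), curve.tolist()))


def top_k_class_count(matrix: DissimilarityMatrix, hierarchy: ClassHierarchy,
                      level: str, class_label: str, k: int = 30
                      ) -> tuple[list[int], float, float]:
    """Per-query count of same-class members in the top-k ranked targets.

    Mirrors conformer tracking: for every query in ``class_label``, count
    its class mates among its first ``k`` retrieved shapes (query
    excluded).  Returns (counts, mean, population SD).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = hierarchy.labels_for(level, matrix.ids)
    members = np.flatnonzero(labels == class_label)
    if len(members) == 0:
        raise KeyError(f"unknown class {class_label!r} at level {level!r}")
    if len(members) < 2:
        raise ValueError(f"class {class_label!r} has fewer than 2 members")
    counts = []
    for q in members:
        ranked = _ranked_indices(matrix.values, q)
        counts.append(int((labels[ranked[:k]] == class_label).sum()))
    arr = np.asarray(counts, dtype=float)
    return counts, float(arr.mean()), float(arr.std())


def evaluate_level(matrix: DissimilarityMatrix, hierarchy: ClassHierarchy,
                   level: str, n_recall_points: int = 20) -> RetrievalStats:
    nn, ft, st = nn_ft_st(matrix, hierarchy, level)
    return RetrievalStats(
        level=level, nn=nn, ft=ft, st=st,
        map=mean_average_precision(matrix, hierarchy, level),
        pr_curve=precision_recall_curve(matrix, hierarchy, level, n_recall_points),
    )
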