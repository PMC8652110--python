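"""Distant surficial homolog detection.

Proteins with near-identical surface shapes but low sequence identity are
*distant surficial homologs*.  The procedure combines, per shape method,
a min-max-normalized dissimilarity matrix M with a sequence-identity
matrix H: for each query i the best target is argmin_j (H + M)[i, j] —
the target joining the least sequence identity with the highest shape
similarity.  A pair is accepted when at least ``min_methods`` methods
agree on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .retrieval import DissimilarityMatrix

__all__ = [
    "SequenceIdentityMatrix",
    "HomologCandidateSet",
    "pairwise_sequence_identity",
    "normalize_dissimilarity",
    "combined_best_target",
    "consensus_pairs",
]


@dataclass
class SequenceIdentityMatrix:
    """Symmetric N x N pairwise sequence identities in [0, 1], unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("identity matrix shape mismatch")
        if np.abs(self.values - self.values.T).max() > 1e-9:
            raise ValueError("identity matrix must be symmetric")
        if np.abs(np.diag(self.values) - 1.0).max() > 1e-9:
            raise ValueError("identity diagonal must be exactly 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("identities must lie in [0, 1]")


@dataclass
class HomologCandidateSet:
    """Per-method best targets, the consensus pairs, and per-pair records."""

    per_method_best: dict[str, dict[str, str]]
    pairs: set[frozenset]
    records: list[dict] = field(default_factory=list)


def _align_identity(aligner, seq_a: str, seq_b: str, denominator: str) -> float:
    alignment = aligner.align(seq_a, seq_b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        sub_a = seq_a[a0:a1]
        sub_b = seq_b[b0:b1]
        ident += sum(x == y for x, y in zip(sub_a, sub_b))
    if denominator == "alignment_length":
        denom = alignment.shape[1]
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "ungapped":
        denom = sum(a1 - a0 for (a0, a1), _ in zip(*alignment.aligned))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return ident / denom if denom else 0.0


def pairwise_sequence_identity(sequences: dict[str, str],
                               denominator: str = "alignment_length"
                               ) -> SequenceIdentityMatrix:
    """All-vs-all global Needleman-Wunsch identity (BLOSUM62, gap open 10,
    extend 0.5).

    ``denominator`` picks the identity-ratio convention:
    ``alignment_length`` (gap-inclusive, default), ``shorter`` (shorter
    sequence length) or ``ungapped`` (aligned columns only).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for id {sid!r}")
    ids = list(sequences)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5

    n = len(ids)
    values = np.eye(n)
    cache: dict[str, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[ids[i]], sequences[ids[j]]
            key = a + "\x00" + b if a <= b else b + "\x00" + a
            if key not in cache:
                cache[key] = 1.0 if a == b else _align_identity(
                    aligner, a, b, denominator)
            values[i, j] = values[j, i] = cache[key]
    return SequenceIdentityMatrix(ids=ids, values=values)


def normalize_dissimilarity(matrix: DissimilarityMatrix,
                            scheme: str = "minmax") -> DissimilarityMatrix:
    """Rescale off-diagonal dissimilarities into [0, 1].

    ``minmax`` (default) maps the off-diagonal minimum to 0 and maximum
    to 1; ``zscore`` standardizes and then min-max rescales the result
    (so the output range contract still holds).
    """
    v = matrix.values.copy()
    n = matrix.n
    off = ~np.eye(n, dtype=bool)
    vals = v[off]
    if np.ptp(vals) <= 0:
        raise ValueError("cannot normalize a constant dissimilarity matrix")
    if scheme == "zscore":
        vals = (vals - vals.mean()) / vals.std()
    elif scheme != "minmax":
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    lo, hi = vals.min(), vals.max()
    v[off] = (vals - lo) / (hi - lo)
    np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix(ids=matrix.ids, values=v)


def combined_best_target(H: SequenceIdentityMatrix, M_norm: DissimilarityMatrix
                         ) -> dict[str, tuple[str, float]]:
    """argmin_j != i of (H + M)[i, j] per query, ties by ascending index."""
    if H.ids != M_norm.ids:
        raise ValueError("identity and dissimilarity matrices must share ids")
    S = H.values + M_norm.values
    out: dict[str, tuple[str, float]] = {}
    n = len(H.ids)
    for i in range(n):
        row = S[i].copy()
        row[i] = np.inf
        j = int(np.argmin(row))        # argmin takes the first minimum
        out[H.ids[i]] = (H.ids[j], float(row[j]))
    return out


def consensus_pairs(per_method_best: dict[str, dict[str, str]],
                    min_methods: int = 2,
                    H: SequenceIdentityMatrix | None = None,
                    normalized: dict[str, DissimilarityMatrix] | None = None
                    ) -> HomologCandidateSet:
    """Unordered pairs {i, j} proposed as best target by >= ``min_methods``
    methods; reciprocal hits merge onto the same pair.

    When ``H`` and the per-method normalized matrices are supplied, each
    pair gets a record with its identity and per-method distances.
    """
    if min_methods < 2:
        raise ValueError("min_methods must be >= 2")
    if min_methods > len(per_method_best):
        raise ValueError("min_methods exceeds the number of methods")
    support: dict[frozenset, set[str]] = {}
    for method, best in per_method_best.items():
        for query, target in best.items():
            if query == target:
                raise ValueError(f"self-pair for query {query!r}")
            support.setdefault(frozenset((query, target)), set()).add(method)
    pairs: set[frozenset] = set()
    pair_methods: dict[frozenset, set[str]] = {}
    for key, methods in support.items():
        if len(methods) >= min_methods:
            pairs.add(key)
            pair_methods[key] = methods
    records = []
    for pair in sorted(pairs, key=sorted):
        i, j = sorted(pair)
        rec = {"id_i": i, "id_j": j,
               "methods": sorted(pair_methods[pair]),
               "n_methods": len(pair_methods[pair])}
        if H is not None:
            ii, jj = H.ids.index(i), H.ids.index(j)
            rec["identity"] = float(H.values[ii, jj])
        if normalized is not None:
            for method, mat in normalized.items():
                ii, jj = mat.ids.index(i), mat.ids.index(j)
                rec[f"dist_{method}"] = float(mat.values[ii, jj])
        records.append(rec)
    return HomologCandidateSet(per_method_best=per_method_best, pairs=pairs,
                               records=records)
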