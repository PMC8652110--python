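"""Descriptor container and the vector distances used to compare them."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ShapeDescriptor", "DescriptorContractError", "descriptor_distance",
           "distance_matrix"]

METRICS = ("euclidean", "manhattan", "canberra", "panorama_composite")


class DescriptorContractError(ValueError):
    """Descriptors being compared disagree in method, length or parameters."""


@dataclass
class ShapeDescriptor:
    """A fixed-length real descriptor vector with its method and parameters."""

    method: str
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.method} descriptor contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def _canberra(a: np.ndarray, b: np.ndarray) -> float:
    num = np.abs(a - b)
    den = np.abs(a) + np.abs(b)
    mask = den > 0              # 0/0 terms contribute 0
    return float((num[mask] / den[mask]).sum())


def descriptor_distance(a: ShapeDescriptor, b: ShapeDescriptor,
                        metric: str = "euclidean") -> float:
    """Distance between two descriptors of the same method and parameters.

    ``panorama_composite`` is the equal-weight sum of the length-normalized
    Manhattan and Canberra distances.
    """
    if a.method != b.method:
        raise DescriptorContractError(f"method mismatch: {a.method} vs {b.method}")
    if len(a) != len(b):
        raise DescriptorContractError(f"length mismatch: {len(a)} vs {len(b)}")
    if a.params != b.params:
        raise DescriptorContractError("descriptor parameters differ")
    return _vector_distance(a.values, b.values, metric)


def _vector_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "manhattan":
        return float(np.abs(x - y).sum())
    if metric == "canberra":
        return _canberra(x, y)
    if metric == "panorama_composite":
        n = len(x)
        return 0.5 * np.abs(x - y).sum() / n + 0.5 * _canberra(x, y) / n
    raise ValueError(f"unknown metric {metric!r}")


def distance_matrix(descriptors: dict[str, ShapeDescriptor], metric: str):
    """All-vs-all distances; returns a retrieval.DissimilarityMatrix."""
    from ..retrieval import DissimilarityMatrix

    ids = list(descriptors)
    vecs = np.stack([descriptors[i].values for i in ids])
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _vector_distance(vecs[i], vecs[j], metric)
    return DissimilarityMatrix(ids=ids, values=out)
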