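"""Kernel families for genomic prediction: linear, (inhomogeneous)
polynomial, and L_p-distance kernels.

The polynomial kernel is K(x, t) = (x't + c)^l; the distance family is
K(x, t) = exp(-(d_p(x, t) / bandwidth)^q) with d_p the L_p norm of x - t.
p = 2, q = 1 is the RBF/Gaussian form used here (the literal exponentiated
Euclidean distance at bandwidth 1); p = 1 gives the Laplacian kernel; q = 2
with p = 2 is the classical squared-exponential Gaussian.

A bandwidth is needed because with thousands of markers raw distances are
large and exp(-d) underflows for every pair; "auto" uses the median
heuristic (median pairwise training distance), and bandwidth = 1 recovers
the unscaled form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "lp_distance",
    "kernel_value",
    "resolve_bandwidth",
    "gram",
    "cross",
]

_FAMILIES = ("linear", "polynomial", "distance")


@dataclass(frozen=True)
class KernelSpec:
    """Declarative kernel description, expressible in YAML.

    family='linear' ignores the other fields; 'polynomial' uses degree and
    shift; 'distance' uses p (norm order), q (exponent on the scaled
    distance) and bandwidth (positive number or "auto").
    """

    family: str = "distance"
    degree: int = 2
    shift: float = 1.0
    p: float = 2.0
    q: int = 1
    bandwidth: float | str = "auto"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial":
            if not (isinstance(self.degree, (int, np.integer)) and self.degree >= 1):
                raise ValueError("polynomial degree must be an integer >= 1")
            if self.shift < 0:
                raise ValueError("polynomial shift c must be >= 0")
        if self.family == "distance":
            if self.p < 1:
                raise ValueError("distance order p must be >= 1")
            if self.q not in (1, 2):
                raise ValueError("distance exponent q must be 1 or 2")
            if self.bandwidth != "auto" and not self.bandwidth > 0:
                raise ValueError("bandwidth must be positive or 'auto'")

    @classmethod
    def from_dict(cls, raw: dict) -> "KernelSpec":
        raw = dict(raw)
        if "l" in raw:
            raw["degree"] = raw.pop("l")
        if "c" in raw:
            raw["shift"] = raw.pop("c")
        return cls(**raw)


@dataclass
class GramMatrix:
    """Realized kernel matrix among training animals."""

    values: np.ndarray
    spec: KernelSpec
    ids: np.ndarray | None = None
    bandwidth: float | None = None  # resolved value for distance kernels

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("Gram matrix must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("Gram matrix must be symmetric")
        self.values = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def lp_distance(x, t, p: float) -> float:
    """L_p norm distance (sum |x_i - t_i|^p)^(1/p); a metric for p >= 1."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape:
        raise ValueError("vectors must have equal length")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float(np.sum(np.abs(x - t) ** p) ** (1.0 / p))


def resolve_bandwidth(X_train: np.ndarray, spec: KernelSpec) -> float:
    """Return the numeric bandwidth: pass-through, or the median pairwise
    training distance when bandwidth='auto' (median heuristic)."""
    if spec.family != "distance":
        raise ValueError("bandwidth only applies to distance kernels")
    if spec.bandwidth != "auto":
        return float(spec.bandwidth)
    d = _pairwise_self(np.asarray(X_train, dtype=float), spec.p, condensed=True)
    med = float(np.median(d))
    if med <= 0:
        raise ValueError(
            "median pairwise distance is zero (identical training genotypes); "
            "set an explicit bandwidth"
        )
    return med


def kernel_value(x, t, spec: KernelSpec, bandwidth_resolved: float | None = None) -> float:
    """Single kernel evaluation; matches gram/cross entrywise."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape:
        raise ValueError("vectors must have equal length")
    if spec.family == "linear":
        return float(x @ t)
    if spec.family == "polynomial":
        base = float(x @ t) + spec.shift
        try:
            val = base ** spec.degree
        except OverflowError:
            val = np.inf
        if not np.isfinite(val):
            raise OverflowError(
                "polynomial kernel overflow; center and scale the genotypes"
            )
        return float(val)
    h = bandwidth_resolved
    if h is None:
        if spec.bandwidth == "auto":
            raise ValueError("auto bandwidth needs a training set to resolve")
        h = float(spec.bandwidth)
    d = lp_distance(x, t, spec.p)
    return float(np.exp(-((d / h) ** spec.q)))


def _pairwise_self(X: np.ndarray, p: float, condensed: bool = False) -> np.ndarray:
    if p == 2:
        d = pdist(X, metric="euclidean")
    elif p == 1:
        d = pdist(X, metric="cityblock")
    else:
        d = pdist(X, metric="minkowski", p=p)
    return d if condensed else None


def _pairwise_cross(A: np.ndarray, B: np.ndarray, p: float) -> np.ndarray:
    if p == 2:
        return cdist(A, B, metric="euclidean")
    if p == 1:
        return cdist(A, B, metric="cityblock")
    return cdist(A, B, metric="minkowski", p=p)


def _poly(M: np.ndarray, spec: KernelSpec) -> np.ndarray:
    K = (M + spec.shift) ** spec.degree
    if not np.isfinite(K).all():
        raise OverflowError(
            "polynomial kernel overflow; center and scale the genotypes"
        )
    return K


def gram(
    X_train: np.ndarray,
    spec: KernelSpec,
    ids: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> GramMatrix:
    """Kernel matrix among training animals (K of the dual predictor)."""
    X = np.asarray(X_train, dtype=float)
    if spec.family == "linear":
        K = X @ X.T
    elif spec.family == "polynomial":
        K = _poly(X @ X.T, spec)
    else:
        h = bandwidth if bandwidth is not None else resolve_bandwidth(X, spec)
        from scipy.spatial.distance import squareform

        d = squareform(_pairwise_self(X, spec.p, condensed=True))
        K = np.exp(-((d / h) ** spec.q))
        np.fill_diagonal(K, 1.0)
        return GramMatrix((K + K.T) / 2.0, spec, ids, bandwidth=h)
    return GramMatrix((K + K.T) / 2.0, spec, ids)


def cross(
    X_train: np.ndarray,
    X_test: np.ndarray,
    spec: KernelSpec,
    bandwidth: float | None = None,
) -> np.ndarray:
    """n_train x n_test matrix of kernel values (the k vectors, columnwise)."""
    A = np.asarray(X_train, dtype=float)
    B = np.asarray(X_test, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"marker mismatch: train has {A.shape[1]} markers, test {B.shape[1]}"
        )
    if spec.family == "linear":
        return A @ B.T
    if spec.family == "polynomial":
        return _poly(A @ B.T, spec)
    h = bandwidth if bandwidth is not None else resolve_bandwidth(A, spec)
    d = _pairwise_cross(A, B, spec.p)
    return np.exp(-((d / h) ** spec.q))
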