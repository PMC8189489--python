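r"""Smooth-sparse gene-graph learning.

Genes are nodes of a weighted undirected graph; a gene's expression vector
across cells is a signal on that graph.  The graph is learned by minimizing,
over symmetric nonnegative hollow adjacency matrices :math:`W`,

.. math::

    \|W \circ Z\|_{1,1} \;-\; \mathbf{1}^T \log(W\mathbf{1})
    \;+\; \tfrac{1}{2}\|W\|_F^2,

where :math:`Z_{jk} = \|x_j - x_k\|^2` is the squared Euclidean distance
between gene expression vectors.  The first term rewards putting weight on
pairs of genes with similar signals (it equals twice the Laplacian quadratic
form :math:`\mathrm{tr}(X L X^T)`), the log-degree barrier forces every gene
to keep positive degree (node-level connectivity), and the Frobenius penalty
discourages large edges, yielding a sparse graph.

In the half-vectorized form over the :math:`m(m-1)/2` unordered gene pairs
(upper-triangular, row-major indexing — the scipy ``squareform`` convention)
the problem reads

.. math::

    \min_{w \ge 0} \; 2 w^T z - \alpha \mathbf{1}^T\log(Kw) + \beta \|w\|^2,

with :math:`K` the linear degree operator satisfying :math:`W\mathbf{1}=Kw`.
Defaults :math:`\alpha=\beta=1` reproduce the matrix objective exactly.  The
problem is strictly convex on the feasible region, so the minimizer is unique
and independent of initialization; it is computed by a primal-dual
forward-backward-forward scheme with the dual variable attached to ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import isqrt
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix

__all__ = [
    "SolverSettings",
    "GeneGraph",
    "ConvergenceError",
    "pairwise_sq_distances",
    "vectorize",
    "devectorize",
    "degree_operator",
    "objective_value",
    "learn_graph",
    "smoothness",
    "GeneGraphLearner",
]


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the last iterate and objective trace."""

    def __init__(self, message: str, last_w: np.ndarray, objective_trace: list[float]):
        super().__init__(message)
        self.last_w = last_w
        self.objective_trace = objective_trace


@dataclass(frozen=True)
class SolverSettings:
    """Tunables of the graph solver.

    alpha/beta weight the log-degree barrier and the squared-norm penalty;
    the defaults (1, 1) give the canonical objective.  ``weight_floor`` zeroes
    tiny weights post hoc, applied only if all degrees stay positive.
    ``distance_scale`` uniformly rescales z before solving — the fixed-
    coefficient objective's sparsity level depends on the scale of Z.
    """

    max_iter: int = 100_000
    rel_tol: float = 1e-5
    step_scale: float = 0.5
    weight_floor: float = 0.0
    alpha: float = 1.0
    beta: float = 1.0
    distance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.step_scale <= 1:
            raise ValueError("step_scale must lie in (0, 1]")
        for name in ("rel_tol", "alpha", "beta", "distance_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_floor < 0:
            raise ValueError("weight_floor must be nonnegative")


@dataclass(frozen=True)
class GeneGraph:
    """Learned gene graph: symmetric nonnegative hollow adjacency + metadata."""

    weights: np.ndarray
    gene_ids: tuple[str, ...] | None = None
    n_iter: int | None = None
    objective: float | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(W, W.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("adjacency must be nonnegative")
        W.setflags(write=False)
        object.__setattr__(self, "weights", W)

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree_matrix - self.weights

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Nonzero edges as (j, k, weight) with j < k."""
        jj, kk = np.triu_indices(self.n_genes, k=1)
        w = self.weights[jj, kk]
        nz = w > 0
        return list(zip(jj[nz].tolist(), kk[nz].tolist(), w[nz].tolist()))


def _num_pairs(m: int) -> int:
    return m * (m - 1) // 2


def _infer_m(n_pairs: int) -> int:
    m = (1 + isqrt(1 + 8 * n_pairs)) // 2
    if _num_pairs(m) != n_pairs:
        raise ValueError(f"length {n_pairs} is not of the form m(m-1)/2")
    return m


def _as_matrix(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def pairwise_sq_distances(
    X: ExpressionMatrix | np.ndarray, transform: Literal["none", "log1p"] = "none"
) -> np.ndarray:
    """Squared Euclidean distances between gene columns of a cells x genes matrix.

    ``transform="log1p"`` applies log(1+x) first, a common variance-stabilizer
    for counts; the default leaves the values as provided.
    """
    V = _as_matrix(X)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 genes")
    if not np.all(np.isfinite(V)):
        raise ValueError("matrix contains NaN or inf")
    if transform == "log1p":
        V = np.log1p(V)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return squareform(pdist(V.T, metric="sqeuclidean"), checks=False)


def vectorize(Z: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric hollow matrix (upper triangle, row-major)."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(Z, Z.T):
        raise ValueError("matrix must be symmetric")
    if np.any(np.diag(Z) != 0):
        raise ValueError("matrix must have a zero diagonal")
    return squareform(Z, checks=False).astype(np.float64)


def devectorize(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 1:
        raise ValueError("expected a 1-D pair vector")
    _infer_m(z.size)
    return squareform(z, checks=False)


def degree_operator(w: np.ndarray) -> np.ndarray:
    """Apply the linear degree map K: per-gene sums of incident pair weights."""
    w = np.asarray(w, dtype=np.float64)
    m = _infer_m(w.size)
    jj, kk = np.triu_indices(m, k=1)
    return np.bincount(jj, weights=w, minlength=m) + np.bincount(
        kk, weights=w, minlength=m
    )


def _degree_adjoint(v: np.ndarray, jj: np.ndarray, kk: np.ndarray) -> np.ndarray:
    # K^T maps node values to pair values: (K^T v)_{jk} = v_j + v_k
    return v[jj] + v[kk]


def objective_value(
    w: np.ndarray, z: np.ndarray, settings: SolverSettings | None = None
) -> float:
    """Evaluate 2 w'z - alpha * sum(log(Kw)) + beta * ||w||^2 (+inf if infeasible)."""
    s = settings or SolverSettings()
    w = np.asarray(w, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if w.shape != z.shape:
        raise ValueError("w and z must have the same length")
    if np.any(w < 0):
        return float("inf")
    d = degree_operator(w)
    if np.any(d <= 0):
        return float("inf")
    return float(2 * w @ z - s.alpha * np.sum(np.log(d)) + s.beta * (w @ w))


def learn_graph(
    Z: np.ndarray,
    settings: SolverSettings | None = None,
    gene_ids: tuple[str, ...] | None = None,
) -> GeneGraph:
    """Solve the smooth-sparse graph-learning problem for the adjacency W.

    Primal-dual forward-backward-forward iteration: the nonsmooth term
    2 w'z + indicator(w >= 0) enters through its proximal map
    ``max(0, y - 2*gamma*z)``, the log-degree barrier through the proximal map
    of its Fenchel conjugate composed with K, and the quadratic penalty
    through its gradient.  The step size is ``step_scale / (2*beta + ||K||)``
    with ``||K|| = sqrt(2(m-1))``, inside the scheme's convergence range.

    Raises :class:`ConvergenceError` when the relative change in w stays above
    ``rel_tol`` after ``max_iter`` iterations.
    """
    s = settings or SolverSettings()
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValueError("Z must be square")
    m = Z.shape[0]
    if m < 2:
        raise ValueError("graph learning needs at least 2 genes")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains NaN or inf")
    if np.any(Z < 0):
        raise ValueError("Z must be nonnegative")
    z = vectorize(Z) * s.distance_scale

    # Exact reparametrization w = c*u with c = min(1, 1/mean(z)): the objective
    # in u is the same family with z -> c*z and beta -> beta*c^2 (plus a
    # constant), so the optimum is unchanged while the iterates stay O(1) when
    # distances are large.  Without this the dual variable is O(mean(z)) and
    # the fixed step size makes convergence scale-dependent.  Small distance
    # scales are left alone (c = 1): shrinking them would inflate beta*c^2 and
    # collapse the step size instead.
    zbar = float(z.mean())
    c = min(1.0, 1.0 / zbar) if zbar > 0 else 1.0
    z_s = z * c
    beta_s = s.beta * c * c

    jj, kk = np.triu_indices(m, k=1)
    norm_K = np.sqrt(2.0 * (m - 1))
    gamma = s.step_scale / (2.0 * beta_s + norm_K)

    w = np.ones_like(z)
    v = np.zeros(m)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, s.max_iter + 1):
        # forward step on both variables
        Kw = np.bincount(jj, weights=w, minlength=m) + np.bincount(kk, weights=w, minlength=m)
        y = w - gamma * (2.0 * beta_s * w + _degree_adjoint(v, jj, kk))
        ybar = v + gamma * Kw
        # backward (proximal) step
        p = np.maximum(0.0, y - 2.0 * gamma * z_s)
        pbar = 0.5 * (ybar - np.sqrt(ybar * ybar + 4.0 * s.alpha * gamma))
        # second forward step (the FBF correction)
        Kp = np.bincount(jj, weights=p, minlength=m) + np.bincount(kk, weights=p, minlength=m)
        q = p - gamma * (2.0 * beta_s * p + _degree_adjoint(pbar, jj, kk))
        qbar = pbar + gamma * Kp
        w_next = w - y + q
        v_next = v - ybar + qbar
        rel = np.linalg.norm(w_next - w) / max(np.linalg.norm(w), 1e-30)
        w, v = w_next, v_next
        if n_iter % 10 == 0:  # objective trace kept for diagnostics/error reports
            trace.append(objective_value(np.maximum(c * w, 0.0), z, s))
        if rel < s.rel_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"graph solver did not converge in {s.max_iter} iterations "
            f"(last relative change {rel:.3e})",
            last_w=w,
            objective_trace=trace,
        )

    w = np.maximum(c * w, 0.0)
    if s.weight_floor > 0:
        floored = np.where(w < s.weight_floor, 0.0, w)
        if np.all(degree_operator(floored) > 0):
            w = floored
    final_obj = objective_value(w, z, s)
    return GeneGraph(
        weights=devectorize(w), gene_ids=gene_ids, n_iter=n_iter, objective=final_obj
    )


def smoothness(X: ExpressionMatrix | np.ndarray, W: np.ndarray) -> float:
    """Laplacian quadratic form 2 tr(X L X^T) of gene signals on the graph.

    Equals ``sum_{jk} W_jk * ||x_j - x_k||^2``, the elementwise-L1 smoothness
    term of the learning objective.
    """
    V = _as_matrix(X)
    W = np.asarray(W, dtype=np.float64)
    L = np.diag(W.sum(axis=1)) - W
    return float(2.0 * np.trace(V @ L @ V.T))


class GeneGraphLearner(BaseEstimator):
    """scikit-learn style estimator wrapping distance computation + graph solving.

    Parameters mirror :class:`SolverSettings`; ``fit(X)`` expects a cells x
    genes array (or :class:`ExpressionMatrix`) and exposes the learned graph
    as fitted attributes.

    Attributes
    ----------
    graph_ : GeneGraph
    weights_ : ndarray of shape (m, m)
    degrees_ : ndarray of shape (m,)
    laplacian_ : ndarray of shape (m, m)
    n_iter_ : int
    objective_ : float
    """

    def __init__(
        self,
        *,
        transform: Literal["none", "log1p"] = "none",
        max_iter: int = 100_000,
        rel_tol: float = 1e-5,
        step_scale: float = 0.5,
        weight_floor: float = 0.0,
        alpha: float = 1.0,
        beta: float = 1.0,
        distance_scale: float = 1.0,
    ):
        self.transform = transform
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.step_scale = step_scale
        self.weight_floor = weight_floor
        self.alpha = alpha
        self.beta = beta
        self.distance_scale = distance_scale

    def _settings(self) -> SolverSettings:
        return SolverSettings(
            max_iter=self.max_iter,
            rel_tol=self.rel_tol,
            step_scale=self.step_scale,
            weight_floor=self.weight_floor,
            alpha=self.alpha,
            beta=self.beta,
            distance_scale=self.distance_scale,
        )

    def fit(self, X, y=None):
        gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else None
        V = _as_matrix(X)
        Z = pairwise_sq_distances(V, transform=self.transform)
        self.graph_ = learn_graph(Z, self._settings(), gene_ids=gene_ids)
        self.weights_ = self.graph_.weights
        self.degrees_ = self.graph_.degrees
        self.laplacian_ = self.graph_.laplacian
        self.n_iter_ = self.graph_.n_iter
        self.objective_ = self.graph_.objective
        self.n_features_in_ = V.shape[1]
        return self
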