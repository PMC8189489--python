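r"""Lazy random-walk imputation on the learned gene graph.

Given the adjacency :math:`W` with degree matrix :math:`D`, the lazy walk
transition matrix is :math:`M = (D^{-1}W + I)/2`: at every step a gene keeps
half of its signal and distributes the other half to its neighbors in
proportion to edge weight.  A ``t``-step walk imputes the expression matrix
via :math:`X_\text{imputed}^T = M^t X^T`, i.e. each gene becomes a convex
combination of itself and similar genes, filling dropout zeros with
information borrowed from the graph neighborhood.

``t`` defaults to 1 (a single step) to avoid over-smoothing away cell-to-cell
variation; alternatively ``t`` is tuned by minimizing the mean squared
difference between the diffused and observed matrices over ``t = 1..t_max``
(the "stay close to the raw data" heuristic).  After diffusion, each gene is
rescaled so its mean over all cells matches the observed mean, since the walk
redistributes mass across genes within each cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .graph import GeneGraph, GeneGraphLearner, SolverSettings
from .io import ExpressionMatrix, library_size_normalize

__all__ = [
    "ImputationResult",
    "build_transition",
    "random_walk_impute",
    "tune_steps",
    "rescale_to_gene_means",
    "impute",
    "GraphDiffusionImputer",
]


@dataclass(frozen=True)
class ImputationResult:
    """Imputed matrix plus the step count used and the MSE trace (if tuned)."""

    X_imputed: ExpressionMatrix
    t_star: int
    mse_trace: np.ndarray | None
    rescaled: bool
    unscaled_genes: tuple[str, ...] = ()


def _adjacency(G: GeneGraph | np.ndarray) -> np.ndarray:
    if isinstance(G, GeneGraph):
        return G.weights
    return GeneGraph(np.asarray(G, dtype=np.float64)).weights  # validates


def build_transition(G: GeneGraph | np.ndarray) -> np.ndarray:
    """Lazy random-walk matrix M = (D^-1 W + I)/2; rows sum to 1, diag = 1/2."""
    W = _adjacency(G)
    d = W.sum(axis=1)
    if np.any(d <= 0):
        bad = np.flatnonzero(d <= 0)
        names = (
            [G.gene_ids[i] for i in bad[:5]]
            if isinstance(G, GeneGraph) and G.gene_ids is not None
            else bad[:5].tolist()
        )
        raise ValueError(f"zero-degree genes {names}: transition matrix undefined")
    M = 0.5 * (W / d[:, None])
    np.fill_diagonal(M, 0.5)
    return M


def _check_transition(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1")
    return M


def random_walk_impute(
    X: ExpressionMatrix | np.ndarray, M: np.ndarray, t: int
) -> ExpressionMatrix | np.ndarray:
    """Apply t diffusion steps: gene vectors (rows of X^T) become M^t X^T.

    ``t = 0`` returns the input unchanged.  Powers are applied iteratively
    (t matrix products), never through eigendecomposition.
    """
    M = _check_transition(M)
    if t < 0:
        raise ValueError("t must be nonnegative")
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    if values.shape[1] != M.shape[0]:
        raise ValueError(
            f"matrix has {values.shape[1]} genes but transition matrix is {M.shape[0]}x{M.shape[0]}"
        )
    Y = values.T.copy()
    for _ in range(t):
        Y = M @ Y
    out = Y.T
    if isinstance(X, ExpressionMatrix):
        return X.with_values(np.maximum(out, 0.0))
    return out


def tune_steps(
    X: ExpressionMatrix | np.ndarray, M: np.ndarray, t_max: int = 10
) -> tuple[int, np.ndarray]:
    """Pick the step count minimizing MSE(M^t X^T, X^T) over t = 1..t_max.

    Returns ``(t_star, mse_trace)`` with ``mse_trace[t-1]`` the mean squared
    entrywise difference after t steps.  Ties break to the smallest t (less
    smoothing).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    M = _check_transition(M)
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    Xt = values.T
    Y = Xt.copy()
    trace = np.empty(t_max)
    for t in range(1, t_max + 1):
        Y = M @ Y
        trace[t - 1] = np.mean((Y - Xt) ** 2)
    t_star = int(np.argmin(trace)) + 1  # argmin takes the first minimum
    return t_star, trace


def rescale_to_gene_means(
    X_imp: ExpressionMatrix | np.ndarray,
    X_obs: ExpressionMatrix | np.ndarray,
    cells: Literal["all", "nonzero"] = "all",
) -> tuple[np.ndarray, list[int]]:
    """Scale each imputed gene so its mean matches the observed gene mean.

    Means are taken over all cells by default (``cells="nonzero"`` restricts
    the *observed* mean to nonzero cells).  Genes with zero observed mean are
    set to all-zero; genes with zero imputed mean but positive observed mean
    cannot be rescaled multiplicatively and are left as-is, returned in the
    warning list.
    """
    imp = X_imp.values if isinstance(X_imp, ExpressionMatrix) else np.asarray(X_imp, dtype=np.float64)
    obs = X_obs.values if isinstance(X_obs, ExpressionMatrix) else np.asarray(X_obs, dtype=np.float64)
    if imp.shape != obs.shape:
        raise ValueError("imputed and observed matrices must have the same shape")
    if (
        isinstance(X_imp, ExpressionMatrix)
        and isinstance(X_obs, ExpressionMatrix)
        and X_imp.gene_ids != X_obs.gene_ids
    ):
        raise ValueError("imputed and observed gene labels differ")
    if cells == "all":
        obs_mean = obs.mean(axis=0)
    elif cells == "nonzero":
        nz = obs > 0
        counts = nz.sum(axis=0)
        with np.errstate(invalid="ignore"):
            obs_mean = np.where(counts > 0, obs.sum(axis=0) / np.maximum(counts, 1), 0.0)
    else:
        raise ValueError(f"unknown cells mode {cells!r}")
    imp_mean = imp.mean(axis=0)

    out = imp.copy()
    unscaled: list[int] = []
    for j in range(imp.shape[1]):
        if obs_mean[j] == 0:
            out[:, j] = 0.0
        elif imp_mean[j] == 0:
            unscaled.append(j)
        else:
            out[:, j] *= obs_mean[j] / imp_mean[j]
    if unscaled:
        warnings.warn(
            f"{len(unscaled)} gene(s) have zero imputed mean but positive observed "
            "mean; left unscaled",
            RuntimeWarning,
            stacklevel=2,
        )
    return out, unscaled


class GraphDiffusionImputer(TransformerMixin, BaseEstimator):
    """Impute dropouts by diffusing expression over a learned gene graph.

    ``fit`` (on a cells x genes matrix) optionally library-size normalizes,
    drops all-zero genes, learns the gene graph, builds the lazy-walk
    transition matrix and — when ``t="auto"`` — tunes the step count by the
    MSE rule.  ``transform`` diffuses, rescales each gene back to its observed
    mean, and re-inserts all-zero genes untouched.  The whole pipeline is
    deterministic.

    Parameters
    ----------
    t : int or "auto", default=1
        Number of diffusion steps.  One step avoids over-smoothing; "auto"
        minimizes the MSE between diffused and observed data over 1..t_max.
    t_max : int, default=10
        Search range for ``t="auto"``.
    normalize : bool, default=True
        Library-size normalize (median target) before graph learning;
        recommended for UMI counts so sequencing depth does not drive the
        gene-gene distances.
    transform_dist : {"none", "log1p"}, default="none"
        Optional transform applied only when computing gene-gene distances.
    rescale : bool, default=True
        Match per-gene means of the output to the (preprocessed) input.
    rescale_cells : {"all", "nonzero"}, default="all"
        Cells over which the observed gene mean is computed for rescaling.
    alpha, beta, max_iter, rel_tol, step_scale, weight_floor, distance_scale
        Graph-solver settings; see :class:`~graphimpute.graph.SolverSettings`.

    Attributes
    ----------
    graph_ : GeneGraph           learned on the kept (non-all-zero) genes
    transition_ : ndarray        lazy-walk matrix over kept genes
    t_star_ : int                step count actually used
    mse_trace_ : ndarray or None MSE at t = 1..t_max when tuned
    kept_genes_ : ndarray(bool)  mask of genes that entered the graph
    norm_target_ : float or None library-size target fixed at fit time
    """

    def __init__(
        self,
        *,
        t: int | Literal["auto"] = 1,
        t_max: int = 10,
        normalize: bool = True,
        transform_dist: Literal["none", "log1p"] = "none",
        rescale: bool = True,
        rescale_cells: Literal["all", "nonzero"] = "all",
        alpha: float = 1.0,
        beta: float = 1.0,
        max_iter: int = 100_000,
        rel_tol: float = 1e-5,
        step_scale: float = 0.5,
        weight_floor: float = 0.0,
        distance_scale: float = 1.0,
    ):
        self.t = t
        self.t_max = t_max
        self.normalize = normalize
        self.transform_dist = transform_dist
        self.rescale = rescale
        self.rescale_cells = rescale_cells
        self.alpha = alpha
        self.beta = beta
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.step_scale = step_scale
        self.weight_floor = weight_floor
        self.distance_scale = distance_scale

    # -- internal helpers -------------------------------------------------
    def _validate_t(self) -> None:
        if self.t != "auto" and (not isinstance(self.t, (int, np.integer)) or self.t < 1):
            raise ValueError('t must be a positive integer or "auto"')
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")

    def _preprocess(self, values: np.ndarray) -> np.ndarray:
        if not self.normalize:
            return values
        totals = values.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(
                "[normalize] cells with zero totals present; filter them first"
            )
        return values * (self.norm_target_ / totals)[:, None]

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        self._validate_t()
        values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("expected a 2-D cells x genes matrix")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite and nonnegative")
        self.n_features_in_ = values.shape[1]
        self.kept_genes_ = values.sum(axis=0) > 0
        if int(self.kept_genes_.sum()) < 2:
            raise ValueError("m < 2: need at least two genes with nonzero expression")
        self.norm_target_ = (
            float(np.median(values.sum(axis=1))) if self.normalize else None
        )
        V = self._preprocess(values)[:, self.kept_genes_]

        learner = GeneGraphLearner(
            transform=self.transform_dist,
            max_iter=self.max_iter,
            rel_tol=self.rel_tol,
            step_scale=self.step_scale,
            weight_floor=self.weight_floor,
            alpha=self.alpha,
            beta=self.beta,
            distance_scale=self.distance_scale,
        )
        try:
            learner.fit(V)
        except Exception as exc:
            raise RuntimeError(f"[learn_graph] {exc}") from exc
        self.graph_ = learner.graph_
        self.transition_ = build_transition(self.graph_)

        if self.t == "auto":
            self.t_star_, self.mse_trace_ = tune_steps(V, self.transition_, self.t_max)
        else:
            self.t_star_, self.mse_trace_ = int(self.t), None
        return self

    def transform(self, X):
        check_is_fitted(self, "transition_")
        is_em = isinstance(X, ExpressionMatrix)
        values = X.values if is_em else np.asarray(X, dtype=np.float64)
        if values.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {values.shape[1]} genes; imputer was fit with {self.n_features_in_}"
            )
        V = self._preprocess(values)
        kept = V[:, self.kept_genes_]
        diffused = random_walk_impute(kept, self.transition_, self.t_star_)
        if self.rescale:
            diffused, unscaled = rescale_to_gene_means(
                diffused, kept, cells=self.rescale_cells
            )
            self.unscaled_genes_ = tuple(int(j) for j in unscaled)
        else:
            self.unscaled_genes_ = ()
        out = np.zeros_like(V)
        out[:, self.kept_genes_] = diffused
        # all-zero genes at fit time pass through unchanged
        out[:, ~self.kept_genes_] = V[:, ~self.kept_genes_]
        if is_em:
            return X.with_values(out)
        return out


def impute(
    X: ExpressionMatrix,
    t: int | Literal["auto"] = 1,
    t_max: int = 10,
    transform: Literal["none", "log1p"] = "none",
    normalize: bool = True,
    settings: SolverSettings | None = None,
    rescale_cells: Literal["all", "nonzero"] = "all",
) -> ImputationResult:
    """Run the full pipeline: normalize → distances → graph → walk → rescale.

    Thin functional wrapper over :class:`GraphDiffusionImputer`; stage errors
    propagate with a stage label in the message.
    """
    s = settings or SolverSettings()
    imputer = GraphDiffusionImputer(
        t=t,
        t_max=t_max,
        normalize=normalize,
        transform_dist=transform,
        rescale_cells=rescale_cells,
        alpha=s.alpha,
        beta=s.beta,
        max_iter=s.max_iter,
        rel_tol=s.rel_tol,
        step_scale=s.step_scale,
        weight_floor=s.weight_floor,
        distance_scale=s.distance_scale,
    )
    X_imp = imputer.fit(X).transform(X)
    gene_ids = X.gene_ids
    return ImputationResult(
        X_imputed=X_imp,
        t_star=imputer.t_star_,
        mse_trace=imputer.mse_trace_,
        rescaled=imputer.rescale,
        unscaled_genes=tuple(
            gene_ids[j]
            for j in np.flatnonzero(imputer.kept_genes_)[list(imputer.unscaled_genes_)]
        )
        if imputer.unscaled_genes_
        else (),
    )
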