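"""Down-sampling evaluation protocol for imputation accuracy.

A high-depth reference count matrix is treated as ground truth; a
down-sampled "observed" matrix is produced by masking each UMI independently
with probability ``p_mask`` (binomial thinning of each count).  Imputation
quality is then quantified by per-gene Pearson and per-cell Spearman
correlations between the imputed and reference matrices, with the unimputed
observed matrix as the baseline.  Genes are stratified by their detection
fraction in the observed data (widely / mildly / rarely expressed), since
imputation behaves very differently across those regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .diffusion import impute
from .io import ExpressionMatrix, library_size_normalize

__all__ = [
    "MaskingSpec",
    "EvalReport",
    "binomial_mask",
    "gene_wise_pearson",
    "cell_wise_spearman",
    "stratify_genes",
    "cv_per_gene",
    "inter_intra_ratio",
    "run_downsample_benchmark",
]

STRATA = ("widely", "mildly", "rarely")


@dataclass(frozen=True)
class MaskingSpec:
    """Down-sampling parameters: per-UMI masking probability and seed."""

    p_mask: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_mask <= 1:
            raise ValueError("p_mask must lie in [0, 1]")


def binomial_mask(X_ref: ExpressionMatrix, spec: MaskingSpec) -> ExpressionMatrix:
    """Mask each UMI independently with probability ``spec.p_mask``.

    Implemented as binomial thinning: each count c is replaced by a
    Binomial(c, 1 - p_mask) draw, which is distributionally identical to
    retaining each of the c UMIs independently.  Deterministic under the seed.
    """
    if not X_ref.is_count:
        raise ValueError("binomial masking requires integer counts")
    rng = np.random.default_rng(spec.seed)
    counts = X_ref.values.astype(np.int64)
    masked = rng.binomial(counts, 1.0 - spec.p_mask)
    return X_ref.with_values(masked.astype(np.float64))


def _paired_values(
    X_a: ExpressionMatrix | np.ndarray, X_b: ExpressionMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    a = X_a.values if isinstance(X_a, ExpressionMatrix) else np.asarray(X_a, dtype=np.float64)
    b = X_b.values if isinstance(X_b, ExpressionMatrix) else np.asarray(X_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per column; NaN where either column is constant."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def gene_wise_pearson(
    X_a: ExpressionMatrix | np.ndarray, X_b: ExpressionMatrix | np.ndarray
) -> np.ndarray:
    """Pearson correlation across cells, per gene; NaN for constant genes."""
    a, b = _paired_values(X_a, X_b)
    return _columnwise_pearson(a, b)


def cell_wise_spearman(
    X_a: ExpressionMatrix | np.ndarray, X_b: ExpressionMatrix | np.ndarray
) -> np.ndarray:
    """Spearman rank correlation across genes, per cell (average ranks on ties)."""
    a, b = _paired_values(X_a, X_b)
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    return _columnwise_pearson(ra.T, rb.T)


def stratify_genes(
    X_obs: ExpressionMatrix | np.ndarray, lower: float = 0.3, upper: float = 0.8
) -> tuple[np.ndarray, dict[str, int]]:
    """Label genes widely/mildly/rarely expressed by detection fraction.

    A gene is *widely* expressed if detected (nonzero) in strictly more than
    ``upper`` of cells, *rarely* if in strictly less than ``lower``, and
    *mildly* otherwise (boundaries fall in the middle bin).
    """
    if not 0 <= lower < upper <= 1:
        raise ValueError("need 0 <= lower < upper <= 1")
    v = X_obs.values if isinstance(X_obs, ExpressionMatrix) else np.asarray(X_obs)
    frac = (v > 0).mean(axis=0)
    labels = np.full(v.shape[1], "mildly", dtype=object)
    labels[frac > upper] = "widely"
    labels[frac < lower] = "rarely"
    counts = {s: int(np.sum(labels == s)) for s in STRATA}
    return labels, counts


def cv_per_gene(
    X: ExpressionMatrix | np.ndarray, cells: Literal["all", "nonzero"] = "all"
) -> np.ndarray:
    """Coefficient of variation (sample sd / mean) per gene; NaN if undefined.

    ``cells="nonzero"`` restricts to cells where the gene is detected.  The CV
    is undefined (NaN) when the mean is 0 or fewer than 2 cells remain.
    """
    v = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    out = np.full(v.shape[1], np.nan)
    for j in range(v.shape[1]):
        col = v[:, j]
        if cells == "nonzero":
            col = col[col > 0]
        elif cells != "all":
            raise ValueError(f"unknown cells mode {cells!r}")
        if col.size < 2:
            continue
        mean = col.mean()
        if mean == 0:
            continue
        out[j] = col.std(ddof=1) / mean
    return out


def inter_intra_ratio(
    scores: np.ndarray, labels, k_max: int = 50
) -> np.ndarray:
    """Inter/intra-subtype mean-distance ratio using the top K coordinates.

    ``scores`` is a cells x components table (e.g. PC scores).  For each
    K = 1..k_max, returns the mean Euclidean distance over all cross-subtype
    cell pairs divided by the mean over within-subtype pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ValueError("scores must be cells x components matching labels")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two subtypes")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"subtype(s) with fewer than 2 cells: {small}")
    k_max = min(k_max, scores.shape[1])
    n = labels.size
    ii, jj = np.triu_indices(n, k=1)
    same_pair = labels[ii] == labels[jj]
    ratios = np.empty(k_max)
    for k in range(1, k_max + 1):
        d = pdist(scores[:, :k], metric="euclidean")
        intra = d[same_pair].mean()
        inter = d[~same_pair].mean()
        if intra == 0:
            raise ValueError(f"zero average intra-subtype distance at K={k}")
        ratios[k - 1] = inter / intra
    return ratios


@dataclass
class EvalReport:
    """Recovery statistics for one down-sampling experiment."""

    gene_correlations: np.ndarray
    cell_correlations: np.ndarray
    baseline_gene_correlations: np.ndarray
    baseline_cell_correlations: np.ndarray
    strata: np.ndarray
    strata_counts: dict[str, int]
    cv_reference: np.ndarray
    cv_observed: np.ndarray
    cv_correlation: float
    t_star: int
    mse_trace: np.ndarray | None = None

    def median_gene_correlation(
        self, stratum: str | None = None, baseline: bool = False
    ) -> float:
        """Median per-gene Pearson r, optionally within one stratum."""
        r = self.baseline_gene_correlations if baseline else self.gene_correlations
        if stratum is not None:
            r = r[self.strata == stratum]
        r = r[~np.isnan(r)]
        return float(np.median(r)) if r.size else float("nan")

    def median_cell_correlation(self, baseline: bool = False) -> float:
        r = self.baseline_cell_correlations if baseline else self.cell_correlations
        r = r[~np.isnan(r)]
        return float(np.median(r)) if r.size else float("nan")

    def summary(self) -> dict:
        out = {
            "median_cell_spearman": self.median_cell_correlation(),
            "median_cell_spearman_baseline": self.median_cell_correlation(baseline=True),
            "cv_correlation": self.cv_correlation,
            "t_star": self.t_star,
            "strata_counts": dict(self.strata_counts),
        }
        for s in STRATA:
            out[f"median_gene_pearson_{s}"] = self.median_gene_correlation(s)
            out[f"median_gene_pearson_{s}_baseline"] = self.median_gene_correlation(
                s, baseline=True
            )
        return out


def run_downsample_benchmark(
    X_ref: ExpressionMatrix,
    spec: MaskingSpec | None = None,
    impute_kwargs: dict | None = None,
    lower: float = 0.3,
    upper: float = 0.8,
) -> EvalReport:
    """Mask the reference, impute the observed data, and score the recovery.

    The imputed, observed and reference matrices are library-size normalized
    to the reference's median cell total before computing correlations, so
    depth differences introduced by masking do not dominate the comparison.
    Strata are assigned from detection fractions in the *observed* counts.
    """
    spec = spec or MaskingSpec()
    if not X_ref.is_count:
        raise ValueError("the down-sampling benchmark requires integer reference counts")
    X_obs = binomial_mask(X_ref, spec)
    result = impute(X_obs, **(impute_kwargs or {"t": "auto"}))

    target = float(np.median(X_ref.cell_totals()))
    ref_n = library_size_normalize(X_ref, target)
    obs_n = library_size_normalize(X_obs, target)
    imp_n = library_size_normalize(result.X_imputed, target)

    strata, counts = stratify_genes(X_obs, lower=lower, upper=upper)
    cv_ref = cv_per_gene(X_ref, cells="nonzero")
    cv_obs = cv_per_gene(X_obs, cells="all")
    ok = ~np.isnan(cv_ref) & ~np.isnan(cv_obs)
    cv_corr = (
        float(np.corrcoef(cv_ref[ok], cv_obs[ok])[0, 1]) if ok.sum() >= 2 else float("nan")
    )
    return EvalReport(
        gene_correlations=gene_wise_pearson(ref_n, imp_n),
        cell_correlations=cell_wise_spearman(ref_n, imp_n),
        baseline_gene_correlations=gene_wise_pearson(ref_n, obs_n),
        baseline_cell_correlations=cell_wise_spearman(ref_n, obs_n),
        strata=strata,
        strata_counts=counts,
        cv_reference=cv_ref,
        cv_observed=cv_obs,
        cv_correlation=cv_corr,
        t_star=result.t_star,
        mse_trace=result.mse_trace,
    )
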