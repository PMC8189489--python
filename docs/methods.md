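# Methods

## Model and assumptions

graphimpute treats the `m` genes of a cells × genes expression matrix
`X ∈ R^{n×m}` as nodes of a weighted undirected graph and each gene's
expression profile across cells as a signal on that graph. The working
assumption is that co-regulated genes have similar profiles, so a faithful
gene graph lets dropout zeros in one gene be filled from its neighbors
without averaging over cells (which would erase cell-to-cell variability and
amplify subject effects).

The adjacency `W` is the minimizer over
`𝒲 = {W ≥ 0, W = Wᵀ, diag(W) = 0}` of

```
‖W ∘ Z‖₁,₁ − 1ᵀ log(W1) + ½‖W‖²_F,        Z_jk = ‖x_j − x_k‖².
```

- The smoothness term `‖W∘Z‖₁,₁ = 2 tr(X L Xᵀ)` penalizes edges between
  dissimilar genes (L is the graph Laplacian).
- The log-degree barrier `−1ᵀlog(W1)` forces every gene's degree to stay
  strictly positive, guaranteeing node-level connectivity. Without it the
  smoothness + Frobenius terms would return the empty graph.
- The Frobenius term discourages a few dominant edges; together with the L1
  smoothness term it yields sparse graphs.

In half-vectorized form over the `m(m−1)/2` unordered gene pairs
(upper-triangular, row-major — the scipy `squareform` convention, used
everywhere in the package) the problem is

```
min_{w≥0}  2wᵀz − α·1ᵀlog(Kw) + β‖w‖²,
```

where `K` is the degree operator (`W1 = Kw`). `α = β = 1` reproduces the
matrix objective exactly and is the default; both are exposed because they
control smoothness vs sparsity trade-offs, but no automatic selection is
attempted.

Imputation is a lazy random walk with transition matrix `M = (D⁻¹W + I)/2`
(row-stochastic, diagonal exactly 1/2, invariant under rescaling of `W`):
`X_imputedᵀ = Mᵗ Xᵀ`, followed by a per-gene rescaling so every gene's mean
over all cells matches its observed mean. Each imputed entry is a convex
combination of the cell's observed values across genes, so values stay within
the cell's observed range before rescaling. Note the walk redistributes
counts across genes within a cell; per-cell totals are only approximately
conserved, which is one reason the per-gene mean rescaling is applied.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `t` | 1 | diffusion steps; 1 avoids over-smoothing. `"auto"` selects `t* = argmin_t MSE(MᵗXᵀ, Xᵀ)` over `1..t_max`, ties to the smallest t |
| `t_max` | 10 | search range for `t="auto"` |
| `normalize` | True | median-target library-size normalization before graph learning (recommended for UMI data so depth does not drive distances) |
| `alpha`, `beta` | 1, 1 | barrier and sparsity coefficients of the objective |
| `rel_tol` | 1e-5 | convergence: relative ℓ2 change of `w` per iteration |
| `max_iter` | 100 000 | iteration cap; exceeded ⇒ `ConvergenceError` with the trace |
| `step_scale` | 0.5 | fraction of the maximal provably convergent step size |
| `weight_floor` | 0 | post-hoc zeroing of tiny edges, applied only if degrees stay positive |
| `distance_scale` | 1 | uniform rescaling of `z`; with fixed α, β the graph's sparsity depends on the scale of `Z` |
| `rescale_cells` | "all" | cells over which the observed gene mean is computed when rescaling ("nonzero" offered as an alternative) |

The MSE criterion for `t` is computed as the mean squared entrywise
difference — the natural reading of "minimize the MSE between imputed and
observed data"; the tie-break to the smallest `t` prefers less smoothing.

## Numerical choices

- **Solver.** Primal-dual forward-backward-forward iteration with the dual
  variable attached to the degree map `K` (‖K‖ = √(2(m−1))). Step size
  `γ = step_scale/(2β + ‖K‖)`, within the scheme's convergence range
  `γ < 1/(2β + ‖K‖)`. The objective is strictly convex on the feasible set,
  so the optimum is unique; the solver's correctness contract is agreement
  with an independent convex minimizer on small instances (tested), not any
  particular iteration path.
- **Scale conditioning.** Raw squared distances can be numerically huge. The
  solver uses the exact reparametrization `w = c·u` with `c = 1/mean(z)`,
  equivalent to solving with `z → cz`, `β → βc²`: the optimum is unchanged
  but the iterates and dual variables stay O(1) at any distance scale.
- **Convergence** is declared when the relative ℓ2 change of `w` drops below
  `rel_tol`. At realistic sizes (hundreds of genes) the fixed-step scheme
  needs tens of thousands of cheap O(m²) vector iterations, hence the large
  default `max_iter`.
- **Degenerate inputs.** Genes that are zero in every cell carry no pairwise
  information and would force the barrier to attach edges to uninformative
  nodes; they are removed before graph learning and re-inserted unchanged.
  Cells with zero totals make library-size normalization undefined and raise
  an error instructing the caller to filter first. Genes with zero observed
  mean are output as all-zero; genes whose diffused mean is zero while the
  observed mean is positive cannot be mean-matched multiplicatively and are
  left unscaled with a warning.
- **Diffusion** applies `M` iteratively (`t` dense products), never via
  eigendecomposition — exact and O(t·m²·n).
- **Memory.** Graph learning uses dense pair vectors and m×m workspaces:
  O(m²) memory. Pre-filter genes (as is standard for reference sets of a few
  thousand genes) before learning graphs over very large gene sets.

## Evaluation protocol

`binomial_mask` replaces each count `c` by `Binomial(c, 1−p_mask)` — exactly
the distribution of retaining each of the `c` UMIs independently, without
materializing individual UMIs. The benchmark masks a high-depth reference at
`p_mask = 0.8`, imputes the masked matrix, library-size normalizes reference,
observed and imputed matrices to the reference's median cell total, and
reports per-gene Pearson (across cells) and per-cell Spearman (across genes,
average ranks on ties) correlations against the reference, for both the
imputed matrix and the unimputed observed baseline. Genes are stratified by
detection fraction in the observed data: widely (> 80%), mildly (30–80%,
boundaries inclusive), rarely (< 30%). Constant genes/cells yield undefined
correlations, reported as missing and excluded from medians — never silently
zero. CV diagnostics use the sample (n−1) standard deviation. The
inter/intra-subtype distance ratio takes a precomputed coordinate table
(e.g. PC scores) — computing PCs is standard and not re-implemented; the
bespoke statistic is the ratio itself.

## Synthetic generator

`generate_reference` draws, per cell, a global activity and one activity per
gene block from a mean-1 Gamma with variance `dispersion` (default 0.5), and
gene counts from `Poisson(mu_j · (s·a_block + (1−s)·a_global))` with
`s = within_block_strength`. Marginally each gene is Gamma-Poisson
(over-dispersed, UMI-like); genes in the same block are positively correlated
through the shared activity. Base means are log-uniform on (0.1, 20) so that
after 80% masking all three detection strata are populated (roughly 10–20% of
genes widely expressed). The benchmark defaults — 300 genes, 500 cells, 6
blocks, strength 0.9, 80% masking — are the study conditions used by the
tests and the acceptance script.

What the generator does **not** emulate: negative gene-gene correlations
(all pairs share nonnegative activity mixtures), batch/subject effects,
cell-type or trajectory structure, and real-data library-size distributions.
Consequently, passing recovery tests shows the pipeline exploits modular
positive co-expression under binomial dropout; it does not certify behavior
on negatively correlated regulons or multi-subject data. One visible
consequence: the CV-before/after-masking diagnostic, which on real tissue
reference sets correlates positively, can correlate negatively on this
generator because conditioning the reference CV on nonzero cells interacts
differently with the generator's mean-variance profile.

## Design choices on genuinely open points

- Canonical orientation is cells × genes in memory; on-disk MatrixMarket
  defaults to genes-in-rows (10x convention) with an override flag.
- Reference filtering is cells first then genes, strict inequalities.
- Library-size normalization target defaults to the median cell total
  (scale-free, robust); normalization before graph learning is on by default
  for the benchmark pipeline but exposed as a flag, since either choice is
  defensible and distances are depth-sensitive.
- No transform is applied before computing `Z` by default (the literal
  squared-Euclidean definition); `log1p` is offered as an option.
- Rescaling means are over all cells (zeros included); a "nonzero" mode is
  provided as the alternative reading.
- The MSE trace is empirically non-decreasing in `t` (diffusion moves
  monotonically away from the observed matrix), which is why the tuned
  `t*` equals 1 on every benchmark tested; the default is therefore `t = 1`.

## Known limitations

- All values are imputed at once; no dropout-probability model decides which
  zeros are technical, so truly-zero entries are also smoothed (and then
  partially restored by the mean rescaling).
- Edge weights depend only on gene-gene similarity, not on observation
  reliability (library size, dispersion).
- Rarely expressed genes (< 30% detection) are not improved — there is too
  little signal to diffuse; this matches the evaluation results.
- O(m²) memory and a fixed-step first-order solver make graphs over more
  than a few thousand genes slow; pre-filter genes first.
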