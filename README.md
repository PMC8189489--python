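# graphimpute

Dropout imputation for single-cell RNA-seq count matrices by diffusion on a
learned gene-gene graph.

Single-cell RNA-seq measures the transcriptome of individual cells, but
inefficient transcript capture produces *dropouts*: genes that are expressed
in a cell yet recorded as zero. graphimpute recovers these values by
borrowing information across **similar genes** rather than similar cells,
which preserves cell-to-cell variability and avoids amplifying subject-level
batch structure. It is aimed at analysts preparing UMI count matrices for
clustering, trajectory and differential-expression analyses.

## Method

Let `X ∈ R^{n×m}` hold counts of `m` genes in `n` cells; column `x_j` is gene
`j`'s expression across cells, viewed as a signal on a gene graph. The graph
adjacency `W` (symmetric, nonnegative, zero diagonal) is learned by solving
the convex problem

```
min_W  ‖W ∘ Z‖₁,₁  −  1ᵀ log(W1)  +  ½‖W‖²_F
```

where `Z_jk = ‖x_j − x_k‖²`. The first term (equal to the Laplacian quadratic
form `2·tr(X L Xᵀ)`) favors edges between genes with similar signals, the
log-degree barrier keeps every gene connected, and the Frobenius penalty
keeps edges sparse and small. In half-vectorized form over gene pairs the
problem is `min_{w≥0} 2wᵀz − 1ᵀlog(Kw) + ‖w‖²` with `K` the degree operator;
it is solved by a primal-dual forward-backward-forward scheme.

Imputation is a lazy random walk on this graph:

```
M = (D⁻¹W + I)/2,      X_imputedᵀ = Mᵗ Xᵀ
```

so each gene becomes a convex combination of itself (weight ≥ 1/2) and its
graph neighbors. One step (`t = 1`) is the default to avoid over-smoothing;
`t = "auto"` selects `t* = argmin_t ‖MᵗXᵀ − Xᵀ‖` (mean squared difference
from the observed data) over `t = 1..10`. Finally each gene is rescaled so
its mean across cells matches the observed mean.

The package also ships the standard down-sampling evaluation protocol
(binomial thinning that masks each UMI independently, gene-wise Pearson and
cell-wise Spearman recovery correlations, detection-fraction gene strata,
CV diagnostics, inter/intra-subtype distance ratios) and a seeded synthetic
generator with planted gene modules, so the whole pipeline is testable
without external data.

## Worked example

```python
import numpy as np
from graphimpute import (generate_reference, make_benchmark, MaskingSpec,
                         run_downsample_benchmark)

ds = generate_reference(m=300, n=500, n_blocks=6,
                        within_block_strength=0.9, seed=7)
report = run_downsample_benchmark(ds.X_true, MaskingSpec(p_mask=0.8, seed=11))
print("t* =", report.t_star)
print("widely expressed: imputed %.3f vs observed %.3f" % (
    report.median_gene_correlation("widely"),
    report.median_gene_correlation("widely", baseline=True)))
print("mildly expressed: imputed %.3f vs observed %.3f" % (
    report.median_gene_correlation("mildly"),
    report.median_gene_correlation("mildly", baseline=True)))
```

prints

```
t* = 1
widely expressed: imputed 0.807 vs observed 0.751
mildly expressed: imputed 0.630 vs observed 0.605
```

After masking 80% of UMIs, the MSE-tuned walk length is a single step, and
the median per-gene Pearson correlation with the hidden truth is higher for
the imputed data than for the raw down-sampled data in both the widely
(detected in >80% of cells) and mildly (30–80%) expressed strata — the raw
data remains a better estimate only for rarely expressed genes, which carry
too little signal to impute.

The same pipeline is available from the shell:

```bash
graphimpute simulate --genes 300 --cells 500 --blocks 6 --seed 7 --out-prefix sim
graphimpute impute --input sim_observed.mtx --output imputed.mtx --steps auto
graphimpute evaluate --reference sim_true.mtx --observed sim_observed.mtx \
                     --imputed imputed.mtx --report report
```

As a scikit-learn transformer:

```python
from graphimpute import GraphDiffusionImputer
X_imputed = GraphDiffusionImputer(t=1).fit_transform(X_counts)  # cells x genes
```

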