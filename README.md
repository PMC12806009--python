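# vmpln

Joint cell clustering and sparse gene-regulatory-network inference from
single-cell RNA-seq count data, via a variational mixture Poisson
log-normal (MPLN) model.

## Why

Most scRNA-seq datasets mix several cell types, each with its own
expression program and regulatory network. The standard two-step recipe —
cluster first, then estimate one network per cluster — breaks down when
populations overlap: cells near a cluster boundary are assigned
arbitrarily, and the misassignment propagates into badly biased precision
matrices. `vmpln` instead fits clustering and network inference *jointly*:
soft cell-type responsibilities and per-type networks regularize each
other inside a single objective.

## Model

For cells *i* = 1..n and genes *j* = 1..p with counts *Y*, library sizes
*l*, and G latent populations:

    Z_i ~ Multinomial(1, π)
    X_i | Z_i = g ~ N(μ_g, Θ_g⁻¹)
    Y_ij | X_ij ~ Poisson(l_i · exp(X_ij))

Each population's precision matrix Θ_g is the object of interest: a zero
off-diagonal entry means conditional independence between two genes, so
the support of Θ_g is population g's regulatory network, and the signed
edge weight is the partial correlation −Θ_lm/√(Θ_ll·Θ_mm).

The marginal likelihood is intractable, so the package maximizes an
evidence lower bound (ELBO) over a mean-field family — per-cell normal
posteriors N(M_g,ij, S_g,ij) for the latent log-expression and
responsibilities P_ig for cell type — penalized by λ·Σ_g‖Θ_g‖₁,off to make
the networks sparse. A block-descent loop cycles through closed-form
updates (P, π, μ), scalar Newton solves (S), an ADMM solver for the
coupled means M that needs only one matrix factorization per population
per sweep, and one graphical-lasso problem per Θ_g. The penalty is chosen
per population either by an integrated-complete-likelihood (ICL) score or
by targeting a desired network density.

The package also ships the benchmarking stack around the model: seeded
generators for ground-truth graphs (random / hub / blocked / scale-free
topologies with ±0.3 edges), MPLN and misspecified multinomial log-normal
count simulators with calibrated population-mixing and dropout levels,
and density-normalized recovery metrics (pAUPRC ratio, early precision
ratio, down-sampling stability).

## Worked example

```python
import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from vmpln import (FitConfig, TrueNetwork, generate_graph, simulate_mpln,
                   select_lambda_density, vmpln_edge_scores, pauprc_ratio)
from vmpln.simulation import calibrate_mixing_dropout

G, p, n = 3, 50, 1500
graphs = [generate_graph("hub", p, seed=101 + g) for g in range(G)]
pi = np.full(G, 1 / G)
cal = calibrate_mixing_dropout(np.zeros((G, p)), "low", "low", graphs,
                               pi=pi, seed=101)
ds = simulate_mpln(graphs, cal.mus, pi, n, seed=101)

path = select_lambda_density(ds.data, FitConfig(G=G, seed=0,
                                                max_outer_iter=25), 0.20)
fit_res = path.fit_result
print("clustering ARI:",
      round(adjusted_rand_score(ds.true_labels, fit_res.cluster_labels), 2))

# match fitted groups to the simulated truth by cluster-label overlap
overlap = np.array([[np.sum((ds.true_labels == t) & (fit_res.cluster_labels == f))
                     for f in range(G)] for t in range(G)])
_, col = linear_sum_assignment(-overlap)

scores = vmpln_edge_scores(fit_res)
for t in range(G):
    truth = TrueNetwork(adjacency=graphs[t].adjacency)
    print(f"population {t}: pAUPRC ratio "
          f"{pauprc_ratio(scores[col[t]], truth, 0.2):.2f}")
```

Output from this exact script:

```
clustering ARI: 0.99
population 0: pAUPRC ratio 21.08
population 1: pAUPRC ratio 26.84
population 2: pAUPRC ratio 18.32
```

A ratio of 1 means no better than random edge ranking at that density; a
perfect ranking here would score 1/d_true ≈ 27.

The same workflow is available from the shell:

```bash
vmpln simulate --kind hub --p 50 --n 1500 --g 3 --seed 1 --out sim/
vmpln fit --counts sim/counts.mtx --g 3 --select density --target 0.20 --out fit/
vmpln evaluate --scores fit/precision_group0.tsv --truth sim/adjacency_group0.tsv \
      --from-precision --density 0.20
```

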