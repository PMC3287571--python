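# ssmgrn

Gene regulatory network (GRN) inference from short time-series expression
data with a linear-Gaussian state space model (SSM).

Time-course microarray or RNA profiling experiments measure many genes at
few time points. `ssmgrn` infers a directed gene regulatory network from
such data by fitting a latent linear dynamical system

```
x_t = F x_{t-1} + w_t ,   w_t ~ N(0, Q)        (state equation)
y_t = H x_t     + v_t ,   v_t ~ N(0, R)        (observation equation)
```

where `y_t` is the vector of `l` gene expression values at time `t` and
`x_t` is an `m`-dimensional hidden state (`m << l`, the "hidden variables"
that make estimation feasible when `T << l`). Parameters are estimated by
EM: the E-step is an exact Kalman filter plus Rauch–Tung–Striebel smoother,
the M-step updates `F, H, Q, diag(R), mu0` in closed form. The fitted model
is projected back to the genes through the connectivity matrix

```
C = H F (H'H)^{-1} H'
```

whose entry `C[i][j]` scores the influence of gene `j` on gene `i`; directed
edges `gene_j -> gene_i` are called from `|C_ij|` either by a threshold or
by taking the top `k` entries. The hidden dimension `m` can be fixed,
selected by BIC (`ll - (1/2) N_theta ln N`, maximized), or by the PCA rule
(smallest `m` whose residual eigenvalue mass is at most 20%). Inferred
networks are scored against gold standards by precision/recall and ROC /
AUROC over all ordered gene pairs. A seeded synthetic benchmark generator
(sparse hub-biased topologies driving a stable linear autoregression)
provides gold standards and datasets at published benchmark scales
(10 networks of 30 genes x 41 time points, 10 of 50 genes x 101 time
points), so the whole pipeline is testable offline.

Audience: computational biologists benchmarking network-inference methods
on time-series data, and anyone needing a compact, exact, seeded
linear-Gaussian SSM/EM implementation with network readouts.

## Worked example

```python
import numpy as np
from ssmgrn import StateSpaceGRN, generate_network, simulate_expressions

net = generate_network(n_genes=10, n_edges=20, seed=0)       # gold standard
data = simulate_expressions(net, T=500, noise_sd=0.1, seed=0)

res = StateSpaceGRN(data, m=3).fit(max_iter=150, seed=0)
print(res.summary())
ev = res.score(net, top_k=20)
print(f"precision={ev.precision:.2f} recall={ev.recall:.2f} "
      f"auroc={res.roc(net).auroc:.3f}")
```

prints

```
Linear-Gaussian state space model (EM fit)
============================================
genes (l):            10
time points (T):      500
hidden dimension (m): 3
free parameters:      58
log-likelihood:       2548.7104
BIC (max is best):    2301.7118
EM iterations:        150 (max_iter reached)
restart used:         0
|C| off-diagonal:     max 0.3731, median 0.0757
precision=0.60 recall=0.60 auroc=0.761
```

Twelve of the 20 top-scoring edges are true edges of the 22%-dense gold
standard (precision 0.60, well above the 0.22 random-guess baseline), and
an AUROC of 0.76 says true edges receive systematically larger `|C_ij|`
than non-edges. The same workflow is available from the shell:

```sh
ssmgrn simulate --preset 30x41 --seed 7 --outdir bench/
ssmgrn select-m --data bench/dataset_01.tsv --method pca --fraction 0.2
ssmgrn fit --data bench/dataset_01.tsv --m 2 --seed 0 --out model.txt
ssmgrn infer --model model.txt --top-k 101 --out-network inferred.tsv
ssmgrn evaluate --inferred inferred.tsv --truth bench/gold_01.tsv
ssmgrn roc --model model.txt --truth bench/gold_01.tsv --out roc.tsv
ssmgrn sweep-m --preset 30x41 --seed 7 --out sweep.tsv
```

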