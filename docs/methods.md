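# Methods

## Model

`ssmgrn` fits the time-invariant linear-Gaussian state space model

    x_t = F x_{t-1} + w_t,   w_t ~ N(0, Q),    x_1 ~ N(mu0, Sigma0)
    y_t = H x_t     + v_t,   v_t ~ N(0, R)

to an `l x T` expression matrix (genes as rows). The hidden state dimension
`m` is the central tuning quantity: it trades identifiability (the number
of free parameters grows roughly as `m^2 + l*m`, while the data supply only
`l*T` numbers) against the rank of the gene-level readout. The model
assumes stationary linear dynamics, Gaussian noise, and no intercept, which
is why every gene row is mean-centered across time before fitting.

Assumed noise structure: `Q` is a full symmetric PSD matrix; `R` is
constrained diagonal. With `l` in the tens and `T` below ~100, a full `R`
(l(l+1)/2 parameters) would be unidentifiable; a diagonal `R` reads as
independent per-gene measurement noise. `Sigma0` is held fixed at the
identity rather than re-estimated: with a single observed trajectory the
initial-state covariance is not identifiable, and re-estimating it drives
`Sigma0 -> 0` at no benefit.

## Estimation

The E-step is exact: a forward Kalman filter (prediction-error
decomposition gives the marginal log-likelihood), an RTS backward smoother,
and the lag-one smoothed covariances `Cov(x_{t+1}, x_t | y_1..T) =
P^s_{t+1} J_t'`. The M-step is the standard closed form from the smoothed
second moments; `F`, `H`, full `Q`, `diag(R)` and `mu0` are updated
jointly, which can only increase the marginal likelihood, so every
log-likelihood trace is non-decreasing (asserted in the tests to 1e-6).

Initialization is deterministic and data-driven: `H` from the first `m`
principal-component loadings of the centered data, latent scores from the
PC scores, `F` by regressing scores at `t` on `t-1`, `Q` and `diag(R)` from
the residual variances, `mu0` from the first score column. Optional
restarts perturb this start with seeded Gaussian noise (10% of the largest
entry magnitude of `F` and `H`); the restart with the best final
log-likelihood wins, ties to the lowest index.

Numerical choices: all covariance recursions symmetrize their outputs;
innovation and prediction covariances are solved by Cholesky with a
jitter-retry policy (add 1e-10 I, escalate tenfold at most three times
before raising); the M-step floors the diagonal of `R` at 1e-10 and adds
1e-10 I to `Q` against roundoff-negative eigenvalues. Convergence is
declared when `|dll| / (1 + |ll|) < 1e-6` (default `max_iter` 500).
Constant gene rows are retained with a warning — centered to zero they
carry no signal and can never earn edges. The latent basis is only
identified up to orthogonal rotation; the likelihood and the connectivity
matrix are rotation-invariant (tested), so this non-identifiability is
harmless for network inference.

## Choosing the hidden dimension

Three modes:

* **fixed** — the user sets `m`; small values (1–5) are the intended
  operating regime of the method.
* **BIC** — each candidate is fitted by EM and scored with
  `ll - (1/2) N_theta ln N`, maximized, ties to smaller `m`. The
  likelihood term is the *marginal* log-likelihood from the Kalman filter
  (the complete-data likelihood is not computable because the states are
  latent). `N_theta = m^2 + lm + m(m+1)/2 + l + m` counts exactly the
  scalars the M-step updates. `N` defaults to `l*T` scalar observations;
  `N = T` is available as a switch since either reading of "number of data
  points" is defensible.
* **PCA** — eigenvalues of the gene-by-gene covariance matrix (computed
  via singular values of the centered data; at most `min(l, T-1)` are
  nonzero, values below 1e-12 of the largest are treated as zero). The rule
  picks the smallest `m` with residual mass `sum_{k>m} λ_k / sum λ_k <=
  0.2` by default.

## From parameters to a network

`C = H F (H'H)^{-1} H'` with the convention `C[i][j]` = effect of gene `j`
on gene `i`. When `cond(H'H) >= 1e12` the Moore–Penrose pseudo-inverse is
used with a warning (near-collinear loadings are likely at small `T`).
Edge calling excludes the diagonal (self-loops are not part of the gold
standards), keeps the signed weight but evaluates unsigned, and is either
`|C_ij| >= th` or the top-`k` entries with a deterministic tie-break
(larger `|C|`, then smaller row, then smaller column index).

Evaluation: precision = TP / inferred edges, recall = TP / true edges,
with exact directed matching. ROC sweeps the threshold over every distinct
off-diagonal `|C_ij|`; the candidate universe is all ordered off-diagonal
pairs; AUROC by the trapezoid rule. Curves from several networks are
averaged by interpolating TPR onto a common FPR grid (101 evenly spaced
points by default). The random-guess baseline precision equals the gold
standard's edge density `|E| / (l(l-1))`.

## Synthetic benchmarks

The generator stands in for simulator-based benchmark suites that extract
sparse subnetworks of curated E. coli / yeast regulatory maps and simulate
expression from them. Topologies: exactly `n_edges` directed edges, no
self-loops, regulators drawn with probability proportional to
`1 + hub_bias * out_degree` (preferential attachment; `hub_bias = 0` is
uniform, default 1.0 gives mild hubs as in curated maps). Dynamics: a
gene-level linear autoregression `y_t = A y_{t-1} + eps_t` with nonzero
entries of `A` exactly on (target, regulator) positions, weights of
magnitude Uniform[0.5, 1.5] with random sign (so no true effect is
unlearnably small), `A` rescaled to spectral radius 0.9 (stationarity),
isotropic process noise `noise_sd = 0.1` (the data are scale-free in this
choice: the whole matrix scales linearly with it), and 50 burn-in steps.
Presets match the published benchmark scales: 10 networks of 30 genes x 41
time points (101 edges each) and 10 networks of 50 genes x 101 time points
(169 edges, the density of the published 50-gene example network).

What the generator does **not** emulate: nonlinear (saturating) kinetics,
perturbation/relaxation experimental designs, mRNA/protein separation, and
technical noise models of real microarrays. Passing benchmarks here
therefore demonstrates that the pipeline recovers sparse directed linear
influence from short noisy series — not performance on real expression
data. One consequence worth stating plainly: on this linear, stationary
benchmark the top-k precision *increases* with the hidden dimension,
because a higher-rank `C` simply approximates the true gene-level operator
better; the often-reported advantage of very small `m` did not reproduce
here under any surrogate variant we examined (heavier measurement noise,
low-dimensional driving noise, relaxation trajectories, saturating
dynamics, random EM initialization). Small `m` remains the right regime
for real data with few informative dimensions, but it is a modelling
judgement, not a property this benchmark can certify.

## Problem sizes used in tests

Exactness checks run on instances with `m <= 4`, `l <= 5`, `T <= 8`
against a brute-force stacked-joint-Gaussian oracle. EM behavior is
checked on tens of fits of small mixed shapes, and the benchmark-level
properties on the two presets above (10 networks each, EM capped at
150–500 iterations; the cap is stated in each test). The acceptance script
uses the same presets with 200–300 EM iterations and 10 BIC-recovery
seeds.

## Known limitations

* Single-trajectory fitting only: no replicate series, no missing data.
* BIC with `N = l*T` penalizes heavily; on short series it tends toward
  very small `m` (the `N = T` switch is gentler).
* The marginal likelihood surface is multimodal; the PCA initialization is
  good in practice but global optimality is not guaranteed — use restarts
  for difficult fits.
* Edge weights are linear effect sizes of a misspecified model on real
  (nonlinear) systems; their sign is reported but unvalidated.
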