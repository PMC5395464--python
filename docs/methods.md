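# Methods

## Model

Traits evolve by Brownian motion (BM) along a rooted phylogeny. For a
single trait with rate `sigma^2`, tip values are jointly normal with
mean `mu0 * 1` and covariance `sigma^2 * C`, where `C_ij` is the depth
of the most recent common ancestor of tips `i` and `j`. For `M` traits
with rate matrix `Sigma` (M x M, positive definite), the stacked tip
vector (trait-major: entry `m*N + i` is trait `m` at tip `i`) has
covariance `W = Sigma (x) C` (Kronecker product).

The ML ancestral state at node `e` is the GLS mean estimator computed
with `e` as the root. Because BM is time-reversible, rerooting changes
`C` but the estimator can be obtained for every node without ever
forming a rerooted covariance matrix.

## The two-pass algorithm

**Node numbering.** Tips are numbered `1..N` in Newick left-to-right
order, the root is `N+1`, and remaining internal nodes follow in
preorder discovery order.

**Postorder pass.** For each edge `e` (from child `e` to its parent),
local quantities summarize the subtree below `e` as seen from the
parent end of the edge, with edge length `t`:

- tips: `mu~ = y`, `p~ = 1/t`, `U~' = L/t`, `V~ = R/t`,
  `Q~ = L'R/t`, `log|C~| = log t`;
- internal nodes: sum the daughters' local quantities (`pA = sum p~(d)`,
  likewise `UA, VA, QA, log|CA| = sum log|C~(d)|`), then "stretch" by
  the edge: with `F = 1 + t*pA` (scalar) or `F = I + T(e) @ pA`
  (matrix),

  ```
  p~ = pA / F          U~' = UA / F         V~ = VA / F
  Q~ = QA - UA (T/F) VA                     log|C~| = log|CA| + log|F|
  ```

`L` and `R` are design matrices: `L = 1`, `R = y` reproduces the scalar
recursion; `L = [1 y]`, `R = [1 y]` yields the cross-product matrix `Q`
whose entries give both the estimator and the residual quadratic form.
In the multivariate pass `L` is the trait-indicator block and
`R = [indicator | y]`, so the root `Q` holds `Q11 = L'W^-1 L` and
`Q1y = L'W^-1 y` and `mu_hat = Q11^-1 Q1y`.

At the root there is no stretch (`t = 0`), so root locals are already
the global (rerooted-at-root) quantities.

**Preorder pass.** For each non-root internal edge `e` with parent `a`,
remove `e`'s own local contribution from the parent's globals and
stretch the remainder *down* the edge:

```
p_oth   = p(a) - p~(e)
F_o     = 1 + t * p_oth                  (matrix: I + T(e) @ p_oth)
p(e)    = pA(e) + p_oth / F_o
U'(e)   = UA(e) + (U'(a) - U~'(e)) / F_o
Q(e)    = QA(e) + (Q(a) - Q~(e)) - dU (t/F_o) dV
log|C(e)| = log|C(a)| - log|F(e)| + log|F_o|
```

where `F(e)` is the stretch factor stored during the postorder pass and
`dU, dV` are the parent-minus-local differences. Each pass touches each
edge exactly once, so the total cost is `O(N M^3)`.

**Numerical form of the "un-stretch".** Removing the stretch from a
local quantity could be written `p~ / (1 - t p~)`, which cancels
catastrophically for long edges. We instead use the identity
`1 - t p~ = 1/(1 + t pA)`: the un-stretched quantity *equals the stored
pre-stretch sum* (`p* = pA`, `U'* = UA`, `Q* = QA`,
`log|C*| = log|C(e)| - log|F(e)|`). The implementation therefore keeps
`pA, UA, QA, log|F|` from the postorder pass and never divides by
`1 - t p~`. The rerooted log-determinant at node `e` is accordingly
defined — and verified against dense `slogdet` of the literally
rerooted covariance — as
`log|C(e)| = log|C(a)| - log|F(e)| + log|F_o|`.

**Uncertainty.** With `L = R = [1 y]` the residual quadratic form is
`Q_yy - Q_1y * mu_hat(root)`, giving
`sigma^2_hat = (Q_yy - Q_1y mu_hat) / (N - reml)`. The variance of the
node estimate is `sigma^2_hat / p(e)` and the reported 95% interval is
`mu_hat +- 1.96 sqrt(var)`. `reml = 0` (the ML divisor) is the default;
`reml = 1` gives the restricted-ML divisor used for calibrated
confidence intervals (empirical root coverage on a 64-tip tree over
1,000 simulations: ≈0.93–0.95).

## Missing data and imputation

A tip with observed trait subset `k` contributes only through the
`k`-block of its edge matrix: `p~_kk = T_kk^-1`, zero elsewhere (a
fully missing tip contributes nothing). After the two passes, the
missing traits `u` at tip `e` with parent `a` are predicted by

```
mu_hat_u = T_uk T_kk^-1 (y_k - mu_hat_k(a)) + mu_hat_u(a)
Cov_u    = ( [ p_oth (I + T(e) p_oth)^-1 ]_uu )^-1
```

The covariance grouping is the best linear unbiased *prediction*
covariance: it equals the conditional-normal Schur complement **plus**
the propagated uncertainty of the estimated mean,
`Schur + D (L' W_oo^-1 L)^-1 D'`. This was verified analytically and
against a dense conditional-normal oracle (agreement ~1e-14). The mean
formula is exact for the no-measurement-error case.

## Within-species variation

- **Summary mode** (species means + standard errors): the per-species
  error matrix `B` (diagonal of squared SEs) is added to the tip's edge
  matrix `T(e)` during the postorder tip initialization *only*; it is
  deliberately not added inside the step-5 imputation, which predicts
  the latent species mean rather than a noisy observation. With
  `B != 0` the imputation mean is therefore a (standard) plug-in
  approximation.
- **Raw mode** (individual measurements): the tree is augmented with
  one pseudo-tip per individual attached to its species node by an edge
  whose matrix is `B`; the species nodes become internal and receive
  shrinkage (BLUP) estimates from the ordinary passes. Validated
  against explicit individual-level dense GLS.

## Rate models and branch-length transforms

- **BM:** `T(e) = t(e) * Sigma`; `Sigma` is estimated in closed form
  from complete data via `Sigma_hat = (Q_YY - q_1y q_1y' / q_11) /
  (N - reml)`, or supplied by the user (required when data are missing).
- **Regimes:** each edge maps to a regime label with its own `Sigma^(s)`;
  `T(e) = t(e) * Sigma^(s(e))`.
- **OU (root-fixed, scalar strength `alpha`):** node heights `s` are
  transformed by `g(s) = exp(-2 alpha (T_h - s)) (1 - exp(-2 alpha s))
  / (2 alpha)` with `T_h` the tree height; `T(e) = (g(s_child) -
  g(s_parent)) * Sigma`. Requires an ultrametric tree (checked to
  relative tolerance 1e-6). This is the root-fixed variant whose induced
  tip covariance is exactly the transformed MRCA-depth matrix; as
  `alpha -> 0` it reduces to BM. Matrix-valued `alpha` is out of scope.
- **Early burst:** `g(s) = (exp(r s) - 1) / r`, with `g(s) = s` at
  `r = 0` handled exactly. 

Transform parameters (`alpha`, `r`, `B`) are taken as given; numerical
optimization of them is out of scope.

## Simulator

`sim_tree` draws a random bifurcating topology by recursive splitting
with branch lengths Uniform(0.01, 1.01) (optionally ultrametric by
assigning node heights); `make_polytomies` contracts internal edges
while preserving tip depths. `sim_traits` simulates BM by preorder
Cholesky increments, with optional missingness (never a fully missing
trait column), within-species replicates, and measurement error `B`.
The simulator emulates the data-generating model the estimator assumes;
it does not emulate diversification dynamics, non-Gaussian traits, or
informative missingness.

## Validation strategy and problem sizes

All fast-path results are tested against deliberately naive oracles:
literal rerooting + dense GLS (univariate: 100 random instances of
5–200 tips, ~20% with polytomies, agreement < 1e-8; multivariate with
0–30% missingness: 50 instances, n ≤ 30, M ≤ 3), Felsenstein's
independent contrasts (`1/p~` equals the PIC transformed branch length,
< 1e-10), the dense conditional normal for imputation, and brute-force
`slogdet` for transformed covariances. Linearity is enforced by a visit
counter (exactly 2 visits per edge across both passes) and a runtime
ratio (< 3x when doubling 2,048 → 4,096 tips). These sizes were chosen
to keep the full suite under a minute per property while covering the
regimes where naive implementations are still feasible.

## Limitations

- `alpha`, EB rate, and `B` are not estimated — supply them.
- `Sigma` estimation requires complete data (no missing cells).
- OU requires an ultrametric tree.
- The within-species summary-mode imputation mean is approximate when
  `B != 0` (raw mode is exact).
- Trees must be rooted with positive tip branch lengths; a root edge
  length is ignored with a warning.
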