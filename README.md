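# fastasr

Fast maximum-likelihood ancestral state reconstruction of continuous
characters on phylogenetic trees, without rerooting.

## The problem

Given a rooted phylogeny with `N` tips and trait values observed at the
tips, the maximum-likelihood estimate of the ancestral state at an
internal node `e` under Brownian motion is the generalized least squares
(GLS) estimator computed on the tree rerooted at `e`:

```
mu_hat(e) = (1' C(e)^-1 1)^-1 1' C(e)^-1 y,      p(e) = 1' C(e)^-1 1
```

where `C(e)` is the among-tip covariance implied by the tree rooted at
`e` (entries are shared path lengths from the root to the most recent
common ancestor of each tip pair). Evaluating this literally at every
internal node costs `O(N^3)` per node. `fastasr` obtains the identical
estimates, precisions `p(e)`, and log-determinants `log|C(e)|` for **all**
internal nodes in two linear-time passes over the tree:

1. a **postorder pass** that accumulates, for every edge, the local GLS
   summaries of the subtree below it ("tilde" quantities), and
2. a **preorder pass** that converts local quantities to rerooted global
   quantities in `O(1)` work per edge by reusing the parent's globals.

The same recursion generalizes to multiple correlated traits (`M x M`
matrix quantities), missing observations (each tip contributes only its
observed trait subset), within-species variation (standard errors or raw
individual measurements), regime-specific evolutionary rates, and
Ornstein–Uhlenbeck / early-burst branch-length transforms.

## Quick start (Python)

```python
import numpy as np
from fastasr import parse_newick, anc_recon

tree = parse_newick("((A:1,B:1):1,C:2);")
res = anc_recon(tree, {"A": 1.0, "B": 3.0, "C": 6.0})
print(res.to_frame())
```

gives the exact GLS reconstruction at both internal nodes:

```
   node label  estimate  variance  ci_lower  ci_upper
0     4  root  3.714286  6.122449 -1.135667  8.564238
1     5        2.571429  3.061224 -0.858247  6.001104
```

The root estimate is `26/7 = 3.714285714...` with precision `7/6`; the
A–B ancestor is `18/7 = 2.571428571...` with precision `7/3` — identical
to dense GLS on the rerooted tree, at a fraction of the cost.

## Quick start (command line)

The package installs an `asr` executable:

```
# simulate a 32-tip Brownian data set
asr simulate --n 32 --seed 1 --out-prefix demo

# reconstruct ancestral states (CSV to stdout or --out)
asr recon --tree demo.nwk --traits demo.csv --out anc.csv

# verify against the dense rerooted-GLS oracle
asr check --tree demo.nwk --traits demo.csv
```

`asr recon` accepts multivariate trait tables with missing cells
(imputed with uncertainty), `--se` tables of per-species standard
errors, `--raw` tables of individual measurements, `--model ou --alpha`
or `--model eb --eb-rate` branch-length transforms, and a fixed `--sigma`
rate matrix. See `asr recon --help`.

## Package layout

- `fastasr.treeio` — Newick parsing/writing, node numbering, traversal
  orders, rerooting, patristic distances.
- `fastasr.univariate` — the two-pass algorithm for one trait, including
  general GLS regression on tree-structured errors.
- `fastasr.multivariate` — matrix-valued passes, missing-data handling,
  tip imputation, within-species variation, rate-matrix estimation.
- `fastasr.models` — per-edge covariance construction: Brownian motion,
  regime-specific rates, OU and early-burst height transforms.
- `fastasr.oracle` — deliberately slow dense reference implementations
  used to validate the fast algorithm.
- `fastasr.simulate` — tree and trait simulators.
- `fastasr.cli` — the `asr` command-line interface.

See `docs/methods.md` for the statistical model, algorithmic details,
and numerical design choices.
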