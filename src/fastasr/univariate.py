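"""Two-pass (postorder-preorder) ML ancestral state reconstruction, univariate.

The postorder pass accumulates, for every edge ``e`` (keyed by its child
node), *local* quantities computed on the subtree hanging from ``e``::

    mu_t[e]   = (1' Ct^-1 1)^-1 1' Ct^-1 y      local ancestral estimate
    p_t[e]    = 1' Ct^-1 1                      local precision
    U_t[e]'   = L' Ct^-1 (column sums)          per column of L
    V_t[e]    = Ct^-1 R (column sums)           per column of R
    Q_t[e]    = L' Ct^-1 R
    logdet[e] = log |Ct|

where ``Ct`` is the Brownian-motion covariance of the subtree including
the stretch contributed by edge ``e`` itself.  At the root (which has no
edge, t = 0) the local quantities are the global GLS quantities.  The
preorder pass then converts local to global quantities at every internal
node by algebraically "rerooting": the edge stretch is cancelled on the
subtree side and added to the rest-of-tree side, so each node costs O(1)
and the whole reconstruction is linear in the number of edges.

Degenerate cases: zero-length *internal* edges are fine (the stretch is a
no-op); zero-length terminal edges are rejected at parse time because tip
initialization divides by t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Tree, edge_orders

__all__ = [
    "TildeQuantities",
    "GlobalQuantities",
    "ASRResult",
    "GLSRegressionResult",
    "postorder_pass",
    "preorder_pass",
    "anc_recon",
    "gls_regression",
]


class MissingDataError(ValueError):
    """Univariate mode requires a complete trait vector."""


@dataclass
class TildeQuantities:
    """Per-edge local quantities from the postorder pass.

    Arrays are indexed by the edge's child node id (slot 0 unused).  For
    internal edges the pre-stretch sums over immediate descendants
    (``pA``, ``UA``, ``VA``, ``QA``, ``logdetA``) are retained: they are
    exactly the "un-stretched" subtree quantities the preorder pass needs,
    and using them avoids the cancellation-prone form 1 - t*p_t
    (algebraically 1 - t*p_t = 1/(1 + t*pA)).
    """

    mu: np.ndarray
    p: np.ndarray
    pA: np.ndarray
    U: np.ndarray  # (n_nodes+1, qL)
    V: np.ndarray  # (n_nodes+1, qR)
    Q: np.ndarray  # (n_nodes+1, qL, qR)
    logdet: np.ndarray
    UA: np.ndarray
    VA: np.ndarray
    QA: np.ndarray
    logdetA: np.ndarray
    visits: int = 0


@dataclass
class GlobalQuantities:
    """Per-node global (whole-tree) quantities from the preorder pass.

    ``mu_hat[v]`` is the ML ancestral estimate at internal node ``v``;
    ``p[v] = 1' C(v)^-1 1`` where ``C(v)`` is the tip covariance of the
    tree rerooted at ``v``; ``logdet[v] = log |C(v)|``.  Only internal
    nodes are populated (tip states are observed).
    """

    mu_hat: np.ndarray
    p: np.ndarray
    U: np.ndarray
    V: np.ndarray
    Q: np.ndarray
    logdet: np.ndarray
    internal_nodes: np.ndarray
    visits: int = 0


@dataclass
class ASRResult:
    """Ancestral reconstruction with rate estimate and confidence bands."""

    node_ids: np.ndarray
    node_labels: tuple
    estimate: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma2: float
    logdet_root: float
    n_tips: int
    reml: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": self.node_ids,
                "label": [lab if lab else "" for lab in self.node_labels],
                "estimate": self.estimate,
                "variance": self.variance,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass
class GLSRegressionResult:
    beta_root: np.ndarray
    beta_nodes: np.ndarray | None
    internal_nodes: np.ndarray | None
    logdet_root: float


def tip_values(tree: Tree, y) -> np.ndarray:
    """Coerce a trait vector to tip-id order; accepts mapping or array."""
    if hasattr(y, "to_dict"):  # pandas Series keyed by species
        y = y.to_dict()
    if isinstance(y, dict):
        missing = [lab for lab in tree.tip_labels if lab not in y]
        if missing:
            raise ValueError(f"no trait value for tip(s): {missing}")
        arr = np.array([float(y[lab]) for lab in tree.tip_labels])
    else:
        arr = np.asarray(y, dtype=float).reshape(-1)
        if arr.shape[0] != tree.n_tips:
            raise ValueError(
                f"expected {tree.n_tips} tip values, got {arr.shape[0]}"
            )
    return arr


def postorder_pass(
    tree: Tree, y, L: np.ndarray | None = None, R: np.ndarray | None = None
) -> tuple[TildeQuantities, GlobalQuantities]:
    """Tips-to-root accumulation of local quantities (one visit per edge).

    Parameters
    ----------
    tree
        Rooted phylogeny; terminal edges must have positive length.
    y
        Complete tip trait values (array in tip order or mapping by label).
    L, R
        Optional tip-row matrices for the generalized cross-products
        ``Q = L' C^-1 R``; default ``L = 1`` (column of ones), ``R = y``.

    Returns the per-edge local quantities and the root globals.
    """
    yv = tip_values(tree, y)
    if np.isnan(yv).any():
        bad = [tree.tip_labels[i] for i in np.flatnonzero(np.isnan(yv))]
        raise MissingDataError(
            f"missing trait values for {bad}; univariate reconstruction "
            "requires complete data - use the multivariate module for "
            "missing-data support"
        )
    n = tree.n_tips
    if L is None:
        L = np.ones((n, 1))
    else:
        L = np.atleast_2d(np.asarray(L, dtype=float))
        if L.shape[0] != n:
            L = L.T
    if R is None:
        R = yv[:, None]
    else:
        R = np.asarray(R, dtype=float)
        if R.ndim == 1:
            R = R[:, None]
        if R.shape[0] != n:
            R = R.T
    qL, qR = L.shape[1], R.shape[1]
    nn = tree.n_nodes
    t = TildeQuantities(
        mu=np.zeros(nn + 1),
        p=np.zeros(nn + 1),
        pA=np.full(nn + 1, np.nan),
        U=np.zeros((nn + 1, qL)),
        V=np.zeros((nn + 1, qR)),
        Q=np.zeros((nn + 1, qL, qR)),
        logdet=np.zeros(nn + 1),
        UA=np.zeros((nn + 1, qL)),
        VA=np.zeros((nn + 1, qR)),
        QA=np.zeros((nn + 1, qL, qR)),
        logdetA=np.zeros(nn + 1),
    )
    orders = edge_orders(tree)
    visits = 0
    length = tree.length
    children = tree.children
    for e in orders.postorder:
        e = int(e)
        visits += 1
        te = length[e]
        if tree.is_tip(e):
            ye = yv[e - 1]
            t.mu[e] = ye
            t.p[e] = 1.0 / te
            t.U[e] = L[e - 1] / te
            t.V[e] = R[e - 1] / te
            t.Q[e] = np.outer(L[e - 1], R[e - 1]) / te
            t.logdet[e] = np.log(te)
        else:
            _accumulate(t, e, te, children[e])
    # Root: its (virtual) edge has t = 0.
    r = tree.root
    _accumulate(t, r, 0.0, children[r])
    t.visits = visits
    g = GlobalQuantities(
        mu_hat=np.full(nn + 1, np.nan),
        p=np.full(nn + 1, np.nan),
        U=np.zeros((nn + 1, qL)),
        V=np.zeros((nn + 1, qR)),
        Q=np.zeros((nn + 1, qL, qR)),
        logdet=np.full(nn + 1, np.nan),
        internal_nodes=np.array(
            [v for v in range(1, nn + 1) if not tree.is_tip(v)]
        ),
    )
    g.mu_hat[r] = t.mu[r]
    g.p[r] = t.p[r]
    g.U[r] = t.U[r]
    g.V[r] = t.V[r]
    g.Q[r] = t.Q[r]
    g.logdet[r] = t.logdet[r]
    return t, g


def _accumulate(t: TildeQuantities, e: int, te: float, kids) -> None:
    pA = 0.0
    muw = 0.0
    UA = t.UA[e]
    VA = t.VA[e]
    QA = t.QA[e]
    ldA = 0.0
    UA[:] = 0.0
    VA[:] = 0.0
    QA[:] = 0.0
    for d in kids:
        pA += t.p[d]
        muw += t.mu[d] * t.p[d]
        UA += t.U[d]
        VA += t.V[d]
        QA += t.Q[d]
        ldA += t.logdet[d]
    denom = 1.0 + te * pA
    t.pA[e] = pA
    t.logdetA[e] = ldA
    t.mu[e] = muw / pA
    t.p[e] = pA / denom
    t.U[e] = UA / denom
    t.V[e] = VA / denom
    t.Q[e] = QA - np.outer(UA, VA) * (te / denom)
    t.logdet[e] = ldA + np.log(denom)


def preorder_pass(
    tree: Tree,
    tilde: TildeQuantities,
    root_globals: GlobalQuantities,
    general_mu: bool = False,
) -> GlobalQuantities:
    """Root-to-tips propagation of global quantities (one visit per edge).

    For an internal non-root edge ``e`` with parent edge ``a``, the
    subtree side is un-stretched (its pre-stretch sums were retained by
    the postorder pass) and the rest-of-tree side, with precision
    ``p(a) - p_t(e)``, is stretched by ``t(e)``; the two parts add.  The
    ancestral estimate uses the scalar shortcut
    ``mu_hat(e) = mu_t(e) p_t(e) t(e) + mu_hat(a) (1 - p_t(e) t(e))``
    unless ``general_mu`` is set, in which case the generalized form
    ``mu_hat = Q11^-1 Q1Y`` from the propagated cross-products is used
    (required when L is a design matrix rather than a column of ones).

    Tips are enumerated but skipped: their states are observed, so no
    global quantities are produced for them in univariate mode.
    """
    g = root_globals
    if np.isnan(g.mu_hat[tree.root]):
        raise RuntimeError("preorder_pass requires a completed postorder_pass")
    orders = edge_orders(tree)
    visits = 0
    length = tree.length
    parent = tree.parent
    for e in orders.preorder:
        e = int(e)
        visits += 1
        if tree.is_tip(e):
            continue
        a = int(parent[e])
        te = length[e]
        p_oth = g.p[a] - tilde.p[e]
        denom_o = 1.0 + te * p_oth
        g.p[e] = tilde.pA[e] + p_oth / denom_o
        dU = g.U[a] - tilde.U[e]
        dV = g.V[a] - tilde.V[e]
        g.U[e] = tilde.UA[e] + dU / denom_o
        g.V[e] = tilde.VA[e] + dV / denom_o
        g.Q[e] = (
            tilde.QA[e]
            + (g.Q[a] - tilde.Q[e])
            - np.outer(dU, dV) * (te / denom_o)
        )
        g.logdet[e] = (
            g.logdet[a]
            - np.log1p(te * tilde.pA[e])
            + np.log(denom_o)
        )
        if general_mu:
            # mu_hat = Q11^-1 Q1Y with L = [1 | ...]; column 0 is the 1s.
            g.mu_hat[e] = g.Q[e][0, -1] / g.Q[e][0, 0]
        else:
            w = tilde.p[e] * te
            g.mu_hat[e] = tilde.mu[e] * w + g.mu_hat[a] * (1.0 - w)
    g.visits = visits
    return g


def anc_recon(tree: Tree, y, reml: int = 0, ci: bool = True) -> ASRResult:
    """ML ancestral states with variances and 95% confidence intervals.

    The Brownian-motion rate is estimated from the accumulated root
    cross-products (never forming the N x N covariance)::

        sigma2 = (Qyy - Q1y * mu_hat_root) / (N - reml)

    and ``var(mu_hat(e)) = sigma2 / p(e)`` at every internal node, with
    the 95% band ``mu_hat +- 1.96 sqrt(var)``.

    Parameters
    ----------
    reml
        0 for the ML rate (divide by N), 1 for restricted ML (N - 1).
    """
    yv = tip_values(tree, y)
    n = tree.n_tips
    if n - reml <= 0:
        raise ValueError("need N - REML > 0 tips to estimate a rate")
    LR = np.column_stack([np.ones(n), yv])
    tilde, g = postorder_pass(tree, yv, L=LR, R=LR)
    g = preorder_pass(tree, tilde, g)
    r = tree.root
    Qr = g.Q[r]
    mu_r = g.mu_hat[r]
    quad = Qr[1, 1] - Qr[0, 1] * mu_r  # (y - 1 mu)' C^-1 (y - 1 mu)
    sigma2 = quad / (n - reml)
    nodes = g.internal_nodes
    est = g.mu_hat[nodes]
    var = sigma2 / g.p[nodes]
    half = 1.96 * np.sqrt(var) if ci else np.full_like(var, np.nan)
    return ASRResult(
        node_ids=nodes,
        node_labels=tuple(tree.labels[v] for v in nodes),
        estimate=est,
        variance=var,
        ci_lower=est - half,
        ci_upper=est + half,
        sigma2=float(sigma2),
        logdet_root=float(g.logdet[r]),
        n_tips=n,
        reml=int(reml),
    )


def gls_regression(
    tree: Tree, X: np.ndarray, y, node_wise: bool = False
) -> GLSRegressionResult:
    """Phylogenetic GLS regression coefficients via the two-pass algorithm.

    Runs the passes with ``L = X`` and ``R = y`` and returns
    ``beta_root = Qxx^-1 Qxy`` evaluated at the root; with ``node_wise``
    the same solve is performed on the propagated cross-products at every
    internal node (the coefficients the rerooted tree would yield).
    """
    yv = tip_values(tree, y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != tree.n_tips:
        raise ValueError("X must have one row per tip")
    q = X.shape[1]
    LR = np.column_stack([X, yv])
    tilde, g = postorder_pass(tree, yv, L=LR, R=LR)
    r = tree.root
    Qxx = g.Q[r][:q, :q]
    Qxy = g.Q[r][:q, q]

    def solve_beta(Qxx, Qxy, where):
        try:
            beta = np.linalg.solve(Qxx, Qxy)
        except np.linalg.LinAlgError:
            rank = np.linalg.matrix_rank(Qxx)
            raise np.linalg.LinAlgError(
                f"singular X' C^-1 X at {where} (rank {rank} < {q}); "
                "drop collinear predictors"
            ) from None
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError(f"singular X' C^-1 X at {where}")
        return beta

    beta_root = solve_beta(Qxx, Qxy, "root")
    beta_nodes = None
    nodes = None
    if node_wise:
        g = preorder_pass(tree, tilde, g, general_mu=True)
        nodes = g.internal_nodes
        beta_nodes = np.empty((len(nodes), q))
        for i, v in enumerate(nodes):
            beta_nodes[i] = solve_beta(
                g.Q[v][:q, :q], g.Q[v][:q, q], f"node {v}"
            )
    return GLSRegressionResult(
        beta_root=beta_root,
        beta_nodes=beta_nodes,
        internal_nodes=nodes,
        logdet_root=float(g.logdet[r]),
    )
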