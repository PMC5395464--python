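"""Slow, obviously-correct reference implementations for testing.

These deliberately use the strategies the two-pass algorithm supersedes:
explicit construction of the N x N Brownian-motion covariance matrix,
literal rerooting at every internal node followed by dense GLS, the
textbook independent-contrasts recursion, and conditional multivariate
normals on the full (Kronecker) species-trait covariance.  They exist
solely as ground truth for the fast code paths; no performance target
applies to them.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .treeio import Tree, _mrca_depths, preorder_nodes, reroot

__all__ = [
    "build_covariance",
    "rerooted_gls_estimates",
    "pic_transform",
    "build_mv_covariance",
    "mv_gls_root",
    "rerooted_mv_gls_estimates",
    "conditional_impute_oracle",
]


def build_covariance(tree: Tree) -> np.ndarray:
    """Brownian-motion tip covariance: C[i, j] = depth of MRCA(i, j).

    Tips are in tip-id order (1..N); the diagonal holds tip depths.
    """
    return _mrca_depths(tree)


def rerooted_gls_estimates(tree: Tree, y) -> dict:
    """Global (mu_hat, p, log|C|) at every internal node by literal rerooting.

    For each internal node the tree is rerooted there, the covariance is
    rebuilt, and the GLS root quantities are computed by dense solves:
    ``mu_hat = (1'C^-1 1)^-1 1'C^-1 y``, ``p = 1'C^-1 1``.  O(N^3) per
    node; testing only.
    """
    yv = np.asarray(y, dtype=float).reshape(-1)
    out = {}
    lab_to_val = dict(zip(tree.tip_labels, yv))
    for v in range(tree.n_tips + 1, tree.n_nodes + 1):
        rt = reroot(tree, v)
        C = build_covariance(rt)
        yr = np.array([lab_to_val[lab] for lab in rt.tip_labels])
        cf = linalg.cho_factor(C)
        ones = np.ones(rt.n_tips)
        a = linalg.cho_solve(cf, ones)
        p = ones @ a
        mu = (a @ yr) / p
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular covariance at node %d" % v)
        out[v] = (mu, p, logdet)
    return out


def pic_transform(tree: Tree, y) -> tuple[dict, dict]:
    """Felsenstein's independent-contrasts recursion.

    Returns (transformed branch length above each node, nodal value at
    each node).  Each node's value is the precision-weighted mean of its
    daughters' values and the edge above it is stretched by the harmonic
    contribution of the daughter edges (the textbook t1*t2/(t1+t2) step
    for a bifurcation; a polytomy contributes 1/sum(1/t_d), the natural
    multi-daughter generalization).
    """
    yv = np.asarray(y, dtype=float).reshape(-1)
    tlen: dict = {}
    value: dict = {}
    for v in preorder_nodes(tree)[::-1]:
        if tree.is_tip(v):
            tlen[v] = float(tree.length[v])
            value[v] = yv[v - 1]
        else:
            winv = [1.0 / tlen[d] for d in tree.children[v]]
            value[v] = sum(w * value[d] for w, d in zip(winv, tree.children[v]))
            value[v] /= sum(winv)
            extra = 1.0 / sum(winv)
            base = float(tree.length[v]) if v != tree.root else 0.0
            tlen[v] = base + extra
    return tlen, value


def _stack_indices(n_tips: int, M: int, mask: np.ndarray):
    """Observed/missing positions in the trait-major NM stacking.

    Position ``m * N + i`` holds trait ``m`` of tip ``i`` (consistent
    with W = Sigma (x) C partitioned into M^2 blocks of size N x N).
    ``mask`` is True where a value is missing.
    """
    flat = mask.T.reshape(-1)  # trait-major
    obs = np.flatnonzero(~flat)
    mis = np.flatnonzero(flat)
    return obs, mis


def build_mv_covariance(
    tree: Tree, Sigma: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense species-trait covariance W = Sigma (x) C, missing rows deleted.

    Returns ``(W_obs, obs_index, mis_index)`` where the indices address
    the trait-major NM stacking; ``W_obs`` is W with missing rows and
    columns removed.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    C = build_covariance(tree)
    W = np.kron(Sigma, C)
    M = Sigma.shape[0]
    if mask is None:
        mask = np.zeros((tree.n_tips, M), dtype=bool)
    obs, mis = _stack_indices(tree.n_tips, M, np.asarray(mask, dtype=bool))
    return W[np.ix_(obs, obs)], obs, mis


def _design(n_tips: int, M: int) -> np.ndarray:
    """NM x M indicator mapping each stacked observation to its trait."""
    return np.kron(np.eye(M), np.ones((n_tips, 1)))


def mv_gls_root(tree: Tree, Sigma, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """Root trait means and log|W| by dense GLS on the deleted-row W.

    ``Y`` is N x M with NaN marking missing entries.
    """
    Y = np.asarray(Y, dtype=float)
    mask = np.isnan(Y)
    Woo, obs, _ = build_mv_covariance(tree, Sigma, mask)
    yo = Y.T.reshape(-1)[obs]
    Lo = _design(tree.n_tips, np.asarray(Sigma).shape[0])[obs]
    cf = linalg.cho_factor(Woo)
    A = linalg.cho_solve(cf, Lo)
    mu = np.linalg.solve(Lo.T @ A, A.T @ yo)
    sign, logdet = np.linalg.slogdet(Woo)
    return mu, float(logdet)


def rerooted_mv_gls_estimates(tree: Tree, Sigma, Y: np.ndarray) -> dict:
    """Per-internal-node multivariate estimates by rerooting + dense GLS.

    Handles missing entries by deleting the corresponding rows/columns of
    the rerooted W = Sigma (x) C.  Returns {node: (mu_hat, p_matrix,
    log|W|)} where p_matrix = L' W^-1 L (M x M).
    """
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(Sigma).shape[0]
    mask = np.isnan(Y)
    row_of = dict(zip(tree.tip_labels, range(tree.n_tips)))
    out = {}
    for v in range(tree.n_tips + 1, tree.n_nodes + 1):
        rt = reroot(tree, v)
        perm = np.array([row_of[lab] for lab in rt.tip_labels])
        Yp = Y[perm]
        Woo, obs, _ = build_mv_covariance(rt, Sigma, np.isnan(Yp))
        yo = Yp.T.reshape(-1)[obs]
        Lo = _design(rt.n_tips, M)[obs]
        cf = linalg.cho_factor(Woo)
        A = linalg.cho_solve(cf, Lo)
        P = Lo.T @ A
        mu = np.linalg.solve(P, A.T @ yo)
        sign, logdet = np.linalg.slogdet(Woo)
        out[v] = (mu, P, float(logdet))
    return out


def conditional_impute_oracle(
    tree: Tree, Sigma, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Conditional-normal ground truth for missing-entry imputation.

    Under y ~ N(L mu, W) with W = Sigma (x) C and mu the GLS mean
    estimated from the observed rows, the missing entries have

        mean = W_mo W_oo^-1 (y_o - L_o mu) + L_m mu
        cov_cond = W_mm - W_mo W_oo^-1 W_om
        cov_pred = cov_cond + D (L'W_oo^-1 L)^-1 D',
                   D = L_m - W_mo W_oo^-1 L_o

    ``cov_pred`` additionally carries the uncertainty of the estimated
    mean (the flat-root-prior BLUP prediction covariance), which is what
    the fast algorithm's imputation covariance corresponds to.

    Returns ``(mean, cov_cond, cov_pred, mis_index)`` with ``mis_index``
    in trait-major NM stacking order.
    """
    Y = np.asarray(Y, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    M = Sigma.shape[0]
    mask = np.isnan(Y)
    C = build_covariance(tree)
    W = np.kron(Sigma, C)
    obs, mis = _stack_indices(tree.n_tips, M, mask)
    if mis.size == 0:
        return np.zeros(0), np.zeros((0, 0)), np.zeros((0, 0)), mis
    Woo = W[np.ix_(obs, obs)]
    Wmo = W[np.ix_(mis, obs)]
    Wmm = W[np.ix_(mis, mis)]
    Ld = _design(tree.n_tips, M)
    Lo, Lm = Ld[obs], Ld[mis]
    cf = linalg.cho_factor(Woo)
    A = linalg.cho_solve(cf, Lo)
    P = Lo.T @ A
    yo = Y.T.reshape(-1)[obs]
    mu = np.linalg.solve(P, A.T @ yo)
    K = linalg.cho_solve(cf, Wmo.T).T  # W_mo W_oo^-1
    mean = K @ (yo - Lo @ mu) + Lm @ mu
    cov_cond = Wmm - K @ Wmo.T
    D = Lm - K @ Lo
    cov_pred = cov_cond + D @ np.linalg.solve(P, D.T)
    return mean, cov_cond, cov_pred, mis
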