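"""Evolutionary models as per-edge length matrices T(e).

The multivariate recursions consume only an M x M matrix per edge.  Under
Brownian motion with rate matrix Sigma, ``T(e) = t(e) * Sigma``; regime
models substitute the regime's rate matrix; the (scalar-attraction)
Ornstein-Uhlenbeck and Early-Burst models rescale node *heights* on an
ultrametric tree with a monotone map g and set
``T(e) = (g(s_child) - g(s_parent)) * Sigma``.

The OU transform used here is the root-fixed (non-stationary) form

    g(s) = exp(-2 alpha (Th - s)) * (1 - exp(-2 alpha s)) / (2 alpha)

with Th the tree height, which gives the familiar ultrametric OU tip
covariance exp(-alpha d_ij) (1 - exp(-2 alpha Th)) / (2 alpha) and
reduces to Brownian motion as alpha -> 0.  The Early-Burst map is
``g(s) = (exp(r s) - 1) / r`` with the removable singularity g(s) = s at
r = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Tree

__all__ = ["EdgeMatrices", "edge_length_matrices", "transform_heights"]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class EdgeMatrices:
    """Per-edge M x M length matrices, indexed by the edge's child node.

    ``T[v]`` is the length matrix of the edge above node ``v`` (the root
    slot is all zeros: the tree has no root edge).  ``model`` is one of
    ``{"BM", "BM-regimes", "OU", "EB", "custom"}``; ``params`` records
    the generating parameters for logging.
    """

    T: np.ndarray  # (n_nodes + 1, M, M)
    M: int
    model: str = "BM"
    params: dict | None = None

    def validate_psd(self, atol: float = 1e-10) -> None:
        for v in range(1, self.T.shape[0]):
            w = np.linalg.eigvalsh(self.T[v])
            if w.min() < -atol:
                raise ValueError(
                    f"edge matrix above node {v} is not positive "
                    f"semidefinite (min eigenvalue {w.min():.3g})"
                )


def _check_pd(Sigma: np.ndarray, name: str = "Sigma") -> np.ndarray:
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if Sigma.shape[0] != Sigma.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(Sigma, Sigma.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(Sigma)
    if w.min() <= 0:
        raise ValueError(
            f"{name} must be positive definite (min eigenvalue "
            f"{w.min():.3g})"
        )
    return Sigma


def edge_length_matrices(
    tree: Tree,
    sigma=None,
    regimes: dict | None = None,
    regime_sigmas: dict | None = None,
) -> EdgeMatrices:
    """Brownian-motion edge matrices ``T(e) = t(e) * Sigma``.

    With ``regimes`` (a map from edge child-node id to regime label) and
    ``regime_sigmas`` (label -> rate matrix), each edge uses its regime's
    matrix instead; every edge must be assigned.
    """
    if regimes is not None or regime_sigmas is not None:
        if regimes is None or regime_sigmas is None:
            raise ValueError(
                "regime models need both the regime map and the per-"
                "regime rate matrices"
            )
        mats = {k: _check_pd(v, f"Sigma[{k}]") for k, v in regime_sigmas.items()}
        M = next(iter(mats.values())).shape[0]
        T = np.zeros((tree.n_nodes + 1, M, M))
        for v in range(1, tree.n_nodes + 1):
            if v == tree.root:
                continue
            if v not in regimes:
                raise ValueError(
                    f"edge above node {v} has no regime assignment"
                )
            lab = regimes[v]
            if lab not in mats:
                raise ValueError(f"unknown regime {lab!r} for node {v}")
            T[v] = tree.length[v] * mats[lab]
        return EdgeMatrices(
            T=T, M=M, model="BM-regimes", params={"regimes": dict(regimes)}
        )
    Sigma = _check_pd(sigma)
    M = Sigma.shape[0]
    T = tree.length[:, None, None] * Sigma[None, :, :]
    T[0] = 0.0
    T[tree.root] = 0.0
    return EdgeMatrices(T=T, M=M, model="BM", params={"sigma": Sigma})


def _check_ultrametric(tree: Tree, depth: np.ndarray) -> float:
    tip_h = depth[1 : tree.n_tips + 1]
    Th = float(tip_h.mean())
    if Th <= 0:
        raise ValueError("tree height must be positive")
    if np.max(np.abs(tip_h - Th)) / Th > ULTRAMETRIC_RTOL:
        raise ValueError(
            "the Ornstein-Uhlenbeck transform requires an ultrametric "
            f"tree (tip depths range over [{tip_h.min():.6g}, "
            f"{tip_h.max():.6g}])"
        )
    return Th


def transform_heights(tree: Tree, model: str, sigma, alpha: float | None = None,
                      rate: float | None = None) -> EdgeMatrices:
    """OU or EB edge matrices from transformed node heights.

    Parameters
    ----------
    model
        ``"ou"`` (requires ``alpha`` > 0 and an ultrametric tree) or
        ``"eb"`` (requires ``rate``; 0 recovers Brownian motion exactly).
    sigma
        The M x M trait rate matrix scaling every edge.
    """
    Sigma = _check_pd(sigma)
    M = Sigma.shape[0]
    depth = tree.node_depths()
    model = model.lower()
    if model == "ou":
        if alpha is None or alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        Th = _check_ultrametric(tree, depth)

        def g(s):
            return (
                np.exp(-2.0 * alpha * (Th - s))
                * -np.expm1(-2.0 * alpha * s)
                / (2.0 * alpha)
            )

    elif model == "eb":
        if rate is None:
            raise ValueError("EB requires a rate parameter")
        r = float(rate)
        if r == 0.0:

            def g(s):
                return s

        else:

            def g(s):
                return np.expm1(r * s) / r

    else:
        raise ValueError(f"unknown model {model!r}; expected 'ou' or 'eb'")
    gs = g(depth)
    T = np.zeros((tree.n_nodes + 1, M, M))
    for v in range(1, tree.n_nodes + 1):
        if v == tree.root:
            continue
        dg = gs[v] - gs[tree.parent[v]]
        if dg < 0:
            raise ValueError(
                "height transform is not monotone along the edge above "
                f"node {v}"
            )
        T[v] = dg * Sigma
    return EdgeMatrices(
        T=T,
        M=M,
        model=model.upper(),
        params={"alpha": alpha, "rate": rate, "sigma": Sigma},
    )
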