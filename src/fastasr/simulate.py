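"""Random trees and Brownian-motion trait data for tests and benchmarks.

Everything is generated in-process from a single integer seed, so any
failure replays exactly and no external data are ever required.  The
generator mirrors a standard comparative-methods simulation design:
random topologies with uniform branch lengths and (multivariate)
Brownian traits, optionally with missing entries and within-species
replicate observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treeio import Tree, _build_from_structure, preorder_nodes

__all__ = ["SimulationSpec", "sim_tree", "sim_traits", "make_polytomies"]


@dataclass
class SimulationSpec:
    """Study conditions for a simulated data set.

    Branch lengths are i.i.d. Uniform(0.01, 1.01): uniform lengths with a
    small positive floor so terminal edges satisfy the t > 0 requirement
    of tip initialization.  ``n_obs`` > 1 emits replicate rows per
    species with N(0, B) within-species noise around the species mean.
    """

    n_tips: int
    M: int = 1
    sigma: np.ndarray | float = 1.0
    mu0: np.ndarray | float = 0.0
    missing_rate: float = 0.0
    n_obs: int = 1
    B: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def sim_tree(n: int, seed: int, ultrametric: bool = False) -> Tree:
    """Random rooted bifurcating tree with ``n`` tips.

    Topology by recursive uniform-random splitting of the tip set;
    branch lengths i.i.d. Uniform(0.01, 1.01).  With ``ultrametric``,
    node heights are drawn instead (each internal node uniformly between
    its parent's height and the tip height 1), giving a tree whose tips
    are all at depth 1, as required by the Ornstein-Uhlenbeck transform.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    children_of: dict = {}
    lengths: dict = {}
    labels: dict = {}
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return next_id[0]

    def split(tipset, parent_key):
        key = new_node()
        if parent_key is not None:
            children_of[parent_key].append(key)
        children_of[key] = []
        if len(tipset) == 1:
            labels[key] = f"t{tipset[0]}"
        else:
            k = int(rng.integers(1, len(tipset)))
            perm = rng.permutation(len(tipset))
            left = [tipset[i] for i in perm[:k]]
            right = [tipset[i] for i in perm[k:]]
            split(left, key)
            split(right, key)
        return key

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        root_key = split(list(range(1, n + 1)), None)
    finally:
        sys.setrecursionlimit(old)
    nonroot = [k for k in range(1, next_id[0] + 1) if k != root_key]
    if ultrametric:
        height = {root_key: 0.0}
        for k in range(1, next_id[0] + 1):  # keys were created parent-first
            if k == root_key:
                continue
            parent = next(
                p for p, kids in children_of.items() if k in kids
            )
            if children_of[k]:
                height[k] = rng.uniform(height[parent], 1.0)
            else:
                height[k] = 1.0
            lengths[k] = height[k] - height[parent]
            if lengths[k] <= 0:  # guard against zero-width draws
                lengths[k] = 1e-6
    else:
        draws = rng.uniform(0.01, 1.01, size=len(nonroot))
        lengths = dict(zip(nonroot, draws))
    for k in range(1, next_id[0] + 1):
        labels.setdefault(k, None)
    return _build_from_structure(root_key, children_of, lengths, labels)


def make_polytomies(tree: Tree, prob: float, seed: int) -> Tree:
    """Contract random internal edges to produce polytomies.

    Each internal non-root node is, with probability ``prob``, removed
    and its children reattached to its parent (child edge lengths are
    extended by the contracted edge so tip depths are preserved).
    """
    rng = np.random.default_rng(seed)
    children_of = {v: list(tree.children[v]) for v in range(1, tree.n_nodes + 1)}
    lengths = {v: float(tree.length[v]) for v in range(1, tree.n_nodes + 1)}
    labels = {v: tree.labels[v] for v in range(1, tree.n_nodes + 1)}
    for v in range(tree.n_tips + 1, tree.n_nodes + 1):
        if v == tree.root or rng.random() >= prob:
            continue
        parent = next(
            (p for p, kids in children_of.items() if v in kids), None
        )
        if parent is None:
            continue  # already contracted transitively
        i = children_of[parent].index(v)
        kids = children_of.pop(v)
        for c in kids:
            lengths[c] += lengths[v]
        children_of[parent][i : i + 1] = kids
        lengths.pop(v)
    return _build_from_structure(tree.root, children_of, lengths, labels)


def sim_traits(tree: Tree, spec: SimulationSpec, edge_T=None):
    """Simulate (multivariate) Brownian traits along ``tree``.

    Each child state is the parent state plus a draw from N(0, T(e)),
    with T(e) = t(e) * Sigma by default or taken from ``edge_T`` (an
    ``EdgeMatrices``-like object with a ``T`` array indexed by child
    node) for transformed models.  Returns a dict with the tip matrix
    ``Y`` (NaN where masked), the true node states ``states`` (indexed
    by node id), and, when ``spec.n_obs > 1`` or ``spec.B`` is set, a
    long-format replicate table ``raw`` of (species, trait columns).
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.M
    Sigma = np.atleast_2d(np.asarray(spec.sigma, dtype=float))
    if Sigma.shape != (M, M):
        Sigma = np.eye(M) * float(np.asarray(spec.sigma).reshape(-1)[0])
    mu0 = np.broadcast_to(
        np.asarray(spec.mu0, dtype=float).reshape(-1), (M,)
    ).astype(float)
    if mu0.size == 1 and M > 1:
        mu0 = np.full(M, float(mu0[0]))
    states = np.zeros((tree.n_nodes + 1, M))
    states[tree.root] = mu0
    chol_sigma = np.linalg.cholesky(Sigma)
    for v in preorder_nodes(tree):
        if v == tree.root:
            continue
        if edge_T is not None:
            Te = edge_T.T[v]
            L = np.linalg.cholesky(Te + 1e-15 * np.eye(M))
        else:
            L = np.sqrt(tree.length[v]) * chol_sigma
        states[v] = states[tree.parent[v]] + L @ rng.standard_normal(M)
    Y = states[1 : tree.n_tips + 1].copy()
    raw = None
    if spec.n_obs > 1 or spec.B is not None:
        B = (
            np.atleast_2d(np.asarray(spec.B, dtype=float))
            if spec.B is not None
            else np.zeros((M, M))
        )
        cB = np.linalg.cholesky(B + 1e-15 * np.eye(M))
        rows = []
        for i, lab in enumerate(tree.tip_labels):
            for _ in range(spec.n_obs):
                rows.append((lab, Y[i] + cB @ rng.standard_normal(M)))
        raw = rows
    if spec.missing_rate > 0:
        mask = rng.random(Y.shape) < spec.missing_rate
        # never blank out a trait everywhere (it would be unidentifiable)
        for m in range(M):
            if mask[:, m].all():
                mask[rng.integers(0, tree.n_tips), m] = False
        Y = Y.copy()
        Y[mask] = np.nan
    return {"Y": Y, "states": states, "raw": raw}
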