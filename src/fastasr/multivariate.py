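"""Multivariate two-pass reconstruction with missing data and within-species
variation.

The univariate recursions generalize by replacing each scalar edge length
with an M x M length matrix T(e) (see :mod:`fastasr.models`) and each
precision scalar with an M x M matrix.  Conceptually the N x M trait
matrix is stacked into an NM-vector with covariance W = Sigma (x) C and
the column of ones becomes an NM x M trait indicator, but the algorithm
only ever performs M x M solves: missing entries are handled at tip
initialization by restricting to the observed trait subset k and
zero-padding, after which the recursions are unchanged.

Within-species variation enters in two ways:

* summary mode: a per-species covariance B(e) (e.g. squared standard
  errors on the diagonal) is added to T(e) at tip initialization only;
* raw mode: individual observations become the tips of an augmented tree
  in which species nodes are internal, the individual-to-species edges
  carry B, and the preorder pass then yields reconstructed species means.

Missing tip entries are imputed by the conditional-normal step
``mu_u = T_uk T_kk^-1 (y_k - mu_k(a)) + mu_u(a)`` whose covariance is the
flat-root-prior prediction covariance ``([ (p_oth^-1 + T)^-1 ]_uu)^-1``
with ``p_oth = p(a) - p_tilde(e)`` (in summary mode B is deliberately
left out of T here: the target is the latent species mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import EdgeMatrices, edge_length_matrices
from .treeio import Tree, _build_from_structure, edge_orders
from .univariate import postorder_pass as _uni_postorder

__all__ = [
    "TraitData",
    "MVTildeQuantities",
    "MVGlobalQuantities",
    "MVASRResult",
    "postorder_pass_mv",
    "preorder_pass_mv",
    "impute_tip",
    "anc_recon_mv",
    "estimate_rate_matrix",
]


@dataclass
class TraitData:
    """Species-by-trait observations with missingness and replicates.

    ``Y`` is N x M in tip-id order with NaN marking missing entries; the
    mask is always derived from NaN, never supplied separately.  ``B``
    optionally holds one M x M within-species covariance per species.
    ``raw`` holds the individual-level table (one row per observation)
    when replicates are available.
    """

    Y: np.ndarray
    species: tuple
    traits: tuple
    B: np.ndarray | None = None
    raw: pd.DataFrame | None = None

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.Y)

    @property
    def M(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_frame(
        cls, tree: Tree, df: pd.DataFrame, se: pd.DataFrame | None = None
    ) -> "TraitData":
        """Build from a table whose first column is the species label.

        Repeated species labels are interpreted as raw within-species
        observations (kept in ``raw``; ``Y`` then holds species means).
        An optional ``se`` table of identical layout provides per-species
        standard errors, stored as diagonal B matrices of squared SEs.
        """
        df = df.copy()
        sp_col = df.columns[0]
        df[sp_col] = df[sp_col].astype(str)
        unknown = sorted(set(df[sp_col]) - set(tree.tip_labels))
        if unknown:
            raise ValueError(
                f"species not present in the tree: {unknown}"
            )
        traits = tuple(df.columns[1:])
        if len(traits) == 0:
            raise ValueError("trait table has no trait columns")
        M = len(traits)
        n = tree.n_tips
        Y = np.full((n, M), np.nan)
        has_dupes = df[sp_col].duplicated().any()
        means = df.groupby(sp_col, sort=False)[list(traits)].mean()
        for lab, row in means.iterrows():
            Y[tree.tip_index()[lab] - 1] = row.to_numpy(dtype=float)
        B = None
        if se is not None:
            se = se.copy()
            se_sp = se.columns[0]
            se[se_sp] = se[se_sp].astype(str)
            B = np.zeros((n, M, M))
            for _, row in se.iterrows():
                i = tree.tip_index()[row[se_sp]] - 1
                vals = row[list(traits)].to_numpy(dtype=float)
                B[i] = np.diag(np.nan_to_num(vals, nan=0.0) ** 2)
        raw = df if has_dupes else None
        return cls(
            Y=Y,
            species=tree.tip_labels,
            traits=traits,
            B=B,
            raw=raw,
        )

    def validate_B(self) -> None:
        if self.B is None:
            return
        for i in range(self.B.shape[0]):
            Bi = self.B[i]
            if not np.allclose(Bi, Bi.T, atol=1e-10):
                raise ValueError(
                    f"B for species {self.species[i]!r} is not symmetric"
                )
            if np.linalg.eigvalsh(Bi).min() < -1e-10:
                raise ValueError(
                    f"B for species {self.species[i]!r} is not positive "
                    "semidefinite"
                )


@dataclass
class MVTildeQuantities:
    """Per-edge local matrix quantities (and their pre-stretch sums)."""

    p: np.ndarray  # (nn+1, M, M)
    pA: np.ndarray
    U: np.ndarray  # (nn+1, M, M)        L' side, L = trait indicator
    V: np.ndarray  # (nn+1, M, M+1)      R = [indicator | y]
    Q: np.ndarray  # (nn+1, M, M+1)
    logdet: np.ndarray
    UA: np.ndarray
    VA: np.ndarray
    QA: np.ndarray
    logdetA: np.ndarray
    logdetF: np.ndarray  # log|I + T pA| per edge, reused by the preorder
    visits: int = 0


@dataclass
class MVGlobalQuantities:
    mu_hat: np.ndarray  # (nn+1, M)
    p: np.ndarray  # (nn+1, M, M)
    U: np.ndarray
    V: np.ndarray
    Q: np.ndarray
    logdet: np.ndarray
    internal_nodes: np.ndarray
    visits: int = 0


@dataclass
class MVASRResult:
    """Multivariate reconstruction: node estimates, covariances, imputations."""

    node_ids: np.ndarray
    node_labels: tuple
    node_types: tuple  # "internal" | "species"
    estimates: np.ndarray  # (n_nodes_out, M)
    covariances: np.ndarray  # (n_nodes_out, M, M)
    traits: tuple
    imputations: list  # of (node id, label, missing trait idx, mean, cov)
    sigma: np.ndarray | None
    logdet_root: float
    reml: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(self.node_ids):
            for m, tr in enumerate(self.traits):
                var = self.covariances[i][m, m]
                half = 1.96 * np.sqrt(var) if var >= 0 else np.nan
                est = self.estimates[i][m]
                rows.append(
                    (
                        int(v),
                        self.node_labels[i] or "",
                        tr,
                        est,
                        var,
                        est - half,
                        est + half,
                        self.node_types[i],
                    )
                )
        for v, lab, u, mean, cov in self.imputations:
            for j, m in enumerate(u):
                var = cov[j, j]
                half = 1.96 * np.sqrt(var) if np.isfinite(var) else np.nan
                rows.append(
                    (
                        int(v),
                        lab or "",
                        self.traits[m],
                        mean[j],
                        var,
                        mean[j] - half,
                        mean[j] + half,
                        "imputed",
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "node",
                "label",
                "trait",
                "estimate",
                "variance",
                "ci_lower",
                "ci_upper",
                "node_type",
            ],
        )


def _tip_T(edge_mats: EdgeMatrices, B: np.ndarray | None, tip: int):
    T = edge_mats.T[tip]
    if B is not None:
        T = T + B[tip - 1]
    return T


def postorder_pass_mv(
    tree: Tree,
    Y: np.ndarray,
    edge_mats: EdgeMatrices,
    B: np.ndarray | None = None,
) -> tuple[MVTildeQuantities, MVGlobalQuantities]:
    """Matrix postorder pass with observed-subset tip initialization.

    Parameters
    ----------
    Y
        N x M tip matrix, NaN for missing entries (a tip may be entirely
        missing; it then contributes nothing and is an imputation
        target).
    edge_mats
        Per-edge T(e) matrices encoding the evolutionary model.
    B
        Optional (N, M, M) per-species within-species covariances, added
        to the tip T(e) at initialization (summary mode).
    """
    Y = np.asarray(Y, dtype=float)
    n, M = Y.shape
    if n != tree.n_tips:
        raise ValueError("Y must have one row per tip")
    if M != edge_mats.M:
        raise ValueError("trait dimension mismatch between Y and T matrices")
    mask = np.isnan(Y)
    for m in range(M):
        if mask[:, m].all():
            raise ValueError(
                f"trait column {m} is missing for every species and is "
                "unidentifiable"
            )
    nn = tree.n_nodes
    qR = M + 1
    t = MVTildeQuantities(
        p=np.zeros((nn + 1, M, M)),
        pA=np.zeros((nn + 1, M, M)),
        U=np.zeros((nn + 1, M, M)),
        V=np.zeros((nn + 1, M, qR)),
        Q=np.zeros((nn + 1, M, qR)),
        logdet=np.zeros(nn + 1),
        UA=np.zeros((nn + 1, M, M)),
        VA=np.zeros((nn + 1, M, qR)),
        QA=np.zeros((nn + 1, M, qR)),
        logdetA=np.zeros(nn + 1),
        logdetF=np.zeros(nn + 1),
    )
    eye = np.eye(M)
    orders = edge_orders(tree)
    visits = 0
    for e in orders.postorder:
        e = int(e)
        visits += 1
        if tree.is_tip(e):
            k = np.flatnonzero(~mask[e - 1])
            if k.size == 0:
                continue  # fully missing tip: zero contribution
            T = _tip_T(edge_mats, B, e)
            Tkk = T[np.ix_(k, k)]
            try:
                pkk = np.linalg.inv(Tkk)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"tip {tree.labels[e]!r}: T restricted to its "
                    "observed traits is singular"
                ) from None
            pkk = 0.5 * (pkk + pkk.T)
            t.p[e][np.ix_(k, k)] = pkk
            t.U[e] = t.p[e]
            Rk = np.zeros((k.size, qR))
            Rk[:, k] = eye[np.ix_(k, k)]
            Rk[:, M] = Y[e - 1, k]
            t.V[e][k] = pkk @ Rk
            t.Q[e] = t.V[e].copy()  # L = indicator: L_k' pkk R_k, padded
            sign, ld = np.linalg.slogdet(Tkk)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"tip {tree.labels[e]!r}: T on observed traits is "
                    "not positive definite"
                )
            t.logdet[e] = ld
        else:
            _accumulate_mv(t, tree, e, edge_mats.T[e], eye)
    _accumulate_mv(t, tree, tree.root, None, eye)
    t.visits = visits
    g = MVGlobalQuantities(
        mu_hat=np.full((nn + 1, M), np.nan),
        p=np.full((nn + 1, M, M), np.nan),
        U=np.zeros((nn + 1, M, M)),
        V=np.zeros((nn + 1, M, qR)),
        Q=np.zeros((nn + 1, M, qR)),
        logdet=np.full(nn + 1, np.nan),
        internal_nodes=np.array(
            [v for v in range(1, nn + 1) if not tree.is_tip(v)]
        ),
    )
    r = tree.root
    g.p[r] = t.p[r]
    g.U[r] = t.U[r]
    g.V[r] = t.V[r]
    g.Q[r] = t.Q[r]
    g.logdet[r] = t.logdet[r]
    g.mu_hat[r] = _solve_mu(g.Q[r], M, r)
    return t, g


def _accumulate_mv(t, tree, e, T, eye):
    kids = tree.children[e]
    pA = sum(t.p[d] for d in kids)
    UA = sum(t.U[d] for d in kids)
    VA = sum(t.V[d] for d in kids)
    QA = sum(t.Q[d] for d in kids)
    ldA = sum(t.logdet[d] for d in kids)
    t.pA[e] = pA
    t.UA[e] = UA
    t.VA[e] = VA
    t.QA[e] = QA
    t.logdetA[e] = ldA
    if T is None:  # the root has no edge: t = 0, stretch is a no-op
        t.p[e] = pA
        t.U[e] = UA
        t.V[e] = VA
        t.Q[e] = QA
        t.logdet[e] = ldA
        return
    F = eye + T @ pA
    Finv = np.linalg.inv(F)
    ptil = pA @ Finv
    t.p[e] = 0.5 * (ptil + ptil.T)
    t.U[e] = UA @ Finv
    t.V[e] = Finv.T @ VA
    t.Q[e] = QA - UA @ Finv @ T @ VA
    sign, ldF = np.linalg.slogdet(F)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"non-positive determinant of I + T pA at node {e}"
        )
    t.logdetF[e] = ldF
    t.logdet[e] = ldA + ldF


def _solve_mu(Q, M, node):
    Q11 = Q[:, :M]
    Q1y = Q[:, M]
    try:
        mu = np.linalg.solve(Q11, Q1y)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(Q11)
        deficient = _deficient_traits(Q11)
        raise np.linalg.LinAlgError(
            f"node {node}: trait precision matrix is singular (rank "
            f"{rank} < {M}); unidentifiable trait subset {deficient} "
            "given the missingness pattern"
        ) from None
    return mu


def _deficient_traits(Q11):
    w, V = np.linalg.eigh(0.5 * (Q11 + Q11.T))
    null = np.abs(V[:, np.abs(w) < 1e-12 * max(1.0, np.abs(w).max())])
    return sorted(np.flatnonzero(null.sum(axis=1) > 1e-8).tolist())


def preorder_pass_mv(
    tree: Tree,
    edge_mats: EdgeMatrices,
    tilde: MVTildeQuantities,
    root_globals: MVGlobalQuantities,
) -> MVGlobalQuantities:
    """Matrix preorder pass: global quantities at every internal node.

    Only M x M solves are performed per edge; tips are enumerated but
    skipped (their imputation is a separate step, see
    :func:`impute_tip`).
    """
    g = root_globals
    if np.isnan(g.mu_hat[tree.root]).all() and tree.n_nodes > 1:
        raise RuntimeError(
            "preorder_pass_mv requires a completed postorder_pass_mv"
        )
    M = edge_mats.M
    eye = np.eye(M)
    orders = edge_orders(tree)
    visits = 0
    for e in orders.preorder:
        e = int(e)
        visits += 1
        if tree.is_tip(e):
            continue
        a = int(tree.parent[e])
        T = edge_mats.T[e]
        p_oth = g.p[a] - tilde.p[e]
        Fo = eye + T @ p_oth
        Foinv = np.linalg.inv(Fo)
        pg = tilde.pA[e] + p_oth @ Foinv
        g.p[e] = 0.5 * (pg + pg.T)
        dU = g.U[a] - tilde.U[e]
        dV = g.V[a] - tilde.V[e]
        g.U[e] = tilde.UA[e] + dU @ Foinv
        g.V[e] = tilde.VA[e] + Foinv.T @ dV
        g.Q[e] = (
            tilde.QA[e] + (g.Q[a] - tilde.Q[e]) - dU @ Foinv @ T @ dV
        )
        sign, ldFo = np.linalg.slogdet(Fo)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"non-positive determinant of I + T (p(a) - p~) at node {e}"
            )
        g.logdet[e] = g.logdet[a] - tilde.logdetF[e] + ldFo
        g.mu_hat[e] = _solve_mu(g.Q[e], M, e)
    g.visits = visits
    return g


def impute_tip(
    tree: Tree,
    tip: int,
    Y: np.ndarray,
    edge_mats: EdgeMatrices,
    tilde: MVTildeQuantities,
    globals_: MVGlobalQuantities,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional-normal imputation of a tip's missing trait subset.

    Returns ``(u, mean, cov)`` where ``u`` indexes the missing traits.
    ``mean = T_uk T_kk^-1 (y_k - mu_k(a)) + mu_u(a)`` (the exact
    conditional mean of the missing entries given all observed data under
    the flat-root-prior Gaussian model) and ``cov`` is the matching
    prediction covariance ``([ p_oth (I + T p_oth)^-1 ]_uu)^-1`` with
    ``p_oth = p(a) - p_tilde(e)``.  A tip with nothing missing yields an
    empty result.  Note T(e) here is the *evolutionary* edge matrix: in
    summary (means + SE) mode the within-species B is deliberately not
    added, so the imputation targets the latent species mean.
    """
    if not tree.is_tip(tip):
        raise ValueError("impute_tip expects a tip")
    Y = np.asarray(Y, dtype=float)
    M = edge_mats.M
    miss = np.isnan(Y[tip - 1])
    u = np.flatnonzero(miss)
    if u.size == 0:
        return u, np.zeros(0), np.zeros((0, 0))
    k = np.flatnonzero(~miss)
    a = int(tree.parent[tip])
    mu_a = globals_.mu_hat[a]
    if np.isnan(mu_a).any():
        raise RuntimeError("impute_tip requires a completed preorder pass")
    T = edge_mats.T[tip]
    if k.size:
        resid = Y[tip - 1, k] - mu_a[k]
        mean = T[np.ix_(u, k)] @ np.linalg.solve(T[np.ix_(k, k)], resid)
        mean = mean + mu_a[u]
    else:
        mean = mu_a[u].copy()
    p_oth = globals_.p[a] - tilde.p[tip]
    G = p_oth @ np.linalg.inv(np.eye(M) + T @ p_oth)
    G = 0.5 * (G + G.T)
    Guu = G[np.ix_(u, u)]
    try:
        cov = np.linalg.inv(Guu)
    except np.linalg.LinAlgError:
        cov = np.full((u.size, u.size), np.inf)
    return u, mean, cov


def estimate_rate_matrix(tree: Tree, Y: np.ndarray, reml: int = 0) -> np.ndarray:
    """Closed-form ML/REML Brownian rate matrix for complete data.

    ``Sigma_hat = (Y - 1 mu')' C^-1 (Y - 1 mu') / (N - REML)``, assembled
    from the scalar-engine cross-products with L = R = [1 Y] (for
    complete data the trait means decouple from Sigma, so the estimate
    is exact without iteration).  Missing entries are not supported: a
    rate matrix must then be supplied by the user.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(Y).any():
        raise ValueError(
            "closed-form rate estimation requires complete data; supply "
            "a rate matrix when observations are missing"
        )
    n, M = Y.shape
    if n - reml <= 0:
        raise ValueError("need N - REML > 0")
    LR = np.column_stack([np.ones(n), Y])
    _, g = _uni_postorder(tree, Y[:, 0], L=LR, R=LR)
    Q = g.Q[tree.root]
    q11 = Q[0, 0]
    q1y = Q[0, 1:]
    qyy = Q[1:, 1:]
    S = (qyy - np.outer(q1y, q1y) / q11) / (n - reml)
    return 0.5 * (S + S.T)


def _augment_raw_tree(
    tree: Tree, raw: pd.DataFrame, edge_mats: EdgeMatrices, B: np.ndarray
):
    """Attach individual observations as pseudo-tips below species nodes.

    Species tips become internal nodes; each individual edge carries the
    shared within-species covariance B as its length matrix.  Species
    with no observations get a single all-missing pseudo-individual so
    the recursion shape is preserved.
    """
    sp_col = raw.columns[0]
    traits = list(raw.columns[1:])
    M = len(traits)
    groups = {
        str(k): v[traits].to_numpy(dtype=float)
        for k, v in raw.groupby(sp_col, sort=False)
    }
    children_of: dict = {}
    lengths: dict = {}
    labels: dict = {}
    rows = []

    key = [0]

    def nk():
        key[0] += 1
        return key[0]

    keymap = {}
    for v in range(1, tree.n_nodes + 1):
        keymap[v] = nk()
        labels[keymap[v]] = tree.labels[v]
        lengths[keymap[v]] = float(tree.length[v])
    for v in range(1, tree.n_nodes + 1):
        # preserve the original child order so node correspondence holds
        children_of[keymap[v]] = [keymap[c] for c in tree.children[v]]
    ind_edges = []  # pseudo-tip keys
    for v in range(1, tree.n_tips + 1):
        lab = tree.labels[v]
        obs = groups.get(lab)
        if obs is None or len(obs) == 0:
            obs = np.full((1, M), np.nan)
        for j, row in enumerate(obs):
            kk = nk()
            labels[kk] = f"{lab}__obs{j + 1}"
            children_of[kk] = []
            lengths[kk] = 1.0  # placeholder; the matrix below is B
            children_of[keymap[v]].append(kk)
            ind_edges.append(kk)
            rows.append(row)
    aug = _build_from_structure(keymap[tree.root], children_of, lengths, labels)
    # Map keys -> new ids to place edge matrices and data rows.
    lab_to_id = aug.tip_index()
    Yaug = np.full((aug.n_tips, M), np.nan)
    for kk, row in zip(ind_edges, rows):
        Yaug[lab_to_id[labels[kk]] - 1] = row
    Taug = np.zeros((aug.n_nodes + 1, M, M))
    # species-and-above edges keep their evolutionary matrices
    old_by_label = {}
    for v in range(1, tree.n_nodes + 1):
        if tree.labels[v]:
            old_by_label[tree.labels[v]] = v
    # Rebuild a node correspondence by walking both trees in parallel.
    corr = _node_correspondence(tree, aug)
    for old_v, new_v in corr.items():
        if old_v != tree.root:
            Taug[new_v] = edge_mats.T[old_v]
    for lab, i in lab_to_id.items():
        Taug[i] = B
    aug_mats = EdgeMatrices(T=Taug, M=M, model=edge_mats.model, params=edge_mats.params)
    species_nodes = {corr[v]: tree.labels[v] for v in range(1, tree.n_tips + 1)}
    return aug, Yaug, aug_mats, species_nodes, corr


def _node_correspondence(tree: Tree, aug: Tree) -> dict:
    """Old-tree node id -> augmented-tree node id, by matching tip sets.

    Both trees were built with the same child ordering, so parallel
    preorder walks visit corresponding nodes in the same sequence (the
    augmented tree has extra pseudo-tip children appended after the
    originals at species nodes).
    """
    corr = {}
    stack = [(tree.root, aug.root)]
    while stack:
        ov, nv = stack.pop()
        corr[ov] = nv
        okids = tree.children[ov]
        nkids = aug.children[nv]
        for i, ok in enumerate(okids):
            stack.append((ok, nkids[i]))
    return corr


def anc_recon_mv(
    tree: Tree,
    data,
    sigma="estimate",
    edge_mats: EdgeMatrices | None = None,
    mode: str = "means",
    reml: int = 0,
) -> MVASRResult:
    """Multivariate ancestral reconstruction / imputation, end to end.

    Parameters
    ----------
    data
        A :class:`TraitData`, a pandas DataFrame (first column species),
        or a bare N x M array in tip order.
    sigma
        ``"estimate"`` (complete data only), an M x M rate matrix, or
        ignored when ``edge_mats`` is given.
    mode
        ``"means"`` (one row per species), ``"means_se"`` (B added to
        tip edges), or ``"raw"`` (individual observations as tips;
        requires ``data.raw`` or replicate rows and a shared B in
        ``data.B``).
    """
    if isinstance(data, pd.DataFrame):
        data = TraitData.from_frame(tree, data)
    elif isinstance(data, np.ndarray):
        data = TraitData(
            Y=np.asarray(data, dtype=float),
            species=tree.tip_labels,
            traits=tuple(f"trait_{i + 1}" for i in range(data.shape[1])),
        )
    data.validate_B()
    Y = data.Y
    M = data.M
    if edge_mats is None:
        if isinstance(sigma, str) and sigma == "estimate":
            Sig = estimate_rate_matrix(tree, Y, reml=reml)
            sigma_out = Sig
        else:
            Sig = np.atleast_2d(np.asarray(sigma, dtype=float))
            sigma_out = Sig
        edge_mats = edge_length_matrices(tree, Sig)
    else:
        sigma_out = None
    if mode not in {"means", "means_se", "raw"}:
        raise ValueError(f"unknown mode {mode!r}")
    B = data.B if mode in {"means_se", "raw"} else None
    if mode == "raw":
        if data.raw is None:
            # single observation per species: treat Y rows as individuals
            raw = pd.DataFrame(
                {"species": list(tree.tip_labels)}
                | {tr: Y[:, i] for i, tr in enumerate(data.traits)}
            )
        else:
            raw = data.raw
        if data.B is None:
            raise ValueError("raw mode requires a within-species covariance B")
        Bshared = data.B[0] if data.B.ndim == 3 else np.atleast_2d(data.B)
        run_tree, run_Y, run_mats, species_nodes, _ = _augment_raw_tree(
            tree, raw, edge_mats, Bshared
        )
        run_B = None
    else:
        run_tree, run_Y, run_mats = tree, Y, edge_mats
        run_B = B if mode == "means_se" else None
        species_nodes = {}
    tilde, g = postorder_pass_mv(run_tree, run_Y, run_mats, B=run_B)
    g = preorder_pass_mv(run_tree, run_mats, tilde, g)
    node_ids, node_labels, node_types, ests, covs = [], [], [], [], []
    for v in g.internal_nodes:
        node_ids.append(int(v))
        node_labels.append(run_tree.labels[v])
        node_types.append("species" if v in species_nodes else "internal")
        ests.append(g.mu_hat[v])
        try:
            cov = np.linalg.inv(g.p[v])
        except np.linalg.LinAlgError:
            cov = np.full((M, M), np.nan)
        covs.append(0.5 * (cov + cov.T))
    imputations = []
    for v in range(1, run_tree.n_tips + 1):
        miss = np.isnan(run_Y[v - 1])
        if miss.any():
            u, mean, cov = impute_tip(run_tree, v, run_Y, run_mats, tilde, g)
            imputations.append((int(v), run_tree.labels[v], u, mean, cov))
    return MVASRResult(
        node_ids=np.asarray(node_ids),
        node_labels=tuple(node_labels),
        node_types=tuple(node_types),
        estimates=np.asarray(ests),
        covariances=np.asarray(covs),
        traits=data.traits,
        imputations=imputations,
        sigma=sigma_out,
        logdet_root=float(g.logdet[run_tree.root]),
        reml=int(reml),
    )
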