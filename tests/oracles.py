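"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the library's own code paths: influence
matrices are built by explicit path walks over raw parent/length arrays,
eigenvectors come from a dense eigendecomposition of the Gram matrix
(instead of the SVD route), and regressions are solved through explicitly
inverted normal equations (instead of lstsq/QR).
"""

from __future__ import annotations

import numpy as np


def tree_arrays(graph):
    """Raw arrays of a PhyloGraph, so oracle code only sees plain data."""
    return np.asarray(graph.parent, int), np.asarray(graph.length, float), list(graph.labels)


def tips_of(parent):
    nv = len(parent)
    has_child = [False] * nv
    for v in range(1, nv):
        has_child[parent[v]] = True
    return [v for v in range(nv) if not has_child[v]]


def root_path(parent, v):
    path = []
    while v != 0:
        path.append(v - 1)  # edge index = child vertex - 1
        v = parent[v]
    return path


def weighted_influence(parent, length, a, psi=1.0):
    """Tips × edges weighted influence matrix via explicit path walks."""
    tips = tips_of(parent)
    m = len(parent) - 1
    W = np.zeros((len(tips), m))
    for i, t in enumerate(tips):
        for e in root_path(parent, t):
            W[i, e] = psi * length[e + 1] ** ((1.0 - a) / 2.0)
    return W, tips


def pem_scores_dense(parent, length, a, psi=1.0):
    """Eigenvector tip scores via eigendecomposition of the Gram matrix."""
    W, tips = weighted_influence(parent, length, a, psi)
    mu = W.sum(axis=0) / W.shape[0]
    Wc = W - mu
    G = Wc @ Wc.T
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # eigenvalues of the Gram matrix carry O(eps * lambda_max) noise, so the
    # null-space cut must be taken on that scale
    keep = vals > max(Wc.shape) * np.finfo(float).eps * max(vals[0], 0.0)
    s = np.sqrt(vals[keep])
    U = vecs[:, keep]
    for k in range(U.shape[1]):
        col = np.abs(U[:, k])
        j = int(np.flatnonzero(col >= (1.0 - 1e-9) * col.max())[0])
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return U, s, mu, Wc, tips


def target_score_row(parent, length, loc_edge, loc_distance, a, psi, mu, Wc, s, U):
    """Score row for a detached tip, rebuilt from scratch: weighted partial
    influence row, centring, and projection through V·S⁻¹ obtained from the
    dense decomposition (V = Wcᵀ·U·S⁻¹)."""
    m = len(parent) - 1
    x = np.zeros(m)
    origin = parent[loc_edge + 1]
    for e in root_path(parent, origin):
        x[e] = psi * length[e + 1] ** ((1.0 - a) / 2.0)
    if loc_distance > 0:
        x[loc_edge] = psi * loc_distance ** ((1.0 - a) / 2.0)
    V = Wc.T @ U / s
    return (x - mu) @ V / s


def ols_normal_equations(X, y):
    """OLS through the explicitly inverted normal equations."""
    XtX = X.T @ X
    beta = np.linalg.inv(XtX) @ X.T @ y
    resid = y - X @ beta
    return beta, float(resid @ resid), np.linalg.inv(XtX)


def aicc_value(n, k, rss):
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def forward_select_oracle(columns: dict, y: np.ndarray):
    """Greedy forward AICc selection over named candidate columns."""
    n = y.size
    included: list[str] = []

    def fit(terms):
        X = np.column_stack([np.ones(n)] + [columns[t] for t in terms])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return None
        return ols_normal_equations(X, y)

    beta, rss, xtx_inv = fit(included)
    current = aicc_value(n, 1, max(rss, 1e-300))
    remaining = list(columns)
    while remaining and n - (len(included) + 2) - 1 > 1:
        best = None
        for t in remaining:
            out = fit(included + [t])
            if out is None:
                continue
            a = aicc_value(n, len(included) + 2, max(out[1], 1e-300))
            if best is None or a < best[1]:
                best = (t, a, out)
        if best is None or best[1] >= current - 1e-10:
            break
        included.append(best[0])
        remaining.remove(best[0])
        current = best[1]
        beta, rss, xtx_inv = best[2]
    return included, beta, rss, xtx_inv


def loocv_pem_oracle(graph, data, a, graph_locations_fn):
    """From-scratch LOOCV of the PEM framework at fixed steepness.

    Uses the library only to obtain the reduced graph + attachment
    bookkeeping (itself validated by round-trip tests); the design, the
    selection, and the predictions are rebuilt densely here.
    """
    preds = {}
    for species in data.index:
        reduced, (loc,) = graph_locations_fn(graph, [species])
        parent, length, _ = tree_arrays(reduced)
        U, s, mu, Wc, tips = pem_scores_dense(parent, length, a)
        labels = [reduced.labels[t] for t in tips]
        train = data.loc[labels]
        y = train["glw_years"].to_numpy(float)
        columns = {f"V{k + 1}": U[:, k] for k in range(U.shape[1])}
        columns["log10_mass"] = train["log10_mass"].to_numpy(float)
        included, beta, rss, xtx_inv = forward_select_oracle(columns, y)
        row_scores = target_score_row(parent, length, loc.edge, loc.distance, a, 1.0, mu, Wc, s, U)
        x = [1.0]
        for t in included:
            if t == "log10_mass":
                x.append(float(data.loc[species, "log10_mass"]))
            else:
                x.append(float(row_scores[int(t[1:]) - 1]))
        preds[species] = float(np.asarray(x) @ beta)
    return preds
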