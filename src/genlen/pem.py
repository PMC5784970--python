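"""Phylogenetic Eigenvector Maps: basis construction, steepness fit,
forward AICc selection and out-of-sample prediction.

A PEM turns a phylogenetic graph into regression descriptors.  The binary
influence matrix B (tips × edges) marks which edges lie on each
root-to-tip path.  Columns are weighted by w(φ) = ψ·φ^((1−a)/2) — the
steepness parameter a ∈ [0, 1] interpolating between gradual change along
edges (a → 0, Brownian-like: edge variance ∝ φ) and abrupt change at
vertices (a → 1: every edge contributes equally) — then column-centred and
decomposed by SVD.  The left singular vectors are the tip scores: exactly
n − 1 mutually orthogonal, zero-mean, unit-norm eigenvectors for an n-tip
tree, ordered by decreasing singular value (early eigenvectors describe
divergences near the root, late ones fine structure among species).

ψ rescales all columns uniformly: it changes neither eigenvector
directions nor any downstream selection or prediction, and is fixed to 1
during construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from genlen.phylograph import GraphLocation, PhyloGraph

logger = logging.getLogger(__name__)


def edge_weights(graph: PhyloGraph, a: float, psi: float = 1.0) -> np.ndarray:
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"steepness a must lie in [0, 1], got {a}")
    if psi <= 0:
        raise ValueError(f"psi must be positive, got {psi}")
    phi = graph.length[1:]
    return psi * phi ** ((1.0 - a) / 2.0)


@dataclass(frozen=True)
class PEMBasis:
    """Eigenvector descriptors of a phylogenetic graph.

    ``scores`` is the n × r matrix of tip scores (r ≤ n−1 after dropping
    numerically null singular values), columns named V1..Vr in decreasing
    singular-value order, zero-mean, orthonormal.  The sign of each column
    is fixed so its largest-magnitude element is positive.
    """

    graph: PhyloGraph
    a: float
    psi: float
    weights: np.ndarray       # (m,) edge weights w(φ)
    col_means: np.ndarray     # (m,) means of the weighted influence columns
    scores: np.ndarray        # (n, r) tip scores U
    singular_values: np.ndarray  # (r,)
    right_vectors: np.ndarray    # (m, r) V
    n_dropped: int = 0

    @property
    def tip_labels(self) -> tuple:
        return self.graph.tip_labels

    @property
    def n_eigenvectors(self) -> int:
        return self.scores.shape[1]

    @property
    def names(self) -> list:
        return [f"V{k + 1}" for k in range(self.n_eigenvectors)]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.tip_labels), columns=self.names)

    def location_scores(self, locations: Sequence[GraphLocation]) -> np.ndarray:
        """Eigenvector scores for removed tips placed back at recorded
        attachment points, under the basis's own (a, ψ) weighting.

        The target's weighted influence row carries the full weight w(φ_j)
        for every reduced-graph edge on the path from the root to the
        attachment edge's origin, and w(d) for the partly traversed
        attachment edge (d the distance from its origin).  The pendant
        branch has no counterpart among the basis columns and contributes
        nothing to the scores (its variance is unexplainable by
        construction).  The row is centred with the training column means
        and projected through V·S⁻¹.
        """
        m = self.graph.n_edges
        rows = np.zeros((len(locations), m))
        ex = (1.0 - self.a) / 2.0
        for i, loc in enumerate(locations):
            if not 0 <= loc.edge < m:
                raise ValueError(f"location for {loc.species!r}: unknown edge {loc.edge}")
            origin = int(self.graph.parent[loc.edge + 1])
            path = self.graph.root_path_edges(origin)
            rows[i, path] = self.weights[path]
            if loc.distance > 0:
                rows[i, loc.edge] = self.psi * loc.distance ** ex
        centred = rows - self.col_means
        return centred @ self.right_vectors / self.singular_values


def build_pem(graph: PhyloGraph, a: float, psi: float = 1.0) -> PEMBasis:
    """Build the PEM basis of a phylogenetic graph at steepness ``a``."""
    n = graph.n_tips
    if n < 2:
        raise ValueError("PEM needs at least two tips")
    w = edge_weights(graph, a, psi)
    B = graph.influence_matrix() * w
    mu = B.mean(axis=0)
    Bc = B - mu
    U, s, Vt = np.linalg.svd(Bc, full_matrices=False)
    tol = max(Bc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    n_dropped = int((n - 1) - keep.sum())
    if n_dropped > 0:
        logger.info("dropping %d numerically null eigenvector(s)", n_dropped)
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    # deterministic sign: largest-magnitude tip score positive (ties broken
    # by the first index within a relative tolerance, so exact ±x pairs are
    # resolved identically across platforms and branch-length rescalings)
    for k in range(U.shape[1]):
        col = np.abs(U[:, k])
        j = int(np.flatnonzero(col >= (1.0 - 1e-9) * col.max())[0])
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return PEMBasis(
        graph=graph,
        a=float(a),
        psi=float(psi),
        weights=w,
        col_means=mu,
        scores=U,
        singular_values=s,
        right_vectors=V,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class SteepnessFit:
    a: float
    psi: float
    log_likelihood: float
    flat: bool = False


def _whitened_rss(basis: PEMBasis, trait: np.ndarray, aux: np.ndarray | None) -> float:
    """RSS of the trait in the whitened eigenbasis, auxiliary fixed effects
    profiled out.  The intercept is annihilated by the zero-mean property
    of the eigenvectors and needs no column."""
    U, s = basis.scores, basis.singular_values
    yt = (U.T @ trait) / s
    if aux is None or aux.size == 0:
        return float(yt @ yt)
    Zt = (U.T @ aux) / s[:, None]
    _, res, rank, _ = np.linalg.lstsq(Zt, yt, rcond=None)
    if rank < Zt.shape[1] or res.size == 0:
        fitted = Zt @ np.linalg.pinv(Zt) @ yt
        return float(np.sum((yt - fitted) ** 2))
    return float(res[0])


def fit_steepness(
    graph: PhyloGraph,
    trait,
    aux=None,
    *,
    xatol: float = 1e-3,
) -> SteepnessFit:
    """Maximum-likelihood steepness, single value for the whole tree.

    Under the PEM model the trait is Gaussian with covariance
    Σ(a) ∝ B_c(a)·B_c(a)ᵀ; projecting onto the eigenbasis makes the
    components independent with variances σ²·s_k², so the profile
    log-likelihood is −r/2·ln(RSS_w/r) − Σ ln s_k up to constants, with
    auxiliary covariates (e.g. log10 body mass) as fixed effects.  The
    search is a bounded one-dimensional optimisation over a ∈ [0, 1].
    ψ is reported as the fitted residual scale.
    """
    y = np.asarray(trait, float)
    if y.size != graph.n_tips:
        raise ValueError("trait length must match the number of tips")
    if np.ptp(y) == 0.0:
        warnings.warn("constant trait: steepness likelihood is flat, returning a=0")
        return SteepnessFit(a=0.0, psi=1.0, log_likelihood=np.nan, flat=True)
    Z = None
    if aux is not None:
        Z = np.asarray(aux, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != y.size:
            raise ValueError("aux covariates must match trait length")

    def negloglik(a: float) -> float:
        basis = build_pem(graph, float(np.clip(a, 0.0, 1.0)))
        s = basis.singular_values
        r = s.size
        rss = max(_whitened_rss(basis, y, Z), 1e-300)
        return r * np.log(rss / r) + 2.0 * float(np.sum(np.log(s)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
    )
    a_hat = float(np.clip(res.x, 0.0, 1.0))
    basis = build_pem(graph, a_hat)
    rss = _whitened_rss(basis, y, Z)
    r = basis.singular_values.size
    psi_hat = float(np.sqrt(max(rss, 0.0) / r))
    return SteepnessFit(a=a_hat, psi=psi_hat, log_likelihood=-0.5 * float(res.fun))


def aicc(n: int, k: int, rss: float) -> float:
    """Small-sample Akaike criterion n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),
    with k the number of regression coefficients (intercept included)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    if rss < 0:
        raise ValueError("negative RSS")
    return float(n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass(frozen=True)
class SelectedModel:
    """Linear model found by forward AICc selection.

    ``terms`` excludes the intercept; ``coef`` maps 'intercept' and each
    term to its estimate.  ``xtx_inv`` (on the intercept-first design) and
    ``sigma2`` support prediction intervals.
    """

    terms: tuple
    coef: dict
    n: int
    rss: float
    aicc: float
    path: tuple            # ((term_added_or_'intercept', aicc), ...)
    skipped: tuple         # candidates skipped for rank deficiency
    xtx_inv: np.ndarray
    sigma2: float

    @property
    def k(self) -> int:
        return len(self.terms) + 1

    @property
    def df_resid(self) -> int:
        return self.n - self.k

    def design_row(self, values: Mapping[str, float]) -> np.ndarray:
        row = np.empty(self.k)
        row[0] = 1.0
        for j, t in enumerate(self.terms, start=1):
            row[j] = float(values[t])
        return row

    def predict_row(self, values: Mapping[str, float]) -> float:
        beta = np.array([self.coef["intercept"]] + [self.coef[t] for t in self.terms])
        return float(self.design_row(values) @ beta)


def forward_select_aicc(
    candidates: pd.DataFrame,
    response,
    forced: Sequence[str] = (),
) -> SelectedModel:
    """Forward stepwise selection over candidate predictors by AICc.

    Starts from the intercept (plus any ``forced`` covariates), adds at
    each step the candidate giving the lowest AICc, and stops when no
    addition lowers it or the correction denominator would vanish.
    Rank-deficient (collinear) additions are skipped and reported.
    """
    y = np.asarray(response, float)
    n = y.size
    if candidates.shape[0] != n:
        raise ValueError("candidate matrix and response length differ")
    if n < 3:
        raise ValueError("need at least 3 observations")
    names = list(candidates.columns)
    unknown_forced = [f for f in forced if f not in names]
    if unknown_forced:
        raise ValueError(f"forced terms not among candidates: {unknown_forced}")
    cols = {name: np.asarray(candidates[name], float) for name in names}

    def fit(terms: Sequence[str]):
        X = np.column_stack([np.ones(n)] + [cols[t] for t in terms])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            return None
        resid = y - X @ beta
        return X, beta, float(resid @ resid)

    included = list(forced)
    base = fit(included)
    if base is None:
        raise ValueError("forced covariates are collinear")
    current_aicc = aicc(n, len(included) + 1, base[2])
    path = [("intercept" + ("+" + "+".join(forced) if forced else ""), current_aicc)]
    skipped: list[str] = []
    remaining = [t for t in names if t not in included]

    while remaining and n - (len(included) + 2) - 1 > 1:
        best = None
        for t in remaining:
            trial = fit(included + [t])
            if trial is None:
                continue
            a = aicc(n, len(included) + 2, trial[2])
            if best is None or a < best[1]:
                best = (t, a, trial)
        if best is None or best[1] >= current_aicc - 1e-10:
            break
        t, current_aicc, trial = best
        included.append(t)
        remaining.remove(t)
        path.append((t, current_aicc))

    final = fit(included)
    X, beta, rss = final
    # record candidates that were unusable against the final design
    for t in remaining:
        if fit(included + [t]) is None:
            skipped.append(t)
            logger.info("candidate %s skipped: collinear with selected design", t)
    k = len(included) + 1
    coef = {"intercept": float(beta[0])}
    coef.update({t: float(b) for t, b in zip(included, beta[1:])})
    sigma2 = rss / (n - k) if n > k else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    return SelectedModel(
        terms=tuple(included),
        coef=coef,
        n=n,
        rss=rss,
        aicc=current_aicc,
        path=tuple(path),
        skipped=tuple(skipped),
        xtx_inv=xtx_inv,
        sigma2=float(sigma2),
    )


def predict_pem(
    basis: PEMBasis,
    model: SelectedModel,
    locations: Sequence[GraphLocation],
    extra: Mapping[str, Mapping[str, float]] | pd.DataFrame | None = None,
    *,
    level: float = 0.95,
) -> pd.DataFrame:
    """Point predictions with prediction intervals for removed tips.

    ``extra`` supplies non-eigenvector covariate values (e.g. log10 body
    mass) per target species.  Intervals are t-based prediction intervals
    (new-observation variance included) at the model's residual degrees of
    freedom.
    """
    eig_terms = [t for t in model.terms if t.startswith("V")]
    unknown = [t for t in eig_terms if t not in basis.names]
    if unknown:
        raise ValueError(f"model references eigenvectors absent from basis: {unknown}")
    if isinstance(extra, pd.DataFrame):
        extra = {sp: row.to_dict() for sp, row in extra.iterrows()}
    extra = extra or {}
    scores = basis.location_scores(locations)
    name_to_col = {nm: j for j, nm in enumerate(basis.names)}
    tcrit = stats.t.ppf(0.5 + level / 2.0, model.df_resid) if model.df_resid > 0 else np.nan
    rows = []
    for i, loc in enumerate(locations):
        values = {}
        for t in model.terms:
            if t in name_to_col:
                values[t] = scores[i, name_to_col[t]]
            else:
                try:
                    values[t] = float(extra[loc.species][t])
                except KeyError as exc:
                    raise ValueError(
                        f"covariate {t!r} missing for target {loc.species!r}"
                    ) from exc
        x = model.design_row(values)
        fit_val = model.predict_row(values)
        se = float(np.sqrt(model.sigma2 * (1.0 + x @ model.xtx_inv @ x)))
        rows.append(
            {
                "species": loc.species,
                "fit": fit_val,
                "lower95": fit_val - tcrit * se,
                "upper95": fit_val + tcrit * se,
                "se_pred": se,
            }
        )
    return pd.DataFrame(rows)
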