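"""Validation of the prediction frameworks.

Leave-one-out cross-validation (LOOCV) of the PEM and binning predictors,
summarised by the prediction coefficient P² = 1 − Σ(obs−pred)²/Σ(obs−ȳ)²
(a cross-validated analogue of R²; 1 means perfect predictability), an
identity-line regression of observed on predicted values testing
slope = 1 and intercept = 0, the Genizi decomposition of a fitted model's
R² into non-negative per-predictor importance shares, and the allometric
regression of wild generation length on log10 body mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, linalg

from genlen.binning import BinningConfig, predict_bin, predict_combined
from genlen.pem import build_pem, fit_steepness, forward_select_aicc, predict_pem
from genlen.phylograph import PhyloGraph, graph_locations, restrict_to


# ---------------------------------------------------------------------------
# generic LOOCV
# ---------------------------------------------------------------------------

def loocv(dataset: pd.DataFrame, procedure) -> pd.Series:
    """Hold out each row in turn and predict it from the rest.

    ``procedure(train, row)`` runs the *full* fitting pipeline on the
    training frame and returns a prediction for the held-out row (or None
    when no prediction is feasible; recorded as NaN, never dropped
    silently).  The dataset must be indexed by species.  Predictions are
    independent of row order.
    """
    if dataset.index.has_duplicates:
        raise ValueError("dataset index (species) must be unique")
    if len(dataset) < 3:
        raise ValueError("LOOCV needs at least 3 complete cases")
    preds = {}
    for species in dataset.index:
        train = dataset.drop(index=species)
        assert species not in train.index, "leakage: held-out species in training set"
        value = procedure(train, dataset.loc[species])
        preds[species] = np.nan if value is None else float(value)
    return pd.Series(preds, name="predicted").reindex(dataset.index)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def prediction_coefficient(observed, predicted) -> float:
    """P² = 1 − Σ(obs−pred)² / Σ(obs−mean(obs))²."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal lengths")
    keep = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[keep], pred[keep]
    if obs.size < 3:
        raise ValueError("need at least 3 complete pairs")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance: P² undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


@dataclass(frozen=True)
class IdentityLineTest:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    p_slope_vs_1: float | None
    p_intercept_vs_0: float | None
    n: int
    degenerate: bool = False


def identity_line_test(observed, predicted) -> IdentityLineTest:
    """OLS of observed on predicted, t-tests of slope against 1 and
    intercept against 0 (classical standard errors, two-sided).

    A perfect fit (zero residual) leaves the standard errors undefined;
    the result is flagged degenerate with no p-values.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    keep = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[keep], pred[keep]
    if obs.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(pred) == 0.0:
        raise ValueError("predicted values have zero variance")
    res = sm.OLS(obs, sm.add_constant(pred)).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    if res.ssr <= 1e-12 * max(1.0, float(np.sum(obs**2))):
        return IdentityLineTest(
            float(slope), float(intercept), float(se_slope), float(se_int),
            None, None, int(obs.size), degenerate=True,
        )
    t_slope = (slope - 1.0) / se_slope
    t_int = intercept / se_int
    df = res.df_resid
    return IdentityLineTest(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_int),
        p_slope_vs_1=2.0 * float(stats.t.sf(abs(t_slope), df)),
        p_intercept_vs_0=2.0 * float(stats.t.sf(abs(t_int), df)),
        n=int(obs.size),
        degenerate=False,
    )


@dataclass(frozen=True)
class ImportanceShares:
    """Genizi decomposition of a model's R² into per-predictor shares."""

    labels: tuple
    shares: np.ndarray          # same order as labels; sums to total_r2
    total_r2: float
    grouped: dict               # group label -> summed share
    percentages: dict           # label -> share as % of explained variance

    def grouped_percentages(self) -> dict:
        return {g: 100.0 * v / self.total_r2 for g, v in self.grouped.items()}


def genizi_importance(design: pd.DataFrame, response, grouping=None) -> ImportanceShares:
    """Genizi (1993) relative-importance shares λ_j = Σ_k (S_jk c_k)².

    S is the symmetric PSD square root of the predictor correlation matrix
    and c = S⁻¹·r with r the predictor–response correlations.  Shares are
    non-negative, reduce to squared marginal correlations when predictors
    are orthogonal, and sum to the model R².  ``grouping`` maps predictor
    names to group labels (e.g. all eigenvectors to 'phylogeny') for the
    grouped summary.
    """
    y = np.asarray(response, float)
    X = design.to_numpy(float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("design and response length differ")
    if n <= p:
        raise ValueError("need more observations than predictors")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(design.columns, sds) if s == 0]
        raise ValueError(f"constant predictor columns: {bad}")
    if np.std(y, ddof=1) == 0:
        raise ValueError("constant response")
    Xs = (X - X.mean(axis=0)) / sds
    ys = (y - y.mean()) / np.std(y, ddof=1)
    R = (Xs.T @ Xs) / (n - 1)
    r = (Xs.T @ ys) / (n - 1)
    vals, vecs = np.linalg.eigh(R)
    if np.min(vals) < 1e-10:
        weights = np.abs(vecs[:, np.argmin(vals)])
        bad = [design.columns[int(i)] for i in np.argsort(-weights)[:3]]
        raise ValueError(f"rank-deficient design; offending columns include {bad}")
    S = (vecs * np.sqrt(vals)) @ vecs.T
    c = np.linalg.solve(S, r)
    shares = np.sum((S * c[None, :]) ** 2, axis=1)
    total = float(r @ np.linalg.solve(R, r))
    grouping = grouping or {}
    grouped: dict[str, float] = {}
    for label, share in zip(design.columns, shares):
        grouped.setdefault(grouping.get(label, label), 0.0)
        grouped[grouping.get(label, label)] += float(share)
    pct = {label: 100.0 * float(s) / total for label, s in zip(design.columns, shares)}
    return ImportanceShares(
        labels=tuple(design.columns),
        shares=shares,
        total_r2=total,
        grouped=grouped,
        percentages=pct,
    )


@dataclass(frozen=True)
class AllometricFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def allometric_regression(gl_years, mass_g) -> AllometricFit:
    """OLS of GLw (years) on log10 body mass (grams)."""
    gl = np.asarray(gl_years, float)
    mass = np.asarray(mass_g, float)
    keep = ~(np.isnan(gl) | np.isnan(mass))
    gl, mass = gl[keep], mass[keep]
    if gl.size < 3:
        raise ValueError("need at least 3 species with both GLw and mass")
    if np.any(mass <= 0):
        raise ValueError("non-positive mass")
    x = np.log10(mass)
    if np.ptp(x) == 0.0:
        raise ValueError("constant mass: allometric slope undefined")
    res = sm.OLS(gl, sm.add_constant(x)).fit()
    return AllometricFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        n=int(gl.size),
    )


# ---------------------------------------------------------------------------
# framework-specific LOOCV drivers
# ---------------------------------------------------------------------------

def _require_columns(data: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns: {missing}")


def pem_fold(
    graph: PhyloGraph,
    train: pd.DataFrame,
    targets: pd.DataFrame,
    *,
    use_mass: bool = True,
    fit_a: bool = True,
    fixed_a: float = 0.0,
    steepness_xatol: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """One PEM fitting-and-prediction pass.

    ``graph`` must contain both training and target species as tips; the
    targets are detached, the steepness is (re)fitted on the training
    species, eigenvectors plus log10 mass compete in forward AICc
    selection, and the targets are predicted at their recorded locations.
    Returns the prediction frame and a model summary dict.
    """
    _require_columns(train, ["glw_years", "log10_mass"])
    reduced, locations = graph_locations(graph, list(targets.index))
    order = [lab for lab in reduced.tip_labels]
    missing = set(order) - set(train.index)
    if missing:
        raise ValueError(f"training data missing for tips: {sorted(missing)}")
    tr = train.loc[order]
    y = tr["glw_years"].to_numpy(float)
    aux = tr["log10_mass"].to_numpy(float) if use_mass else None
    if fit_a:
        a_hat = fit_steepness(reduced, y, aux=aux, xatol=steepness_xatol).a
    else:
        a_hat = fixed_a
    basis = build_pem(reduced, a_hat)
    candidates = basis.scores_frame()
    if use_mass:
        candidates["log10_mass"] = tr["log10_mass"].to_numpy(float)
    model = forward_select_aicc(candidates, y)
    extra = (
        {sp: {"log10_mass": float(targets.loc[sp, "log10_mass"])} for sp in targets.index}
        if use_mass
        else None
    )
    preds = predict_pem(basis, model, locations, extra=extra)
    summary = {
        "a_hat": a_hat,
        "n_terms": len(model.terms),
        "n_eigenvectors": sum(t.startswith("V") for t in model.terms),
        "mass_included": "log10_mass" in model.terms,
        "aicc": model.aicc,
        "terms": list(model.terms),
    }
    return preds, summary


def pem_loocv(
    graph: PhyloGraph,
    data: pd.DataFrame,
    *,
    use_mass: bool = True,
    fit_a: bool = True,
    fixed_a: float = 0.0,
    steepness_xatol: float = 0.01,
) -> pd.DataFrame:
    """LOOCV of the PEM framework over species with observed GLw.

    For every fold the whole pipeline — steepness optimisation and forward
    model selection — is repeated on the remaining species.  ``data`` is
    indexed by species with columns glw_years and log10_mass; the graph is
    pruned to exactly those species first.
    """
    _require_columns(data, ["glw_years", "log10_mass"])
    g = restrict_to(graph, list(data.index))
    rows = []
    for species in data.index:
        preds, summary = pem_fold(
            g,
            data.drop(index=species),
            data.loc[[species]],
            use_mass=use_mass,
            fit_a=fit_a,
            fixed_a=fixed_a,
            steepness_xatol=steepness_xatol,
        )
        rows.append(
            {
                "species": species,
                "observed": float(data.loc[species, "glw_years"]),
                "predicted": float(preds["fit"].iloc[0]),
                "lower95": float(preds["lower95"].iloc[0]),
                "upper95": float(preds["upper95"].iloc[0]),
                "a_hat": summary["a_hat"],
                "n_terms": summary["n_terms"],
            }
        )
    return pd.DataFrame(rows).set_index("species")


def bin_loocv(
    data: pd.DataFrame,
    config: BinningConfig = BinningConfig(),
    mode: str = "mass",
) -> pd.DataFrame:
    """LOOCV of a binning framework (`mode` in mass / taxon / combined).

    ``data`` is indexed by species with columns genus, family, mass_g and
    glw_years; every held-out species is predicted from the others.
    """
    _require_columns(data, ["genus", "family", "mass_g", "glw_years"])
    if mode not in ("mass", "taxon", "combined"):
        raise ValueError(f"unknown binning mode {mode!r}")

    def procedure(train: pd.DataFrame, row: pd.Series):
        ref = train.reset_index()
        focal = {"species": row.name, **row.to_dict()}
        if mode == "combined":
            out = predict_combined(focal, ref, config)
        else:
            out = predict_bin(focal, ref, config, use_mass=(mode == "mass"))
        procedure.last_levels[row.name] = out.level_used
        return out.predicted_gl_years

    procedure.last_levels = {}
    preds = loocv(data, procedure)
    out = pd.DataFrame(
        {
            "observed": data["glw_years"].astype(float),
            "predicted": preds,
        }
    )
    out["level_used"] = pd.Series(procedure.last_levels).reindex(data.index)
    return out
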