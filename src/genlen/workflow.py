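"""High-level drivers tying the stages together.

These functions are what the numbered analysis scripts and the acceptance
script call: compile records into a generation-length table, fit and
summarise the explanatory PEM, cross-validate the three prediction
frameworks, and produce estimates for true missing-data species with both
the PEM and the combined binning fallback.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from genlen.binning import BinningConfig, predict_combined
from genlen.genlength import DEFAULT_Z, gl_table, paired_comparison
from genlen.pem import build_pem, fit_steepness, forward_select_aicc
from genlen.phylograph import PhyloGraph, restrict_to
from genlen.records import compile_database
from genlen.validation import (
    bin_loocv,
    genizi_importance,
    identity_line_test,
    pem_fold,
    pem_loocv,
    prediction_coefficient,
)


def compiled_gl_table(records: pd.DataFrame, taxonomy: pd.DataFrame,
                      z: float = DEFAULT_Z, exclude_species=()) -> pd.DataFrame:
    """Compile records and attach GLw/GLc and log10 mass, indexed by species.

    ``exclude_species`` drops named species before any analysis (sensitivity
    runs such as removing taxonomic outliers)."""
    gl = gl_table(compile_database(records, taxonomy), z=z)
    if len(exclude_species):
        from genlen.records import canonical_name
        drop = {canonical_name(s) for s in exclude_species}
        gl = gl[~gl["species"].isin(drop)]
    gl["log10_mass"] = np.log10(gl["mass_g"].astype(float))
    return gl.set_index("species")


def complete_cases(data: pd.DataFrame) -> pd.DataFrame:
    """Species with both an observed GLw and a body mass."""
    return data[data["glw_years"].notna() & data["log10_mass"].notna()]


def explanatory_pem(graph: PhyloGraph, complete: pd.DataFrame) -> dict:
    """Fit the explanatory model on all complete cases.

    Steepness by ML with GLw and log10 mass as auxiliary traits, then
    forward AICc selection over the n−1 eigenvectors plus log10 mass, then
    the Genizi importance split of the selected model's R² into a mass
    share and a summed phylogeny share.
    """
    g = restrict_to(graph, list(complete.index))
    order = list(g.tip_labels)
    y = complete.loc[order, "glw_years"].to_numpy(float)
    mass = complete.loc[order, "log10_mass"].to_numpy(float)
    steep = fit_steepness(g, y, aux=mass)
    basis = build_pem(g, steep.a)
    candidates = basis.scores_frame()
    candidates["log10_mass"] = mass
    model = forward_select_aicc(candidates, y)
    out = {
        "a_hat": steep.a,
        "psi_hat": steep.psi,
        "n_eigenvectors_available": basis.n_eigenvectors,
        "terms": list(model.terms),
        "n_selected_eigenvectors": sum(t.startswith("V") for t in model.terms),
        "mass_selected": "log10_mass" in model.terms,
        "aicc": model.aicc,
        "aicc_path": [(t, float(a)) for t, a in model.path],
    }
    if model.terms:
        grouping = {t: ("mass" if t == "log10_mass" else "phylogeny") for t in model.terms}
        imp = genizi_importance(candidates[list(model.terms)], y, grouping)
        shares_pct = imp.grouped_percentages()
        out["r_squared"] = imp.total_r2
        out["mass_importance_pct"] = shares_pct.get("mass", 0.0)
        out["phylogeny_importance_pct"] = shares_pct.get("phylogeny", 0.0)
        out["eigenvector_importance_pct"] = {
            t: imp.percentages[t] for t in model.terms if t.startswith("V")
        }
    return out


def validate_frameworks(graph: PhyloGraph, complete: pd.DataFrame,
                        bin_config: BinningConfig = BinningConfig()) -> dict:
    """LOOCV of the PEM and both binning frameworks, with P² and the
    identity-line regression of observed on predicted values."""
    results = {}
    pem = pem_loocv(graph, complete[["glw_years", "log10_mass"]])
    results["pem"] = {"predictions": pem}
    for mode, key in (("mass", "bin_mass"), ("taxon", "bin_taxon")):
        results[key] = {"predictions": bin_loocv(complete, bin_config, mode=mode)}
    for key, res in results.items():
        preds = res["predictions"]
        res["p2"] = prediction_coefficient(preds["observed"], preds["predicted"])
        ident = identity_line_test(preds["observed"], preds["predicted"])
        res["identity"] = ident
        if "level_used" in preds:
            res["level_counts"] = preds["level_used"].value_counts().to_dict()
    return results


def predict_missing_species(graph: PhyloGraph, complete: pd.DataFrame,
                            missing: pd.DataFrame,
                            bin_config: BinningConfig = BinningConfig()) -> pd.DataFrame:
    """PEM and combined-binning GLw estimates for true missing-data species.

    ``missing`` needs genus/family/mass columns; the PEM locates each
    missing species on the tree pruned to the complete cases and predicts
    from the model selected there, the binning walks the four-level
    hierarchy against the complete cases.
    """
    g = restrict_to(graph, list(complete.index) + list(missing.index))
    pem_preds, summary = pem_fold(
        g, complete[["glw_years", "log10_mass"]], missing[["log10_mass"]]
    )
    pem_preds = pem_preds.set_index("species")
    reference = complete.reset_index()[["species", "genus", "family", "mass_g", "glw_years"]]
    rows = []
    for sp in missing.index:
        focal = {
            "species": sp,
            "genus": missing.loc[sp, "genus"],
            "family": missing.loc[sp, "family"],
            "mass_g": missing.loc[sp, "mass_g"],
        }
        bp = predict_combined(focal, reference, bin_config)
        rows.append(
            {
                "species": sp,
                "pem_gl_years": float(pem_preds.loc[sp, "fit"]),
                "pem_lower95": float(pem_preds.loc[sp, "lower95"]),
                "pem_upper95": float(pem_preds.loc[sp, "upper95"]),
                "bin_gl_years": bp.predicted_gl_years,
                "bin_level": bp.level_used,
                "bin_n_reference": bp.n_reference_species,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def compare_missing_predictions(missing_preds: pd.DataFrame):
    """Paired comparison of PEM vs combined-binning estimates."""
    both = missing_preds.dropna(subset=["pem_gl_years", "bin_gl_years"])
    return paired_comparison(both["pem_gl_years"], both["bin_gl_years"])
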