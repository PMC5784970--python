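"""Leave-one-out cross-validation of the three prediction frameworks.

For every complete-case species in turn: detach it from the tree, refit
the PEM steepness, rerun forward AICc selection, and predict it back; or
predict it as the mean GLw of congenerics/confamilials with and without
log10 body-mass bins.  Summarises each framework by the prediction
coefficient P² and the identity-line regression (observed ~ predicted,
H0: slope 1, intercept 0).  Writes results/loocv_predictions.csv and
results/validation.json.
"""

import json
import pathlib

import pandas as pd

from genlen.workflow import complete_cases, validate_frameworks

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    import numpy as np
    from genlen.phylograph import tree_to_graph

    gl = pd.read_csv(ROOT / "gl.csv")
    gl["log10_mass"] = np.log10(gl["mass_g"])
    complete = complete_cases(gl.set_index("species"))
    graph = tree_to_graph((ROOT / "world" / "tree.nwk").read_text())

    results = validate_frameworks(graph, complete)

    frames = []
    summary = {}
    for key, res in results.items():
        preds = res["predictions"].copy()
        preds["framework"] = key
        frames.append(preds.reset_index())
        ident = res["identity"]
        summary[key] = {
            "p2": res["p2"],
            "identity_slope": ident.slope,
            "identity_intercept": ident.intercept,
            "p_slope_vs_1": ident.p_slope_vs_1,
            "p_intercept_vs_0": ident.p_intercept_vs_0,
            "n": ident.n,
            "level_counts": res.get("level_counts"),
        }
    pd.concat(frames).round(5).to_csv(ROOT / "loocv_predictions.csv", index=False)
    (ROOT / "validation.json").write_text(json.dumps(summary, indent=2))

    print(f"LOOCV over {len(complete)} species -> {ROOT / 'validation.json'}")
    for key in ("pem", "bin_mass", "bin_taxon"):
        s = summary[key]
        print(f"  {key:9s} P² = {s['p2']:.2f}; identity slope {s['identity_slope']:.2f} "
              f"(p = {s['p_slope_vs_1']:.2f}), intercept {s['identity_intercept']:.2f} "
              f"(p = {s['p_intercept_vs_0']:.2f})")
    print(f"  mass-bin assignments: {summary['bin_mass']['level_counts']}")
    print(f"  taxon-only assignments: {summary['bin_taxon']['level_counts']}")


if __name__ == "__main__":
    main()
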