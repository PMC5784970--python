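"""Synthetic worlds with the statistical structure the analysis assumes.

Generates (i) a pure-birth ultrametric species tree with genera and
families assigned to monophyletic clades, (ii) true traits — log10 body
mass evolving by Brownian motion, wild generation length as a log-mass
allometry plus a phylogenetically structured (Brownian) residual plus
independent noise, ages of first/last reproduction back-solved so the
Rspan identity holds exactly, and a captive longevity exceeding the wild
one by a positive offset — and (iii) a multi-source literature-record
table: 1–5 noisy records per parameter per species, some reported as
ranges, units mixed, wild/captive/unknown provenance, and a configured
fraction of species with all wild longevity records deleted.

Longevity records are generated as *under*-estimates of the true maximum
lifespan (a record reports the oldest individual actually observed, which
falls short of the true maximum by an absolute, lifespan-independent
deficit), with ranges whose upper bound is the source's point estimate —
the situation the compile-time maximum/upper-bound rules are designed
for.  AFR-type records carry symmetric multiplicative noise and
central-value ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from genlen.genlength import DEFAULT_Z, rspan_gl
from genlen.phylograph import PhyloGraph
from genlen.records import DAYS_PER_MONTH, DAYS_PER_YEAR


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic world.

    Defaults emulate the antelope setting: 86 species in 34 genera, about
    a third lacking wild longevity data, captive longevity exceeding wild
    by about 2200 days, and generation length dominated by the log-mass
    allometry with a weaker phylogenetic residual.
    """

    n_species: int = 86
    n_genera: int = 34
    n_families: int = 4
    birth_rate: float = 1.0          # per unit time; tree rescaled to tree_depth
    tree_depth: float = 15.0         # crown age, arbitrary time units
    seed: int = 20180125

    # traits
    root_log10_mass: float = 4.5     # log10 grams (~30 kg)
    mass_tip_sd: float = 0.35        # BM sd of log10 mass at the tips
    mass_indep_sd: float = 0.40      # species-specific (non-phylogenetic) log10-mass spread
    allometry_slope: float = 2.0     # GLw years per log10 gram
    allometry_intercept: float = -2.5
    phylo_resid_sd: float = 0.7      # BM residual sd of GLw at the tips (years)
    indep_resid_sd: float = 0.25     # iid residual sd of GLw (years)
    z: float = DEFAULT_Z
    rspan_fraction_band: tuple = (0.15, 0.35)  # AFR/ALR ratio
    gestation_mean_days: float = 240.0
    gestation_sd_days: float = 30.0
    captive_offset_days: float = 2200.0
    captive_offset_sd_days: float = 400.0

    # records
    sources_min: int = 1
    sources_max: int = 5
    p_direct_afr: float = 0.25       # source reports AFR directly vs maturity+gestation
    noise_cv: float = 0.04           # multiplicative noise scale (AFR-type, mass)
    longevity_deficit_sd_days: float = 150.0  # |N(0, sd)| under-report per record
    p_range: float = 0.3             # record emitted as a range
    range_halfwidth: tuple = (0.05, 0.15)
    p_unknown_provenance: float = 0.35  # captive record labelled 'unknown'
    unit_probs_age: tuple = (0.1, 0.3, 0.6)  # days, months, years
    unit_probs_mass: tuple = (0.7, 0.3)      # g, kg
    missing_wild_fraction: float = 32.0 / 86.0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if not (1 <= self.n_families <= self.n_genera <= self.n_species):
            raise ValueError("need 1 <= n_families <= n_genera <= n_species")
        if min(self.phylo_resid_sd, self.indep_resid_sd, self.mass_tip_sd) < 0:
            raise ValueError("variances must be non-negative")
        for frac in (self.p_direct_afr, self.noise_cv, self.p_range,
                     self.p_unknown_provenance, self.missing_wild_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        lo, hi = self.rspan_fraction_band
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("rspan fraction band must lie inside (0, 1)")


@dataclass(frozen=True)
class SyntheticWorld:
    config: SimulationConfig
    tree: PhyloGraph
    taxonomy: pd.DataFrame   # species, genus, family
    truth: pd.DataFrame      # true per-species traits incl. GLw
    records: pd.DataFrame    # SourceRecord table


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(
    n_species: int, birth_rate: float, rng: np.random.Generator, depth: float = 1.0
) -> PhyloGraph:
    """Pure-birth (Yule) crown tree with ``n_species`` tips, rescaled so the
    root-to-tip depth equals ``depth``.  Ultrametric by construction."""
    if n_species < 3:
        raise ValueError("need at least 3 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    # node table: parent, birth-time; root (first split) at time 0
    parent = [-1, 0, 0]
    time = [0.0, None, None]
    active = [1, 2]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        time[v] = t
        parent.extend([v, v])
        time.extend([None, None])
        active.extend([len(parent) - 2, len(parent) - 1])
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for v in active:
        time[v] = t_end
    scale = depth / t_end
    nv = len(parent)
    labels = [None] * nv
    for i, v in enumerate(sorted(active)):
        labels[v] = f"tip{i:03d}"  # provisional; renamed by clade assignment
    # node table is already in preorder (children appended after parents)
    length = np.zeros(nv)
    for v in range(1, nv):
        length[v] = (time[v] - time[parent[v]]) * scale
    return PhyloGraph(parent=np.array(parent), length=length, labels=tuple(labels))


def _clades_at_count(graph: PhyloGraph, k: int) -> list[list[int]]:
    """Partition tips into k clades by cutting the ultrametric tree at the
    time when exactly k lineages existed."""
    depths = graph.depths()
    tips = graph.tip_ids
    if k == 1:
        return [list(tips)]
    internal_depths = sorted(
        depths[v] for v in range(graph.n_vertices) if v not in set(tips.tolist())
    )
    # after the i-th split (depth d_i) the lineage count is i+2 for a crown
    # tree; lineage count == k on [d_{k-2}, d_{k-1})
    lo = internal_depths[k - 2]
    hi = internal_depths[k - 1] if k - 1 < len(internal_depths) else float(np.max(depths))
    tau = 0.5 * (lo + hi)
    clades = []
    # edges crossing tau: parent depth <= tau < child depth
    children = graph.children()

    def tips_below(v):
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if not children[u]:
                out.append(u)
            else:
                stack.extend(children[u])
        return sorted(out)

    for v in range(1, graph.n_vertices):
        if depths[graph.parent[v]] <= tau < depths[v]:
            clades.append(tips_below(v))
    return clades


def assign_taxonomy(
    graph: PhyloGraph, n_genera: int, n_families: int
) -> tuple[PhyloGraph, pd.DataFrame]:
    """Name tips binomially with genera/families as monophyletic clades.

    Genera are clades at the tree slice with ``n_genera`` lineages,
    families at the coarser ``n_families`` slice; the finer cut refines the
    coarser one, so every genus is nested in exactly one family.
    """
    genera = _clades_at_count(graph, n_genera)
    families = _clades_at_count(graph, n_families)
    tip_to_family = {}
    for fi, clade in enumerate(sorted(families, key=min)):
        for t in clade:
            tip_to_family[t] = f"Family{fi + 1:02d}"
    labels = list(graph.labels)
    rows = []
    for gi, clade in enumerate(sorted(genera, key=min)):
        genus = f"Genus{gi + 1:02d}"
        for si, t in enumerate(clade):
            species = f"{genus} sp{si + 1:02d}"
            labels[t] = species
            rows.append(
                {"species": species, "genus": genus, "family": tip_to_family[t]}
            )
    named = PhyloGraph(parent=graph.parent, length=graph.length, labels=tuple(labels))
    taxonomy = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    return named, taxonomy


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _brownian_tips(graph: PhyloGraph, tip_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Brownian motion along the tree, scaled so tip sd (about the root
    value) equals ``tip_sd``.  Returns deviations per tip."""
    if tip_sd == 0.0:
        return np.zeros(graph.n_tips)
    depth = float(graph.depths().max())
    rate = tip_sd**2 / depth
    phi = graph.length[1:]
    eps = rng.normal(0.0, np.sqrt(rate * phi))
    return graph.influence_matrix() @ eps


def simulate_traits(
    graph: PhyloGraph,
    taxonomy: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True per-species traits on the (named) tree.

    GLw = intercept + slope·log10(mass) + Brownian residual + iid noise;
    AFR (integer days) and wild ALR are back-solved from GLw and a drawn
    AFR/ALR fraction so that rspan_gl(AFR, ALRw, z) reproduces GLw
    exactly; captive ALR adds a positive offset.
    """
    order = list(graph.tip_labels)
    n = len(order)
    log_mass = (
        config.root_log10_mass
        + _brownian_tips(graph, config.mass_tip_sd, rng)
        + rng.normal(0.0, config.mass_indep_sd, n)
    )
    gl = (
        config.allometry_intercept
        + config.allometry_slope * log_mass
        + _brownian_tips(graph, config.phylo_resid_sd, rng)
        + rng.normal(0.0, config.indep_resid_sd, n)
    )
    if np.any(gl <= 0.5):
        raise ValueError(
            "configuration yields non-positive or implausibly small generation "
            "lengths; increase the allometry intercept or reduce residual variance"
        )
    f = rng.uniform(*config.rspan_fraction_band, n)
    z = config.z
    gl_days = gl * DAYS_PER_YEAR
    alr0 = gl_days / (f + z * (1.0 - f))
    afr_days = np.ceil(f * alr0)
    # keep the Rspan identity exact after the integer-day AFR convention
    alr_wild = afr_days + (gl_days - afr_days) / z
    if np.any(alr_wild <= afr_days):
        raise ValueError("configuration yields ALR <= AFR")
    offset = np.maximum(
        rng.normal(config.captive_offset_days, config.captive_offset_sd_days, n), 1.0
    )
    gestation = np.clip(
        rng.normal(config.gestation_mean_days, config.gestation_sd_days, n),
        60.0,
        0.7 * afr_days,
    )
    truth = pd.DataFrame(
        {
            "species": order,
            "log10_mass": log_mass,
            "mass_g": 10.0**log_mass,
            "glw_years": gl,
            "afr_days": afr_days,
            "alr_wild_days": alr_wild,
            "alr_captive_days": alr_wild + offset,
            "gestation_days": gestation,
            "rspan_fraction": f,
        }
    )
    truth = truth.merge(taxonomy, on="species")
    # invariant: GLw recomputable from the stored ages
    check = np.array(
        [rspan_gl(a, w, z) for a, w in zip(truth["afr_days"], truth["alr_wild_days"])]
    )
    assert np.allclose(check, truth["glw_years"], atol=1e-9)
    return truth.set_index("species").loc[order].reset_index()


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

_AGE_UNITS = ("days", "months", "years")
_AGE_FACTORS = (1.0, DAYS_PER_MONTH, DAYS_PER_YEAR)
_MASS_UNITS = ("g", "kg")
_MASS_FACTORS = (1.0, 1000.0)


def _emit(rows, species, genus, family, parameter, days_or_grams, unit_idx, kind,
          provenance, source, rng, config, *, as_range, range_rule):
    """Append one record row, converting to the chosen reporting unit."""
    if kind == "age":
        unit = _AGE_UNITS[unit_idx]
        value = days_or_grams / _AGE_FACTORS[unit_idx]
    else:
        unit = _MASS_UNITS[unit_idx]
        value = days_or_grams / _MASS_FACTORS[unit_idx]
    row = {
        "species": species,
        "genus": genus,
        "family": family,
        "parameter": parameter,
        "value": np.nan,
        "value_min": np.nan,
        "value_max": np.nan,
        "unit": unit,
        "provenance": provenance,
        "source_id": source,
    }
    if as_range:
        r = rng.uniform(*config.range_halfwidth)
        if range_rule == "central":
            row["value_min"], row["value_max"] = value * (1 - r), value * (1 + r)
        else:  # 'upper': the point estimate is the range's upper bound
            row["value_min"], row["value_max"] = value * (1 - 2 * r), value
    else:
        row["value"] = value
    rows.append(row)


def simulate_records(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Multi-source record table for a world's true traits.

    With ``noise_cv = 0`` and ``p_range = 0`` the compile rules recover the
    true values exactly.  A fixed-size subset of species
    (round(missing_wild_fraction · n)) loses all wild longevity records.
    """
    n = len(truth)
    n_missing = int(round(config.missing_wild_fraction * n))
    missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist())

    def n_sources():
        return int(rng.integers(config.sources_min, config.sources_max + 1))

    def sym_noise(v):
        return float(v) * (1.0 + rng.normal(0.0, config.noise_cv))

    def under_noise(v):
        # a source reports the oldest individual it observed: an absolute,
        # lifespan-independent shortfall from the true maximum
        return max(float(v) - abs(rng.normal(0.0, config.longevity_deficit_sd_days)), 1.0)

    def age_unit():
        return int(rng.choice(3, p=config.unit_probs_age))

    rows: list[dict] = []
    for i, row in enumerate(truth.itertuples(index=False)):
        sp, gen, fam = row.species, row.genus, row.family
        # --- AFR block -----------------------------------------------------
        for s in range(n_sources()):
            source = f"src{s + 1}"
            as_range = rng.random() < config.p_range
            if rng.random() < config.p_direct_afr:
                _emit(rows, sp, gen, fam, "afr", sym_noise(row.afr_days), age_unit(),
                      "age", "unknown", source, rng, config,
                      as_range=as_range, range_rule="central")
            else:
                maturity = row.afr_days - row.gestation_days
                _emit(rows, sp, gen, fam, "maturity_female", sym_noise(maturity),
                      age_unit(), "age", "unknown", source, rng, config,
                      as_range=as_range, range_rule="central")
                _emit(rows, sp, gen, fam, "gestation", sym_noise(row.gestation_days),
                      age_unit(), "age", "unknown", source, rng, config,
                      as_range=False, range_rule="central")
        # --- wild longevity ------------------------------------------------
        if i not in missing_idx:
            for s in range(n_sources()):
                _emit(rows, sp, gen, fam, "longevity", under_noise(row.alr_wild_days),
                      age_unit(), "age", "wild", f"src{s + 1}", rng, config,
                      as_range=rng.random() < config.p_range, range_rule="upper")
        # --- captive longevity ---------------------------------------------
        for s in range(n_sources()):
            prov = "unknown" if rng.random() < config.p_unknown_provenance else "captive"
            _emit(rows, sp, gen, fam, "longevity", under_noise(row.alr_captive_days),
                  age_unit(), "age", prov, f"src{s + 1}", rng, config,
                  as_range=rng.random() < config.p_range, range_rule="upper")
        # --- body mass ------------------------------------------------------
        uidx = int(rng.choice(2, p=config.unit_probs_mass))
        _emit(rows, sp, gen, fam, "mass", sym_noise(row.mass_g), uidx, "mass",
              "unknown", "src1", rng, config, as_range=False, range_rule="central")
    return pd.DataFrame(rows)


def simulate_world(config: SimulationConfig) -> SyntheticWorld:
    """End-to-end synthetic world; identical configs give identical tables."""
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_trait, rng_rec = (np.random.default_rng(s) for s in ss.spawn(3))
    tree = simulate_tree(config.n_species, config.birth_rate, rng_tree, config.tree_depth)
    tree, taxonomy = assign_taxonomy(tree, config.n_genera, config.n_families)
    truth = simulate_traits(tree, taxonomy, config, rng_trait)
    records = simulate_records(truth, config, rng_rec)
    return SyntheticWorld(
        config=config, tree=tree, taxonomy=taxonomy, truth=truth, records=records
    )


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write records.csv, taxa.csv, tree.nwk and truth.csv to a directory."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.records.to_csv(out / "records.csv", index=False)
    world.taxonomy.to_csv(out / "taxa.csv", index=False)
    world.truth.to_csv(out / "truth.csv", index=False)
    (out / "tree.nwk").write_text(world.tree.to_newick() + "\n")
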