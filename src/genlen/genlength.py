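"""Generation length: Rspan, life-table and mortality estimators.

Generation length (GL) is the average age of the parents of the current
cohort.  The life-table definition is GL = Σ x·l(x)·m(x) / Σ l(x)·m(x);
when only ages of first (AFR) and last (ALR) reproduction are available,
the reproductive-lifespan approximation GL = AFR + z·(ALR − AFR) is used,
with z the fraction of the adult lifespan elapsed before half of the
age-weighted lifetime reproduction is achieved.  z defaults to the
published cross-mammal constant 0.29; the mortality approximation
GL = 1/(adult annual mortality) + AFR is provided for completeness.

Captive and wild longevities are kept apart throughout: GLw uses the wild
ALR, GLc the captive one, and `paired_comparison` quantifies their
difference over species carrying both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from genlen.records import DAYS_PER_YEAR

#: Published cross-mammal value of the Rspan constant z (221 species).
DEFAULT_Z = 0.29


def rspan_gl(
    afr_days: float, alr_days: float, z: float = DEFAULT_Z, species: str | None = None
) -> float:
    """GL in years from the Rspan formula AFR + z·(ALR − AFR)."""
    tag = f" for {species}" if species else ""
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must lie in [0, 1], got {z}")
    if alr_days < afr_days:
        raise ValueError(f"ALR ({alr_days} d) < AFR ({afr_days} d){tag}")
    return (afr_days + z * (alr_days - afr_days)) / DAYS_PER_YEAR


def life_table_gl(x, lx, mx) -> float:
    """GL in the units of ``x`` from a life table (age-weighted mean age of
    reproduction)."""
    x = np.asarray(x, float)
    lx = np.asarray(lx, float)
    mx = np.asarray(mx, float)
    if not (x.shape == lx.shape == mx.shape):
        raise ValueError("x, lx, mx must have equal lengths")
    if np.any(lx < 0) or np.any(lx > 1):
        raise ValueError("survivorship lx must lie in [0, 1]")
    if np.any(np.diff(lx) > 1e-12):
        raise ValueError("survivorship lx must be non-increasing")
    if np.any(mx < 0):
        raise ValueError("fecundity mx must be non-negative")
    denom = float(np.sum(lx * mx))
    if denom <= 0:
        raise ValueError("no reproduction: sum of lx*mx is zero")
    return float(np.sum(x * lx * mx) / denom)


def mortality_gl(adult_annual_mortality: float, afr_years: float) -> float:
    """GL in years as 1/(adult annual mortality) + AFR."""
    if not 0.0 < adult_annual_mortality <= 1.0:
        raise ValueError(f"adult mortality must lie in (0, 1], got {adult_annual_mortality}")
    return 1.0 / adult_annual_mortality + afr_years


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t comparison of two measurements over the same species."""

    n: int
    mean_diff: float
    ci95_halfwidth: float
    t_stat: float | None
    df: int
    p_value: float | None
    degenerate: bool = False


def paired_comparison(a, b) -> PairedComparison:
    """Paired t-test of a − b over complete pairs.

    Pairs with a missing member are dropped.  A zero-variance difference
    vector is flagged degenerate and no p-value is fabricated.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal lengths")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    n = int(d.size)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        return PairedComparison(n, mean, 0.0, None, df, None, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    hw = float(stats.t.ppf(0.975, df) * se)
    return PairedComparison(n, mean, hw, float(t), df, p)


def gl_table(compiled: pd.DataFrame, z: float = DEFAULT_Z) -> pd.DataFrame:
    """Per-species GLw and GLc (years) from a compiled life-history table.

    Species lacking an AFR get no GL at all; a missing wild or captive ALR
    leaves the corresponding GL missing.  A species whose ALR proxy falls
    below its AFR (possible with noisy sources) is left missing rather than
    forced through the formula.
    """
    rows = []
    for row in compiled.itertuples(index=False):
        glw = glc = np.nan
        afr = row.afr_days
        if afr is not None and not pd.isna(afr):
            for alr, slot in ((row.alr_wild_days, "w"), (row.alr_captive_days, "c")):
                if alr is None or pd.isna(alr) or alr < afr:
                    continue
                val = rspan_gl(float(afr), float(alr), z, species=row.species)
                if slot == "w":
                    glw = val
                else:
                    glc = val
        rows.append(
            {
                "species": row.species,
                "genus": row.genus,
                "family": row.family,
                "afr_days": afr,
                "alr_wild_days": row.alr_wild_days,
                "alr_captive_days": row.alr_captive_days,
                "mass_g": row.mass_g,
                "glw_years": glw,
                "glc_years": glc,
            }
        )
    return pd.DataFrame(rows)
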