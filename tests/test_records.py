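"""Compilation rules for multi-source life-history records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genlen.records import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    SourceRecord,
    canonical_name,
    compile_afr,
    compile_alr,
    compile_database,
    resolve_range,
)


def rec(parameter, value=None, unit="days", provenance="unknown", source="s1",
        vmin=None, vmax=None, species="Aepyceros melampus"):
    return SourceRecord(
        species=species, genus="Aepyceros", family="Bovidae",
        parameter=parameter, unit=unit, provenance=provenance, source_id=source,
        value=value, value_min=vmin, value_max=vmax,
    )


class TestResolveRange:
    @pytest.mark.parametrize(
        "vmin, vmax, rule, expected",
        [
            (6, 8, "central", 7),        # months-style midpoint
            (10, 12, "upper", 12),       # longevity upper bound
            (5, 5, "central", 5),        # degenerate range
            (5, 5, "upper", 5),
        ],
    )
    def test_rules(self, vmin, vmax, rule, expected):
        assert resolve_range(vmin, vmax, rule) == expected

    def test_inverted_range_rejected_with_context(self):
        with pytest.raises(ValueError, match="inverted"):
            resolve_range(8, 6, "central")
        with pytest.raises(ValueError, match="Aepyceros"):
            # the record wrapper names the offender
            from genlen.records import record_days
            r = SourceRecord(
                species="Aepyceros melampus", genus="Aepyceros", family="Bovidae",
                parameter="longevity", unit="years", value=10.0,
            )
            record_days(r.__class__(**{**r.__dict__, "value": None,
                                       "value_min": 8.0, "value_max": 6.0}), "upper")


class TestCompileAfr:
    def test_single_source_maturity_plus_gestation(self):
        assert compile_afr([rec("maturity_female", 540), rec("gestation", 180)]) == 720

    def test_direct_median_with_ceiling(self):
        records = [rec("afr", v, source=f"s{i}") for i, v in enumerate([700, 720.5, 800])]
        assert compile_afr(records) == 721  # ceil(median 720.5)

    def test_year_conversion_then_ceiling(self):
        records = [rec("afr", v, unit="years", source=f"s{i}") for i, v in enumerate([2.0, 2.0, 2.2])]
        assert compile_afr(records) == 731  # ceil(2.0 * 365.25)

    def test_direct_estimates_preferred_over_components(self):
        records = [rec("afr", 700), rec("maturity_female", 540, source="s2"),
                   rec("gestation", 180, source="s2")]
        assert compile_afr(records) == 700

    def test_pairing_within_source(self):
        # source s1 has both components; s2's lone maturity must not dilute it
        records = [rec("maturity_female", 500, source="s1"), rec("gestation", 200, source="s1"),
                   rec("maturity_female", 900, source="s2")]
        assert compile_afr(records) == 700

    def test_range_resolved_centrally(self):
        assert compile_afr([rec("afr", vmin=6, vmax=8, unit="months")]) == int(
            np.ceil(7 * DAYS_PER_MONTH)
        )

    def test_male_maturity_never_used_alone(self):
        assert compile_afr([rec("maturity_male", 400)]) is None

    def test_no_usable_records(self):
        assert compile_afr([rec("gestation", 180)]) is None

    @given(days=st.integers(30, 20000))
    @settings(max_examples=60, deadline=None)
    def test_unit_round_trip_within_one_day(self, days):
        """A value expressed in months or years compiles to the same day
        count as its day-denominated equivalent."""
        base = compile_afr([rec("afr", days)])
        via_years = compile_afr([rec("afr", days / DAYS_PER_YEAR, unit="years")])
        via_months = compile_afr([rec("afr", days / DAYS_PER_MONTH, unit="months")])
        assert abs(via_years - base) <= 1 and abs(via_months - base) <= 1


class TestCompileAlr:
    def test_wild_range_upper_bound(self):
        w, c = compile_alr([rec("longevity", vmin=10, vmax=12, unit="years", provenance="wild")])
        assert w == pytest.approx(12 * DAYS_PER_YEAR)
        assert c is None

    def test_unknown_provenance_pooled_into_captive(self):
        w, c = compile_alr([rec("longevity", 15, unit="years", provenance="unknown")])
        assert w is None
        assert c == pytest.approx(15 * DAYS_PER_YEAR)

    def test_max_per_provenance_class(self):
        records = [
            rec("longevity", 14, unit="years", provenance="wild"),
            rec("longevity", 20, unit="years", provenance="captive", source="s2"),
            rec("longevity", 18, unit="years", provenance="unknown", source="s3"),
        ]
        w, c = compile_alr(records)
        assert w == pytest.approx(14 * DAYS_PER_YEAR)
        assert c == pytest.approx(20 * DAYS_PER_YEAR)

    def test_direct_alr_preferred_over_longevity_proxy(self):
        records = [
            rec("alr", 10, unit="years", provenance="wild"),
            rec("longevity", 14, unit="years", provenance="wild", source="s2"),
        ]
        w, _ = compile_alr(records)
        assert w == pytest.approx(10 * DAYS_PER_YEAR)

    def test_duplicate_maximum_is_idempotent(self):
        records = [rec("longevity", 14, unit="years", provenance="wild"),
                   rec("longevity", 12, unit="years", provenance="wild", source="s2")]
        w1, _ = compile_alr(records)
        w2, _ = compile_alr(records + [rec("longevity", 14, unit="years",
                                           provenance="wild", source="s3")])
        assert w1 == w2

    def test_captive_record_never_changes_wild_value(self):
        records = [rec("longevity", 14, unit="years", provenance="wild")]
        w1, _ = compile_alr(records)
        w2, _ = compile_alr(records + [rec("longevity", 30, unit="years",
                                           provenance="captive", source="s9")])
        assert w1 == w2


class TestCompileDatabase:
    TAXONOMY = pd.DataFrame(
        {"species": ["Aepyceros melampus", "Oryx gazella"],
         "genus": ["Aepyceros", "Oryx"],
         "family": ["Bovidae", "Bovidae"]}
    )

    def _frame(self, records):
        return pd.DataFrame([r.__dict__ for r in records])

    def test_empty_table(self):
        out = compile_database(pd.DataFrame(), self.TAXONOMY)
        assert out.empty

    def test_two_full_species(self):
        records = []
        for sp in ("Aepyceros melampus", "Oryx gazella"):
            records += [
                rec("afr", 700, species=sp),
                rec("longevity", 12, unit="years", provenance="wild", species=sp),
                rec("longevity", 18, unit="years", provenance="captive", species=sp),
                rec("mass", 50, unit="kg", species=sp),
            ]
        out = compile_database(self._frame(records), self.TAXONOMY)
        assert len(out) == 2
        assert out[["afr_days", "alr_wild_days", "alr_captive_days", "mass_g"]].notna().all().all()
        assert (out["mass_g"] == 50000).all()

    def test_name_normalisation(self):
        records = [rec("afr", 700, species="aepyceros_melampus")]
        out = compile_database(self._frame(records), self.TAXONOMY)
        assert list(out["species"]) == ["Aepyceros melampus"]

    def test_conflicting_taxonomy_rejected(self):
        bad = pd.concat([self.TAXONOMY,
                         pd.DataFrame({"species": ["Oryx gazella"], "genus": ["Wrong"],
                                       "family": ["Bovidae"]})])
        with pytest.raises(ValueError, match="conflicting"):
            compile_database(self._frame([rec("afr", 700)]), bad)

    def test_unresolved_names_reported(self):
        records = [rec("afr", 700, species="Nope nope")]
        with pytest.warns(UserWarning, match="Nope nope"):
            out = compile_database(self._frame(records), self.TAXONOMY)
        assert out.empty

    def test_synthetic_world_missing_mask(self, paper_scale_world):
        w = paper_scale_world
        out = compile_database(w.records, w.taxonomy)
        assert len(out) == 86
        assert int(out["alr_wild_days"].isna().sum()) == 32
        assert (out.loc[out["afr_days"].notna(), "n_sources_afr"] >= 1).all()


def test_canonical_name():
    assert canonical_name(" Oryx_ gazella ") == "Oryx gazella"
    assert canonical_name("ORYX GAZELLA") == "Oryx gazella"
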