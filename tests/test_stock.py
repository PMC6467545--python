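"""Record cleaning, SAP-like parameterisation, retrofit and emission configs."""

import numpy as np
import pandas as pd
import pytest

from stockiaq.stock import (RetrofitRule, canonical_archetype, deduplicate,
                            emission_config, emission_rate_columns,
                            parameterise, retrofit)


def make_records(**overrides):
    base = dict(
        building_ref=["B1", "B2"], inspection_date=pd.to_datetime(["2015-06-01",
                                                                   "2016-06-01"]),
        postcode=["PC1", "PC2"], archetype=["semi", "detached"],
        wall_type=["cavity", "solid"], terrain=["urban", "rural"],
        main_fuel=["gas", "electric"], age_band=["1930_1995", "post1995"],
        floor_area=[90.0, 120.0], ceiling_height=[2.4, 2.5],
        glazing_ratio=[0.2, 0.25], permeability_q50=[10.0, 8.0],
        wall_U=[1.2, 0.5], roof_U=[0.6, 0.2], window_U=[3.1, 2.0],
        mains_gas=[True, False],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestDeduplicate:
    def test_latest_inspection_kept(self):
        df = make_records(building_ref=["B1", "B1"],
                          inspection_date=pd.to_datetime(["2015-01-01",
                                                          "2018-01-01"]))
        out = deduplicate(df)
        assert len(out) == 1
        assert out["inspection_date"].iloc[0] == pd.Timestamp("2018-01-01")

    def test_missing_required_field_dropped(self):
        df = make_records(floor_area=[np.nan, 120.0])
        out, log = deduplicate(df, return_log=True)
        assert list(out["building_ref"]) == ["B2"]
        assert log["removed_missing"] == 1

    def test_unique_input_unchanged(self):
        df = make_records()
        out = deduplicate(df)
        assert len(out) == 2

    def test_order_independence(self):
        df = make_records(building_ref=["B1", "B1"],
                          inspection_date=pd.to_datetime(["2015-01-01",
                                                          "2018-01-01"]))
        a = deduplicate(df)
        b = deduplicate(df.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)


class TestParameterise:
    def test_measured_q50_passed_through(self):
        out = parameterise(make_records())
        np.testing.assert_allclose(out["permeability_q50"], [10.0, 8.0])

    def test_ach_q50_identity(self):
        """ach = q50 · envelope / volume / 20, invertible both ways."""
        out = parameterise(make_records())
        expected = (out["permeability_q50"] * out["envelope_area"]
                    / out["volume"] / 20.0)
        np.testing.assert_allclose(out["ach_estimate"], expected)
        # inverse: ach 0.6, A=300, V=250 → q50 = 0.6·20·250/300 = 10
        assert 0.6 * 20 * 250 / 300 == pytest.approx(10.0)

    def test_missing_q50_filled_by_age_band_rule(self):
        df = make_records(permeability_q50=[np.nan, np.nan])
        out = parameterise(df)
        # row 0: 1930–1995 base 0.7 h⁻¹, gas (no flue adder)
        expected = 0.7 * 20.0 * out["volume"].iloc[0] / out["envelope_area"].iloc[0]
        assert out["permeability_q50"].iloc[0] == pytest.approx(expected)

    def test_display_archetype_names_mapped(self):
        assert canonical_archetype("Converted Flats") == "converted_flat"
        assert canonical_archetype("High rise Flats") == "high_rise_flat"
        with pytest.raises(ValueError, match="castle"):
            canonical_archetype("castle")


class TestRetrofit:
    def test_never_loosens_fabric(self):
        cur = parameterise(make_records())
        post = retrofit(cur)
        assert (post["permeability_q50"] <= cur["permeability_q50"] + 1e-12).all()
        assert (post["wall_U"] <= cur["wall_U"]).all()
        assert (post["ach_estimate"] >= RetrofitRule().ach_floor - 1e-12).all()

    def test_idempotent(self):
        cur = parameterise(make_records())
        once = retrofit(cur)
        twice = retrofit(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_already_minimal_fabric_unchanged(self):
        cur = parameterise(make_records())
        rules = RetrofitRule()
        post = retrofit(cur, rules)
        # row 1 (post-1995, already at roof/window minima-ish levels)
        assert post["roof_U"].iloc[1] <= rules.roof_u_min + 1e-12


class TestEmissionConfig:
    def test_gas_mains_heating(self):
        rec = make_records().iloc[0]
        sources = emission_config(rec, smoking=False)
        heating = [s for s in sources if s.trigger == "thermostat"]
        assert len(heating) == 1
        assert heating[0].rate == pytest.approx(15.9)
        assert heating[0].vented_fraction == pytest.approx(0.9)
        # effective emission into the living room: 10% of 15.9
        assert heating[0].rate * (1 - heating[0].vented_fraction) == pytest.approx(1.59)

    def test_electric_stove_without_mains_gas(self):
        rec = make_records().iloc[1]  # electric, no mains gas
        sources = emission_config(rec, smoking=False)
        assert all(s.zone != "kitchen" for s in sources)
        rates = emission_rate_columns(make_records())
        assert rates["cooking_rate"].iloc[1] == 0.0
        assert rates["cooking_rate"].iloc[0] == pytest.approx(29.0)

    def test_smoking_flag_adds_living_source(self):
        rec = make_records().iloc[0]
        with_s = emission_config(rec, smoking=True)
        without = emission_config(rec, smoking=False)
        extra = [s for s in with_s if s.rate == 7.2]
        assert len(extra) == 1 and extra[0].zone == "living"
        assert len(with_s) == len(without) + 1

    def test_unknown_fuel_rejected(self):
        rec = make_records().iloc[0].copy()
        rec["main_fuel"] = "plutonium"
        with pytest.raises(ValueError, match="plutonium"):
            emission_config(rec, smoking=False)

    @pytest.mark.parametrize("fuel,rate", [
        ("Gas (mains)", 15.9), ("LPG/Propane", 8.7),
        ("Heating oil", 1.7), ("solid", 2889.0)])
    def test_fuel_rate_table(self, fuel, rate):
        rec = make_records().iloc[0].copy()
        rec["main_fuel"] = fuel
        heating = [s for s in emission_config(rec, smoking=False)
                   if s.trigger == "thermostat"]
        assert heating[0].rate == pytest.approx(rate)
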