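"""Exposure assembly: joins, weighting, summaries, spatial correlation."""

import numpy as np
import pandas as pd
import pytest

from stockiaq.assembly import (indoor_from_io, join_outdoor, smoking_weighted,
                               spatial_correlation, summarise, total_co,
                               weighted_quantile)


class TestPointwiseOps:
    def test_indoor_from_io(self):
        assert indoor_from_io(0.5, 10.0) == pytest.approx(5.0)
        assert indoor_from_io(0.9, 0.0) == 0.0
        with pytest.raises(ValueError):
            indoor_from_io(-0.1, 10.0)

    def test_total_co(self):
        assert total_co(3.0, 0.7) == pytest.approx(3.7)
        assert total_co(0.0, 1.3) == pytest.approx(1.3)
        s = total_co(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        assert np.all(s >= [1.0, 2.0]) and np.all(s >= 0.5)  # sum ≥ each part

    def test_smoking_weighted(self):
        assert smoking_weighted(5.0, 3.0, 0.0) == 3.0
        assert smoking_weighted(5.0, 3.0, 1.0) == 5.0
        assert smoking_weighted(1.0, 0.0, 0.2) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            smoking_weighted(1.0, 0.0, 1.2)

    def test_median_composition_is_not_product_of_medians(self):
        """Medians do not compose: median(io·out) ≠ median(io)·median(out)."""
        rng = np.random.default_rng(0)
        io = rng.uniform(0.3, 0.9, 1000)
        out = rng.lognormal(2.3, 0.3, 1000)
        indoor = indoor_from_io(io, out)
        assert np.median(indoor) != pytest.approx(
            np.median(io) * np.median(out), rel=1e-3)


class TestSummarise:
    def test_interpolated_percentiles(self):
        s = summarise(np.arange(1.0, 101.0))
        assert s.median == pytest.approx(50.5)
        assert s.p1 == pytest.approx(1.99)
        assert s.p99 == pytest.approx(99.01)

    def test_single_value(self):
        s = summarise([4.2])
        assert s.median == s.p1 == s.p99 == 4.2

    def test_exceedance_fraction(self):
        s = summarise([7.0, 9.0], threshold=8.1)
        assert s.exceedance == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarise([])

    def test_equal_weights_reduce_to_numpy(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=200)
        for q in (0.01, 0.25, 0.5, 0.99):
            assert weighted_quantile(v, q, np.full(200, 2.5)) == pytest.approx(
                np.percentile(v, 100 * q))

    def test_weighted_median_shifts_with_weight(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.05, 0.05, 0.9])
        assert weighted_quantile(v, 0.5, w) > 2.0

    def test_p1_median_p99_ordered(self):
        rng = np.random.default_rng(2)
        s = summarise(rng.lognormal(0, 1, 500), rng.uniform(0.1, 1, 500))
        assert s.p1 <= s.median <= s.p99


class TestJoinOutdoor:
    def geo(self):
        return pd.DataFrame({
            "postcode": ["PC1", "PC2", "PC3"],
            "grid_row": [0, 0, 1], "grid_col": [0, 0, 0],
            "local_authority": ["LA1", "LA1", "LA2"],
            "smoking_prevalence": [0.2, 0.2, 0.1]})

    def grid(self):
        return pd.DataFrame({"grid_row": [0, 1], "grid_col": [0, 0],
                             "pm25_annual_mean": [10.0, 12.0],
                             "no2_annual_mean": [20.0, 30.0],
                             "co_max_8h": [0.5, 0.9]})

    def stock(self, postcodes):
        return pd.DataFrame({"building_ref": [f"B{i}" for i in range(len(postcodes))],
                             "postcode": postcodes})

    def test_single_cell_grid_shares_values(self):
        grid = self.grid().iloc[:1]
        geo = self.geo().iloc[:2]
        out = join_outdoor(self.stock(["PC1", "PC2"]), geo, grid)
        assert (out["pm25_annual_mean"] == 10.0).all()

    def test_unknown_postcode_dropped_and_logged(self):
        out, log = join_outdoor(self.stock(["PC1", "PC9"]), self.geo(),
                                self.grid(), return_log=True)
        assert len(out) == 1 and log["dropped_unmatched"] == 1

    def test_idempotent(self):
        once = join_outdoor(self.stock(["PC1", "PC3"]), self.geo(), self.grid())
        twice = join_outdoor(once, self.geo(), self.grid())
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            join_outdoor(self.stock(["PC1"]), self.geo(), self.grid().iloc[:0])


class TestSpatialCorrelation:
    def table(self, indoor):
        return pd.DataFrame({
            "postcode": ["PC1", "PC2", "PC3"],
            "grid_row": [0, 0, 1], "grid_col": [0, 0, 0],
            "indoor": indoor, "outdoor": [20.0, 20.0, 30.0]})

    def test_merges_shared_cells(self):
        rho, n_units = spatial_correlation(self.table([8.0, 10.0, 15.0]),
                                           "indoor", "outdoor")
        assert n_units == 2  # PC1+PC2 share a cell

    def test_proportional_indoor_gives_unit_correlation(self):
        rho, _ = spatial_correlation(self.table([10.0, 10.0, 15.0]),
                                     "indoor", "outdoor")
        assert rho == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        tab = self.table([5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="undefined"):
            spatial_correlation(tab, "indoor", "outdoor")


def test_pipeline_smoke(tmp_path):
    """Reduced-size end-to-end run emits all tables and ordered summaries."""
    from stockiaq.assembly import run_pipeline
    res = run_pipeline({"seed": 5, "n_dwellings": 400, "n_design": 150,
                        "surrogate_n_hours": 1200,
                        "surrogate_hyperparams": {"hidden_layer_sizes": (32,),
                                                  "max_iter": 400}},
                       out_dir=tmp_path)
    assert (tmp_path / "exposure.csv").exists()
    assert (tmp_path / "summary.json").exists()
    summary = res["summary"]
    assert summary["no2"]["io_median"] < summary["pm25"]["io_median"]
    assert len(res["exposure"]) == res["logs"]["join_outdoor"]["output"]
    for key in ("co_kitchen_current", "co_living_retrofit"):
        assert summary[key]["p1"] <= summary[key]["median"] <= summary[key]["p99"]
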