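"""Regional statistics, gyre selection and anomaly comparisons."""

import numpy as np
import pandas as pd
import pytest

from pomstoich.models import MHConfig
from pomstoich.regional import (
    GYRE_LONGITUDE_BLOCKS,
    holm_adjust,
    detect_sign_flips,
    filter_surface,
    gyre_anomalies,
    regional_anova,
    regional_summary,
    select_gyres,
    slope_sign_comparison,
    stars,
)


class TestRegionalSummary:
    def test_single_region_identical_stations(self):
        df = pd.DataFrame({"region": ["SIO"] * 5, "cp": [150.0] * 5})
        out = regional_summary(df, ["cp"])
        row = out.iloc[0]
        assert row["mean"] == row["median"] == 150.0
        assert row["sd"] == 0.0 and row["n"] == 5

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "region": ["A"] * 10 + ["B"] * 20 + ["C"] * 5,
                "cp": rng.normal(130, 10, 35),
            }
        )
        out = regional_summary(df, ["cp"])
        assert out["n"].sum() == 35


class TestStars:
    @pytest.mark.parametrize(
        "p,s", [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.2, "")]
    )
    def test_encoding(self, p, s):
        assert stars(p) == s


class TestHolmAdjustment:
    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            raw = rng.uniform(0, 1, rng.integers(2, 8))
            np.testing.assert_allclose(
                holm_adjust(raw), multipletests(raw, method="holm")[1]
            )


class TestRegionalAnova:
    def test_identical_group_distributions(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = pd.DataFrame(
            {"region": ["A"] * 5 + ["B"] * 5 + ["C"] * 5, "cp": vals * 3}
        )
        res = regional_anova(df, "cp")
        assert res["p_value"] == pytest.approx(1.0)
        assert res["stars"] == ""
        assert (res["pairwise"]["stars"] == "").all()

    def test_widely_separated_groups(self, rng):
        df = pd.DataFrame(
            {
                "region": ["A"] * 30 + ["B"] * 30 + ["C"] * 30,
                "cp": np.concatenate(
                    [
                        rng.normal(0, 1, 30),
                        rng.normal(10, 1, 30),
                        rng.normal(20, 1, 30),
                    ]
                ),
            }
        )
        res = regional_anova(df, "cp")
        assert res["p_value"] < 0.001
        assert (res["pairwise"]["stars"] == "***").all()

    def test_small_region_excluded(self, rng):
        df = pd.DataFrame(
            {
                "region": ["A"] * 10 + ["B"] * 10 + ["C"],
                "cp": np.r_[rng.normal(0, 1, 20), 5.0],
            }
        )
        res = regional_anova(df, "cp")
        regions = set(res["pairwise"]["region_a"]) | set(res["pairwise"]["region_b"])
        assert "C" not in regions

    def test_tukey_mode(self, rng):
        df = pd.DataFrame(
            {
                "region": ["A"] * 15 + ["B"] * 15,
                "cp": np.r_[rng.normal(0, 1, 15), rng.normal(5, 1, 15)],
            }
        )
        res = regional_anova(df, "cp", method="tukey")
        assert res["pairwise"]["p_value"].iloc[0] < 0.001

    def test_too_few_regions_errors(self):
        df = pd.DataFrame({"region": ["A"] * 5, "cp": np.arange(5.0)})
        with pytest.raises(ValueError):
            regional_anova(df, "cp")


class TestGyreSelection:
    def _grid(self):
        return pd.DataFrame(
            {
                "lat": [30.0, 30.0, -25.0, -25.0, -25.0, 30.0],
                "lon": [-40.0, -40.0, 80.0, -170.0, 170.0, -170.0],
                "znut_m": [200.0, 140.0, 180.0, 200.0, 200.0, 200.0],
            }
        )

    def test_shallow_nutricline_excluded(self):
        masks = select_gyres(self._grid())
        assert not masks["North Atlantic"][1]

    def test_deep_atlantic_cell_selected(self):
        masks = select_gyres(self._grid())
        assert masks["North Atlantic"][0]
        assert masks["South Indian"][2]

    def test_antimeridian_spanning_south_pacific(self):
        masks = select_gyres(self._grid())
        # 170 W and 170 E both fall inside the 150 E -> 60 W block
        assert masks["South Pacific"][3] and masks["South Pacific"][4]

    def test_hemisphere_split_disambiguates_pacific(self):
        masks = select_gyres(self._grid())
        assert masks["North Pacific"][5] and not masks["South Pacific"][5]
        assert masks["South Pacific"][3] and not masks["North Pacific"][3]

    def test_selection_order_independent(self):
        grid = self._grid()
        shuffled = grid.sample(frac=1.0, random_state=1)
        m1 = select_gyres(grid)
        m2 = select_gyres(shuffled)
        for name in GYRE_LONGITUDE_BLOCKS:
            assert (
                sorted(grid.index[m1[name]])
                == sorted(shuffled.index[m2[name]])
            )


class TestGyreAnomalies:
    def test_identical_gyres_zero_anomaly(self):
        df = pd.DataFrame(
            {"gyre": list("ABCDE") * 3, "poc": [2.0] * 15}
        )
        out = gyre_anomalies(df, ["poc"])
        np.testing.assert_allclose(out["anomaly"], 0.0)

    def test_one_shifted_gyre(self):
        df = pd.DataFrame(
            {
                "gyre": list("ABCDE"),
                "poc": [10.0, 10.0, 10.0, 10.0, 20.0],
            }
        )
        out = gyre_anomalies(df, ["poc"]).set_index("gyre")
        assert out.loc["E", "anomaly"] == pytest.approx(8.0)
        assert out.loc["A", "anomaly"] == pytest.approx(-2.0)

    def test_anomalies_sum_to_zero_when_complete(self, rng):
        df = pd.DataFrame(
            {"gyre": np.repeat(list("ABCDE"), 10), "poc": rng.normal(2, 0.5, 50)}
        )
        out = gyre_anomalies(df, ["poc"])
        assert out["anomaly"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_missing_gyre_variable_flagged(self):
        df = pd.DataFrame(
            {
                "gyre": list("ABCDE"),
                "pop": [1.0, 2.0, np.nan, 4.0, 5.0],
            }
        )
        out = gyre_anomalies(df, ["pop"]).set_index("gyre")
        assert out.loc["C", "missing"]
        assert out["cross_gyre_mean"].iloc[0] == pytest.approx(3.0)

    def test_mean_mode(self):
        df = pd.DataFrame({"gyre": ["A", "A", "B"], "poc": [1.0, 3.0, 5.0]})
        out = gyre_anomalies(df, ["poc"], center="mean").set_index("gyre")
        assert out.loc["A", "mean"] == pytest.approx(2.0)


class TestSurfaceFilter:
    def test_top_30m_only(self):
        df = pd.DataFrame({"depth_m": [5.0, 30.0, 31.0, 100.0]})
        assert len(filter_surface(df)) == 2


class TestSlopeSignComparison:
    def test_flip_detected_and_repeatability(self, rng):
        sst = rng.uniform(15, 30, 80)
        io_df = pd.DataFrame({"sst": sst, "cp": 250 - 4 * sst + rng.normal(0, 5, 80)})
        gl_df = pd.DataFrame({"sst": sst, "cp": 80 + 3 * sst + rng.normal(0, 5, 80)})
        cfg = MHConfig(steps=3000, seed=5)
        table = slope_sign_comparison(
            {"indian_ocean": io_df, "global": gl_df}, ["cp"], ["sst"], config=cfg
        )
        signs = dict(zip(table["dataset"], table["sign"]))
        assert signs == {"indian_ocean": -1, "global": 1}
        assert table["excludes_zero"].all()
        flips = detect_sign_flips(table)
        assert len(flips) == 1

        # the same dataset twice gives identical signs
        t2 = slope_sign_comparison(
            {"a": io_df, "b": io_df}, ["cp"], ["sst"], config=cfg
        )
        assert t2["sign"].nunique() == 1

    def test_zero_slope_interval_covers_zero(self, rng):
        x = rng.uniform(10, 20, 100)
        df = pd.DataFrame({"x": x, "y": 5 + rng.normal(0, 1, 100)})
        table = slope_sign_comparison({"d": df}, ["y"], ["x"],
                                      config=MHConfig(steps=4000, seed=6))
        assert not table["excludes_zero"].iloc[0]
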