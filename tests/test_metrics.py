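"""Space-use indices, control variables, and analysis-table assembly."""

import numpy as np
import pandas as pd
import pytest

from feederdef import metrics
from feederdef.metrics import (JoinError, assemble_analysis_table,
                               feeder_rank, grid_usage,
                               seasonal_concentration,
                               spatial_concentration, spatial_stability)
from feederdef.simdata import make_treatment_schedule

from conftest import D1, D2, D3, make_visits


def conc_at(visits, tag, date, feeder):
    df = spatial_concentration(visits)
    row = df[(df.tag_id == tag) & (df.date == date)
             & (df.feeder_id == feeder)]
    return float(row["spatial_concentration"].iloc[0])


class TestConcentration:
    def test_examples(self):
        v = make_visits([("i", "A", D1, 9), ("i", "B", D1, 1)])
        assert conc_at(v, "i", D1, "A") == pytest.approx(0.9)
        v = make_visits([("i", "A", D1, 1)])
        assert conc_at(v, "i", D1, "A") == 1.0
        v = make_visits([("i", "A", D1, 2), ("i", "B", D1, 2)])
        assert conc_at(v, "i", D1, "A") == 0.5
        assert conc_at(v, "i", D1, "B") == 0.5

    def test_sums_to_one_per_bird_day(self, small_stream):
        from feederdef.sessionize import detections_to_visits
        df = spatial_concentration(detections_to_visits(small_stream))
        sums = df.groupby(["tag_id", "date"])["spatial_concentration"].sum()
        assert np.allclose(sums, 1.0)


class TestSeasonalConcentration:
    def test_shares(self):
        v = make_visits([("i", "A", D1, 20), ("i", "A", D2, 10),
                         ("i", "B", D2, 10)])
        s = seasonal_concentration(v).set_index("feeder_id")
        assert s.loc["A", "seasonal_concentration"] == pytest.approx(0.75)
        assert s.loc["B", "seasonal_concentration"] == pytest.approx(0.25)
        assert s["seasonal_concentration"].sum() == pytest.approx(1.0)


class TestStability:
    def test_daily_mimics_seasonal_gives_one(self):
        v = make_visits([("i", "A", d, 2) for d in (D1, D2, D3)]
                        + [("i", "B", d, 1) for d in (D1, D2, D3)])
        out = spatial_stability(v)
        assert out["stability"].iloc[0] == pytest.approx(1.0)
        assert bool(out["defined"].iloc[0])

    def test_single_feeder_is_degenerate(self):
        v = make_visits([("i", "A", d, 3) for d in (D1, D2, D3)])
        out = spatial_stability(v)
        assert not bool(out["defined"].iloc[0])
        assert np.isnan(out["stability"].iloc[0])

    def test_under_three_days_not_a_focal(self):
        v = make_visits([("i", "A", D1, 3), ("i", "B", D2, 3)])
        assert spatial_stability(v).empty

    def test_three_day_toy_against_direct_pearson(self):
        # daily shares (1,0), (0,1), (.5,.5) over feeders (A,B) with
        # unequal seasonal shares: A = 4/6, B = 2/6
        v = make_visits([("i", "A", D1, 3), ("i", "B", D2, 1),
                         ("i", "A", D3, 1), ("i", "B", D3, 1)])
        out = spatial_stability(v)
        x = np.array([1, 0, 0, 1, 0.5, 0.5])      # daily, (day, feeder)
        y = np.array([4 / 6, 2 / 6] * 3)          # seasonal, matched
        expected = np.corrcoef(x, y)[0, 1]
        assert out["stability"].iloc[0] == pytest.approx(expected)
        assert out["n_days_followed"].iloc[0] == 3


class TestGridUsage:
    def test_mean_over_active_birds(self):
        v = make_visits([("i", "A", D1, 10), ("j", "B", D1, 20)])
        out = grid_usage(v).set_index("date")
        assert out.loc[D1, "grid_usage"] == pytest.approx(15.0)

    def test_single_bird(self):
        v = make_visits([("i", "A", D1, 7)])
        assert grid_usage(v)["grid_usage"].iloc[0] == pytest.approx(7.0)

    def test_inactive_days_absent(self):
        v = make_visits([("i", "A", D1, 5), ("i", "A", D3, 5)])
        assert set(grid_usage(v)["date"]) == {D1, D3}


class TestFeederRank:
    def test_rank_by_distinct_individuals(self):
        v = make_visits([(t, "F1", D1, 1) for t in "abcde"]
                        + [(t, "F2", D1, 9) for t in "abc"]
                        + [("a", "F3", D1, 30)])
        out = feeder_rank(v, ["F1", "F2", "F3"]).set_index("feeder_id")
        assert out["feeder_rank"].tolist() == [1.0, 2.0, 3.0]

    def test_tie_average(self):
        v = make_visits([(t, "F1", D1, 1) for t in "abcde"]
                        + [(t, "F2", D1, 1) for t in "abc"]
                        + [(t, "F3", D1, 1) for t in "xyz"])
        out = feeder_rank(v, ["F1", "F2", "F3"]).set_index("feeder_id")
        assert out["feeder_rank"].tolist() == [1.0, 2.5, 2.5]

    def test_unvisited_ranks_last_and_ranks_are_a_permutation(self):
        v = make_visits([("a", "F1", D1, 1)])
        out = feeder_rank(v, ["F1", "F2", "F3"]).set_index("feeder_id")
        assert out.loc["F1", "feeder_rank"] == 1.0
        assert out.loc[["F2", "F3"], "feeder_rank"].tolist() == [2.5, 2.5]
        assert out["feeder_rank"].sum() == pytest.approx(6.0)  # 1+2+3


@pytest.fixture()
def feeders_meta(grid):
    return grid


@pytest.fixture()
def sched():
    return make_treatment_schedule(2008)


class TestAnalysisTable:
    def base_visits(self):
        # three adult males at feeder F01 on D1; focal histories span
        # 3+ days with two feeders so stability is defined
        rows = []
        for tag in ("i", "j", "k"):
            rows += [(tag, "F01", D1, {"i": 10, "j": 5, "k": 2}[tag])]
            rows += [(tag, "F01", D2, 3), (tag, "F02", D2, 1),
                     (tag, "F01", D3, 2), (tag, "F02", D3, 2)]
        return make_visits(rows)

    def test_nvc_sums_other_individuals(self, individuals, feeders_meta,
                                        sched):
        table, _ = assemble_analysis_table(self.base_visits(), individuals,
                                           feeders_meta, sched)
        row = table[(table.tag_id == "i") & (table.feeder_id == "F01")
                    & (table.date == D1)]
        assert row["nvc"].iloc[0] == 7
        assert row["n_competitors"].iloc[0] == 2
        assert row["log_nvc"].iloc[0] == pytest.approx(np.log(7))

    def test_nvc_symmetry_on_two_bird_feeder_days(self, individuals,
                                                  feeders_meta, sched):
        v = self.base_visits()
        v = v[v.tag_id != "k"]
        table, _ = assemble_analysis_table(v, individuals, feeders_meta,
                                           sched)
        d2 = table[(table.date == D2) & (table.feeder_id == "F01")]
        nvc = d2.set_index("tag_id")["nvc"]
        assert nvc["i"] == 3 and nvc["j"] == 3

    def test_focal_only_feeder_days_dropped(self, individuals,
                                            feeders_meta, sched):
        v = self.base_visits()
        v = pd.concat([v, make_visits([("i", "F03", D1, 4)])])
        table, dropped = assemble_analysis_table(v, individuals,
                                                 feeders_meta, sched)
        assert table[(table.feeder_id == "F03")].empty
        assert dropped["no_competitor_visits"] >= 1
        assert (table["nvc"] >= 1).all()
        assert (table["n_competitors"] >= 1).all()

    def test_juvenile_visits_excluded_from_nvc(self, individuals,
                                               feeders_meta, sched):
        v = pd.concat([self.base_visits(),
                       make_visits([("juv", "F01", D1, 50)])])
        table, _ = assemble_analysis_table(v, individuals, feeders_meta,
                                           sched)
        row = table[(table.tag_id == "i") & (table.date == D1)]
        assert row["nvc"].iloc[0] == 7  # unchanged by the juvenile

    def test_other_sex_not_counted_for_mm(self, individuals, feeders_meta,
                                          sched):
        v = pd.concat([self.base_visits(),
                       make_visits([("f", "F01", D1, 50)])])
        table, _ = assemble_analysis_table(v, individuals, feeders_meta,
                                           sched, focal_sex="M",
                                           competitor_sex="M")
        row = table[(table.tag_id == "i") & (table.date == D1)]
        assert row["nvc"].iloc[0] == 7

    def test_row_accounting_reconciles(self, individuals, feeders_meta,
                                       sched):
        table, dropped = assemble_analysis_table(self.base_visits(),
                                                 individuals, feeders_meta,
                                                 sched)
        assert dropped["candidate_rows"] == (
            len(table) + dropped["under_min_days"]
            + dropped["undefined_stability"]
            + dropped["no_competitor_visits"])

    def test_covariates_joined(self, individuals, feeders_meta, sched):
        table, _ = assemble_analysis_table(self.base_visits(), individuals,
                                           feeders_meta, sched)
        assert (table["sucrose"] == "low").all()  # 2008: no treatment
        assert table["openness"].isin(["open", "closed"]).all()
        assert table["lateral_visibility_m"].notna().all()
        assert (table["year"] == 2008).all()
        assert table["spatial_stability"].notna().all()

    def test_unknown_tag_raises(self, individuals, feeders_meta, sched):
        v = pd.concat([self.base_visits(),
                       make_visits([("ghost", "F01", D1, 1)])])
        with pytest.raises(JoinError, match="ghost"):
            assemble_analysis_table(v, individuals, feeders_meta, sched)
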