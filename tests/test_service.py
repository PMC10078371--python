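import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pollinet.networks import NetworkSeries
from pollinet.records import TaxonEntry, TaxonomyMap
from pollinet.service import (
    activity_periods,
    annual_service,
    community_total,
    estimate_service,
    estimate_transport,
    fit_line,
    service_vs_activity,
    svd_table,
)

from conftest import make_net


def _svd_obs(rows):
    return pd.DataFrame(rows, columns=["genus", "family", "grains", "is_control"])


@pytest.fixture
def svd_tab():
    rows = [("Aedes", "Culicidae", g, False) for g in (40, 50, 60)]
    rows += [("Rhamphomyia", "Empididae", g, False) for g in (10, 20, 30)]
    rows += [("", "Empididae", 40, False)]
    rows += [("", "", g, True) for g in (0, 0, 2, 2, 3, 1, 9, 4, 150)]
    return svd_table(_svd_obs(rows))


class TestSvdTable:
    def test_genus_means(self, svd_tab):
        g = svd_tab.genus.set_index("genus")
        assert g.loc["Aedes", "mean"] == 50.0
        assert g.loc["Rhamphomyia", "mean"] == 20.0

    def test_family_mean_pools_genus_resolved_rows(self, svd_tab):
        f = svd_tab.family.set_index("family")
        # Empididae: genus rows 10,20,30 plus family-only row 40
        assert f.loc["Empididae", "mean"] == 25.0
        assert f.loc["Empididae", "n"] == 4

    def test_two_equal_n_genera_average_in_family(self):
        rows = [("A", "Fam", 10, False), ("B", "Fam", 30, False)]
        tab = svd_table(_svd_obs(rows))
        assert tab.family.set_index("family").loc["Fam", "mean"] == 20.0

    def test_control_summary_median(self, svd_tab):
        assert svd_tab.control["median"] == 2.0
        assert svd_tab.control["n"] == 9
        assert svd_tab.control["mean"] == pytest.approx(np.mean([0, 0, 2, 2, 3, 1, 9, 4, 150]))

    def test_no_trials_errors(self):
        with pytest.raises(ValueError):
            svd_table(_svd_obs([("", "", 2, True)]))


def _taxmap():
    return TaxonomyMap(
        {
            "Aedes impiger": TaxonEntry("Aedes impiger", "species", "Culicidae"),
            "Rhamphomyia nigrita": TaxonEntry("Rhamphomyia nigrita", "species", "Empididae"),
            "Drymeia segnis": TaxonEntry("Drymeia segnis", "species", "Muscidae"),
            "Dryas": TaxonEntry("Dryas", "genus", "Rosaceae"),
        }
    )


def _series():
    """3-taxon, 2-week worked fixture around the focal plant."""
    net1 = make_net([[10, 2, 1]])
    net1.plants = ["Dryas"]
    net1.insects = ["Aedes impiger", "Rhamphomyia nigrita", "Drymeia segnis"]
    net2 = make_net([[4, 3]])
    net2.plants = ["Dryas"]
    net2.insects = ["Aedes impiger", "Rhamphomyia nigrita"]
    return NetworkSeries({(2016, 0): net1, (2016, 1): net2})


class TestEstimateService:
    def test_visits_times_genus_mean(self, svd_tab):
        df = estimate_service(_series(), svd_tab, "Dryas", taxmap=_taxmap())
        row = df[(df.insect_taxon == "Aedes impiger") & (df.week == 0)].iloc[0]
        assert row.visits == 10 and row.svd_mean == 50.0
        assert row.estimated_grains == 500.0 and row.svd_level == "genus"

    def test_family_fallback(self, svd_tab):
        # Drymeia has no genus-level trials and Muscidae no family rows ->
        # excluded; give it Empididae family instead to exercise fallback
        taxmap = _taxmap()
        taxmap.entries["Drymeia segnis"] = TaxonEntry("Drymeia segnis", "species", "Empididae")
        df = estimate_service(_series(), svd_tab, "Dryas", taxmap=taxmap)
        row = df[df.insect_taxon == "Drymeia segnis"].iloc[0]
        assert row.svd_level == "family" and row.svd_mean == 25.0
        assert row.estimated_grains == 25.0

    def test_taxon_without_any_svd_excluded(self, svd_tab):
        df = estimate_service(_series(), svd_tab, "Dryas", taxmap=_taxmap())
        assert "Drymeia segnis" not in set(df.insect_taxon)

    def test_focal_absent_everywhere_errors(self, svd_tab):
        with pytest.raises(ValueError, match="Salix"):
            estimate_service(_series(), svd_tab, "Salix", taxmap=_taxmap())

    def test_community_total_equals_hand_sum(self, svd_tab):
        # week 0: 10*50 + 2*20 = 540 (Drymeia excluded); week 1: 4*50 + 3*20 = 260
        df = estimate_service(_series(), svd_tab, "Dryas", taxmap=_taxmap())
        assert community_total(df) == 540.0 + 260.0

    def test_annual_is_exact_sum_of_weeks(self, svd_tab):
        df = estimate_service(_series(), svd_tab, "Dryas", taxmap=_taxmap())
        ann = annual_service(df)
        aedes = ann[ann.insect_taxon == "Aedes impiger"].iloc[0]
        assert aedes.visits == 14 and aedes.estimated_grains == 700.0
        assert ann.estimated_grains.sum() == community_total(df)

    def test_linear_in_visits(self, svd_tab):
        df = estimate_service(_series(), svd_tab, "Dryas", taxmap=_taxmap())
        doubled = _series()
        for _, net in doubled:
            net.weights = net.weights * 2
        df2 = estimate_service(doubled, svd_tab, "Dryas", taxmap=_taxmap())
        assert community_total(df2) == 2 * community_total(df)

    def test_removing_genus_entry_only_switches_that_taxon(self, svd_tab):
        taxmap = _taxmap()
        df_before = estimate_service(_series(), svd_tab, "Dryas", taxmap=taxmap)
        reduced = svd_tab
        reduced.genus = reduced.genus[reduced.genus.genus != "Rhamphomyia"]
        df_after = estimate_service(_series(), reduced, "Dryas", taxmap=taxmap)
        changed = df_after[df_after.insect_taxon == "Rhamphomyia nigrita"]
        assert (changed.svd_level == "family").all()
        others_b = df_before[df_before.insect_taxon != "Rhamphomyia nigrita"]
        others_a = df_after[df_after.insect_taxon != "Rhamphomyia nigrita"]
        pd.testing.assert_frame_equal(
            others_a.reset_index(drop=True), others_b.reset_index(drop=True)
        )


class TestActivityPeriods:
    def test_mean_distinct_weeks_over_years(self):
        recs = pd.DataFrame(
            [
                {"plant_taxon": "Dryas", "insect_taxon": "A", "year": y, "week": w,
                 "count": 1, "evidence": "visit"}
                for y, weeks in ((1996, [23, 24, 25]), (1997, [24, 25]))
                for w in weeks
            ]
        )
        out = activity_periods(recs)
        assert out.set_index("insect_taxon").loc["A", "activity_weeks"] == 2.5

    def test_single_observation_gives_one(self):
        recs = pd.DataFrame(
            [{"plant_taxon": "p", "insect_taxon": "A", "year": 1996, "week": 3,
              "count": 2, "evidence": "visit"}]
        )
        assert activity_periods(recs)["activity_weeks"].iloc[0] == 1.0

    def test_recovers_generator_windows(self, baseline_data, baseline_interactions):
        truth = baseline_data["truth"]
        act = activity_periods(baseline_interactions).set_index("insect_taxon")
        # window width in integer weeks ~ number of covered weeks
        widths, observed = [], []
        for insect, (center, width) in truth.insect_windows.items():
            if insect not in act.index:
                continue
            lo, hi = center - width / 2, center + width / 2
            covered = sum(1 for w in range(13) if lo <= w <= hi)
            widths.append(covered)
            observed.append(act.loc[insect, "activity_weeks"])
        widths, observed = np.array(widths), np.array(observed)
        assert np.corrcoef(widths, observed)[0, 1] > 0.8
        assert abs(np.mean(observed - widths)) < 1.5


class TestEstimateTransport:
    def test_mean_load_over_individuals(self):
        pollen = pd.DataFrame(
            [
                {"individual": "a", "insect": "A", "plant_genus": "P", "grains": 100,
                 "year": 2016, "week": 0},
                {"individual": "b", "insect": "A", "plant_genus": "P", "grains": 50,
                 "year": 2016, "week": 0},
            ]
        )
        out = estimate_transport(pollen)
        assert out.mean_load.iloc[0] == 75.0
        assert out.estimated_removed.iloc[0] == 150.0

    def test_totals_match_brute_force_recount(self, baseline_data):
        from pollinet.records import pollen_assign_weeks

        pollen = pollen_assign_weeks(baseline_data["pollen"])
        out = estimate_transport(pollen)
        # estimated_removed aggregates exactly the raw grains per taxon/plant/week
        brute = (
            pollen.groupby(["insect", "plant_genus", "year", "week"])["grains"].sum()
        )
        for row in out.itertuples():
            assert row.estimated_removed == pytest.approx(
                brute.loc[(row.insect_taxon, row.plant, row.year, row.week)]
            )


class TestFitLine:
    def test_exact_line(self):
        x = np.arange(5, dtype=float)
        res = fit_line(x, 2 * x)
        assert res.slope == pytest.approx(2.0) and res.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        res = fit_line(np.arange(5.0), np.full(5, 3.0))
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_zero_x_variance_errors(self):
        with pytest.raises(ValueError):
            fit_line(np.ones(5), np.arange(5.0))

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        res = fit_line(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert res.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert res.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
        assert res.adj_r_squared == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert res.p_slope == pytest.approx(ref.pvalues[1], abs=1e-10)
        assert res.adj_r_squared <= res.r_squared


class TestServiceVsActivity:
    @staticmethod
    def _annual(rows):
        return pd.DataFrame(rows, columns=["insect_taxon", "year", "estimated_grains"])

    @staticmethod
    def _activity(d):
        return pd.DataFrame(
            [{"insect_taxon": k, "activity_weeks": v} for k, v in d.items()]
        )

    def test_no_year_effect_simplifies_to_activity_only(self):
        rng = np.random.default_rng(17)
        taxa = [f"t{k}" for k in range(10)]
        act = {t: float(1 + k) for k, t in enumerate(taxa)}
        rows = [
            (t, 2000 + y, 100.0 * act[t] + rng.normal(scale=20.0))
            for t in taxa
            for y in range(4)
        ]
        res = service_vs_activity(self._annual(rows), self._activity(act))
        assert set(res.dropped_terms) == {"activity:year", "year"}
        assert res.slope == pytest.approx(100.0, rel=0.15)
        assert res.p_slope < 0.01

    def test_constant_service_gives_zero_slope(self):
        taxa = {f"t{k}": float(k + 1) for k in range(5)}
        rows = [(t, 2000, 50.0) for t in taxa]
        res = service_vs_activity(self._annual(rows), self._activity(taxa))
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_strong_year_effect_retained(self):
        rng = np.random.default_rng(23)
        taxa = {f"t{k}": float(k + 1) for k in range(8)}
        rows = [
            (t, 2000 + y, 10.0 * taxa[t] + 500.0 * y + rng.normal(scale=1.0))
            for t in taxa
            for y in range(5)
        ]
        res = service_vs_activity(self._annual(rows), self._activity(taxa))
        assert "year" not in res.dropped_terms
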