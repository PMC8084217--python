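"""Stand-structure summaries, class distributions and the NR/TNR index."""

import math

import numpy as np
import pandas as pd
import pytest

from beniforest import study
from beniforest.errors import ParameterError, SurveyDataError
from beniforest.model import SiteDesign, SurveyDataset, validate_dataset
from beniforest.regeneration import (
    class_distribution,
    compose_stages,
    density_per_ha,
    life_stage_composition,
    nr_table,
    site_stage_summary,
    stem_basal_area,
    total_regeneration,
)

from conftest import make_sapling


class TestBasalArea:
    @pytest.mark.parametrize(
        "dbh, expected",
        [
            (0.0, 0.0),
            (20.0, math.pi * 0.1**2),  # 0.031416 m²
            (200.0 / math.sqrt(math.pi), 1.0),
        ],
    )
    def test_closed_form(self, dbh, expected):
        assert stem_basal_area(dbh) == pytest.approx(expected, abs=1e-9)

    def test_negative_dbh_rejected(self):
        with pytest.raises(ParameterError):
            stem_basal_area(-1)

    def test_strictly_increasing_in_dbh(self):
        d = np.linspace(0, 120, 200)
        ba = [stem_basal_area(x) for x in d]
        assert all(b2 > b1 for b1, b2 in zip(ba, ba[1:]))


class TestDensity:
    @pytest.mark.parametrize(
        "count, area, expected", [(1, 400, 25), (5, 20, 2500), (0, 123.4, 0)]
    )
    def test_scaling(self, count, area, expected):
        assert density_per_ha(count, area) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ParameterError):
            density_per_ha(1, 0)


class TestStageSummary:
    def test_two_plot_mean_and_sample_sd(self, two_plot_dataset):
        table = site_stage_summary(two_plot_dataset).table
        row = table[(table.stage == "adult") & (table.group == "broadleaf")].iloc[0]
        assert row.mean_density_per_ha == pytest.approx(25.0)
        assert row.sd_density == pytest.approx(35.355339, abs=1e-5)

    def test_single_plot_gives_zero_sd(self):
        design = SiteDesign(site_id="s", treatment="grazed", n_plots=1)
        stems = pd.DataFrame([
            {"site_id": "s", "plot_id": "s-P1", "stage": "adult", "group": "motacu",
             "dbh_cm": 35.0, "height_m": 12.0, "alive": True, "grazing_damage": False},
        ])
        ds = validate_dataset(SurveyDataset(designs={"s": design}, stems=stems))
        table = site_stage_summary(ds).table
        assert (table["sd_density"] == 0).all()

    def test_composition_pct_sums_to_100_per_stage(self, sim_dataset):
        table = site_stage_summary(sim_dataset).table
        for (_, _), sub in table.groupby(["site_id", "stage"]):
            pct = sub["pct_of_stage_total"].dropna()
            if len(pct):
                assert pct.sum() == pytest.approx(100.0, abs=0.5)

    def test_site_totals_invariant_under_plot_relabeling(self, sim_dataset):
        base = site_stage_summary(sim_dataset).table
        shuffled = SurveyDataset(
            designs=sim_dataset.designs,
            stems=sim_dataset.stems.sample(frac=1, random_state=0).reset_index(drop=True),
            quadrats=sim_dataset.quadrats,
            seedlings=sim_dataset.seedlings,
            intercepts=sim_dataset.intercepts,
            efforts=sim_dataset.efforts,
            observations=sim_dataset.observations,
        )
        again = site_stage_summary(shuffled).table
        pd.testing.assert_frame_equal(base, again)

    def test_motacu_saplings_carry_no_basal_area(self, sim_dataset):
        table = site_stage_summary(sim_dataset).table
        row = table[(table.stage == "sapling") & (table.group == "motacu")]
        assert row["mean_basal_area_m2_ha"].isna().all()


class TestClassDistribution:
    def _dataset(self, stems):
        design = SiteDesign(site_id="g", treatment="grazed", n_plots=1)
        return validate_dataset(
            SurveyDataset(designs={"g": design}, stems=pd.DataFrame(stems))
        )

    def test_height_binning_left_closed(self):
        ds = self._dataset([
            make_sapling("g", "g-P1", "broadleaf", h) for h in (1.2, 1.9, 2.5, 2.0)
        ])
        table = class_distribution(ds, "sapling_height_1m").table
        by_band = table.set_index("band")["mean_per_ha"]
        assert by_band["[1,2)"] == pytest.approx(2 * 50.0)
        assert by_band["[2,3)"] == pytest.approx(2 * 50.0)  # 2.0 m joins [2,3)

    def test_acaulescent_saplings_form_first_dbh_band(self):
        ds = self._dataset(
            [make_sapling("g", "g-P1", "motacu", 1.5) for _ in range(3)]
            + [{"site_id": "g", "plot_id": "g-P1", "stage": "adult", "group": "motacu",
                "dbh_cm": 36.0, "height_m": 12.0, "alive": True, "grazing_damage": False}]
        )
        table = class_distribution(ds, "stem_dbh_10cm").table
        bands = table.set_index("band")["mean_per_ha"]
        assert bands["acaulescent"] == pytest.approx(3 * 50.0)  # sapling frame 200 m²
        assert bands["[30,40)"] == pytest.approx(25.0)  # adult frame 400 m²

    def test_unmeasured_stems_are_bucketed_not_dropped(self):
        # broadleaf sapling without dbh cannot be dbh-binned
        ds = self._dataset([make_sapling("g", "g-P1", "broadleaf", 1.5)])
        table = class_distribution(ds, "stem_dbh_10cm").table
        assert set(table["band"]) == {"unmeasured"}

    @pytest.mark.parametrize(
        "scheme, stage, area",
        [("sapling_height_1m", "sapling", 200.0), ("adult_height_3m", "adult", 400.0)],
    )
    def test_band_totals_cover_every_stem(self, sim_dataset, scheme, stage, area):
        # single-stage schemes: summed band means invert exactly to the
        # stem count (unmeasured bucket included), so nothing is dropped
        dist = class_distribution(sim_dataset, scheme)
        stems = sim_dataset.stems
        live = stems[stems["alive"] & (stems["stage"] == stage)]
        for site_id, design in sim_dataset.designs.items():
            sub = dist.table[dist.table["site_id"] == site_id]
            implied = sub["mean_per_ha"].sum() * design.n_plots * area / 10_000.0
            assert implied == pytest.approx(len(live[live["site_id"] == site_id]))

    def test_unknown_scheme_rejected(self, sim_dataset):
        with pytest.raises(ParameterError):
            class_distribution(sim_dataset, "nope")


class TestLifeStageComposition:
    @pytest.mark.parametrize(
        "dens, total, shares",
        [
            ({"seedling": 10875, "sapling": 1300, "adult": 225}, 12400, (88, 10, 2)),
            ({"seedling": 10750, "sapling": 3200, "adult": 412}, 14362, (75, 22, 3)),
        ],
    )
    def test_reported_motacu_totals_and_shares(self, dens, total, shares):
        comp = compose_stages(dens)
        assert comp["total_per_ha"] == pytest.approx(total)
        assert (comp["pct"]["seedling"], comp["pct"]["sapling"], comp["pct"]["adult"]) == shares

    def test_single_stage_is_100_percent(self):
        comp = compose_stages({"seedling": 0.0, "sapling": 500.0, "adult": 0.0})
        assert comp["pct"]["sapling"] == 100

    def test_all_zero_group_reports_null_shares(self):
        comp = compose_stages({"seedling": 0.0, "sapling": 0.0, "adult": 0.0})
        assert comp["total_per_ha"] == 0
        assert all(v is None for v in comp["pct"].values())

    def test_dataset_pathway_matches_summary(self, sim_dataset):
        comp = life_stage_composition(sim_dataset)
        assert {"site_id", "group", "total_per_ha"} <= set(comp.columns)
        assert (comp["total_per_ha"] >= 0).all()


class TestNRTable:
    def test_toy_oracle_hand_computed(self, nr_toy_dataset):
        with pytest.warns(UserWarning, match="holds no eligible saplings"):
            nr = nr_table(nr_toy_dataset)
        t = nr.table.set_index("group")
        # class 1–2 m: RD motacú 2/3, broadleaf 1/3; RF 50/50
        assert t.loc["motacu", "nr_1-2m"] == pytest.approx((200 / 3 + 50) / 2 / 3)
        assert t.loc["broadleaf", "nr_1-2m"] == pytest.approx((100 / 3 + 50) / 2 / 3)
        # class 2–3 m: broadleaf alone
        assert t.loc["broadleaf", "nr_2-3m"] == pytest.approx(100 / 3)
        assert t.loc["motacu", "nr_2-3m"] == 0.0
        assert t.loc["motacu", "tnr_pct"] == pytest.approx(19.4444, abs=1e-3)
        assert t.loc["broadleaf", "tnr_pct"] == pytest.approx(47.2222, abs=1e-3)

    def test_single_group_everywhere_normalises_to_third_per_class(self):
        design = SiteDesign(site_id="g", treatment="grazed", n_plots=2)
        stems = pd.DataFrame(
            [make_sapling("g", p, "motacu", h)
             for p in ("g-P1", "g-P2") for h in (1.5, 2.5, 3.5)]
        )
        ds = validate_dataset(SurveyDataset(designs={"g": design}, stems=stems))
        t = nr_table(ds).table
        for c in ("nr_1-2m", "nr_2-3m", "nr_>3m"):
            assert t[c].iloc[0] == pytest.approx(100 / 3)
        assert t["tnr_pct"].iloc[0] == pytest.approx(100.0)

    def test_two_identical_groups_split_tnr_evenly(self):
        design = SiteDesign(site_id="g", treatment="grazed", n_plots=2)
        stems = pd.DataFrame(
            [make_sapling("g", p, g, h)
             for p in ("g-P1", "g-P2")
             for g in ("motacu", "broadleaf")
             for h in (1.5, 2.5, 3.5)]
        )
        ds = validate_dataset(SurveyDataset(designs={"g": design}, stems=stems))
        t = nr_table(ds).table
        assert t["tnr_pct"].tolist() == pytest.approx([50.0, 50.0])

    def test_reported_per_class_values_sum_to_reported_tnr(self):
        # published per-class values aggregate to the published TNR ± 0.02
        for site, groups in study.NR_REPORTED.items():
            for group, per_class in groups.items():
                assert total_regeneration(per_class) == pytest.approx(
                    study.TNR_REPORTED[site][group], abs=0.02
                )

    def test_conservation_invariants_on_simulation(self, sim_dataset):
        nr = nr_table(sim_dataset)
        for site_id, sub in nr.table.groupby("site_id"):
            for c in [c for c in sub.columns if c.startswith("nr_")]:
                assert sub[c].sum() == pytest.approx(100 / 3, abs=0.02)
            assert sub["tnr_pct"].sum() == pytest.approx(100.0, abs=0.05)

    def test_exclusions_dead_tall_broadleaf(self):
        design = SiteDesign(site_id="g", treatment="grazed", n_plots=1)
        stems = pd.DataFrame([
            make_sapling("g", "g-P1", "motacu", 1.5),
            make_sapling("g", "g-P1", "motacu", 2.5),
            make_sapling("g", "g-P1", "motacu", 3.5),
            make_sapling("g", "g-P1", "broadleaf", 1.5, dbh=6.0),  # dbh ≥ 5: excluded
            make_sapling("g", "g-P1", "broadleaf", 2.5, alive=False),  # dead: excluded
            make_sapling("g", "g-P1", "broadleaf", 0.8),  # below 1 m: excluded
        ])
        ds = validate_dataset(SurveyDataset(designs={"g": design}, stems=stems))
        t = nr_table(ds).table
        assert t["group"].tolist() == ["motacu"]
        assert t["tnr_pct"].iloc[0] == pytest.approx(100.0)

    def test_all_classes_empty_is_an_error(self):
        design = SiteDesign(site_id="g", treatment="grazed", n_plots=1)
        stems = pd.DataFrame([make_sapling("g", "g-P1", "broadleaf", 0.9)])
        ds = validate_dataset(SurveyDataset(designs={"g": design}, stems=stems))
        with pytest.raises(SurveyDataError, match="no eligible"):
            nr_table(ds)
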