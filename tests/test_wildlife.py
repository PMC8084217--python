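"""Encounter rates, richness, segmentation and exact accumulation."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beniforest import study
from beniforest.errors import SurveyDataError
from beniforest.wildlife import (
    IncidenceMatrix,
    encounter_table,
    exact_accumulation,
    richness_and_uniques,
    segmentize,
)


def _efforts(rows):
    return pd.DataFrame(rows, columns=["transect_id", "site_id", "survey",
                                       "distance_km", "duration_min"])


def _obs(rows):
    return pd.DataFrame(rows, columns=["transect_id", "site_id", "survey",
                                       "elapsed_min", "taxon_id", "taxon_class",
                                       "n_individuals", "detection"])


class TestEncounterTable:
    def test_reported_mammal_rates_reproduced(self):
        et = encounter_table(
            study.reported_observations(), study.reported_efforts(),
            site_order=("grazed", "restored"),
        )
        t = et.table.set_index("taxon_id")
        assert t.loc["south_american_coati", "er_per_km_grazed"] == pytest.approx(4.00)
        assert t.loc["brown_agouti", "er_per_km_restored"] == pytest.approx(2.85)
        assert t.loc["capybara", "er_per_km_grazed"] == pytest.approx(1.88)
        assert t.loc["black_howler_monkey", "diff_er_per_km"] == pytest.approx(1.13)

    def test_mammal_effort_pools_dusk_and_night(self):
        et = encounter_table(study.reported_observations(), study.reported_efforts())
        eff = et.effort_km.set_index(["site_id", "taxon_class"])["distance_km"]
        assert eff[("grazed", "mammal")] == pytest.approx(4.25)
        assert eff[("restored", "mammal")] == pytest.approx(3.86)
        assert eff[("grazed", "nocturnal_bird")] == pytest.approx(2.10)

    def test_zero_events_gives_zero_rate_and_mirror_diff(self):
        efforts = _efforts([("t1", "A", "dusk", 2.0, 60.0), ("t2", "B", "dusk", 2.0, 60.0),
                            ("t1", "A", "night", 2.0, 60.0), ("t2", "B", "night", 2.0, 60.0)])
        obs = _obs([("t1", "A", "dusk", 5.0, "capybara", "mammal", 4, "visual")])
        et = encounter_table(obs, efforts, site_order=("A", "B"))
        row = et.table.iloc[0]
        assert row["er_per_km_B"] == 0.0
        assert row["diff_er_per_km"] == pytest.approx(-row["er_per_km_A"])

    def test_individuals_vs_events_basis(self):
        efforts = _efforts([("t1", "A", "dusk", 2.0, 60.0)])
        obs = _obs([("t1", "A", "dusk", 5.0, "capybara", "mammal", 4, "visual")])
        ind = encounter_table(obs, efforts, rate_basis="individuals")
        ev = encounter_table(obs, efforts, rate_basis="events")
        assert ind.rates["er_per_km"].iloc[0] == pytest.approx(2.0)
        assert ev.rates["er_per_km"].iloc[0] == pytest.approx(0.5)

    def test_individual_totals_conserved(self):
        obs = study.reported_observations()
        et = encounter_table(obs, study.reported_efforts())
        assert et.rates["n_individuals"].sum() == obs["n_individuals"].sum()

    def test_unknown_transect_rejected(self):
        efforts = _efforts([("t1", "A", "dusk", 2.0, 60.0)])
        obs = _obs([("tX", "A", "dusk", 5.0, "capybara", "mammal", 1, "visual")])
        with pytest.raises(SurveyDataError, match="unknown transect"):
            encounter_table(obs, efforts)


class TestRichness:
    def test_disjoint_single_species_sites(self):
        obs = _obs([("t1", "A", "dusk", 1.0, "sp1", "mammal", 1, "visual"),
                    ("t2", "B", "dusk", 1.0, "sp2", "mammal", 1, "visual")])
        rich = richness_and_uniques(obs)
        assert rich.richness["richness"].tolist() == [1, 1]
        assert rich.richness["n_unique"].tolist() == [1, 1]
        assert rich.shared["mammal"] == set()

    def test_reported_species_lists(self):
        rich = richness_and_uniques(study.reported_observations())
        assert rich.total["mammal"] == 14
        r = rich.richness.set_index(["site_id", "taxon_class"])
        assert r.loc[("grazed", "nocturnal_bird"), "richness"] == 6
        assert r.loc[("restored", "nocturnal_bird"), "richness"] == 6
        assert r.loc[("grazed", "nocturnal_bird"), "n_unique"] == 1
        assert r.loc[("restored", "nocturnal_bird"), "n_unique"] == 1
        assert rich.unique[("grazed", "nocturnal_bird")] == {"common_potoo"}
        assert rich.unique[("restored", "nocturnal_bird")] == {"barn_owl"}


class TestSegmentize:
    def test_bin_edges_left_closed(self):
        efforts = _efforts([("t1", "A", "night", 2.0, 60.0)])
        obs = _obs([("t1", "A", "night", 0.0, "sp1", "mammal", 1, "visual"),
                    ("t1", "A", "night", 15.0, "sp2", "mammal", 1, "visual")])
        inc = segmentize(obs, efforts)["A"]
        assert bool(inc.matrix.loc["sp1", 1]) and not bool(inc.matrix.loc["sp1", 2])
        assert bool(inc.matrix.loc["sp2", 2])

    def test_segment_counts_concatenate_walks(self):
        efforts = _efforts([("t1", "A", "dusk", 1.0, 60.0),
                            ("t1", "A", "night", 1.0, 120.0)])
        inc = segmentize(_obs([]), efforts)["A"]
        assert inc.T == 4 + 8

    def test_partial_final_segment_kept_and_truncation_applies(self):
        efforts = _efforts([("t1", "A", "night", 1.0, 100.0)])  # 7 segments
        inc = segmentize(_obs([]), efforts, max_segments=5)["A"]
        assert inc.T == 5

    def test_default_study_effort_yields_24_segments(self):
        for site in ("grazed", "restored"):
            eff = study.reported_efforts()
            eff = eff[eff["site_id"] == site]
            inc = segmentize(_obs([]), eff)[site]
            assert inc.T == 24

    def test_observation_at_walk_end_joins_last_segment(self):
        efforts = _efforts([("t1", "A", "night", 2.0, 60.0)])
        obs = _obs([("t1", "A", "night", 60.0, "sp1", "mammal", 1, "visual")])
        inc = segmentize(obs, efforts)["A"]
        assert bool(inc.matrix.loc["sp1", 4])


def enumeration_oracle(M: np.ndarray):
    """Mean and SD of richness over all k-subsets by brute force."""
    S, T = M.shape
    out = []
    for k in range(1, T + 1):
        vals = [
            int((M[:, list(cols)].any(axis=1)).sum())
            for cols in combinations(range(T), k)
        ]
        vals = np.array(vals, dtype=float)
        out.append((vals.mean(), vals.std(ddof=0)))
    return out


def _curve(M: np.ndarray) -> pd.DataFrame:
    inc = IncidenceMatrix(
        site_id="x",
        matrix=pd.DataFrame(M.astype(bool),
                            index=[f"sp{i}" for i in range(M.shape[0])],
                            columns=pd.RangeIndex(1, M.shape[1] + 1)),
        segments=pd.DataFrame(),
    )
    return exact_accumulation(inc).table


class TestExactAccumulation:
    def test_toy_matrix_matches_enumeration(self):
        # 3 taxa over T=4 segments with incidences {1, 2, 4}
        M = np.array([
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 1, 1],
        ])
        table = _curve(M)
        for (mean, sd), row in zip(enumeration_oracle(M), table.itertuples(index=False)):
            assert row.expected_richness == pytest.approx(mean, abs=1e-10)
            assert row.sd == pytest.approx(sd, abs=1e-10)

    def test_endpoint_equals_observed_richness_with_zero_sd(self):
        M = (np.random.default_rng(5).random((6, 8)) < 0.4)
        M[0, :] = True  # ensure nonempty
        table = _curve(M)
        assert table["expected_richness"].iloc[-1] == pytest.approx(
            float(M.any(axis=1).sum())
        )
        assert table["sd"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_ubiquitous_taxon_gives_flat_curve(self):
        M = np.ones((1, 6), dtype=bool)
        table = _curve(M)
        assert np.allclose(table["expected_richness"], 1.0)
        assert np.allclose(table["sd"], 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=10).flatmap(
            lambda T: st.lists(
                st.lists(st.booleans(), min_size=T, max_size=T),
                min_size=1, max_size=5,
            )
        )
    )
    def test_property_equals_enumeration_small_T(self, rows):
        M = np.array(rows, dtype=bool)
        table = _curve(M)
        for (mean, sd), row in zip(enumeration_oracle(M), table.itertuples(index=False)):
            assert row.expected_richness == pytest.approx(mean, abs=1e-10)
            assert row.sd == pytest.approx(sd, abs=1e-10)

    def test_expectation_monotone_in_k(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            M = rng.random((rng.integers(1, 8), rng.integers(1, 12))) < 0.35
            e = _curve(M)["expected_richness"].to_numpy()
            assert np.all(np.diff(e) >= -1e-12)
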