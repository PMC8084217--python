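"""Reference summary values from the grazed-vs-restored monitoring campaign.

These are the published plot-mean summaries of the Beni gallery-forest
study the package is built around: stand densities and basal areas per
functional group and life stage, the reported natural-regeneration table,
the wildlife species list with per-site individual counts and encounter
rates, and the survey effort.  They serve two purposes:

* calibration targets for :func:`beniforest.synthetic.default_profiles`
  (the generator's default expected densities/rates ARE these values), and
* worked-example inputs: the arithmetic published alongside them (stage
  totals and shares, TNR row sums, encounter rates per km) can be
  recomputed through the package's own operations.

Densities are individuals per hectare, basal areas m² per hectare,
distances km, encounter rates per km walked.
"""

from __future__ import annotations

import pandas as pd

# --- stand structure: site → stage → group → (mean, sd) per-ha density ----
DENSITY_PER_HA: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "grazed": {
        "seedling": {"broadleaf": (27875, 11665), "motacu": (10875, 3250)},
        "sapling": {"broadleaf": (2938, 1551), "motacu": (1300, 1363)},
        "adult": {"broadleaf": (388, 171), "motacu": (225, 95.7), "other_palm": (0, 0)},
    },
    "restored": {
        "seedling": {"broadleaf": (22125, 15418), "motacu": (10750, 13763)},
        "sapling": {"broadleaf": (2838, 1672), "motacu": (3200, 2618)},
        "adult": {"broadleaf": (31, 31.5), "motacu": (412, 32.3), "other_palm": (6, 12.5)},
    },
}

# snag (standing-dead) densities per ha, site → stage → group → density
SNAG_DENSITY_PER_HA: dict[str, dict[str, dict[str, float]]] = {
    "grazed": {"sapling": {"broadleaf": 50}, "adult": {"broadleaf": 25, "motacu": 6}},
    "restored": {"sapling": {}, "adult": {"motacu": 6}},
}

# --- basal area, site → stage → group → (mean, sd) m²/ha ------------------
BASAL_AREA_M2_HA: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "grazed": {
        "sapling": {"broadleaf": (3.3, 2.3)},
        "adult": {"broadleaf": (17.5, 11.6), "motacu": (28.4, 18.7), "other_palm": (0, 0)},
    },
    "restored": {
        "sapling": {"broadleaf": (0.8, 0.8)},
        "adult": {"broadleaf": (1.88, 1.3), "motacu": (46.8, 5.7), "other_palm": (0.74, 1.5)},
    },
}

# adult motacú stem size/height summaries, (mean, sd)
ADULT_MOTACU_DBH_CM = {"grazed": (36.4, 7.67), "restored": (37.4, 0.9)}
ADULT_MOTACU_HEIGHT_M = {"grazed": (11.9, 3.52), "restored": (14.3, 1.0)}

# --- reported natural-regeneration table: site → group → per-class NR% ----
# height classes 1–2 m, 2–3 m, > 3 m; TNR is the row sum.
NR_REPORTED: dict[str, dict[str, tuple[float, float, float]]] = {
    "grazed": {"motacu": (15.00, 12.83, 10.57), "broadleaf": (18.33, 20.50, 22.76)},
    "restored": {"motacu": (17.98, 20.24, 9.39), "broadleaf": (15.35, 13.09, 23.94)},
}
TNR_REPORTED = {
    "grazed": {"motacu": 38.41, "broadleaf": 61.59},
    "restored": {"motacu": 47.62, "broadleaf": 52.38},
}

# --- survey effort ---------------------------------------------------------
#: total distance walked per site (dusk + night, both transects), km
TOTAL_DISTANCE_KM = {"grazed": 4.25, "restored": 3.86}
#: total survey duration per site, minutes (5 h 51 m and 6 h 02 m)
TOTAL_DURATION_MIN = {"grazed": 351.0, "restored": 362.0}
#: night-only distance per site, km — not printed in the study; implied by
#: back-calculation from the nocturnal-bird rates and used only as the
#: generator's default effort split.
NIGHT_DISTANCE_KM = {"grazed": 2.10, "restored": 2.20}

# --- wildlife species list -------------------------------------------------
# taxon_id, common name, scientific name, class, IUCN population trend,
# individuals counted per site (grazed, restored), encounter rate per km of
# eligible effort per site (mammals: dusk+night km; birds: night km).
_WILDLIFE_ROWS = [
    ("brown_agouti", "Brown Agouti", "Dasyprocta variegata", "mammal", "DD", 4, 11, 0.94, 2.85),
    ("capybara", "Capybara", "Hydrochoerus hydrochaeris", "mammal", "stable", 8, 4, 1.88, 1.04),
    ("collared_peccary", "Collared Peccary", "Pecari tajacu", "mammal", "stable", 0, 3, 0.0, 0.78),
    ("south_american_coati", "South American Coati", "Nasua nasua", "mammal", "declining", 17, 1, 4.00, 0.26),
    ("black_howler_monkey", "Black Howler Monkey", "Alouatta caraya", "mammal", "declining", 15, 18, 3.53, 4.66),
    ("yellow_armadillo", "Yellow Armadillo", "Euphractus sexcinctus", "mammal", "stable", 0, 1, 0.0, 0.26),
    ("nine_banded_armadillo", "Nine-banded Armadillo", "Dasypus novemcinctus", "mammal", "stable", 4, 2, 0.94, 0.52),
    ("gray_brocket_deer", "Gray Brocket Deer", "Mazama gouazoubira", "mammal", "declining", 0, 1, 0.0, 0.26),
    ("pampas_deer", "Pampas Deer", "Ozotoceros bezoarticus", "mammal", "declining", 0, 1, 0.0, 0.26),
    ("marsh_deer", "Marsh Deer", "Blastocerus dichotomus", "mammal", "declining", 0, 1, 0.0, 0.26),
    ("crab_eating_fox", "Crab-eating Fox", "Cerdocyon thous", "mammal", "stable", 1, 0, 0.24, 0.0),
    ("southern_tamandua", "Southern Tamandua", "Tamandua tetradactyla", "mammal", "DD", 1, 1, 0.24, 0.26),
    ("brazilian_porcupine", "Brazilian Porcupine", "Coendou prehensilis", "mammal", "stable", 0, 1, 0.0, 0.26),
    ("gray_four_eyed_opossum", "Gray Four Eyed Opossum", "Philander opossum", "mammal", "stable", 0, 1, 0.0, 0.26),
    ("great_potoo", "Great Potoo", "Nyctibius grandis", "nocturnal_bird", "declining", 1, 3, 0.48, 1.36),
    ("common_potoo", "Common Potoo", "Nyctibius griseus", "nocturnal_bird", "declining", 2, 0, 0.95, 0.0),
    ("ferruginous_pygmy_owl", "Ferruginous Pygmy Owl", "Glaucidium brasilianum", "nocturnal_bird", "declining", 3, 7, 1.43, 3.18),
    ("tropical_screech_owl", "Tropical Screech Owl", "Megascops choliba", "nocturnal_bird", "stable", 9, 9, 4.29, 4.09),
    ("barn_owl", "Barn Owl", "Tyto alba", "nocturnal_bird", "stable", 0, 1, 0.0, 0.45),
    ("common_pauraque", "Common Pauraque", "Nyctidromus albicollis", "nocturnal_bird", "declining", 7, 17, 3.33, 7.73),
    ("scissor_tailed_nightjar", "Scissor-tailed Nightjar", "Hydropsalis torquata", "nocturnal_bird", "stable", 1, 4, 0.48, 1.81),
]

WILDLIFE_COLUMNS = [
    "taxon_id", "common_name", "scientific_name", "taxon_class", "iucn_trend",
    "n_grazed", "n_restored", "er_per_km_grazed", "er_per_km_restored",
]


def wildlife_table() -> pd.DataFrame:
    """Species list with per-site counts and published encounter rates."""
    return pd.DataFrame(_WILDLIFE_ROWS, columns=WILDLIFE_COLUMNS)


def taxa_table() -> pd.DataFrame:
    """Static taxon annotation (the ``taxa.csv`` layout)."""
    df = wildlife_table()
    return df[["taxon_id", "common_name", "scientific_name", "taxon_class", "iucn_trend"]]


def reported_observations() -> pd.DataFrame:
    """Reconstruct an observation table from the per-site individual counts.

    One observation row per recorded individual (group size 1), placed on
    the site's first transect at an arbitrary but valid elapsed time.  This
    carries exactly the information the published counts do, and feeds the
    encounter-rate and richness operations for the worked examples.
    """
    rows = []
    for r in wildlife_table().itertuples(index=False):
        for site, n in (("grazed", r.n_grazed), ("restored", r.n_restored)):
            survey = "night" if r.taxon_class == "nocturnal_bird" else "dusk"
            for k in range(int(n)):
                rows.append(
                    {
                        "transect_id": f"{site}-T1",
                        "site_id": site,
                        "survey": survey,
                        "elapsed_min": float(k % 50),
                        "taxon_id": r.taxon_id,
                        "taxon_class": r.taxon_class,
                        "n_individuals": 1,
                        "detection": "visual",
                    }
                )
    return pd.DataFrame(rows)


def reported_efforts() -> pd.DataFrame:
    """Site-level effort split across two transects and two survey periods.

    Distances reproduce the published per-site totals (4.25 / 3.86 km) and
    durations (351 / 362 min); the dusk/night split uses the implied
    night-only distances.
    """
    rows = []
    for site in ("grazed", "restored"):
        night = NIGHT_DISTANCE_KM[site]
        dusk = TOTAL_DISTANCE_KM[site] - night
        dusk_min = {"grazed": 60.0, "restored": 61.0}[site]
        night_min = (TOTAL_DURATION_MIN[site] - 2 * dusk_min) / 2
        for t in (1, 2):
            rows.append({"transect_id": f"{site}-T{t}", "site_id": site, "survey": "dusk",
                         "distance_km": round(dusk / 2, 5), "duration_min": dusk_min})
            rows.append({"transect_id": f"{site}-T{t}", "site_id": site, "survey": "night",
                         "distance_km": round(night / 2, 5), "duration_min": night_min})
    return pd.DataFrame(rows)
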