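"""Domain types and controlled vocabularies for gallery-forest field surveys.

The sampling design mirrors a paired grazed/restored monitoring campaign in
Beni-savanna gallery forest: each site holds four plots, and each plot is a
100 m transect (shrub-layer line intercepts to 2 m height) with a 400 m²
subplot for adult trees (dbh > 10 cm), its western 200 m² half for saplings
(height > 0.3 m, dbh < 10 cm) and five 4 m² quadrats for ground cover and
seedling counts (< 0.3 m).  Wildlife is surveyed on two line transects per
site, each walked once at dusk (mammals) and once at night (mammals and
nocturnal birds).

Records are validated individually (pydantic models) and held collectively
as pandas DataFrames inside :class:`SurveyDataset`, the in-memory container
every analysis module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ParameterError, ValidationError, VocabularyError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

TREATMENTS = ("grazed", "restored")
#: Life stages of woody individuals.  Seedlings are never measured
#: individually — they enter the data only as quadrat counts — so a
#: StemRecord may only be a sapling or an adult.
STEM_STAGES = ("sapling", "adult")
STEM_GROUPS = ("broadleaf", "motacu", "other_palm")
#: Shrub-layer functional groups recorded by line intercept.
SHRUB_GROUPS = ("palms", "broadleafs", "woody_shrubs", "vines", "ferns")
#: Ground-cover categories recorded in the 4 m² quadrats.
GROUND_CATEGORIES = (
    "bare_ground",
    "leaf_litter",
    "motacu_nuts",
    "deadwood",
    "cow_dung",
    "forbs",
    "ferns",
    "graminoids",
)
#: Seedling groups counted per quadrat (other-palm seedlings do not occur).
SEEDLING_GROUPS = ("motacu", "woody")
SURVEYS = ("dusk", "night")
TAXON_CLASSES = ("mammal", "nocturnal_bird")
DETECTIONS = ("visual", "aural")

#: dbh threshold separating saplings from adults, cm.  A stem of exactly
#: 10 cm is an adult (left-closed binning convention).
ADULT_DBH_MIN_CM = 10.0
#: minimum sapling height, m (below this an individual is a seedling).
SAPLING_HEIGHT_MIN_M = 0.3


def match_vocab(value: str, vocab: tuple[str, ...], fieldname: str) -> str:
    """Case-insensitively match ``value`` against a controlled vocabulary.

    Returns the canonical (lower-case) form, or raises
    :class:`VocabularyError` listing the allowed values.
    """
    v = str(value).strip().lower()
    if v not in vocab:
        raise VocabularyError(
            f"{fieldname}={value!r} is not recognised; allowed values: {', '.join(vocab)}"
        )
    return v


class _DomainModel(BaseModel):
    """Base model that surfaces the package's own error types.

    pydantic wraps every validator exception in its ValidationError; here
    the original domain error (VocabularyError, ValidationError,
    ParameterError) is unwrapped so callers see a precise type and message.
    """

    def __init__(self, /, **data):
        import pydantic

        try:
            super().__init__(**data)
        except pydantic.ValidationError as exc:
            for err in exc.errors(include_context=True):
                cause = err.get("ctx", {}).get("error")
                if isinstance(cause, (ValidationError, VocabularyError, ParameterError)):
                    raise cause from None
            raise ValidationError(str(exc)) from None


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


class SiteDesign(_DomainModel):
    """Geometry of the nested sampling design at one site."""

    model_config = ConfigDict(frozen=True)

    site_id: str
    treatment: str
    n_plots: int = 4
    transect_length_m: float = 100.0
    adult_subplot_area_m2: float = 400.0
    sapling_subplot_area_m2: float = 200.0
    quadrat_area_m2: float = 4.0
    quadrats_per_plot: int = 5
    shrub_layer_max_height_m: float = 2.0

    @field_validator("treatment")
    @classmethod
    def _treatment_vocab(cls, v: str) -> str:
        return match_vocab(v, TREATMENTS, "treatment")

    @model_validator(mode="after")
    def _check_geometry(self) -> "SiteDesign":
        positives = {
            "n_plots": self.n_plots,
            "transect_length_m": self.transect_length_m,
            "adult_subplot_area_m2": self.adult_subplot_area_m2,
            "sapling_subplot_area_m2": self.sapling_subplot_area_m2,
            "quadrat_area_m2": self.quadrat_area_m2,
            "quadrats_per_plot": self.quadrats_per_plot,
            "shrub_layer_max_height_m": self.shrub_layer_max_height_m,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if self.sapling_subplot_area_m2 > self.adult_subplot_area_m2:
            raise ParameterError(
                "sapling subplot cannot exceed the adult subplot "
                f"({self.sapling_subplot_area_m2} > {self.adult_subplot_area_m2} m²)"
            )
        return self

    @property
    def seedling_area_m2(self) -> float:
        """Total quadrat area per plot — the sampling frame for seedlings."""
        return self.quadrat_area_m2 * self.quadrats_per_plot

    def plot_ids(self) -> list[str]:
        """Canonical plot labels, ``<site_id>-P1 .. -Pn``."""
        return [f"{self.site_id}-P{i}" for i in range(1, self.n_plots + 1)]


def default_designs() -> tuple[SiteDesign, SiteDesign]:
    """The study layout: one grazed and one restored site, four plots each."""
    return (
        SiteDesign(site_id="grazed", treatment="grazed"),
        SiteDesign(site_id="restored", treatment="restored"),
    )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


class StemRecord(_DomainModel):
    """One measured woody individual (sapling or adult).

    Adults require dbh ≥ 10 cm; saplings require height > 0.3 m and, when a
    dbh was measured (broadleaf only), dbh < 10 cm.  Motacú saplings are
    acaulescent and never carry a dbh.  Snags are live=False stems, not a
    separate group.
    """

    site_id: str
    plot_id: str
    stage: str
    group: str
    dbh_cm: Optional[float] = None
    height_m: Optional[float] = None
    alive: bool = True
    grazing_damage: bool = False

    @field_validator("stage")
    @classmethod
    def _stage_vocab(cls, v: str) -> str:
        v = str(v).strip().lower()
        if v == "seedling":
            raise ValidationError(
                "seedlings are counted per quadrat, never measured as individual stems"
            )
        return match_vocab(v, STEM_STAGES, "stage")

    @field_validator("group")
    @classmethod
    def _group_vocab(cls, v: str) -> str:
        return match_vocab(v, STEM_GROUPS, "group")

    @model_validator(mode="after")
    def _check_stage_rules(self) -> "StemRecord":
        if self.dbh_cm is not None and self.dbh_cm < 0:
            raise ValidationError(f"dbh_cm must be non-negative, got {self.dbh_cm}")
        if self.height_m is not None and self.height_m < 0:
            raise ValidationError(f"height_m must be non-negative, got {self.height_m}")
        if self.stage == "adult":
            if self.dbh_cm is None or self.dbh_cm < ADULT_DBH_MIN_CM:
                raise ValidationError(
                    f"adult stems require dbh ≥ {ADULT_DBH_MIN_CM:g} cm, got {self.dbh_cm}"
                )
        else:  # sapling
            if self.height_m is None or self.height_m <= SAPLING_HEIGHT_MIN_M:
                raise ValidationError(
                    f"saplings require height > {SAPLING_HEIGHT_MIN_M:g} m, got {self.height_m}"
                )
            if self.group == "motacu" and self.dbh_cm is not None:
                raise ValidationError(
                    "motacú saplings are acaulescent and carry no dbh measurement"
                )
            if self.dbh_cm is not None and self.dbh_cm >= ADULT_DBH_MIN_CM:
                raise ValidationError(
                    f"sapling dbh must be < {ADULT_DBH_MIN_CM:g} cm, got {self.dbh_cm}"
                )
        return self


class QuadratCover(_DomainModel):
    """Percent cover of one ground category in one 4 m² quadrat."""

    site_id: str
    plot_id: str
    quadrat_index: int
    category: str
    cover_pct: float

    @field_validator("category")
    @classmethod
    def _cat_vocab(cls, v: str) -> str:
        return match_vocab(v, GROUND_CATEGORIES, "category")

    @model_validator(mode="after")
    def _check(self) -> "QuadratCover":
        if self.quadrat_index < 1:
            raise ValidationError(f"quadrat_index must be ≥ 1, got {self.quadrat_index}")
        if not 0.0 <= self.cover_pct <= 100.0:
            raise ValidationError(f"cover_pct must lie in [0, 100], got {self.cover_pct}")
        return self


class SeedlingCount(_DomainModel):
    """Seedling tally for one group in one quadrat."""

    site_id: str
    plot_id: str
    quadrat_index: int
    group: str
    count: int

    @field_validator("group")
    @classmethod
    def _grp(cls, v: str) -> str:
        return match_vocab(v, SEEDLING_GROUPS, "group")

    @model_validator(mode="after")
    def _check(self) -> "SeedlingCount":
        if self.quadrat_index < 1:
            raise ValidationError(f"quadrat_index must be ≥ 1, got {self.quadrat_index}")
        if self.count < 0:
            raise ValidationError(f"seedling count must be ≥ 0, got {self.count}")
        return self


class InterceptRecord(_DomainModel):
    """One shrub-layer intercept interval on the 100 m transect."""

    site_id: str
    plot_id: str
    group: str
    start_m: float
    end_m: float

    @field_validator("group")
    @classmethod
    def _grp(cls, v: str) -> str:
        return match_vocab(v, SHRUB_GROUPS, "group")

    @model_validator(mode="after")
    def _check(self) -> "InterceptRecord":
        if not self.start_m < self.end_m:
            raise ValidationError(
                f"intercept requires start < end, got [{self.start_m}, {self.end_m}]"
            )
        if self.start_m < 0:
            raise ValidationError(f"intercept start must be ≥ 0, got {self.start_m}")
        return self


class TransectEffort(_DomainModel):
    """Distance and duration of one survey walk along one transect."""

    transect_id: str
    site_id: str
    survey: str
    distance_km: float
    duration_min: float

    @field_validator("survey")
    @classmethod
    def _survey(cls, v: str) -> str:
        return match_vocab(v, SURVEYS, "survey")

    @model_validator(mode="after")
    def _check(self) -> "TransectEffort":
        if self.distance_km <= 0:
            raise ValidationError(f"distance_km must be > 0, got {self.distance_km}")
        if self.duration_min <= 0:
            raise ValidationError(f"duration_min must be > 0, got {self.duration_min}")
        return self

    @property
    def n_segments(self) -> int:
        """Number of 15-minute segments this walk contributes (partial kept)."""
        import math

        return math.ceil(self.duration_min / 15.0)


class WildlifeObservation(_DomainModel):
    """One wildlife encounter on a survey walk."""

    transect_id: str
    site_id: str
    survey: str
    elapsed_min: float
    taxon_id: str
    taxon_class: str
    n_individuals: int = 1
    detection: str = "visual"

    @field_validator("survey")
    @classmethod
    def _survey(cls, v: str) -> str:
        return match_vocab(v, SURVEYS, "survey")

    @field_validator("taxon_class")
    @classmethod
    def _tclass(cls, v: str) -> str:
        return match_vocab(v, TAXON_CLASSES, "taxon_class")

    @field_validator("detection")
    @classmethod
    def _det(cls, v: str) -> str:
        return match_vocab(v, DETECTIONS, "detection")

    @model_validator(mode="after")
    def _check(self) -> "WildlifeObservation":
        if self.elapsed_min < 0:
            raise ValidationError(f"elapsed_min must be ≥ 0, got {self.elapsed_min}")
        if self.n_individuals < 1:
            raise ValidationError(f"n_individuals must be ≥ 1, got {self.n_individuals}")
        if self.taxon_class == "nocturnal_bird" and self.survey != "night":
            raise ValidationError(
                f"nocturnal birds are surveyed only at night; {self.taxon_id} recorded on a "
                f"{self.survey} walk"
            )
        return self


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

STEM_COLUMNS = [
    "site_id", "plot_id", "stage", "group", "dbh_cm", "height_m", "alive", "grazing_damage",
]
QUADRAT_COLUMNS = ["site_id", "plot_id", "quadrat_index", "category", "cover_pct"]
SEEDLING_COLUMNS = ["site_id", "plot_id", "quadrat_index", "group", "count"]
INTERCEPT_COLUMNS = ["site_id", "plot_id", "group", "start_m", "end_m"]
EFFORT_COLUMNS = ["transect_id", "site_id", "survey", "distance_km", "duration_min"]
OBSERVATION_COLUMNS = [
    "transect_id", "site_id", "survey", "elapsed_min", "taxon_id", "taxon_class",
    "n_individuals", "detection",
]


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class SurveyDataset:
    """A validated, in-memory field-survey dataset (one or more sites).

    Tables are plain DataFrames with the canonical column orders above;
    ``designs`` maps site_id to its :class:`SiteDesign`.  Use
    :func:`beniforest.io.read_survey_tables` or
    :func:`beniforest.synthetic.simulate_site` to construct one — both
    guarantee the record invariants hold.
    """

    designs: dict[str, SiteDesign]
    stems: pd.DataFrame = field(default_factory=lambda: _empty(STEM_COLUMNS))
    quadrats: pd.DataFrame = field(default_factory=lambda: _empty(QUADRAT_COLUMNS))
    seedlings: pd.DataFrame = field(default_factory=lambda: _empty(SEEDLING_COLUMNS))
    intercepts: pd.DataFrame = field(default_factory=lambda: _empty(INTERCEPT_COLUMNS))
    efforts: pd.DataFrame = field(default_factory=lambda: _empty(EFFORT_COLUMNS))
    observations: pd.DataFrame = field(default_factory=lambda: _empty(OBSERVATION_COLUMNS))

    @property
    def site_ids(self) -> list[str]:
        return list(self.designs)

    def plots(self, site_id: str) -> list[str]:
        """Canonical plot list for a site (from the design, so that plots
        with no stems still enter plot-level means as zeros)."""
        return self.designs[site_id].plot_ids()

    def site(self, site_id: str) -> "SurveyDataset":
        """Restrict the dataset to one site."""
        if site_id not in self.designs:
            raise KeyError(site_id)

        def pick(df: pd.DataFrame) -> pd.DataFrame:
            return df[df["site_id"] == site_id].reset_index(drop=True)

        return SurveyDataset(
            designs={site_id: self.designs[site_id]},
            stems=pick(self.stems),
            quadrats=pick(self.quadrats),
            seedlings=pick(self.seedlings),
            intercepts=pick(self.intercepts),
            efforts=pick(self.efforts),
            observations=pick(self.observations),
        )


def merge_datasets(datasets: list[SurveyDataset]) -> SurveyDataset:
    """Concatenate per-site datasets into one multi-site dataset."""
    designs: dict[str, SiteDesign] = {}
    for ds in datasets:
        overlap = designs.keys() & ds.designs.keys()
        if overlap:
            raise ValidationError(f"duplicate site ids when merging: {sorted(overlap)}")
        designs.update(ds.designs)

    def cat(attr: str, columns: list[str]) -> pd.DataFrame:
        frames = [getattr(ds, attr) for ds in datasets if len(getattr(ds, attr))]
        if not frames:
            return _empty(columns)
        return pd.concat(frames, ignore_index=True)[columns]

    return SurveyDataset(
        designs=designs,
        stems=cat("stems", STEM_COLUMNS),
        quadrats=cat("quadrats", QUADRAT_COLUMNS),
        seedlings=cat("seedlings", SEEDLING_COLUMNS),
        intercepts=cat("intercepts", INTERCEPT_COLUMNS),
        efforts=cat("efforts", EFFORT_COLUMNS),
        observations=cat("observations", OBSERVATION_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Whole-dataset validation
# ---------------------------------------------------------------------------

_ROW_MODELS = {
    "stems": (StemRecord, STEM_COLUMNS),
    "quadrats": (QuadratCover, QUADRAT_COLUMNS),
    "seedlings": (SeedlingCount, SEEDLING_COLUMNS),
    "intercepts": (InterceptRecord, INTERCEPT_COLUMNS),
    "efforts": (TransectEffort, EFFORT_COLUMNS),
    "observations": (WildlifeObservation, OBSERVATION_COLUMNS),
}


def _row_to_kwargs(row: Mapping, columns: list[str]) -> dict:
    out = {}
    for c in columns:
        v = row[c]
        if pd.isna(v):
            v = None
        out[c] = v
    return out


def validate_dataset(ds: SurveyDataset) -> SurveyDataset:
    """Validate every record and all cross-record invariants.

    Validation is total: the first offending record raises a located error
    (table name and row number); nothing is silently dropped.  Returns the
    dataset with canonicalised categorical values.
    """
    for table, (model, columns) in _ROW_MODELS.items():
        df = getattr(ds, table)
        missing = [c for c in columns if c not in df.columns]
        if missing:
            from .errors import SchemaError

            raise SchemaError(f"table {table!r} is missing required column(s): {missing}")
        rows = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                rec = model(**_row_to_kwargs(row._asdict(), columns))
            except (ValidationError, VocabularyError) as exc:
                raise type(exc)(f"{table} row {i + 1}: {exc}") from None
            except Exception as exc:  # pydantic wrapping
                raise ValidationError(f"{table} row {i + 1}: {exc}") from None
            rows.append(rec.model_dump())
        setattr(
            ds,
            table,
            pd.DataFrame(rows, columns=columns) if rows else _empty(columns),
        )

    # cross-record checks -------------------------------------------------
    for table in _ROW_MODELS:
        df = getattr(ds, table)
        unknown = set(df["site_id"]) - set(ds.designs)
        if unknown:
            raise ValidationError(f"{table} references unknown site id(s): {sorted(unknown)}")

    for name in ("stems", "quadrats", "seedlings", "intercepts"):
        df = getattr(ds, name)
        for site_id, sub in df.groupby("site_id"):
            valid = set(ds.designs[site_id].plot_ids())
            bad = set(sub["plot_id"]) - valid
            if bad:
                raise ValidationError(
                    f"{name}: plot id(s) {sorted(bad)} not in the {site_id} design "
                    f"({ds.designs[site_id].n_plots} plots)"
                )

    for site_id, sub in ds.intercepts.groupby("site_id"):
        L = ds.designs[site_id].transect_length_m
        over = sub[sub["end_m"] > L]
        if len(over):
            raise ValidationError(
                f"intercepts: interval end beyond the {L:g} m transect at {site_id}"
            )

    for site_id, sub in ds.quadrats.groupby("site_id"):
        qmax = ds.designs[site_id].quadrats_per_plot
        bad = sub[sub["quadrat_index"] > qmax]
        if len(bad):
            raise ValidationError(
                f"quadrats: index beyond {qmax} quadrats per plot at {site_id}"
            )

    if len(ds.observations):
        eff = ds.efforts.set_index(["transect_id", "survey"])
        for i, row in enumerate(ds.observations.itertuples(index=False)):
            key = (row.transect_id, row.survey)
            if key not in eff.index:
                raise ValidationError(
                    f"observations row {i + 1}: no effort record for transect "
                    f"{row.transect_id!r} ({row.survey})"
                )
            dur = float(eff.loc[key, "duration_min"])
            if row.elapsed_min > dur:
                raise ValidationError(
                    f"observations row {i + 1}: elapsed {row.elapsed_min} min exceeds the "
                    f"{dur:g} min walk on {row.transect_id} ({row.survey})"
                )
    return ds
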