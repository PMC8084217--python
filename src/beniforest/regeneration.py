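"""Stand structure and natural-regeneration analysis.

Implements the forest-regeneration half of the monitoring pipeline:

* per-plot densities (individuals ha⁻¹) and basal areas (m² ha⁻¹) averaged
  across the plots of each site, with sample SD (n−1) — the stand-structure
  summary table;
* size/height class distributions (1 m sapling height bands, 10 cm dbh
  bands pooling saplings and adults, 3 m adult height bands), with the
  acaulescent motacú saplings forming the smallest "dbh" band;
* life-stage composition (seedling/sapling/adult shares of a group's total
  density); and
* the Natural Regeneration index.  For species i and sapling height class
  j ∈ {1–2 m, 2–3 m, > 3 m}:

      NR_ij = (RD_ij + RF_ij) / 2,

  where RD_ij is species i's share (%) of the mean per-ha sapling density
  in class j and RF_ij its share (%) of plot occurrences in class j, both
  normalised across species within the class.  Total natural regeneration
  aggregates the classes,

      TNR_i = Σ_j NR_ij / 3.

  Reported per-class values carry the divide-by-3, so each class column
  sums to 100/3 across species and TNR values sum to 100 — the convention
  that reproduces the published table structure exactly.  Only live
  saplings taller than 1 m enter; broadleaf saplings with dbh ≥ 5 cm are
  excluded (advanced regeneration focus), motacú saplings all enter.

All binning is left-closed/right-open; a stem of exactly 10 cm dbh is an
adult.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SurveyDataError
from .model import STEM_GROUPS, SiteDesign, SurveyDataset

DEFAULT_NR_CLASS_EDGES = (1.0, 2.0, 3.0)  # lower edges; last class is open-ended
DEFAULT_BROADLEAF_DBH_MAX_CM = 5.0

CLASS_SCHEMES = ("sapling_height_1m", "stem_dbh_10cm", "adult_height_3m")

_STAGE_AREA_ATTR = {
    "adult": "adult_subplot_area_m2",
    "sapling": "sapling_subplot_area_m2",
    "seedling": "seedling_area_m2",
}


def stem_basal_area(dbh_cm: float) -> float:
    """Cross-sectional area at breast height, m², from dbh in cm.

    Area = π r² with r = dbh/2 converted to metres, i.e. π (dbh/200)².
    """
    if dbh_cm < 0:
        raise ParameterError(f"dbh must be non-negative, got {dbh_cm}")
    return math.pi * (dbh_cm / 200.0) ** 2


def density_per_ha(count: float, sampled_area_m2: float) -> float:
    """Scale a count in ``sampled_area_m2`` to individuals per hectare."""
    if sampled_area_m2 <= 0:
        raise ParameterError(f"sampled area must be > 0, got {sampled_area_m2}")
    return count * 10_000.0 / sampled_area_m2


def stage_area_m2(design: SiteDesign, stage: str) -> float:
    """Sampling frame for a life stage: adults 400 m², saplings 200 m²,
    seedlings the summed quadrat area (20 m²), under the default design."""
    return float(getattr(design, _STAGE_AREA_ATTR[stage]))


# ---------------------------------------------------------------------------
# Plot-level densities
# ---------------------------------------------------------------------------


def _summary_class(row_group: str, alive: bool) -> str:
    """Reporting class: live stems keep their group, snags get their own."""
    return row_group if alive else f"{row_group}_snag"


def _plot_values(
    ds: SurveyDataset, site_id: str, stage: str, per_stem_value
) -> pd.DataFrame:
    """Per-plot, per-reporting-class totals of ``per_stem_value`` for one
    stage, on the full (plot × class) grid so empty plots count as zero."""
    design = ds.designs[site_id]
    plots = design.plot_ids()
    stems = ds.stems
    sub = stems[(stems["site_id"] == site_id) & (stems["stage"] == stage)]
    classes = sorted({_summary_class(g, a) for g, a in zip(sub["group"], sub["alive"])})
    grid = pd.DataFrame(
        0.0, index=pd.Index(plots, name="plot_id"), columns=pd.Index(classes, name="class")
    )
    for row in sub.itertuples(index=False):
        grid.loc[row.plot_id, _summary_class(row.group, row.alive)] += per_stem_value(row)
    return grid


def _seedling_plot_densities(ds: SurveyDataset, site_id: str) -> pd.DataFrame:
    design = ds.designs[site_id]
    plots = design.plot_ids()
    sub = ds.seedlings[ds.seedlings["site_id"] == site_id]
    # "woody" seedlings are broadleaf recruits; report them under that group
    groups = sorted({"broadleaf" if g == "woody" else g for g in sub["group"]})
    grid = pd.DataFrame(
        0.0, index=pd.Index(plots, name="plot_id"), columns=pd.Index(groups, name="class")
    )
    for row in sub.itertuples(index=False):
        g = "broadleaf" if row.group == "woody" else row.group
        grid.loc[row.plot_id, g] += row.count
    return grid * 10_000.0 / design.seedling_area_m2


@dataclass
class StageSummary:
    """Stand-structure summary: one row per (site, stage, reporting class)."""

    table: pd.DataFrame

    COLUMNS = [
        "site_id", "stage", "group",
        "mean_density_per_ha", "sd_density",
        "pct_of_stage_total",
        "mean_basal_area_m2_ha", "sd_basal_area",
        "pct_of_stage_ba",
    ]


def site_stage_summary(ds: SurveyDataset) -> StageSummary:
    """Mean ± SD density and basal area per (site, stage, group).

    Per plot, counts and summed stem basal areas are scaled to per-hectare
    using each stage's sampling frame, then averaged across the site's
    plots (sample SD, n−1 denominator; a single plot gives SD 0).
    Composition percentages are shares of the stage total including snag
    classes.  Motacú saplings are acaulescent and contribute no basal
    area; a stage whose basal area is partly unmeasurable reports no BA
    composition.
    """
    rows = []
    for site_id, design in ds.designs.items():
        if design.n_plots < 1:
            raise SurveyDataError(f"site {site_id} has no plots")
        for stage in ("seedling", "sapling", "adult"):
            if stage == "seedling":
                dens = _seedling_plot_densities(ds, site_id)
                ba = None
            else:
                area = stage_area_m2(design, stage)
                counts = _plot_values(ds, site_id, stage, lambda r: 1.0)
                dens = counts * 10_000.0 / area

                def _ba(row):
                    if row.group == "motacu" and row.stage == "sapling":
                        return math.nan  # acaulescent: no dbh, no basal area
                    if row.dbh_cm is None or (
                        isinstance(row.dbh_cm, float) and math.isnan(row.dbh_cm)
                    ):
                        return math.nan
                    return stem_basal_area(row.dbh_cm)

                ba = _plot_values(ds, site_id, stage, _ba) * 10_000.0 / area

            if dens.shape[1] == 0:
                continue
            mean_d = dens.mean(axis=0)
            sd_d = dens.std(axis=0, ddof=1) if len(dens) > 1 else mean_d * 0.0
            total_d = mean_d.sum()
            pct_d = mean_d / total_d * 100.0 if total_d > 0 else mean_d * np.nan

            if ba is not None:
                mean_b = ba.mean(axis=0)
                sd_b = ba.std(axis=0, ddof=1) if len(ba) > 1 else mean_b * 0.0
                if mean_b.isna().any():
                    pct_b = mean_b * np.nan
                else:
                    tot = mean_b.sum()
                    pct_b = mean_b / tot * 100.0 if tot > 0 else mean_b * np.nan

            for cls in dens.columns:
                rows.append(
                    {
                        "site_id": site_id,
                        "stage": stage,
                        "group": cls,
                        "mean_density_per_ha": float(mean_d[cls]),
                        "sd_density": float(sd_d[cls]),
                        "pct_of_stage_total": float(pct_d[cls]) if total_d > 0 else math.nan,
                        "mean_basal_area_m2_ha": float(mean_b[cls]) if ba is not None else math.nan,
                        "sd_basal_area": float(sd_b[cls]) if ba is not None else math.nan,
                        "pct_of_stage_ba": float(pct_b[cls]) if ba is not None else math.nan,
                    }
                )
    return StageSummary(pd.DataFrame(rows, columns=StageSummary.COLUMNS))


# ---------------------------------------------------------------------------
# Class distributions
# ---------------------------------------------------------------------------

ACAULESCENT_BAND = "acaulescent"
UNMEASURED_BAND = "unmeasured"


@dataclass
class ClassDistribution:
    """Banded stem counts per (site, group, band), mean ± SD per ha.

    ``bands`` are contiguous left-closed intervals; the motacú dbh scheme
    places all acaulescent saplings in a flagged first band and any stem
    missing its binning measurement lands in an explicit ``unmeasured``
    bucket rather than being dropped.
    """

    scheme: str
    width: float
    table: pd.DataFrame  # site_id, group, band, band_low, band_high, mean_per_ha, sd

    def band_total_count(self, counts: pd.DataFrame) -> float:  # pragma: no cover
        return counts["mean_per_ha"].sum()


def _band_label(low: float, width: float) -> str:
    return f"[{low:g},{low + width:g})"


def class_distribution(
    ds: SurveyDataset, scheme: str, include_dead: bool = False
) -> ClassDistribution:
    """Bin stems of each site/group into size or height bands.

    Schemes: ``sapling_height_1m`` (live saplings, 1 m height bands),
    ``stem_dbh_10cm`` (saplings + adults, 10 cm dbh bands; acaulescent
    motacú saplings form the first band), ``adult_height_3m`` (adults,
    3 m height bands — measured for motacú only; others are unmeasured).
    Returns per-ha mean and sample SD across plots.
    """
    if scheme not in CLASS_SCHEMES:
        raise ParameterError(f"unknown scheme {scheme!r}; expected one of {CLASS_SCHEMES}")
    width = {"sapling_height_1m": 1.0, "stem_dbh_10cm": 10.0, "adult_height_3m": 3.0}[scheme]

    stems = ds.stems
    rows = []
    for site_id, design in ds.designs.items():
        plots = design.plot_ids()
        sub = stems[stems["site_id"] == site_id]
        if not include_dead:
            sub = sub[sub["alive"]]
        if scheme == "sapling_height_1m":
            sub = sub[sub["stage"] == "sapling"]
        elif scheme == "adult_height_3m":
            sub = sub[sub["stage"] == "adult"]

        for group, gsub in sub.groupby("group"):
            # per plot: band -> count, plus area weighting by stage
            per_plot: dict[str, dict[str, float]] = {p: {} for p in plots}
            bands_seen: set[str] = set()
            for r in gsub.itertuples(index=False):
                area = stage_area_m2(design, r.stage)
                if scheme == "stem_dbh_10cm":
                    value = r.dbh_cm
                    if r.stage == "sapling" and group == "motacu":
                        band = ACAULESCENT_BAND
                    elif value is None or (isinstance(value, float) and math.isnan(value)):
                        band = UNMEASURED_BAND
                    else:
                        band = _band_label(math.floor(value / width) * width, width)
                else:
                    value = r.height_m
                    if value is None or (isinstance(value, float) and math.isnan(value)):
                        band = UNMEASURED_BAND
                    else:
                        band = _band_label(math.floor(value / width) * width, width)
                bands_seen.add(band)
                per_plot[r.plot_id][band] = per_plot[r.plot_id].get(band, 0.0) + 10_000.0 / area

            def _band_key(b: str) -> tuple[int, float]:
                if b == ACAULESCENT_BAND:
                    return (-1, 0.0)
                if b == UNMEASURED_BAND:
                    return (1, math.inf)
                return (0, float(b[1:].split(",")[0]))

            for band in sorted(bands_seen, key=_band_key):
                vals = np.array([per_plot[p].get(band, 0.0) for p in plots])
                low = high = math.nan
                if band not in (ACAULESCENT_BAND, UNMEASURED_BAND):
                    low = float(band[1:].split(",")[0])
                    high = low + width
                rows.append(
                    {
                        "site_id": site_id,
                        "group": group,
                        "band": band,
                        "band_low": low,
                        "band_high": high,
                        "mean_per_ha": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["site_id", "group", "band", "band_low", "band_high", "mean_per_ha", "sd"],
    )
    return ClassDistribution(scheme=scheme, width=width, table=table)


# ---------------------------------------------------------------------------
# Life-stage composition
# ---------------------------------------------------------------------------


def compose_stages(densities: dict[str, float]) -> dict:
    """Total density across life stages plus integer-rounded stage shares.

    ``densities`` maps stage → mean per-ha density.  An all-zero input has
    undefined shares (returned as None).
    """
    total = float(sum(densities.values()))
    if total <= 0:
        return {"total_per_ha": 0.0, "pct": {k: None for k in densities}}
    pct = {k: round(v / total * 100.0) for k, v in densities.items()}
    return {"total_per_ha": total, "pct": pct}


def life_stage_composition(ds: SurveyDataset) -> pd.DataFrame:
    """Per (site, group): summed mean density over stages and stage shares.

    Shares are reported rounded to integer percent, matching the study's
    style ("88% seedlings, 10% saplings, 2% adults").  Snags are excluded.
    """
    summary = site_stage_summary(ds).table
    live = summary[~summary["group"].str.endswith("_snag")]
    rows = []
    for (site_id, group), sub in live.groupby(["site_id", "group"]):
        dens = {
            stage: float(sub.loc[sub["stage"] == stage, "mean_density_per_ha"].sum())
            for stage in ("seedling", "sapling", "adult")
        }
        comp = compose_stages(dens)
        rows.append(
            {
                "site_id": site_id,
                "group": group,
                "total_per_ha": comp["total_per_ha"],
                "pct_seedling": comp["pct"]["seedling"],
                "pct_sapling": comp["pct"]["sapling"],
                "pct_adult": comp["pct"]["adult"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Natural Regeneration index
# ---------------------------------------------------------------------------


def total_regeneration(per_class_nr: "list[float] | tuple[float, ...]") -> float:
    """Aggregate reported per-class NR percentages into TNR (their sum).

    On the reported scale each class value already carries the 1/3 class
    weight, so TNR is simply the row sum.
    """
    return float(sum(per_class_nr))


@dataclass
class NRTable:
    """Natural-regeneration index results for one or more sites.

    ``table`` holds the reported scale (per-class columns sum to 100/3
    over groups, TNR to 100 per site); ``rd``, ``rf`` and ``nr_raw`` are
    the within-class intermediates ((RD+RF)/2 before the 1/3 weight).
    """

    classes: list[str]
    table: pd.DataFrame  # site_id, group, nr_<class>..., tnr_pct
    rd: pd.DataFrame
    rf: pd.DataFrame
    nr_raw: pd.DataFrame


def _class_label(lo: float, hi: float | None) -> str:
    return f"{lo:g}-{hi:g}m" if hi is not None else f">{lo:g}m"


def nr_table(
    ds: SurveyDataset,
    class_edges: tuple[float, ...] = DEFAULT_NR_CLASS_EDGES,
    broadleaf_dbh_max_cm: float = DEFAULT_BROADLEAF_DBH_MAX_CM,
) -> NRTable:
    """Compute the Natural Regeneration table per site.

    Live saplings taller than the first class edge (1 m) enter; broadleaf
    saplings with a measured dbh at or above ``broadleaf_dbh_max_cm`` are
    excluded, motacú saplings are always included.  A height class empty
    across all groups contributes zero and emits a warning; a site with
    every class empty is an error.
    """
    if len(class_edges) < 1:
        raise ParameterError("need at least one class edge")
    edges = sorted(class_edges)
    n_classes = len(edges)
    labels = [
        _class_label(edges[i], edges[i + 1] if i + 1 < n_classes else None)
        for i in range(n_classes)
    ]

    stems = ds.stems
    rows, rd_rows, rf_rows, raw_rows = [], [], [], []
    for site_id, design in ds.designs.items():
        plots = design.plot_ids()
        area = stage_area_m2(design, "sapling")
        sub = stems[
            (stems["site_id"] == site_id)
            & (stems["stage"] == "sapling")
            & (stems["alive"])
        ].copy()
        # eligibility: height above first edge; broadleaf dbh screen
        sub = sub[sub["height_m"] > edges[0]]
        dbh = pd.to_numeric(sub["dbh_cm"], errors="coerce")
        keep = (sub["group"] == "motacu") | dbh.isna() | (dbh < broadleaf_dbh_max_cm)
        sub = sub[keep]
        if not len(sub):
            raise SurveyDataError(
                f"site {site_id}: no eligible live saplings in any height class"
            )
        groups = sorted(sub["group"].unique())

        def class_index(h: float) -> int:
            i = np.searchsorted(edges, h, side="right") - 1
            return int(i)

        # per (group, class): mean per-ha density and plot occurrence count
        dens = np.zeros((len(groups), n_classes))
        occ = np.zeros((len(groups), n_classes))
        for gi, g in enumerate(groups):
            gsub = sub[sub["group"] == g]
            for j in range(n_classes):
                per_plot = {p: 0 for p in plots}
                for r in gsub.itertuples(index=False):
                    if class_index(r.height_m) == j:
                        per_plot[r.plot_id] += 1
                counts = np.array([per_plot[p] for p in plots], dtype=float)
                dens[gi, j] = (counts * 10_000.0 / area).mean()
                occ[gi, j] = (counts > 0).sum()

        empty = dens.sum(axis=0) == 0
        for j in np.flatnonzero(empty):
            warnings.warn(
                f"site {site_id}: height class {labels[j]} holds no eligible saplings; "
                "it contributes zero to NR",
                stacklevel=2,
            )

        with np.errstate(invalid="ignore", divide="ignore"):
            rd = np.where(dens.sum(axis=0) > 0, dens / dens.sum(axis=0) * 100.0, 0.0)
            rf = np.where(occ.sum(axis=0) > 0, occ / occ.sum(axis=0) * 100.0, 0.0)
        nr_raw = (rd + rf) / 2.0
        nr_reported = nr_raw / n_classes

        for gi, g in enumerate(groups):
            row = {"site_id": site_id, "group": g}
            for j, lab in enumerate(labels):
                row[f"nr_{lab}"] = float(nr_reported[gi, j])
            row["tnr_pct"] = total_regeneration(nr_reported[gi, :])
            rows.append(row)
            for store, mat in ((rd_rows, rd), (rf_rows, rf), (raw_rows, nr_raw)):
                rec = {"site_id": site_id, "group": g}
                rec.update({labels[j]: float(mat[gi, j]) for j in range(n_classes)})
                store.append(rec)

    return NRTable(
        classes=labels,
        table=pd.DataFrame(rows),
        rd=pd.DataFrame(rd_rows),
        rf=pd.DataFrame(rf_rows),
        nr_raw=pd.DataFrame(raw_rows),
    )
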