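"""Understory cover matrices and standardized principal components analysis.

The shrub layer is summarised per plot as the percent of the 100 m
transect intercepted by each of five functional groups (overlapping
intervals of a group are merged before summing — cover is a union length).
The ground layer is summarised per plot as the mean of the five quadrat
percentages per category, optionally with a derived total-plant-cover
column (forbs + ferns + graminoids).

Both matrices feed the same ordination: columns are z-scored to zero mean
and unit variance (n−1 SD) and the correlation matrix is
eigendecomposed.  Axes are retained by the latent-root criterion
(eigenvalue > 1); loadings are eigenvectors scaled by √eigenvalue, i.e.
variable–axis correlations, and variables with |loading| > 0.5 are the
salient set of each axis.  Per-site centroids and SDs of the first two
axis scores parameterise the (axis-aligned) 1-SD site ellipses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SurveyDataError, ValidationError
from .model import GROUND_CATEGORIES, SHRUB_GROUPS, SurveyDataset

LOADING_THRESHOLD = 0.5
LATENT_ROOT = 1.0

#: derived ground variable: summed cover of the three plant groups
TOTAL_PLANT_COVER = "total_plant_cover"
_PLANT_CATEGORIES = ("forbs", "ferns", "graminoids")

DEFAULT_GROUND_COLUMNS = list(GROUND_CATEGORIES) + [TOTAL_PLANT_COVER]


def merged_length(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of possibly overlapping intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total, cur_lo, cur_hi = 0.0, *intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


def shrub_cover_matrix(ds: SurveyDataset) -> pd.DataFrame:
    """Plot × functional-group percent cover from line intercepts.

    Rows are indexed by (site_id, plot_id) over every plot in the designs;
    plots without intercepts of a group score 0 for it.
    """
    index = pd.MultiIndex.from_tuples(
        [(s, p) for s, d in ds.designs.items() for p in d.plot_ids()],
        names=["site_id", "plot_id"],
    )
    mat = pd.DataFrame(0.0, index=index, columns=list(SHRUB_GROUPS))
    for (site_id, plot_id, group), sub in ds.intercepts.groupby(
        ["site_id", "plot_id", "group"]
    ):
        L = ds.designs[site_id].transect_length_m
        if (sub["end_m"] > L).any() or (sub["start_m"] < 0).any():
            raise ValidationError(
                f"intercept outside [0, {L:g}] m on {site_id}/{plot_id}"
            )
        length = merged_length(list(zip(sub["start_m"], sub["end_m"])))
        mat.loc[(site_id, plot_id), group] = length / L * 100.0
    return mat


def ground_cover_matrix(
    ds: SurveyDataset, columns: list[str] | None = None
) -> pd.DataFrame:
    """Plot × category percent cover: mean of each plot's five quadrats.

    ``columns`` selects/derives the variable set (default: the 8 recorded
    categories plus total plant cover).  A plot missing part of its
    quadrat set is an error naming the plot.
    """
    if columns is None:
        columns = DEFAULT_GROUND_COLUMNS
    index = pd.MultiIndex.from_tuples(
        [(s, p) for s, d in ds.designs.items() for p in d.plot_ids()],
        names=["site_id", "plot_id"],
    )
    base = pd.DataFrame(np.nan, index=index, columns=list(GROUND_CATEGORIES))
    for (site_id, plot_id), sub in ds.quadrats.groupby(["site_id", "plot_id"]):
        nq = ds.designs[site_id].quadrats_per_plot
        counts = sub.groupby("category")["quadrat_index"].nunique()
        short = [c for c in GROUND_CATEGORIES if counts.get(c, 0) != nq]
        if short:
            raise SurveyDataError(
                f"plot {site_id}/{plot_id}: incomplete quadrat set for "
                f"categories {short} (need all {nq} quadrats)"
            )
        means = sub.groupby("category")["cover_pct"].mean()
        for c in GROUND_CATEGORIES:
            base.loc[(site_id, plot_id), c] = means[c]
    if base.isna().any().any():
        missing = base.index[base.isna().any(axis=1)].tolist()
        raise SurveyDataError(f"no quadrat records for plot(s): {missing}")
    out = pd.DataFrame(index=index)
    for c in columns:
        if c == TOTAL_PLANT_COVER:
            out[c] = base[list(_PLANT_CATEGORIES)].sum(axis=1)
        elif c in base.columns:
            out[c] = base[c]
        else:
            raise SurveyDataError(f"unknown ground-cover column {c!r}")
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a plot × variable cover matrix."""

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    retained_axes: list[int]  # 1-based axis numbers with eigenvalue > 1
    scores: pd.DataFrame  # plots × PC1..PCp
    loadings: pd.DataFrame  # variables × PC1..PCp
    salient: dict[int, dict[str, float]]  # axis -> {variable: loading} with |l| > 0.5
    group_summary: pd.DataFrame  # per site: centroid & SD on PC1, PC2
    dropped_columns: list[str] = field(default_factory=list)
    eigenvectors: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Standardized (correlation-matrix) PCA with the study's conventions.

    Columns are z-scored (n−1 SD); zero-variance columns are dropped with
    a warning.  Axes are sorted by descending eigenvalue and sign-flipped
    so each axis's largest-magnitude loading is positive, making the
    output deterministic and row-order invariant.
    """
    if len(matrix) < 2:
        raise SurveyDataError(f"PCA needs at least 2 rows, got {len(matrix)}")
    X = matrix.astype(float)
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping zero-variance column(s) before standardization: {constant}",
            stacklevel=2,
        )
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise SurveyDataError("all columns are constant; nothing to ordinate")

    variables = list(X.columns)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.asarray(Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    loadings = eigvec * np.sqrt(eigval)
    # sign convention: dominant loading positive on every axis
    for j in range(loadings.shape[1]):
        col = loadings[:, j] if eigval[j] > 0 else eigvec[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            eigvec[:, j] *= -1
            loadings[:, j] *= -1

    scores = np.asarray(Z) @ eigvec
    axes = [f"PC{j + 1}" for j in range(len(variables))]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=axes)
    loadings_df = pd.DataFrame(loadings, index=variables, columns=axes)

    retained = [j + 1 for j, ev in enumerate(eigval) if ev > LATENT_ROOT]
    salient = {
        j + 1: {
            v: float(loadings_df.iloc[i, j])
            for i, v in enumerate(variables)
            if abs(loadings_df.iloc[i, j]) > LOADING_THRESHOLD
        }
        for j in range(len(variables))
    }

    # site centroids and SDs on the first two axes
    rows = []
    if isinstance(matrix.index, pd.MultiIndex) and "site_id" in matrix.index.names:
        pc_cols = axes[: min(2, len(axes))]
        for site_id, sub in scores_df.groupby(level="site_id", sort=True):
            row = {"site_id": site_id}
            for c in pc_cols:
                row[f"centroid_{c.lower()}"] = float(sub[c].mean())
                row[f"sd_{c.lower()}"] = (
                    float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
                )
            rows.append(row)
    group_summary = pd.DataFrame(rows)

    return PCAResult(
        eigenvalues=eigval,
        variance_fraction=eigval / eigval.sum(),
        retained_axes=retained,
        scores=scores_df,
        loadings=loadings_df,
        salient=salient,
        group_summary=group_summary,
        dropped_columns=constant,
        eigenvectors=eigvec,
    )
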