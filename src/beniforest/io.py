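"""CSV input/output for survey datasets and pipeline results.

All tables are UTF-8 CSV with a header row and "." decimal point.  The
canonical file names inside a dataset directory are::

    stems.csv intercepts.csv quadrats.csv seedlings.csv
    efforts.csv observations.csv taxa.csv (optional annotation)
    design.json

Reading validates every record; writing then reading a validated dataset
reproduces all field values exactly (floats are written at full precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import SchemaError
from .model import (
    EFFORT_COLUMNS,
    INTERCEPT_COLUMNS,
    OBSERVATION_COLUMNS,
    QUADRAT_COLUMNS,
    SEEDLING_COLUMNS,
    STEM_COLUMNS,
    SiteDesign,
    SurveyDataset,
    validate_dataset,
)

DATASET_FILES = {
    "stems": ("stems.csv", STEM_COLUMNS),
    "quadrats": ("quadrats.csv", QUADRAT_COLUMNS),
    "seedlings": ("seedlings.csv", SEEDLING_COLUMNS),
    "intercepts": ("intercepts.csv", INTERCEPT_COLUMNS),
    "efforts": ("efforts.csv", EFFORT_COLUMNS),
    "observations": ("observations.csv", OBSERVATION_COLUMNS),
}

_BOOL_COLUMNS = {"stems": ["alive", "grazing_damage"]}


def _read_table(path: Path, columns: list[str], table: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"missing survey table: {path}") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    for c in _BOOL_COLUMNS.get(table, []):
        if df[c].dtype == object:
            df[c] = df[c].map(
                lambda v: str(v).strip().lower() in ("true", "1", "yes", "t")
            )
    return df[columns]


def read_survey_tables(
    source: str | Path | Mapping[str, str | Path],
    designs: Iterable[SiteDesign],
) -> SurveyDataset:
    """Load and validate a survey dataset.

    Parameters
    ----------
    source
        Either a directory containing the canonical file names, or a
        mapping table-name → path (``{"stems": ..., "quadrats": ...}``).
        Missing optional tables load as empty.
    designs
        One :class:`SiteDesign` per site present in the data.
    """
    designs = list(designs)
    paths: dict[str, Path] = {}
    if isinstance(source, (str, Path)):
        root = Path(source)
        for table, (fname, _) in DATASET_FILES.items():
            p = root / fname
            if p.exists():
                paths[table] = p
    else:
        paths = {k: Path(v) for k, v in source.items()}
        unknown = set(paths) - set(DATASET_FILES)
        if unknown:
            raise SchemaError(f"unknown table name(s): {sorted(unknown)}")

    kwargs = {}
    for table, (fname, columns) in DATASET_FILES.items():
        if table in paths:
            kwargs[table] = _read_table(paths[table], columns, table)
    ds = SurveyDataset(designs={d.site_id: d for d in designs}, **kwargs)
    return validate_dataset(ds)


def write_dataset(ds: SurveyDataset, out_dir: str | Path) -> list[Path]:
    """Write a dataset to the canonical CSV layout plus ``design.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for table, (fname, columns) in DATASET_FILES.items():
        p = out / fname
        getattr(ds, table)[columns].to_csv(p, index=False)
        written.append(p)
    p = out / "design.json"
    p.write_text(
        json.dumps(
            {sid: d.model_dump() for sid, d in ds.designs.items()},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    written.append(p)
    return written


def read_designs(path: str | Path) -> list[SiteDesign]:
    """Load the ``design.json`` written by :func:`write_dataset`."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return [SiteDesign(**v) for v in raw.values()]


def read_dataset(in_dir: str | Path) -> SurveyDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(in_dir)
    return read_survey_tables(root, read_designs(root / "design.json"))


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------


def _versions() -> dict[str, str]:
    import numpy
    import scipy

    from . import __version__

    return {
        "beniforest": __version__,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def write_outputs(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> list[Path]:
    """Write result tables as CSV plus a run-metadata JSON.

    Column order of each table is preserved as given; re-running with the
    same inputs produces byte-identical files (no timestamps are written).
    An empty ``results`` mapping still produces the metadata file.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    written = []
    for name, df in results.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    meta = {
        "config": config or {},
        "seed": seed,
        "tables": sorted(results),
        "versions": _versions(),
    }
    p = out / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(p)
    return written
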