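"""Readers, writers and validation for the tabular formats of the pipeline.

Every table is a long ("tidy") CSV, UTF-8, ``.`` decimal separator. The
mandatory column sets are fixed (see the ``*_COLUMNS`` constants); unknown
extra columns are ignored with a logged warning so that instrument exports
carrying extra annotation still load.

Dataset containers are thin wrappers around :class:`pandas.DataFrame` that
carry their validated invariants:

* :class:`PlateDataset` -- plate-reader OD time series plus strain metadata,
  one row per (strain, replicate, temperature, time) observation.
* :class:`CfuDataset` -- viability assay counts (total and spore CFU/ml) per
  strain, incubation temperature and replicate.
* :class:`ColonyTable` -- colony diameters (three colonies per strain x
  temperature x incubation time; diameter 0 encodes "no growth observed").

Validation is total: every malformed input raises a typed error
(:class:`~thermonorms.errors.SchemaError` or
:class:`~thermonorms.errors.ValidationError`), never a silent drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

LINEAGES = ("Bc", "Bs")
ENVIRONMENTS = ("T", "H", "LAB")

PLATE_COLUMNS = ("strain_id", "replicate", "temperature_c", "time_h", "od")
META_COLUMNS = ("strain_id", "lineage", "environment")
#: optional metadata column: a per-plate blank OD subtracted before fitting
META_BLANK_COLUMN = "blank_od"
CFU_COLUMNS = ("strain_id", "temperature_c", "replicate", "total_cfu_ml", "spore_cfu_ml")
COLONY_COLUMNS = ("strain_id", "temperature_c", "time_h", "colony_index", "diameter_mm")

#: spore counts may exceed totals by up to this relative excess (plating
#: noise); beyond it the record is considered irreconcilable.
SPORE_EXCESS_TOLERANCE = 0.10

RUN_PARAMS_FILENAME = "run_params.yaml"
MANIFEST_FILENAME = "manifest.txt"


# ---------------------------------------------------------------------------
# containers


@dataclass(eq=False)
class PlateDataset:
    """Validated plate-reader OD series with attached strain metadata."""

    data: pd.DataFrame
    meta: pd.DataFrame

    @property
    def strain_ids(self) -> list[str]:
        return list(self.meta["strain_id"])

    @property
    def temperatures(self) -> np.ndarray:
        return np.unique(self.data["temperature_c"].to_numpy())

    def n_series(self) -> int:
        return self.data.groupby(["strain_id", "replicate", "temperature_c"]).ngroups

    def iter_series(self) -> Iterator[tuple[str, int, float, np.ndarray, np.ndarray]]:
        """Yield (strain_id, replicate, temperature_c, times, od) per series."""
        keys = ["strain_id", "replicate", "temperature_c"]
        for (strain, rep, temp), grp in self.data.groupby(keys, sort=True):
            yield (
                str(strain),
                int(rep),
                float(temp),
                grp["time_h"].to_numpy(float),
                grp["od"].to_numpy(float),
            )

    def blank_for(self, strain_id: str) -> float | None:
        """Per-plate blank OD from metadata, or None when not declared."""
        if META_BLANK_COLUMN not in self.meta.columns:
            return None
        row = self.meta.loc[self.meta["strain_id"] == strain_id, META_BLANK_COLUMN]
        if row.empty or pd.isna(row.iloc[0]):
            return None
        return float(row.iloc[0])


@dataclass(eq=False)
class CfuDataset:
    """Validated CFU viability assay. ``spore_excess`` flags records whose
    spore count exceeded the total (retained; capped downstream)."""

    data: pd.DataFrame

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.data["strain_id"].unique())

    def for_strain(self, strain_id: str) -> pd.DataFrame:
        return self.data[self.data["strain_id"] == strain_id]


@dataclass(eq=False)
class ColonyTable:
    """Validated colony-diameter measurements (<=3 colonies per condition)."""

    data: pd.DataFrame


# ---------------------------------------------------------------------------
# validation


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing mandatory column(s): {', '.join(missing)}")


def _drop_unknown(df: pd.DataFrame, known: tuple[str, ...], what: str) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("%s table: ignoring unknown column(s) %s", what, unknown)
    return df[[c for c in df.columns if c in known]]


def _coerce_numeric(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise SchemaError(f"{what} table: column '{col}' contains non-numeric values")
        df[col] = coerced
    return df


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    _require_columns(meta, META_COLUMNS, "metadata")
    keep = META_COLUMNS + (META_BLANK_COLUMN,)
    meta = _drop_unknown(meta, keep, "metadata")
    if meta["strain_id"].duplicated().any():
        dupes = meta.loc[meta["strain_id"].duplicated(), "strain_id"].tolist()
        raise ValidationError(f"duplicate strain_id in metadata: {dupes}")
    bad_lineage = set(meta["lineage"]) - set(LINEAGES)
    if bad_lineage:
        raise ValidationError(f"unknown lineage value(s) {sorted(bad_lineage)}; allowed: {LINEAGES}")
    bad_env = set(meta["environment"]) - set(ENVIRONMENTS)
    if bad_env:
        raise ValidationError(
            f"unknown environment value(s) {sorted(bad_env)}; allowed: {ENVIRONMENTS}"
        )
    return meta.reset_index(drop=True)


def validate_plate(data: pd.DataFrame, meta: pd.DataFrame) -> PlateDataset:
    """Validate a long plate table against its metadata and wrap it.

    Enforces: every strain present in metadata; no duplicated
    (strain, replicate, temperature, time) rows; strictly increasing times
    and >= 2 points within each series; non-negative OD and times.
    """
    _require_columns(data, PLATE_COLUMNS, "plate")
    data = _drop_unknown(data, PLATE_COLUMNS, "plate")
    data = _coerce_numeric(data, ("replicate", "temperature_c", "time_h", "od"), "plate")
    meta = validate_meta(meta)

    unknown_strains = set(data["strain_id"]) - set(meta["strain_id"])
    if unknown_strains:
        raise ValidationError(f"plate strains absent from metadata: {sorted(unknown_strains)}")
    if (data["replicate"] < 1).any():
        raise ValidationError("replicate indices must be >= 1")
    if (data["time_h"] < 0).any() or (data["od"] < 0).any():
        raise ValidationError("time_h and od must be non-negative")

    key = ["strain_id", "replicate", "temperature_c", "time_h"]
    if data.duplicated(subset=key).any():
        first = data[data.duplicated(subset=key)].iloc[0]
        raise ValidationError(
            "duplicated observation row for series "
            f"({first['strain_id']}, rep {int(first['replicate'])}, "
            f"{first['temperature_c']} C) at t={first['time_h']} h"
        )
    for (strain, rep, temp), grp in data.groupby(["strain_id", "replicate", "temperature_c"]):
        t = grp["time_h"].to_numpy(float)
        if len(t) < 2:
            raise ValidationError(
                f"series ({strain}, rep {int(rep)}, {temp} C) has fewer than 2 time points"
            )
        if not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"non-monotone times in series ({strain}, rep {int(rep)}, {temp} C)"
            )
    return PlateDataset(data=data.reset_index(drop=True), meta=meta)


def validate_cfu(data: pd.DataFrame) -> CfuDataset:
    """Validate a CFU table. Zero totals (complete kill) are allowed; spore
    counts above total are flagged up to +10% relative excess and rejected
    beyond it."""
    _require_columns(data, CFU_COLUMNS, "CFU")
    data = _drop_unknown(data, CFU_COLUMNS, "CFU")
    data = _coerce_numeric(
        data, ("temperature_c", "replicate", "total_cfu_ml", "spore_cfu_ml"), "CFU"
    )
    if (data["total_cfu_ml"] < 0).any() or (data["spore_cfu_ml"] < 0).any():
        raise ValidationError("CFU counts must be non-negative")
    data = data.copy()
    total = data["total_cfu_ml"].to_numpy(float)
    spore = data["spore_cfu_ml"].to_numpy(float)
    excess = spore > total
    beyond = spore > total * (1.0 + SPORE_EXCESS_TOLERANCE)
    # spore > 0 with total == 0 is irreconcilable at any tolerance
    beyond |= (total == 0) & (spore > 0)
    if beyond.any():
        bad = data.loc[beyond].iloc[0]
        raise ValidationError(
            f"spore CFU exceeds total by more than {SPORE_EXCESS_TOLERANCE:.0%} "
            f"for strain {bad['strain_id']} at {bad['temperature_c']} C"
        )
    data["spore_excess"] = excess
    if excess.any():
        log.warning("CFU table: %d record(s) with spore > total flagged (retained)", excess.sum())
    return CfuDataset(data=data.reset_index(drop=True))


def validate_colony(data: pd.DataFrame) -> ColonyTable:
    _require_columns(data, COLONY_COLUMNS, "colony")
    data = _drop_unknown(data, COLONY_COLUMNS, "colony")
    data = _coerce_numeric(data, ("temperature_c", "time_h", "colony_index", "diameter_mm"), "colony")
    if (data["diameter_mm"] < 0).any():
        raise ValidationError("colony diameters must be >= 0")
    counts = data.groupby(["strain_id", "temperature_c", "time_h"]).size()
    if (counts > 3).any():
        key = counts[counts > 3].index[0]
        raise ValidationError(f"more than 3 colonies recorded for {key}")
    return ColonyTable(data=data.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return pd.read_csv(path)


def read_plate_table(path: str | Path, meta_path: str | Path) -> PlateDataset:
    """Read a long-format plate CSV and its strain metadata CSV."""
    return validate_plate(_read_csv(path, "plate"), _read_csv(meta_path, "metadata"))


def read_cfu_table(path: str | Path) -> CfuDataset:
    """Read a CFU viability CSV."""
    return validate_cfu(_read_csv(path, "CFU"))


def read_colony_table(path: str | Path) -> ColonyTable:
    """Read a colony-diameter CSV."""
    return validate_colony(_read_csv(path, "colony"))


# ---------------------------------------------------------------------------
# writers


def write_plate_dataset(dataset: PlateDataset, plate_path: str | Path, meta_path: str | Path) -> None:
    """Write a plate dataset to two CSVs (observations + metadata)."""
    dataset.data.to_csv(plate_path, index=False)
    dataset.meta.to_csv(meta_path, index=False)


def write_cfu_dataset(dataset: CfuDataset, path: str | Path) -> None:
    dataset.data.drop(columns=["spore_excess"], errors="ignore").to_csv(path, index=False)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    params: Mapping | None = None,
) -> list[Path]:
    """Write one CSV per named result table plus a run-parameters file.

    Returns the manifest: every file written (tables first, parameters file
    last). The manifest is also persisted as ``manifest.txt`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, table in tables.items():
            path = out_dir / f"{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
        params_path = out_dir / RUN_PARAMS_FILENAME
        with open(params_path, "w") as fh:
            yaml.safe_dump(dict(params or {}), fh, sort_keys=True)
        written.append(params_path)
        (out_dir / MANIFEST_FILENAME).write_text(
            "".join(f"{p.name}\n" for p in written)
        )
    except OSError as exc:
        raise OSError(f"cannot write results to {out_dir}: {exc}") from exc
    return written
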