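"""Domain types, tabular I/O and validation for screen morphometry data.

A screen is a flat table of segmented 3D structures, one row per structure,
carrying two morphometric traits (area, a size proxy; circularity, a symmetry
proxy in [0, 1]) plus the experimental design labels: the experimental set the
structure was grown in, the shRNA construct ("population") it belongs to, a
control flag, and the oncogene condition (with or without active MYC).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ONCOGENE_CONDITIONS = ("none", "MYC")

#: canonical column names; a schema mapping may rename any of them
COLUMNS = (
    "structure_id",
    "set_id",
    "population_id",
    "is_control",
    "oncogene",
    "area",
    "circularity",
)

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n"}


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclasses.dataclass
class ScreenDataset:
    """A validated-shape morphometry table plus units/provenance metadata.

    ``records`` has exactly the columns in :data:`COLUMNS`, one row per
    segmented structure, in the original file order.
    """

    records: pd.DataFrame
    units: str = "pixel^2"
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing columns: {missing}")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.records["oncogene"].unique())

    def condition_subset(self, condition: str) -> pd.DataFrame:
        if condition not in ONCOGENE_CONDITIONS:
            raise ValueError(
                f"unknown oncogene condition {condition!r}; expected one of {ONCOGENE_CONDITIONS}"
            )
        return self.records[self.records["oncogene"] == condition]

    def populations(self, condition: str) -> list[tuple[str, str]]:
        """(set_id, population_id) pairs present in a condition, in file order."""
        sub = self.condition_subset(condition)
        seen = sub[["set_id", "population_id"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def control_population(self, set_id: str, condition: str) -> str:
        sub = self.condition_subset(condition)
        ctrl = sub[(sub["set_id"] == set_id) & sub["is_control"]]["population_id"].unique()
        if len(ctrl) != 1:
            raise ValueError(
                f"set {set_id!r} (condition {condition!r}) has {len(ctrl)} control "
                "populations; exactly one is required"
            )
        return ctrl[0]

    def trait_values(
        self, set_id: str, population_id: str, condition: str, trait: str
    ) -> np.ndarray:
        sub = self.condition_subset(condition)
        mask = (sub["set_id"] == set_id) & (sub["population_id"] == population_id)
        return sub.loc[mask, trait].to_numpy(dtype=float)


@dataclasses.dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    warnings: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    counts: dict = dataclasses.field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ok": self.ok,
            "errors": [{"where": w, "rule": r} for w, r in self.errors],
            "warnings": [{"where": w, "rule": r} for w, r in self.warnings],
            "counts": self.counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _parse_bool(value, row: int):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise SchemaError(f"row {row}: cannot parse boolean control flag {value!r}")


def read_morphometry_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    units: str = "pixel^2",
    control_label: str | None = None,
) -> ScreenDataset:
    """Read a delimited morphometry table into a :class:`ScreenDataset`.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row.
    schema
        Mapping from canonical column names (:data:`COLUMNS`) to the names used
        in the file; unmapped names are taken verbatim.
    sep
        Field delimiter; inferred from the extension when ``None``
        (``.csv`` -> comma, otherwise tab).
    control_label
        If the file has no ``is_control`` column, rows whose population equals
        this label are taken as controls.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    schema = dict(schema or {})
    raw = pd.read_csv(path, sep=sep, dtype=str)

    rename = {}
    for canon in COLUMNS:
        source = schema.get(canon, canon)
        if source in raw.columns:
            rename[source] = canon
    df = raw.rename(columns=rename)

    optional = {"is_control"} if control_label is not None else set()
    missing = [c for c in COLUMNS if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if "is_control" not in df.columns:
        df["is_control"] = df["population_id"] == control_label
    df = df[list(COLUMNS)].copy()

    for col in ("area", "circularity"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header
            raise SchemaError(f"{path.name}: unparseable {col} value at line {row}")
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0]) + 2
            raise SchemaError(f"{path.name}: missing {col} value at line {row}")
        df[col] = parsed.astype(float)

    df["is_control"] = [
        _parse_bool(v, i + 2) for i, v in enumerate(df["is_control"].tolist())
    ]
    for col in ("structure_id", "set_id", "population_id", "oncogene"):
        df[col] = df[col].astype(str)

    dup = df["structure_id"].duplicated()
    if dup.any():
        first = df.loc[dup, "structure_id"].iloc[0]
        raise SchemaError(f"{path.name}: duplicate structure_id {first!r}")

    bad_area = df["area"] <= 0
    if bad_area.any():
        row = int(np.flatnonzero(bad_area)[0]) + 2
        raise SchemaError(f"{path.name}: non-positive area at line {row}")
    bad_circ = (df["circularity"] < 0) | (df["circularity"] > 1)
    if bad_circ.any():
        row = int(np.flatnonzero(bad_circ)[0]) + 2
        raise SchemaError(f"{path.name}: circularity outside [0, 1] at line {row}")

    bad_onc = ~df["oncogene"].isin(ONCOGENE_CONDITIONS)
    if bad_onc.any():
        value = df.loc[bad_onc, "oncogene"].iloc[0]
        raise SchemaError(
            f"{path.name}: unknown oncogene condition {value!r}; expected one of "
            f"{ONCOGENE_CONDITIONS}"
        )

    return ScreenDataset(records=df.reset_index(drop=True), units=units, provenance=str(path))


def validate_dataset(ds: ScreenDataset, min_population_size: int = 2) -> ValidationReport:
    """Check design invariants; violations are reported, never raised.

    Rules: exactly one control population per (set, condition); every
    population has at least ``min_population_size`` structures; a population's
    control flag is consistent across its rows; trait values are in range.
    """
    report = ValidationReport()
    df = ds.records

    out_of_range = df[(df["area"] <= 0) | (df["circularity"] < 0) | (df["circularity"] > 1)]
    for sid in out_of_range["structure_id"]:
        report.errors.append((f"structure {sid}", "trait value out of range"))

    for (set_id, cond), grp in df.groupby(["set_id", "oncogene"], sort=False):
        flags = grp.groupby("population_id", sort=False)["is_control"].agg(["any", "all"])
        inconsistent = flags.index[flags["any"] & ~flags["all"]]
        for pop in inconsistent:
            report.errors.append(
                (f"set {set_id}/{cond}, population {pop}", "inconsistent control flag")
            )
        n_controls = int(flags["all"].sum())
        if n_controls == 0:
            report.errors.append((f"set {set_id}/{cond}", "missing control for set"))
        elif n_controls > 1:
            report.errors.append((f"set {set_id}/{cond}", "multiple controls for set"))

    pop_sizes = df.groupby(["oncogene", "set_id", "population_id"], sort=False).size()
    for (cond, set_id, pop), n in pop_sizes.items():
        if n < min_population_size:
            report.errors.append(
                (f"set {set_id}/{cond}, population {pop}", f"population has {n} < "
                 f"{min_population_size} structures")
            )

    report.counts = {
        "structures": int(len(df)),
        "sets": int(df["set_id"].nunique()),
        "populations": {
            cond: int(sub[["set_id", "population_id"]].drop_duplicates().shape[0])
            for cond, sub in df.groupby("oncogene", sort=False)
        },
    }
    return report


def write_results_table(results, path: str | Path, *, sep: str = "\t") -> Path:
    """Write a results collection (DataFrame or iterable of dataclasses/dicts)
    as delimited text with a header and full-precision floats."""
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = list(results)
        if rows and dataclasses.is_dataclass(rows[0]):
            rows = [dataclasses.asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("refusing to write an empty results table")
    path.parent.mkdir(parents=True, exist_ok=True)
    # 17 significant digits round-trip IEEE doubles exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def write_morphometry_table(ds: ScreenDataset, path: str | Path, *, sep: str = "\t") -> Path:
    return write_results_table(ds.records, path, sep=sep)
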