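"""Tabular EHR data model: schemas, loading, validation and round-trip IO.

The bundle holds one pandas DataFrame per record type (prescriptions, drug
administrations, admissions, care episodes, investigations, diagnoses,
specimens, isolates, susceptibilities). Hospital extracts are dirty, so
loading never aborts on a bad row: malformed rows are quarantined to a
row-errors table and everything else proceeds. Validation is report-only.

Timestamps are parsed to timezone-naive pandas datetimes at minute
resolution; one implicit timezone per bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# column kinds: id, str, float, int, ts (timestamp), and enum:<v1|v2|...>
TABLE_SCHEMAS: dict[str, list[tuple[str, str, bool]]] = {
    # (column, kind, required)
    "prescriptions": [
        ("prescription_id", "id", True),
        ("patient_id", "id", True),
        ("admission_id", "id", False),
        ("drug_code", "str", True),
        ("drug_name", "str", False),
        ("route", "enum:IV|oral|other", True),
        ("dose", "float", True),
        ("dose_unit", "str", True),
        ("frequency", "str", False),
        ("authored_time", "ts", False),
        ("start_time", "ts", True),
        ("end_time", "ts", True),
        ("status", "enum:completed|cancelled|draft", True),
    ],
    "administrations": [
        ("prescription_id", "id", True),
        ("administration_time", "ts", True),
        ("dose_given", "float", True),
    ],
    "admissions": [
        ("admission_id", "id", True),
        ("patient_id", "id", True),
        ("admit_time", "ts", True),
        ("discharge_time", "ts", True),
        ("method", "enum:elective|emergency", True),
        ("age_at_admission", "int", True),
    ],
    "care_episodes": [
        ("admission_id", "id", True),
        ("consultant_team_id", "str", True),
        ("speciality", "str", True),
        ("start_time", "ts", True),
        ("end_time", "ts", True),
    ],
    "investigations": [
        ("patient_id", "id", True),
        ("concept", "enum:temperature|heart_rate|respiratory_rate|systolic_bp|wcc|crp|urea", True),
        ("observed_time", "ts", True),
        ("value", "float", True),
        ("unit", "str", False),
    ],
    "diagnoses": [
        ("admission_id", "id", True),
        ("icd10_code", "str", True),
        ("position", "int", True),
    ],
    "specimens": [
        ("specimen_id", "id", True),
        ("patient_id", "id", True),
        ("collection_time", "ts", True),
        ("specimen_group", "enum:blood|urine|drain|respiratory|intravascular_device|cns|aspirate|tissue_bone|skin|other", True),
    ],
    "isolates": [
        ("isolate_id", "id", True),
        ("specimen_id", "id", True),
        ("organism_code", "str", True),
        ("no_growth", "int", True),
    ],
    "susceptibilities": [
        ("isolate_id", "id", True),
        ("agent_code", "str", True),
        ("measure_type", "enum:MIC|disc_zone", True),
        ("measure_value", "float", True),
        ("reported_interpretation", "str", False),
    ],
}

EXPECTED_UNITS = {
    "temperature": "°C",
    "heart_rate": "bpm",
    "respiratory_rate": "breaths/min",
    "systolic_bp": "mmHg",
    "wcc": "10^9/L",
    "crp": "mg/L",
    "urea": "mmol/L",
}

_ROW_ERROR_COLUMNS = ["table", "row", "column", "message"]


class SchemaError(ValueError):
    """A table is structurally unusable (e.g. a mandatory column is absent)."""


@dataclass
class ValidationEntry:
    severity: str  # "error" | "warning"
    table: str
    rule: str
    message: str
    n: int = 1


@dataclass
class ValidationReport:
    entries: list[ValidationEntry] = field(default_factory=list)

    def add(self, severity: str, table: str, rule: str, message: str, n: int = 1) -> None:
        if n > 0:
            self.entries.append(ValidationEntry(severity, table, rule, message, n))

    @property
    def n_errors(self) -> int:
        return sum(e.n for e in self.entries if e.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(e.n for e in self.entries if e.severity == "warning")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def by_rule(self, rule: str) -> list[ValidationEntry]:
        return [e for e in self.entries if e.rule == rule]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_errors": self.n_errors,
                "n_warnings": self.n_warnings,
                "entries": [vars(e) for e in self.entries],
            },
            indent=2,
        )

    def __str__(self) -> str:  # human-readable log form
        lines = [f"validation: {self.n_errors} error(s), {self.n_warnings} warning(s)"]
        lines += [f"  [{e.severity}] {e.table}/{e.rule}: {e.message} (n={e.n})" for e in self.entries]
        return "\n".join(lines)


@dataclass
class EHRBundle:
    prescriptions: pd.DataFrame
    administrations: pd.DataFrame
    admissions: pd.DataFrame
    care_episodes: pd.DataFrame
    investigations: pd.DataFrame
    diagnoses: pd.DataFrame
    specimens: pd.DataFrame
    isolates: pd.DataFrame
    susceptibilities: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    row_errors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_ROW_ERROR_COLUMNS)
    )

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}


def _empty_table(name: str) -> pd.DataFrame:
    cols = {}
    for col, kind, _req in TABLE_SCHEMAS[name]:
        if kind == "ts":
            cols[col] = pd.Series(dtype="datetime64[ns]")
        elif kind == "float":
            cols[col] = pd.Series(dtype=float)
        elif kind == "int":
            cols[col] = pd.Series(dtype="Int64")
        else:
            cols[col] = pd.Series(dtype=object)
    return pd.DataFrame(cols)


def empty_bundle() -> EHRBundle:
    return EHRBundle(**{name: _empty_table(name) for name in TABLE_SCHEMAS})


def _coerce_table(name: str, raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coerce a raw frame to the schema; return (clean table, row errors)."""
    schema = TABLE_SCHEMAS[name]
    required = [c for c, _k, req in schema if req]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{name}: missing column {', '.join(missing)}")

    df = raw.copy()
    errors: list[dict] = []
    bad = pd.Series(False, index=df.index)

    for col, kind, req in schema:
        if col not in df.columns:
            df[col] = pd.NA
            continue
        if kind == "ts":
            parsed = pd.to_datetime(df[col], errors="coerce")  # ISO-8601 expected
            broken = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            for i in df.index[broken]:
                errors.append({"table": name, "row": int(i), "column": col,
                               "message": f"unparseable timestamp: {df.at[i, col]!r}"})
            if req:
                bad |= parsed.isna()
            df[col] = parsed.dt.floor("min")
        elif kind in ("float", "int"):
            parsed = pd.to_numeric(df[col], errors="coerce")
            broken = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            for i in df.index[broken]:
                errors.append({"table": name, "row": int(i), "column": col,
                               "message": f"not numeric: {df.at[i, col]!r}"})
            if req:
                bad |= parsed.isna()
            df[col] = parsed.astype("Int64") if kind == "int" else parsed.astype(float)
        elif kind.startswith("enum:"):
            allowed = set(kind.split(":", 1)[1].split("|"))
            vals = df[col].astype(str).str.strip()
            broken = ~vals.isin(allowed) & df[col].notna()
            for i in df.index[broken]:
                errors.append({"table": name, "row": int(i), "column": col,
                               "message": f"value {df.at[i, col]!r} not in {sorted(allowed)}"})
            if req:
                bad |= broken | df[col].isna()
            df[col] = vals.where(~broken & df[col].notna())
        else:  # id / str
            df[col] = df[col].astype(object).where(df[col].notna())
            df[col] = df[col].map(lambda v: str(v) if v is not None and v is not pd.NA else v)
            if req:
                miss = df[col].isna() | (df[col].astype(str).str.strip() == "")
                for i in df.index[miss & ~bad]:
                    errors.append({"table": name, "row": int(i), "column": col,
                                   "message": "missing required value"})
                bad |= miss

    clean = df.loc[~bad, [c for c, _k, _r in schema]].reset_index(drop=True)
    err_df = pd.DataFrame(errors, columns=_ROW_ERROR_COLUMNS)
    return clean, err_df


def load_ehr_bundle(paths: Mapping[str, str | Path],
                    linkage_config=None) -> EHRBundle:
    """Read delimited text files (comma or tab separated, header row) into a
    typed bundle. Tables absent from `paths` load empty. Rows that cannot be
    typed are quarantined to ``bundle.row_errors`` rather than dropped
    silently; a missing mandatory column raises :class:`SchemaError`.
    """
    unknown = set(paths) - set(TABLE_SCHEMAS)
    if unknown:
        raise SchemaError(f"unknown table(s): {sorted(unknown)}")

    tables: dict[str, pd.DataFrame] = {}
    all_errors: list[pd.DataFrame] = []
    provenance: dict = {"sources": {}, "load_time": pd.Timestamp.now().isoformat()}

    for name in TABLE_SCHEMAS:
        if name in paths:
            path = Path(paths[name])
            raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                              skip_blank_lines=True)
            clean, errs = _coerce_table(name, raw)
            tables[name] = clean
            all_errors.append(errs)
            provenance["sources"][name] = {"path": str(path), "rows": int(len(raw))}
        else:
            tables[name] = _empty_table(name)

    row_errors = (pd.concat(all_errors, ignore_index=True)
                  if all_errors else pd.DataFrame(columns=_ROW_ERROR_COLUMNS))
    return EHRBundle(**tables, provenance=provenance, row_errors=row_errors)


def bundle_from_frames(frames: Mapping[str, pd.DataFrame]) -> EHRBundle:
    """Build a bundle from in-memory frames, applying the same coercion and
    quarantine rules as file loading."""
    tables, all_errors = {}, []
    for name in TABLE_SCHEMAS:
        if name in frames and len(frames[name]):
            clean, errs = _coerce_table(name, frames[name].astype(object))
            tables[name] = clean
            all_errors.append(errs)
        else:
            tables[name] = _empty_table(name)
    row_errors = (pd.concat(all_errors, ignore_index=True)
                  if all_errors else pd.DataFrame(columns=_ROW_ERROR_COLUMNS))
    return EHRBundle(**tables, row_errors=row_errors)


def write_bundle(bundle: EHRBundle, directory: str | Path) -> dict[str, Path]:
    """Write each table as CSV (ISO-8601 minute timestamps); returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in TABLE_SCHEMAS:
        df = bundle.table(name).copy()
        for col, kind, _ in TABLE_SCHEMAS[name]:
            if kind == "ts" and col in df.columns:
                df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_ICD10_RE = r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$"


def validate_bundle(bundle: EHRBundle) -> ValidationReport:
    """Report-only integrity checks; the bundle is not modified.

    Errors: broken references, inverted intervals, susceptibilities on
    no-growth isolates. Warnings: administrations far outside their
    prescription window, care episodes outside the admission (24 h
    tolerance), paediatric ages, unit mismatches, malformed ICD-10 codes.
    """
    rep = ValidationReport()
    rx, ad = bundle.prescriptions, bundle.administrations
    adm, ce = bundle.admissions, bundle.care_episodes
    inv, dx = bundle.investigations, bundle.diagnoses
    sp, iso, sus = bundle.specimens, bundle.isolates, bundle.susceptibilities

    def _ref(child: pd.DataFrame, ckey: str, parent: pd.DataFrame, pkey: str,
             ctable: str, ptable: str, severity: str = "error") -> None:
        if not len(child):
            return
        present = child[ckey].dropna()
        orphan = ~present.isin(set(parent[pkey].dropna()))
        rep.add(severity, ctable, "referential_integrity",
                f"{ckey} not found in {ptable}", int(orphan.sum()))

    _ref(ad, "prescription_id", rx, "prescription_id", "administrations", "prescriptions")
    _ref(ce, "admission_id", adm, "admission_id", "care_episodes", "admissions")
    _ref(dx, "admission_id", adm, "admission_id", "diagnoses", "admissions")
    _ref(iso, "specimen_id", sp, "specimen_id", "isolates", "specimens")
    _ref(sus, "isolate_id", iso, "isolate_id", "susceptibilities", "isolates")
    if len(rx):
        has_adm = rx["admission_id"].notna()
        _ref(rx[has_adm], "admission_id", adm, "admission_id", "prescriptions", "admissions")

    # intervals
    if len(rx):
        both = rx["start_time"].notna() & rx["end_time"].notna()
        rep.add("error", "prescriptions", "interval",
                "end_time before start_time",
                int((rx.loc[both, "end_time"] < rx.loc[both, "start_time"]).sum()))
    if len(adm):
        rep.add("error", "admissions", "interval",
                "discharge_time not after admit_time",
                int((adm["discharge_time"] <= adm["admit_time"]).sum()))
        rep.add("warning", "admissions", "age",
                "age_at_admission below 18",
                int((adm["age_at_admission"].astype(float) < 18).sum()))

    # administrations within prescription window +/- 24 h
    if len(ad) and len(rx):
        m = ad.merge(rx[["prescription_id", "start_time", "end_time"]],
                     on="prescription_id", how="inner")
        slack = pd.Timedelta(hours=24)
        out = ((m["administration_time"] < m["start_time"] - slack) |
               (m["administration_time"] > m["end_time"] + slack))
        rep.add("warning", "administrations", "admin_window",
                "administration outside prescription interval ± 24 h",
                int(out.sum()))

    # care episodes inside parent admission (24 h tolerance)
    if len(ce) and len(adm):
        m = ce.merge(adm[["admission_id", "admit_time", "discharge_time"]],
                     on="admission_id", how="inner")
        slack = pd.Timedelta(hours=24)
        out = ((m["start_time"] < m["admit_time"] - slack) |
               (m["end_time"] > m["discharge_time"] + slack))
        rep.add("warning", "care_episodes", "episode_window",
                "care episode outside admission interval ± 24 h", int(out.sum()))

    # units
    if len(inv):
        with_unit = inv[inv["unit"].notna()]
        expected = with_unit["concept"].map(EXPECTED_UNITS)
        rep.add("warning", "investigations", "unit",
                "unit differs from expected for concept",
                int((with_unit["unit"] != expected).sum()))
        rep.add("error", "investigations", "finite",
                "non-finite value", int((~np.isfinite(with_unit["value"].astype(float))).sum()
                                        if len(with_unit) else 0))

    # ICD-10 syntax (dots stripped before matching)
    if len(dx):
        codes = dx["icd10_code"].astype(str).str.replace(".", "", regex=False)
        rep.add("warning", "diagnoses", "icd10_syntax",
                "code does not match ICD-10 pattern",
                int((~codes.str.match(_ICD10_RE)).sum()))

    # no-growth isolates must carry no susceptibilities
    if len(iso) and len(sus):
        ng = set(iso.loc[iso["no_growth"].astype(float) == 1, "isolate_id"])
        rep.add("error", "susceptibilities", "no_growth",
                "susceptibility reported for a no-growth isolate",
                int(sus["isolate_id"].isin(ng).sum()))

    return rep
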