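"""Treatment-mean database: records, I/O, validation, and descriptive summaries.

The experimental unit throughout is the *treatment mean*: the average of all
animals on one dietary treatment within one respiration-calorimetry study.
Each row carries the animal description, diet composition (% of DM), energy
concentrations (Mcal/kg of DM), and the fractions of digestible energy lost
as methane and urine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentMean",
    "EnergyDatabase",
    "ValidationIssue",
    "ValidationReport",
    "read_database",
    "write_database",
    "load_table1",
    "validate",
    "derived_fields",
    "with_derived",
    "describe",
    "median_split_summary",
]

#: canonical column order; also the schema of the packaged fixture
COLUMNS = [
    "citation_id",
    "diet_label",
    "animal_desc",
    "n_animals",
    "bw",
    "dmi",
    "cp",
    "ndf",
    "ee",
    "starch",
    "tdn",
    "ge",
    "de",
    "me",
    "me_de_ratio",
    "ch4_pct_de",
    "urine_pct_de",
]

NUMERIC_COLUMNS = COLUMNS[3:]
TEXT_COLUMNS = COLUMNS[:3]

#: header spellings accepted out of the box (lower-cased, stripped); extendable
#: via the ``column_map`` argument of :func:`read_database`.
DEFAULT_ALIASES: dict[str, str] = {
    "source": "citation_id",
    "citation": "citation_id",
    "study": "citation_id",
    "diet": "diet_label",
    "treatment": "diet_label",
    "animal": "animal_desc",
    "no. of observations": "n_animals",
    "n": "n_animals",
    "mean bw, kg": "bw",
    "bw, kg": "bw",
    "dmi, kg/d": "dmi",
    "crude protein": "cp",
    "neutral detergent fiber": "ndf",
    "ether extract": "ee",
    "ch4": "ch4_pct_de",
    "urine": "urine_pct_de",
    "me:de": "me_de_ratio",
}

DERIVED_COLUMNS = [
    "me_de_ratio_calc",
    "ch4_mcal_per_kg_dm",
    "urine_mcal_per_kg_dm",
    "dmi_pct_bw",
    "ge_intake_mcal_d",
]


@dataclass
class TreatmentMean:
    """One dietary treatment averaged over the animals that received it.

    Energy concentrations (``ge``, ``de``, ``me``) are Mcal/kg of dry matter;
    diet composition (``cp`` .. ``tdn``) is % of DM; ``ch4_pct_de`` and
    ``urine_pct_de`` are the percentage of DE lost in methane and urine.
    Missing values are ``None`` (or NaN once inside a frame), never zero.
    """

    citation_id: str
    diet_label: str = ""
    animal_desc: str = ""
    n_animals: float | None = None
    bw: float | None = None
    dmi: float | None = None
    cp: float | None = None
    ndf: float | None = None
    ee: float | None = None
    starch: float | None = None
    tdn: float | None = None
    ge: float | None = None
    de: float | None = None
    me: float | None = None
    me_de_ratio: float | None = None  # ratio as printed in the source table
    ch4_pct_de: float | None = None
    urine_pct_de: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


class EnergyDatabase:
    """Ordered collection of treatment means backed by a :class:`pandas.DataFrame`."""

    def __init__(self, frame: pd.DataFrame, source_label: str = ""):
        frame = frame.copy()
        for col in COLUMNS:
            if col not in frame.columns:
                frame[col] = "" if col in TEXT_COLUMNS else np.nan
        extra = [c for c in frame.columns if c not in COLUMNS]
        frame = frame[COLUMNS + extra].reset_index(drop=True)
        for col in NUMERIC_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        if len(frame) and (frame["citation_id"].astype(str).str.strip() == "").any():
            raise ValueError("every row needs a non-empty citation_id")
        keys = list(zip(frame["citation_id"], frame["diet_label"]))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (citation_id, diet_label) pairs: {dupes}")
        self.frame = frame
        self.source_label = source_label

    # -- construction ------------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Iterable[TreatmentMean], source_label: str = "") -> "EnergyDatabase":
        return cls(pd.DataFrame([r.as_dict() for r in rows], columns=COLUMNS), source_label)

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.rows())

    def rows(self) -> list[TreatmentMean]:
        out = []
        for _, r in self.frame.iterrows():
            kw = {c: r[c] for c in COLUMNS}
            for c in NUMERIC_COLUMNS:
                if pd.isna(kw[c]):
                    kw[c] = None
            out.append(TreatmentMean(**kw))
        return out

    def studies(self) -> list[str]:
        return list(dict.fromkeys(self.frame["citation_id"]))


@dataclass
class ValidationIssue:
    row_key: tuple[str, str]
    issue_code: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.issues

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "citation_id": i.row_key[0],
                    "diet_label": i.row_key[1],
                    "issue_code": i.issue_code,
                    "severity": i.severity,
                    "message": i.message,
                }
                for i in self.issues
            ],
            columns=["citation_id", "diet_label", "issue_code", "severity", "message"],
        )


def _normalize_header(name: str) -> str:
    return str(name).strip().lower().replace("_", " ").replace("-", " ")


def read_database(
    path,
    dialect: str | None = None,
    column_map: Mapping[str, str] | None = None,
    source_label: str | None = None,
) -> EnergyDatabase:
    """Read a treatment-mean table from CSV/TSV or a spreadsheet.

    ``column_map`` maps file headers onto canonical field names so differently
    labelled spreadsheets load without code changes.  Headers already matching
    canonical names (case/space-insensitively) need no mapping.  Missing cells
    become missing values, never zeros.

    Raises ``ValueError`` if the citation column or both energy columns
    (DE and ME) cannot be located, naming the offending column.
    """
    path_str = str(path)
    if dialect is None:
        low = path_str.lower()
        if low.endswith((".xlsx", ".xls", ".xlsm")):
            dialect = "spreadsheet"
        elif low.endswith((".tsv", ".tab", ".txt")):
            dialect = "tsv"
        else:
            dialect = "csv"
    if dialect == "spreadsheet":
        raw = pd.read_excel(path, sheet_name=0)
    elif dialect == "tsv":
        raw = pd.read_csv(path, sep="\t")
    elif dialect == "csv":
        raw = pd.read_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    mapping = dict(DEFAULT_ALIASES)
    if column_map:
        mapping.update({_normalize_header(k): v for k, v in column_map.items()})
    canonical = {_normalize_header(c): c for c in COLUMNS}

    rename: dict[str, str] = {}
    for col in raw.columns:
        key = _normalize_header(col)
        if key in canonical:
            rename[col] = canonical[key]
        elif key in mapping:
            rename[col] = mapping[key]
    frame = raw.rename(columns=rename)

    for mandatory in ("citation_id",):
        if mandatory not in frame.columns:
            raise ValueError(f"mandatory column {mandatory!r} not found in {path_str}")
    if "de" not in frame.columns and "me" not in frame.columns:
        raise ValueError(f"neither 'de' nor 'me' column found in {path_str}")
    frame = frame.dropna(how="all")
    label = source_label if source_label is not None else path_str
    return EnergyDatabase(frame, source_label=label)


def write_database(db: EnergyDatabase, path, dialect: str | None = None) -> None:
    """Write the database back out; round-trips every populated field."""
    path_str = str(path)
    if dialect is None:
        dialect = "tsv" if path_str.lower().endswith((".tsv", ".tab")) else "csv"
    sep = "\t" if dialect == "tsv" else ","
    cols = [c for c in db.frame.columns if c in COLUMNS]
    db.frame[cols].to_csv(path, sep=sep, index=False)


def load_table1() -> EnergyDatabase:
    """The 47 treatment means from the 11 studies added to the development database.

    Transcribed from the printed descriptive table of the added
    respiration-calorimetry studies (growing bulls, steers and heifers fed
    individually; chamber or headbox calorimetry).
    """
    with resources.as_file(
        resources.files("ruminergy") / "data" / "table1_added_studies.csv"
    ) as p:
        return read_database(p, dialect="csv", source_label="table1_added_studies")


# -- validation ------------------------------------------------------------


def validate(db: EnergyDatabase, ratio_tol: float = 0.005) -> ValidationReport:
    """Check energy-ordering and ratio consistency row by row.

    Flags (never raises): ME > DE, DE > GE, non-positive BW/DMI/n, percentages
    outside [0, 100], and printed ME:DE disagreeing with ME/DE by more than
    ``ratio_tol`` (default 0.005, which covers two-decimal rounding of the
    printed ME and DE columns).
    """
    report = ValidationReport()
    for _, r in db.frame.iterrows():
        key = (r["citation_id"], r["diet_label"])

        def flag(code, severity, msg):
            report.issues.append(ValidationIssue(key, code, severity, msg))

        me, de, ge = r["me"], r["de"], r["ge"]
        if pd.notna(me) and pd.notna(de) and me > de:
            flag("ME_EXCEEDS_DE", "error", f"ME {me} > DE {de}")
        if pd.notna(de) and pd.notna(ge) and de > ge:
            flag("DE_EXCEEDS_GE", "error", f"DE {de} > GE {ge}")
        for col in ("bw", "dmi", "n_animals"):
            v = r[col]
            if pd.notna(v) and v <= 0:
                flag("NONPOSITIVE", "error", f"{col} = {v} must be > 0")
        for col in ("cp", "ndf", "ee", "starch", "tdn", "ch4_pct_de", "urine_pct_de"):
            v = r[col]
            if pd.notna(v) and not (0 <= v <= 100):
                flag("PCT_OUT_OF_RANGE", "error", f"{col} = {v} outside [0, 100]")
        printed = r["me_de_ratio"]
        if pd.notna(printed) and pd.notna(me) and pd.notna(de) and de > 0:
            computed = me / de
            if abs(printed - computed) > ratio_tol:
                flag(
                    "RATIO_MISMATCH",
                    "warning",
                    f"printed ME:DE {printed} vs computed {computed:.5f} "
                    f"(tol {ratio_tol})",
                )
            if not (0.5 < computed < 1.0):
                flag("RATIO_IMPLAUSIBLE", "warning", f"ME/DE = {computed:.4f} outside (0.5, 1)")
    return report


# -- derived fields --------------------------------------------------------


def derived_fields(row: TreatmentMean | pd.Series | Mapping) -> dict:
    """Per-row derived quantities; missing inputs yield missing outputs.

    * ``me_de_ratio_calc`` — ME/DE efficiency of the DE→ME conversion.
    * ``ch4_mcal_per_kg_dm`` — methane energy, Mcal per kg of DM:
      (ch4 % of DE / 100) × DE.  Per kg of DM and per kg of DMI are the same
      scale, since intake is expressed in DM.
    * ``urine_mcal_per_kg_dm`` — likewise for urinary energy.
    * ``dmi_pct_bw`` — intake level, 100 × DMI / BW.
    * ``ge_intake_mcal_d`` — gross energy intake, GE × DMI.
    """
    if isinstance(row, TreatmentMean):
        row = row.as_dict()

    def get(name):
        v = row.get(name) if isinstance(row, Mapping) else row[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    de, me, ge, bw, dmi = (get(k) for k in ("de", "me", "ge", "bw", "dmi"))
    ch4, urine = get("ch4_pct_de"), get("urine_pct_de")
    out: dict[str, float | None] = {}
    out["me_de_ratio_calc"] = me / de if me is not None and de else None
    out["ch4_mcal_per_kg_dm"] = ch4 / 100.0 * de if ch4 is not None and de is not None else None
    out["urine_mcal_per_kg_dm"] = (
        urine / 100.0 * de if urine is not None and de is not None else None
    )
    out["dmi_pct_bw"] = 100.0 * dmi / bw if dmi is not None and bw else None
    out["ge_intake_mcal_d"] = ge * dmi if ge is not None and dmi is not None else None
    return out


def with_derived(db: EnergyDatabase) -> pd.DataFrame:
    """Database frame plus the derived columns (vectorised)."""
    f = db.frame.copy()
    f["me_de_ratio_calc"] = f["me"] / f["de"]
    f["ch4_mcal_per_kg_dm"] = f["ch4_pct_de"] / 100.0 * f["de"]
    f["urine_mcal_per_kg_dm"] = f["urine_pct_de"] / 100.0 * f["de"]
    f["dmi_pct_bw"] = 100.0 * f["dmi"] / f["bw"]
    f["ge_intake_mcal_d"] = f["ge"] * f["dmi"]
    return f


DESCRIBE_DEFAULT_VARS = ["de", "me", "dmi_pct_bw", "ch4_mcal_per_kg_dm", "bw"]


def describe(db: EnergyDatabase, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Unweighted per-variable count, mean, sample SD (n−1), min and max.

    Rows are treatment means; no weighting by the number of animals behind
    each mean.  Variables with no data are dropped with a warning.
    """
    import warnings

    if len(db) == 0:
        raise ValueError("describe() needs a non-empty database")
    frame = with_derived(db)
    variables = list(variables) if variables is not None else list(DESCRIBE_DEFAULT_VARS)
    rows = []
    for var in variables:
        if var not in frame.columns:
            warnings.warn(f"variable {var!r} not present; omitted", stacklevel=2)
            continue
        s = pd.to_numeric(frame[var], errors="coerce").dropna()
        if s.empty:
            warnings.warn(f"variable {var!r} entirely missing; omitted", stacklevel=2)
            continue
        rows.append(
            {
                "variable": var,
                "count": int(s.count()),
                "mean": s.mean(),
                "sd": s.std(ddof=1) if len(s) > 1 else np.nan,
                "min": s.min(),
                "max": s.max(),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def median_split_summary(
    db: EnergyDatabase,
    sort_var: str = "ch4_mcal_per_kg_dm",
    summary_vars: Sequence[str] = ("starch", "ndf", "ee"),
) -> pd.DataFrame:
    """Split rows at the median of ``sort_var`` and compare group means.

    Rows are ranked by ``sort_var`` descending (stable order for ties); the
    top ⌈n/2⌉ form the high group and the remaining ⌊n/2⌋ the low group.
    Returns group means of ``summary_vars`` plus of the sort variable itself,
    with group sizes.
    """
    frame = with_derived(db)
    if sort_var not in frame.columns:
        raise ValueError(f"unknown sort variable {sort_var!r}")
    s = pd.to_numeric(frame[sort_var], errors="coerce")
    if s.isna().any():
        raise ValueError(f"{sort_var!r} not computable for every row")
    n = len(frame)
    if n < 2:
        raise ValueError("median split needs at least 2 rows")
    order = s.sort_values(ascending=False, kind="stable").index
    n_top = math.ceil(n / 2)
    groups = {"top": frame.loc[order[:n_top]], "bottom": frame.loc[order[n_top:]]}
    cols = [sort_var] + [v for v in summary_vars if v != sort_var]
    out = []
    for name, g in groups.items():
        rec = {"group": name, "n": len(g)}
        for v in cols:
            rec[v] = pd.to_numeric(g[v], errors="coerce").mean()
        out.append(rec)
    return pd.DataFrame(out).set_index("group")
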