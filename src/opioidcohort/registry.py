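"""Canonical record schemas, CSV readers/writers, reference code sets, and
dispensing-registry cleaning rules.

The package passes data between stages as pandas DataFrames with the fixed
column schemas below.  Five linked tables are used throughout:

``fills``
    One row per dispensed opioid prescription (PDMP-style): patient and
    prescriber identifiers, fill date, base opioid ingredient, co-formulated
    non-opioid ingredient, tablet strength (mg), quantity, days' supply, and a
    long-acting flag.
``spans``
    Insurance enrollment spans (APCD-style), half-open ``[start_date,
    end_date)``, with the plan type.
``claims``
    ED / inpatient encounters with a list of ICD-10 diagnosis codes.
``deaths``
    Death records: underlying cause, multiple-cause codes, and the death
    certificate literal text.  At most one row per patient.
``demographics``
    Age (as of a configurable reference date), gender, race/ethnicity, and
    6-level urbanization of county of residence.

List-valued columns (diagnosis codes, multiple causes) are stored in CSV as
semicolon-separated strings and held in memory as Python lists.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DRUG_BASES = [
    "hydrocodone",
    "oxycodone",
    "codeine",
    "tramadol",
    "morphine",
    "hydromorphone",
    "other",
]
COMBINATION_INGREDIENTS = ["none", "acetaminophen", "ibuprofen", "other"]
PLANS = ["commercial", "medicaid", "medicare", "dual", "unknown"]
SETTINGS = ["ED", "inpatient"]
GENDERS = ["F", "M"]
RACE_ETHNICITY = ["White", "Black", "Hispanic", "Asian-Pacific Islander", "Other", "Unknown"]
URBANIZATION = [
    "large_central_metro",
    "large_fringe_metro",
    "medium_metro",
    "small_metro",
    "micropolitan",
    "noncore",
    "unknown",
]

FILL_COLUMNS = [
    "patient_id",
    "prescriber_id",
    "fill_date",
    "drug_base",
    "combination_ingredient",
    "strength_per_unit",
    "quantity",
    "days_supply",
    "long_acting",
]
SPAN_COLUMNS = ["patient_id", "start_date", "end_date", "plan"]
CLAIM_COLUMNS = ["patient_id", "service_date", "setting", "diagnosis_codes"]
DEATH_COLUMNS = ["patient_id", "death_date", "underlying_cause", "multiple_causes", "literal_text"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "age_years", "gender", "race_ethnicity", "urbanization"]

REMOVAL_REASONS = ["duplicate", "missing_prescriber", "quantity", "days_supply"]

#: fields defining an exact duplicate dispensing record
DUPLICATE_KEY = [
    "patient_id",
    "prescriber_id",
    "fill_date",
    "drug_base",
    "combination_ingredient",
    "strength_per_unit",
    "quantity",
    "days_supply",
]


class ConfigurationError(ValueError):
    """Raised when an input file or resource does not match its documented schema."""


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code for prefix matching: uppercase, dots removed."""
    return str(code).strip().upper().replace(".", "")


@dataclass
class CodeSet:
    """Code lists and literal-text terms identifying opioid overdose.

    Fatal overdoses require an underlying cause in ``underlying_cause_codes``
    together with a multiple-cause match on a ``t_codes`` prefix, or a
    case-insensitive literal-text term match.  Non-fatal overdoses are
    diagnosis-code prefix matches against ``nonfatal_dx_prefixes``.
    """

    name: str
    underlying_cause_codes: list[str]
    t_codes: list[str]
    nonfatal_dx_prefixes: list[str]
    literal_terms: list[str]

    def __post_init__(self) -> None:
        self.underlying_cause_codes = [normalize_icd10(c) for c in self.underlying_cause_codes]
        self.t_codes = [normalize_icd10(c) for c in self.t_codes]
        self.nonfatal_dx_prefixes = [normalize_icd10(c) for c in self.nonfatal_dx_prefixes]
        self.literal_terms = [str(t).lower() for t in self.literal_terms]

    def matches_underlying(self, code: str) -> bool:
        code = normalize_icd10(code)
        return any(code.startswith(c) for c in self.underlying_cause_codes)

    def matches_t_code(self, codes) -> bool:
        return any(
            normalize_icd10(c).startswith(t) for c in codes for t in self.t_codes
        )

    def matches_literal(self, text: str) -> bool:
        text = str(text).lower()
        return any(term in text for term in self.literal_terms)

    def matches_nonfatal(self, codes) -> bool:
        return any(
            normalize_icd10(c).startswith(p) for c in codes for p in self.nonfatal_dx_prefixes
        )

    def is_fatal_overdose(self, underlying: str, multiple_causes, literal_text: str) -> bool:
        by_codes = self.matches_underlying(underlying) and self.matches_t_code(multiple_causes)
        return by_codes or self.matches_literal(literal_text)


def load_code_set(path: str | Path | None = None) -> CodeSet:
    """Load an overdose code set from YAML (the shipped default when *path* is None)."""
    if path is None:
        ref = importlib.resources.files("opioidcohort.resources") / "overdose_codes.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    required = ["name", "underlying_cause_codes", "t_codes", "nonfatal_dx_prefixes", "literal_terms"]
    for key in required:
        if key not in raw:
            raise ConfigurationError(f"code set is missing required key: {key}")
    return CodeSet(**{k: raw[k] for k in required})


def load_mme_table(path: str | Path | None = None) -> dict[str, float]:
    """Load the ingredient -> MME-per-mg conversion table (CDC factors by default)."""
    if path is None:
        ref = importlib.resources.files("opioidcohort.resources") / "mme_factors.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    for col in ("drug_base", "mme_per_mg"):
        if col not in table.columns:
            raise ConfigurationError(f"MME table is missing required column: {col}")
    factors = dict(zip(table["drug_base"], table["mme_per_mg"].astype(float)))
    bad = [d for d, f in factors.items() if not f > 0]
    if bad:
        raise ConfigurationError(f"MME conversion factors must be positive; offending drugs: {bad}")
    return factors


@dataclass
class RegistryTables:
    """The five linked registry tables plus the row-level reject log."""

    fills: pd.DataFrame
    spans: pd.DataFrame
    claims: pd.DataFrame
    deaths: pd.DataFrame
    demographics: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


def _read_raw(path: str | Path, columns: list[str], table: str) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return _empty(columns)
    for col in columns:
        if col not in raw.columns:
            raise ConfigurationError(f"{table} file {path} is missing required column: {col}")
    return raw[columns]


def _coerce(
    raw: pd.DataFrame,
    table: str,
    date_cols: list[str],
    num_cols: list[str],
    list_cols: list[str] = (),
    bool_cols: list[str] = (),
    rejects: list | None = None,
) -> pd.DataFrame:
    """Coerce string columns to typed columns; rows failing coercion go to *rejects*."""
    df = raw.copy()
    bad = pd.Series(False, index=df.index)
    reason = pd.Series("", index=df.index)
    for col in date_cols:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        newly = parsed.isna() & ~bad
        reason[newly] = f"unparseable {col}"
        bad |= parsed.isna()
        df[col] = parsed
    for col in num_cols:
        parsed = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        newly = parsed.isna() & (df[col] != "") & ~bad
        reason[newly] = f"unparseable {col}"
        bad |= parsed.isna() & (df[col] != "").to_numpy()
        df[col] = parsed
    for col in bool_cols:
        df[col] = df[col].str.lower().isin(["true", "1", "t", "yes"])
    for col in list_cols:
        df[col] = [
            [c for c in str(v).split(";") if c.strip() != ""] for v in df[col]
        ]
    if rejects is not None:
        for idx in df.index[bad]:
            rejects.append({"table": table, "row": int(idx), "reason": reason[idx] or "unparseable"})
    return df.loc[~bad].reset_index(drop=True)


def read_registry(
    fills_path: str | Path,
    spans_path: str | Path,
    claims_path: str | Path,
    deaths_path: str | Path,
    demographics_path: str | Path,
) -> RegistryTables:
    """Read the five linked CSV tables into typed DataFrames.

    Unparseable rows are not silently dropped: each lands in the
    ``rejects`` log with its source table, row number, and reason.  A missing
    required column raises :class:`ConfigurationError` naming the column.
    """
    rejects: list[dict] = []
    fills = _coerce(
        _read_raw(fills_path, FILL_COLUMNS, "fills"),
        "fills",
        date_cols=["fill_date"],
        num_cols=["strength_per_unit", "quantity", "days_supply"],
        bool_cols=["long_acting"],
        rejects=rejects,
    )
    spans = _coerce(
        _read_raw(spans_path, SPAN_COLUMNS, "spans"),
        "spans",
        date_cols=["start_date", "end_date"],
        num_cols=[],
        rejects=rejects,
    )
    claims = _coerce(
        _read_raw(claims_path, CLAIM_COLUMNS, "claims"),
        "claims",
        date_cols=["service_date"],
        num_cols=[],
        list_cols=["diagnosis_codes"],
        rejects=rejects,
    )
    deaths = _coerce(
        _read_raw(deaths_path, DEATH_COLUMNS, "deaths"),
        "deaths",
        date_cols=["death_date"],
        num_cols=[],
        list_cols=["multiple_causes"],
        rejects=rejects,
    )
    demographics = _coerce(
        _read_raw(demographics_path, DEMOGRAPHICS_COLUMNS, "demographics"),
        "demographics",
        date_cols=[],
        num_cols=["age_years"],
        rejects=rejects,
    )
    reject_df = pd.DataFrame(rejects, columns=["table", "row", "reason"])
    return RegistryTables(fills, spans, claims, deaths, demographics, reject_df)


def write_registry(tables: RegistryTables, outdir: str | Path) -> dict[str, Path]:
    """Write the five tables (and reject log) as CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("fills", tables.fills),
        ("spans", tables.spans),
        ("claims", tables.claims),
        ("deaths", tables.deaths),
        ("demographics", tables.demographics),
        ("rejects", tables.rejects),
    ]:
        out = df.copy()
        for col in out.columns:
            if len(out) and isinstance(out[col].iloc[0], list):
                out[col] = [";".join(v) for v in out[col]]
            elif pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        paths[name] = outdir / f"{name}.csv"
        out.to_csv(paths[name], index=False)
    return paths


def clean_fills(
    fills: pd.DataFrame,
    quantity_cap_percentile: float = 0.99,
    quantity_cutoff: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the dispensing-registry cleaning rules.

    Removes, in order of precedence: exact duplicate rows (identical on all
    dispensing fields), fills missing a prescriber ID, quantities < 4 or >=
    the quantity cutoff, and days' supply < 0 or > 90.  The quantity cutoff is
    the ``quantity_cap_percentile`` empirical quantile of the *full* input
    fill set, computed once before any filter; pass ``quantity_cutoff`` to
    freeze a previously computed cutoff (re-cleaning a cleaned set with the
    frozen cutoff removes nothing further).

    Returns ``(kept, removal_log)``.  The removal log holds one row per
    removed fill with a single ``reason``; reason counts therefore partition
    the removed rows and kept + removed equals the input count.  The cutoff
    actually used is stored in ``kept.attrs["quantity_cutoff"]``.
    """
    fills = fills.reset_index(drop=True)
    if len(fills) == 0:
        log = pd.DataFrame(columns=list(fills.columns) + ["reason"])
        kept = fills.copy()
        kept.attrs["quantity_cutoff"] = float("inf") if quantity_cutoff is None else quantity_cutoff
        return kept, log

    if quantity_cutoff is None:
        quantity_cutoff = float(np.quantile(fills["quantity"].astype(float), quantity_cap_percentile))

    reason = pd.Series("", index=fills.index, dtype=object)
    dup = fills.duplicated(subset=DUPLICATE_KEY, keep="first")
    reason[dup] = "duplicate"
    missing = fills["prescriber_id"].isna() | (fills["prescriber_id"].astype(str).str.strip() == "")
    reason[missing & (reason == "")] = "missing_prescriber"
    qty = fills["quantity"].astype(float)
    bad_qty = (qty < 4) | (qty >= quantity_cutoff)
    reason[bad_qty & (reason == "")] = "quantity"
    ds = fills["days_supply"].astype(float)
    bad_ds = (ds < 0) | (ds > 90)
    reason[bad_ds & (reason == "")] = "days_supply"

    removed = reason != ""
    log = fills.loc[removed].copy()
    log["reason"] = reason[removed]
    kept = fills.loc[~removed].reset_index(drop=True)
    kept.attrs["quantity_cutoff"] = quantity_cutoff
    return kept, log
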