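"""Index-event identification, enrollment eligibility, and exposure covariates.

A patient enters the cohort at their first qualifying short-acting
hydrocodone or oxycodone fill (the *index prescription*) in the study window.
Qualifying means opioid-naive: no opioid fill and no opioid-related
ED/inpatient encounter in the 365 days strictly before the index date.
Patients must then hold continuous insurance enrollment in the index calendar
year (gaps under 90 days allowed); patients who died during the index year
are retained if continuous up to death.

Dates are ISO-8601 and every interval is half-open ``[start, end)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import CodeSet, normalize_icd10

LOOKBACK_DAYS = 365
ENROLLMENT_GAP_DAYS = 90
MIN_PLAN_DAYS = 183  # "at least 6 months" of the index year

AGE_EDGES = [18, 25, 35, 45, 55, 65, 75]
AGE_LABELS = ["18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+"]
MME_BREAKPOINTS = [75.0, 100.0, 200.0, 300.0]
MME_LABELS = ["<=75", "76-100", "101-200", "201-300", ">300"]
DAYS_SUPPLY_LABELS = ["<=3", "4-6", "7+"]
DRUG_GROUPS = ["hydrocodone_SA", "oxycodone_SA"]
SUBGROUP_LABELS = ["hydro_apap_5mg", "oxy_apap_5mg", "oxy_mono_5mg", "other"]

COHORT_COLUMNS = [
    "patient_id",
    "drug_group",
    "subgroup_drug",
    "age_category",
    "gender",
    "race_ethnicity",
    "insurance",
    "urbanization",
    "index_year",
    "index_date",
    "index_mme",
    "mme_category",
    "days_supply_category",
    "prescriber_id",
]


def _prev_event_date(candidates: pd.DataFrame, events: pd.DataFrame, date_col: str) -> pd.Series:
    """Date of the most recent event strictly before each candidate fill (same patient)."""
    if len(events) == 0 or len(candidates) == 0:
        return pd.Series(pd.NaT, index=candidates.index)
    left = candidates[["patient_id", "fill_date"]].reset_index()
    left = left.sort_values("fill_date", kind="mergesort")
    right = (
        events[["patient_id", date_col]]
        .dropna()
        .rename(columns={date_col: "_prev_date"})
        .sort_values("_prev_date", kind="mergesort")
    )
    merged = pd.merge_asof(
        left,
        right,
        left_on="fill_date",
        right_on="_prev_date",
        by="patient_id",
        allow_exact_matches=False,
    )
    return merged.set_index("index")["_prev_date"].reindex(candidates.index)


def find_index_events(
    fills: pd.DataFrame,
    claims: pd.DataFrame,
    overdose_code_set: CodeSet,
    window: tuple[str, str] = ("2015-01-01", "2018-01-01"),
) -> pd.DataFrame:
    """Identify each patient's earliest qualifying index fill.

    Candidates are non-long-acting hydrocodone/oxycodone fills with
    ``fill_date`` in ``[window[0], window[1])``.  A candidate qualifies when
    the patient has no opioid fill of any kind and no opioid-related
    ED/inpatient claim (diagnosis matching the code set's non-fatal prefixes)
    dated within the 365 days strictly before it.  At most one row per
    patient is returned — the earliest qualifying candidate.
    """
    fills = fills.reset_index(drop=True)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    cand = fills[
        fills["drug_base"].isin(["hydrocodone", "oxycodone"])
        & ~fills["long_acting"].astype(bool)
        & (fills["fill_date"] >= start)
        & (fills["fill_date"] < end)
    ].copy()
    if len(cand) == 0:
        return pd.DataFrame(columns=fills.columns.tolist() + ["drug_group", "index_date", "index_year"])

    prev_fill = _prev_event_date(cand, fills, "fill_date")

    if len(claims):
        mask = claims["diagnosis_codes"].map(overdose_code_set.matches_nonfatal)
        opioid_claims = claims.loc[mask, ["patient_id", "service_date"]]
    else:
        opioid_claims = pd.DataFrame(columns=["patient_id", "service_date"])
    prev_claim = _prev_event_date(cand, opioid_claims, "service_date")

    lookback = cand["fill_date"] - pd.Timedelta(days=LOOKBACK_DAYS)
    ok_fill = prev_fill.isna() | (prev_fill < lookback)
    ok_claim = prev_claim.isna() | (prev_claim < lookback)
    qualified = cand[ok_fill & ok_claim]

    index_events = (
        qualified.sort_values(["fill_date", "patient_id"], kind="mergesort")
        .groupby("patient_id", as_index=False)
        .head(1)
        .reset_index(drop=True)
    )
    index_events["drug_group"] = index_events["drug_base"].map(
        {"hydrocodone": "hydrocodone_SA", "oxycodone": "oxycodone_SA"}
    )
    index_events["index_date"] = index_events["fill_date"]
    index_events["index_year"] = index_events["index_date"].dt.year
    index_events["subgroup_drug"] = recode_combination_subgroup(index_events)
    return index_events


def _to_day(ts) -> int:
    return int(np.datetime64(ts, "D").astype(np.int64))


def spans_day_index(spans: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Per-patient sorted enrollment intervals as integer days since epoch
    (fast path shared by the enrollment filter and survival construction)."""
    if len(spans) == 0:
        return {}
    starts = spans["start_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    ends = spans["end_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    out: dict[str, list[tuple[int, int]]] = {}
    for pid, st, en in zip(spans["patient_id"].to_numpy(), starts, ends):
        out.setdefault(pid, []).append((int(st), int(en)))
    for v in out.values():
        v.sort()
    return out


def _continuous_days(intervals, ys: int, ye: int, max_gap_days: int) -> bool:
    """Gap check over integer-day intervals clipped to ``[ys, ye)``."""
    if ye <= ys:
        return True
    cursor = ys
    for st, en in intervals:
        st, en = max(st, ys), min(en, ye)
        if st >= en:
            continue
        if st - cursor >= max_gap_days:
            return False
        cursor = max(cursor, en)
    return ye - cursor < max_gap_days


def year_continuity(
    spans: pd.DataFrame,
    year: int,
    max_gap_days: int = ENROLLMENT_GAP_DAYS,
    until: pd.Timestamp | None = None,
) -> bool:
    """True when enrollment in calendar *year* has no gap of >= *max_gap_days*.

    Gaps are measured within the year only: year start to first span, between
    successive spans, and last span to year end.  When *until* is given
    (death date) the evaluation window is truncated there, so a patient
    continuously enrolled up to death counts as continuous.
    """
    ys = _to_day(pd.Timestamp(year=year, month=1, day=1))
    ye = _to_day(pd.Timestamp(year=year + 1, month=1, day=1))
    if until is not None:
        ye = min(ye, _to_day(until))
    intervals = []
    if len(spans):
        intervals = sorted(
            zip(
                spans["start_date"].to_numpy().astype("datetime64[D]").astype(np.int64),
                spans["end_date"].to_numpy().astype("datetime64[D]").astype(np.int64),
            )
        )
    return _continuous_days(intervals, ys, ye, max_gap_days)


def apply_enrollment_filter(
    index_events: pd.DataFrame,
    spans: pd.DataFrame,
    deaths: pd.DataFrame,
    max_gap_days: int = ENROLLMENT_GAP_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep patients continuously enrolled during the index calendar year.

    Patients whose enrollment fails only because they died during the index
    year are retained.  Returns ``(kept, excluded)`` where *excluded* carries
    a ``reason`` column: ``no_enrollment`` (no spans at all in the index
    year) or ``enrollment_gap``.
    """
    death_dates = deaths.set_index("patient_id")["death_date"] if len(deaths) else pd.Series(dtype="datetime64[ns]")
    day_index = spans_day_index(spans)

    keep = np.zeros(len(index_events), dtype=bool)
    reasons = []
    for i, row in enumerate(index_events.itertuples()):
        year = int(row.index_year)
        intervals = day_index.get(row.patient_id, [])
        died = death_dates.get(row.patient_id, pd.NaT)
        ys = _to_day(pd.Timestamp(year, 1, 1))
        ye = _to_day(pd.Timestamp(year + 1, 1, 1))
        until = ye
        if pd.notna(died) and died.year == year:
            until = min(ye, _to_day(died))
        if _continuous_days(intervals, ys, until, max_gap_days):
            keep[i] = True
            reasons.append(None)
        elif not any(st < ye and en > ys for st, en in intervals):
            reasons.append("no_enrollment")
        else:
            reasons.append("enrollment_gap")

    kept = index_events.loc[keep].reset_index(drop=True)
    excluded = index_events.loc[~keep].copy()
    excluded["reason"] = [r for r in reasons if r is not None]
    return kept, excluded.reset_index(drop=True)


def compute_index_mme(fill, mme_table: dict[str, float]) -> float:
    """Total MME of one fill: strength_per_unit x quantity x conversion factor."""
    drug = fill["drug_base"]
    if drug not in mme_table:
        raise KeyError(f"no MME conversion factor for drug: {drug}")
    return float(fill["strength_per_unit"]) * float(fill["quantity"]) * float(mme_table[drug])


def categorize_mme(mme, breakpoints=MME_BREAKPOINTS) -> pd.Series | str:
    """Bin total index MME at the configured breakpoints (right-closed bins)."""
    bins = [-np.inf] + list(breakpoints) + [np.inf]
    return pd.cut(pd.Series(np.atleast_1d(mme), dtype=float), bins=bins, labels=MME_LABELS).astype(str)


def categorize_days_supply(days) -> pd.Series:
    bins = [-np.inf, 3, 6, np.inf]
    return pd.cut(pd.Series(np.atleast_1d(days), dtype=float), bins=bins, labels=DAYS_SUPPLY_LABELS).astype(str)


def categorize_age(age_years) -> pd.Series:
    bins = AGE_EDGES + [np.inf]
    return pd.cut(
        pd.Series(np.atleast_1d(age_years), dtype=float), bins=bins, labels=AGE_LABELS, right=False
    ).astype(str)


def _insurance_for_year(spans: pd.DataFrame, year: int, min_days: int = MIN_PLAN_DAYS) -> str:
    """Plan held >= *min_days* of calendar *year*; 'unknown' when none qualifies."""
    if len(spans) == 0:
        return "unknown"
    ys, ye = pd.Timestamp(year, 1, 1), pd.Timestamp(year + 1, 1, 1)
    start = spans["start_date"].clip(lower=ys)
    end = spans["end_date"].clip(upper=ye)
    days = (end - start).dt.days.clip(lower=0)
    per_plan = days.groupby(spans["plan"].values).sum()
    per_plan = per_plan[per_plan >= min_days]
    if len(per_plan) == 0:
        return "unknown"
    # deterministic tie-break: most covered days, then fixed plan order
    order = {p: i for i, p in enumerate(["commercial", "medicaid", "medicare", "dual", "unknown"])}
    best = sorted(per_plan.items(), key=lambda kv: (-kv[1], order.get(kv[0], 99)))
    return best[0][0]


def recode_combination_subgroup(index_events: pd.DataFrame) -> pd.Series:
    """Label 5 mg immediate-release index fills for the combination-product subgroup.

    ``hydro_apap_5mg`` / ``oxy_apap_5mg`` / ``oxy_mono_5mg`` for 5 mg
    strength-per-unit fills; everything else is ``other`` and excluded from
    the subgroup models.
    """
    strength5 = (index_events["strength_per_unit"].astype(float) == 5.0) & ~index_events[
        "long_acting"
    ].astype(bool)
    drug = index_events["drug_base"]
    combo = index_events["combination_ingredient"]
    out = pd.Series("other", index=index_events.index, dtype=object)
    out[strength5 & (drug == "hydrocodone") & (combo == "acetaminophen")] = "hydro_apap_5mg"
    out[strength5 & (drug == "oxycodone") & (combo == "acetaminophen")] = "oxy_apap_5mg"
    out[strength5 & (drug == "oxycodone") & (combo == "none")] = "oxy_mono_5mg"
    return out


def categorize(
    index_events: pd.DataFrame,
    demographics: pd.DataFrame,
    spans: pd.DataFrame,
    mme_table: dict[str, float],
    mme_breakpoints=MME_BREAKPOINTS,
    min_plan_days: int = MIN_PLAN_DAYS,
) -> pd.DataFrame:
    """Build the one-row-per-patient cohort table of modelling covariates.

    Requires one demographics record per index patient.  MME is binned at the
    fixed default breakpoints {75, 100, 200, 300}; days' supply at {<=3, 4-6,
    7+}; insurance is the plan held at least *min_plan_days* of the index
    year; age uses the 7 standard bins.
    """
    demo = demographics.set_index("patient_id")
    missing = index_events.loc[~index_events["patient_id"].isin(demo.index), "patient_id"]
    if len(missing):
        raise ValueError(f"missing demographics for patients: {missing.tolist()[:5]}")

    df = index_events.reset_index(drop=True).copy()
    if "subgroup_drug" not in df.columns:
        df["subgroup_drug"] = recode_combination_subgroup(df)
    factors = df["drug_base"].map(mme_table)
    unknown = df.loc[factors.isna(), "drug_base"].unique().tolist()
    if unknown:
        raise KeyError(f"no MME conversion factor for drug: {unknown}")
    df["index_mme"] = df["strength_per_unit"].astype(float) * df["quantity"].astype(float) * factors

    demo_rows = demo.loc[df["patient_id"]]
    spans_by_patient = dict(tuple(spans.groupby("patient_id"))) if len(spans) else {}
    empty_spans = spans.iloc[0:0] if len(spans) else pd.DataFrame(columns=["start_date", "end_date", "plan"])

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "drug_group": df["drug_group"],
            "subgroup_drug": df["subgroup_drug"],
            "age_category": categorize_age(demo_rows["age_years"].to_numpy()).to_numpy(),
            "gender": demo_rows["gender"].to_numpy(),
            "race_ethnicity": demo_rows["race_ethnicity"].to_numpy(),
            "insurance": [
                _insurance_for_year(
                    spans_by_patient.get(pid, empty_spans), int(yr), min_days=min_plan_days
                )
                for pid, yr in zip(df["patient_id"], df["index_year"])
            ],
            "urbanization": demo_rows["urbanization"].to_numpy(),
            "index_year": df["index_year"].astype(int),
            "index_date": df["index_date"],
            "index_mme": df["index_mme"],
            "mme_category": categorize_mme(df["index_mme"].to_numpy(), mme_breakpoints).to_numpy(),
            "days_supply_category": categorize_days_supply(df["days_supply"].to_numpy()).to_numpy(),
            "prescriber_id": df["prescriber_id"],
        }
    )
    return out
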