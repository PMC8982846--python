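"""Outcome phenotyping: chronic-use definitions, overdose events, survival
time with calendar-year censoring, cumulative 6-month MME, and drug switching.

Chronic use (primary definition) requires, within the 365 days starting at
the index fill: (a) at least six opioid fills of any type including the
index, and (b) average uncovered days of 30 or less.  The uncovered period
between consecutive fills is ``max(0, next_fill_date - (fill_date +
days_supply))`` — early refills do not accumulate negative credit — and the
terminal gap substitutes day 365 for the next fill date.  The average divides
total uncovered days by the number of inter-fill gaps plus one.

The alternative definition flags episodes longer than 90 days (index to last
in-window fill) with either total days' supply >= 120 or >= 10 fills.

Survival time runs from the index date to the earliest of: first fatal or
non-fatal opioid overdose (the event), loss of continuous enrollment in a
post-index calendar year (censored at December 31 of the preceding year),
death from a non-opioid cause, or the study end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ENROLLMENT_GAP_DAYS, _continuous_days, _to_day, spans_day_index
from .registry import CodeSet

CHRONIC_WINDOW_DAYS = 365
SECONDARY_WINDOW_DAYS = 183  # "6 months", half-open, index day excluded
STUDY_END = "2018-12-31"

CENSOR_REASONS = ["enrollment_loss", "non_opioid_death", "study_end", "none"]

CHRONIC_COLUMNS = [
    "patient_id",
    "n_fills_365",
    "total_uncovered_days",
    "n_gaps",
    "avg_uncovered",
    "chronic_primary",
    "episode_length_days",
    "total_days_supply",
    "chronic_alternative",
]


def classify_chronic(fills: pd.DataFrame, index_events: pd.DataFrame) -> pd.DataFrame:
    """Compute both chronic-use definitions for every index patient.

    *fills* is the cleaned fill table (any opioid type); the index fill must
    be present for every patient in *index_events*, else a contract-violation
    error is raised.  Returns one row per patient with the uncovered-days
    accounting and both flags.
    """
    idx = index_events[["patient_id", "index_date"]].reset_index(drop=True)
    merged = fills.merge(idx, on="patient_id", how="inner")
    window_end = merged["index_date"] + pd.Timedelta(days=CHRONIC_WINDOW_DAYS)
    in_window = (merged["fill_date"] >= merged["index_date"]) & (merged["fill_date"] < window_end)
    w = merged.loc[in_window].sort_values(["patient_id", "fill_date"], kind="mergesort")

    has_index = w.groupby("patient_id")["fill_date"].min().eq(
        idx.set_index("patient_id")["index_date"]
    )
    bad = has_index.reindex(idx["patient_id"]).fillna(False)
    if not bad.all():
        missing = idx.loc[~bad.to_numpy(), "patient_id"].tolist()
        raise ValueError(f"index fill absent from patient fills: {missing[:5]}")

    cover_end = w["fill_date"] + pd.to_timedelta(w["days_supply"].astype(float), unit="D")
    next_fill = w.groupby("patient_id")["fill_date"].shift(-1)
    terminal = w["index_date"] + pd.Timedelta(days=CHRONIC_WINDOW_DAYS)
    next_or_end = next_fill.fillna(terminal)
    gap = (next_or_end - cover_end).dt.days.astype(float).clip(lower=0.0)

    grp = w.groupby("patient_id", sort=True)
    res = pd.DataFrame(
        {
            "n_fills_365": grp.size(),
            "total_uncovered_days": gap.groupby(w["patient_id"]).sum(),
            "last_fill": grp["fill_date"].max(),
            "index_date": grp["index_date"].first(),
            "total_days_supply": grp["days_supply"].sum().astype(int),
        }
    )
    res["n_gaps"] = res["n_fills_365"] - 1
    res["avg_uncovered"] = res["total_uncovered_days"] / (res["n_gaps"] + 1)
    res["chronic_primary"] = (res["n_fills_365"] >= 6) & (res["avg_uncovered"] <= 30)
    res["episode_length_days"] = (res["last_fill"] - res["index_date"]).dt.days.astype(int)
    res["chronic_alternative"] = (res["episode_length_days"] > 90) & (
        (res["total_days_supply"] >= 120) | (res["n_fills_365"] >= 10)
    )
    res = res.reset_index().rename(columns={"index": "patient_id"})
    return res[CHRONIC_COLUMNS]


def definition_overlap(results: pd.DataFrame) -> tuple[float, float]:
    """Percent agreement between the two chronic-use definitions.

    Returns ``(pct_alt_also_primary, pct_primary_also_alt)`` on a 0-100
    scale, each with the respective definition's patients as denominator;
    ``nan`` when a denominator is empty.
    """
    alt = results["chronic_alternative"].astype(bool)
    pri = results["chronic_primary"].astype(bool)
    pct_alt_also_primary = 100.0 * (alt & pri).sum() / alt.sum() if alt.sum() else float("nan")
    pct_primary_also_alt = 100.0 * (alt & pri).sum() / pri.sum() if pri.sum() else float("nan")
    return pct_alt_also_primary, pct_primary_also_alt


def detect_overdose(
    claims: pd.DataFrame,
    death_record: pd.Series | None,
    code_set: CodeSet,
    index_date: pd.Timestamp,
) -> dict | None:
    """Earliest opioid overdose on/after *index_date* for one patient.

    Non-fatal events come from ED/inpatient diagnosis prefix matches; fatal
    events from the underlying-cause + multiple-cause combination or a
    literal-text term match.  Returns ``{patient_id, event_date, fatal,
    source}`` or ``None``.
    """
    events: list[tuple[pd.Timestamp, bool, str]] = []
    if claims is not None and len(claims):
        hits = claims[claims["diagnosis_codes"].map(code_set.matches_nonfatal)]
        for row in hits.itertuples():
            source = "ED_claim" if row.setting == "ED" else "inpatient_claim"
            events.append((row.service_date, False, source))
    if death_record is not None:
        by_codes = code_set.matches_underlying(death_record["underlying_cause"]) and code_set.matches_t_code(
            death_record["multiple_causes"]
        )
        if by_codes:
            events.append((death_record["death_date"], True, "death_codes"))
        elif code_set.matches_literal(death_record["literal_text"]):
            events.append((death_record["death_date"], True, "death_literal"))
    events = [e for e in events if pd.notna(e[0]) and e[0] >= index_date]
    if not events:
        return None
    # earliest event; on ties a fatal record outranks a same-day claim
    date, fatal, source = sorted(events, key=lambda e: (e[0], not e[1]))[0]
    return {"event_date": date, "fatal": fatal, "source": source}


def detect_overdoses(
    claims: pd.DataFrame,
    deaths: pd.DataFrame,
    code_set: CodeSet,
    index_events: pd.DataFrame,
) -> pd.DataFrame:
    """Batch overdose detection: one row per patient with an event."""
    claims_by_patient = dict(tuple(claims.groupby("patient_id"))) if len(claims) else {}
    deaths_by_patient = (
        {r["patient_id"]: r for _, r in deaths.iterrows()} if len(deaths) else {}
    )
    rows = []
    for row in index_events.itertuples():
        ev = detect_overdose(
            claims_by_patient.get(row.patient_id),
            deaths_by_patient.get(row.patient_id),
            code_set,
            row.index_date,
        )
        if ev is not None:
            rows.append({"patient_id": row.patient_id, **ev})
    return pd.DataFrame(rows, columns=["patient_id", "event_date", "fatal", "source"])


def compute_survival(
    index_events: pd.DataFrame,
    spans: pd.DataFrame,
    overdose_events: pd.DataFrame,
    deaths: pd.DataFrame,
    study_end: str = STUDY_END,
    max_gap_days: int = ENROLLMENT_GAP_DAYS,
) -> pd.DataFrame:
    """Survival days from index with event indicator and censoring reason.

    Continuous enrollment is evaluated per post-index calendar year; the
    first failing year backdates the censor date to December 31 of the
    preceding year.  The year of death is evaluated only up to the death
    date, mirroring the deceased exception of the inclusion filter.  On
    same-day ties the overdose event takes precedence, then study end, then
    non-opioid death, then enrollment loss.
    """
    study_end = pd.Timestamp(study_end)
    day_index = spans_day_index(spans)
    od = overdose_events.set_index("patient_id") if len(overdose_events) else pd.DataFrame()
    death_dates = deaths.set_index("patient_id")["death_date"] if len(deaths) else pd.Series(dtype="datetime64[ns]")

    rows = []
    for row in index_events.itertuples():
        index_date = row.index_date
        # tie-break priority on equal dates: the overdose event, then study
        # end (so survival equals the index->study-end span only under
        # study_end censoring), then death, then enrollment loss
        candidates: list[tuple[pd.Timestamp, int, str]] = [(study_end, 1, "study_end")]

        died = death_dates.get(row.patient_id, pd.NaT)
        od_date, od_fatal = pd.NaT, False
        if len(od) and row.patient_id in od.index:
            od_date = od.loc[row.patient_id, "event_date"]
            od_fatal = bool(od.loc[row.patient_id, "fatal"])
            candidates.append((od_date, 0, "event"))
        if pd.notna(died) and not (od_fatal and died == od_date):
            candidates.append((died, 2, "non_opioid_death"))

        intervals = day_index.get(row.patient_id, [])
        last_year = min(study_end.year, died.year if pd.notna(died) else study_end.year)
        for year in range(int(row.index_year) + 1, last_year + 1):
            ys = _to_day(pd.Timestamp(year, 1, 1))
            ye = _to_day(pd.Timestamp(year + 1, 1, 1))
            if pd.notna(died) and died.year == year:
                ye = min(ye, _to_day(died))
            if not _continuous_days(intervals, ys, ye, max_gap_days):
                candidates.append((pd.Timestamp(year - 1, 12, 31), 3, "enrollment_loss"))
                break

        end_date, _, kind = sorted(candidates, key=lambda c: (c[0], c[1]))[0]
        days = (end_date - index_date).days
        if days < 0:
            raise ValueError(
                f"negative survival interval for {row.patient_id}: index {index_date.date()}, end {end_date.date()}"
            )
        event = kind == "event"
        rows.append(
            {
                "patient_id": row.patient_id,
                "survival_days": int(days),
                "event": event,
                "censor_reason": "none" if event else kind,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "survival_days", "event", "censor_reason"])


def secondary_outcomes(
    fills: pd.DataFrame,
    index_events: pd.DataFrame,
    mme_table: dict[str, float],
    window_days: int = SECONDARY_WINDOW_DAYS,
) -> pd.DataFrame:
    """Cumulative 6-month MME (excluding the index fill) and the switch flag.

    The window is ``(index_date, index_date + window_days)`` — strictly after
    the index day, half-open at the end.  ``switched`` is true when any
    in-window fill has a different base opioid than the index fill, and is
    missing (pd.NA) for patients with no additional fill.
    """
    idx = index_events[["patient_id", "index_date", "drug_base"]].rename(
        columns={"drug_base": "index_drug"}
    )
    merged = fills.merge(idx, on="patient_id", how="inner")
    in_window = (merged["fill_date"] > merged["index_date"]) & (
        merged["fill_date"] < merged["index_date"] + pd.Timedelta(days=window_days)
    )
    w = merged.loc[in_window].copy()
    factors = w["drug_base"].map(mme_table)
    unknown = w.loc[factors.isna(), "drug_base"].unique().tolist()
    if unknown:
        raise KeyError(f"no MME conversion factor for drug: {unknown}")
    w["fill_mme"] = w["strength_per_unit"].astype(float) * w["quantity"].astype(float) * factors
    w["is_switch"] = w["drug_base"] != w["index_drug"]

    grp = w.groupby("patient_id")
    agg = pd.DataFrame({"cumulative_mme_6mo": grp["fill_mme"].sum(), "switched": grp["is_switch"].any()})

    out = idx[["patient_id"]].copy()
    out["cumulative_mme_6mo"] = agg["cumulative_mme_6mo"].reindex(out["patient_id"]).fillna(0.0).to_numpy()
    out["any_additional_fill"] = out["patient_id"].isin(agg.index).to_numpy()
    switched = agg["switched"].reindex(out["patient_id"]).to_numpy(dtype=object)
    out["switched"] = pd.array(
        [bool(s) if s is not None and s == s else pd.NA for s in switched], dtype="boolean"
    )
    return out


def died_within_year(index_events: pd.DataFrame, deaths: pd.DataFrame, days: int = 365) -> pd.Series:
    """Boolean mask (indexed like *index_events*) of patients who died within
    *days* of index — used by the sensitivity variant that excludes them."""
    death_dates = deaths.set_index("patient_id")["death_date"] if len(deaths) else pd.Series(dtype="datetime64[ns]")
    dd = index_events["patient_id"].map(death_dates)
    return dd.notna() & (dd < index_events["index_date"] + pd.Timedelta(days=days))
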