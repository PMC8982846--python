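import numpy as np
import pandas as pd
import pytest

import opioidcohort as oc


def make_fill(
    patient_id="P1",
    prescriber_id="D1",
    fill_date="2016-01-01",
    drug_base="hydrocodone",
    combination_ingredient="acetaminophen",
    strength_per_unit=5.0,
    quantity=20.0,
    days_supply=5,
    long_acting=False,
):
    return {
        "patient_id": patient_id,
        "prescriber_id": prescriber_id,
        "fill_date": pd.Timestamp(fill_date),
        "drug_base": drug_base,
        "combination_ingredient": combination_ingredient,
        "strength_per_unit": strength_per_unit,
        "quantity": quantity,
        "days_supply": days_supply,
        "long_acting": long_acting,
    }


def fills_frame(rows):
    return pd.DataFrame([make_fill(**r) if isinstance(r, dict) else r for r in rows])


def trajectory(index_date, day_supply_pairs, patient_id="P1", drug_base="hydrocodone"):
    """Fill table for one patient from (day-offset, days-supply) pairs."""
    index_date = pd.Timestamp(index_date)
    return fills_frame(
        [
            dict(
                patient_id=patient_id,
                fill_date=index_date + pd.Timedelta(days=int(d)),
                days_supply=int(s),
                drug_base=drug_base,
            )
            for d, s in day_supply_pairs
        ]
    )


def index_frame(patient_id="P1", index_date="2016-01-01", drug_base="hydrocodone", **kw):
    fill = make_fill(patient_id=patient_id, fill_date=index_date, drug_base=drug_base, **kw)
    fill["index_date"] = fill["fill_date"]
    fill["index_year"] = fill["fill_date"].year
    fill["drug_group"] = "oxycodone_SA" if drug_base == "oxycodone" else "hydrocodone_SA"
    return pd.DataFrame([fill])


def day_coverage_oracle(day_supply_pairs, window=365):
    """Independent day-by-day uncovered-days count.

    Coverage restarts at each fill: on any given day the patient is covered
    iff the most recent fill on/before that day still has supply left.
    """
    pairs = sorted((int(d), int(s)) for d, s in day_supply_pairs)
    uncovered = 0
    for day in range(window):
        last = None
        for fd, s in pairs:
            if fd <= day:
                last = (fd, s)
            else:
                break
        if last is None or day >= last[0] + last[1]:
            uncovered += 1
    return uncovered


@pytest.fixture(scope="session")
def code_set():
    return oc.load_code_set()


@pytest.fixture(scope="session")
def mme_table():
    return oc.load_mme_table()


@pytest.fixture(scope="session")
def small_population():
    """One shared mechanistic population for cross-module tests."""
    cfg = oc.SimulationConfig(n_patients=6000, seed=42)
    tables, gt = oc.generate_population(cfg)
    return cfg, tables, gt
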