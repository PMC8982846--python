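"""Synthetic linked-registry generator with known ground truth.

Real prescription-registry linkages of this kind cannot be shared, so every
pipeline stage here is exercised on synthetic data whose effect structure is
configured explicitly.  Two generation paths are provided:

``generate_population``
    Emits the four linked registry tables (fills, enrollment spans,
    encounter claims, death records) plus demographics.  Chronic use arises
    *mechanistically* through a per-patient refill continuation process — the
    chronic-use label is never stamped directly — while overdose times are
    drawn from an exponential hazard with configured covariate log hazard
    ratios.  Fatal overdoses emit death records with qualifying code
    combinations (or literal-text-only records, to exercise that detection
    path); non-fatal overdoses emit ED/inpatient claims with T40.x codes;
    enrollment churn generates calendar-year censoring.  Optional impurities
    (duplicate rows, missing prescribers, pre-index history) exercise the
    cleaning and naive-lookback exclusions.

``generate_model_frame``
    Emits a model-ready cohort frame in which each outcome is drawn directly
    from the parametric form the corresponding estimation stage assumes
    (logistic chronic use, exponential-hazard overdose, zero-inflated
    negative binomial cumulative MME, logistic switching).  This is the path
    used for null-recovery and parameter-recovery simulation, where the
    estimand must equal the configured coefficient exactly.

Default parameters emulate the published cohort margins: 68% hydrocodone
index share, a female majority, oxycodone index prescriptions shifted toward
higher MME and longer days' supply, ~2.8% first-year chronic use, and a
~0.3% overdose rate over follow-up.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registry import RegistryTables

STUDY_END = pd.Timestamp("2018-12-31")

AGE_LABELS = ["18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+"]
AGE_LOW = [18, 25, 35, 45, 55, 65, 75]
AGE_HIGH = [24, 34, 44, 54, 64, 74, 94]
RACE_LABELS = ["White", "Black", "Hispanic", "Asian-Pacific Islander", "Other", "Unknown"]
PLAN_LABELS = ["commercial", "medicaid", "medicare", "dual"]
URBAN_LABELS = [
    "large_central_metro",
    "large_fringe_metro",
    "medium_metro",
    "small_metro",
    "micropolitan",
    "noncore",
    "unknown",
]

_MME_EDGES = [75.0, 100.0, 200.0, 300.0]
_MME_LABELS = ["<=75", "76-100", "101-200", "201-300", ">300"]


@dataclass
class SimulationConfig:
    """Ground-truth effect sizes, rates, and distributions for the generator.

    Effect sizes are on the log odds-ratio / log hazard-ratio scale.  The
    defaults encode the study conditions: drug assignment 68% hydrocodone,
    chronic-use drug log-OR log(0.95) confounded by an MME gradient (so the
    unadjusted association runs the other way), overdose log-HRs by
    combination subgroup (1.0 / 1.26 / 2.18, and 1.65 for other oxycodone),
    zero-MME log-OR log(0.88), count-portion log rate ratio log(1.20), and
    switching log-OR log(1.24).
    """

    n_patients: int = 20_000
    seed: int = 0
    index_start: str = "2015-01-01"
    index_end: str = "2017-12-31"
    study_end: str = "2018-12-31"
    enrollment_start: str = "2014-01-01"

    # exposure and covariate margins
    p_oxycodone: float = 0.32
    p_oxy_combination: float = 0.48
    p_female: float = 0.552
    age_probs: tuple = (0.1274, 0.2049, 0.1745, 0.1737, 0.1743, 0.0929, 0.0523)
    race_probs: tuple = (0.7351, 0.0316, 0.0912, 0.0241, 0.0152, 0.1028)
    plan_probs: tuple = (0.448, 0.380, 0.129, 0.043)
    urban_probs: tuple = (0.1805, 0.2208, 0.1896, 0.1418, 0.0937, 0.0142, 0.1594)
    n_prescribers: int = 600
    prescriber_sigma: float = 1.0  # lognormal spread of prescriber volumes

    # index prescription distributions, hydrocodone vs oxycodone
    strength_choices_hydro: tuple = (5.0, 7.5, 10.0)
    strength_probs_hydro: tuple = (0.75, 0.15, 0.10)
    strength_choices_oxy: tuple = (5.0, 10.0, 15.0, 20.0)
    strength_probs_oxy: tuple = (0.62, 0.25, 0.08, 0.05)
    quantity_logmean_hydro: float = 2.71  # ~15 tablets
    quantity_logmean_oxy: float = 3.33  # ~28 tablets
    quantity_logsd: float = 0.45
    days_supply_choices: tuple = (1, 2, 3, 4, 5, 6, 7, 10, 14, 30)
    days_supply_probs_hydro: tuple = (0.18, 0.20, 0.22, 0.10, 0.08, 0.05, 0.07, 0.05, 0.03, 0.02)
    days_supply_probs_oxy: tuple = (0.10, 0.15, 0.20, 0.12, 0.10, 0.07, 0.10, 0.08, 0.05, 0.03)

    # chronic-use effect structure (log odds ratios)
    chronic_intercept: float = -5.55  # direct (model-frame) mode
    chronic_logor_oxycodone: float = float(np.log(0.95))
    chronic_logor_mme: tuple = (0.0, 0.03, 0.39, 0.61, 1.36)
    chronic_logor_age: tuple = (0.0, 0.59, 1.00, 1.27, 1.34, 1.09, 1.12)
    chronic_logor_medicaid: float = 1.05
    chronic_re_sd: float = 0.25  # prescriber random-intercept SD

    # mechanistic refill process (population generator).  Each patient has a
    # per-fill continuation probability on the logit scale: intercept +
    # scaled chronic-use covariate effects + a latent heaviness frailty.
    # Heavier patients also draw longer "maintenance" days' supplies on
    # refills, which is what lets a small tail of trajectories satisfy the
    # coverage criterion while ~40% of patients refill at least once.
    cont_intercept: float = -1.05  # logit of per-fill continuation at reference
    cont_scale: float = 0.45  # maps chronic log-ORs onto the continuation logit
    cont_re_sd: float = 0.85  # latent heaviness SD on the continuation logit
    maintenance_supply_choices: tuple = (7, 10, 14, 30)
    maintenance_supply_probs: tuple = (0.10, 0.15, 0.25, 0.50)
    maintenance_boost: float = 2.4  # scales p(maintenance supply) vs continuation
    refill_extra_gap_mean: float = 5.0
    refill_extra_gap_sd: float = 10.0
    max_fills: int = 20
    p_switch_per_refill_hydro: float = 0.20
    p_switch_per_refill_oxy: float = 0.24
    p_same_prescriber_refill: float = 0.7

    # overdose hazard (log hazard ratios; exponential event times)
    overdose_base_daily_hazard: float = 1.5e-6
    overdose_loghr_oxy_apap: float = float(np.log(1.26))
    overdose_loghr_oxy_mono: float = float(np.log(2.18))
    overdose_loghr_oxy_other: float = float(np.log(1.65))
    overdose_loghr_male: float = 0.386
    overdose_loghr_medicaid: float = 1.0
    p_fatal_given_overdose: float = 0.2
    p_literal_only_death: float = 0.15

    # cumulative-MME (ZINB) and switching effect structure
    zero_mme_intercept: float = 0.40
    zero_mme_logor_oxycodone: float = float(np.log(0.88))
    count_mme_intercept: float = float(np.log(260.0))
    count_mme_logrr_oxycodone: float = float(np.log(1.20))
    nb_alpha: float = 1.5
    switch_intercept: float = -0.58
    switch_logor_oxycodone: float = float(np.log(1.24))

    # enrollment and mortality
    annual_churn: float = 0.12
    p_index_year_gap: float = 0.03
    p_no_enrollment: float = 0.01
    annual_background_mortality: float = 0.013

    # data impurities for cleaning/exclusion testing
    p_prior_fill: float = 0.04
    p_prior_overdose_claim: float = 0.004
    p_missing_prescriber: float = 0.005
    p_duplicate_fill: float = 0.002
    p_background_claim: float = 0.08

    def validate(self) -> None:
        probs = {
            name: getattr(self, name)
            for name in (
                "p_oxycodone", "p_oxy_combination", "p_female", "annual_churn",
                "p_index_year_gap", "p_no_enrollment", "p_prior_fill",
                "p_prior_overdose_claim", "p_missing_prescriber", "p_duplicate_fill",
                "p_background_claim", "p_fatal_given_overdose", "p_literal_only_death",
                "p_switch_per_refill_hydro", "p_switch_per_refill_oxy",
                "p_same_prescriber_refill",
            )
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"configuration error: {name}={p} is not a probability")
        for name in ("age_probs", "race_probs", "plan_probs", "urban_probs"):
            vec = np.asarray(getattr(self, name), float)
            if (vec < 0).any() or not np.isclose(vec.sum(), 1.0, atol=1e-6):
                raise ValueError(f"configuration error: {name} must be a probability vector")
        for name in ("overdose_base_daily_hazard", "annual_background_mortality", "nb_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"configuration error: {name} must be non-negative")
        if self.n_patients < 0:
            raise ValueError("configuration error: n_patients must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        listy = {
            k: tuple(v) if isinstance(v, list) else v for k, v in known.items()
        }
        cfg = cls(**listy)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def replace(self, **kw) -> "SimulationConfig":
        cfg = dc_replace(self, **kw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Per-patient latent assignments and the configuration that produced them."""

    frame: pd.DataFrame
    config: SimulationConfig
    run_id: str


def _normalized(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    return v / v.sum()


def _sample_covariates(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> pd.DataFrame:
    """Patient-level exposure and covariate draws shared by both generators."""
    start = pd.Timestamp(cfg.index_start)
    n_days = (pd.Timestamp(cfg.index_end) - start).days + 1
    index_date = start + pd.to_timedelta(rng.integers(0, n_days, size=n), unit="D")

    oxy = rng.random(n) < cfg.p_oxycodone
    combo = np.where(
        oxy,
        np.where(rng.random(n) < cfg.p_oxy_combination, "acetaminophen", "none"),
        np.where(rng.random(n) < 0.97, "acetaminophen", "ibuprofen"),
    )
    strength = np.where(
        oxy,
        rng.choice(cfg.strength_choices_oxy, size=n, p=_normalized(cfg.strength_probs_oxy)),
        rng.choice(cfg.strength_choices_hydro, size=n, p=_normalized(cfg.strength_probs_hydro)),
    )
    logmean = np.where(oxy, cfg.quantity_logmean_oxy, cfg.quantity_logmean_hydro)
    quantity = np.clip(np.round(rng.lognormal(logmean, cfg.quantity_logsd)), 4, 120)
    ds_choices = np.asarray(cfg.days_supply_choices)
    ds = np.where(
        oxy,
        rng.choice(ds_choices, size=n, p=_normalized(cfg.days_supply_probs_oxy)),
        rng.choice(ds_choices, size=n, p=_normalized(cfg.days_supply_probs_hydro)),
    ).astype(int)

    mme = strength * quantity * np.where(oxy, 1.5, 1.0)
    mme_cat = pd.cut(mme, [-np.inf] + _MME_EDGES + [np.inf], labels=_MME_LABELS).astype(str)

    age_idx = rng.choice(len(AGE_LABELS), size=n, p=_normalized(cfg.age_probs))
    low = np.asarray(AGE_LOW)[age_idx]
    high = np.asarray(AGE_HIGH)[age_idx]
    age_years = low + (rng.random(n) * (high - low + 1)).astype(int)

    volumes = rng.lognormal(0.0, cfg.prescriber_sigma, size=max(cfg.n_prescribers, 1))
    prescriber_idx = rng.choice(len(volumes), size=n, p=volumes / volumes.sum())

    subgroup = np.full(n, "other", dtype=object)
    five = strength == 5.0
    subgroup[five & ~oxy & (combo == "acetaminophen")] = "hydro_apap_5mg"
    subgroup[five & oxy & (combo == "acetaminophen")] = "oxy_apap_5mg"
    subgroup[five & oxy & (combo == "none")] = "oxy_mono_5mg"

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "prescriber_id": [f"D{i:05d}" for i in prescriber_idx],
            "index_date": index_date,
            "index_year": index_date.year,
            "oxy": oxy,
            "drug_base": np.where(oxy, "oxycodone", "hydrocodone"),
            "drug_group": np.where(oxy, "oxycodone_SA", "hydrocodone_SA"),
            "combination_ingredient": combo,
            "subgroup_drug": subgroup,
            "strength_per_unit": strength.astype(float),
            "quantity": quantity.astype(float),
            "days_supply": ds,
            "index_mme": mme,
            "mme_category": mme_cat,
            "days_supply_category": pd.cut(ds, [-np.inf, 3, 6, np.inf], labels=["<=3", "4-6", "7+"]).astype(str),
            "age_category": np.asarray(AGE_LABELS, dtype=object)[age_idx],
            "age_years": age_years,
            "gender": np.where(rng.random(n) < cfg.p_female, "F", "M"),
            "race_ethnicity": rng.choice(RACE_LABELS, size=n, p=_normalized(cfg.race_probs)),
            "insurance": rng.choice(PLAN_LABELS, size=n, p=_normalized(cfg.plan_probs)),
            "urbanization": rng.choice(URBAN_LABELS, size=n, p=_normalized(cfg.urban_probs)),
        }
    )


def _chronic_linpred(cfg: SimulationConfig, cov: pd.DataFrame) -> np.ndarray:
    """Covariate contribution to the chronic-use logit (excluding intercept)."""
    mme_map = dict(zip(_MME_LABELS, cfg.chronic_logor_mme))
    age_map = dict(zip(AGE_LABELS, cfg.chronic_logor_age))
    lp = (
        cfg.chronic_logor_oxycodone * cov["oxy"].to_numpy(float)
        + cov["mme_category"].map(mme_map).to_numpy(float)
        + cov["age_category"].map(age_map).to_numpy(float)
        + cfg.chronic_logor_medicaid * (cov["insurance"] == "medicaid").to_numpy(float)
    )
    return lp


def _overdose_hazard(cfg: SimulationConfig, cov: pd.DataFrame) -> np.ndarray:
    """Per-patient daily overdose hazard under the configured log-HRs."""
    sub = cov["subgroup_drug"].to_numpy()
    oxy = cov["oxy"].to_numpy(bool)
    loghr = np.zeros(len(cov))
    loghr += np.where(sub == "oxy_apap_5mg", cfg.overdose_loghr_oxy_apap, 0.0)
    loghr += np.where(sub == "oxy_mono_5mg", cfg.overdose_loghr_oxy_mono, 0.0)
    loghr += np.where((sub == "other") & oxy, cfg.overdose_loghr_oxy_other, 0.0)
    loghr += np.where(cov["gender"].to_numpy() == "M", cfg.overdose_loghr_male, 0.0)
    loghr += np.where(cov["insurance"].to_numpy() == "medicaid", cfg.overdose_loghr_medicaid, 0.0)
    return cfg.overdose_base_daily_hazard * np.exp(loghr)


def _censoring_days(rng: np.random.Generator, cfg: SimulationConfig, cov: pd.DataFrame):
    """Days from index to enrollment-churn censor, background death, study end.

    Enrollment churn fails whole post-index calendar years at rate
    ``annual_churn``; the censor date backdates to Dec 31 preceding the first
    failed year.  Returns (churn_days, churn_year, death_days, end_days).
    """
    n = len(cov)
    study_end = pd.Timestamp(cfg.study_end)
    end_days = (study_end - cov["index_date"]).dt.days.to_numpy()

    if cfg.annual_churn > 0:
        u = rng.random(n)
        k = np.floor(np.log(np.clip(u, 1e-300, None)) / np.log(1.0 - cfg.annual_churn)).astype(int)
    else:
        k = np.full(n, 10**6)
    churn_year = cov["index_year"].to_numpy() + 1 + k
    churn_date = pd.Series(
        pd.to_datetime(
            [
                pd.Timestamp(int(y) - 1, 12, 31) if y <= study_end.year else pd.NaT
                for y in churn_year
            ]
        ),
        index=cov.index,
    )
    churn_days = (churn_date - cov["index_date"]).dt.days.to_numpy(float)
    churn_days = np.where(np.isnan(churn_days), np.inf, churn_days)

    daily_mort = cfg.annual_background_mortality / 365.0
    death_days = (
        rng.exponential(1.0 / daily_mort, size=n) if daily_mort > 0 else np.full(n, np.inf)
    )
    return churn_days, np.where(np.isinf(churn_days), -1, churn_year), death_days, end_days


def generate_model_frame(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Model-ready cohort frame with outcomes drawn from the configured
    parametric effect models (used for estimator recovery simulations)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    cov = _sample_covariates(rng, cfg, n)

    # chronic use: logistic with prescriber random intercept
    codes, _ = pd.factorize(cov["prescriber_id"], sort=True)
    re = rng.normal(0.0, cfg.chronic_re_sd, size=codes.max() + 1 if n else 0)
    lp = cfg.chronic_intercept + _chronic_linpred(cfg, cov) + (re[codes] if n else 0.0)
    p_chronic = 1.0 / (1.0 + np.exp(-lp))
    chronic = rng.random(n) < p_chronic

    # overdose: exponential hazard with calendar censoring
    lam = _overdose_hazard(cfg, cov)
    t_od = rng.exponential(1.0, size=n) / np.clip(lam, 1e-300, None)
    churn_days, churn_year, death_days, end_days = _censoring_days(rng, cfg, cov)
    censor = np.minimum.reduce([churn_days, death_days, end_days.astype(float)])
    event = t_od <= censor
    survival_days = np.minimum(t_od, censor).astype(int)

    # cumulative 6-month MME: zero-inflated NB2
    p_zero = 1.0 / (1.0 + np.exp(-(cfg.zero_mme_intercept + cfg.zero_mme_logor_oxycodone * cov["oxy"])))
    structural_zero = rng.random(n) < p_zero
    mu = np.exp(cfg.count_mme_intercept + cfg.count_mme_logrr_oxycodone * cov["oxy"].to_numpy(float))
    nb_n = 1.0 / cfg.nb_alpha
    nb_p = nb_n / (nb_n + mu)
    counts = rng.negative_binomial(nb_n, nb_p, size=n) if n else np.array([], int)
    cumulative = np.where(structural_zero, 0, counts).astype(float)

    p_switch = 1.0 / (1.0 + np.exp(-(cfg.switch_intercept + cfg.switch_logor_oxycodone * cov["oxy"])))
    any_fill = cumulative > 0
    switched_draw = rng.random(n) < p_switch
    switched = pd.array(
        [bool(s) if a else pd.NA for s, a in zip(switched_draw, any_fill)], dtype="boolean"
    )

    frame = cov.copy()
    frame["chronic_primary"] = chronic
    frame["survival_days"] = survival_days
    frame["event"] = event
    frame["cumulative_mme_6mo"] = cumulative
    frame["any_additional_fill"] = any_fill
    frame["switched"] = switched

    truth = cov.copy()
    truth["p_chronic"] = p_chronic
    truth["daily_hazard"] = lam
    truth["t_overdose_days"] = t_od
    truth["censor_days"] = censor
    gt = GroundTruth(frame=truth, config=cfg, run_id=cfg.config_hash())
    return frame, gt


def _empty_tables() -> RegistryTables:
    from . import registry as reg

    return RegistryTables(
        fills=pd.DataFrame(columns=reg.FILL_COLUMNS),
        spans=pd.DataFrame(columns=reg.SPAN_COLUMNS),
        claims=pd.DataFrame(columns=reg.CLAIM_COLUMNS),
        deaths=pd.DataFrame(columns=reg.DEATH_COLUMNS),
        demographics=pd.DataFrame(columns=reg.DEMOGRAPHICS_COLUMNS),
    )


_OTHER_OPIOIDS = ["codeine", "tramadol", "morphine", "hydromorphone"]
_NONFATAL_DX = {
    "heroin": "T40.1X1A",
    "opium": "T40.0X1A",
    "other": "T40.2X1A",
    "methadone": "T40.3X1A",
    "synthetic": "T40.4X1A",
    "unspecified": "T40.601A",
}
_FATAL_T = ["T40.1", "T40.2", "T40.3", "T40.4", "T40.6"]
_FATAL_UNDERLYING = ["X42", "X44", "X41", "X64", "Y12"]
_OD_LITERALS = [
    "acute heroin toxicity",
    "fentanyl intoxication",
    "oxycodone overdose",
    "mixed opioid toxicity",
    "methadone toxicity",
]
_NONOPIOID_DEATHS = [
    ("I21.9", "acute myocardial infarction"),
    ("C34.90", "lung cancer"),
    ("J44.9", "chronic obstructive pulmonary disease"),
    ("I64", "cerebrovascular accident"),
]
_BACKGROUND_DX = ["S52.501A", "J18.9", "R10.9", "M54.5"]


def _chronic_truth_from_plan(
    m: np.ndarray, supplies: np.ndarray, extras: np.ndarray, fill_pid: np.ndarray
) -> pd.DataFrame:
    """Apply the chronic-use arithmetic to the *planned* trajectories.

    Works on the planned refill schedule before death truncation, giving the
    latent process-level truth the emitted classifier is compared against.
    """
    offsets = np.zeros(len(fill_pid))
    df = pd.DataFrame({"pid": fill_pid, "supply": supplies, "inc": extras})
    df["day"] = df.groupby("pid")["inc"].cumsum() - df["inc"] + offsets
    w = df[df["day"] < 365]
    nxt = w.groupby("pid")["day"].shift(-1)
    gap = np.clip((nxt.fillna(365.0) - (w["day"] + w["supply"])), 0.0, None)
    grp = w.groupby("pid")
    out = pd.DataFrame(
        {
            "n_fills": grp.size(),
            "uncovered": gap.groupby(w["pid"]).sum(),
            "last_day": grp["day"].max(),
            "tds": grp["supply"].sum(),
        }
    )
    out["true_chronic_primary"] = (out["n_fills"] >= 6) & (out["uncovered"] / out["n_fills"] <= 30)
    out["true_chronic_alternative"] = (out["last_day"] > 90) & (
        (out["tds"] >= 120) | (out["n_fills"] >= 10)
    )
    return out


def generate_population(cfg: SimulationConfig) -> tuple[RegistryTables, GroundTruth]:
    """Generate the four linked registry tables plus demographics.

    See the module docstring for the generating mechanisms.  Identical
    config and seed yield byte-identical tables.
    """
    cfg.validate()
    if cfg.n_patients == 0:
        return _empty_tables(), GroundTruth(pd.DataFrame(), cfg, cfg.config_hash())
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    cov = _sample_covariates(rng, cfg, n)
    study_end = pd.Timestamp(cfg.study_end)

    # ---- refill trajectories (mechanistic chronic use) -------------------
    heaviness = rng.normal(0.0, cfg.cont_re_sd, size=n)
    cont_logit = cfg.cont_intercept + cfg.cont_scale * _chronic_linpred(cfg, cov) + heaviness
    p_cont = 1.0 / (1.0 + np.exp(-cont_logit))
    u = rng.random(n)
    n_refills = np.floor(np.log(np.clip(u, 1e-300, None)) / np.log(np.clip(p_cont, 1e-12, 1 - 1e-12))).astype(int)
    # u < p^k gives k successes; cap the chain
    n_refills = np.minimum(n_refills, cfg.max_fills - 1)
    m = n_refills + 1  # fills including index

    fill_pid = np.repeat(np.arange(n), m)
    fill_no = np.concatenate([np.arange(k) for k in m])
    n_fills_total = len(fill_pid)

    is_index = fill_no == 0
    oxy_f = cov["oxy"].to_numpy()[fill_pid]
    # per-fill supplies: index uses the sampled index supply, refills redrawn
    ds_choices = np.asarray(cfg.days_supply_choices)
    supply = np.where(
        oxy_f,
        rng.choice(ds_choices, size=n_fills_total, p=_normalized(cfg.days_supply_probs_oxy)),
        rng.choice(ds_choices, size=n_fills_total, p=_normalized(cfg.days_supply_probs_hydro)),
    ).astype(int)
    # heavier patients transition to maintenance-length refill supplies
    maint = rng.choice(
        np.asarray(cfg.maintenance_supply_choices),
        size=n_fills_total,
        p=_normalized(cfg.maintenance_supply_probs),
    )
    use_maint = (rng.random(n_fills_total) < np.minimum(1.0, cfg.maintenance_boost * p_cont[fill_pid])) & ~is_index
    supply = np.where(use_maint, maint, supply)
    supply[is_index] = cov["days_supply"].to_numpy()[fill_pid[is_index]]

    extra = np.clip(rng.normal(cfg.refill_extra_gap_mean, cfg.refill_extra_gap_sd, n_fills_total), 0, None)
    inc = pd.Series(supply + np.round(extra)).groupby(fill_pid).shift(1).fillna(0.0).to_numpy()
    day = pd.Series(inc).groupby(fill_pid).cumsum().to_numpy()
    fill_date = cov["index_date"].to_numpy()[fill_pid] + day.astype("timedelta64[D]")

    p_sw = np.where(oxy_f, cfg.p_switch_per_refill_oxy, cfg.p_switch_per_refill_hydro)
    switch = (rng.random(n_fills_total) < p_sw) & ~is_index
    other_drug = np.where(
        rng.random(n_fills_total) < 0.5,
        np.where(oxy_f, "hydrocodone", "oxycodone"),
        rng.choice(_OTHER_OPIOIDS, size=n_fills_total),
    )
    drug = np.where(switch, other_drug, cov["drug_base"].to_numpy()[fill_pid])

    strength = np.where(np.isin(drug, ["hydrocodone", "oxycodone"]), 5.0, 30.0)
    strength[is_index] = cov["strength_per_unit"].to_numpy()[fill_pid[is_index]]
    qty = np.clip(np.round(rng.lognormal(2.9, 0.4, n_fills_total)), 4, 120)
    qty[is_index] = cov["quantity"].to_numpy()[fill_pid[is_index]]
    combo = np.where(
        drug == "hydrocodone", "acetaminophen", np.where(rng.random(n_fills_total) < 0.4, "acetaminophen", "none")
    )
    combo[is_index] = cov["combination_ingredient"].to_numpy()[fill_pid[is_index]]

    same_presc = rng.random(n_fills_total) < cfg.p_same_prescriber_refill
    rand_presc = rng.integers(0, max(cfg.n_prescribers, 1), size=n_fills_total)
    prescriber = np.where(
        same_presc | is_index,
        cov["prescriber_id"].to_numpy()[fill_pid],
        np.char.add("D", np.char.zfill(rand_presc.astype(str), 5)),
    )
    missing_p = (rng.random(n_fills_total) < cfg.p_missing_prescriber) & ~is_index
    prescriber = np.where(missing_p, "", prescriber)

    # ---- overdose, censoring, mortality ----------------------------------
    lam = _overdose_hazard(cfg, cov)
    t_od = rng.exponential(1.0, size=n) / np.clip(lam, 1e-300, None)
    churn_days, churn_year, death_days, end_days = _censoring_days(rng, cfg, cov)
    horizon = np.minimum.reduce([death_days, end_days.astype(float)])
    # an overdose is emitted when it happens while alive, enrolled, in-study
    od_emitted = t_od <= np.minimum(horizon, churn_days)
    od_fatal = od_emitted & (rng.random(n) < cfg.p_fatal_given_overdose)
    od_date = cov["index_date"] + pd.to_timedelta(np.where(od_emitted, np.round(t_od), 0), unit="D")

    bg_death = (death_days <= end_days) & ~od_fatal
    bg_death_date = cov["index_date"] + pd.to_timedelta(
        np.where(bg_death, np.round(np.clip(death_days, 0, None)), 0), unit="D"
    )
    death_date = pd.Series(pd.NaT, index=cov.index)
    death_date[od_fatal] = od_date[od_fatal]
    death_date[bg_death] = bg_death_date[bg_death]

    # ---- fills table (truncate at death, inject history/duplicates) ------
    dd = death_date.to_numpy()[fill_pid]
    alive = pd.isna(dd) | (fill_date < dd)
    in_study = fill_date <= np.datetime64(study_end)
    fills = pd.DataFrame(
        {
            "patient_id": cov["patient_id"].to_numpy()[fill_pid],
            "prescriber_id": prescriber,
            "fill_date": fill_date,
            "drug_base": drug,
            "combination_ingredient": combo,
            "strength_per_unit": strength,
            "quantity": qty,
            "days_supply": supply,
            "long_acting": False,
        }
    )[alive & in_study]

    prior = rng.random(n) < cfg.p_prior_fill
    if prior.any():
        back = rng.integers(30, 331, size=int(prior.sum()))
        hist = pd.DataFrame(
            {
                "patient_id": cov.loc[prior, "patient_id"].to_numpy(),
                "prescriber_id": [f"D{i:05d}" for i in rng.integers(0, max(cfg.n_prescribers, 1), int(prior.sum()))],
                "fill_date": cov.loc[prior, "index_date"].to_numpy() - back.astype("timedelta64[D]"),
                "drug_base": rng.choice(["codeine", "tramadol"], size=int(prior.sum())),
                "combination_ingredient": "none",
                "strength_per_unit": 30.0,
                "quantity": rng.integers(10, 40, int(prior.sum())).astype(float),
                "days_supply": rng.integers(3, 15, int(prior.sum())),
                "long_acting": False,
            }
        )
        fills = pd.concat([fills, hist], ignore_index=True)
    dup_mask = rng.random(len(fills)) < cfg.p_duplicate_fill
    if dup_mask.any():
        fills = pd.concat([fills, fills[dup_mask]], ignore_index=True)
    fills = fills.sort_values(["patient_id", "fill_date", "drug_base"], kind="mergesort").reset_index(drop=True)

    # ---- enrollment spans -------------------------------------------------
    enroll_start = pd.Timestamp(cfg.enrollment_start)
    churn_date = pd.Series(
        [pd.Timestamp(int(y), 2, 1) if y > 0 else pd.NaT for y in churn_year + 1]
    )
    span_end = pd.Series(study_end + pd.Timedelta(days=1), index=cov.index)
    has_churn = churn_date.notna()
    span_end[has_churn] = churn_date[has_churn]
    died = death_date.notna()
    span_end[died] = np.minimum(span_end[died], death_date[died] + pd.Timedelta(days=1))

    gap_patients = rng.random(n) < cfg.p_index_year_gap
    no_enroll = (rng.random(n) < cfg.p_no_enrollment) & ~gap_patients
    rows = []
    for i in np.flatnonzero(~no_enroll.to_numpy() if isinstance(no_enroll, pd.Series) else ~no_enroll):
        pid = cov["patient_id"].iat[i]
        plan = cov["insurance"].iat[i]
        end_i = span_end.iat[i]
        if gap_patients[i]:
            year = int(cov["index_year"].iat[i])
            g1, g2 = pd.Timestamp(year, 3, 1), pd.Timestamp(year, 6, 15)
            if end_i > g2:
                rows.append((pid, enroll_start, g1, plan))
                rows.append((pid, g2, end_i, plan))
            else:
                rows.append((pid, enroll_start, min(g1, end_i), plan))
        else:
            if end_i > enroll_start:
                rows.append((pid, enroll_start, end_i, plan))
    spans = pd.DataFrame(rows, columns=["patient_id", "start_date", "end_date", "plan"])

    # ---- claims -----------------------------------------------------------
    claim_rows = []
    nonfatal = od_emitted & ~od_fatal
    dx_keys = list(_NONFATAL_DX)
    for i in np.flatnonzero(nonfatal):
        key = dx_keys[int(rng.integers(0, len(dx_keys)))]
        setting = "ED" if rng.random() < 0.75 else "inpatient"
        claim_rows.append(
            (cov["patient_id"].iat[i], od_date.iat[i], setting, [_NONFATAL_DX[key], "R06.9"])
        )
    background = rng.random(n) < cfg.p_background_claim
    for i in np.flatnonzero(background):
        offset = int(rng.integers(0, max(end_days[i], 1)))
        date = cov["index_date"].iat[i] + pd.Timedelta(days=offset)
        dx = _BACKGROUND_DX[int(rng.integers(0, len(_BACKGROUND_DX)))]
        claim_rows.append((cov["patient_id"].iat[i], date, "ED", [dx]))
    prior_claim = rng.random(n) < cfg.p_prior_overdose_claim
    for i in np.flatnonzero(prior_claim):
        date = cov["index_date"].iat[i] - pd.Timedelta(days=int(rng.integers(30, 331)))
        claim_rows.append((cov["patient_id"].iat[i], date, "ED", ["T40.2X4A"]))
    claims = pd.DataFrame(claim_rows, columns=["patient_id", "service_date", "setting", "diagnosis_codes"])
    claims = claims.sort_values(["patient_id", "service_date"], kind="mergesort").reset_index(drop=True)

    # ---- deaths -----------------------------------------------------------
    death_rows = []
    for i in np.flatnonzero(od_fatal.to_numpy() if isinstance(od_fatal, pd.Series) else od_fatal):
        literal_only = rng.random() < cfg.p_literal_only_death
        literal = _OD_LITERALS[int(rng.integers(0, len(_OD_LITERALS)))]
        if literal_only:
            death_rows.append((cov["patient_id"].iat[i], death_date.iat[i], "R99", ["J96.0"], literal))
        else:
            underlying = _FATAL_UNDERLYING[int(rng.integers(0, len(_FATAL_UNDERLYING)))]
            t_code = _FATAL_T[int(rng.integers(0, len(_FATAL_T)))]
            death_rows.append(
                (cov["patient_id"].iat[i], death_date.iat[i], underlying, [t_code, "J96.0"], literal)
            )
    for i in np.flatnonzero(bg_death.to_numpy() if isinstance(bg_death, pd.Series) else bg_death):
        cause, literal = _NONOPIOID_DEATHS[int(rng.integers(0, len(_NONOPIOID_DEATHS)))]
        death_rows.append((cov["patient_id"].iat[i], death_date.iat[i], cause, ["I46.9"], literal))
    deaths = pd.DataFrame(
        death_rows, columns=["patient_id", "death_date", "underlying_cause", "multiple_causes", "literal_text"]
    ).sort_values("patient_id", kind="mergesort").reset_index(drop=True)

    demographics = cov[["patient_id", "age_years", "gender", "race_ethnicity", "urbanization"]].copy()

    truth = cov.copy()
    truth["p_continuation"] = p_cont
    truth["n_fills_planned"] = m
    truth["daily_hazard"] = lam
    truth["t_overdose_days"] = t_od
    truth["overdose_emitted"] = od_emitted
    truth["overdose_date"] = pd.Series(od_date).where(pd.Series(od_emitted))
    truth["overdose_fatal"] = od_fatal
    truth["death_date"] = death_date
    truth["churn_year"] = churn_year
    truth["prior_fill"] = prior
    truth["prior_overdose_claim"] = prior_claim
    truth["index_year_gap"] = gap_patients
    truth["no_enrollment"] = no_enroll
    plan_truth = _chronic_truth_from_plan(m, supply.astype(float), inc, fill_pid)
    truth = truth.join(
        plan_truth[["true_chronic_primary", "true_chronic_alternative"]].set_axis(
            cov["patient_id"].to_numpy()[plan_truth.index.to_numpy()], axis=0
        ),
        on="patient_id",
    )

    tables = RegistryTables(fills=fills, spans=spans, claims=claims, deaths=deaths, demographics=demographics)
    return tables, GroundTruth(frame=truth, config=cfg, run_id=cfg.config_hash())


def make_trajectory(kind: str, patient_id: str = "P_TRAJ", index_date: str = "2016-01-15") -> pd.DataFrame:
    """Emit a fill trajectory guaranteed to satisfy/violate each chronic-use
    criterion (for unit tests and classifier-agreement checks).

    Kinds: ``chronic_both`` (meets both definitions), ``alternative_only``,
    ``neither``, ``single`` (index fill only).
    """
    index_date = pd.Timestamp(index_date)
    plans = {
        # (day, days_supply) pairs
        "chronic_both": [(d, 60) for d in range(0, 360, 60)],
        "alternative_only": [(d, 3) for d in range(0, 300, 30)],
        "neither": [(d, 10) for d in range(0, 200, 40)],
        "single": [(0, 30)],
    }
    if kind not in plans:
        raise ValueError(f"unknown trajectory kind: {kind}")
    rows = [
        {
            "patient_id": patient_id,
            "prescriber_id": "D00001",
            "fill_date": index_date + pd.Timedelta(days=d),
            "drug_base": "hydrocodone",
            "combination_ingredient": "acetaminophen",
            "strength_per_unit": 5.0,
            "quantity": 20.0,
            "days_supply": s,
            "long_acting": False,
        }
        for d, s in plans[kind]
    ]
    return pd.DataFrame(rows)


def truth_report(ground_truth: GroundTruth, outputs: dict) -> dict:
    """Tabulate configured-vs-recovered quantities for a pipeline run.

    *outputs* may contain ``overdose_events`` (detected events frame),
    ``chronic`` (chronic-use result frame), and must carry the ``run_id`` of
    the generating configuration; a mismatch raises ``ValueError``.
    """
    if outputs.get("run_id") != ground_truth.run_id:
        raise ValueError(
            f"run identifier mismatch: ground truth {ground_truth.run_id}, outputs {outputs.get('run_id')}"
        )
    gt = ground_truth.frame
    report: dict = {"run_id": ground_truth.run_id, "n_patients": int(len(gt))}

    if "overdose_events" in outputs and "overdose_emitted" in gt:
        emitted = gt.loc[gt["overdose_emitted"].fillna(False).astype(bool), "patient_id"]
        if "patients" in outputs:  # restrict to patients the pipeline retained
            emitted = emitted[emitted.isin(set(outputs["patients"]))]
        detected = set(outputs["overdose_events"]["patient_id"])
        n_emitted = len(emitted)
        n_found = sum(p in detected for p in emitted)
        report["overdose_detection_completeness_pct"] = (
            100.0 * n_found / n_emitted if n_emitted else float("nan")
        )
        report["overdoses_emitted"] = n_emitted

    if "chronic" in outputs and "true_chronic_primary" in gt:
        merged = gt.merge(outputs["chronic"][["patient_id", "chronic_primary"]], on="patient_id", how="inner")
        truth_flag = merged["true_chronic_primary"].fillna(False).astype(bool)
        est = merged["chronic_primary"].astype(bool)
        tp = int((truth_flag & est).sum())
        tn = int((~truth_flag & ~est).sum())
        report["chronic_sensitivity"] = tp / truth_flag.sum() if truth_flag.sum() else float("nan")
        report["chronic_specificity"] = tn / (~truth_flag).sum() if (~truth_flag).sum() else float("nan")
        report["chronic_prevalence_est"] = float(est.mean()) if len(est) else float("nan")

    if "model_reports" in outputs:
        cfg = ground_truth.config
        configured = {
            "drug_group:oxycodone_SA (chronic log-OR)": cfg.chronic_logor_oxycodone,
            "drug_group:oxycodone_SA (overdose log-HR)": cfg.overdose_loghr_oxy_other,
            "switch log-OR": cfg.switch_logor_oxycodone,
        }
        estimated = {}
        for name, rep in outputs["model_reports"].items():
            for e in rep.estimates:
                if e.term == "drug_group:oxycodone_SA" and not e.reference:
                    estimated[f"{name}: drug_group:oxycodone_SA"] = e.estimate
        report["configured_effects"] = configured
        report["estimated_effects"] = estimated
    return report


def empirical_log_hazard_ratio(frame: pd.DataFrame) -> float:
    """Person-time incidence-ratio estimate of the oxycodone-vs-hydrocodone
    log hazard ratio, model-free (for generator fidelity checks)."""
    oxy = frame["oxy"].astype(bool)
    ev = frame["event"].astype(bool)
    days = frame["survival_days"].astype(float)
    rate_oxy = ev[oxy].sum() / days[oxy].sum()
    rate_hyd = ev[~oxy].sum() / days[~oxy].sum()
    return float(np.log(rate_oxy / rate_hyd))
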