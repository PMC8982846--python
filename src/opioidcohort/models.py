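"""Balance diagnostics and the estimation stages.

Four model families are fit on the cohort/outcome tables:

* multilevel (prescriber random-intercept) logistic regression for first-year
  chronic use and for drug switching, reported as adjusted odds ratios;
* Cox proportional hazards for time to opioid overdose, reported as adjusted
  hazard ratios, with an optional shared gamma frailty by prescriber on the
  subgroup of high-volume prescribers;
* zero-inflated negative binomial for cumulative 6-month MME (odds of a zero
  total, and rate ratios for the non-zero count portion);
* the combination-product subgroup versions of the logistic and Cox models.

All 95% confidence intervals are Wald intervals on the log scale
(``exp(estimate +/- 1.96 SE)``).  Reference levels are fixed:
hydrocodone SA, age 18-24, male, White, commercial insurance, noncore
county, index year 2015, MME <=75, days' supply <=3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special, stats
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.duration.hazard_regression import PHReg
from lifelines import CoxPHFitter

Z95 = 1.96
#: terms whose |log estimate| or SE suggest separation; withheld from reports
SEPARATION_COEF = 10.0
SEPARATION_SE = 50.0

REFERENCE_LEVELS = {
    "drug_group": "hydrocodone_SA",
    "subgroup_drug": "hydro_apap_5mg",
    "age_category": "18-24",
    "gender": "M",
    "race_ethnicity": "White",
    "insurance": "commercial",
    "urbanization": "noncore",
    "index_year": "2015",
    "mme_category": "<=75",
    "days_supply_category": "<=3",
}

DEFAULT_COVARIATES = [
    "drug_group",
    "age_category",
    "gender",
    "race_ethnicity",
    "insurance",
    "urbanization",
    "index_year",
    "mme_category",
    "days_supply_category",
]


@dataclass
class EffectEstimate:
    term: str
    estimate: float  # log scale
    se: float
    ratio: float  # exp scale (OR / HR / rate ratio)
    ci_low: float
    ci_high: float
    p_value: float
    reference: bool = False
    withheld: bool = False


@dataclass
class ModelReport:
    name: str
    method: str
    n: int
    events: int
    estimates: list[EffectEstimate] = field(default_factory=list)
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    random_effect_variance: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.estimates])

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=float)

    def get(self, term: str) -> EffectEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    def to_text(self) -> str:
        lines = [
            f"{self.name}  (method: {self.method})",
            f"n = {self.n}, events = {self.events}, converged = {self.converged}",
        ]
        if self.random_effect_variance is not None:
            lines.append(f"random-effect variance (prescriber) = {self.random_effect_variance:.4f}")
        for wmsg in self.warnings:
            lines.append(f"warning: {wmsg}")
        lines.append(f"{'term':<38}{'ratio':>8}  {'95% CI':>16}  {'p':>8}")
        for e in self.estimates:
            if e.reference:
                lines.append(f"{e.term:<38}{'ref':>8}")
            elif e.withheld:
                lines.append(f"{e.term:<38}{'--':>8}  (withheld: unstable)")
            else:
                ci = f"({e.ci_low:.2f}-{e.ci_high:.2f})"
                lines.append(f"{e.term:<38}{e.ratio:>8.2f}  {ci:>16}  {e.p_value:>8.3g}")
        return "\n".join(lines)


def standardized_difference(p1: float, p2: float) -> float:
    """Two-proportion standardized difference (Cohen's d, pooled-variance form).

    ``|p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)``; returns 0 when both
    variances are zero and the proportions agree.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    if p1 == p2:
        return 0.0
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0.0:  # degenerate {0, 1} pair: difference is unbounded
        return float("inf")
    return abs(p1 - p2) / np.sqrt(pooled)


def balance_table(
    cohort: pd.DataFrame,
    group_col: str = "drug_group",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate balance between the two exposure groups: n, %, and the
    absolute standardized difference per level."""
    covariates = covariates or [c for c in DEFAULT_COVARIATES if c != group_col and c in cohort]
    groups = sorted(cohort[group_col].astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"balance table requires exactly 2 groups, got {groups}")
    g1 = cohort[cohort[group_col].astype(str) == groups[0]]
    g2 = cohort[cohort[group_col].astype(str) == groups[1]]
    rows = []
    for cov in covariates:
        for level in _ordered_levels(cohort, cov):
            n_all = int((cohort[cov].astype(str) == level).sum())
            n1 = int((g1[cov].astype(str) == level).sum())
            n2 = int((g2[cov].astype(str) == level).sum())
            p1 = n1 / len(g1) if len(g1) else 0.0
            p2 = n2 / len(g2) if len(g2) else 0.0
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "n_total": n_all,
                    "pct_total": 100.0 * n_all / len(cohort) if len(cohort) else 0.0,
                    f"n_{groups[0]}": n1,
                    f"pct_{groups[0]}": 100.0 * p1,
                    f"n_{groups[1]}": n2,
                    f"pct_{groups[1]}": 100.0 * p2,
                    "standardized_difference": standardized_difference(p1, p2),
                }
            )
    return pd.DataFrame(rows)


def _ordered_levels(df: pd.DataFrame, cov: str) -> list[str]:
    """Observed levels with the reference level first, then sorted order."""
    levels = sorted(df[cov].astype(str).unique())
    ref = str(REFERENCE_LEVELS.get(cov, levels[0]))
    if ref in levels:
        levels.remove(ref)
        levels = [ref] + levels
    return levels


def build_design(
    df: pd.DataFrame,
    covariates: list[str] | None = None,
    include_mme: bool = True,
    add_const: bool = True,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Dummy-encode covariates against the fixed reference levels.

    Returns ``(X, reference_terms)`` where term names are ``cov:level`` and
    *reference_terms* lists the reference level of each covariate actually
    encoded (for report annotation).
    """
    covariates = [c for c in (covariates or DEFAULT_COVARIATES) if c in df.columns]
    if not include_mme:
        covariates = [c for c in covariates if c != "mme_category"]
    cols: dict[str, np.ndarray] = {}
    refs: list[tuple[str, str]] = []
    for cov in covariates:
        values = df[cov].astype(str)
        levels = _ordered_levels(df, cov)
        if len(levels) < 2:
            continue
        refs.append((cov, levels[0]))
        for level in levels[1:]:
            cols[f"{cov}:{level}"] = (values == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    if add_const:
        X.insert(0, "const", 1.0)
    return X, refs


def _wald_estimates(terms, params, ses, refs) -> list[EffectEstimate]:
    ests = []
    for cov, level in refs:
        ests.append(
            EffectEstimate(f"{cov}:{level}", 0.0, 0.0, 1.0, 1.0, 1.0, float("nan"), reference=True)
        )
    for term, b, s in zip(terms, params, ses):
        if term == "const":
            continue
        withheld = (not np.isfinite(b)) or (not np.isfinite(s)) or abs(b) > SEPARATION_COEF or s > SEPARATION_SE
        if withheld:
            ests.append(
                EffectEstimate(term, float(b), float(s), float("nan"), float("nan"), float("nan"), float("nan"), withheld=True)
            )
            continue
        z = b / s if s > 0 else np.inf
        ests.append(
            EffectEstimate(
                term=term,
                estimate=float(b),
                se=float(s),
                ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * s)),
                ci_high=float(np.exp(b + Z95 * s)),
                p_value=float(2 * stats.norm.sf(abs(z))),
            )
        )
    return ests


def _fit_logistic_report(
    name: str,
    y: np.ndarray,
    X: pd.DataFrame,
    refs,
    groups: pd.Series | None = None,
) -> ModelReport:
    """Shared logistic fitting path; random intercept by *groups* when given."""
    report = ModelReport(name=name, method="", n=len(y), events=int(np.sum(y)))
    if groups is not None and groups.nunique() < 2:
        report.warnings.append("fewer than 2 prescriber groups; fell back to single-level fit")
        groups = None
    if groups is not None:
        codes, _ = pd.factorize(groups, sort=True)
        exog_vc = sparse.csr_matrix(
            (np.ones(len(codes)), (np.arange(len(codes)), codes)),
            shape=(len(codes), codes.max() + 1),
        )
        model = BinomialBayesMixedGLM(
            np.asarray(y, dtype=float),
            np.asarray(X, dtype=float),
            exog_vc,
            ident=np.zeros(exog_vc.shape[1], dtype=int),
            vc_names=["prescriber"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_vb()
        k = X.shape[1]
        params, ses = res.fe_mean[:k], res.fe_sd[:k]
        report.method = "variational Bayes mixed logistic regression (random intercept by prescriber)"
        report.random_effect_variance = float(np.exp(2.0 * res.vcp_mean[0]))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(np.asarray(y, dtype=float), np.asarray(X, dtype=float)).fit(
                    disp=0, maxiter=200
                )
                params, ses = res.params, res.bse
                report.converged = bool(res.mle_retvals.get("converged", True))
            except Exception as exc:  # perfect separation, singular design
                report.converged = False
                report.warnings.append(f"logistic fit failed: {exc}")
                report.method = "maximum-likelihood logistic regression"
                return report
        report.method = "maximum-likelihood logistic regression"
        if not report.converged:
            report.warnings.append("maximum-likelihood fit did not converge")
    report.estimates = _wald_estimates(X.columns, params, ses, refs)
    return report


def fit_chronic_logistic(
    cohort: pd.DataFrame,
    chronic: pd.DataFrame,
    definition: str = "primary",
    random_effect: bool = False,
    include_mme: bool = True,
    covariates: list[str] | None = None,
) -> ModelReport:
    """Adjusted odds ratios for first-year chronic use.

    ``include_mme=False`` reproduces the no-dosage specification (the index
    MME category is dropped from the fixed effects); ``random_effect=True``
    adds a prescriber random intercept.
    """
    flag = {"primary": "chronic_primary", "alternative": "chronic_alternative"}[definition]
    df = cohort.drop(columns=[flag], errors="ignore").merge(
        chronic[["patient_id", flag]], on="patient_id", how="inner"
    )
    X, refs = build_design(df, covariates=covariates, include_mme=include_mme)
    groups = df["prescriber_id"] if random_effect else None
    return _fit_logistic_report(
        f"first-year chronic use ({definition} definition)", df[flag].astype(float).to_numpy(), X, refs, groups
    )


def fit_switch_logistic(
    cohort: pd.DataFrame,
    secondary: pd.DataFrame,
    random_effect: bool = False,
    include_mme: bool = True,
    covariates: list[str] | None = None,
) -> ModelReport:
    """Adjusted odds ratios for switching opioids, among patients with at
    least one additional fill in the 6-month window."""
    df = cohort.drop(columns=["any_additional_fill", "switched", "cumulative_mme_6mo"], errors="ignore").merge(
        secondary, on="patient_id", how="inner"
    )
    df = df[df["any_additional_fill"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no at-risk patients: nobody filled an additional prescription")
    X, refs = build_design(df, covariates=covariates, include_mme=include_mme)
    groups = df["prescriber_id"] if random_effect else None
    return _fit_logistic_report(
        "drug switching within 6 months", df["switched"].astype(bool).astype(float).to_numpy(), X, refs, groups
    )


def _drop_eventless_terms(X: pd.DataFrame, event: np.ndarray, report: ModelReport) -> pd.DataFrame:
    keep = []
    for col in X.columns:
        if col != "const" and (X[col].to_numpy() * event).sum() == 0:
            report.warnings.append(f"term dropped (no events in stratum): {col}")
        else:
            keep.append(col)
    return X[keep]


def fit_overdose_cox(
    cohort: pd.DataFrame,
    survival: pd.DataFrame,
    frailty: bool = False,
    min_patients_per_prescriber: int = 200,
    include_mme: bool = True,
    covariates: list[str] | None = None,
    exposure: str | None = None,
) -> ModelReport:
    """Adjusted hazard ratios for time to first opioid overdose (Efron ties).

    With ``frailty=True`` the sample is restricted to prescribers with at
    least ``min_patients_per_prescriber`` cohort patients and a shared gamma
    frailty (random effect) by prescriber is added, estimated by EM.
    """
    df = cohort.drop(columns=["survival_days", "event"], errors="ignore").merge(
        survival[["patient_id", "survival_days", "event"]], on="patient_id", how="inner"
    )
    name = "opioid overdose (Cox PH)"
    if frailty:
        sizes = df.groupby("prescriber_id")["patient_id"].size()
        qualifying = sizes.index[sizes >= min_patients_per_prescriber]
        df = df[df["prescriber_id"].isin(qualifying)].reset_index(drop=True)
        name = f"opioid overdose (Cox PH, prescriber frailty, prescribers with >= {min_patients_per_prescriber} patients)"

    cov = covariates or DEFAULT_COVARIATES
    if exposure is not None:
        cov = [exposure] + [c for c in cov if c not in (exposure, "drug_group")]
    X, refs = build_design(df, covariates=cov, include_mme=include_mme, add_const=False)
    event = df["event"].astype(bool).to_numpy()
    report = ModelReport(name=name, method="Cox proportional hazards (Efron ties)", n=len(df), events=int(event.sum()))
    if event.sum() == 0:
        report.converged = False
        report.warnings.append("no events observed; estimates withheld")
        return report
    X = _drop_eventless_terms(X, event.astype(float), report)

    if frailty:
        params, ses, theta, niter = _gamma_frailty_cox(
            df["survival_days"].to_numpy(float), event, X, df["prescriber_id"]
        )
        report.method = "Cox proportional hazards with shared gamma frailty by prescriber (EM, Efron ties)"
        report.random_effect_variance = float(theta)
        report.warnings.append(f"frailty EM iterations: {niter}")
        report.estimates = _wald_estimates(X.columns, params, ses, refs)
        return report

    data = X.copy()
    data["duration"] = df["survival_days"].to_numpy(float)
    data["event"] = event.astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="duration", event_col="event")
    except Exception as exc:
        report.converged = False
        report.warnings.append(f"Cox fit failed: {exc}")
        return report
    report.estimates = _wald_estimates(
        cph.params_.index, cph.params_.to_numpy(), cph.standard_errors_.to_numpy(), refs
    )
    return report


def _gamma_frailty_cox(
    duration: np.ndarray,
    event: np.ndarray,
    X: pd.DataFrame,
    groups: pd.Series,
    max_iter: int = 50,
    tol: float = 1e-4,
):
    """EM for a shared gamma frailty Cox model.

    E-step: conditional on the current hazard, group frailties are gamma with
    ``E[w_j] = (1/theta + D_j) / (1/theta + H_j)`` where ``D_j`` is the event
    count and ``H_j`` the summed cumulative hazards of group j's subjects.
    M-step: Cox fit with ``log w`` as an offset (Efron ties), and a 1-D
    maximization of the gamma-frailty profile for the variance ``theta``.
    """
    codes, _ = pd.factorize(groups, sort=True)
    n_groups = codes.max() + 1
    w = np.ones(n_groups)
    theta = 0.5
    params_old = None
    Xv = np.asarray(X, dtype=float)
    niter = 0
    for niter in range(1, max_iter + 1):
        offset = np.log(np.clip(w[codes], 1e-10, None))
        model = PHReg(duration, Xv, status=event.astype(int), ties="efron", offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
        params = res.params
        lp = Xv @ params
        times, cumhaz, _ = res.baseline_cumulative_hazard[0]
        H0 = np.interp(duration, times, cumhaz, left=0.0)
        Hi = H0 * np.exp(lp)
        D = np.bincount(codes, weights=event.astype(float), minlength=n_groups)
        H = np.bincount(codes, weights=Hi, minlength=n_groups)
        nu = 1.0 / theta
        w = (nu + D) / (nu + H)
        e_log_w = special.digamma(nu + D) - np.log(nu + H)

        def neg_gamma_ll(log_nu):
            v = np.exp(log_nu)
            return -np.sum(v * log_nu - special.gammaln(v) + (v - 1) * e_log_w - v * w)

        opt = optimize.minimize_scalar(neg_gamma_ll, bounds=(-7, 7), method="bounded")
        theta = float(np.exp(-opt.x))
        if params_old is not None and np.max(np.abs(params - params_old)) < tol:
            break
        params_old = params
    ses = res.bse
    return params, ses, theta, niter


def fit_cumulative_zinb(
    cohort: pd.DataFrame,
    secondary: pd.DataFrame,
    include_mme: bool = True,
    covariates: list[str] | None = None,
) -> ModelReport:
    """Zero-inflated negative binomial for cumulative 6-month MME.

    The cumulative MME is discretized to integer MME units.  The inflation
    (logistic) portion reports odds ratios of a zero cumulative MME; the
    count portion reports rate ratios conditioned on non-zero use.  On
    non-convergence a staged fallback is used (plain negative binomial for
    the counts plus a separate logistic zero model) and recorded.
    """
    df = cohort.drop(columns=["cumulative_mme_6mo"], errors="ignore").merge(
        secondary[["patient_id", "cumulative_mme_6mo"]], on="patient_id", how="inner"
    )
    y = np.round(df["cumulative_mme_6mo"].astype(float)).astype(int).to_numpy()
    X, refs = build_design(df, covariates=covariates, include_mme=include_mme)
    report = ModelReport(
        name="cumulative 6-month MME (zero-inflated negative binomial)",
        method="zero-inflated negative binomial (NB2)",
        n=len(df),
        events=int((y > 0).sum()),
    )
    n_zero = int((y == 0).sum())
    if n_zero == 0:
        report.warnings.append("no zero counts; zero-inflation portion degenerate, fitting NB only")
        return _nb_fallback(report, y, X, refs, fit_zero=False)
    if n_zero == len(y):
        report.converged = False
        report.warnings.append("all counts zero; model inestimable")
        return report

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.ZeroInflatedNegativeBinomialP(y, np.asarray(X, float), exog_infl=np.asarray(X, float), p=2)
            res = model.fit(method="bfgs", maxiter=500, disp=0)
        converged = bool(res.mle_retvals.get("converged", False)) and np.all(np.isfinite(res.bse))
    except Exception:
        converged = False
    if not converged:
        report.warnings.append("ZINB did not converge; staged fallback to NB count + logistic zero models")
        report.method = "fallback: negative binomial (counts) + logistic (zero portion)"
        return _nb_fallback(report, y, X, refs, fit_zero=True)

    k = X.shape[1]
    infl_params, infl_se = res.params[:k], res.bse[:k]
    count_params, count_se = res.params[k : 2 * k], res.bse[k : 2 * k]
    zero_terms = _wald_estimates(X.columns, infl_params, infl_se, refs)
    count_terms = _wald_estimates(X.columns, count_params, count_se, refs)
    for e in zero_terms:
        e.term = "zero:" + e.term
    for e in count_terms:
        e.term = "count:" + e.term
    report.estimates = zero_terms + count_terms
    report.random_effect_variance = None
    alpha = float(res.params[-1])
    report.warnings.append(f"NB dispersion alpha = {alpha:.3f}")
    return report


def _drop_constant_columns(X: pd.DataFrame, report: ModelReport, portion: str) -> pd.DataFrame:
    keep = ["const"] if "const" in X.columns else []
    for col in X.columns:
        if col == "const":
            continue
        if X[col].nunique() < 2:
            report.warnings.append(f"{portion} term dropped (constant in subset): {col}")
        else:
            keep.append(col)
    return X[keep]


def _nb_fallback(report: ModelReport, y, X, refs, fit_zero: bool) -> ModelReport:
    ests: list[EffectEstimate] = []
    if fit_zero:
        z = (y == 0).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                logit = sm.Logit(z, np.asarray(X, float)).fit(disp=0, maxiter=200)
            zero_terms = _wald_estimates(X.columns, logit.params, logit.bse, refs)
            for e in zero_terms:
                e.term = "zero:" + e.term
            ests += zero_terms
        except Exception as exc:
            report.converged = False
            report.warnings.append(f"zero-portion logistic failed: {exc}")
    pos = y > 0
    Xp = _drop_constant_columns(X.loc[pos], report, "count")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = sm.NegativeBinomialP(y[pos], np.asarray(Xp, float), p=2).fit(disp=0, maxiter=200)
        count_terms = _wald_estimates(Xp.columns, nb.params[:-1], nb.bse[:-1], refs)
        for e in count_terms:
            e.term = "count:" + e.term
        ests += count_terms
    except Exception as exc:
        report.converged = False
        report.warnings.append(f"count-portion negative binomial failed: {exc}")
    report.estimates = ests
    return report


def run_combination_subgroup(
    cohort: pd.DataFrame,
    chronic: pd.DataFrame,
    survival: pd.DataFrame,
    include_mme: bool = True,
    random_effect: bool = False,
) -> tuple[ModelReport, ModelReport]:
    """Chronic-use logistic and overdose Cox models on the 5 mg
    combination-product subgroup, with the 3-level exposure
    (hydrocodone-acetaminophen reference, oxycodone-acetaminophen,
    oxycodone monotherapy)."""
    sub = cohort[cohort["subgroup_drug"] != "other"].reset_index(drop=True)
    if sub["subgroup_drug"].nunique() < 2:
        raise ValueError("subgroup exposure inestimable: fewer than 2 subgroup levels present")
    cov = ["subgroup_drug"] + [c for c in DEFAULT_COVARIATES if c != "drug_group"]
    logistic = fit_chronic_logistic(
        sub, chronic, random_effect=random_effect, include_mme=include_mme, covariates=cov
    )
    logistic.name = "subgroup: " + logistic.name
    cox = fit_overdose_cox(
        sub, survival, include_mme=include_mme, covariates=cov, exposure="subgroup_drug"
    )
    cox.name = "subgroup: " + cox.name
    return logistic, cox
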