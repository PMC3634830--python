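"""Kaplan–Meier, log-rank, multivariate Cox fits and the per-age curves.

The pooled model follows the registry analysis convention: cause-specific
death within five years of diagnosis as the endpoint, with terms sex, age,
race, tumour type and stage, reference levels female / African-American /
hematological / distant.  The per-age hazard-ratio sweep refits the same
model (age dropped) inside every single-year age stratum and records the
male-term HR, Wald 95% CI and p-value; ages where the stratified fit is not
identified are undefined, never zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from ._coxph import ConvergenceError, fit_coxph
from .curves import HRCurve, SurvDiffCurve

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TERMS", "REFERENCE_LEVELS", "KMEstimate", "CoxFit",
    "km_fit", "logrank", "cox_fit", "hr_by_age", "survdiff_by_age",
    "build_design", "ConvergenceError",
]

DEFAULT_TERMS = ("sex", "age", "race", "tumor_type", "stage")

REFERENCE_LEVELS = {
    "sex": "female",
    "race": "african_american",
    "tumor_type": "hematological",
    "stage": "distant",
}

_FACTOR_LEVELS = {
    "sex": ("female", "male"),
    "race": ("african_american", "caucasian"),
    "tumor_type": ("hematological", "sarcoma", "solid"),
    "stage": ("distant", "localized", "regional"),
}

MALE_TERM = "sex[male]"


@dataclass
class KMEstimate:
    """Product-limit survival estimate with its risk table."""

    grid: np.ndarray       # observed event times, ascending
    survival: np.ndarray   # S(t) at each grid point
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.grid, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(df: pd.DataFrame, time_col="time_months", event_col="event") -> KMEstimate:
    """Kaplan–Meier estimate with right censoring (events before censorings
    at tied times, the product-limit convention)."""
    if len(df) == 0:
        raise ValueError("km_fit requires a non-empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(df[time_col], df[event_col])
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    grid = ev.index.to_numpy(float)
    surv = np.asarray([kmf.predict(t) for t in grid], float)
    return KMEstimate(grid=grid, survival=surv,
                      at_risk=ev["at_risk"].to_numpy(int),
                      events=ev["observed"].to_numpy(int), n=len(df))


def logrank(a: pd.DataFrame, b: pd.DataFrame,
            time_col="time_months", event_col="event") -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and asymptotic p-value."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("logrank requires two non-empty groups")
    res = logrank_test(a[time_col], b[time_col],
                       event_observed_A=a[event_col], event_observed_B=b[event_col])
    return float(res.test_statistic), float(res.p_value)


def build_design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str], list[str]]:
    """Dummy-coded design matrix with pinned reference levels.

    Factors with fewer than two observed levels are dropped with a warning;
    the returned column names read ``factor[level]`` (or ``age``).
    """
    cols, names, dropped = [], [], []
    for term in terms:
        if term == "age":
            cols.append(df["age_at_dx"].to_numpy(float))
            names.append("age")
            continue
        levels = _FACTOR_LEVELS[term]
        observed = [lv for lv in levels if (df[term] == lv).any()]
        if len(observed) < 2:
            dropped.append(term)
            continue
        for lv in levels:
            if lv == REFERENCE_LEVELS[term] or lv not in observed:
                continue
            cols.append((df[term] == lv).to_numpy(float))
            names.append(f"{term}[{lv}]")
    if dropped:
        warnings.warn(f"factor(s) dropped (single observed level): {dropped}",
                      stacklevel=2)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, dropped


@dataclass
class CoxFit:
    """Results of a multivariate proportional-hazards fit.

    Coefficients are log hazard ratios versus the pinned reference levels;
    confidence intervals and p-values are Wald-based.
    """

    params: pd.Series
    cov: pd.DataFrame
    n: int
    n_events: int
    loglik: float
    n_iter: int
    reference_levels: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))
    dropped: list = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - 1.96 * self.se)
        hi = np.exp(self.params + 1.96 * self.se)
        return pd.DataFrame({"lo95": lo, "hi95": hi})

    @property
    def pvalues(self) -> pd.Series:
        zval = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(zval)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame({
            "coef": self.params,
            "HR": self.hazard_ratios,
            "se(coef)": self.se,
            "HR lo95": ci["lo95"],
            "HR hi95": ci["hi95"],
            "p": self.pvalues,
        })

    def __str__(self) -> str:
        head = (f"Cox proportional hazards (Efron ties)  "
                f"n={self.n}, events={self.n_events}, "
                f"log-PL={self.loglik:.3f}, iterations={self.n_iter}\n"
                f"reference levels: {self.reference_levels}\n")
        return head + self.summary().to_string(float_format=lambda v: f"{v:.4g}")


def cox_fit(df: pd.DataFrame, terms=DEFAULT_TERMS, tol=1e-9,
            max_iter=100) -> CoxFit:
    """Fit the multivariate Cox model by Efron partial likelihood.

    Requires at least two distinct event times; factors with a single
    observed level are dropped with a warning.  Non-convergence and complete
    separation raise :class:`ConvergenceError` carrying the iteration trace.
    """
    ev = df[df["event"] == 1]
    if ev["time_months"].nunique() < 2:
        raise ValueError("cox_fit requires >= 2 distinct event times")
    X, names, dropped = build_design(df, terms)
    if X.shape[1] == 0:
        raise ValueError("no usable model terms after dropping "
                         f"single-level factors {dropped}")
    beta, cov, ll, n_iter = fit_coxph(
        X, df["time_months"].to_numpy(float), df["event"].to_numpy(bool),
        tol=tol, max_iter=max_iter)
    return CoxFit(params=pd.Series(beta, index=names),
                  cov=pd.DataFrame(cov, index=names, columns=names),
                  n=len(df), n_events=int(df["event"].sum()),
                  loglik=ll, n_iter=n_iter, dropped=dropped)


def _stratum_male_hr(sub: pd.DataFrame, terms) -> tuple[float, float, float, float]:
    """(hr, lo, hi, p) for the male term within one age stratum."""
    X, names, _ = build_design(sub, terms)
    if MALE_TERM not in names:
        raise ConvergenceError("sex not estimable in stratum")
    beta, cov, _, _ = fit_coxph(X, sub["time_months"].to_numpy(float),
                                sub["event"].to_numpy(bool))
    i = names.index(MALE_TERM)
    b, se = beta[i], float(np.sqrt(cov[i, i]))
    p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan
    return float(np.exp(b)), float(np.exp(b - 1.96 * se)), \
        float(np.exp(b + 1.96 * se)), float(p)


def hr_by_age(df: pd.DataFrame, terms=("sex", "race", "tumor_type", "stage"),
              ages=None, alpha=0.05, method="stratified") -> HRCurve:
    """Male-vs-female HR at each integer age at diagnosis.

    ``method="stratified"`` (default) refits the multivariate model within
    each single-year age stratum; ``method="interaction"`` fits one pooled
    model with a sex-by-age interaction and reads the curve off the
    coefficients (delta-method CIs).  Ages whose stratum lacks both sexes,
    any event, or an identified fit are undefined.
    """
    if "age" in terms:
        terms = tuple(t for t in terms if t != "age")
    if ages is None:
        lo, hi = int(df["age_at_dx"].min()), int(df["age_at_dx"].max())
        ages = np.arange(lo, hi + 1)
    ages = np.asarray(ages, int)
    if method == "interaction":
        return _hr_by_age_interaction(df, terms, ages, alpha)

    rows = []
    grouped = dict(tuple(df.groupby(df["age_at_dx"].astype(int))))
    for a in ages:
        sub = grouped.get(int(a))
        row = {"age": int(a), "hr": np.nan, "lo": np.nan, "hi": np.nan,
               "p": np.nan, "n": 0 if sub is None else len(sub),
               "n_events": 0 if sub is None else int(sub["event"].sum()),
               "significant": False}
        if sub is not None and sub["sex"].nunique() == 2 \
                and sub["event"].sum() >= 1:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hr, lo95, hi95, p = _stratum_male_hr(sub, terms)
                row.update(hr=hr, lo=lo95, hi=hi95, p=p,
                           significant=bool(p < alpha))
            except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
                log.debug("age %d undefined: %s", a, exc)
        rows.append(row)
    return HRCurve(pd.DataFrame(rows))


def _hr_by_age_interaction(df, terms, ages, alpha) -> HRCurve:
    """Pooled model with male and male-x-age terms; HR(a) = exp(b0 + b1 a)."""
    X, names, _ = build_design(df, tuple(terms) + ("age",))
    if MALE_TERM not in names:
        raise ValueError("interaction curve requires both sexes")
    male = X[:, names.index(MALE_TERM)]
    age = df["age_at_dx"].to_numpy(float)
    X = np.column_stack([X, male * age])
    names = names + ["sex[male]:age"]
    beta, cov, _, _ = fit_coxph(X, df["time_months"].to_numpy(float),
                                df["event"].to_numpy(bool))
    i, j = names.index(MALE_TERM), names.index("sex[male]:age")
    rows = []
    counts = df.groupby(df["age_at_dx"].astype(int)).size()
    nev = df[df["event"] == 1].groupby(
        df.loc[df["event"] == 1, "age_at_dx"].astype(int)).size()
    for a in ages:
        b = beta[i] + beta[j] * a
        var = cov[i, i] + a * a * cov[j, j] + 2 * a * cov[i, j]
        se = float(np.sqrt(var))
        p = 2 * stats.norm.sf(abs(b) / se)
        rows.append({"age": int(a), "hr": float(np.exp(b)),
                     "lo": float(np.exp(b - 1.96 * se)),
                     "hi": float(np.exp(b + 1.96 * se)), "p": float(p),
                     "n": int(counts.get(int(a), 0)),
                     "n_events": int(nev.get(int(a), 0)),
                     "significant": bool(p < alpha)})
    return HRCurve(pd.DataFrame(rows))


def survdiff_by_age(df: pd.DataFrame, horizon_months: float = 60,
                    ages=None, alpha=0.05) -> SurvDiffCurve:
    """Female-minus-male 5-year survival difference by age (percentage
    points, positive = female advantage), with per-age log-rank p-values."""
    if ages is None:
        lo, hi = int(df["age_at_dx"].min()), int(df["age_at_dx"].max())
        ages = np.arange(lo, hi + 1)
    rows = []
    grouped = dict(tuple(df.groupby(df["age_at_dx"].astype(int))))
    for a in np.asarray(ages, int):
        sub = grouped.get(int(a))
        row = {"age": int(a), "delta": np.nan, "p_logrank": np.nan,
               "significant": False, "n": 0 if sub is None else len(sub)}
        if sub is not None and sub["sex"].nunique() == 2 \
                and sub["event"].sum() >= 1:
            f = sub[sub["sex"] == "female"]
            m = sub[sub["sex"] == "male"]
            delta = 100.0 * (km_fit(f).survival_at(horizon_months)
                             - km_fit(m).survival_at(horizon_months))
            stat, p = logrank(f, m)
            row.update(delta=float(delta), p_logrank=float(p),
                       significant=bool(p < alpha))
        rows.append(row)
    return SurvDiffCurve(pd.DataFrame(rows))
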