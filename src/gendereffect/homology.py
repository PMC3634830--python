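"""Biomarker age profiles and their homology with the HR-by-age curve.

A survey variable is summarised as its per-integer-age median (one value per
age and sex).  Candidate variables are screened two ways against the
male-vs-female hazard-ratio curve:

* Spearman rank correlation over the ages where both are defined;
* the "% homology" score — the percentage of seeded bootstrap replicates in
  which a two-sample Kolmogorov–Smirnov test does *not* reject that the
  z-scored HR series and the z-scored variable profile share a distribution.

Both series are z-scored over their own full series (population standard
deviation), so the score is invariant to the variable's measurement units.

Two bootstrap schemes are provided.  The default, ``mode="series"``,
resamples the age grid with replacement — weighting ages by the survey's
per-age sample sizes, which is the size-matching step — and compares the
fixed estimated HR series with the variable profile on the resampled grid.
``mode="refit"`` redraws size-matched patients from the registry at every
age and re-estimates the whole per-age Cox sweep per replicate; at
survey-matched stratum sizes the re-estimated curve is dominated by sampling
noise of the same order as the age signal itself, which destroys the
discrimination of the score (see docs/methods.md), so it is not the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._coxph import ConvergenceError, fit_coxph
from .curves import AgeProfile, HRCurve
from .survival import MALE_TERM, build_design

log = logging.getLogger(__name__)

__all__ = [
    "ZScoredSeries", "HomologyResult", "compute_fti", "age_profile",
    "zscore", "spearman_screen", "size_matched_resample", "ks_homology",
    "homology_score", "homology_screen",
]


def compute_fti(tt, shbg):
    """Free Testosterone Index, (TT / SHBG) * 100.

    Total testosterone and sex-hormone-binding globulin must be in
    consistent units.  Non-positive or missing SHBG yields a missing value
    (logged), not an exception.
    """
    tt = np.asarray(tt, float)
    shbg = np.asarray(shbg, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(shbg > 0, tt / shbg * 100.0, np.nan)
    n_bad = int(np.sum(~(shbg > 0)))
    if n_bad:
        log.info("compute_fti: %d value(s) undefined (SHBG <= 0 or missing)", n_bad)
    return float(out) if out.ndim == 0 else out


def age_profile(survey: pd.DataFrame, variable: str, sex: str,
                ages=None) -> AgeProfile:
    """Per-integer-age median of one variable for one sex.

    Ages with no non-missing observation are omitted from the grid.  A
    variable absent from the table, or never measured in the requested sex,
    raises a named error.
    """
    if variable not in survey.columns:
        raise KeyError(f"variable {variable!r} not present in survey")
    sub = survey.loc[survey["sex"] == sex, ["age", variable]].dropna()
    if ages is not None:
        sub = sub[sub["age"].isin(np.asarray(ages, int))]
    if len(sub) == 0:
        raise ValueError(f"variable {variable!r} has no data for sex {sex!r}")
    g = sub.groupby(sub["age"].astype(int))[variable]
    frame = pd.DataFrame({"age": g.median().index, "value": g.median().to_numpy(),
                          "n": g.size().to_numpy()}).sort_values("age")
    return AgeProfile(variable=variable, sex=sex, frame=frame.reset_index(drop=True))


@dataclass
class ZScoredSeries:
    """Series standardised by its own pooled mean and population SD."""

    values: np.ndarray
    mu: float
    sigma: float


def zscore(values) -> ZScoredSeries:
    """(x - mu) / sigma with mu, sigma over the whole supplied sample
    (population SD, divisor N).  Zero spread or fewer than two values is an
    error — the score is undefined."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("zscore requires at least 2 values")
    mu = float(x.mean())
    sigma = float(x.std())  # ddof=0: population SD
    if not sigma > 0:
        raise ValueError("zscore undefined: zero spread")
    return ZScoredSeries(values=(x - mu) / sigma, mu=mu, sigma=sigma)


def _overlap(profile: AgeProfile, hr: HRCurve) -> np.ndarray:
    hr_ages = hr.ages[hr.defined]
    return np.intersect1d(profile.ages, hr_ages)


def spearman_screen(profiles, hr: HRCurve) -> pd.DataFrame:
    """Spearman R and two-sided p of each profile against the HR curve.

    Computed over the intersection of defined ages; fewer than three
    overlapping ages (or a constant profile) yields an NA row.
    """
    hr_series = hr.defined_series()
    rows = []
    for prof in profiles:
        ages = _overlap(prof, hr)
        row = {"variable": prof.variable, "sex": prof.sex,
               "spearman_r": np.nan, "spearman_p": np.nan,
               "n_overlap": int(ages.size)}
        if ages.size >= 3:
            x = prof.series().loc[ages].to_numpy()
            y = hr_series.loc[ages].to_numpy()
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r, p = stats.spearmanr(x, y)
                row.update(spearman_r=float(r), spearman_p=float(p))
        rows.append(row)
    return pd.DataFrame(rows)


def size_matched_resample(registry: pd.DataFrame, target_counts,
                          seed=None) -> pd.DataFrame:
    """Draw, with replacement and per age, ``target_counts[age]`` patients.

    Ages whose registry pool is empty are skipped and reported via the
    ``skipped_ages`` attribute of the returned frame.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pools = dict(tuple(registry.groupby(registry["age_at_dx"].astype(int))))
    parts, skipped = [], []
    for a, c in dict(target_counts).items():
        pool = pools.get(int(a))
        if pool is None or len(pool) == 0:
            skipped.append(int(a))
            continue
        idx = rng.integers(0, len(pool), int(c))
        parts.append(pool.iloc[idx])
    if skipped:
        log.warning("size_matched_resample: no registry pool at ages %s", skipped)
    out = (pd.concat(parts, ignore_index=True) if parts
           else registry.iloc[0:0].copy())
    out.attrs["skipped_ages"] = skipped
    return out


def _ks_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    method = "exact" if max(a.size, b.size) <= 10 else "asymp"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.ks_2samp(a, b, method=method).pvalue)


def ks_homology(z_hr: np.ndarray, z_profile: np.ndarray, n_boot: int,
                alpha: float = 0.05, seed=None, weights=None) -> float:
    """% of paired age-grid bootstrap replicates where the KS test does not
    reject homology of two pre-z-scored, age-aligned series.

    Each replicate draws grid positions with replacement (optionally
    weighted, e.g. by survey per-age counts) and applies the two-sample KS
    test to the two series evaluated on that common resampled grid.
    """
    z_hr = np.asarray(z_hr, float)
    z_profile = np.asarray(z_profile, float)
    if z_hr.size != z_profile.size:
        raise ValueError("series must be age-aligned (equal length)")
    m = z_hr.size
    if weights is not None:
        weights = np.asarray(weights, float)
        weights = weights / weights.sum()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_pass = 0
    for _ in range(int(n_boot)):
        ia = rng.choice(m, m, replace=True, p=weights)
        n_pass += _ks_pvalue(z_hr[ia], z_profile[ia]) >= alpha
    return 100.0 * n_pass / n_boot


@dataclass
class HomologyResult:
    """Screening result for one variable and sex."""

    variable: str
    sex: str
    spearman_r: float
    spearman_p: float
    pct_homology: float
    n_boot: int
    n_overlap: int
    seed: object = None

    def __post_init__(self):
        assert np.isnan(self.pct_homology) or 0 <= self.pct_homology <= 100


def _precompute_pools(registry, terms, ages):
    pools = {}
    grouped = dict(tuple(registry.groupby(registry["age_at_dx"].astype(int))))
    for a in ages:
        sub = grouped.get(int(a))
        if sub is None or len(sub) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X, names, _ = build_design(sub, terms)
        pools[int(a)] = (X, names, sub["time_months"].to_numpy(float),
                         sub["event"].to_numpy(bool))
    return pools


def _refit_hr_series(pools, counts, rng):
    """One bootstrap replicate of the per-age male log-HR (refit mode)."""
    ages, hrs = [], []
    for a, c in counts.items():
        if a not in pools:
            continue
        X, names, t, d = pools[a]
        if MALE_TERM not in names:
            continue
        idx = rng.integers(0, len(t), int(c))
        Xb, tb, db = X[idx], t[idx], d[idx]
        keep = np.ptp(Xb, axis=0) > 0
        if not keep[names.index(MALE_TERM)] or not db.any():
            continue
        try:
            beta, _, _, _ = fit_coxph(Xb[:, keep], tb, db)
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
        kept_names = [nm for nm, k in zip(names, keep) if k]
        ages.append(a)
        hrs.append(np.exp(beta[kept_names.index(MALE_TERM)]))
    return np.asarray(ages, int), np.asarray(hrs, float)


def homology_score(hr: HRCurve, profile: AgeProfile,
                   registry: pd.DataFrame | None = None, n_boot: int = 10_000,
                   alpha: float = 0.05, seed=None, mode: str = "series",
                   terms=("sex", "race", "tumor_type", "stage")) -> HomologyResult:
    """Bootstrap-KS % homology (and Spearman R) of one profile vs the HR curve.

    Requires >= 3 overlapping defined ages, ``n_boot >= 1`` and
    ``0 < alpha < 1``.  A replicate with a degenerate z-score (zero spread)
    counts as rejecting, and is logged.  ``mode="refit"`` requires the
    registry and re-estimates the per-age Cox sweep on a size-matched
    resample in every replicate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sp = spearman_screen([profile], hr).iloc[0]
    ages = _overlap(profile, hr)
    if ages.size < 3:
        raise ValueError("fewer than 3 overlapping defined ages")
    counts = profile.n_per_age.loc[ages]
    prof_vals = profile.series().loc[ages].to_numpy()
    hr_vals = hr.defined_series().loc[ages].to_numpy()
    rng = np.random.default_rng(seed)

    if mode == "series":
        try:
            z_hr = zscore(hr_vals).values
            z_prof = zscore(prof_vals).values
            pct = ks_homology(z_hr, z_prof, n_boot=n_boot, alpha=alpha,
                              seed=rng, weights=counts.to_numpy(float))
        except ValueError as exc:
            log.warning("degenerate z-score for %s/%s: %s; all replicates "
                        "count as rejecting", profile.variable, profile.sex, exc)
            pct = 0.0
    elif mode == "refit":
        if registry is None:
            raise ValueError("mode='refit' requires the registry")
        pools = _precompute_pools(registry, terms, ages)
        cdict = {int(a): int(c) for a, c in counts.items()}
        prof_series = profile.series()
        n_pass = 0
        for _ in range(int(n_boot)):
            rep_ages, rep_hr = _refit_hr_series(pools, cdict, rng)
            common = np.intersect1d(rep_ages, ages)
            if common.size < 3:
                continue  # counted as rejecting
            try:
                za = zscore(pd.Series(rep_hr, index=rep_ages)
                            .loc[common].to_numpy()).values
                zb = zscore(prof_series.loc[common].to_numpy()).values
            except ValueError:
                log.info("degenerate z-score in replicate; counted as rejecting")
                continue
            n_pass += _ks_pvalue(za, zb) >= alpha
        pct = 100.0 * n_pass / n_boot
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return HomologyResult(variable=profile.variable, sex=profile.sex,
                          spearman_r=float(sp["spearman_r"]),
                          spearman_p=float(sp["spearman_p"]),
                          pct_homology=float(pct), n_boot=int(n_boot),
                          n_overlap=int(ages.size), seed=seed)


def homology_screen(survey: pd.DataFrame, hr: HRCurve,
                    variables=None, sexes=("female", "male"),
                    registry=None, n_boot: int = 10_000, alpha: float = 0.05,
                    seed=None, mode: str = "series") -> pd.DataFrame:
    """Run the Spearman and % homology screen for every variable and sex.

    Variables never measured in a sex yield NA cells (kept in the output,
    mirroring a lab panel with sex-specific assays).  Each variable/sex gets
    an independent child seed split from ``seed``.
    """
    if variables is None:
        variables = [c for c in survey.columns if c not in ("age", "sex")]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(variables) * len(sexes))
    rows = []
    k = 0
    for var in variables:
        for sex in sexes:
            child = children[k]
            k += 1
            try:
                prof = age_profile(survey, var, sex)
                res = homology_score(hr, prof, registry=registry,
                                     n_boot=n_boot, alpha=alpha,
                                     seed=child, mode=mode)
                rows.append({"variable": var, "sex": sex,
                             "spearman_r": res.spearman_r,
                             "spearman_p": res.spearman_p,
                             "pct_homology": res.pct_homology,
                             "n_overlap": res.n_overlap})
            except (ValueError, KeyError) as exc:
                log.info("screen: %s/%s marked NA (%s)", var, sex, exc)
                rows.append({"variable": var, "sex": sex,
                             "spearman_r": np.nan, "spearman_p": np.nan,
                             "pct_homology": np.nan, "n_overlap": 0})
    return pd.DataFrame(rows)
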