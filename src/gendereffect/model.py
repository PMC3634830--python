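"""Top-level Model/Results interface for the full analysis.

`GenderEffectAnalysis` is built from a registry table (and optionally a
survey table); ``fit()`` applies case selection and administrative
censoring, fits the pooled and age-stratified multivariate Cox models, the
per-age HR sweep and the per-age Kaplan-Meier survival-difference curve,
and — when a survey is supplied — runs the Spearman and % homology screens.
The returned `GenderEffectResults` carries every table and can serialise the
whole run to a directory of CSV artifacts plus a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (ExclusionReport, apply_censoring, apply_exclusions,
                     read_registry, stratify_age)
from .curves import HRCurve, SurvDiffCurve
from .homology import homology_screen
from .survival import DEFAULT_TERMS, CoxFit, cox_fit, hr_by_age, survdiff_by_age

log = logging.getLogger(__name__)

__all__ = ["GenderEffectAnalysis", "GenderEffectResults"]

DEFAULT_AGE_STRATA = ((17, 61), (62, 84))


class GenderEffectAnalysis:
    """Age-resolved male-vs-female cancer mortality analysis.

    Parameters
    ----------
    registry : DataFrame with the registry schema (see `cohort`).
    survey : optional DataFrame with columns age, sex and variable columns.
    terms : pooled Cox model terms.
    horizon_months : administrative censoring horizon (default 60 = 5 years).
    age_strata : closed age intervals for the stratified Cox tables.
    n_boot, alpha, homology_mode : forwarded to the homology screen.
    seed : master seed for every stochastic stage.
    """

    def __init__(self, registry: pd.DataFrame, survey: pd.DataFrame | None = None,
                 terms=DEFAULT_TERMS, horizon_months: float = 60,
                 age_strata=DEFAULT_AGE_STRATA, n_boot: int = 10_000,
                 alpha: float = 0.05, seed=None, homology_mode: str = "series"):
        self.registry = registry
        self.survey = survey
        self.terms = tuple(terms)
        self.horizon_months = horizon_months
        self.age_strata = tuple(tuple(s) for s in age_strata)
        self.n_boot = n_boot
        self.alpha = alpha
        self.seed = seed
        self.homology_mode = homology_mode
        if survey is not None and n_boot > 0 and seed is None:
            raise ValueError("seed is mandatory when the homology bootstrap runs")

    @classmethod
    def from_csv(cls, registry_path, survey_path=None, **kwargs):
        registry = read_registry(registry_path)
        survey = pd.read_csv(survey_path) if survey_path else None
        return cls(registry, survey, **kwargs)

    def fit(self) -> "GenderEffectResults":
        cohort, report = apply_exclusions(self.registry)
        cohort = apply_censoring(cohort, self.horizon_months)
        log.info("cohort after selection: %d of %d records", report.n_out,
                 report.n_in)
        pooled = cox_fit(cohort, self.terms)
        stratum_fits = {}
        for lo, hi in self.age_strata:
            try:
                stratum_fits[(lo, hi)] = cox_fit(stratify_age(cohort, lo, hi),
                                                 self.terms)
            except ValueError as exc:
                log.warning("age stratum %d-%d not fitted: %s", lo, hi, exc)
        sweep_terms = tuple(t for t in self.terms if t != "age")
        curve = hr_by_age(cohort, sweep_terms, alpha=self.alpha)
        survdiff = survdiff_by_age(cohort, self.horizon_months, alpha=self.alpha)
        screen = None
        if self.survey is not None:
            screen = homology_screen(self.survey, curve, registry=cohort,
                                     n_boot=self.n_boot, alpha=self.alpha,
                                     seed=self.seed, mode=self.homology_mode)
        return GenderEffectResults(
            model=self, cohort=cohort, exclusion_report=report, pooled=pooled,
            stratum_fits=stratum_fits, hr_curve=curve, survdiff=survdiff,
            screen=screen)


@dataclass
class GenderEffectResults:
    """Fitted tables and curves of one analysis run."""

    model: GenderEffectAnalysis
    cohort: pd.DataFrame
    exclusion_report: ExclusionReport
    pooled: CoxFit
    stratum_fits: dict
    hr_curve: HRCurve
    survdiff: SurvDiffCurve
    screen: pd.DataFrame | None = None
    artifacts: dict = field(default_factory=dict)

    def summary(self) -> str:
        male_hr = self.pooled.hazard_ratios.get("sex[male]", float("nan"))
        lines = [
            "Gender effect on cause-specific cancer mortality",
            "=" * 56,
            str(self.exclusion_report),
            "",
            f"Pooled male-vs-female HR: {male_hr:.3f}",
            str(self.pooled),
        ]
        for (lo, hi), fit in self.stratum_fits.items():
            hr = fit.hazard_ratios.get("sex[male]", float("nan"))
            lines.append(f"\nAges {lo}-{hi}: male HR {hr:.3f} "
                         f"(n={fit.n}, events={fit.n_events})")
        d = self.hr_curve.frame
        n_sig = int(d["significant"].sum())
        lines.append(f"\nHR-by-age: {int(self.hr_curve.defined.sum())} defined "
                     f"ages, {n_sig} significant at p<{self.model.alpha}")
        if self.screen is not None:
            top = self.screen.dropna(subset=["pct_homology"]) \
                .sort_values("pct_homology", ascending=False).head(3)
            lines.append("\nTop homology scores:")
            for _, r in top.iterrows():
                lines.append(f"  {r['variable']}/{r['sex']}: "
                             f"{r['pct_homology']:.1f}% "
                             f"(Spearman R={r['spearman_r']:.3f})")
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write all artifacts as CSV plus a JSON manifest; returns paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(name, writer):
            p = out / name
            writer(p)
            paths[name] = str(p)

        _write("exclusion_report.csv", self.exclusion_report.to_csv)
        _write("cox_pooled.csv",
               lambda p: self.pooled.summary().to_csv(p, index_label="term"))
        for (lo, hi), fit in self.stratum_fits.items():
            _write(f"cox_age_{lo}_{hi}.csv",
                   lambda p, f=fit: f.summary().to_csv(p, index_label="term"))
        _write("hr_by_age.csv", self.hr_curve.to_csv)
        _write("survdiff_by_age.csv", self.survdiff.to_csv)
        if self.screen is not None:
            _write("screen.csv", lambda p: self.screen.to_csv(p, index=False))
            spear = self.screen.pivot(index="variable", columns="sex",
                                      values="spearman_r")
            _write("spearman_table.csv", lambda p: spear.to_csv(p))
            hom = self.screen.pivot(index="variable", columns="sex",
                                    values="pct_homology")
            _write("homology_table.csv", lambda p: hom.to_csv(p))
        manifest = {
            "package": "gendereffect",
            "version": __version__,
            "seed": self.model.seed,
            "terms": list(self.model.terms),
            "horizon_months": self.model.horizon_months,
            "age_strata": [list(s) for s in self.model.age_strata],
            "n_boot": self.model.n_boot,
            "alpha": self.model.alpha,
            "homology_mode": self.model.homology_mode,
            "n_cohort": int(len(self.cohort)),
            "artifacts": sorted(paths),
        }
        _write("manifest.json",
               lambda p: p.write_text(json.dumps(manifest, indent=2,
                                                 sort_keys=True) + "\n"))
        self.artifacts = paths
        return paths
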