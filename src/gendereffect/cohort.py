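"""Registry data model, I/O, case-selection rules and administrative censoring.

The registry table mirrors a cancer-registry research extract: one row per
patient with diagnosis covariates, follow-up in months and a cause-specific
death indicator.  Case selection removes sex-specific primary sites (breast,
uterus, ovary, vagina/vulva, prostate, testis, penis — the ICD-9 three-digit
codes 174–187), records reported by death certificate or autopsy only,
multiple primaries, patients alive with no survival time, ages outside 1–84,
and records with any missing required covariate (complete-case analysis).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "REGISTRY_COLUMNS", "SEXES", "RACES", "TUMOR_TYPES", "STAGES",
    "EXCLUDED_SITE_CODES", "ExclusionReport", "SchemaError",
    "read_registry", "write_registry", "apply_exclusions",
    "apply_censoring", "stratify_age",
]

SEXES = ("female", "male")
RACES = ("african_american", "caucasian")
TUMOR_TYPES = ("hematological", "sarcoma", "solid")
STAGES = ("distant", "localized", "regional")
REPORTING_SOURCES = ("standard", "death_certificate_only", "autopsy_only")

#: Sex-specific primary sites excluded from analysis (3-digit ICD-9 codes):
#: breast (174 female / 175 male), uterus NOS 179, cervix 180, other female
#: genital 181/184 (incl. vagina, vulva), corpus uteri 182, ovary 183,
#: prostate 185, testis 186, penis & other male genital 187.
EXCLUDED_SITE_CODES = frozenset(
    {"174", "175", "179", "180", "181", "182", "183", "184", "185", "186", "187"}
)

REGISTRY_COLUMNS = [
    "age_at_dx", "sex", "race", "site_code", "tumor_type", "stage",
    "time_months", "event", "reporting_source", "multiple_primary",
    "alive_no_survival_time",
]

#: covariates that must be present for complete-case analysis
_REQUIRED_COVARIATES = ["age_at_dx", "sex", "race", "tumor_type", "stage"]

_ENUMS = {
    "sex": SEXES,
    "race": RACES,
    "tumor_type": TUMOR_TYPES,
    "stage": STAGES,
    "reporting_source": REPORTING_SOURCES,
}


class SchemaError(ValueError):
    """A mandatory column is missing from a registry file."""


@dataclass
class ExclusionReport:
    """Per-rule tallies of excluded records.

    A record matched by several rules is tallied once, under the first
    matching rule in the documented order, so tallies sum to ``n_in - n_out``.
    """

    n_in: int = 0
    n_out: int = 0
    counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "excluded": v} for k, v in self.counts.items()]
        rows.append({"rule": "total_excluded", "excluded": self.n_in - self.n_out})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [f"records in: {self.n_in}"]
        lines += [f"  excluded by {k}: {v}" for k, v in self.counts.items()]
        lines.append(f"records out: {self.n_out}")
        return "\n".join(lines)


def read_registry(path) -> pd.DataFrame:
    """Read a registry CSV into a typed DataFrame.

    Malformed rows (unparseable enum, negative follow-up) are dropped and
    reported with their line numbers via a ``row_errors`` attribute on the
    returned frame; a missing mandatory column raises :class:`SchemaError`.
    Reading all rows as malformed is an error.
    """
    df = pd.read_csv(path, dtype={"site_code": str}, keep_default_na=True)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry file missing mandatory column(s): {missing}")
    df = df[REGISTRY_COLUMNS].copy()

    bad = pd.Series(False, index=df.index)
    reasons = {}
    for col, levels in _ENUMS.items():
        ok = df[col].isin(levels) | df[col].isna()
        for i in df.index[~ok]:
            reasons.setdefault(i, f"unparseable {col}: {df.at[i, col]!r}")
        bad |= ~ok
    neg = pd.to_numeric(df["time_months"], errors="coerce") < 0
    for i in df.index[neg.fillna(False)]:
        reasons.setdefault(i, "negative time_months")
    bad |= neg.fillna(False)

    if bad.all() and len(df) > 0:
        raise ValueError("all registry rows are malformed; first error: "
                         + next(iter(reasons.values())))
    # +2: header line and 1-based numbering
    row_errors = [(int(i) + 2, msg) for i, msg in sorted(reasons.items())]
    for line, msg in row_errors:
        log.warning("registry row error at line %d: %s", line, msg)

    df = df[~bad].copy()
    df["age_at_dx"] = pd.to_numeric(df["age_at_dx"], errors="coerce")
    df["time_months"] = pd.to_numeric(df["time_months"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce").astype("Int64")
    for col in ("multiple_primary", "alive_no_survival_time"):
        df[col] = df[col].astype(bool)
    df = df.reset_index(drop=True)
    df.attrs["row_errors"] = row_errors
    return df


def write_registry(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=REGISTRY_COLUMNS)


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the case-selection rules in the documented, order-pinned sequence.

    Order: (1) age at diagnosis outside 1-84; (2) death-certificate-only or
    autopsy-only reporting; (3) multiple primaries; (4) alive with no survival
    time; (5) sex-specific primary site codes; (6) missing required covariate.
    Filtering is total: no input record can raise.
    """
    report = ExclusionReport(n_in=len(df))
    age = pd.to_numeric(df["age_at_dx"], errors="coerce")
    rules = [
        ("age_outside_1_84", ~age.between(1, 84)),
        ("death_certificate_or_autopsy_only",
         df["reporting_source"].isin(["death_certificate_only", "autopsy_only"])),
        ("multiple_primary", df["multiple_primary"].astype(bool)),
        ("alive_no_survival_time", df["alive_no_survival_time"].astype(bool)),
        ("sex_specific_site",
         df["site_code"].astype(str).str.strip().isin(EXCLUDED_SITE_CODES)),
        ("missing_covariate",
         df[_REQUIRED_COVARIATES].isna().any(axis=1)
         | (df[_REQUIRED_COVARIATES].astype(str).apply(
             lambda s: s.str.strip() == "").any(axis=1))),
    ]
    already = pd.Series(False, index=df.index)
    for name, mask in rules:
        mask = mask.fillna(True) if mask.dtype == object else mask
        fresh = mask & ~already
        report.counts[name] = int(fresh.sum())
        already |= mask
    kept = df[~already].reset_index(drop=True)
    report.n_out = len(kept)
    return kept, report


def apply_censoring(df: pd.DataFrame, horizon_months: float = 60) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon_months`` (default 5 years).

    Records with follow-up strictly beyond the horizon get time set to the
    horizon and the event flag cleared; a death exactly at the horizon is kept
    as an event.
    """
    if horizon_months <= 0:
        raise ValueError(f"horizon_months must be positive, got {horizon_months}")
    out = df.copy()
    over = out["time_months"] > horizon_months
    out.loc[over, "time_months"] = horizon_months
    out.loc[over, "event"] = 0
    return out


def stratify_age(df: pd.DataFrame, lo: int, hi: int) -> pd.DataFrame:
    """Keep records with lo <= age at diagnosis <= hi (closed interval)."""
    if lo > hi:
        raise ValueError(f"invalid age stratum: lo={lo} > hi={hi}")
    return df[df["age_at_dx"].between(lo, hi)].reset_index(drop=True)
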