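"""Per-age curve containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HRCurve", "SurvDiffCurve", "AgeProfile"]

_HR_COLUMNS = ["age", "hr", "lo", "hi", "p", "n", "n_events", "significant"]


@dataclass
class HRCurve:
    """Male-vs-female hazard ratio per integer age at diagnosis.

    ``frame`` has one row per age on the grid with columns
    age, hr, lo, hi, p, n, n_events, significant; ages where the stratified
    model could not be fitted carry NaN estimates (undefined, never zero).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        for c in _HR_COLUMNS:
            if c not in self.frame.columns:
                self.frame[c] = np.nan
        self.frame = self.frame[_HR_COLUMNS].reset_index(drop=True)

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(int)

    @property
    def hr(self) -> np.ndarray:
        return self.frame["hr"].to_numpy(float)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.frame["hr"].to_numpy(float))

    def defined_series(self) -> pd.Series:
        """HR indexed by age, defined ages only."""
        f = self.frame[self.defined]
        return pd.Series(f["hr"].to_numpy(), index=f["age"].to_numpy(int))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HRCurve":
        return cls(pd.read_csv(path))

    @classmethod
    def from_values(cls, ages, hr, **extra) -> "HRCurve":
        df = pd.DataFrame({"age": np.asarray(ages, int),
                           "hr": np.asarray(hr, float)})
        for k, v in extra.items():
            df[k] = v
        return cls(df)


@dataclass
class SurvDiffCurve:
    """Female-minus-male 5-year survival difference (percentage points) by age."""

    frame: pd.DataFrame  # age, delta, p_logrank, significant, n

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(int)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.frame["delta"].to_numpy(float))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvDiffCurve":
        return cls(pd.read_csv(path))


@dataclass
class AgeProfile:
    """Per-age median of one survey variable for one sex."""

    variable: str
    sex: str
    frame: pd.DataFrame  # age, value, n

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(int)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(float)

    @property
    def n_per_age(self) -> pd.Series:
        return pd.Series(self.frame["n"].to_numpy(int),
                         index=self.frame["age"].to_numpy(int))

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ages)
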