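"""Shared fixtures and independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest


def toy_row(**kw):
    """One registry record with innocuous defaults, overridable per field."""
    row = dict(age_at_dx=50, sex="female", race="caucasian", site_code="162",
               tumor_type="solid", stage="distant", time_months=24.0, event=1,
               reporting_source="standard", multiple_primary=False,
               alive_no_survival_time=False)
    row.update(kw)
    return row


def registry_frame(rows):
    return pd.DataFrame([toy_row(**r) for r in rows])


@pytest.fixture
def make_registry():
    return registry_frame


def efron_loglik_oracle(beta, x, time, event):
    """Direct textbook evaluation of the Efron partial log likelihood for a
    single covariate: explicit loops over event times and risk sets."""
    n = len(x)
    ll = 0.0
    for t in sorted({time[i] for i in range(n) if event[i]}):
        dead = [i for i in range(n) if event[i] and time[i] == t]
        risk = [i for i in range(n) if time[i] >= t]
        D = len(dead)
        s = sum(math.exp(beta * x[i]) for i in dead)
        r = sum(math.exp(beta * x[i]) for i in risk)
        ll += sum(beta * x[i] for i in dead)
        for ell in range(D):
            ll -= math.log(r - (ell / D) * s)
    return ll


def grid_max_efron(x, time, event, lo=-8.0, hi=8.0):
    """Brute-force maximisation of the Efron partial likelihood over a log-HR
    grid, refined to well below 1e-6."""
    grid = np.linspace(lo, hi, 3201)  # 5e-3 spacing
    vals = [efron_loglik_oracle(b, x, time, event) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    lo, hi = b0 - 5e-3, b0 + 5e-3
    for _ in range(60):  # ternary refinement
        m1, m2 = lo + (hi - lo) / 3, hi - (hi - lo) / 3
        if efron_loglik_oracle(m1, x, time, event) < \
                efron_loglik_oracle(m2, x, time, event):
            lo = m1
        else:
            hi = m2
    return 0.5 * (lo + hi)


def logrank_oracle(time, event, group):
    """Two-sample log-rank chi-square by direct risk-set summation."""
    obs_minus_exp = 0.0
    var = 0.0
    for t in sorted({time[i] for i in range(len(time)) if event[i]}):
        risk = [i for i in range(len(time)) if time[i] >= t]
        dead = [i for i in risk if event[i] and time[i] == t]
        n = len(risk)
        n1 = sum(1 for i in risk if group[i] == 1)
        d = len(dead)
        d1 = sum(1 for i in dead if group[i] == 1)
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp ** 2 / var


@pytest.fixture
def oracles():
    return {"efron_loglik": efron_loglik_oracle, "grid_max": grid_max_efron,
            "logrank": logrank_oracle}
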