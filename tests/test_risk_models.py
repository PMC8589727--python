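import math

import numpy as np
import pandas as pd
import pytest

from antithrombo.adherence import build_supply_episodes
from antithrombo.risk_models import (
    UNCOVERED_CATEGORIES,
    age_band,
    derive_uncovered_exposure,
    fit_bleeding_model,
    fit_cox,
    fit_logistic,
    fit_nonpersistence_model,
    uncovered_category,
)


@pytest.mark.parametrize(
    "days,label",
    [
        (0, "<1 week"),
        (6, "<1 week"),
        (7, "1 week to 1 month"),
        (29, "1 week to 1 month"),
        (30, "1 to 3 months"),
        (90, "1 to 3 months"),
        (91, "3 to 6 months"),
        (100, "3 to 6 months"),
        (182, "3 to 6 months"),
        (183, ">6 months"),
        (200, ">6 months"),
    ],
)
def test_uncovered_category_boundaries(days, label):
    assert uncovered_category(days) == label


def test_fully_covered_followup_is_reference_category():
    eps = build_supply_episodes(list(range(0, 365, 30)), 30)
    exp = derive_uncovered_exposure(eps, 0, 365, "A")
    assert exp.uncovered_days == 0
    assert exp.category == "<1 week"


def test_age_bands():
    assert [age_band(a) for a in (35, 55, 65, 75, 85)] == ["30-49", "50-59", "60-69", "70-79", "80+"]


def test_logistic_matches_contingency_table_cross_ratio():
    """40/100 vs 20/100 non-adherent: OR = (40·80)/(60·20) = 8/3."""
    df = pd.DataFrame(
        {
            "y": [1] * 40 + [0] * 60 + [1] * 20 + [0] * 80,
            "x": [1] * 100 + [0] * 100,
        }
    )
    (eff,) = fit_logistic(df, "y", ["x"])
    assert eff.estimate == pytest.approx((40 * 80) / (60 * 20), rel=1e-6)
    assert eff.ci_low < eff.estimate < eff.ci_high


def test_cox_recovers_exponential_rate_ratio():
    """Two exponential groups with rate ratio 2 and no censoring."""
    rng = np.random.default_rng(77)
    n = 1000
    t0 = rng.exponential(100.0, size=n)
    t1 = rng.exponential(50.0, size=n)
    df = pd.DataFrame(
        {
            "t": np.concatenate([t0, t1]),
            "e": 1,
            "g": [0] * n + [1] * n,
        }
    )
    effects, _ = fit_cox(df, "t", "e", ["g"])
    assert 1.8 <= effects[0].estimate <= 2.2


def test_bleeding_scale_reparameterisation_identity():
    """Doubling the PDC scale divisor halves the log-estimate exactly."""
    rng = np.random.default_rng(5)
    n = 2000
    pdc = rng.uniform(0, 1, n)
    rate = 0.01 * 1.2 ** (pdc * 10)
    t = rng.exponential(1 / rate)
    fu = rng.uniform(200, 700, n)
    df = pd.DataFrame(
        {"pdc": pdc, "bleed_time_days": np.minimum(t, fu), "bleed_event": t < fu}
    )
    e10 = fit_bleeding_model(df, scale=0.10)
    e20 = fit_bleeding_model(df, scale=0.20)
    assert math.log(e20.estimate) == pytest.approx(2 * math.log(e10.estimate), rel=1e-6)


def test_nonpersistence_model_reports_ph_diagnostic():
    rng = np.random.default_rng(8)
    n = 800
    x = rng.integers(0, 2, n)
    t = rng.exponential(np.where(x == 1, 120, 200))
    fu = rng.uniform(100, 600, n)
    df = pd.DataFrame(
        {
            "event_time_days": np.minimum(t, fu),
            "event_flag": t < fu,
            "drug": np.where(x == 1, "apixaban", "warfarin"),
        }
    )
    effects, diag = fit_nonpersistence_model(df, covariates=("drug",))
    assert effects[0].term == "drug[apixaban]"
    assert effects[0].estimate > 1  # apixaban group discontinues faster here
    assert {"term", "test_statistic", "p"} <= set(diag.columns)
    assert ((diag["p"] >= 0) & (diag["p"] <= 1)).all()


def test_single_level_covariate_dropped_with_warning():
    df = pd.DataFrame({"y": [0, 1] * 50, "x": [1] * 100, "z": [0, 1] * 50})
    with pytest.warns(UserWarning, match="single level"):
        effects = fit_logistic(df, "y", ["x", "z"])
    assert [e.term for e in effects] == ["z"]


def test_changing_reference_level_inverts_effect():
    rng = np.random.default_rng(10)
    n = 2000
    g = rng.integers(0, 2, n)
    p = np.where(g == 1, 0.3, 0.5)
    y = rng.random(n) < p
    df = pd.DataFrame({"y": y.astype(int), "drug": np.where(g == 1, "apixaban", "warfarin")})
    (e_w,) = fit_logistic(df, "y", ["drug"], {"drug": "warfarin"})
    (e_a,) = fit_logistic(df, "y", ["drug"], {"drug": "apixaban"})
    assert e_w.estimate == pytest.approx(1 / e_a.estimate, rel=1e-6)
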