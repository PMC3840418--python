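"""Dissolution-experiment statistics: losses, ANOVA, Tukey, exponential fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import curve_fit

import reefdiss as rd
from reefdiss.dissolution import (
    ConvergenceError,
    ExponentialLossModel,
    FitError,
    fit_exponential_loss,
    one_way_anova,
    tukey_hsd,
)


def _table(w0, w1, sa=100.0, dur=7.0):
    n = len(w0)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "genus": "Montipora",
            "growth_form": "foliose",
            "porosity_class": "perforate",
            "treatment": "acidified",
            "w0_g": w0,
            "w1_g": w1,
            "surface_area_cm2": sa,
            "volume_ml": 10.0,
            "duration_d": dur,
        }
    )


# ---------------------------------------------------------------------- losses

@pytest.mark.parametrize(
    "w0, w1, expected",
    [(10.0, 9.9, -0.01), (5.0, 5.0, 0.0), (8.40, 8.3706, -0.0035)],
)
def test_normalized_loss(w0, w1, expected):
    out = rd.normalized_loss(_table([w0], [w1]))
    assert out.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_normalized_loss_rejects_nonpositive_w0():
    with pytest.raises(ValueError, match="w0"):
        rd.normalized_loss(_table([0.0], [1.0]))


@pytest.mark.parametrize(
    "dw, sa, dur, expected",
    [(-0.0294, 100.0, 7.0, -4.2e-5), (0.0, 100.0, 7.0, 0.0), (-0.147, 50.0, 7.0, -4.2e-4)],
)
def test_areal_dissolution_rate(dw, sa, dur, expected):
    out = rd.areal_dissolution_rate(_table([10.0], [10.0 + dw], sa=sa, dur=dur))
    assert out.iloc[0] == pytest.approx(expected, rel=1e-12)


def test_loss_measures_scale_linearly_in_weight_change(rng):
    w0 = rng.uniform(5, 50, 8)
    dw = -rng.uniform(0.001, 0.3, 8)
    t1, t2 = _table(w0, w0 + dw), _table(w0, w0 + 3 * dw)
    assert np.allclose(rd.normalized_loss(t2), 3 * rd.normalized_loss(t1))
    assert np.allclose(rd.areal_dissolution_rate(t2), 3 * rd.areal_dissolution_rate(t1))
    # order invariance
    shuffled = t1.sample(frac=1, random_state=0)
    assert np.allclose(
        sorted(rd.normalized_loss(shuffled)), sorted(rd.normalized_loss(t1))
    )


def test_group_summary_means():
    df = pd.concat(
        [
            _table([10.0] * 3, [9.0, 8.0, 7.0]).assign(growth_form="branching"),
            _table([10.0] * 3, [10.0] * 3).assign(growth_form="encrusting"),
        ]
    )
    out = rd.group_summary(df, grouping=["growth_form"])
    means = dict(zip(out["growth_form"], out["mean_normalized_loss"]))
    assert means["branching"] == pytest.approx(-0.2)
    assert means["encrusting"] == 0.0
    sds = dict(zip(out["growth_form"], out["sd_normalized_loss"]))
    assert sds["encrusting"] == 0.0


def test_group_summary_rejects_empty():
    with pytest.raises(ValueError):
        rd.group_summary(_table([], []))


# ---------------------------------------------------------------------- ANOVA

def test_anova_two_group_example():
    res = one_way_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
    assert res.F == pytest.approx(1.5)
    assert (res.df_between, res.df_within) == (1, 4)
    assert res.p == pytest.approx(0.2879, abs=1e-4)


def test_anova_matches_scipy(rng):
    groups = [rng.normal(m, 1.0, n) for m, n in [(0, 5), (0.5, 7), (1.2, 4)]]
    labels = np.repeat(["a", "b", "c"], [5, 7, 4])
    res = one_way_anova(np.concatenate(groups), labels)
    ref = stats.f_oneway(*groups)
    assert res.F == pytest.approx(ref.statistic, rel=1e-10)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-10)


def test_anova_degenerate_cases():
    all_equal = one_way_anova([2.0] * 6, ["a"] * 3 + ["b"] * 3)
    assert (all_equal.F, all_equal.p) == (0.0, 1.0)
    assert all_equal.degenerate
    separated = one_way_anova([0.0, 0.0, 1.0, 1.0], ["a", "a", "b", "b"])
    assert separated.p == 0.0 and np.isinf(separated.F) and separated.degenerate


def test_anova_rejects_single_group():
    with pytest.raises(ValueError):
        one_way_anova([1.0, 2.0, 3.0], ["a"] * 3)


@given(shift=st.floats(-50, 50, allow_nan=False), scale=st.floats(0.1, 10))
def test_anova_invariance_under_affine_maps(shift, scale):
    rng = np.random.default_rng(7)
    values = rng.normal(0, 1, 12)
    labels = np.repeat(["a", "b", "c"], 4)
    base = one_way_anova(values, labels)
    moved = one_way_anova(values * scale + shift, labels)
    assert moved.F == pytest.approx(base.F, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------- Tukey

def test_tukey_no_differences():
    out = tukey_hsd([1.0, 2.0] * 3, np.repeat(["a", "b", "c"], 2))
    assert np.allclose(out["mean_diff"], 0.0)
    assert not out["significant"].any()


def test_tukey_clear_separation_significant():
    values = [0.0, 0.001, -0.001, 0.0, 10.0, 10.001, 9.999, 10.0]
    labels = ["a"] * 4 + ["b"] * 4
    out = tukey_hsd(values, labels, alpha=0.05)
    assert out["significant"].all()


def test_tukey_matches_scipy_oracle():
    groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [1.0, 2.0, 3.0]]
    labels = np.repeat(["g1", "g2", "g3"], 3)
    mine = tukey_hsd(np.concatenate(groups), labels)
    ref = stats.tukey_hsd(*groups)
    lookup = {("g1", "g2"): (0, 1), ("g1", "g3"): (0, 2), ("g2", "g3"): (1, 2)}
    for _, row in mine.iterrows():
        i, j = lookup[(row["group1"], row["group2"])]
        assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-3)


def test_tukey_conservative_vs_pairwise_t(rng):
    """Adjusted p never falls below the pooled-variance pairwise-t p."""
    for _ in range(10):
        k = rng.integers(3, 6)
        sizes = rng.integers(3, 8, k)
        values = np.concatenate([rng.normal(rng.normal(0, 1), 1, n) for n in sizes])
        labels = np.repeat([f"g{i}" for i in range(k)], sizes)
        res = one_way_anova(values, labels)
        msw = res.ss_within / res.df_within
        out = tukey_hsd(values, labels)
        cells = {f"g{i}": values[labels == f"g{i}"] for i in range(k)}
        for _, row in out.iterrows():
            x, y = cells[row["group1"]], cells[row["group2"]]
            t = abs(row["mean_diff"]) / np.sqrt(msw * (1 / len(x) + 1 / len(y)))
            p_t = 2 * stats.t.sf(t, res.df_within)
            assert row["p_adj"] >= p_t - 1e-12


# ------------------------------------------------------------- exponential fit

def test_fit_recovers_noiseless_coefficients_exactly():
    sa = np.arange(40.0, 241.0, 40.0)
    loss = -0.005 * np.exp(0.017 * sa)
    res = fit_exponential_loss(sa, loss)
    assert res.k_amp == pytest.approx(0.005, rel=1e-6)
    assert res.k_exp == pytest.approx(0.017, rel=1e-6)
    assert res.rss == pytest.approx(0.0, abs=1e-12)


@given(
    k_amp=st.floats(1e-4, 0.05),
    k_exp=st.floats(0.001, 0.05),
)
def test_fit_recovery_property(k_amp, k_exp):
    sa = np.linspace(20.0, 240.0, 8)
    loss = -k_amp * np.exp(k_exp * sa)
    res = fit_exponential_loss(sa, loss)
    assert res.k_amp == pytest.approx(k_amp, rel=1e-6)
    assert res.k_exp == pytest.approx(k_exp, rel=1e-6)


def test_fit_noisy_recovery_and_curve_fit_oracle():
    rng = np.random.default_rng(42)
    sa = rng.uniform(20, 250, 50)
    loss = -0.005 * np.exp(0.017 * sa) + rng.normal(0, 0.01, 50)
    res = fit_exponential_loss(sa, loss)
    assert res.k_exp == pytest.approx(0.017, rel=0.10)
    # independent nonlinear least-squares oracle
    popt, _ = curve_fit(lambda s, ka, ke: -ka * np.exp(ke * s), sa, loss, p0=(0.005, 0.017))
    assert res.k_amp == pytest.approx(popt[0], rel=1e-5)
    assert res.k_exp == pytest.approx(popt[1], rel=1e-5)


def test_fit_predictions_are_nonpositive():
    sa = np.linspace(20, 240, 6)
    res = fit_exponential_loss(sa, -0.005 * np.exp(0.017 * sa))
    assert (res.predict(np.linspace(0, 300, 20)) <= 0).all()


def test_fit_degenerate_inputs_rejected():
    with pytest.raises(FitError):
        fit_exponential_loss([100.0, 150.0, 200.0], [0.0, 0.0, 0.0])  # all zero losses
    with pytest.raises(FitError):
        fit_exponential_loss([100.0, 150.0], [-0.1, -0.2])  # too few points
    with pytest.raises(FitError):
        fit_exponential_loss([100.0] * 4, [-0.1, -0.2, -0.3, -0.4])  # equal areas
    with pytest.raises(FitError):
        fit_exponential_loss([50.0, 100.0, 150.0], [0.1, 0.2, -0.3])  # <2 negative losses


def test_convergence_error_carries_last_iterate():
    sa = np.linspace(20, 240, 8)
    loss = -0.005 * np.exp(0.017 * sa)
    with pytest.raises(ConvergenceError) as err:
        ExponentialLossModel(sa, loss).fit(max_iter=1, tol=1e-16)
    assert len(err.value.last_params) == 2
    assert err.value.last_params[0] > 0


def test_weight_gainers_kept_in_fit_but_not_initialization():
    sa = np.linspace(20.0, 240.0, 10)
    loss = -0.005 * np.exp(0.017 * sa)
    loss[0] = 0.002  # one sample gained weight
    res = fit_exponential_loss(sa, loss)
    assert res.nobs == 10
    assert res.k_exp == pytest.approx(0.017, rel=0.05)


# --------------------------------------------------------- experiment wrapper

def test_experiment_fit_on_default_synthetic_data(default_samples, default_analysis):
    summ = rd.group_summary(default_samples, grouping=["treatment", "porosity_class"])
    means = {
        (r["treatment"], r["porosity_class"]): r["mean_normalized_loss"]
        for _, r in summ.iterrows()
    }
    perf_acid = means[("acidified", "perforate")]
    assert perf_acid < means[("acidified", "imperforate")]
    assert perf_acid < means[("control", "perforate")]
    assert perf_acid < means[("control", "imperforate")]
    assert default_analysis.anova.p < 0.05
    assert default_analysis.loss_fit is not None
    assert default_analysis.loss_fit.k_exp == pytest.approx(0.017, rel=0.10)
    assert default_analysis.loss_fit.k_amp == pytest.approx(0.005, rel=0.25)
    text = default_analysis.summary()
    assert "ANOVA" in text and "k_exp" in text
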