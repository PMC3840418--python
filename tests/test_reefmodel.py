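"""Reef accretion-dissolution ODE, RK4 convergence and keep-up comparisons."""

import numpy as np
import pytest

import reefdiss as rd
from reefdiss.reefmodel import ACCRETION_COEFFICIENTS, DISSOLUTION_RATES


def test_rhs_constant_mode_arithmetic():
    # high-cover perforate reef: 7 + 1 - 10.5 = -2.5 mm/y
    p = rd.ReefModelParams(a=7.0, b=1.0, S=1.0, c=1.0, D=10.5)
    assert rd.reef_rhs(100.0, p) == pytest.approx(-2.5)
    assert p.net_rate == pytest.approx(-2.5)


def test_rhs_no_dissolution_limit_and_asymptote():
    for mode in ("constant", "literal"):
        p = rd.ReefModelParams(a=3.0, D=0.0, mode=mode)
        assert rd.reef_rhs(50.0, p) == pytest.approx(4.0)
    lit = rd.ReefModelParams(a=7.0, D=10.5, mode="literal")
    assert rd.reef_rhs(1e9, lit) == pytest.approx(8.0, abs=1e-6)


def test_rhs_literal_floor_and_rejection():
    lit = rd.ReefModelParams(a=0.0, b=0.0, D=10.0, mode="literal", eps=1.0)
    assert rd.reef_rhs(0.5, lit) == pytest.approx(-10.0)  # floored at eps
    with pytest.raises(ValueError):
        rd.reef_rhs(-1.0, lit, floor=False)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        rd.ReefModelParams(D=-1.0)
    with pytest.raises(ValueError):
        rd.ReefModelParams(mode="literal", A0=0.0)
    with pytest.raises(ValueError):
        rd.ReefModelParams(mode="implicit")


def test_constant_mode_exactly_linear():
    p = rd.ReefModelParams(a=7.0, b=1.0, S=1.0, D=0.0)
    traj = rd.integrate_reef(p, t0=0.0, t1=10.0)
    assert traj.values[-1] - traj.values[0] == pytest.approx(80.0, abs=1e-9)
    # net -2.5 mm/y over 110 years
    p = rd.ReefModelParams(a=7.0, D=10.5)
    traj = rd.integrate_reef(p, t0=1990.0, t1=2100.0)
    assert traj.values[-1] - traj.values[0] == pytest.approx(-275.0, abs=1e-8)
    assert np.allclose(np.diff(traj.values), -2.5)


def test_literal_mode_matches_closed_form():
    # a = b = 0: A dA = -cD dt  =>  A(t) = sqrt(A0^2 - 2 c D t)
    p = rd.ReefModelParams(a=0.0, b=0.0, D=2.0, A0=5.0, mode="literal", eps=1e-6)
    traj = rd.integrate_reef(p, t0=0.0, t1=5.0, step=0.01)
    expected = np.sqrt(25.0 - 4.0 * traj.years)
    assert np.allclose(traj.values, expected, rtol=1e-7)


def test_literal_mode_rk4_fourth_order_convergence():
    p = rd.ReefModelParams(a=0.0, b=0.0, D=2.0, A0=5.0, mode="literal", eps=1e-6)
    exact = np.sqrt(25.0 - 4.0 * 5.0)
    errors = []
    for h in (1.0, 0.5, 0.25):
        traj = rd.integrate_reef(p, t0=0.0, t1=5.0, step=h)
        errors.append(abs(traj.values[-1] - exact))
    r1 = errors[0] / errors[1]
    r2 = errors[1] / errors[2]
    assert 10.0 < r1 < 26.0
    assert 10.0 < r2 < 26.0


def test_framework_exhaustion_flagged_not_fatal():
    p = rd.ReefModelParams(a=0.0, b=0.0, D=5.0, A0=3.0, mode="literal")
    traj = rd.integrate_reef(p, t0=0.0, t1=10.0, step=0.1)
    assert traj.metadata["framework_exhausted"]


def test_keep_up_trivial_outcomes():
    years = np.arange(1990.0, 2101.0)
    growing = rd.Trajectory(years, 8.0 * (years - 1990.0), "reef_elevation_mm")
    flat_sea = rd.Trajectory(years, np.zeros_like(years), "sea_level_mm")
    rep = rd.keep_up_report(growing, flat_sea)
    assert rep.keeps_up and rep.rate_crossover_year is None and rep.submergence_year is None

    stalled = rd.Trajectory(years, np.full_like(years, 100.0), "reef_elevation_mm")
    rising = rd.parametric_sea_level(900.0, exponent=1.0)
    rep = rd.keep_up_report(stalled, rising)
    assert not rep.keeps_up
    assert rep.rate_crossover_year == 1990.0
    assert rep.submergence_year == 1991.0


def test_keep_up_disjoint_spans_rejected():
    a = rd.Trajectory([1990.0, 2000.0], [0.0, 1.0], "reef_elevation_mm")
    b = rd.Trajectory([2050.0, 2060.0], [0.0, 1.0], "sea_level_mm")
    with pytest.raises(ValueError):
        rd.keep_up_report(a, b)


def test_imperforate_high_cover_crossover_mid_century():
    """Net 8 mm/y growth vs the accelerating A1FI curve crosses over around 2044."""
    reef = rd.integrate_reef(rd.ReefModelParams(a=7.0, D=0.0))
    sea = rd.parametric_sea_level(900.0, exponent=2.0)
    rep = rd.keep_up_report(reef, sea)
    assert rep.rate_crossover_year is not None
    assert 2040.0 <= rep.rate_crossover_year <= 2060.0


def test_crossover_monotone_in_net_rate():
    sea = rd.parametric_sea_level(900.0, exponent=2.0)
    years = []
    for a in (0.75, 3.0, 7.0, 10.0):
        reef = rd.integrate_reef(rd.ReefModelParams(a=a, D=0.0))
        years.append(rd.keep_up_report(reef, sea).rate_crossover_year)
    assert all(y is not None for y in years)
    assert years == sorted(years)


def test_dominance_when_growth_exceeds_max_sea_rate():
    sea = rd.parametric_sea_level(900.0, exponent=2.0)  # max rate ~16.4 mm/y at 2100
    reef = rd.integrate_reef(rd.ReefModelParams(a=20.0, D=0.0))
    assert rd.keep_up_report(reef, sea).keeps_up


def test_scenario_matrix_default_shape_and_outcomes():
    table = rd.scenario_matrix()
    assert len(table) == 18
    assert set(table["density"]) == set(ACCRETION_COEFFICIENTS)
    assert set(table["porosity_class"]) == set(DISSOLUTION_RATES)
    perforate = table[table["porosity_class"] == "perforate"]
    assert (~perforate["keeps_up"]).all()
    assert (perforate["net_rate_mm_per_y"] < 0).all()
    # imperforate crossover comes later the denser the reef
    imp = table[(table["porosity_class"] == "imperforate") & (table["scenario"] == "A1FI")]
    by_density = imp.set_index("density")["rate_crossover_year"]
    assert by_density["low"] < by_density["medium"] < by_density["high"]


def test_perforate_reefs_decline_monotonically():
    for a in ACCRETION_COEFFICIENTS.values():
        p = rd.ReefModelParams(a=a, D=DISSOLUTION_RATES["perforate"])
        traj = rd.integrate_reef(p)
        assert (np.diff(traj.values) < 0).all()


def test_scenario_matrix_rejects_empty_configs():
    with pytest.raises(ValueError):
        rd.scenario_matrix(reef_configs={}, sea_configs={})
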