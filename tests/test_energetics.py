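"""DLW chain: isotope dilution, turnover kinetics, CO2 production, FMR,
water influx and fasting-adjusted mass change."""

import math

import numpy as np
import pytest

from sealflux.energetics import (
    MOLAR_MASS_WATER,
    L_PER_MOL_GAS,
    AttendanceRecord,
    EnergeticsConfig,
    IsotopeRecord,
    WashoutError,
    adjusted_mass_change,
    analyze_record,
    at_sea_fmr,
    co2_production,
    field_metabolic_rate,
    total_body_water,
    turnover_rates,
    water_influx,
)
from sealflux.simulate import SimulationConfig, simulate_study, simulate_washout


def make_record(**overrides):
    base = dict(
        seal_id="t", dose_o18_mass=60.0, dose_o18_enrichment=10.0, dose_h3_activity=1.0,
        background_o18=1995.0, equilib_o18=2250.0, final_o18=2050.0,
        background_h3=30.0, equilib_h3=4000.0, final_h3=1200.0,
        t_equilib=0.125, t_final=8.125, mass_initial=36.0, mass_final=40.0,
    )
    base.update(overrides)
    return IsotopeRecord(**base)


# -- total body water -------------------------------------------------------


def test_scaling_identity_with_constant_mass():
    r = make_record(mass_final=36.0)
    assert total_body_water(r, "scaling", tbw_initial=21.0) == pytest.approx(21.0)


def test_plateau_inverts_known_pool():
    # forward-compute the equilibration excess implied by TBW* = 20 kg
    tbw_star, dsf = 20.0, 1.007
    r0 = make_record()
    moles_label = r0.dose_o18_mass / MOLAR_MASS_WATER * r0.dose_o18_enrichment / 100.0
    dilution_mol = tbw_star * dsf * 1000.0 / MOLAR_MASS_WATER
    excess_ppm = moles_label / dilution_mol * 1e6
    r = make_record(equilib_o18=r0.background_o18 + excess_ppm)
    assert total_body_water(r, "plateau") == pytest.approx(tbw_star, rel=1e-6)


def test_plateau_linear_in_dose():
    r = make_record()
    double = make_record(dose_o18_mass=2 * r.dose_o18_mass)
    assert total_body_water(double) == pytest.approx(2 * total_body_water(r))


def test_plateau_rejects_non_positive_excess():
    with pytest.raises(ValueError):
        total_body_water(make_record(equilib_o18=1990.0))


# -- turnover ---------------------------------------------------------------


def test_decline_by_e_over_one_day_gives_unit_rate():
    r = make_record(
        t_equilib=0.0, t_final=1.0,
        equilib_o18=1995.0 + 100.0, final_o18=1995.0 + 100.0 / math.e,
        equilib_h3=30.0 + 50.0, final_h3=30.0 + 50.0 / math.e,
    )
    kd, ko = turnover_rates(r)
    assert kd == pytest.approx(1.0, abs=1e-12)
    assert ko == pytest.approx(1.0, abs=1e-12)


def test_forward_simulated_rates_recovered_exactly():
    ko_true, kd_true, dt = 0.35, 0.25, 6.0
    r = make_record(
        t_equilib=0.0, t_final=dt,
        equilib_o18=1995.0 + 300.0, final_o18=1995.0 + 300.0 * math.exp(-ko_true * dt),
        equilib_h3=30.0 + 5000.0, final_h3=30.0 + 5000.0 * math.exp(-kd_true * dt),
    )
    kd, ko = turnover_rates(r)
    assert kd == pytest.approx(kd_true, abs=1e-12)
    assert ko == pytest.approx(ko_true, abs=1e-12)


def test_zero_interval_rejected():
    with pytest.raises(ValueError):
        turnover_rates(make_record(t_final=0.125))


def test_washed_out_label_raises_washout_error():
    with pytest.raises(WashoutError):
        turnover_rates(make_record(final_o18=1995.0))


# -- CO2 and FMR ------------------------------------------------------------


def test_two_pool_equation_hand_value():
    # N=1000 mol, ko=0.35, kd=0.25: 1000/2.078*0.10 - 0.0062*0.25*1000 mol/d
    expect_mol = 1000.0 / 2.078 * 0.10 - 0.0062 * 0.25 * 1000.0
    assert co2_production(1000.0, 0.25, 0.35) == pytest.approx(expect_mol * L_PER_MOL_GAS)


def test_equal_rates_rejected():
    with pytest.raises(ValueError):
        co2_production(1000.0, 0.3, 0.3)


def test_fmr_unit_round_trip():
    r_co2 = 86_400.0 / 23.9  # L/day chosen so that a 1 kg animal runs at 1 kW/kg
    assert field_metabolic_rate(r_co2, 1.0) == pytest.approx(1000.0)


def test_fmr_inverse_in_mass():
    assert field_metabolic_rate(500.0, 20.0) == pytest.approx(
        2 * field_metabolic_rate(500.0, 40.0)
    )


def test_units_audit_grams_vs_kilograms():
    fmr_kg = field_metabolic_rate(400.0, 36.0)
    fmr_g = field_metabolic_rate(400.0, 36_000.0)  # per gram
    assert fmr_g * 1000.0 == pytest.approx(fmr_kg)


# -- at-sea partitioning ----------------------------------------------------


def att(release=0.0, depart=1.0, arrive=9.0, recapture=10.0, season="summer"):
    return AttendanceRecord(release, depart, arrive, recapture, season=season)


def test_no_shore_time_identity():
    a = att(release=0.0, depart=0.0, arrive=10.0, recapture=10.0)
    assert at_sea_fmr(6.0, a, onshore_mr=4.0) == pytest.approx(6.0)


def test_fixed_point_when_rates_equal():
    assert at_sea_fmr(4.0, att(), onshore_mr=4.0) == pytest.approx(4.0)


def test_hand_partitioning_example():
    # 10 d interval, 2 d ashore at 4.0, total 6.0: (60 - 8) / 8 = 6.5
    a = att(release=0.0, depart=1.0, arrive=9.0, recapture=10.0)
    assert at_sea_fmr(6.0, a, onshore_mr=4.0) == pytest.approx(6.5)


def test_at_sea_fmr_decreases_with_onshore_assumption():
    a = att()
    vals = [at_sea_fmr(6.0, a, onshore_mr=m) for m in (3.0, 4.0, 5.0)]
    assert vals[0] > vals[1] > vals[2]


# -- water influx -----------------------------------------------------------


def test_steady_state_influx_equals_efflux():
    out = water_influx(kd=0.12, tbw_initial=20.0, tbw_final=20.0, dt=8.0, mass_ref=36.0)
    assert out == pytest.approx(0.12 * 20.0 * 1000.0 / 36.0)


def test_zero_turnover_growing_pool():
    out = water_influx(kd=0.0, tbw_initial=20.0, tbw_final=22.0, dt=4.0, mass_ref=40.0)
    assert out == pytest.approx((2.0 / 4.0) * 1000.0 / 40.0)


def test_simulator_oracle_influx_recovery():
    cfg = SimulationConfig(seed=11)
    a = att(release=0.0, depart=0.7, arrive=7.7, recapture=8.5)
    rec, excluded = simulate_washout(
        true_rco2_l=300.0, true_influx_ml_kg_d=170.0, tbw_initial=21.6,
        mass_initial=36.0, mass_final=39.0, attendance=a, config=cfg,
        rng=np.random.default_rng(0),
    )
    assert not excluded
    kd, _ = turnover_rates(rec)
    tbw_i = total_body_water(rec, "plateau", dilution_space_factor=cfg.dilution_space_factor)
    tbw_f = total_body_water(rec, "scaling", tbw_initial=tbw_i)
    got = water_influx(kd, tbw_i, tbw_f, rec.dt_days, rec.mass_mean)
    assert got == pytest.approx(170.0, rel=0.01)


# -- adjusted mass change ---------------------------------------------------


def test_adjusted_mass_no_shore_time():
    got = adjusted_mass_change(36.0, 39.0, 0.0, "summer", {"summer": 0.5, "fall": 0.6})
    assert got == pytest.approx(3.0)


def test_adjusted_mass_hand_example():
    got = adjusted_mass_change(36.0, 39.0, 1.5, "fall", {"summer": 0.5, "fall": 0.8})
    assert got == pytest.approx(4.2)


def test_fixture_mean_adjusted_mass_gain(table1):
    assert table1.records["mass_change_adj"].mean() == pytest.approx(4.6, abs=0.05)


# -- end-to-end recovery ----------------------------------------------------


def test_noise_free_chain_recovers_truth_to_float_precision():
    study = simulate_study(SimulationConfig(seed=21, n_seals=60))
    cfg = study.energetics_config()
    for trip in study.trips:
        if trip.excluded:
            continue
        res = analyze_record(trip.isotope, trip.attendance, cfg)
        assert res.fmr_at_sea == pytest.approx(trip.fmr_at_sea_true, rel=1e-9)
        assert res.r_co2 == pytest.approx(trip.r_co2_true, rel=1e-9)
        assert res.water_influx == pytest.approx(trip.influx_true, rel=1e-9)
        assert res.mass_change_adj == pytest.approx(trip.gain_at_sea_true, abs=1e-9)


def test_one_percent_assay_noise_is_unbiased():
    study = simulate_study(SimulationConfig(seed=22, n_seals=100, assay_noise=0.01))
    cfg = study.energetics_config()
    rel_rco2, rel_influx = [], []
    for trip in study.trips:
        if trip.excluded:
            continue
        res = analyze_record(trip.isotope, trip.attendance, cfg)
        rel_rco2.append(res.r_co2 / trip.r_co2_true - 1.0)
        rel_influx.append(res.water_influx / trip.influx_true - 1.0)
    assert abs(np.mean(rel_rco2)) < 0.01
    assert abs(np.mean(rel_influx)) < 0.01
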