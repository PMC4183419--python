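"""Two-phase calibration: closure rules, epsilon estimation, round trips."""

import numpy as np
import pandas as pd
import pytest

from isoflux import (
    baseline_topology,
    calibrate_fractionation,
    calibrate_rates,
    calibration_report,
    find_steady_state,
)
from isoflux.calibration import (
    DEFAULT_FREE_EPSILONS,
    CalibrationError,
    measured_pools,
)
from isoflux.rat import OX_TISSUES, TI_TISSUES


@pytest.fixture(scope="module")
def rate_cal(measurements, constraints):
    return calibrate_rates(measurements, constraints)


def test_fsr_rule(rate_cal, measurements, constraints):
    """f_sT = f_dT = FSR_T * T_P, e.g. muscle at 11 %/d."""
    pools = measured_pools(measurements)
    assert constraints.fsr["Mp"] == 0.11
    assert rate_cal.fluxes["sM"] == pytest.approx(0.11 * pools["Mp"], rel=1e-12)
    for t in OX_TISSUES:
        if t == "Sk":
            continue  # skin degradation nets out the desquamation loss
        assert rate_cal.fluxes[f"d{t}"] == rate_cal.fluxes[f"s{t}"]


def test_transport_index_rule(rate_cal, constraints):
    """f_inT = TI * f_sT; TI is 1.5 everywhere but 0.8 in skin."""
    for t in TI_TISSUES:
        expected = 0.8 if t == "Sk" else 1.5
        assert constraints.ti[t] == expected
        assert rate_cal.fluxes[f"in{t}"] == pytest.approx(
            expected * rate_cal.fluxes[f"s{t}"], rel=1e-12
        )


def test_oxidation_closure(rate_cal, constraints):
    """Uniform %ox sized so total urea production equals intake (~29%)."""
    f_up = sum(rate_cal.fluxes[f"ox{t}"] for t in OX_TISSUES)
    assert f_up == pytest.approx(constraints.intake, rel=1e-12)
    assert rate_cal.pct_ox == pytest.approx(
        constraints.intake
        / (constraints.intake
           + sum(rate_cal.fluxes[f"s{t}"] for t in OX_TISSUES)
           + rate_cal.fluxes["sPl"]),
        rel=1e-12,
    )
    assert rate_cal.pct_ox == pytest.approx(0.29, abs=0.005)


def test_rules_do_not_depend_on_residual_resolution(rate_cal, measurements,
                                                    constraints):
    """Fluxes pinned directly by FSR/TI rules equal their formulas no matter
    how the remaining balance equations were closed."""
    pools = measured_pools(measurements)
    for pool, fsr in constraints.fsr.items():
        fid = {"SIp": "sSI", "Lp": "sL", "Plp": "sPl", "Mp": "sM", "Kp": "sK",
               "Hp": "sH", "Rp": "sR", "Skp": "sSk"}[pool]
        assert rate_cal.fluxes[fid] == pytest.approx(fsr * pools[pool], rel=1e-12)


def test_measured_pools_are_exact_steady_state(rate_cal, measurements):
    pools = measured_pools(measurements)
    ss = find_steady_state(rate_cal.topology)
    target = np.array([pools[c] for c in rate_cal.topology.ids])
    assert np.max(np.abs(ss.N - target)) < 1e-9


def test_infeasible_closure_raises(measurements, constraints):
    from dataclasses import replace
    # with almost no proximal absorption the portal flux must go negative
    bad = replace(constraints, ileal_digestibility=0.2)
    with pytest.raises(CalibrationError, match="negative"):
        calibrate_rates(measurements, bad)


def test_epsilon_estimation_recovers_shipped_model(rate_cal, measurements):
    """Calibrating on the shipped fixture reproduces the shipped epsilons."""
    shipped = baseline_topology()
    eps = calibrate_fractionation(measurements, rate_cal.topology)
    for fid, truth in shipped.epsilons().items():
        assert eps.values[fid] == pytest.approx(truth, abs=1e-9), fid
    assert eps.residuals.abs().max() < 1e-9
    # rates too: the full shipped config is the two-phase calibration output
    for fid, truth in shipped.rates().items():
        assert rate_cal.topology.flux(fid).k == pytest.approx(truth, rel=1e-9)


def test_degradation_and_transport_epsilons_pinned_at_zero(rate_cal,
                                                           measurements):
    eps = calibrate_fractionation(measurements, rate_cal.topology)
    for t in OX_TISSUES:
        assert eps.values[f"d{t}"] == 0.0
    for t in TI_TISSUES:
        assert eps.values[f"in{t}"] == 0.0
        assert eps.values[f"out{t}"] == 0.0
    assert set(eps.free) == set(DEFAULT_FREE_EPSILONS)


def test_muscle_synthesis_epsilon_is_p_minus_aa_difference(rate_cal,
                                                           measurements):
    """eps_sM equals the muscle protein-minus-AA Delta15N difference (4.8)."""
    eps = calibrate_fractionation(measurements, rate_cal.topology)
    m = measurements.set_index("compartment")["Delta15N_permil"]
    assert eps.values["sM"] == pytest.approx(m["Mp"] - m["Ma"], abs=1e-9)
    assert eps.values["sM"] == pytest.approx(4.8, abs=1e-9)
    assert eps.values["sH"] == pytest.approx(4.1, abs=1e-9)
    assert eps.values["sK"] == pytest.approx(0.6, abs=1e-9)


def test_oxidation_epsilons_negative_except_muscle(rate_cal, measurements):
    eps = calibrate_fractionation(measurements, rate_cal.topology)
    for t in OX_TISSUES:
        if t == "M":
            assert eps.values["oxM"] > 0
        else:
            assert eps.values[f"ox{t}"] < 0, t


def test_rank_deficiency_reported(rate_cal, measurements):
    """Freeing degradation alongside synthesis creates an exact null
    direction (eps_s and eps_d shift together); it must be reported."""
    free = tuple(DEFAULT_FREE_EPSILONS) + ("dM",)
    with pytest.raises(CalibrationError, match="unidentifiable"):
        calibrate_fractionation(measurements, rate_cal.topology, free=free)


def test_calibration_report_on_baseline(rate_cal, measurements):
    shipped = baseline_topology()
    rep = calibration_report(shipped, measurements, pct_ox=rate_cal.pct_ox)
    assert np.nanmax(np.abs(rep.residuals["delta_residual"])) < 0.1
    assert np.nanmax(np.abs(rep.residuals["N_residual"])) < 1e-6
    assert rep.flags["urea_production_equals_intake"]
    assert rep.flags["delta_residuals_within_noise"]
    assert 0.0 <= rep.indices.recycling_efficiency <= 1.0
    assert "M" in rep.indices.p
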