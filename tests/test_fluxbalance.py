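"""Flux-balance solver, turnover/dilution arithmetic and protocol unit conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hepaflux as hf
from conftest import WORKED_FLUXES, random_feasible_params


class TestDilution:
    def test_reference_value(self):
        assert hf.compute_dilution(0.033, 1.0) == pytest.approx(0.033)

    def test_undiluted_pool(self):
        assert hf.compute_dilution(0.99, 0.99) == pytest.approx(1.0)

    def test_purity_normalization(self):
        assert hf.compute_dilution(0.0495, 0.99) == pytest.approx(0.05)

    def test_zero_excess_indeterminate(self):
        with pytest.raises(hf.IndeterminateError):
            hf.compute_dilution(0.0)

    def test_excess_above_purity_rejected(self):
        with pytest.raises(hf.DomainError):
            hf.compute_dilution(0.995, 0.99)


class TestExchange:
    def test_reference_ratio(self):
        c_glc, _ = hf.compute_exchange(0.0071, 0.033, 0.01, 0.05)
        assert c_glc == pytest.approx(0.0071 / 0.033)
        assert c_glc == pytest.approx(0.215, abs=0.001)

    def test_full_exchange(self):
        c_glc, c_udpglc = hf.compute_exchange(0.03, 0.03, 0.04, 0.04)
        assert c_glc == 1.0 and c_udpglc == 1.0

    def test_zero_numerators(self):
        c_glc, c_udpglc = hf.compute_exchange(0.0, 0.03, 0.0, 0.04)
        assert c_glc == 0.0 and c_udpglc == 0.0

    def test_denominator_floor(self):
        with pytest.raises(hf.IndeterminateError):
            hf.compute_exchange(0.0071, 0.0, 0.01, 0.05)


class TestTurnoverAndClearance:
    def test_arithmetic(self):
        total, endogenous = hf.compute_turnover(2.0, 0.05)
        assert total == pytest.approx(40.0)
        assert endogenous == pytest.approx(38.0)

    def test_pure_tracer_pool(self):
        total, endogenous = hf.compute_turnover(2.0, 1.0)
        assert total == pytest.approx(2.0) and endogenous == pytest.approx(0.0)

    def test_invalid_dilution(self):
        with pytest.raises(hf.DomainError):
            hf.compute_turnover(2.0, 0.0)

    def test_clearance(self):
        assert hf.compute_clearance(40.0, 8.0) == pytest.approx(5.0)
        assert hf.compute_clearance(0.0, 8.0) == 0.0
        with pytest.raises(hf.DomainError):
            hf.compute_clearance(40.0, 0.0)

    def test_m3m6(self):
        assert hf.m3m6_ratio(0.01, 0.04) == pytest.approx(0.25)
        assert hf.m3m6_ratio(0.0, 0.04) == 0.0
        with pytest.raises(hf.IndeterminateError):
            hf.m3m6_ratio(0.01, 0.0)


class TestProtocolUnits:
    def test_default_glucose_tracer_rate(self):
        # independent hand conversion: 2.5 mg/mL x 0.5 mL/h = 1.25 mg/h;
        # / 186.11 g/mol = 6.7164 umol/h; / 60 min / 0.022 kg
        proto = hf.DEFAULT_PROTOCOL
        by_hand = (2.5 * 0.5) / 186.11 * 1000.0 / 60.0 / 0.022
        assert proto.I6 == pytest.approx(by_hand, rel=1e-12)
        assert 5.0 < proto.I6 < 5.2  # the ~5.1 umol/kg/min of the study protocol

    def test_turnover_at_reference_dilution(self):
        ra, _ = hf.compute_turnover(hf.DEFAULT_PROTOCOL.I6, 0.033)
        assert 150.0 < ra < 157.0

    def test_from_rates_exact(self):
        proto = hf.InfusionProtocol.from_rates(3.7, 11.1)
        assert proto.I6 == pytest.approx(3.7, rel=1e-12)
        assert proto.Igal == pytest.approx(11.1, rel=1e-12)

    def test_positive_validation(self):
        with pytest.raises(hf.DomainError):
            hf.InfusionProtocol(body_weight_g=0.0)


class TestSolveFluxes:
    def test_worked_example(self, worked_params, unit_protocol):
        fs = hf.solve_fluxes(worked_params, unit_protocol)
        for name, expected in WORKED_FLUXES.items():
            assert getattr(fs, name) == pytest.approx(expected, abs=1e-9), name

    def test_no_exchange_no_gng_boundary(self, unit_protocol):
        params = hf.PrimaryIsotopeParams(
            d_glc=0.0625, d_udpglc=1 / 31, c_glc=0.0,
            c_udpglc=0.0, f_glc=0.0, f_udpglc=0.0,
        )
        fs = hf.solve_fluxes(params, unit_protocol)
        assert fs.gck == 0.0 and fs.gng_g6p == 0.0
        assert fs.gp == pytest.approx(fs.g6pase + fs.gs)

    def test_zero_phosphorylase_boundary(self, unit_protocol):
        params = hf.PrimaryIsotopeParams(
            d_glc=0.0625, d_udpglc=1 / 31, c_glc=0.4,
            c_udpglc=0.1, f_glc=0.5, f_udpglc=0.6,
        )
        fs = hf.solve_fluxes(params, unit_protocol)
        assert fs.gp == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_parameters_reported_not_clipped(self, unit_protocol):
        params = hf.PrimaryIsotopeParams(
            d_glc=0.0625, d_udpglc=1 / 31, c_glc=0.5,
            c_udpglc=0.1, f_glc=0.5, f_udpglc=0.6,
        )
        with pytest.raises(hf.InfeasibleParametersError) as err:
            hf.solve_fluxes(params, unit_protocol)
        assert err.value.value < 0.0

    def test_unknown_closure(self, worked_params, unit_protocol):
        with pytest.raises(hf.ConfigurationError):
            hf.solve_fluxes(worked_params, unit_protocol, closure="no-such-closure")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, derandomize=True)
    def test_balance_identity_always_holds(self, seed):
        rng = np.random.default_rng(seed)
        params = random_feasible_params(rng)
        fs = hf.solve_fluxes(params, hf.InfusionProtocol.from_rates(2.5, 1.0))
        scale = max(1.0, fs.g6pase + fs.gs)
        assert abs(fs.balance_residual) < 1e-9 * scale
        for name in ("ra", "ru", "gck", "g6pase", "gs", "gp", "gng_g6p"):
            assert getattr(fs, name) >= 0.0
        assert fs.ra >= 2.5 - 1e-12  # total appearance includes the infusion

    def test_monotonicity(self, unit_protocol):
        def fluxes(**overrides):
            base = dict(d_glc=0.05, d_udpglc=0.1, c_glc=0.2,
                        c_udpglc=0.1, f_glc=0.5, f_udpglc=0.4)
            base.update(overrides)
            return hf.solve_fluxes(hf.PrimaryIsotopeParams(**base), unit_protocol)

        # Ra strictly decreases with d_glc
        assert fluxes(d_glc=0.04).ra > fluxes(d_glc=0.05).ra > fluxes(d_glc=0.06).ra
        # GS strictly increases with 1/d_udpglc
        assert fluxes(d_udpglc=0.05).gs > fluxes(d_udpglc=0.1).gs
        # GCK share strictly increases with c_glc at fixed total G6P turnover:
        # compare via the gck / (g6pase + gs) ratio
        low, high = fluxes(c_glc=0.1), fluxes(c_glc=0.3)
        assert high.gck / (high.g6pase + high.gs) > low.gck / (low.g6pase + low.gs)

    def test_clearance_and_m3m6_passthrough(self, worked_params, unit_protocol):
        fs = hf.solve_fluxes(worked_params, unit_protocol,
                             blood_glucose_mM=8.0, excess_m3m6=(0.25, 0.1))
        assert fs.clearance == pytest.approx(40.0 / 8.0)
        assert fs.m3m6_glc == 0.25 and fs.m3m6_udpglc == 0.1


class TestFluxSetValidation:
    def test_balance_violation_rejected(self):
        with pytest.raises(hf.DomainError):
            hf.FluxSet(ra=40, ru=31, egp=37.5, gck=25, g6pase=50, gs=30,
                       gp=20, gng_g6p=40, gng_blood=30,
                       glucose_balance=25, glycogen_balance=10)

    def test_negative_flux_rejected(self):
        with pytest.raises(hf.DomainError):
            hf.FluxSet(ra=40, ru=31, egp=37.5, gck=-5, g6pase=50, gs=30,
                       gp=45, gng_g6p=40, gng_blood=30,
                       glucose_balance=55, glycogen_balance=-15)
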