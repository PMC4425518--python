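import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonet.channels import (
    CHOSEN_MULTIPLIERS,
    DensityConfig,
    GHKConstants,
    RateParams,
    channel_registry,
    gate_steady_state,
    gate_time_constant,
    ghk_current,
    multiplier_table,
    ohmic_current,
    rate,
    realise_densities,
)
from axonet.morphology import ConfigurationError, build_din_morphology, compartmentalise


@pytest.fixture(scope="module")
def reg():
    return channel_registry()


def _gate(reg, kind, name):
    return next(g for g in reg[kind].gates if g.name == name)


class TestRateFunctions:
    def test_sodium_alpha_m_at_symmetric_point(self, reg):
        # at V = 1.01 mV the exponent vanishes: alpha = 8.67 / (1 + 1)
        g = _gate(reg, "na", "m_na")
        assert g.alpha_rate(1.01) == pytest.approx(8.67 / 2.0, rel=1e-12)

    def test_fast_potassium_beta_at_symmetric_point(self, reg):
        # C = 0 for Kf beta: at V = -28.7, beta = 0.505 / e^0
        g = _gate(reg, "kf", "n_kf")
        assert g.beta_rate(-28.7) == pytest.approx(0.505, rel=1e-12)

    def test_calcium_beta_branches_agree_at_split(self, reg):
        g = _gate(reg, "ca", "m_ca")
        low = rate(g.beta, -25.0)
        high = rate(g.beta_high, -25.0)
        assert abs(low - high) / high < 0.03

    def test_vanishing_denominator_raises(self):
        from axonet.channels import NumericalDomainError

        p = RateParams(A=1.0, B=0.0, C=-1.0, D=0.0, E=10.0)
        with pytest.raises(NumericalDomainError):
            rate(p, 0.0)  # C + exp(0) = 0

    def test_zero_E_rejected(self):
        with pytest.raises(ConfigurationError):
            RateParams(A=1.0, B=0.0, C=1.0, D=0.0, E=0.0)

    @settings(deadline=None, max_examples=200)
    @given(v=st.floats(min_value=-100.0, max_value=60.0))
    def test_rates_nonnegative_over_working_range(self, reg, v):
        for kind, spec in reg.items():
            for gate in spec.gates:
                assert gate.alpha_rate(v) >= 0.0
                assert gate.beta_rate(v) >= 0.0


class TestGates:
    @settings(deadline=None, max_examples=100)
    @given(v=st.floats(min_value=-100.0, max_value=60.0))
    def test_steady_state_in_unit_interval(self, reg, v):
        for kind, spec in reg.items():
            for gate in spec.gates:
                x = gate_steady_state(gate, v)
                assert 0.0 <= x <= 1.0

    def test_sodium_activation_monotone_increasing(self, reg):
        g = _gate(reg, "na", "m_na")
        vv = np.linspace(-80.0, 0.0, 400)
        minf = gate_steady_state(g, vv)
        assert np.all(np.diff(minf) > 0)

    def test_time_constant_consistency(self, reg):
        # X_inf / tau = alpha by construction
        g = _gate(reg, "na", "h_na")
        v = -60.0
        xinf = gate_steady_state(g, v)
        tau = gate_time_constant(g, v)
        assert xinf / tau == pytest.approx(g.alpha_rate(v), rel=1e-12)
        assert tau == pytest.approx(1.0 / (g.alpha_rate(v) + g.beta_rate(v)))
        assert tau > 0


class TestOhmicCurrent:
    def test_zero_at_reversal(self, reg):
        spec = reg["na"]
        assert ohmic_current(spec, spec.reversal_potential, (0.7, 0.4)) == 0.0

    def test_zero_when_gate_closed(self, reg):
        assert ohmic_current(reg["na"], -20.0, (0.0, 0.9)) == 0.0

    def test_linear_in_density(self, reg):
        from dataclasses import replace

        spec = reg["kf"]
        doubled = replace(spec, base_density=2 * spec.base_density)
        v = -30.0
        assert ohmic_current(doubled, v, (0.5,)) == pytest.approx(
            2 * ohmic_current(spec, v, (0.5,))
        )

    def test_sign_convention_depolarising_below_reversal(self, reg):
        # sodium current is positive (depolarising) below its reversal
        assert ohmic_current(reg["na"], -52.0, (0.5, 0.5)) > 0


class TestGHK:
    def test_zero_voltage_limit_matches_lhopital(self):
        k = GHKConstants()
        # limit: P * 2F * ([Ca]_o - [Ca]_i) (mol/cm^3), in uA/cm^2
        expected = 0.016 * 2 * k.F * (k.ca_external - k.ca_internal) * 1e-3 * 1e6
        assert ghk_current(0.016, 1.0, 0.0, k) == pytest.approx(expected, rel=1e-9)

    def test_continuous_at_zero(self):
        k = GHKConstants()
        at0 = ghk_current(0.016, 1.0, 0.0, k)
        left = ghk_current(0.016, 1.0, -1e-7, k)
        right = ghk_current(0.016, 1.0, 1e-7, k)
        assert abs(left - at0) / abs(at0) < 1e-6
        assert abs(right - at0) / abs(at0) < 1e-6

    def test_removable_singularity_guard(self):
        # tiny offsets around the singular point agree with a nearby
        # well-conditioned evaluation to first order
        k = GHKConstants()
        v = np.array([-1e-12, 0.0, 1e-12])
        vals = ghk_current(0.016, 0.5, v, k)
        assert np.allclose(vals, vals[1], rtol=1e-9)

    def test_closed_gate_gives_zero(self):
        assert ghk_current(0.016, 0.0, -20.0) == 0.0

    def test_depolarising_with_outward_gradient(self):
        # with [Ca]_o >> [Ca]_i the current is inward (positive) at
        # physiological potentials
        for v in (-80.0, -52.0, -20.0, 0.0, 20.0):
            assert ghk_current(0.016, 1.0, v) > 0


@pytest.fixture(scope="module")
def comps():
    return compartmentalise(build_din_morphology())


class TestDensities:
    def test_noise_free_densities_match_base_values(self, reg, comps):
        cfg = DensityConfig(noise_sd=0.0)
        d1 = realise_densities(reg, cfg, comps, np.random.default_rng(1))
        d2 = realise_densities(reg, cfg, comps, np.random.default_rng(999))
        for kind in ("lk", "na", "kf", "ks"):
            assert np.allclose(d1[kind], reg[kind].base_density)
            assert np.array_equal(d1[kind], d2[kind])  # seed-independent
        assert np.allclose(d1["ca"], reg["ca"].permeability)

    def test_chosen_multiplier_scales_sodium(self, reg, comps):
        cfg = DensityConfig(multipliers={"na": 3.0}, noise_sd=0.0)
        d = realise_densities(reg, cfg, comps, np.random.default_rng(0))
        assert np.allclose(d["na"], 30.0)

    def test_regional_override_scales_initial_segment(self, reg, comps):
        cfg = DensityConfig(
            noise_sd=0.0, regional_overrides=((20.0, 70.0, "na", 5.0),)
        )
        d = realise_densities(reg, cfg, comps, np.random.default_rng(0))
        arc = np.array([c.arc_distance_from_soma for c in comps])
        inside = (arc >= 20.0) & (arc < 70.0)
        assert np.allclose(d["na"][inside], 50.0)
        assert np.allclose(d["na"][~inside], 10.0)

    def test_one_noise_draw_per_neuron(self, reg):
        comps = []
        for nid in range(3):
            comps.extend(
                compartmentalise(build_din_morphology(), neuron_id=nid,
                                 soma_position=10.0 * nid)
            )
        cfg = DensityConfig(noise_sd=0.05)
        d = realise_densities(reg, cfg, comps, np.random.default_rng(5))
        ids = np.array([c.neuron_id for c in comps])
        for nid in range(3):
            vals = d["na"][ids == nid]
            assert np.allclose(vals, vals[0])
        assert len(np.unique(np.round(d["na"], 12))) == 3

    def test_override_outside_cable_rejected(self, reg, comps):
        cfg = DensityConfig(regional_overrides=((0.0, 5000.0, "na", 2.0),))
        with pytest.raises(ConfigurationError):
            realise_densities(reg, cfg, comps, np.random.default_rng(0))

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ConfigurationError):
            DensityConfig(multipliers={"na": -1.0})


def test_multiplier_table_matches_chosen_values():
    table = multiplier_table()
    for kind, chosen in CHOSEN_MULTIPLIERS.items():
        assert table[kind]["chosen"] == chosen
        assert chosen in table[kind]["tested"]
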