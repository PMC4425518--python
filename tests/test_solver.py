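import numpy as np
import pytest

from axonet.channels import DensityConfig, realise_densities
from axonet.fixtures import single_cable, three_chain, two_neuron_one_junction
from axonet.morphology import build_din_morphology, build_population
from axonet.network import LayoutScheme, NetworkModel, generate_density_layout
from axonet.presets import default_population
from axonet.solver import (
    StimulusProtocol,
    assemble,
    axial_conductance_nS,
    detect_spikes,
    integrate,
    steady_state_solve,
)


class TestAssembly:
    def test_axial_conductance_closed_form(self):
        # two 5 um x 0.4 um compartments at R_i = 80 Ohm cm:
        # R = 2 * R_i * (l/2) / (pi d^2 / 4)  ->  31.4 nS
        g = axial_conductance_nS(5.0, 0.4, 5.0, 0.4, 80.0)
        area_cm2 = np.pi * (0.4e-4) ** 2 / 4
        r_hand = 2 * 80.0 * 2.5e-4 / area_cm2
        assert g == pytest.approx(1e9 / r_hand, rel=1e-12)

    def test_junction_conductance_in_matrix(self):
        model = two_neuron_one_junction(resistance=600.0)
        system = assemble(model)
        assert len(system.gj_g) == 1
        assert system.gj_g[0] == pytest.approx(1.667, abs=1e-3)

    def test_no_junctions_block_diagonal(self):
        model = three_chain().without_junctions()
        system = assemble(model)
        G = system.conductance_matrix().toarray()
        n = system.n_compartments // 3
        assert np.all(G[:n, n:] == 0)
        assert np.all(G[n : 2 * n, 2 * n :] == 0)

    def test_conductance_matrix_conventions(self):
        model = two_neuron_one_junction()
        system = assemble(model)
        G = system.conductance_matrix().toarray()
        assert np.allclose(G, G.T)
        off = G - np.diag(np.diag(G))
        assert np.all(off <= 1e-12)
        # row sums equal the leak conductance of each compartment
        assert np.allclose(G.sum(axis=1), system.leak_nS)

    def test_junction_outside_axon_raises(self):
        from axonet.morphology import ConfigurationError
        from axonet.network import GapJunction

        pop = build_population(2, 10.0, build_din_morphology(axon_length=100.0))
        gj = GapJunction(1, 0, 105.0, 115.0, 600.0)
        with pytest.raises(ConfigurationError):
            NetworkModel(pop, (gj,))


class TestSteadyState:
    def test_zero_current_zero_deflection(self):
        system = assemble(two_neuron_one_junction())
        dv = steady_state_solve(system, np.zeros(system.n_compartments))
        assert np.allclose(dv, 0.0)

    def test_linearity(self):
        system = assemble(two_neuron_one_junction())
        I = np.zeros(system.n_compartments)
        I[system.soma_index[0]] = -100.0
        dv1 = steady_state_solve(system, I)
        dv2 = steady_state_solve(system, 2 * I)
        assert np.allclose(dv2, 2 * dv1, rtol=1e-10)

    def test_charge_balance(self):
        # at steady state the injected current equals the total leak current
        system = assemble(three_chain())
        I = np.zeros(system.n_compartments)
        I[system.soma_index[1]] = -100.0
        dv = steady_state_solve(system, I)
        assert np.sum(system.leak_nS * dv) == pytest.approx(-100.0, rel=1e-9)

    def test_reciprocity_against_dense_oracle(self):
        """Transfer resistance is symmetric in any passive resistive
        network; checked against a dense inverse on random small columns."""
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 6))
            pop = default_population(n=n)
            gjs = generate_density_layout(pop, LayoutScheme(), rng)
            model = NetworkModel(pop, tuple(gjs), DensityConfig(lk_density=0.25))
            system = assemble(model)
            G = system.conductance_matrix().toarray()
            R = np.linalg.inv(G)
            si = system.soma_index
            T = R[np.ix_(si, si)]
            assert np.allclose(T, T.T, atol=1e-12)
            # sparse solve agrees with the dense oracle
            I = np.zeros(system.n_compartments)
            I[si[0]] = -100.0
            assert np.allclose(steady_state_solve(system, I), R @ I, atol=1e-9)

    def test_space_constant_matches_cable_theory(self):
        """Voltage decay along a long passive axon has
        lambda = sqrt(R_m d / (4 R_i)) within 2 %."""
        for g_lk, ri in ((0.25, 80.0), (0.125, 80.0)):
            model = single_cable(axon_length=3000.0, g_lk=g_lk)
            system = assemble(model, ri=ri)
            I = np.zeros(system.n_compartments)
            I[0] = -100.0
            dv = steady_state_solve(system, I)
            mask = (system.arc >= 100) & (system.arc <= 350)
            lam = -1.0 / np.polyfit(system.arc[mask], np.log(-dv[mask]), 1)[0]
            lam_theory = np.sqrt((1.0 / (g_lk * 1e-3)) * 0.4e-4 / (4 * ri)) * 1e4
            assert abs(lam - lam_theory) / lam_theory < 0.02

    def test_discretisation_refinement_stability(self):
        """Halving every bin size changes the somatic input resistance by
        < 1 %."""
        from axonet.morphology import DiscretisationRules

        model = single_cable(axon_length=1500.0)
        coarse = assemble(model, rules=DiscretisationRules())
        fine = assemble(
            model,
            rules=DiscretisationRules(
                hillock_step=2.5, axon_proximal_step=2.5, axon_distal_step=50.0
            ),
        )
        out = []
        for system in (coarse, fine):
            I = np.zeros(system.n_compartments)
            I[0] = -100.0
            out.append(steady_state_solve(system, I)[0])
        assert abs(out[1] - out[0]) / abs(out[0]) < 0.01


class TestIntegration:
    def test_passive_rest_is_equilibrium(self):
        system = assemble(two_neuron_one_junction())
        res = integrate(system, None, None, dt=0.1, t_stop=20.0)
        assert np.allclose(res.traces, -52.0, atol=1e-9)

    def test_steady_state_equals_long_time_dynamics(self):
        """The exact linear solve is the long-time limit of the passive
        dynamic response (compared at 10 membrane time constants)."""
        system = assemble(two_neuron_one_junction())
        I = np.zeros(system.n_compartments)
        I[system.soma_index[0]] = -100.0
        dv = steady_state_solve(system, I)
        # tau_m = R_m C_m = 4000 Ohm cm^2 * 1 uF/cm^2 = 4 ms -> run 15 tau
        res = integrate(
            system, None, StimulusProtocol.step(0, -100.0, 0.0, 100.0),
            dt=0.05, t_stop=60.0, probes=[(0, 0.0), (1, 0.0)],
        )
        for k, nid in enumerate((0, 1)):
            expected = -52.0 + dv[system.soma_index[nid]]
            assert res.traces[k, -1] == pytest.approx(expected, rel=5e-3)

    def test_backends_agree(self):
        """The compiled kernel (table-interpolated rates) reproduces the
        reference numpy loop (exact rates) on an active coupled pair."""
        model = two_neuron_one_junction()
        system = assemble(model)
        cfg = DensityConfig(multipliers={"na": 3.0}, noise_sd=0.0, lk_density=0.125)
        from axonet.channels import channel_registry

        dens = realise_densities(channel_registry(), cfg, system.compartments)
        prot = StimulusProtocol.step(0, 150.0, 5.0, 40.0)
        kw = dict(dt=0.01, t_stop=60.0, probes=[(0, 0.0), (1, 0.0)])
        r_nb = integrate(system, dens, prot, backend="numba", **kw)
        r_np = integrate(system, dens, prot, backend="numpy", **kw)
        assert np.abs(r_nb.traces - r_np.traces).max() < 0.05
        for k in (0, 1):
            s1, s2 = r_nb.spikes(k), r_np.spikes(k)
            assert len(s1) == len(s2)
            if len(s1):
                assert np.abs(s1 - s2).max() < 0.05

    def test_semi_implicit_junctions_converge_to_full_implicit(self):
        """The lagged-junction splitting agrees with the exact implicit
        solve as dt shrinks (same first-order limit)."""
        model = two_neuron_one_junction()
        system = assemble(model)
        cfg = DensityConfig(multipliers={"na": 3.0}, noise_sd=0.0, lk_density=0.125)
        from axonet.channels import channel_registry

        dens = realise_densities(channel_registry(), cfg, system.compartments)
        prot = StimulusProtocol.step(0, 150.0, 5.0, 40.0)
        kw = dict(dt=0.005, t_stop=50.0, probes=[(0, 0.0), (0, 200.0)])
        r_full = integrate(system, dens, prot, gj_mode="implicit", **kw)
        r_semi = integrate(system, dens, prot, gj_mode="semi", **kw)
        for probe in ((0, 0.0), (0, 200.0)):
            s1, s2 = r_full.spikes(*probe), r_semi.spikes(*probe)
            assert len(s1) == len(s2) and len(s1) >= 1
            assert np.abs(s1 - s2).max() < 0.02

    def test_spike_time_self_convergence(self):
        """Halving dt moves the somatic spike time by < 0.05 ms."""
        model = single_cable(axon_length=1500.0, g_lk=0.125)
        system = assemble(model)
        cfg = DensityConfig(multipliers={"na": 3.0}, noise_sd=0.0, lk_density=0.125)
        from axonet.channels import channel_registry

        dens = realise_densities(channel_registry(), cfg, system.compartments)
        prot = StimulusProtocol.step(0, 200.0, 5.0, 50.0)
        times = []
        for dt in (0.02, 0.01, 0.005):
            res = integrate(system, dens, prot, dt=dt, t_stop=40.0, probes=[(0, 0.0)])
            sp = res.spikes(0)
            assert len(sp) >= 1
            times.append(sp[0])
        assert abs(times[1] - times[2]) < 0.05

    def test_gates_remain_in_unit_interval(self):
        """Gate variables stay in [0, 1] along a spiking trajectory (the
        relaxation update cannot overshoot its target)."""
        from axonet.channels import channel_registry, gate_steady_state

        model = single_cable(axon_length=400.0)
        system = assemble(model)
        reg = channel_registry()
        cfg = DensityConfig(multipliers={"na": 3.0}, noise_sd=0.0, lk_density=0.125)
        dens = realise_densities(reg, cfg, system.compartments)
        res = integrate(
            system, dens, StimulusProtocol.step(0, 300.0, 5.0, 80.0),
            dt=0.02, t_stop=100.0, probes=[(0, 0.0)], backend="numpy",
        )
        v = res.traces[0]
        # replay the exact gate update along the recorded trajectory
        for kind in ("na", "kf", "ks", "ca"):
            for gate in reg[kind].gates:
                x = float(gate_steady_state(gate, v[0]))
                for vv in v:
                    a = gate.alpha_rate(vv)
                    b = gate.beta_rate(vv)
                    xinf = a / (a + b)
                    x = xinf + (x - xinf) * np.exp(-0.02 * (a + b))
                    assert 0.0 <= x <= 1.0


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 100, 0.1)
        assert len(detect_spikes(t, np.full_like(t, -52.0))) == 0

    def test_refractory_merges_double_crossing(self):
        t = np.arange(0, 10, 0.1)
        v = np.full_like(t, -52.0)
        v[(t > 2) & (t < 2.4)] = 20.0
        v[(t > 2.8) & (t < 3.2)] = 20.0  # second crossing within 3 ms
        assert len(detect_spikes(t, v, refractory=3.0)) == 1

    def test_counts_constructed_train(self):
        t = np.arange(0, 200, 0.1)
        v = np.full_like(t, -52.0)
        for t0 in (10, 50, 90, 130, 170):
            v[(t > t0) & (t < t0 + 1.0)] = 30.0
        sp = detect_spikes(t, v)
        assert len(sp) == 5
        assert np.allclose(sp, [10, 50, 90, 130, 170], atol=0.2)


def test_result_to_frame_columns():
    system = assemble(two_neuron_one_junction())
    res = integrate(system, None, None, dt=0.1, t_stop=5.0,
                    probes=[(0, 0.0), (1, 200.0)])
    frame = res.to_frame()
    assert list(frame.columns) == ["t_ms", "n0_arc0", "n1_arc200"]
    assert len(frame) == len(res.t)
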