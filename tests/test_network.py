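import numpy as np
import pytest

from axonet.morphology import ConfigurationError
from axonet.network import (
    GapJunction,
    LayoutScheme,
    NetworkModel,
    classify_pairs,
    coupling_graph,
    generate_density_layout,
    generate_fixed_point_layout,
    gj_subsample,
)
from axonet.presets import default_population


@pytest.fixture(scope="module")
def pop():
    return default_population()


class TestDensityLayout:
    def test_network_scale_statistics(self, pop):
        """Junction count, per-axon contacts and direct-pair fraction of
        the 30-neuron column under the chosen scheme."""
        counts, per_axon, direct = [], [], []
        for seed in range(50):
            gjs = generate_density_layout(pop, LayoutScheme(), np.random.default_rng(seed))
            counts.append(len(gjs))
            contacts = np.zeros(30)
            for gj in gjs:
                contacts[gj.caudal_neuron_id] += 1
                contacts[gj.rostral_neuron_id] += 1
            per_axon.append(contacts.mean())
            model = NetworkModel(pop, tuple(gjs))
            direct.append(
                np.mean([v == 1 for v in classify_pairs(model).values()])
            )
        assert 80 <= np.mean(counts) <= 120
        assert 5.0 <= np.mean(per_axon) <= 8.0
        assert 0.15 <= np.mean(direct) <= 0.35

    def test_junction_positions_within_region(self, pop):
        scheme = LayoutScheme(min_dist=0.0, max_dist=50.0)
        gjs = generate_density_layout(pop, scheme, np.random.default_rng(0))
        d = np.array([g.d_gj for g in gjs])
        assert np.all((d >= 0.0) & (d < 50.0))

    def test_zero_density_gives_empty_layout(self, pop):
        scheme = LayoutScheme(probability_density=0.0)
        assert generate_density_layout(pop, scheme, np.random.default_rng(0)) == []

    def test_two_neuron_expected_count(self):
        """Binomial expectation: 50 bins x p=0.015 x 1 partner = 0.75 per
        caudal neuron; only neuron 1 has a rostral partner."""
        pop2 = default_population(n=2)
        scheme = LayoutScheme()
        total = 0
        n_draws = 4000
        rng = np.random.default_rng(42)
        for _ in range(n_draws):
            total += len(generate_density_layout(pop2, scheme, rng))
        mean = total / n_draws
        expected = 50 * 0.015  # = 0.75
        assert mean == pytest.approx(expected, rel=0.05)

    def test_partner_cap_respected(self, pop):
        scheme = LayoutScheme(probability_density=1.0)  # p = 1 per bin
        gjs = generate_density_layout(pop, scheme, np.random.default_rng(1))
        per_bin = {}
        for gj in gjs:
            key = (gj.caudal_neuron_id, gj.d_gj)
            per_bin[key] = per_bin.get(key, 0) + 1
        assert max(per_bin.values()) <= 6

    def test_reproducible_under_seed(self, pop):
        a = generate_density_layout(pop, LayoutScheme(), np.random.default_rng(9))
        b = generate_density_layout(pop, LayoutScheme(), np.random.default_rng(9))
        assert a == b


class TestFixedPointLayout:
    def test_probability_one_connects_all_capped_pairs(self, pop):
        scheme = LayoutScheme(variant="fixed_point", probability=1.0, fixed_point=30.0)
        gjs = generate_fixed_point_layout(pop, scheme, np.random.default_rng(0))
        # every caudal neuron with i rostral partners gets min(i, 6)
        expected = sum(min(i, 6) for i in range(30))
        assert len(gjs) == expected

    def test_probability_zero_empty(self, pop):
        scheme = LayoutScheme(variant="fixed_point", probability=0.0)
        assert generate_fixed_point_layout(pop, scheme, np.random.default_rng(0)) == []

    def test_all_junctions_share_distance(self, pop):
        scheme = LayoutScheme(variant="fixed_point", probability=0.7, fixed_point=25.0)
        gjs = generate_fixed_point_layout(pop, scheme, np.random.default_rng(3))
        assert gjs and all(g.d_gj == 25.0 for g in gjs)


class TestCouplingGraph:
    def test_chain_classification(self):
        pop3 = default_population(n=3)
        gjs = (
            GapJunction(1, 0, 25.0, 35.0, 600.0),
            GapJunction(2, 1, 25.0, 45.0, 600.0),
        )
        model = NetworkModel(pop3, gjs)
        cls = classify_pairs(model)
        assert cls[(0, 1)] == 1
        assert cls[(1, 2)] == 1
        assert cls[(0, 2)] == 2  # indirect via neuron 1's axon

    def test_no_junctions_all_uncoupled(self):
        model = NetworkModel(default_population(n=5), ())
        assert all(v is None for v in classify_pairs(model).values())

    def test_graph_has_all_neurons_as_nodes(self, pop):
        model = NetworkModel(pop, ())
        assert coupling_graph(model).number_of_nodes() == 30


class TestSubsample:
    @pytest.fixture(scope="class")
    def model(self):
        pop = default_population()
        gjs = generate_density_layout(pop, LayoutScheme(), np.random.default_rng(4))
        return NetworkModel(pop, tuple(gjs))

    def test_identity_and_empty(self, model):
        rng = np.random.default_rng(0)
        assert gj_subsample(model, 1.0, rng) is model
        assert gj_subsample(model, 0.0, rng).gap_junctions == ()

    def test_half_retains_floor(self, model):
        n = len(model.gap_junctions)
        sub = gj_subsample(model, 0.5, np.random.default_rng(0))
        assert len(sub.gap_junctions) == n // 2
        assert set(sub.gap_junctions) <= set(model.gap_junctions)

    def test_invalid_fraction(self, model):
        with pytest.raises(ConfigurationError):
            gj_subsample(model, 1.5, np.random.default_rng(0))


class TestInvariants:
    def test_self_junction_rejected(self):
        with pytest.raises(ConfigurationError):
            GapJunction(2, 2, 25.0, 45.0, 600.0)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ConfigurationError):
            GapJunction(1, 0, 25.0, 35.0, 0.0)

    def test_junction_outside_span_rejected(self):
        pop = default_population(n=2)
        gj = GapJunction(1, 0, 2000.0, 2010.0, 600.0)
        with pytest.raises(ConfigurationError):
            NetworkModel(pop, (gj,))

    def test_junction_conductance(self):
        gj = GapJunction(1, 0, 25.0, 35.0, 600.0)
        assert gj.conductance_nS == pytest.approx(1.667, abs=1e-3)

    def test_coupled_leak_is_half_uncoupled(self):
        from axonet.network import COUPLED_LEAK_DENSITY, UNCOUPLED_LEAK_DENSITY

        assert COUPLED_LEAK_DENSITY == pytest.approx(UNCOUPLED_LEAK_DENSITY / 2)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            LayoutScheme(min_dist=50.0, max_dist=50.0)
        with pytest.raises(ConfigurationError):
            LayoutScheme(variant="banana")


class TestSerialisation:
    def test_json_roundtrip_fields(self):
        import json

        from axonet.network import network_to_json

        pop = default_population(n=3)
        gjs = (GapJunction(1, 0, 25.0, 35.0, 600.0),)
        model = NetworkModel(pop, gjs)
        data = json.loads(network_to_json(model, seed=5))
        assert data["n_neurons"] == 3
        assert data["seed"] == 5
        assert data["gap_junctions"][0]["resistance_MOhm"] == 600.0

    def test_junction_table_rows(self):
        from axonet.network import junction_table

        pop = default_population(n=4)
        gjs = (
            GapJunction(1, 0, 25.0, 35.0, 600.0),
            GapJunction(3, 2, 10.0, 40.0, 600.0),
        )
        table = junction_table(NetworkModel(pop, gjs))
        assert len(table) == 2
        assert list(table["caudal_id"]) == [1, 3]
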