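"""Small deterministic networks with hand-checkable expected values.

These fixtures are seed-independent by construction: junctions are placed
by hand rather than drawn from a layout scheme.
"""

from __future__ import annotations

from axonet.channels import DensityConfig
from axonet.morphology import build_din_morphology, build_population
from axonet.network import GapJunction, NetworkModel

__all__ = ["single_cable", "two_neuron_one_junction", "three_chain"]


def single_cable(
    axon_length: float = 3000.0, g_lk: float = 0.25, axon_diameter: float = 0.4
) -> NetworkModel:
    """One passive neuron with a long axon, for cable-theory checks."""
    morph = build_din_morphology(
        axon_diameter=axon_diameter, axon_length=axon_length
    )
    pop = build_population(1, 10.0, morph)
    return NetworkModel(
        pop, (), DensityConfig(lk_density=g_lk, noise_sd=0.0), passive=True
    )


def two_neuron_one_junction(
    d_gj: float = 25.0, resistance: float = 600.0, g_lk: float = 0.25
) -> NetworkModel:
    """Two neurons, one junction at ``d_gj`` um from the caudal soma.

    Neuron 1 (caudal, soma at 10 um) contacts neuron 0's axon at the
    shared coordinate 10 + ``d_gj``.
    """
    pop = build_population(2, 10.0, build_din_morphology())
    gj = GapJunction(
        caudal_neuron_id=1,
        rostral_neuron_id=0,
        d_gj=d_gj,
        rostrocaudal_coordinate=10.0 + d_gj,
        resistance=resistance,
    )
    return NetworkModel(
        pop, (gj,), DensityConfig(lk_density=g_lk, noise_sd=0.0), passive=True
    )


def three_chain(g_lk: float = 0.25) -> NetworkModel:
    """Three neurons coupled in a chain: 0-1 and 1-2 but not 0-2."""
    pop = build_population(3, 10.0, build_din_morphology())
    gjs = (
        GapJunction(1, 0, 25.0, 10.0 + 25.0, 600.0),
        GapJunction(2, 1, 25.0, 20.0 + 25.0, 600.0),
    )
    return NetworkModel(
        pop, gjs, DensityConfig(lk_density=g_lk, noise_sd=0.0), passive=True
    )
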