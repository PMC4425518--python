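"""Stochastic gap-junction layouts and the assembled network model.

A gap junction is a purely resistive contact between the axon of a caudal
neuron (at arc distance ``d_gj`` from its soma) and the axon of a more
rostral neuron passing the same rostrocaudal coordinate.  The density
layout scheme walks 1 um bins over the proximal region of each neuron's
axon, picks up to six overlapping rostral axons per bin at random, and
forms a junction with probability (density * bin width) with each - six
being the maximum number of equal-diameter cylinders that can touch
another at one point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from axonet.channels import DensityConfig
from axonet.morphology import ConfigurationError, PopulationLayout

__all__ = [
    "GapJunction",
    "LayoutScheme",
    "NetworkModel",
    "generate_density_layout",
    "generate_fixed_point_layout",
    "generate_layout",
    "coupling_graph",
    "classify_pairs",
    "gj_subsample",
    "network_to_json",
    "junction_table",
]

DEFAULT_GJ_RESISTANCE = 600.0  # MOhm
COUPLED_LEAK_DENSITY = 0.125  # mS/cm^2, leak halved to offset junctional load
UNCOUPLED_LEAK_DENSITY = 0.25  # mS/cm^2, uniform-leak passive value


@dataclass(frozen=True)
class GapJunction:
    """A resistive contact between two axons at one rostrocaudal coordinate."""

    caudal_neuron_id: int
    rostral_neuron_id: int
    d_gj: float  # um, arc distance from the caudal neuron's soma
    rostrocaudal_coordinate: float  # um, absolute position along the column
    resistance: float = DEFAULT_GJ_RESISTANCE  # MOhm

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ConfigurationError("gap junction resistance must be > 0")
        if self.caudal_neuron_id == self.rostral_neuron_id:
            raise ConfigurationError("self-junctions are not allowed")

    @property
    def conductance_nS(self) -> float:
        return 1e3 / self.resistance  # 1/MOhm = uS -> nS

    @property
    def pair(self) -> tuple[int, int]:
        a, b = self.caudal_neuron_id, self.rostral_neuron_id
        return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class LayoutScheme:
    """Parameters of a stochastic gap-junction placement rule.

    ``variant`` is either ``"density"`` (fixed probability density over
    [min_dist, max_dist) of the caudal axon, binned at ``bin_width``) or
    ``"fixed_point"`` (a single Bernoulli candidate at ``fixed_point`` um
    from the caudal soma).
    """

    variant: str = "density"
    probability_density: float = 0.015  # 1/um
    min_dist: float = 0.0  # um from caudal soma
    max_dist: float = 50.0
    bin_width: float = 1.0
    max_neighbours: int = 6
    fixed_point: float = 30.0  # um, for the fixed_point variant
    probability: float = 0.5  # per-pair, for the fixed_point variant
    resistance: float = DEFAULT_GJ_RESISTANCE  # MOhm

    def __post_init__(self) -> None:
        if self.variant not in ("density", "fixed_point"):
            raise ConfigurationError(f"unknown layout variant {self.variant!r}")
        if self.min_dist >= self.max_dist:
            raise ConfigurationError("min_dist must be < max_dist")
        if self.probability_density < 0:
            raise ConfigurationError("probability_density must be >= 0")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if self.max_neighbours < 1:
            raise ConfigurationError("max_neighbours must be >= 1")
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError("probability must be in [0, 1]")


@dataclass(frozen=True)
class NetworkModel:
    """A population layout plus its gap junctions and density configuration."""

    layout: PopulationLayout
    gap_junctions: tuple[GapJunction, ...]
    density_config: DensityConfig = field(default_factory=DensityConfig)
    passive: bool = True

    def __post_init__(self) -> None:
        # no more than max_neighbours partners at any one axon position is
        # enforced at generation time; here we enforce the basic invariants
        for gj in self.gap_junctions:
            for nid in (gj.caudal_neuron_id, gj.rostral_neuron_id):
                lo, hi = self.layout.cable_span(nid)
                if not (lo <= gj.rostrocaudal_coordinate <= hi):
                    raise ConfigurationError(
                        f"junction at {gj.rostrocaudal_coordinate} um outside "
                        f"the span of neuron {nid}"
                    )

    @property
    def n_neurons(self) -> int:
        return self.layout.n_neurons

    def without_junctions(self) -> "NetworkModel":
        return replace(self, gap_junctions=())


def _rostral_partners(
    pop: PopulationLayout, caudal: int, coordinate: float
) -> list[int]:
    """More-rostral neurons whose cable passes ``coordinate``."""
    out = []
    for j in range(caudal):
        lo, hi = pop.cable_span(j)
        if lo <= coordinate < hi:
            out.append(j)
    return out


def generate_density_layout(
    pop: PopulationLayout,
    scheme: LayoutScheme,
    rng: np.random.Generator,
) -> list[GapJunction]:
    """Place junctions with a fixed probability density over a proximal region.

    For each neuron, the region [min_dist, max_dist) of its axon is divided
    into bins of ``bin_width``; in each bin up to ``max_neighbours`` distinct
    overlapping rostral axons are sampled uniformly without replacement and
    each forms a junction at the bin centre with probability
    ``probability_density * bin_width``.
    """
    if scheme.variant != "density":
        raise ConfigurationError("scheme variant must be 'density'")
    p = scheme.probability_density * scheme.bin_width
    junctions: list[GapJunction] = []
    for i in range(pop.n_neurons):
        x0 = pop.soma_positions[i]
        _, cable_hi = pop.cable_span(i)
        d = scheme.min_dist
        while d < scheme.max_dist - 1e-12:
            centre = d + scheme.bin_width / 2.0
            coord = x0 + centre
            if coord >= cable_hi:
                break
            partners = _rostral_partners(pop, i, coord)
            if partners:
                k = min(scheme.max_neighbours, len(partners))
                chosen = rng.choice(len(partners), size=k, replace=False)
                for idx in chosen:
                    if rng.random() < p:
                        junctions.append(
                            GapJunction(
                                caudal_neuron_id=i,
                                rostral_neuron_id=partners[idx],
                                d_gj=centre,
                                rostrocaudal_coordinate=coord,
                                resistance=scheme.resistance,
                            )
                        )
            d += scheme.bin_width
    return junctions


def generate_fixed_point_layout(
    pop: PopulationLayout,
    scheme: LayoutScheme,
    rng: np.random.Generator,
) -> list[GapJunction]:
    """Place junctions at a single fixed arc distance from each caudal soma.

    Each caudal neuron offers one candidate position; up to
    ``max_neighbours`` overlapping rostral axons are considered and each
    forms a junction there with probability ``scheme.probability``.  Pairs
    whose axons do not reach the fixed point are skipped.
    """
    if scheme.variant != "fixed_point":
        raise ConfigurationError("scheme variant must be 'fixed_point'")
    junctions: list[GapJunction] = []
    for i in range(pop.n_neurons):
        x0 = pop.soma_positions[i]
        _, cable_hi = pop.cable_span(i)
        coord = x0 + scheme.fixed_point
        if coord >= cable_hi:
            continue
        partners = _rostral_partners(pop, i, coord)
        if not partners:
            continue
        k = min(scheme.max_neighbours, len(partners))
        chosen = rng.choice(len(partners), size=k, replace=False)
        for idx in chosen:
            if rng.random() < scheme.probability:
                junctions.append(
                    GapJunction(
                        caudal_neuron_id=i,
                        rostral_neuron_id=partners[idx],
                        d_gj=scheme.fixed_point,
                        rostrocaudal_coordinate=coord,
                        resistance=scheme.resistance,
                    )
                )
    return junctions


def generate_layout(
    pop: PopulationLayout, scheme: LayoutScheme, rng: np.random.Generator
) -> list[GapJunction]:
    if scheme.variant == "density":
        return generate_density_layout(pop, scheme, rng)
    return generate_fixed_point_layout(pop, scheme, rng)


def coupling_graph(model: NetworkModel) -> nx.Graph:
    """Neuron-level graph with an edge wherever >= 1 direct junction exists."""
    g = nx.Graph()
    g.add_nodes_from(range(model.n_neurons))
    for gj in model.gap_junctions:
        g.add_edge(*gj.pair)
    return g


def classify_pairs(model: NetworkModel) -> dict[tuple[int, int], int | None]:
    """Shortest junction-path length per unordered neuron pair.

    1 = directly coupled, k = coupled via k-1 intermediate axons,
    ``None`` = not coupled at all.
    """
    g = coupling_graph(model)
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    out: dict[tuple[int, int], int | None] = {}
    n = model.n_neurons
    for i in range(n):
        for j in range(i + 1, n):
            out[(i, j)] = lengths.get(i, {}).get(j)
    return out


def gj_subsample(
    model: NetworkModel, fraction: float, rng: np.random.Generator
) -> NetworkModel:
    """Keep a uniformly random subset of floor(fraction * N) junctions."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must be in [0, 1]")
    n = len(model.gap_junctions)
    keep = int(np.floor(fraction * n))
    if keep == n:
        return model
    idx = rng.choice(n, size=keep, replace=False)
    kept = tuple(model.gap_junctions[i] for i in sorted(idx))
    return replace(model, gap_junctions=kept)


def network_to_json(model: NetworkModel, seed: int | None = None) -> str:
    """Serialise a network (neurons + junction list) to JSON."""
    import json

    payload = {
        "n_neurons": model.n_neurons,
        "soma_positions": list(model.layout.soma_positions),
        "seed": seed,
        "gap_junctions": [
            {
                "caudal": gj.caudal_neuron_id,
                "rostral": gj.rostral_neuron_id,
                "d_gj_um": gj.d_gj,
                "coordinate_um": gj.rostrocaudal_coordinate,
                "resistance_MOhm": gj.resistance,
            }
            for gj in model.gap_junctions
        ],
    }
    return json.dumps(payload, indent=2)


def junction_table(model: NetworkModel):
    """Junction list as a DataFrame (one row per junction) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "caudal_id": gj.caudal_neuron_id,
                "rostral_id": gj.rostral_neuron_id,
                "d_gj_um": gj.d_gj,
                "coordinate_um": gj.rostrocaudal_coordinate,
                "resistance_MOhm": gj.resistance,
            }
            for gj in model.gap_junctions
        ]
    )
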