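"""Ready-made model configurations.

Two networks recur throughout the analysis:

* the *passive* population used to infer gap-junction locations from
  coupling coefficients (uniform leak 0.25 mS/cm^2, no voltage-gated
  channels), and
* the *final active* model: leak halved to 0.125 mS/cm^2 to offset the
  junctional load, chosen density multipliers (Na x3, others x1), 5 %
  density noise per neuron/channel, and an excitable axon initial segment
  (20-70 um from the soma: Na density x5, K densities halved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from axonet.channels import (
    CHOSEN_MULTIPLIERS,
    DensityConfig,
    GHKConstants,
    channel_registry,
    realise_densities,
)
from axonet.morphology import (
    PopulationLayout,
    build_din_morphology,
    build_population,
)
from axonet.network import (
    COUPLED_LEAK_DENSITY,
    UNCOUPLED_LEAK_DENSITY,
    LayoutScheme,
    NetworkModel,
    generate_layout,
)
from axonet.solver import SystemMatrices, assemble

__all__ = [
    "INITIAL_SEGMENT_REGION",
    "initial_segment_overrides",
    "default_population",
    "passive_network",
    "final_network",
    "FinalModel",
]

#: arc-distance interval (um from the soma) of the excitable initial segment
INITIAL_SEGMENT_REGION = (20.0, 70.0)


def initial_segment_overrides(
    na_scale: float = 5.0, k_scale: float = 0.5
) -> tuple:
    """Density overrides for the axon initial segment."""
    lo, hi = INITIAL_SEGMENT_REGION
    return (
        (lo, hi, "na", na_scale),
        (lo, hi, "kf", k_scale),
        (lo, hi, "ks", k_scale),
    )


def default_population(
    n: int = 30,
    spacing: float = 10.0,
    axon_diameter: float = 0.4,
    axon_length: float = 1500.0,
) -> PopulationLayout:
    template = build_din_morphology(
        axon_diameter=axon_diameter, axon_length=axon_length
    )
    return build_population(n, spacing, template)


def passive_network(
    seed: int,
    g_lk: float = UNCOUPLED_LEAK_DENSITY,
    scheme: LayoutScheme | None = None,
    population: PopulationLayout | None = None,
    coupled: bool = True,
    ri: float = 80.0,
) -> tuple[NetworkModel, SystemMatrices]:
    """A passive coupled column for coupling-coefficient analysis."""
    if scheme is None:
        scheme = LayoutScheme()
    if population is None:
        population = default_population()
    rng = np.random.default_rng(seed)
    junctions = tuple(generate_layout(population, scheme, rng)) if coupled else ()
    model = NetworkModel(
        population,
        junctions,
        DensityConfig(lk_density=g_lk, noise_sd=0.0),
        passive=True,
    )
    return model, assemble(model, ri=ri)


@dataclass
class FinalModel:
    """The assembled final active model plus its realised densities."""

    model: NetworkModel
    system: SystemMatrices
    densities: dict[str, np.ndarray]
    ghk: GHKConstants
    registry: dict = field(repr=False, default_factory=channel_registry)

    def uncoupled(self) -> "FinalModel":
        """The same neurons with every gap junction deleted."""
        model = self.model.without_junctions()
        return FinalModel(
            model=model,
            system=assemble(model),
            densities=self.densities,
            ghk=self.ghk,
            registry=self.registry,
        )


def final_network(
    seed: int,
    coupled: bool = True,
    g_lk: float = COUPLED_LEAK_DENSITY,
    multipliers: dict | None = None,
    noise_sd: float = 0.05,
    initial_segment: bool = True,
    is_na_scale: float = 5.0,
    is_k_scale: float = 0.5,
    scheme: LayoutScheme | None = None,
    population: PopulationLayout | None = None,
    ghk: GHKConstants | None = None,
) -> FinalModel:
    """Build the final active 30-dIN model for one seed.

    The seed controls both the stochastic junction layout and the
    per-neuron density noise (independent child streams).
    """
    if scheme is None:
        scheme = LayoutScheme()
    if population is None:
        population = default_population()
    if multipliers is None:
        multipliers = dict(CHOSEN_MULTIPLIERS)
    if ghk is None:
        ghk = GHKConstants()
    ss = np.random.SeedSequence(seed)
    layout_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    junctions = tuple(generate_layout(population, scheme, layout_rng)) if coupled else ()
    overrides = (
        initial_segment_overrides(is_na_scale, is_k_scale) if initial_segment else ()
    )
    config = DensityConfig(
        multipliers=multipliers,
        noise_sd=noise_sd,
        lk_density=g_lk,
        regional_overrides=overrides,
    )
    model = NetworkModel(population, junctions, config, passive=False)
    system = assemble(model)
    registry = channel_registry()
    densities = realise_densities(registry, config, system.compartments, noise_rng)
    return FinalModel(
        model=model, system=system, densities=densities, ghk=ghk, registry=registry
    )
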