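"""Membrane current kinetics and channel-density configuration.

Five currents are modelled: an ohmic leak, Hodgkin-Huxley type sodium and
fast/slow potassium currents, and a calcium current using the
Goldman-Hodgkin-Katz (constant-field) flux equation.  All rate functions
share the form

    rate(V) = (A + B*V) / (C + exp((D + V) / E))        [1/ms, V in mV]

with per-gate parameter sets shipped in ``data/channels.yaml``.  Current
densities follow the convention that positive membrane current is
depolarising: i = g * (e_rev - V) for the ohmic currents.

Channel densities are realised per compartment as

    g_x = g_hat_x * M_x * N(1.0, noise_sd)

with one normal draw per neuron, per channel, per realisation, optional
regional overrides (e.g. raised Na density in the axon initial segment)
multiplying on top, and negative draws clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from axonet.morphology import Compartment, ConfigurationError

__all__ = [
    "NumericalDomainError",
    "RateParams",
    "GateSpec",
    "ChannelSpec",
    "GHKConstants",
    "DensityConfig",
    "rate",
    "gate_steady_state",
    "gate_time_constant",
    "ohmic_current",
    "ghk_current",
    "realise_densities",
    "channel_registry",
    "multiplier_table",
    "CHOSEN_MULTIPLIERS",
]

_DEN_EPS = 1e-12


class NumericalDomainError(ArithmeticError):
    """Raised when a rate denominator vanishes inside the working range."""


@dataclass(frozen=True)
class RateParams:
    """Parameters of one opening/closing rate function."""

    A: float  # 1/ms
    B: float  # 1/(ms*mV)
    C: float  # dimensionless
    D: float  # mV
    E: float  # mV

    def __post_init__(self) -> None:
        if self.E == 0:
            raise ConfigurationError("rate parameter E must be nonzero")


def rate(params: RateParams, V):
    """Evaluate (A + B*V) / (C + exp((D + V)/E)) at membrane potential V (mV)."""
    V = np.asarray(V, dtype=float)
    den = params.C + np.exp((params.D + V) / params.E)
    if np.any(np.abs(den) < _DEN_EPS):
        raise NumericalDomainError(
            f"rate denominator vanished for params {params} at V={V}"
        )
    out = (params.A + params.B * V) / den
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: exponent and its alpha/beta rate functions.

    ``beta_high`` is only used by the calcium activation gate, whose beta
    rate switches parameter sets at ``split`` (= -25 mV); values at exactly
    the split use the high-voltage branch.
    """

    name: str
    exponent: int
    alpha: RateParams
    beta: RateParams
    beta_high: RateParams | None = None
    split: float = -25.0

    def __post_init__(self) -> None:
        if self.exponent not in (1, 2, 3, 4):
            raise ConfigurationError(f"gate exponent must be 1..4, got {self.exponent}")

    def alpha_rate(self, V):
        """Opening rate, clipped at zero.

        The slow-potassium opening rate's linear numerator crosses zero a
        few mV below rest, going (negligibly) negative; transition rates
        are physically non-negative, so gate evaluation clips there.
        """
        out = np.maximum(rate(self.alpha, V), 0.0)
        return out if np.ndim(out) else float(out)

    def beta_rate(self, V):
        if self.beta_high is None:
            out = np.maximum(rate(self.beta, V), 0.0)
            return out if np.ndim(out) else float(out)
        V = np.asarray(V, dtype=float)
        low = V < self.split
        out = np.where(low, _rate_raw(self.beta, V), _rate_raw(self.beta_high, V))
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)


def _rate_raw(params: RateParams, V):
    """Rate function without the vanishing-denominator guard.

    Used for piecewise branches evaluated outside their own domain by
    ``np.where`` (the discarded branch may hit its singularity).
    """
    den = params.C + np.exp((params.D + V) / params.E)
    den = np.where(np.abs(den) < _DEN_EPS, np.nan, den)
    return (params.A + params.B * V) / den


def gate_steady_state(gate: GateSpec, V):
    """X_inf(V) = alpha / (alpha + beta); lies in [0, 1]."""
    a = gate.alpha_rate(V)
    b = gate.beta_rate(V)
    s = a + b
    if np.any(np.asarray(s) <= 0):
        raise NumericalDomainError(f"alpha + beta <= 0 for gate {gate.name} at V={V}")
    return a / s


def gate_time_constant(gate: GateSpec, V):
    """tau_X(V) = 1 / (alpha + beta), in ms."""
    a = gate.alpha_rate(V)
    b = gate.beta_rate(V)
    s = a + b
    if np.any(np.asarray(s) <= 0):
        raise NumericalDomainError(f"alpha + beta <= 0 for gate {gate.name} at V={V}")
    return 1.0 / s


@dataclass(frozen=True)
class ChannelSpec:
    """A channel type: reversal potential (or GHK permeability) and gates.

    ``base_density`` is in mS/cm^2 for ohmic channels.  For the calcium
    channel the GHK permeability (cm/s) is carried in ``permeability`` and
    ``base_density`` is a dimensionless multiplier on it.
    """

    kind: str  # lk | na | kf | ks | ca
    base_density: float
    reversal_potential: float | None = None
    permeability: float | None = None
    gates: tuple[GateSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.base_density < 0:
            raise ConfigurationError("base_density must be >= 0")
        if self.kind == "ca":
            if self.permeability is None:
                raise ConfigurationError("calcium channel requires a permeability")
        elif self.reversal_potential is None:
            raise ConfigurationError(f"channel {self.kind!r} requires a reversal potential")


@dataclass(frozen=True)
class GHKConstants:
    """Physical constants and ion concentrations for the GHK calcium flux.

    The calcium current depends on the permeability and the two
    concentrations only through the products P*[Ca]_o and P*[Ca]_i, and
    the underlying voltage-clamp literature constrains the current, not
    the factors separately.  Pairing the quoted permeability (0.016 cm/s)
    with millimolar external calcium yields a standing inward current two
    orders of magnitude too large to permit a stable resting state, so the
    default external value here is an *effective* concentration calibrated
    once so that the calcium current plays its spike-broadening /
    depolarisation-block role without destabilising rest.  Both
    concentrations are configurable.
    """

    F: float = 96485.0  # C/mol
    R: float = 8.314  # J/(K*mol)
    T: float = 300.0  # K
    ca_internal: float = 1e-7  # mol/L
    ca_external: float = 1e-5  # mol/L (effective; see class docstring)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.ca_internal <= 0 or self.ca_external <= 0:
            raise ConfigurationError("concentrations must be > 0")


def ohmic_current(spec: ChannelSpec, V, gate_values=()):
    """Ohmic current density, uA/cm^2, for a unit (base) conductance density.

    i = g * prod(X_k^p_k) * (e_rev - V), positive = depolarising.
    ``gate_values`` supplies one open fraction per gate, in spec order.
    """
    V = np.asarray(V, dtype=float)
    g_open = np.asarray(spec.base_density, dtype=float)
    for gate, x in zip(spec.gates, gate_values):
        g_open = g_open * np.asarray(x, dtype=float) ** gate.exponent
    out = g_open * (spec.reversal_potential - V)
    return out if np.ndim(out) else float(out)


def ghk_current(P: float, m, V, constants: GHKConstants | None = None):
    """Calcium current density from the GHK flux equation, uA/cm^2.

    With v = 2VF/RT (dimensionless), the current is

        i = P * 2vF * ([Ca]_o exp(-v) - [Ca]_i) / (1 - exp(-v)) * m^2

    oriented so that with the physiological concentration gradient
    ([Ca]_o >> [Ca]_i) the current is depolarising (inward, positive under
    the sign convention used here).  The v = 0 singularity is removable
    and handled analytically.

    Parameters: P in cm/s, V in mV, concentrations in mol/L.
    """
    if constants is None:
        constants = GHKConstants()
    V = np.asarray(V, dtype=float)
    m = np.asarray(m, dtype=float)
    ca_i = constants.ca_internal * 1e-3  # mol/L -> mol/cm^3
    ca_o = constants.ca_external * 1e-3
    v = 2.0 * (V * 1e-3) * constants.F / (constants.R * constants.T)
    # f(v) = v * (ca_o*exp(-v) - ca_i) / (1 - exp(-v));  f(0) = ca_o - ca_i
    with np.errstate(over="ignore", invalid="ignore"):
        num = v * (ca_o * np.exp(-v) - ca_i)
        den = -np.expm1(-v)
        f = np.where(np.abs(v) < 1e-9, ca_o - ca_i, num / np.where(den == 0, 1.0, den))
    i_A_cm2 = P * 2.0 * constants.F * f * m**2
    out = i_A_cm2 * 1e6  # A/cm^2 -> uA/cm^2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DensityConfig:
    """How channel densities are realised over a population.

    ``multipliers`` maps channel kind to its density multiplier M_x;
    ``regional_overrides`` is a list of ``(arc_lo, arc_hi, kind, scale)``
    tuples applied multiplicatively to compartments whose centre arc
    distance from the soma falls in ``[arc_lo, arc_hi)``.
    """

    multipliers: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    regional_overrides: tuple = ()
    lk_density: float | None = None  # overrides the registry base leak density

    def __post_init__(self) -> None:
        for kind, m in self.multipliers.items():
            if m < 0:
                raise ConfigurationError(f"multiplier for {kind!r} must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def with_multiplier(self, kind: str, value: float) -> "DensityConfig":
        mult = dict(self.multipliers)
        mult[kind] = value
        return replace(self, multipliers=mult)


def _load_registry_data() -> dict:
    text = resources.files("axonet.data").joinpath("channels.yaml").read_text()
    return yaml.safe_load(text)


def _gate_from_dict(d: dict) -> GateSpec:
    return GateSpec(
        name=d["name"],
        exponent=int(d["exponent"]),
        alpha=RateParams(**d["alpha"]),
        beta=RateParams(**d["beta"]),
        beta_high=RateParams(**d["beta_high"]) if "beta_high" in d else None,
    )


def channel_registry() -> dict[str, ChannelSpec]:
    """The packaged channel parameter set, keyed by channel kind."""
    data = _load_registry_data()
    registry = {}
    for kind, entry in data["channels"].items():
        registry[kind] = ChannelSpec(
            kind=kind,
            base_density=float(entry["base_density"]),
            reversal_potential=entry.get("reversal_potential"),
            permeability=entry.get("permeability"),
            gates=tuple(_gate_from_dict(g) for g in entry.get("gates", [])),
        )
    return registry


def multiplier_table() -> dict[str, dict]:
    """Tested multiplier sets and chosen values for the density sweep."""
    return _load_registry_data()["multipliers"]


CHOSEN_MULTIPLIERS = {"ca": 1.0, "kf": 1.0, "ks": 1.0, "na": 3.0, "lk": 1.0}


def realise_densities(
    registry: dict[str, ChannelSpec],
    config: DensityConfig,
    compartments: list[Compartment],
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-compartment channel densities for one network realisation.

    Returns a map from channel kind to an array over compartments: mS/cm^2
    for ohmic channels, cm/s for the calcium permeability.  One noise draw
    is made per neuron per channel; with ``noise_sd = 0`` the result is
    deterministic and the RNG is never consulted.
    """
    if rng is None:
        rng = np.random.default_rng()
    neuron_ids = np.array([c.neuron_id for c in compartments])
    arc = np.array([c.arc_distance_from_soma for c in compartments])
    arc_end = {}
    for c in compartments:
        arc_end[c.neuron_id] = max(arc_end.get(c.neuron_id, 0.0), c.arc_end)
    unique_neurons = np.unique(neuron_ids)

    for lo, hi, kind, _scale in config.regional_overrides:
        if kind not in registry:
            raise ConfigurationError(f"override names unknown channel {kind!r}")
        if lo >= hi:
            raise ConfigurationError("override interval must have lo < hi")
        if lo < 0 or hi > max(arc_end.values()) + 1e-9:
            raise ConfigurationError(
                f"override interval [{lo}, {hi}) lies outside the cable span"
            )

    out: dict[str, np.ndarray] = {}
    for kind, spec in registry.items():
        base = spec.base_density
        if kind == "lk" and config.lk_density is not None:
            base = config.lk_density
        m = config.multipliers.get(kind, 1.0)
        dens = np.full(len(compartments), float(base) * m)
        if config.noise_sd > 0:
            noise = rng.normal(1.0, config.noise_sd, size=unique_neurons.size)
            per_comp = noise[np.searchsorted(unique_neurons, neuron_ids)]
            dens = dens * per_comp
        for lo, hi, okind, scale in config.regional_overrides:
            if okind == kind:
                dens = np.where((arc >= lo) & (arc < hi), dens * scale, dens)
        np.clip(dens, 0.0, None, out=dens)
        if kind == "ca":
            dens = dens * spec.permeability  # -> cm/s
        out[kind] = dens
    return out
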