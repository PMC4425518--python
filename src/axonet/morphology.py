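"""Neuron geometry and its spatial discretisation.

A model dIN (descending interneuron) is built from four sections: an
isopotential soma (the soma-plus-short-dendrites of the real cell, lumped
into one cylinder whose lateral area matches the measured ~1000 um^2), two
short tapering axon-hillock sections, and a long thin unmyelinated axon.
The population is a rostrocaudal column of such neurons with regularly
spaced somata, every axon descending caudally.

All lengths and diameters are in micrometres; areas in um^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "InvalidGeometryError",
    "ConfigurationError",
    "SectionGeometry",
    "NeuronMorphology",
    "Compartment",
    "DiscretisationRules",
    "PopulationLayout",
    "build_din_morphology",
    "compartmentalise",
    "build_population",
    "to_swc",
    "to_json",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive or inconsistent geometric dimensions."""


class ConfigurationError(ValueError):
    """Raised for invalid discretisation or layout configuration."""


@dataclass(frozen=True)
class SectionGeometry:
    """A cylinder or tapered cylinder making up part of a neuron."""

    label: str  # soma | hillock1 | hillock2 | axon
    proximal_diameter: float
    distal_diameter: float
    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidGeometryError(
                f"section {self.label!r}: length must be > 0, got {self.length}"
            )
        if self.proximal_diameter <= 0 or self.distal_diameter <= 0:
            raise InvalidGeometryError(
                f"section {self.label!r}: diameters must be > 0"
            )
        if self.label.startswith("hillock") and (
            self.distal_diameter > self.proximal_diameter
        ):
            raise InvalidGeometryError(
                f"section {self.label!r}: hillock must taper "
                f"(distal {self.distal_diameter} > proximal {self.proximal_diameter})"
            )

    @property
    def lateral_area(self) -> float:
        """Lateral surface area of the (possibly tapered) cylinder, um^2."""
        r1 = self.proximal_diameter / 2.0
        r2 = self.distal_diameter / 2.0
        slant = math.hypot(self.length, r1 - r2)
        return math.pi * (r1 + r2) * slant


@dataclass(frozen=True)
class NeuronMorphology:
    """Four-section dIN geometry: soma -> hillock1 -> hillock2 -> axon."""

    sections: tuple[SectionGeometry, ...]

    def __post_init__(self) -> None:
        if len(self.sections) != 4:
            raise InvalidGeometryError(
                f"expected exactly 4 sections, got {len(self.sections)}"
            )
        labels = [s.label for s in self.sections]
        if labels != ["soma", "hillock1", "hillock2", "axon"]:
            raise InvalidGeometryError(f"unexpected section order: {labels}")

    @property
    def soma(self) -> SectionGeometry:
        return self.sections[0]

    @property
    def axon(self) -> SectionGeometry:
        return self.sections[3]

    @property
    def soma_surface_area(self) -> float:
        return self.soma.lateral_area

    @property
    def axon_diameter(self) -> float:
        return self.axon.distal_diameter

    @property
    def axon_length(self) -> float:
        return self.axon.length

    @property
    def cable_length(self) -> float:
        """Arc length from the soma's distal end to the axon tip (hillock + axon)."""
        return sum(s.length for s in self.sections[1:])

    @property
    def total_area(self) -> float:
        return sum(s.lateral_area for s in self.sections)


@dataclass(frozen=True)
class Compartment:
    """One electrical compartment of a discretised neuron.

    ``arc_distance_from_soma`` is the arc coordinate of the compartment
    *centre* measured caudally from the soma (0 for the soma itself; the
    hillock occupies the first stretch of the cable, the axon follows).
    ``rostrocaudal_coordinate`` is the absolute position along the column.
    """

    neuron_id: int
    index: int
    parent_index: int | None
    section: str
    length: float
    mean_diameter: float
    membrane_area: float
    arc_distance_from_soma: float
    rostrocaudal_coordinate: float

    @property
    def arc_start(self) -> float:
        if self.parent_index is None:
            return 0.0
        return self.arc_distance_from_soma - self.length / 2.0

    @property
    def arc_end(self) -> float:
        if self.parent_index is None:
            return 0.0
        return self.arc_distance_from_soma + self.length / 2.0


@dataclass(frozen=True)
class DiscretisationRules:
    """Compartment lengths per region of the cable.

    The axon is discretised finely (``axon_proximal_step``) out to
    ``axon_fine_extent`` from its proximal end and coarsely
    (``axon_distal_step``) beyond, matching the proximal concentration of
    gap junctions.
    """

    hillock_step: float = 5.0
    axon_proximal_step: float = 5.0
    axon_fine_extent: float = 400.0
    axon_distal_step: float = 100.0

    def __post_init__(self) -> None:
        for name in ("hillock_step", "axon_proximal_step", "axon_distal_step"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.axon_fine_extent < 0:
            raise ConfigurationError("axon_fine_extent must be >= 0")


def build_din_morphology(
    soma_area: float = 1000.0,
    axon_diameter: float = 0.4,
    axon_length: float = 1500.0,
    hillock_proximal_diameter: float = 2.0,
    hillock_section_length: float = 5.0,
) -> NeuronMorphology:
    """Build the four-section dIN geometry.

    The soma is a single cylinder with length equal to its diameter, sized
    so its lateral area equals ``soma_area`` (pi*d*L = pi*d^2 = area). The
    two hillock sections taper linearly from ``hillock_proximal_diameter``
    down to ``axon_diameter``.
    """
    if soma_area <= 0:
        raise InvalidGeometryError("soma_area must be > 0")
    if axon_diameter <= 0:
        raise InvalidGeometryError("axon_diameter must be > 0")
    if axon_length <= 0:
        raise InvalidGeometryError("axon_length must be > 0")
    if hillock_proximal_diameter < axon_diameter:
        raise InvalidGeometryError(
            "hillock_proximal_diameter must be >= axon_diameter"
        )
    soma_d = math.sqrt(soma_area / math.pi)
    mid_d = 0.5 * (hillock_proximal_diameter + axon_diameter)
    sections = (
        SectionGeometry("soma", soma_d, soma_d, soma_d),
        SectionGeometry(
            "hillock1", hillock_proximal_diameter, mid_d, hillock_section_length
        ),
        SectionGeometry("hillock2", mid_d, axon_diameter, hillock_section_length),
        SectionGeometry("axon", axon_diameter, axon_diameter, axon_length),
    )
    return NeuronMorphology(sections)


def _section_bins(length: float, step: float) -> list[float]:
    """Split ``length`` into bins of ``step`` with a final partial bin."""
    n_full = int(length // step)
    bins = [step] * n_full
    rem = length - n_full * step
    if rem > 1e-9:
        bins.append(rem)
    return bins


def _diameter_at(section: SectionGeometry, s: float) -> float:
    """Diameter at arc position ``s`` (0..length) within a section."""
    f = s / section.length
    return section.proximal_diameter + f * (
        section.distal_diameter - section.proximal_diameter
    )


def compartmentalise(
    morphology: NeuronMorphology,
    rules: DiscretisationRules | None = None,
    neuron_id: int = 0,
    soma_position: float = 0.0,
) -> list[Compartment]:
    """Discretise a neuron into a chain of compartments rooted at the soma.

    The soma is one compartment; the hillock is cut into
    ``rules.hillock_step`` pieces; the axon into fine bins out to
    ``rules.axon_fine_extent`` from its own proximal end and coarse bins
    beyond.
    """
    if rules is None:
        rules = DiscretisationRules()

    comps: list[Compartment] = []
    soma = morphology.soma
    comps.append(
        Compartment(
            neuron_id=neuron_id,
            index=0,
            parent_index=None,
            section="soma",
            length=soma.length,
            mean_diameter=soma.proximal_diameter,
            membrane_area=soma.lateral_area,
            arc_distance_from_soma=0.0,
            rostrocaudal_coordinate=soma_position,
        )
    )

    arc = 0.0  # arc coordinate along the cable (hillock start = 0)
    idx = 1
    for section in morphology.sections[1:]:
        if section.label == "axon":
            fine = min(rules.axon_fine_extent, section.length)
            bins = _section_bins(fine, rules.axon_proximal_step)
            if section.length > fine:
                bins += _section_bins(section.length - fine, rules.axon_distal_step)
        else:
            bins = _section_bins(section.length, rules.hillock_step)
        s_local = 0.0
        for ell in bins:
            d1 = _diameter_at(section, s_local)
            d2 = _diameter_at(section, s_local + ell)
            r1, r2 = d1 / 2.0, d2 / 2.0
            slant = math.hypot(ell, r1 - r2)
            area = math.pi * (r1 + r2) * slant
            centre = arc + ell / 2.0
            comps.append(
                Compartment(
                    neuron_id=neuron_id,
                    index=idx,
                    parent_index=idx - 1,
                    section=section.label,
                    length=ell,
                    mean_diameter=0.5 * (d1 + d2),
                    membrane_area=area,
                    arc_distance_from_soma=centre,
                    rostrocaudal_coordinate=soma_position + centre,
                )
            )
            idx += 1
            s_local += ell
            arc += ell
    return comps


@dataclass(frozen=True)
class PopulationLayout:
    """A rostrocaudal column of neurons with uniformly spaced somata."""

    n_neurons: int
    soma_spacing: float
    soma_positions: tuple[float, ...]
    morphologies: tuple[NeuronMorphology, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be >= 1")
        if len(self.soma_positions) != self.n_neurons:
            raise ConfigurationError("one soma position per neuron required")
        if len(self.morphologies) != self.n_neurons:
            raise ConfigurationError("one morphology per neuron required")
        pos = self.soma_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ConfigurationError("soma positions must be strictly increasing")

    def cable_span(self, i: int) -> tuple[float, float]:
        """Rostrocaudal interval covered by neuron i's hillock + axon."""
        x0 = self.soma_positions[i]
        return (x0, x0 + self.morphologies[i].cable_length)

    def axons_covering(self, coordinate: float) -> list[int]:
        """Neurons whose cable passes the given rostrocaudal coordinate."""
        out = []
        for i in range(self.n_neurons):
            lo, hi = self.cable_span(i)
            if lo <= coordinate < hi:
                out.append(i)
        return out


def build_population(
    n: int = 30,
    spacing: float = 10.0,
    morphology_template: NeuronMorphology | None = None,
) -> PopulationLayout:
    """Lay out ``n`` identical neurons with somata at ``i * spacing``."""
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if spacing <= 0:
        raise ConfigurationError(f"spacing must be > 0, got {spacing}")
    if morphology_template is None:
        morphology_template = build_din_morphology()
    positions = tuple(i * spacing for i in range(n))
    return PopulationLayout(
        n_neurons=n,
        soma_spacing=spacing,
        soma_positions=positions,
        morphologies=tuple(morphology_template for _ in range(n)),
    )


def to_swc(compartments: list[Compartment]) -> str:
    """Render a discretised neuron as SWC text.

    The soma is a single sample (type 1); the cable is a chain of axon
    samples (type 2) laid out along the x axis. SWC sample ids are 1-based.
    """
    lines = ["# axonet morphology export", "# id type x y z radius parent"]
    for c in compartments:
        swc_type = 1 if c.section == "soma" else 2
        parent = -1 if c.parent_index is None else c.parent_index + 1
        lines.append(
            f"{c.index + 1} {swc_type} {c.rostrocaudal_coordinate:.3f} 0.0 0.0 "
            f"{c.mean_diameter / 2.0:.4f} {parent}"
        )
    return "\n".join(lines) + "\n"


def to_json(morphology: NeuronMorphology) -> str:
    """Serialise a morphology to JSON."""
    payload = {
        "sections": [
            {
                "label": s.label,
                "proximal_diameter": s.proximal_diameter,
                "distal_diameter": s.distal_diameter,
                "length": s.length,
            }
            for s in morphology.sections
        ]
    }
    return json.dumps(payload, indent=2)
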