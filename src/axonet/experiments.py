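"""Measurement protocols for the coupled-network model.

These reproduce the study's in-silico experiments: steady-state coupling
coefficients versus soma separation, input resistance, firing-pattern
classification under step currents, rebound firing, axonal action
potential propagation and conduction velocity, density sweeps over
channel multipliers, and whole-population step stimulation.

Active protocols integrate with dt = 0.02 ms by default (spike times are
self-converged well below the 0.05 ms level at this step; see the methods
note) and detect somatic/axonal spikes as upward 0 mV crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from axonet.presets import FinalModel
from axonet.solver import (
    SimulationResult,
    StimulusProtocol,
    SystemMatrices,
    integrate,
    steady_state_solver,
)

__all__ = [
    "ProtocolError",
    "CouplingMeasurement",
    "measure_coupling",
    "bin_coupling",
    "input_resistance",
    "input_resistance_dynamic",
    "rheobase",
    "FiringClassification",
    "classify_firing",
    "rebound_test",
    "PropagationResult",
    "propagation_probes",
    "propagation_test",
    "conduction_velocity",
    "SweepPoint",
    "density_sweep",
    "PopulationResponse",
    "population_step",
    "synchrony_index",
]

DT_ACTIVE = 0.02  # ms
GJ_MODE = "semi"


class ProtocolError(RuntimeError):
    """Raised when a measurement protocol cannot be evaluated."""


# ---------------------------------------------------------------------------
# passive protocols


@dataclass(frozen=True)
class CouplingMeasurement:
    """Coupling coefficient between one source-target soma pair."""

    run: int
    source_id: int
    target_id: int
    soma_separation: float  # um
    coefficient: float  # percent

    def __post_init__(self) -> None:
        if not -1e-9 <= self.coefficient <= 100.0 + 1e-9:
            raise ProtocolError(
                f"coupling coefficient {self.coefficient} outside [0, 100]%"
            )


def measure_coupling(
    system: SystemMatrices,
    n_runs: int = 50,
    current: float = -100.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Steady-state coupling coefficients from random-source injections.

    Per run a random source neuron receives a constant somatic current;
    the exact steady state is solved and the deflection of every other
    soma is expressed as a percentage of the source deflection
    (coefficients are linear in, and independent of, the current).
    Returns a tidy frame (run, source, target, separation, coefficient).
    """
    if rng is None:
        rng = np.random.default_rng()
    if current == 0:
        raise ProtocolError("injected current must be nonzero")
    solve = steady_state_solver(system)
    positions = np.asarray(system.model.layout.soma_positions)
    n = system.n_neurons
    rows = []
    for run in range(n_runs):
        src = int(rng.integers(n))
        I = np.zeros(system.n_compartments)
        I[system.soma_index[src]] = current
        dv = solve(I)[system.soma_index]
        if dv[src] == 0:
            raise ProtocolError("zero source deflection")
        cc = 100.0 * dv / dv[src]
        for tgt in range(n):
            if tgt == src:
                continue
            rows.append(
                (run, src, tgt, abs(positions[tgt] - positions[src]), cc[tgt])
            )
    return pd.DataFrame(
        rows, columns=["run", "source", "target", "separation", "coefficient"]
    )


def bin_coupling(
    df: pd.DataFrame, bin_width: float = 50.0
) -> pd.DataFrame:
    """Distance-binned quantiles of coupling coefficients.

    Mirrors the notched-bar summaries used to compare layouts against
    paired-recording data: median, quartiles and 5-95 % percentiles per
    separation bin.
    """
    edges = np.arange(0.0, df["separation"].max() + bin_width, bin_width)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df["separation"] >= lo) & (df["separation"] < hi)]["coefficient"]
        if sel.empty:
            continue
        out.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n": len(sel),
                "median": sel.median(),
                "q25": sel.quantile(0.25),
                "q75": sel.quantile(0.75),
                "p5": sel.quantile(0.05),
                "p95": sel.quantile(0.95),
            }
        )
    return pd.DataFrame(out)


def input_resistance(
    system: SystemMatrices, neuron_id: int, current: float = -100.0
) -> float:
    """Passive somatic input resistance (MOhm) from the exact steady state."""
    I = np.zeros(system.n_compartments)
    I[system.soma_index[neuron_id]] = current
    dv = steady_state_solver(system)(I)
    return 1000.0 * dv[system.soma_index[neuron_id]] / current  # mV/pA -> MOhm


def input_resistance_dynamic(
    fm: FinalModel,
    neuron_id: int,
    current: float = -100.0,
    duration: float = 200.0,
    dt: float = 0.05,
) -> float:
    """Input resistance of the active model from a hyperpolarising step.

    Integrates the full active network, injects ``current`` for
    ``duration`` ms and reads the deflection from the trace mean over the
    last tenth of the step (the subthreshold response has settled there).
    """
    res = integrate(
        fm.system,
        fm.densities,
        StimulusProtocol.step(neuron_id, current, 10.0, duration),
        dt=dt,
        t_stop=duration + 20.0,
        probes=[(neuron_id, 0.0)],
        ghk_constants=fm.ghk,
        gj_mode=GJ_MODE,
    )
    v = res.trace(neuron_id)
    t = res.t
    base = v[(t >= 5.0) & (t < 10.0)].mean()
    tail = v[(t >= 10.0 + 0.9 * duration) & (t < 10.0 + duration)].mean()
    return 1000.0 * (tail - base) / current


# ---------------------------------------------------------------------------
# single-neuron active protocols


def rheobase(
    fm: FinalModel,
    neuron_id: int,
    increment: float = 10.0,
    start: float = 10.0,
    stop: float = 400.0,
    duration: float = 200.0,
    dt: float = DT_ACTIVE,
) -> float:
    """Minimum step current (pA) that elicits a somatic spike.

    Scans upward in ``increment`` steps and returns the first amplitude
    producing at least one spike during the step window.
    """
    amp = start
    while amp <= stop + 1e-9:
        res = integrate(
            fm.system,
            fm.densities,
            StimulusProtocol.step(neuron_id, amp, 10.0, duration),
            dt=dt,
            t_stop=duration + 30.0,
            probes=[(neuron_id, 0.0)],
            ghk_constants=fm.ghk,
            gj_mode=GJ_MODE,
        )
        if len(res.spikes(neuron_id)) > 0:
            return amp
        amp += increment
    raise ProtocolError(f"no spike up to {stop} pA")


@dataclass(frozen=True)
class FiringClassification:
    """Firing-pattern label over a set of step-current levels.

    ``single``: exactly one spike at every suprathreshold level;
    ``repetitive``: more than one spike at some level; ``unstable``:
    firing before stimulus onset or persisting after offset; ``none``:
    no spikes at any level.
    """

    label: str
    spike_counts: dict = field(default_factory=dict)  # level -> count in window


def classify_firing(
    fm: FinalModel,
    neuron_id: int,
    levels: tuple = (50.0, 100.0, 200.0, 300.0),
    duration: float = 200.0,
    dt: float = DT_ACTIVE,
) -> FiringClassification:
    """Classify step-current firing at the soma over ``levels``."""
    onset = 10.0
    counts = {}
    unstable = False
    for level in levels:
        res = integrate(
            fm.system,
            fm.densities,
            StimulusProtocol.step(neuron_id, level, onset, duration),
            dt=dt,
            t_stop=duration + 60.0,
            probes=[(neuron_id, 0.0)],
            ghk_constants=fm.ghk,
            gj_mode=GJ_MODE,
        )
        sp = res.spikes(neuron_id)
        in_window = sp[(sp >= onset) & (sp <= onset + duration)]
        counts[level] = len(in_window)
        if len(sp[sp < onset]) or len(sp[sp > onset + duration + 5.0]):
            unstable = True
    supra = [c for c in counts.values() if c > 0]
    if unstable:
        label = "unstable"
    elif not supra:
        label = "none"
    elif all(c == 1 for c in supra):
        label = "single"
    else:
        label = "repetitive"
    return FiringClassification(label=label, spike_counts=counts)


def rebound_test(
    fm: FinalModel,
    neuron_id: int,
    background: float | None = None,
    pulse: float = -200.0,
    pulse_ms: float = 20.0,
    dt: float = DT_ACTIVE,
) -> bool:
    """Post-inhibitory rebound during depolarisation.

    True when a brief hyperpolarising pulse riding on a depolarising
    background triggers a spike within 20 ms of pulse offset, while the
    same pulse delivered from rest does not.  The background defaults to
    30 pA above the cell's rheobase (rebound requires the cell to be held
    depolarised near firing threshold; the junction-shunted rheobase
    varies severalfold between network realisations).
    """
    onset, bg_dur = 10.0, 300.0
    if background is None:
        background = rheobase(fm, neuron_id, increment=20.0, start=20.0, dt=dt) + 30.0
    p_on = 160.0
    p_off = p_on + pulse_ms
    with_bg = StimulusProtocol(
        steps=(
            (neuron_id, background, onset, bg_dur, 0.0),
            (neuron_id, pulse, p_on, pulse_ms, 0.0),
        )
    )
    res = integrate(
        fm.system, fm.densities, with_bg, dt=dt, t_stop=bg_dur + 30.0,
        probes=[(neuron_id, 0.0)], ghk_constants=fm.ghk, gj_mode=GJ_MODE,
    )
    sp = res.spikes(neuron_id)
    rebound = np.any((sp > p_off) & (sp <= p_off + 20.0))

    from_rest = StimulusProtocol.step(neuron_id, pulse, p_on, pulse_ms)
    res0 = integrate(
        fm.system, fm.densities, from_rest, dt=dt, t_stop=bg_dur + 30.0,
        probes=[(neuron_id, 0.0)], ghk_constants=fm.ghk, gj_mode=GJ_MODE,
    )
    sp0 = res0.spikes(neuron_id)
    rest_spike = np.any((sp0 > p_off) & (sp0 <= p_off + 20.0))
    return bool(rebound and not rest_spike)


# ---------------------------------------------------------------------------
# propagation


@dataclass(frozen=True)
class PropagationResult:
    """Spike arrival along one axon after a brief somatic pulse."""

    neuron_id: int
    success: bool  # spike at the most distal probe within the window
    arrival: dict  # arc distance -> first spike time (ms), or absent
    result: SimulationResult = field(repr=False)


def propagation_probes(
    fm: FinalModel,
    neuron_id: int,
    fine_spacing: float = 20.0,
    fine_extent: float = 400.0,
    coarse_spacing: float = 100.0,
) -> list[tuple[int, float]]:
    """Soma + fine probes over the junction region + coarse to the tip."""
    axon_len = fm.model.layout.morphologies[neuron_id].cable_length
    probes = [(neuron_id, 0.0)]
    a = fine_spacing
    while a <= min(fine_extent, axon_len):
        probes.append((neuron_id, a))
        a += fine_spacing
    a = fine_extent + coarse_spacing
    while a < axon_len:
        probes.append((neuron_id, a))
        a += coarse_spacing
    return probes


def propagation_test(
    fm: FinalModel,
    neuron_id: int,
    pulse: float = 400.0,
    pulse_ms: float = 2.0,
    window: float = 50.0,
    dt: float = DT_ACTIVE,
) -> PropagationResult:
    """Whether a somatically initiated spike reaches the distal axon."""
    probes = propagation_probes(fm, neuron_id)
    res = integrate(
        fm.system,
        fm.densities,
        StimulusProtocol.step(neuron_id, pulse, 5.0, pulse_ms),
        dt=dt,
        t_stop=window,
        probes=probes,
        ghk_constants=fm.ghk,
        gj_mode=GJ_MODE,
    )
    arrival = {}
    for (nid, arc), times in res.all_spikes().items():
        if len(times):
            arrival[arc] = float(times[0])
    distal = max(a for _, a in probes)
    return PropagationResult(
        neuron_id=neuron_id,
        success=distal in arrival,
        arrival=arrival,
        result=res,
    )


def conduction_velocity(
    prop: PropagationResult, region: tuple[float, float] = (20.0, 400.0)
) -> float:
    """Conduction velocity (m/s) from a linear fit over ``region``.

    Fits probe arc distance against first-spike time for probes inside
    the region; requires at least two probes with detected spikes.
    """
    lo, hi = region
    arcs = np.array(sorted(a for a in prop.arrival if lo <= a <= hi))
    if len(arcs) < 2:
        raise ProtocolError("fewer than 2 probes with spikes in the region")
    times = np.array([prop.arrival[a] for a in arcs])
    slope = np.polyfit(times, arcs, 1)[0]  # um/ms
    return slope / 1000.0  # -> m/s


# ---------------------------------------------------------------------------
# density sweep


@dataclass(frozen=True)
class SweepPoint:
    """Phenotype summary at one multiplier combination."""

    multipliers: dict
    replicates: int
    fraction_single: float
    fraction_repetitive: float
    propagation_success: float
    rebound_fraction: float


def density_sweep(
    grids: dict[str, list] | None = None,
    replicates: int = 10,
    seed: int = 0,
    levels: tuple = (50.0, 100.0, 200.0, 300.0),
    initial_segment: bool = False,
    build=None,
    dt: float = DT_ACTIVE,
) -> list[SweepPoint]:
    """Sweep channel-density multipliers and classify the phenotypes.

    At every grid point a fresh coupled network (with per-neuron density
    noise) is built per replicate, and one sampled neuron is scored for
    firing class, axonal propagation and rebound.  The full grid of the
    study (multiplier sets per channel) is combinatorially large; callers
    are expected to pass reduced ``grids`` for desk-scale use.
    """
    from itertools import product

    from axonet.channels import multiplier_table
    from axonet.presets import final_network

    if build is None:
        build = final_network
    if grids is None:
        grids = {k: v["tested"] for k, v in multiplier_table().items()}
    kinds = sorted(grids)
    points = []
    ss = np.random.SeedSequence(seed)
    for combo in product(*(grids[k] for k in kinds)):
        mult = dict(zip(kinds, combo))
        labels, props, rebs = [], [], []
        for rep in range(replicates):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            fm = build(
                child, multipliers=mult, initial_segment=initial_segment
            )
            neuron = int(
                np.random.default_rng(child).integers(6, fm.model.n_neurons - 6)
            )
            cls = classify_firing(fm, neuron, levels=levels, dt=dt)
            labels.append(cls.label)
            if mult.get("na", 1.0) > 0:
                props.append(propagation_test(fm, neuron, dt=dt).success)
                rebs.append(rebound_test(fm, neuron, dt=dt))
            else:
                props.append(False)
                rebs.append(False)
        points.append(
            SweepPoint(
                multipliers=mult,
                replicates=replicates,
                fraction_single=np.mean([l == "single" for l in labels]),
                fraction_repetitive=np.mean([l == "repetitive" for l in labels]),
                propagation_success=np.mean(props),
                rebound_fraction=np.mean(rebs),
            )
        )
    return points


# ---------------------------------------------------------------------------
# population protocols


@dataclass(frozen=True)
class PopulationResponse:
    """Population step response: rasters, rate and synchrony."""

    level: float
    spikes: dict  # neuron_id -> spike-time array
    fraction_firing: float
    mean_frequency: float  # Hz over neurons with >= 2 spikes
    synchrony: float  # mean resultant length in [0, 1]


def synchrony_index(spike_trains: list[np.ndarray]) -> float:
    """Mean resultant length of spike phases on the population cycle.

    The population period is the mean inter-spike interval pooled over
    neurons; each spike is assigned a phase on that cycle and the length
    of the mean phase vector is returned (1 = perfectly locked, 0 =
    phases uniformly spread).  Returns 0 when fewer than two neurons have
    inter-spike intervals.
    """
    isis = np.concatenate(
        [np.diff(t) for t in spike_trains if len(t) >= 2]
        or [np.array([])]
    )
    if isis.size == 0:
        return 0.0
    period = float(np.mean(isis))
    phases = np.concatenate([t for t in spike_trains if len(t)]) / period
    vec = np.exp(2j * np.pi * phases)
    return float(np.abs(vec.mean()))


def population_step(
    fm: FinalModel,
    level: float,
    duration: float = 200.0,
    dt: float = DT_ACTIVE,
) -> PopulationResponse:
    """Inject the same step into every soma and summarise the response."""
    onset = 10.0
    n = fm.model.n_neurons
    res = integrate(
        fm.system,
        fm.densities,
        StimulusProtocol.population_step(n, level, onset, duration),
        dt=dt,
        t_stop=duration + 30.0,
        probes=[(i, 0.0) for i in range(n)],
        ghk_constants=fm.ghk,
        gj_mode=GJ_MODE,
    )
    spikes = {}
    for (nid, _), times in res.all_spikes().items():
        spikes[nid] = times[(times >= onset) & (times <= onset + duration)]
    freqs = [
        1000.0 * (len(t) - 1) / (t[-1] - t[0]) for t in spikes.values() if len(t) >= 2
    ]
    return PopulationResponse(
        level=level,
        spikes=spikes,
        fraction_firing=float(np.mean([len(t) > 0 for t in spikes.values()])),
        mean_frequency=float(np.mean(freqs)) if freqs else 0.0,
        synchrony=synchrony_index(list(spikes.values())),
    )
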