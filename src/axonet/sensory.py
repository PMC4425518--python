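"""Stochastic sensory drive: trigeminal interneuron (tIN) spike trains.

Head-skin stimulation recruits a population of ~20 tINs which excite the
dINs through glutamatergic synapses.  The tIN model is phenomenological:
the number of spikes a tIN fires at normalised stimulus strength s (100 %
= swimming threshold) is drawn from p(N = n | S = s), anchored by
recorded behaviour:

* p(N = 1 | S = 95)  = 0.5  (mean single-spike threshold),
* p(N = 1 | S = 100) = 1.0  (all tINs fire once at threshold),
* p(N = 1 | S > 120) = 0.3  (at strong stimuli most tINs fire bursts but
  a fixed minority still fires once),

with piecewise-linear interpolation in s between anchors and the
remaining probability mass on 0 spikes (weak stimuli) or on bursts of
2-5 spikes (strong stimuli).  Spike times are drawn independently per
spike index k from N(mu_k, sigma_k) and sorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from axonet.morphology import ConfigurationError
from axonet.presets import FinalModel
from axonet.solver import _SynapticDrive, integrate

__all__ = [
    "TINModel",
    "SynapseSpec",
    "sample_spike_count",
    "sample_spike_times",
    "sample_population_trains",
    "epsp_conductance",
    "RecruitmentCurve",
    "recruitment_experiment",
    "calibrate_synaptic_weight",
]

MAX_SPIKES = 5


@dataclass(frozen=True)
class TINModel:
    """Spike-count and spike-timing model of one tIN.

    ``burst_weights`` distribute the multi-spike probability mass over
    n = 2..5 spikes at strong stimuli.  ``mu``/``sigma`` give the mean and
    standard deviation (ms) of the k-th spike time.
    """

    population_size: int = 20
    threshold_half: float = 95.0  # s where p(1) = 0.5
    threshold_full: float = 100.0  # s where p(1) = 1.0
    strong_stimulus: float = 120.0  # s beyond which p(1) = 0.3
    p_single_strong: float = 0.3
    burst_weights: tuple = (0.4, 0.3, 0.2, 0.1)  # n = 2, 3, 4, 5
    mu: tuple = (5.0, 15.0, 25.0, 35.0, 45.0)  # ms
    sigma: tuple = (2.0, 2.0, 2.0, 2.0, 2.0)  # ms

    def __post_init__(self) -> None:
        if not self.threshold_half < self.threshold_full < self.strong_stimulus:
            raise ConfigurationError("stimulus anchors must be ordered")
        if abs(sum(self.burst_weights) - 1.0) > 1e-9:
            raise ConfigurationError("burst weights must sum to 1")
        if len(self.mu) != MAX_SPIKES or len(self.sigma) != MAX_SPIKES:
            raise ConfigurationError(f"need {MAX_SPIKES} spike-time entries")
        if any(s <= 0 for s in self.sigma):
            raise ConfigurationError("sigma_k must be > 0")

    def p_single(self, s: float) -> float:
        """p(N = 1 | S = s), piecewise linear through the anchors."""
        lo = 2.0 * self.threshold_half - self.threshold_full  # p(1) = 0 here
        if s <= lo:
            return 0.0
        if s <= self.threshold_full:
            return (s - lo) / (self.threshold_full - lo)
        if s <= self.strong_stimulus:
            f = (s - self.threshold_full) / (self.strong_stimulus - self.threshold_full)
            return 1.0 + f * (self.p_single_strong - 1.0)
        return self.p_single_strong

    def pmf(self, s: float) -> dict[int, float]:
        """Full spike-count distribution p(N = n | S = s); sums to one."""
        p1 = self.p_single(s)
        rest = 1.0 - p1
        if s <= self.threshold_full:
            pmf = {0: rest, 1: p1}
        else:
            pmf = {0: 0.0, 1: p1}
            for n, w in enumerate(self.burst_weights, start=2):
                pmf[n] = rest * w
        return pmf


def sample_spike_count(
    model: TINModel, s: float, rng: np.random.Generator
) -> int:
    """Draw a spike count from p(N | S = s)."""
    if s < 0:
        raise ConfigurationError("stimulus must be >= 0")
    pmf = model.pmf(s)
    counts = sorted(pmf)
    probs = np.array([pmf[c] for c in counts])
    return int(rng.choice(counts, p=probs / probs.sum()))


def sample_spike_times(
    model: TINModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` spike times (ms, sorted ascending)."""
    if n < 0:
        raise ConfigurationError("spike count must be >= 0")
    if n > MAX_SPIKES:
        raise ConfigurationError(
            f"spike count {n} exceeds the configured table of {MAX_SPIKES}"
        )
    times = np.array(
        [rng.normal(model.mu[k], model.sigma[k]) for k in range(n)]
    )
    return np.sort(times)


def sample_population_trains(
    model: TINModel, s: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Spike trains for the whole tIN population at stimulus ``s``."""
    return [
        sample_spike_times(model, sample_spike_count(model, s, rng), rng)
        for _ in range(model.population_size)
    ]


@dataclass(frozen=True)
class SynapseSpec:
    """Glutamatergic EPSP conductance transient (difference of exponentials)."""

    peak_conductance: float = 0.3  # nS per tIN spike, on every dIN
    tau_rise: float = 1.0  # ms
    tau_decay: float = 5.0  # ms
    reversal_potential: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ConfigurationError("synaptic time constants must be > 0")
        if self.tau_rise >= self.tau_decay:
            raise ConfigurationError("tau_rise must be < tau_decay")
        if self.peak_conductance < 0:
            raise ConfigurationError("peak conductance must be >= 0")

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak conductance waveform at times ``t`` (ms) after a spike."""
        t = np.asarray(t, dtype=float)
        tr, td = self.tau_rise, self.tau_decay
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        norm = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        out = np.where(t > 0, (np.exp(-t / td) - np.exp(-t / tr)) / norm, 0.0)
        return out


def epsp_conductance(
    trains: list[np.ndarray], synapse: SynapseSpec, t: np.ndarray
) -> np.ndarray:
    """Total synaptic conductance (nS) on one dIN soma over time.

    Every tIN contacts every dIN with the same synapse, so all dINs see
    the identical waveform: the sum of one kernel per tIN spike.
    """
    g = np.zeros_like(np.asarray(t, dtype=float))
    for train in trains:
        for ts in train:
            g += synapse.peak_conductance * synapse.kernel(t - ts)
    return g


@dataclass(frozen=True)
class RecruitmentCurve:
    """Fraction of dINs recruited per stimulus level."""

    stimulus: tuple
    fraction: tuple  # mean over replicates
    coupled: bool
    per_replicate: tuple = ()  # tuple of tuples, replicate-major

    @property
    def max_slope(self) -> float:
        """Steepest rise of the recruitment curve per stimulus unit."""
        s = np.asarray(self.stimulus, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        return float(np.max(np.diff(f) / np.diff(s)))


def _run_drive(
    fm: FinalModel,
    g_of_t,
    e_rev: float,
    t_stop: float,
    dt: float,
) -> float:
    """Fraction of dINs firing >= 1 somatic spike under a conductance drive."""
    n = fm.model.n_neurons
    res = integrate(
        fm.system,
        fm.densities,
        syn_drive=_SynapticDrive(g_of_t, e_rev),
        dt=dt,
        t_stop=t_stop,
        probes=[(i, 0.0) for i in range(n)],
        ghk_constants=fm.ghk,
        gj_mode="semi",
    )
    fired = [len(times) > 0 for times in res.all_spikes().values()]
    return float(np.mean(fired))


def recruitment_experiment(
    fm: FinalModel,
    tin_model: TINModel | None = None,
    synapse: SynapseSpec | None = None,
    stimulus_grid: tuple = (70.0, 85.0, 100.0, 115.0, 130.0),
    replicates: int = 3,
    seed: int = 0,
    t_stop: float = 80.0,
    dt: float = 0.02,
) -> RecruitmentCurve:
    """Recruitment of the dIN population by graded sensory drive.

    Per stimulus level and replicate, all tIN spike trains are sampled,
    converted to a common EPSP conductance waveform on every dIN soma,
    and the network is integrated; the curve reports the mean fraction of
    dINs that fire at least once.
    """
    if tin_model is None:
        tin_model = TINModel()
    if synapse is None:
        synapse = SynapseSpec()
    rng = np.random.default_rng(seed)
    fractions = np.zeros((replicates, len(stimulus_grid)))
    for rep in range(replicates):
        for si, s in enumerate(stimulus_grid):
            trains = sample_population_trains(tin_model, s, rng)
            spikes = (
                np.concatenate(trains) if any(len(t) for t in trains) else np.array([])
            )
            if spikes.size == 0:
                fractions[rep, si] = 0.0
                continue

            def g_of_t(t, _spikes=spikes):
                return synapse.peak_conductance * np.sum(
                    synapse.kernel(t - _spikes)
                )

            fractions[rep, si] = _run_drive(
                fm, g_of_t, synapse.reversal_potential, t_stop, dt
            )
    return RecruitmentCurve(
        stimulus=tuple(stimulus_grid),
        fraction=tuple(fractions.mean(axis=0)),
        coupled=len(fm.model.gap_junctions) > 0,
        per_replicate=tuple(tuple(row) for row in fractions),
    )


def calibrate_synaptic_weight(
    fm: FinalModel,
    tin_model: TINModel | None = None,
    synapse: SynapseSpec | None = None,
    target_fraction: float = 0.95,
    seed: int = 0,
    lo: float = 0.02,
    hi: float = 2.0,
    iters: int = 8,
    dt: float = 0.02,
) -> float:
    """Per-spike peak conductance (nS) recruiting the population at s = 100.

    At the threshold stimulus every tIN fires exactly one spike, so the
    drive is deterministic up to spike timing; bisect the peak conductance
    until the recruited fraction reaches ``target_fraction``.  The result
    is meant to be recorded in the experiment configuration, not
    hard-coded.
    """
    if tin_model is None:
        tin_model = TINModel()
    if synapse is None:
        synapse = SynapseSpec()
    rng = np.random.default_rng(seed)
    trains = sample_population_trains(tin_model, 100.0, rng)
    spikes = np.concatenate(trains)

    def fraction_at(g_peak: float) -> float:
        def g_of_t(t):
            return g_peak * np.sum(synapse.kernel(t - spikes))

        return _run_drive(fm, g_of_t, synapse.reversal_potential, 80.0, dt)

    if fraction_at(hi) < target_fraction:
        raise ConfigurationError("upper bound too small to recruit the population")
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        if fraction_at(mid) >= target_fraction:
            hi = mid
        else:
            lo = mid
    return float(hi)
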