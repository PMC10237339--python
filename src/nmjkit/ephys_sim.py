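"""Synthetic intracellular NMJ recordings with ground truth.

This module generates voltage traces that emulate sharp-electrode recordings
from mouse diaphragm neuromuscular junctions: spontaneous miniature endplate
potentials (mEPPs), nerve-evoked endplate potentials (EPPs) at 0.1 Hz, and
2-minute 20 Hz stimulus trains with depletion-driven amplitude rundown.

Group means (mEPP/EPP amplitude, mEPP rate) are parameterized per age and
genotype (wildtype vs. hSOD1-G93A).  Published group means are shipped in
``presets/ephys_scenarios.json`` with ``printed`` flags; values the source
study did not print are interpolated along the reported age trajectories and
flagged as assumptions in the same file.

Conventions
-----------
* Amplitudes in mV, times in s, rates in events/s, membrane potential in mV
  (negative at rest).
* A "true" event amplitude is defined at the -70 mV reference potential; the
  amplitude actually inserted into the trace is scaled by ``|RMP(t)| / 70`` so
  that the standard correction back to -70 mV recovers the reference value.
* All randomness flows through a single ``numpy.random.Generator`` seeded by
  the caller; fixed seeds reproduce traces bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "EphysScenario",
    "StimulusProtocol",
    "Trace",
    "EventGroundTruth",
    "build_scenario",
    "depolarized_fiber_scenario",
    "spontaneous_protocol",
    "evoked_protocol",
    "train_protocol",
    "simulate_recording",
    "simulate_train",
    "epp_for_quantal_content",
    "quantal_content_of_means",
    "steady_state_pool",
    "load_scenario_presets",
    "write_trace_csv",
    "write_trace_h5",
    "read_trace_h5",
]

#: Valid ages (weeks) per genotype.  "sym" = early-symptomatic stage
#: (18-22 weeks in hSOD1-G93A; the age-matched wildtype group is 20 weeks).
WT_AGES = (2, 4, 8, 12, 16, 20)
SOD1_AGES = (2, 4, 8, 12, 16, 18, 19, 20, 21, 22)

DEFAULT_SAMPLING_RATE = 20_000.0  # Hz; resolves sub-ms rise times


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EphysScenario:
    """Generator parameter set for one age x genotype group.

    ``mepp_mean`` and ``epp_mean`` are true mean amplitudes at the -70 mV
    reference.  ``pool_size`` (N0), ``release_fraction`` (p) and
    ``replenish_rate`` (r, per inter-stimulus interval) drive the
    depletion/replenishment recursion used for 20 Hz trains.
    """

    age_weeks: int
    genotype: str
    mepp_mean: float          # mV
    mepp_cv: float            # dimensionless
    mepp_rate: float          # events/s
    epp_mean: float           # mV
    epp_cv: float             # between-NMJ CV of evoked amplitude
    epp_within_cv: float      # stimulus-to-stimulus CV within one NMJ
    rise_time: float          # ms, 0-100% (onset to peak)
    decay_tau: float          # ms
    rmp_mean: float           # mV, negative
    rmp_drift_sd: float       # mV per minute of random walk
    noise_sd: float           # mV
    pool_size: int            # quanta, N0
    release_fraction: float   # p in (0, 1]
    replenish_rate: float     # r in [0, 1]
    n_nmjs: int = 50
    bound_rmp: bool = True    # keep the RMP track below -55 mV
    label: str = ""

    def __post_init__(self) -> None:
        if self.mepp_mean <= 0:
            raise ValueError("mepp_mean must be positive")
        if self.rmp_mean >= -50:
            raise ValueError("rmp_mean must be more negative than -50 mV")
        if not 0 < self.release_fraction <= 1:
            raise ValueError("release_fraction must be in (0, 1]")
        if not 0 <= self.replenish_rate <= 1:
            raise ValueError("replenish_rate must be in [0, 1]")
        if self.rise_time > 1.5:
            raise ValueError("rise_time must be <= 1.5 ms (focal-recording criterion)")
        if self.rise_time >= self.decay_tau:
            raise ValueError("rise_time must be shorter than decay_tau")


@dataclass(frozen=True)
class StimulusProtocol:
    """Recording protocol: what is stimulated, when, and for how long."""

    kind: str                  # "spontaneous" | "evoked_0p1Hz" | "train_20Hz"
    duration: float            # s
    stim_times: tuple = ()     # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("protocol duration must be positive")
        if any(t < 0 or t >= self.duration for t in self.stim_times):
            raise ValueError("stimulus times must lie within the recording")


@dataclass
class Trace:
    """A single-channel membrane-potential recording."""

    sampling_rate: float            # Hz
    samples: np.ndarray             # mV
    stim_times: np.ndarray          # s
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class EventGroundTruth:
    """True synaptic events underlying a synthetic trace."""

    event_times: np.ndarray          # s
    amplitudes: np.ndarray           # mV, as inserted into the trace
    amplitudes_at_minus70: np.ndarray  # mV, at the -70 mV reference
    rmp_at_event: np.ndarray         # mV
    kind: np.ndarray                 # "mEPP" | "EPP"
    quanta_per_stimulus: Optional[np.ndarray] = None  # trains only

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "event_time": self.event_times,
                "amplitude": self.amplitudes,
                "amplitude_at_minus70": self.amplitudes_at_minus70,
                "rmp_at_event": self.rmp_at_event,
                "kind": self.kind,
            }
        )
        return df


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def load_scenario_presets() -> dict:
    """Return the raw preset table (see ``presets/ephys_scenarios.json``)."""
    text = resources.files("nmjkit.presets").joinpath("ephys_scenarios.json").read_text()
    return json.loads(text)


def _age_key(age_weeks: int, genotype: str) -> str:
    if genotype == "WT":
        if age_weeks not in WT_AGES:
            raise ValueError(
                f"no WT group at {age_weeks} weeks; valid ages are {WT_AGES}"
            )
        return "sym" if age_weeks == 20 else str(age_weeks)
    if genotype == "SOD1":
        if age_weeks not in SOD1_AGES:
            raise ValueError(
                f"no SOD1 group at {age_weeks} weeks; valid ages are "
                "2, 4, 8, 12, 16 or 18-22 (early symptomatic)"
            )
        return "sym" if age_weeks >= 18 else str(age_weeks)
    raise ValueError(f"unknown genotype {genotype!r}; expected 'WT' or 'SOD1'")


def build_scenario(age_weeks: int, genotype: str) -> EphysScenario:
    """Build the generator scenario for one age x genotype group.

    Published group means are used where available.  The 16-week SOD1 group is
    parameterized through its *relative* effects: the preset stores the
    reported quantal-content and mEPP-frequency reductions versus wildtype,
    and this builder derives the absolute evoked amplitude by inverting the
    non-linear-summation formula (see :func:`epp_for_quantal_content`).

    Raises
    ------
    ValueError
        If the age/genotype combination was not part of the study design.
    """
    presets = load_scenario_presets()
    key = _age_key(age_weeks, genotype)
    entry = dict(presets[genotype][key])
    defaults = presets["defaults"]

    def get(name, fallback=None):
        return entry.get(name, defaults.get(name, fallback))

    mepp_mean = entry["mepp_mean"]
    mepp_rate = entry.get("mepp_rate")
    epp_mean = entry.get("epp_mean")

    if "qc_reduction_vs_wt" in entry:
        # Encode the printed relative effects against the same-age WT group.
        wt = build_scenario(age_weeks, "WT")
        qc_wt = quantal_content_of_means(wt.epp_mean, wt.mepp_mean)
        qc_target = qc_wt * (1.0 - entry["qc_reduction_vs_wt"])
        epp_mean = epp_for_quantal_content(qc_target, mepp_mean)
        mepp_rate = wt.mepp_rate * (1.0 - entry["rate_reduction_vs_wt"])

    release_fraction = get("release_fraction")
    # Vesicle pool sized so that the first train EPP matches the single-shock
    # quantal content of the group.
    qc = quantal_content_of_means(epp_mean, mepp_mean)
    pool_size = max(1, round(qc / release_fraction))

    return EphysScenario(
        age_weeks=age_weeks,
        genotype=genotype,
        mepp_mean=mepp_mean,
        mepp_cv=get("mepp_cv"),
        mepp_rate=mepp_rate,
        epp_mean=epp_mean,
        epp_cv=get("epp_cv"),
        epp_within_cv=get("epp_within_cv"),
        rise_time=get("rise_time"),
        decay_tau=get("decay_tau"),
        rmp_mean=get("rmp_mean"),
        rmp_drift_sd=get("rmp_drift_sd"),
        noise_sd=get("noise_sd"),
        pool_size=pool_size,
        release_fraction=release_fraction,
        replenish_rate=get("replenish_rate"),
        n_nmjs=get("n_nmjs"),
        label=f"{genotype}-{key}",
    )


def depolarized_fiber_scenario() -> EphysScenario:
    """Scenario of an unhealthy fiber whose RMP drifts above -50 mV.

    Used to exercise the rejection rule: the RMP random walk is unbounded and
    starts near the -50 mV criterion, so recordings routinely depolarize past
    it mid-recording.
    """
    presets = load_scenario_presets()
    spec = presets["special"]["depolarized_fiber"]
    genotype, key = spec["base"]
    base = build_scenario(int(key), genotype)
    return replace(
        base,
        rmp_mean=spec["rmp_mean"],
        rmp_drift_sd=spec["rmp_drift_sd"],
        bound_rmp=spec["bound_rmp"],
        label="depolarized_fiber",
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def spontaneous_protocol(duration: float = 30.0) -> StimulusProtocol:
    """30 s of spontaneous mEPP recording (no stimulation)."""
    return StimulusProtocol("spontaneous", duration, ())


def evoked_protocol(n_stim: int = 3, interval: float = 10.0, first: float = 5.0) -> StimulusProtocol:
    """Three EPPs evoked at 0.1 Hz (one stimulus every 10 s)."""
    stim = tuple(first + i * interval for i in range(n_stim))
    return StimulusProtocol("evoked_0p1Hz", stim[-1] + interval / 2, stim)


def train_protocol(rate_hz: float = 20.0, duration_s: float = 120.0, first: float = 0.5) -> StimulusProtocol:
    """Continuous 20 Hz train for 2 min (2400 stimuli)."""
    n = int(round(rate_hz * duration_s))
    stim = tuple(first + i / rate_hz for i in range(n))
    return StimulusProtocol("train_20Hz", first + duration_s + 0.5, stim)


# ---------------------------------------------------------------------------
# waveform and RMP machinery
# ---------------------------------------------------------------------------

def event_kernel(rise_ms: float, decay_ms: float, sampling_rate: float) -> np.ndarray:
    """Difference-of-exponentials synaptic waveform, peak-normalized to 1.

    The 0-100% rise time is operationalized as onset-to-peak: the fast time
    constant is solved numerically so that the kernel peaks exactly
    ``rise_ms`` after onset.
    """
    if rise_ms <= 0 or decay_ms <= 0 or rise_ms >= decay_ms:
        raise ValueError("need 0 < rise_ms < decay_ms")
    td = decay_ms

    def t_peak(tr):
        return tr * td / (td - tr) * np.log(td / tr)

    tr = brentq(lambda x: t_peak(x) - rise_ms, 1e-6 * td, (1 - 1e-9) * td)
    t = np.arange(0.0, 8.0 * td, 1000.0 / sampling_rate)  # ms grid
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def _rmp_track(scenario: EphysScenario, n_samples: int, sampling_rate: float,
               rng: np.random.Generator) -> np.ndarray:
    """Slow RMP drift: Gaussian random walk on 1-minute knots, interpolated."""
    duration = n_samples / sampling_rate
    n_knots = int(np.ceil(duration / 60.0)) + 1
    steps = rng.normal(0.0, scenario.rmp_drift_sd, n_knots)
    steps[0] = 0.0
    walk = scenario.rmp_mean + np.cumsum(steps)
    knot_t = np.arange(n_knots) * 60.0
    t = np.arange(n_samples) / sampling_rate
    rmp = np.interp(t, knot_t, walk)
    if scenario.bound_rmp:
        # healthy-fiber presets stay comfortably below the -50 mV criterion
        rmp = np.minimum(rmp, -55.0)
    return rmp


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _add_events(samples: np.ndarray, kernel: np.ndarray, indices: np.ndarray,
                amplitudes: np.ndarray) -> None:
    n = len(samples)
    for i, a in zip(indices, amplitudes):
        stop = min(n, i + len(kernel))
        samples[i:stop] += a * kernel[: stop - i]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_recording(
    scenario: EphysScenario,
    protocol: StimulusProtocol,
    seed: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> tuple[Trace, EventGroundTruth]:
    """Simulate one recording under ``protocol``.

    Spontaneous mEPPs arise as a homogeneous Poisson process at
    ``scenario.mepp_rate`` with log-normal amplitudes (stated mean and CV at
    the -70 mV reference).  Evoked EPPs are placed at the protocol's stimulus
    times; their amplitude combines a per-NMJ level (CV ``epp_cv``) with
    stimulus-to-stimulus jitter (CV ``epp_within_cv``).  Gaussian noise of
    ``noise_sd`` is added throughout.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if protocol.kind == "train_20Hz":
        return simulate_train(scenario, seed, sampling_rate)

    # independent substreams per component, so e.g. the number of spontaneous
    # events drawn never shifts the evoked-amplitude stream (keeps paired
    # cross-scenario simulations with a shared seed actually paired)
    rng_rmp, rng_mepp, rng_epp, rng_noise = (
        np.random.default_rng([seed, j]) for j in range(4)
    )
    n = int(round(protocol.duration * sampling_rate))
    rmp = _rmp_track(scenario, n, sampling_rate, rng_rmp)
    samples = rmp.copy()
    kernel = event_kernel(scenario.rise_time, scenario.decay_tau, sampling_rate)

    times, amps, amps70, rmps, kinds = [], [], [], [], []

    # spontaneous mEPPs
    if scenario.mepp_rate > 0:
        n_ev = rng_mepp.poisson(scenario.mepp_rate * protocol.duration)
        ev_t = np.sort(rng_mepp.uniform(0.0, protocol.duration, n_ev))
        mu, sig = _lognormal_params(scenario.mepp_mean, scenario.mepp_cv)
        a70 = rng_mepp.lognormal(mu, sig, n_ev)
        idx = np.minimum((ev_t * sampling_rate).astype(int), n - 1)
        a = a70 * np.abs(rmp[idx]) / 70.0
        _add_events(samples, kernel, idx, a)
        times.append(ev_t)
        amps.append(a)
        amps70.append(a70)
        rmps.append(rmp[idx])
        kinds.append(np.repeat("mEPP", n_ev))

    # evoked EPPs
    if protocol.stim_times:
        stim = np.asarray(protocol.stim_times)
        level = scenario.epp_mean * rng_epp.lognormal(
            *_lognormal_params(1.0, scenario.epp_cv)
        )
        a70 = level * rng_epp.lognormal(
            *_lognormal_params(1.0, scenario.epp_within_cv), len(stim)
        )
        idx = np.minimum((stim * sampling_rate).astype(int), n - 1)
        a = a70 * np.abs(rmp[idx]) / 70.0
        _add_events(samples, kernel, idx, a)
        times.append(stim)
        amps.append(a)
        amps70.append(a70)
        rmps.append(rmp[idx])
        kinds.append(np.repeat("EPP", len(stim)))

    if scenario.noise_sd > 0:
        samples += rng_noise.normal(0.0, scenario.noise_sd, n)

    def cat(parts, dtype=float):
        return np.concatenate(parts) if parts else np.array([], dtype=dtype)

    truth = EventGroundTruth(
        event_times=cat(times),
        amplitudes=cat(amps),
        amplitudes_at_minus70=cat(amps70),
        rmp_at_event=cat(rmps),
        kind=cat(kinds, dtype="U4"),
    )
    trace = Trace(
        sampling_rate=sampling_rate,
        samples=samples,
        stim_times=np.asarray(protocol.stim_times, dtype=float),
        metadata={"scenario": scenario.label, "protocol": protocol.kind, "seed": seed},
    )
    return trace, truth


def simulate_train(
    scenario: EphysScenario,
    seed: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> tuple[Trace, EventGroundTruth]:
    """Simulate a 20 Hz x 2 min train with depletion-driven rundown.

    Per-pulse quantal count and pool update::

        Q_i     = round(p * N_i)
        N_{i+1} = (N_i - p*N_i) + r * (N0 - (N_i - p*N_i))

    The i-th EPP amplitude is ``Q_i`` times the single-quantum amplitude
    (``mepp_mean`` scaled to the local RMP).  The closed-form steady state of
    the recursion is ``N* = r*N0 / (p + r - p*r)`` (see
    :func:`steady_state_pool`).
    """
    p, r, n0 = scenario.release_fraction, scenario.replenish_rate, scenario.pool_size
    rng = np.random.default_rng(seed)
    protocol = train_protocol()
    n = int(round(protocol.duration * sampling_rate))
    rmp = _rmp_track(scenario, n, sampling_rate, rng)
    samples = rmp.copy()
    kernel = event_kernel(scenario.rise_time, scenario.decay_tau, sampling_rate)

    stim = np.asarray(protocol.stim_times)
    quanta = np.empty(len(stim), dtype=int)
    pool = float(n0)
    for i in range(len(stim)):
        q = round(p * pool)
        quanta[i] = q
        remaining = pool - p * pool
        pool = remaining + r * (n0 - remaining)

    idx = np.minimum((stim * sampling_rate).astype(int), n - 1)
    a70 = quanta * scenario.mepp_mean
    amps = a70 * np.abs(rmp[idx]) / 70.0
    _add_events(samples, kernel, idx, amps)
    if scenario.noise_sd > 0:
        samples += rng.normal(0.0, scenario.noise_sd, n)

    truth = EventGroundTruth(
        event_times=stim,
        amplitudes=amps,
        amplitudes_at_minus70=a70.astype(float),
        rmp_at_event=rmp[idx],
        kind=np.repeat("EPP", len(stim)),
        quanta_per_stimulus=quanta,
    )
    trace = Trace(
        sampling_rate=sampling_rate,
        samples=samples,
        stim_times=stim,
        metadata={"scenario": scenario.label, "protocol": "train_20Hz", "seed": seed},
    )
    return trace, truth


def steady_state_pool(pool_size: float, release_fraction: float, replenish_rate: float) -> float:
    """Closed-form fixed point N* of the depletion/replenishment recursion."""
    p, r = release_fraction, replenish_rate
    if p + r - p * r == 0:
        return 0.0
    return r * pool_size / (p + r - p * r)


# ---------------------------------------------------------------------------
# quantal arithmetic shared with scenario construction
# ---------------------------------------------------------------------------

def quantal_content_of_means(epp_mean: float, mepp_mean: float,
                             vm: float = 70.0, f: float = 0.8) -> float:
    """QC = E / [M (1 - f E/Vm)] applied to true group means."""
    denom = 1.0 - f * epp_mean / vm
    if denom <= 0:
        raise ValueError("non-linear summation correction breaks down (denominator <= 0)")
    return epp_mean / (mepp_mean * denom)


def epp_for_quantal_content(qc: float, mepp_mean: float,
                            vm: float = 70.0, f: float = 0.8) -> float:
    """Invert the Martin formula: evoked amplitude that yields a target QC."""
    return qc * mepp_mean / (1.0 + qc * mepp_mean * f / vm)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_trace_csv(trace: Trace, path) -> None:
    """Write a trace as two-column CSV (time_s, vm_mV)."""
    df = pd.DataFrame({"time_s": trace.time, "vm_mV": trace.samples})
    df.to_csv(path, index=False)


def write_trace_h5(trace: Trace, truth: Optional[EventGroundTruth], path) -> None:
    """Write trace (and optional ground truth) to an HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("vm_mV", data=trace.samples, compression="gzip")
        h5.create_dataset("stim_times_s", data=trace.stim_times)
        h5.attrs["sampling_rate_hz"] = trace.sampling_rate
        for k, v in trace.metadata.items():
            h5.attrs[str(k)] = v
        if truth is not None:
            g = h5.create_group("ground_truth")
            g.create_dataset("event_times_s", data=truth.event_times)
            g.create_dataset("amplitudes_mV", data=truth.amplitudes)
            g.create_dataset("amplitudes_at_minus70_mV", data=truth.amplitudes_at_minus70)
            g.create_dataset("rmp_at_event_mV", data=truth.rmp_at_event)
            g.create_dataset("kind", data=truth.kind.astype("S"))
            if truth.quanta_per_stimulus is not None:
                g.create_dataset("quanta_per_stimulus", data=truth.quanta_per_stimulus)


def read_trace_h5(path) -> tuple[Trace, Optional[EventGroundTruth]]:
    """Read a trace written by :func:`write_trace_h5`."""
    with h5py.File(path, "r") as h5:
        trace = Trace(
            sampling_rate=float(h5.attrs["sampling_rate_hz"]),
            samples=h5["vm_mV"][:],
            stim_times=h5["stim_times_s"][:],
            metadata={k: v for k, v in h5.attrs.items() if k != "sampling_rate_hz"},
        )
        truth = None
        if "ground_truth" in h5:
            g = h5["ground_truth"]
            truth = EventGroundTruth(
                event_times=g["event_times_s"][:],
                amplitudes=g["amplitudes_mV"][:],
                amplitudes_at_minus70=g["amplitudes_at_minus70_mV"][:],
                rmp_at_event=g["rmp_at_event_mV"][:],
                kind=g["kind"][:].astype("U"),
                quanta_per_stimulus=(
                    g["quanta_per_stimulus"][:] if "quanta_per_stimulus" in g else None
                ),
            )
    return trace, truth
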