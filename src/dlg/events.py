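"""Event-driven spike-by-spike simulation of a gate under a protocol.

Where the closed forms of :mod:`dlg.analytic` assume a 1:1 response, this
engine actually delivers stimulations: inputs may be skipped probabilistically,
relays may be vetoed by inhibition or silenced by refractoriness, and — the
essential difference — a neuron's latency stretches only per spike it actually
evokes.  With a deterministic 1:1 protocol the two engines agree exactly,
which is the package's central cross-check.

The simulation is a single time-ordered event queue.  Deliveries at identical
times are processed inhibition-first, so an inhibitory arrival vetoes an
excitatory arrival scheduled in the same batch.  All randomness (delivery
skipping, graded-inhibition draws) flows from one seed through independent
child streams, so toggling one stochastic feature does not shift the others.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    EXCITATORY,
    INHIBITORY,
    TIME_EPS,
    CircuitSpec,
    NeuronState,
    fit_delta,
    graded_inhibition_strength,
    latency_of,
)

__all__ = [
    "StimulationProtocol",
    "SpikeRecord",
    "SimulationResult",
    "simulate",
    "reset_latencies",
    "varying_input_run",
    "estimate_delta",
]

CAUSES = (
    "strong",
    "summation",
    "blocked-inhibition",
    "blocked-refractory",
    "blocked-subthreshold",
    "skipped-input",
    "inhibitory",
)


@dataclass(frozen=True)
class StimulationProtocol:
    """Repeated simultaneous stimulation rounds with optional moderation.

    ``count`` rounds are delivered at a fixed ``rate_hz`` (10 Hz by default,
    i.e. 100 ms apart); every logical input and every outer neuron is
    stimulated in each round, each logical input with its delivery
    ``probability`` (Bernoulli per round, seeded).  ``moderation`` lowers an
    input's probability inside a round interval, e.g. ``{"in2": (250, 475,
    0.1)}`` moderates rounds 250..474.  ``times`` overrides the common clock
    with explicit per-input stimulation times (ms, strictly increasing).
    """

    count: int
    rate_hz: float = 10.0
    probabilities: dict[str, float] = field(default_factory=dict)
    moderation: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    times: dict[str, tuple[float, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("stimulation count must be >= 0")
        if self.rate_hz <= 0:
            raise ValueError("stimulation rate must be > 0")
        for name, p in self.probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name!r} outside [0, 1]")
        for name, (_, _, p) in self.moderation.items():
            if not 0 <= p <= 1:
                raise ValueError(f"moderated probability for {name!r} outside [0, 1]")
        if self.times is not None:
            for name, ts in self.times.items():
                if any(b <= a for a, b in zip(ts, ts[1:])):
                    raise ValueError(f"times for {name!r} must be strictly increasing")

    @property
    def period(self) -> float:
        return 1000.0 / self.rate_hz

    def probability(self, input_id: str, round_index: int) -> float:
        if input_id in self.moderation:
            lo, hi, p = self.moderation[input_id]
            if lo <= round_index < hi:
                return p
        return self.probabilities.get(input_id, 1.0)


@dataclass
class SpikeRecord:
    """Outcome of one scheduled arrival (or skipped input stimulation)."""

    neuron: str
    stim_index: int
    origin: str | None
    arrival: float
    strength: float
    sign: str
    cause: str = "blocked-subthreshold"
    evoked: bool = False
    evoked_time: float | None = None


@dataclass
class SimulationResult:
    circuit: CircuitSpec
    protocol: StimulationProtocol
    records: list[SpikeRecord]
    summary: pd.DataFrame  # one row per stimulation round
    states: dict[str, NeuronState]

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stim_index": [r.stim_index for r in self.records],
                "neuron": [r.neuron for r in self.records],
                "origin": [r.origin for r in self.records],
                "arrival_ms": [r.arrival for r in self.records],
                "strength": [r.strength for r in self.records],
                "sign": [r.sign for r in self.records],
                "evoked": [r.evoked for r in self.records],
                "evoked_ms": [r.evoked_time for r in self.records],
                "cause": [r.cause for r in self.records],
            }
        )


def reset_latencies(states: dict[str, NeuronState]) -> dict[str, NeuronState]:
    """Return fresh states with all spike counts back at zero.

    Latency stretching is fully reversible after a rest period; this models
    that recovery as an explicit reset rather than as decay kinetics.
    """
    return {nid: NeuronState() for nid in states}


# ---------------------------------------------------------------------------

def _input_schedule(
    circuit: CircuitSpec, protocol: StimulationProtocol
) -> list[tuple[float, int, str, float]]:
    """(time, round index, neuron, delivery probability) for every stimulation."""
    sched: list[tuple[float, int, str, float]] = []
    drive = [*circuit.inputs, *circuit.outer]
    if protocol.times is not None:
        for nid, ts in protocol.times.items():
            if nid not in circuit.neurons:
                raise ValueError(f"protocol stimulates unknown neuron {nid!r}")
            for idx, t in enumerate(ts):
                sched.append((t, idx, nid, protocol.probability(nid, idx)))
    else:
        for r in range(protocol.count):
            t = r * protocol.period
            for nid in drive:
                p = 1.0 if nid in circuit.outer else protocol.probability(nid, r)
                sched.append((t, r, nid, p))
    sched.sort(key=lambda item: item[0])
    return sched


def simulate(
    circuit: CircuitSpec,
    protocol: StimulationProtocol,
    freeze_output: bool = False,
    states: dict[str, NeuronState] | None = None,
) -> SimulationResult:
    """Run the gate under the protocol, spike by spike.

    Each evoked spike increments its neuron's ``q`` and thereby stretches all
    of that neuron's future latencies.  ``freeze_output=True`` exempts the
    output neuron, recovering the pure delay-line picture in which only input
    chains stretch.  Passing ``states`` resumes from a previous run's state.

    Returns records for every scheduled arrival plus a per-round summary with
    the chain delays (both predicted from the current spike counts and as
    observed arrival times at the output) and the output spike multiplicity.
    """
    ss = np.random.SeedSequence(protocol.seed)
    rng_delivery, rng_inhibition = (
        np.random.default_rng(child) for child in ss.spawn(2)
    )

    if states is None:
        states = {nid: NeuronState() for nid in circuit.neurons}
    a, b = circuit.inhibition_window
    outgoing = {nid: circuit.links_from(nid) for nid in circuit.neurons}
    records: list[SpikeRecord] = []

    # event heap: (time, phase, seq, neuron, strength, sign, origin, round, record)
    heap: list[tuple] = []
    seq = 0

    def push(time: float, nid: str, strength: float, sign: str, origin, rnd) -> SpikeRecord:
        nonlocal seq
        rec = SpikeRecord(nid, rnd, origin, time, strength, sign)
        phase = 0 if sign == INHIBITORY else 1
        heapq.heappush(heap, (time, phase, seq, nid, rec))
        seq += 1
        records.append(rec)
        return rec

    # external stimulations
    round_times: dict[int, float] = {}
    for t, rnd, nid, p in _input_schedule(circuit, protocol):
        round_times.setdefault(rnd, t)
        if p < 1.0 and rng_delivery.random() >= p:
            records.append(
                SpikeRecord(nid, rnd, nid, t, 1.0, EXCITATORY, cause="skipped-input")
            )
            continue
        push(t, nid, 1.0, "external", nid, rnd)

    # per-round output bookkeeping
    out_spikes: dict[int, int] = {}
    observed: dict[tuple[int, str], float] = {}  # (round, origin) -> delay at output

    last_time = -math.inf
    while heap:
        time, phase, _, nid, rec = heapq.heappop(heap)
        if time < last_time:
            raise RuntimeError("event-queue time reversal; internal error")
        last_time = time
        spec = circuit.neurons[nid]
        state = states[nid]

        if rec.sign == INHIBITORY:
            state.add_inhibition(time + a, time + b)
            rec.cause = "inhibitory"
            continue

        # excitatory (or external) delivery
        fired = False
        if rec.sign == "external":
            rec.sign = EXCITATORY
            rec.cause = "strong"
            fired = True
        else:
            if circuit.graded_inhibition:
                # empirical graded veto: blocking probability decays with the
                # inhibition -> excitation gap instead of a sharp window
                gaps = (time - (lo - a) for lo, _ in state.inhibition_intervals)
                pblock = max(
                    (graded_inhibition_strength(g) for g in gaps), default=0.0
                )
                blocked = pblock > 0 and rng_inhibition.random() < pblock
            else:
                blocked = state.inhibited_at(time)
            if blocked:
                rec.cause = "blocked-inhibition"
            elif state.last_trigger_time is not None and (
                time - state.last_trigger_time < spec.refractory - TIME_EPS
            ):
                rec.cause = "blocked-refractory"
            else:
                state.pending = [
                    (tj, sj)
                    for tj, sj in state.pending
                    if tj > time - spec.window + TIME_EPS
                ]
                state.pending.append((time, rec.strength))
                if sum(sj for _, sj in state.pending) >= spec.threshold:
                    rec.cause = "strong" if rec.strength >= spec.threshold else "summation"
                    fired = True
                    state.pending = []
                # else: stays blocked-subthreshold unless a later arrival sums

        if not fired:
            continue
        rec.evoked = True
        spike_time = time + latency_of(spec, state.q)
        rec.evoked_time = spike_time
        state.last_trigger_time = time
        if not (freeze_output and nid == circuit.output):
            state.q += 1
        if nid == circuit.output:
            out_spikes[rec.stim_index] = out_spikes.get(rec.stim_index, 0) + 1
        for link in outgoing[nid]:
            arrival = spike_time + link.delay
            if link.target == circuit.output and link.sign == EXCITATORY:
                key = (rec.stim_index, rec.origin)
                t0 = round_times.get(rec.stim_index, 0.0)
                observed.setdefault(key, arrival - t0)
            push(arrival, link.target, link.strength, link.sign, rec.origin, rec.stim_index)

    summary = _summarise(circuit, protocol, states, records, out_spikes, observed)
    return SimulationResult(circuit, protocol, records, summary, states)


def _chain_paths(circuit: CircuitSpec) -> dict[str, list[str]]:
    """Unique excitatory path (neuron sequence, output excluded) per input."""
    paths: dict[str, list[str]] = {}
    for nid in [*circuit.inputs, *circuit.outer]:
        full = [
            p
            for p in circuit.paths_to_output(nid)
            if all(l.sign == EXCITATORY for l in p)
        ]
        if len(full) == 1:
            paths[nid] = [nid] + [l.target for l in full[0][:-1]]
    return paths


def _summarise(circuit, protocol, states, records, out_spikes, observed) -> pd.DataFrame:
    paths = _chain_paths(circuit)
    # reconstruct per-round q snapshots by replaying evoked counts
    evoked_by_round: dict[str, dict[int, int]] = {nid: {} for nid in circuit.neurons}
    for r in records:
        if r.evoked:
            d = evoked_by_round[r.neuron]
            d[r.stim_index] = d.get(r.stim_index, 0) + 1
    n_rounds = (
        protocol.count
        if protocol.times is None
        else max((r.stim_index for r in records), default=-1) + 1
    )
    rows = []
    qcum = {nid: 0 for nid in circuit.neurons}
    for rnd in range(n_rounds):
        row: dict[str, object] = {"stim_index": rnd}
        for inp, path in paths.items():
            delay = 0.0
            for nid in path:
                delay += latency_of(circuit.neurons[nid], qcum[nid])
            # link delays along the path
            seqs = list(path) + [circuit.output]
            for srcn, dstn in zip(seqs, seqs[1:]):
                link = next(
                    l for l in circuit.links if l.source == srcn and l.target == dstn
                )
                delay += link.delay
            row[f"delay_{inp}"] = delay
            row[f"observed_{inp}"] = observed.get((rnd, inp), float("nan"))
        row["output_spikes"] = out_spikes.get(rnd, 0)
        rows.append(row)
        for nid in circuit.neurons:
            qcum[nid] += evoked_by_round[nid].get(rnd, 0)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalRegion:
    q_start: int
    q_end: int
    label: str


def varying_input_run(
    circuit: CircuitSpec,
    moderation: tuple[tuple[int, int], float],
    count: int = 800,
    seed: int = 0,
    merge_gap: int = 20,
) -> tuple[list[EmpiricalRegion], pd.DataFrame]:
    """Drive a two-input coincidence gate with one input moderated.

    ``moderation=((lo, hi), p)`` lowers the second input's delivery
    probability to ``p`` for rounds ``lo..hi-1``.  The moderated chain's
    latency stretches more slowly, so its delay line can be crossed, re-crossed
    after the moderation ends, and a *re-entry* into a further coincidence
    (AND) region appears — a phenomenon a fixed-rate drive cannot produce.

    Returns the empirically labelled regions (AND where the two chain delays
    sit within the output's coincidence window, NULL elsewhere; runs separated
    by fewer than ``merge_gap`` rounds are merged to absorb boundary jitter
    from the Bernoulli moderation) together with the per-round summary frame.
    """
    if len(circuit.inputs) != 2:
        raise ValueError("varying_input_run expects a two-input gate")
    (lo, hi), p = moderation
    in1, in2 = circuit.inputs
    protocol = StimulationProtocol(
        count=count, moderation={in2: (lo, hi, p)} if lo < hi else {}, seed=seed
    )
    result = simulate(circuit, protocol)
    w = circuit.neurons[circuit.output].window
    diff = (
        result.summary[f"delay_{in1}"] - result.summary[f"delay_{in2}"]
    ).to_numpy()
    inside = np.abs(diff) < w
    regions = _runs_to_regions(inside, merge_gap)
    return regions, result.summary


def _runs_to_regions(inside: np.ndarray, merge_gap: int) -> list[EmpiricalRegion]:
    regions: list[EmpiricalRegion] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append(EmpiricalRegion(start, i - 1, "AND"))
            start = None
    if start is not None:
        regions.append(EmpiricalRegion(start, len(inside) - 1, "AND"))
    merged: list[EmpiricalRegion] = []
    for reg in regions:
        if merged and reg.q_start - merged[-1].q_end - 1 < merge_gap:
            merged[-1] = EmpiricalRegion(merged[-1].q_start, reg.q_end, "AND")
        else:
            merged.append(reg)
    return merged


def estimate_delta(series: Iterable[tuple[float, float]]) -> float:
    """Least-squares latency increment from a (q, latency) series."""
    pts = list(series)
    return fit_delta([q for q, _ in pts], [l for _, l in pts])
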