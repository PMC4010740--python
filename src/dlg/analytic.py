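"""Closed-form delay-line analysis of dynamic logic-gates.

Under the 1:1 assumption — every stimulation evokes a spike in every chain
neuron — each input->output path of a gate is a straight *delay line*

    tau_i(q) = tau0_i + n_i * delta * q

in the (stimulation count, delay) plane, with slope proportional to the number
of neurons the path traverses.  Everything about the gate's logic history then
reduces to line-arrangement geometry:

* two chains can drive the output together only while their lines lie within
  the coincidence window ``w`` of each other, an interval of half-width
  ``w / |slope difference|`` around the lines' intersection;
* an inhibitory line vetoes an excitatory one while their difference sits in
  the inhibition window ``[a, b]``;
* ``k`` pairwise non-parallel chains intersect at most ``k (k - 1) / 2`` times
  at positive counts, bounding the number of mode transitions.

The full :func:`mode_timeline` sweeps integer stimulation counts, evaluates
the gate's truth table at each (by closed-form propagation through the DAG,
not by event simulation) and merges equal consecutive tables into labelled
mode intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

from .core import (
    EXCITATORY,
    INHIBITORY,
    TIME_EPS,
    CircuitSpec,
    LinkSpec,
    latency_of,
)
from .logic import TruthTable, classify

__all__ = [
    "DelayLine",
    "FiringRegion",
    "ModeInterval",
    "ModeTimeline",
    "build_lines",
    "pairwise_intersections",
    "firing_regions",
    "merge_regions",
    "inhibition_regions",
    "evaluate_once",
    "truth_table_at",
    "mode_timeline",
    "rescale_check",
    "synfire_equivalent",
]


@dataclass(frozen=True)
class DelayLine:
    """One chain's delay-vs-stimulation-count line."""

    chain_id: str
    intercept: float  # tau0, ms
    slope: float  # n * delta, ms per stimulation
    strength: float = 1.0
    sign: str = EXCITATORY
    target: str = ""  # neuron the chain terminates on

    def delay(self, q: float) -> float:
        return self.intercept + self.slope * q

    @property
    def excitatory(self) -> bool:
        return self.sign == EXCITATORY


@dataclass(frozen=True)
class FiringRegion:
    """Interval of stimulation counts over which a line subset co-fires."""

    q_start: float
    q_end: float
    members: frozenset[str]  # chain ids whose coincidence defines the region
    contributing_pairs: frozenset[frozenset[str]]
    mode_label: str = "AND"

    def __post_init__(self) -> None:
        if not self.q_start < self.q_end:
            raise ValueError("region must satisfy q_start < q_end")


# ---------------------------------------------------------------------------
# line construction
# ---------------------------------------------------------------------------

def build_lines(circuit: CircuitSpec, delta: float | None = None) -> list[DelayLine]:
    """One delay line per excitatory path to the output, plus one per
    inhibitory delivery point.

    Paths are walked along excitatory links only (an inhibitory link cannot
    relay activity further); the path's slope counts every neuron traversed,
    excluding the neuron the line lands on.  ``delta`` overrides the neurons'
    own increments, giving the homogeneous-Δ picture the closed forms assume.
    """
    lines: list[DelayLine] = []

    def walk(start: str) -> None:
        # stack of (neuron, accumulated delay, neuron count, path suffix)
        stack: list[tuple[str, float, int, str]] = []
        n0 = circuit.neurons[start]
        stack.append((start, n0.l0, 1, start))
        while stack:
            nid, acc, count, pid = stack.pop()
            for link in circuit.links_from(nid):
                arrival = acc + link.delay
                slope = count * (delta if delta is not None else _path_delta(circuit))
                if link.sign == INHIBITORY:
                    lines.append(
                        DelayLine(
                            chain_id=f"{pid}~{link.target}",
                            intercept=arrival,
                            slope=slope,
                            strength=link.strength,
                            sign=INHIBITORY,
                            target=link.target,
                        )
                    )
                    continue
                if link.target == circuit.output:
                    lines.append(
                        DelayLine(
                            chain_id=pid if _single_path(lines, pid) else f"{pid}#{len(lines)}",
                            intercept=arrival,
                            slope=slope,
                            strength=link.strength,
                            sign=EXCITATORY,
                            target=circuit.output,
                        )
                    )
                else:
                    t = circuit.neurons[link.target]
                    stack.append((link.target, arrival + t.l0, count + 1, pid))

    for start in [*circuit.inputs, *circuit.outer]:
        walk(start)
    return lines


def _single_path(lines: list[DelayLine], pid: str) -> bool:
    return all(l.chain_id != pid for l in lines)


def _path_delta(circuit: CircuitSpec) -> float:
    # homogeneous increment assumed by the closed forms; taken from the first
    # neuron when no explicit delta override is given
    deltas = {n.delta for n in circuit.neurons.values()}
    return next(iter(deltas)) if len(deltas) == 1 else min(deltas)


# ---------------------------------------------------------------------------
# line arrangement geometry
# ---------------------------------------------------------------------------

def pairwise_intersections(
    lines: Sequence[DelayLine], horizon: float
) -> list[tuple[tuple[str, str], float]]:
    """All pairwise line crossings at stimulation counts in (0, horizon).

    The crossing of lines i, j is ``q* = (tau0_i - tau0_j) / (slope_j -
    slope_i)``; parallel lines (equal chain length) never cross.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    out: list[tuple[tuple[str, str], float]] = []
    for a, b in combinations(lines, 2):
        ds = b.slope - a.slope
        if ds == 0:
            continue
        q = (a.intercept - b.intercept) / ds
        if 0 < q < horizon:
            out.append(((a.chain_id, b.chain_id), q))
    out.sort(key=lambda item: item[1])
    return out


def _pair_interval(a: DelayLine, b: DelayLine, w: float) -> tuple[float, float] | None:
    """Open q-interval over which |tau_a - tau_b| < w, unclipped."""
    d0 = a.intercept - b.intercept
    s = a.slope - b.slope
    if s == 0:
        return (float("-inf"), float("inf")) if abs(d0) < w else None
    lo, hi = sorted(((-w - d0) / s, (w - d0) / s))
    return (lo, hi)


def firing_regions(
    lines: Sequence[DelayLine],
    theta: float = 1.0,
    w: float = 0.4,
    horizon: float = 1000.0,
) -> list[FiringRegion]:
    """Regions of stimulation counts over which the output neuron fires.

    A subset of excitatory lines drives the output wherever all of its
    members lie pairwise within the coincidence window ``w`` *and* its summed
    strengths reach ``theta``.  Only minimal sufficient subsets are reported
    (a superset can never extend a minimal subset's region); overlapping
    regions are reported per-subset — use :func:`merge_regions` for the merged
    view used in mode labelling.
    """
    exc = [l for l in lines if l.excitatory]
    regions: list[FiringRegion] = []
    ids = list(range(len(exc)))
    for r in range(1, len(exc) + 1):
        for subset in combinations(ids, r):
            strength = sum(exc[i].strength for i in subset)
            if strength < theta:
                continue
            # minimality: no proper sub-subset already reaches theta
            if any(
                sum(exc[i].strength for i in sub) >= theta
                for k in range(1, r)
                for sub in combinations(subset, k)
            ):
                continue
            lo, hi = 0.0, float(horizon)
            ok = True
            for i, j in combinations(subset, 2):
                iv = _pair_interval(exc[i], exc[j], w)
                if iv is None:
                    ok = False
                    break
                lo, hi = max(lo, iv[0]), min(hi, iv[1])
            if not ok or not lo < hi:
                continue
            members = frozenset(exc[i].chain_id for i in subset)
            pairs = frozenset(
                frozenset((exc[i].chain_id, exc[j].chain_id))
                for i, j in combinations(subset, 2)
            )
            regions.append(FiringRegion(lo, hi, members, pairs))
    regions.sort(key=lambda reg: (reg.q_start, reg.q_end))
    return regions


def merge_regions(regions: Iterable[FiringRegion]) -> list[FiringRegion]:
    """Merge overlapping/contiguous regions into maximal firing intervals."""
    ordered = sorted(regions, key=lambda r: (r.q_start, r.q_end))
    merged: list[FiringRegion] = []
    for reg in ordered:
        if merged and reg.q_start <= merged[-1].q_end:
            prev = merged[-1]
            merged[-1] = FiringRegion(
                prev.q_start,
                max(prev.q_end, reg.q_end),
                prev.members | reg.members,
                prev.contributing_pairs | reg.contributing_pairs,
                prev.mode_label,
            )
        else:
            merged.append(reg)
    return merged


def inhibition_regions(
    excitatory_line: DelayLine,
    inhibitory_line: DelayLine,
    window: tuple[float, float] = (1.0, 7.0),
    horizon: float = 1000.0,
) -> list[tuple[float, float]]:
    """q-intervals over which the excitation falls inside the veto window.

    The veto is active wherever ``tau_exc(q) - tau_inh(q)`` lies in ``[a, b]``;
    with offset ``d0`` and relative slope ``s`` the closed form is the interval
    between ``(a - d0)/s`` and ``(b - d0)/s`` (whole horizon when ``s = 0`` and
    ``d0`` already sits inside the window).
    """
    a, b = window
    if not a < b:
        raise ValueError("inhibition window must satisfy a < b")
    d0 = excitatory_line.intercept - inhibitory_line.intercept
    s = excitatory_line.slope - inhibitory_line.slope
    if s == 0:
        return [(0.0, float(horizon))] if a <= d0 <= b else []
    lo, hi = sorted(((a - d0) / s, (b - d0) / s))
    lo, hi = max(lo, 0.0), min(hi, float(horizon))
    return [(lo, hi)] if lo < hi else []


# ---------------------------------------------------------------------------
# closed-form single-round gate evaluation
# ---------------------------------------------------------------------------

class _Compiled:
    """Cached topology for repeated closed-form evaluations."""

    def __init__(self, circuit: CircuitSpec):
        self.circuit = circuit
        self.order = circuit.topological_order()
        self.outgoing: dict[str, list[LinkSpec]] = {nid: [] for nid in circuit.neurons}
        for link in circuit.links:
            self.outgoing[link.source].append(link)


_compiled_cache: dict[int, _Compiled] = {}


def _compiled(circuit: CircuitSpec) -> _Compiled:
    key = id(circuit)
    comp = _compiled_cache.get(key)
    if comp is None or comp.circuit is not circuit:
        comp = _Compiled(circuit)
        _compiled_cache.clear()
        _compiled_cache[key] = comp
    return comp


def evaluate_once(
    circuit: CircuitSpec,
    active_inputs: Iterable[str],
    q: int,
) -> tuple[int, list[float]]:
    """Closed-form probe of one simultaneous stimulation at history count ``q``.

    Every neuron is assumed to carry the same spiking history ``q`` (the 1:1
    assumption), so its latency is ``l0 + q * delta``.  Active logical inputs
    plus all outer neurons are stimulated strongly at t = 0; activity is
    propagated through the DAG in topological order applying summation,
    inhibition-window and refractory rules at each neuron.

    Returns ``(output spike multiplicity, output trigger times)``.
    """
    comp = _compiled(circuit)
    stimulated = set(active_inputs) | set(circuit.outer)
    unknown = stimulated - set(circuit.neurons)
    if unknown:
        raise ValueError(f"unknown input labels: {sorted(unknown)}")
    a, b = circuit.inhibition_window

    exc_arrivals: dict[str, list[tuple[float, float]]] = {n: [] for n in circuit.neurons}
    inh_arrivals: dict[str, list[float]] = {n: [] for n in circuit.neurons}
    out_triggers: list[float] = []

    for nid in comp.order:
        spec = circuit.neurons[nid]
        triggers: list[float] = []
        if nid in stimulated:
            triggers.append(0.0)  # external strong stimulation, 1:1 response
        veto = [(t + a, t + b) for t in inh_arrivals[nid]]
        buffer: list[tuple[float, float]] = []
        last: float | None = None
        for t, s in sorted(exc_arrivals[nid]):
            if any(lo - TIME_EPS <= t <= hi + TIME_EPS for lo, hi in veto):
                continue
            if last is not None and t - last < spec.refractory - TIME_EPS:
                continue
            buffer = [
                (tj, sj) for tj, sj in buffer if tj > t - spec.window + TIME_EPS
            ]
            buffer.append((t, s))
            if sum(sj for _, sj in buffer) >= spec.threshold:
                triggers.append(t)
                buffer = []
                last = t
        if nid == circuit.output:
            out_triggers = triggers
        for trig in triggers:
            spike = trig + latency_of(spec, q)
            for link in comp.outgoing[nid]:
                arrival = spike + link.delay
                if link.sign == INHIBITORY:
                    inh_arrivals[link.target].append(arrival)
                else:
                    exc_arrivals[link.target].append((arrival, link.strength))
    return len(out_triggers), out_triggers


def truth_table_at(circuit: CircuitSpec, q: int) -> TruthTable:
    """Truth table over all 2^k logical input combinations at count ``q``."""
    k = len(circuit.inputs)
    mapping = {}
    for combo in product((0, 1), repeat=k):
        active = [nid for nid, bit in zip(circuit.inputs, combo) if bit]
        mult, _ = evaluate_once(circuit, active, q)
        mapping[combo] = mult
    return TruthTable.from_mapping(mapping)


# ---------------------------------------------------------------------------
# mode timelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeInterval:
    q_start: int
    q_end: int  # inclusive
    label: str
    table: TruthTable


@dataclass
class ModeTimeline:
    """Partition of integer stimulation counts [0, Q] into mode intervals."""

    horizon: int
    intervals: list[ModeInterval] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    def transition_counts(self) -> list[int]:
        return [iv.q_start for iv in self.intervals[1:]]

    def label_at(self, q: int) -> str:
        for iv in self.intervals:
            if iv.q_start <= q <= iv.q_end:
                return iv.label
        raise ValueError(f"q={q} outside timeline horizon {self.horizon}")

    def count(self, label_prefix: str) -> int:
        return sum(1 for iv in self.intervals if iv.label.startswith(label_prefix))


def mode_timeline(circuit: CircuitSpec, horizon: int) -> ModeTimeline:
    """Label every integer stimulation count in ``[0, horizon]`` with its mode.

    Consecutive counts with identical truth tables (including spike
    multiplicities) are merged into one interval; boundaries that fall between
    integers are thereby assigned to the later integer.  Unknown truth-table
    patterns get the label ``OTHER`` and are never dropped.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    intervals: list[ModeInterval] = []
    cur_table: TruthTable | None = None
    cur_start = 0
    for q in range(horizon + 1):
        table = truth_table_at(circuit, q)
        if cur_table is None:
            cur_table, cur_start = table, q
        elif table != cur_table:
            intervals.append(ModeInterval(cur_start, q - 1, classify(cur_table), cur_table))
            cur_table, cur_start = table, q
    if cur_table is not None:
        intervals.append(ModeInterval(cur_start, horizon, classify(cur_table), cur_table))
    return ModeTimeline(horizon, intervals)


# ---------------------------------------------------------------------------
# structural checks
# ---------------------------------------------------------------------------

def _region_boundaries(circuit: CircuitSpec, delta: float, horizon: float) -> list[float]:
    lines = [l for l in build_lines(circuit, delta) if l.target == circuit.output]
    out = circuit.neurons[circuit.output]
    regions = merge_regions(
        firing_regions(lines, theta=out.threshold, w=out.window, horizon=horizon)
    )
    bounds: list[float] = []
    for reg in regions:
        bounds.extend((reg.q_start, reg.q_end))
    return bounds


def rescale_check(
    circuit: CircuitSpec,
    delta1: float,
    delta2: float,
    horizon: float,
    rtol: float = 1e-9,
) -> bool:
    """Whether firing-region boundaries rescale exactly by delta1/delta2.

    With homogeneous increments every boundary is the root of an affine
    function of q whose slope is proportional to delta, so boundaries scale as
    1/delta; the check fails only when that structure is broken — notably when
    a region is truncated by the common horizon, which does not rescale.
    """
    if delta1 <= 0 or delta2 <= 0:
        raise ValueError("latency increments must be > 0")
    b1 = _region_boundaries(circuit, delta1, horizon)
    b2 = _region_boundaries(circuit, delta2, horizon)
    if len(b1) != len(b2):
        return False
    scale = delta1 / delta2
    for x1, x2 in zip(b1, b2):
        ref = x1 * scale
        if abs(x2 - ref) > rtol * max(1.0, abs(ref)):
            return False
    return True


def synfire_equivalent(
    circuit_a: CircuitSpec,
    circuit_b: CircuitSpec,
    delta: float,
    horizon: int,
) -> bool:
    """Whether two gates traverse identical mode sequences at identical counts.

    Guaranteed whenever the pairwise differences of chain lengths and of
    initial delays match between the two gates — the geometry of the line
    arrangement depends only on those differences, so a gate built from long
    chains of short synaptic delays replicates a gate of short chains with
    long delays transition-for-transition.
    """
    ta = mode_timeline(circuit_a.with_delta(delta), horizon)
    tb = mode_timeline(circuit_b.with_delta(delta), horizon)
    return ta.labels() == tb.labels() and ta.transition_counts() == tb.transition_counts()
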