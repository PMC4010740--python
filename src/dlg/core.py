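"""Elastic-latency model and the circuit data model.

The central physiological fact encoded here is that a neuron's response
latency — the lag between a stimulation and its evoked spike — stretches by a
small constant increment per evoked spike,

    l(q) = l0 + q * delta,

where ``q`` counts evoked spikes and ``delta`` is a few microseconds per spike
(0.002–0.007 ms).  For a feedforward chain of ``n`` such neurons the total
chain delay inherits the accumulated stretching,

    tau(q) = tau0 + n * q * delta.

On top of the latency rule sit the local firing rules of a neuron:

* **temporal/spatial summation** — weak (sub-threshold) stimulations evoke a
  spike only when the strengths arriving within a short coincidence window
  ``w`` (~0.4–0.5 ms) sum to at least the threshold ``theta``;
* **inhibition window** — an inhibitory stimulation at time ``T`` vetoes any
  excitatory response in the closed interval ``[T + a, T + b]`` (default
  ``[T + 1, T + 7]`` ms);
* **refractoriness** — two evoked spikes require a gap of at least the
  refractory period ``r`` (~4 ms).

Boundary conventions are deliberate and fixed: summation requires a lag
strictly smaller than ``w``; the inhibition interval is closed at both ends;
refractoriness blocks strictly smaller gaps.  All times are milliseconds.

Knife-edge comparisons (a lag exactly equal to ``w``, a gap exactly equal to
the refractory period, an arrival exactly on a veto bound) are resolved with
a 1 ns guard (``TIME_EPS``): well below every physical scale in the model but
well above accumulated double-precision noise, so the closed-form and
event-driven engines resolve exact boundaries identically instead of by
floating-point rounding of differently-ordered sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "NeuronSpec",
    "NeuronState",
    "LinkSpec",
    "CircuitSpec",
    "ChainSpec",
    "EXCITATORY",
    "INHIBITORY",
    "latency_of",
    "chain_delay",
    "summation_decision",
    "inhibition_covers",
    "refractory_blocks",
    "graded_inhibition_strength",
]

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

#: guard for knife-edge time comparisons (ms); see module docstring
TIME_EPS = 1e-9

#: physiological range of the per-spike latency increment (ms/spike)
PHYSIOLOGICAL_DELTA_RANGE = (0.002, 0.007)


@dataclass(frozen=True)
class NeuronSpec:
    """Static parameters of a single neuron.

    Parameters
    ----------
    id:
        Label, unique within a circuit.
    l0:
        Initial response latency (ms), >= 0.
    delta:
        Latency increment per evoked spike (ms/spike), >= 0.
    window:
        Coincidence (summation) window ``w`` in ms; weak arrivals closer than
        this may sum.  Strictly positive.
    threshold:
        Firing threshold ``theta`` on summed stimulation strength.
    refractory:
        Minimal gap (ms) between two evoked spikes.
    """

    id: str
    l0: float = 2.0
    delta: float = 0.006
    window: float = 0.4
    threshold: float = 1.0
    refractory: float = 4.0

    def __post_init__(self) -> None:
        if self.l0 < 0:
            raise ValueError(f"neuron {self.id!r}: l0 must be >= 0, got {self.l0}")
        if self.delta < 0:
            raise ValueError(f"neuron {self.id!r}: delta must be >= 0, got {self.delta}")
        if self.window <= 0:
            raise ValueError(f"neuron {self.id!r}: window must be > 0, got {self.window}")
        if self.threshold <= 0:
            raise ValueError(f"neuron {self.id!r}: threshold must be > 0")
        if self.refractory < 0:
            raise ValueError(f"neuron {self.id!r}: refractory must be >= 0")

    def latency(self, q: int) -> float:
        return latency_of(self, q)


@dataclass
class NeuronState:
    """Mutable per-neuron bookkeeping used by the simulation engines.

    ``q`` increments only on evoked spikes; a stimulation that fails to fire
    (sub-threshold, inhibited, refractory or skipped) leaves ``q`` unchanged,
    so latency stretching tracks actual spiking history.
    """

    q: int = 0
    last_trigger_time: float | None = None
    inhibition_intervals: list[tuple[float, float]] = field(default_factory=list)
    pending: list[tuple[float, float]] = field(default_factory=list)  # (time, strength)

    def add_inhibition(self, start: float, end: float) -> None:
        if not start < end:
            raise ValueError("inhibition interval must satisfy start < end")
        self.inhibition_intervals.append((start, end))

    def inhibited_at(self, t: float) -> bool:
        return any(
            a - TIME_EPS <= t <= b + TIME_EPS for a, b in self.inhibition_intervals
        )


@dataclass(frozen=True)
class LinkSpec:
    """Directed synaptic link with a fixed conduction delay and strength.

    ``strength`` in (0, 1] is the stimulation weight delivered to the target;
    a weak link (< target threshold) needs summation partners, a strong one
    (>= threshold) drives the target 1:1.  ``sign`` selects excitatory or
    inhibitory action.
    """

    source: str
    target: str
    delay: float
    strength: float = 1.0
    sign: str = EXCITATORY

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError(f"link {self.source}->{self.target}: delay must be >= 0")
        if not 0 < self.strength <= 1:
            raise ValueError(
                f"link {self.source}->{self.target}: strength must be in (0, 1]"
            )
        if self.sign not in (EXCITATORY, INHIBITORY):
            raise ValueError(f"link {self.source}->{self.target}: bad sign {self.sign!r}")

    @property
    def excitatory(self) -> bool:
        return self.sign == EXCITATORY


@dataclass(frozen=True)
class ChainSpec:
    """Closed-form description of one feedforward input chain.

    ``n`` counts the stimulated input neuron and every relay up to — but
    excluding — the neuron the chain terminates on, because only those
    latencies accumulate into the chain delay.
    """

    n: int
    tau0: float
    terminal_strength: float = 1.0
    terminal_sign: str = EXCITATORY

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"chain must contain at least one neuron, got n={self.n}")
        if self.tau0 <= 0:
            raise ValueError(f"chain initial delay must be > 0, got {self.tau0}")


class CircuitValidationError(ValueError):
    pass


@dataclass
class CircuitSpec:
    """A feedforward gate: neurons, links, designated inputs and one output.

    ``inputs`` are the logical input neurons; ``outer`` lists neurons that are
    stimulated on *every* computation regardless of the logical input pattern
    (the outer drive a NOT-style gate needs so that inhibition has something
    to veto).  ``inhibition_window`` is the (a, b) offset pair of the
    inhibitory veto interval.
    """

    neurons: dict[str, NeuronSpec]
    links: list[LinkSpec]
    inputs: list[str]
    output: str
    outer: list[str] = field(default_factory=list)
    inhibition_window: tuple[float, float] = (1.0, 7.0)
    graded_inhibition: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        a, b = self.inhibition_window
        if not a < b:
            raise CircuitValidationError(
                f"inhibition window must satisfy a < b, got ({a}, {b})"
            )
        for link in self.links:
            for end, label in ((link.source, "source"), (link.target, "target")):
                if end not in self.neurons:
                    raise CircuitValidationError(
                        f"link {link.source}->{link.target}: unknown {label} "
                        f"neuron {end!r}"
                    )
        for label in [*self.inputs, *self.outer, self.output]:
            if label not in self.neurons:
                raise CircuitValidationError(f"undeclared neuron label {label!r}")
        order = self.topological_order()  # raises on cycles
        # every non-input neuron reachable from some stimulated neuron
        reachable = set(self.inputs) | set(self.outer)
        for nid in order:
            if nid in reachable:
                for link in self.links:
                    if link.source == nid:
                        reachable.add(link.target)
        unreachable = set(self.neurons) - reachable
        if unreachable:
            raise CircuitValidationError(
                f"neurons unreachable from any input: {sorted(unreachable)}"
            )

    def topological_order(self) -> list[str]:
        indeg = {nid: 0 for nid in self.neurons}
        succ: dict[str, list[str]] = {nid: [] for nid in self.neurons}
        for link in self.links:
            indeg[link.target] += 1
            succ[link.source].append(link.target)
        frontier = sorted(nid for nid, d in indeg.items() if d == 0)
        order: list[str] = []
        while frontier:
            nid = frontier.pop(0)
            order.append(nid)
            for t in succ[nid]:
                indeg[t] -= 1
                if indeg[t] == 0:
                    frontier.append(t)
            frontier.sort()
        if len(order) != len(self.neurons):
            raise CircuitValidationError("circuit contains a cycle; must be feedforward")
        return order

    # -- graph helpers ---------------------------------------------------
    def links_from(self, nid: str) -> list[LinkSpec]:
        return [l for l in self.links if l.source == nid]

    def paths_to_output(self, start: str) -> list[list[LinkSpec]]:
        """Every link path from ``start`` to the output neuron."""
        out: list[list[LinkSpec]] = []

        def walk(nid: str, acc: list[LinkSpec]) -> None:
            if nid == self.output:
                out.append(list(acc))
                return
            for link in self.links_from(nid):
                acc.append(link)
                walk(link.target, acc)
                acc.pop()

        walk(start, [])
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "neurons": [
                {
                    "id": n.id,
                    "l0": n.l0,
                    "delta": n.delta,
                    "window": n.window,
                    "threshold": n.threshold,
                    "refractory": n.refractory,
                }
                for n in self.neurons.values()
            ],
            "links": [
                {
                    "source": l.source,
                    "target": l.target,
                    "delay": l.delay,
                    "strength": l.strength,
                    "sign": l.sign,
                }
                for l in self.links
            ],
            "inputs": list(self.inputs),
            "outer": list(self.outer),
            "output": self.output,
            "inhibition_window": list(self.inhibition_window),
            "graded_inhibition": self.graded_inhibition,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CircuitSpec":
        try:
            neurons = {d["id"]: NeuronSpec(**d) for d in doc["neurons"]}
            links = [LinkSpec(**d) for d in doc["links"]]
            return cls(
                neurons=neurons,
                links=links,
                inputs=list(doc["inputs"]),
                output=doc["output"],
                outer=list(doc.get("outer", [])),
                inhibition_window=tuple(doc.get("inhibition_window", (1.0, 7.0))),
                graded_inhibition=bool(doc.get("graded_inhibition", False)),
            )
        except (KeyError, TypeError) as exc:
            raise CircuitValidationError(f"malformed circuit document: {exc}") from exc

    def with_delta(self, delta: float) -> "CircuitSpec":
        """Copy of the circuit with every neuron's latency increment replaced."""
        return CircuitSpec(
            neurons={nid: replace(n, delta=delta) for nid, n in self.neurons.items()},
            links=list(self.links),
            inputs=list(self.inputs),
            output=self.output,
            outer=list(self.outer),
            inhibition_window=self.inhibition_window,
            graded_inhibition=self.graded_inhibition,
        )


# ---------------------------------------------------------------------------
# elementary rules
# ---------------------------------------------------------------------------

def latency_of(spec: NeuronSpec, q: int) -> float:
    """Response latency after ``q`` evoked spikes: ``l0 + q * delta``."""
    if q < 0:
        raise ValueError(f"spike count q must be >= 0, got {q}")
    return spec.l0 + q * spec.delta


def chain_delay(chain: ChainSpec, delta: float, q: int | float) -> float:
    """Total chain delay after ``q`` stimulations: ``tau0 + n * q * delta``."""
    if q < 0:
        raise ValueError(f"stimulation count q must be >= 0, got {q}")
    return chain.tau0 + chain.n * q * delta


def summation_decision(
    arrivals: Iterable[tuple[float, float]],
    theta: float = 1.0,
    w: float = 0.4,
) -> tuple[bool, float | None]:
    """Decide whether excitatory arrivals evoke a spike by summation.

    ``arrivals`` is any iterable of ``(time, strength)``.  The neuron fires at
    the earliest arrival time ``t`` such that the strengths delivered in the
    half-open window ``(t - w, t]`` sum to at least ``theta`` — i.e. lags
    strictly smaller than ``w`` sum, a lag of exactly ``w`` does not.

    Returns ``(fires, fire_time)`` with ``fire_time`` the triggering arrival's
    time, or ``(False, None)``.
    """
    pts = sorted(arrivals)
    for i, (t, _) in enumerate(pts):
        total = 0.0
        for tj, sj in pts[: i + 1]:
            if tj > t - w + TIME_EPS:  # strictly inside (t - w, t]
                total += sj
        if total >= theta:
            return True, t
    return False, None


def inhibition_covers(
    inhibition_time: float,
    excitation_time: float,
    window: tuple[float, float] = (1.0, 7.0),
) -> bool:
    """True iff the excitation falls in the closed veto interval [T+a, T+b]."""
    a, b = window
    if not a < b:
        raise ValueError(f"inhibition window must satisfy a < b, got ({a}, {b})")
    return (
        inhibition_time + a - TIME_EPS
        <= excitation_time
        <= inhibition_time + b + TIME_EPS
    )


def refractory_blocks(last_spike: float, candidate: float, r: float) -> bool:
    """True iff the candidate trigger is strictly closer than ``r`` to the last."""
    if candidate < last_spike:
        raise ValueError("candidate trigger must not precede the last spike")
    return candidate - last_spike < r - TIME_EPS


def graded_inhibition_strength(
    gap: float, absolute_until: float = 5.0, vanishes_at: float = 10.0
) -> float:
    """Empirical veto probability as a function of the inhibition→excitation gap.

    The measured inhibition profile is not a sharp window: a veto is near
    absolute when the inhibitory stimulation leads the excitatory one by up to
    ~5 ms and fades out linearly, vanishing around ~10 ms.  Returns the blocking
    probability in [0, 1]; gaps <= 0 (excitation first) are never blocked.
    """
    if gap <= 0:
        return 0.0
    if gap <= absolute_until:
        return 1.0
    if gap >= vanishes_at:
        return 0.0
    return (vanishes_at - gap) / (vanishes_at - absolute_until)


def is_physiological_delta(delta: float) -> bool:
    """Whether a latency increment lies in the observed 2–7 us/spike range."""
    lo, hi = PHYSIOLOGICAL_DELTA_RANGE
    return lo <= delta <= hi


def fit_delta(qs: Sequence[float], latencies: Sequence[float]) -> float:
    """Least-squares slope of latency vs. evoked-spike count.

    On noise-free data generated by the linear latency rule this recovers the
    configured increment exactly (up to floating point).
    """
    if len(qs) != len(latencies):
        raise ValueError("q and latency series must have equal length")
    if len(qs) < 2:
        raise ValueError("need at least two points to estimate a slope")
    n = float(len(qs))
    mq = math.fsum(qs) / n
    ml = math.fsum(latencies) / n
    sxx = math.fsum((q - mq) ** 2 for q in qs)
    if sxx == 0:
        raise ValueError("all q values are equal; slope undefined")
    sxy = math.fsum((q - mq) * (l - ml) for q, l in zip(qs, latencies))
    return sxy / sxx
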