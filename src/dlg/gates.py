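"""Builders for the named dynamic logic-gate architectures.

Each builder assembles a :class:`~dlg.core.CircuitSpec` realising one of the
canonical gate families:

* coincidence (AND-type) gates — weak terminal links onto the output, which
  fires only under temporal summation within its window;
* relay (OR-type) gates — strong links throughout, with the refractory period
  deciding between one merged and two independent output spikes;
* veto (NOT/XOR/multi-mode) gates — inhibitory chains whose delay lines sweep
  through the inhibition window as stimulation history accumulates.

Chain totals are honoured exactly: a chain of ``n`` neurons contributing an
initial delay ``tau0`` at its target gets per-neuron initial latencies plus
link delays summing to ``tau0``, so its delay line is ``tau0 + n*q*delta``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .analytic import build_lines, inhibition_regions
from .core import (
    EXCITATORY,
    INHIBITORY,
    CircuitSpec,
    LinkSpec,
    NeuronSpec,
)
from .logic import TruthTable, classify  # noqa: F401  (re-exported classifier)

__all__ = [
    "build_and",
    "build_or",
    "build_not",
    "build_xor",
    "build_generalized_and",
    "build_multimode",
    "random_coincidence_gate",
    "classify",
    "TruthTable",
]

_DEFAULT_L0 = 2.0


def _chain(
    prefix: str,
    n: int,
    total_delay: float,
    target: str,
    delta: float,
    *,
    strength: float = 1.0,
    sign: str = EXCITATORY,
    window: float = 0.4,
    threshold: float = 1.0,
    refractory: float = 4.0,
    l0: float = _DEFAULT_L0,
) -> tuple[dict[str, NeuronSpec], list[LinkSpec], str]:
    """A feedforward chain of ``n`` neurons ending in one link onto ``target``.

    The sum of the neurons' initial latencies and the link delays equals
    ``total_delay``; intermediate links are strong and excitatory, only the
    terminal link carries the requested strength and sign.
    """
    if n < 1:
        raise ValueError("chain needs at least one neuron")
    if total_delay <= 0:
        raise ValueError("chain initial delay must be > 0")
    if total_delay <= n * l0:
        l0 = total_delay / (2 * n)  # keep link delays strictly positive
    per_link = (total_delay - n * l0) / n
    names = [prefix] + [f"{prefix}_r{i}" for i in range(1, n)]
    neurons = {
        name: NeuronSpec(
            name, l0=l0, delta=delta, window=window, threshold=threshold,
            refractory=refractory,
        )
        for name in names
    }
    links = [
        LinkSpec(a, b, delay=per_link, strength=1.0, sign=EXCITATORY)
        for a, b in zip(names, names[1:])
    ]
    links.append(LinkSpec(names[-1], target, delay=per_link, strength=strength, sign=sign))
    return neurons, links, names[-1]


def _assemble(
    chains: Sequence[tuple[str, int, float, float, str]],
    *,
    delta: float,
    window: float,
    threshold: float = 1.0,
    refractory: float = 4.0,
    outer: Sequence[str] = (),
    inhibition_window: tuple[float, float] = (1.0, 7.0),
) -> CircuitSpec:
    """Assemble input chains (name, n, tau0, strength, sign) onto one output."""
    neurons: dict[str, NeuronSpec] = {
        "out": NeuronSpec(
            "out", l0=_DEFAULT_L0, delta=delta, window=window,
            threshold=threshold, refractory=refractory,
        )
    }
    links: list[LinkSpec] = []
    inputs: list[str] = []
    for name, n, tau0, strength, sign in chains:
        ns, ls, _ = _chain(
            name, n, tau0, "out", delta,
            strength=strength, sign=sign, window=window,
            threshold=threshold, refractory=refractory,
        )
        neurons.update(ns)
        links.extend(ls)
        if name not in outer:
            inputs.append(name)
    return CircuitSpec(
        neurons=neurons,
        links=links,
        inputs=inputs,
        output="out",
        outer=list(outer),
        inhibition_window=inhibition_window,
    )


# ---------------------------------------------------------------------------

def build_and(
    chain_lengths: tuple[int, int] = (3, 1),
    tau_long: float = 80.0,
    gap: float = 1.6,
    *,
    delta: float = 0.005,
    window: float = 0.5,
    strength: float = 0.5,
) -> CircuitSpec:
    """Two-input coincidence gate: a multi-neuron and a single-neuron chain.

    Both terminal links are weak (default 0.5 against a threshold of 1), so
    the output fires only when the two chain delays coincide within the
    summation window.  The longer chain starts ``gap`` ms ahead of the
    ``tau_long`` reference delay and, stretching faster, overtakes it —
    producing the NULL -> AND -> NULL history under repeated joint drive.
    """
    n1, n2 = chain_lengths
    return _assemble(
        [
            ("in1", n1, tau_long - gap, strength, EXCITATORY),
            ("in2", n2, tau_long, strength, EXCITATORY),
        ],
        delta=delta,
        window=window,
    )


def build_or(
    chain_lengths: tuple[int, int] = (4, 1),
    taus: tuple[float, float] = (72.0, 80.0),
    *,
    delta: float = 0.006,
    refractory: float = 4.0,
    window: float = 0.4,
) -> CircuitSpec:
    """Two-input relay gate with strong links throughout.

    Each stimulated input reliably drives the output; when both arrivals are
    separated by at least the refractory period the output answers (1, 1)
    with two independent spikes (DOUBLE mode), and with a single spike —
    a true OR — once the chain delays have converged to within it.
    """
    n1, n2 = chain_lengths
    t1, t2 = taus
    return _assemble(
        [
            ("in1", n1, t1, 1.0, EXCITATORY),
            ("in2", n2, t2, 1.0, EXCITATORY),
        ],
        delta=delta,
        window=window,
        refractory=refractory,
    )


def build_not(
    tau_exc: float = 80.0,
    tau_inh: float = 70.0,
    chain_lengths: tuple[int, int] = (3, 1),
    *,
    delta: float = 0.006,
    window: float = 0.4,
    graded: bool = False,
) -> CircuitSpec:
    """Single-input veto gate with an outer excitatory drive.

    The logical input ``in1`` feeds an inhibitory chain onto the output; the
    outer neuron ``in2`` is stimulated on *every* computation and normally
    drives the output 1:1.  While the excitation->inhibition gap sits inside
    the inhibition window the gate computes NOT(in1); outside it the output
    fires regardless, the constant-1 mode flanking the NOT interval.

    ``graded=True`` swaps the sharp [1, 7] ms window for the empirical graded
    veto profile (absolute up to ~5 ms, fading out by ~10 ms) in event-driven
    runs; closed-form analysis always uses the sharp window.
    """
    n_inh, n_exc = chain_lengths
    circuit = _assemble(
        [
            ("in1", n_inh, tau_inh, 1.0, INHIBITORY),
            ("in2", n_exc, tau_exc, 1.0, EXCITATORY),
        ],
        delta=delta,
        window=window,
        outer=["in2"],
    )
    circuit.graded_inhibition = graded
    return circuit


def build_xor(
    exc_lengths: tuple[int, int] = (2, 5),
    exc_taus: tuple[float, float] = (48.0, 50.0),
    inhibitory_delay: float = 32.0,
    *,
    delta: float = 0.004,
    window: float = 0.4,
) -> CircuitSpec:
    """Two-input gate with cross-inhibition: OR flanking a transient XOR.

    Two strong excitatory chains (2 and 5 neurons) relay each input to the
    output; each input additionally sends an inhibitory stimulation, with
    initial delay ``inhibitory_delay``, onto a relay *inside the other
    input's chain*.  The first chain is parked permanently inside the other's
    veto window (zero relative slope), while the longer chain's relay sweeps
    through the window only transiently — so joint stimulation is silenced
    over a bounded history interval, turning OR into XOR and back.
    """
    n1, n2 = exc_lengths
    t1, t2 = exc_taus
    if n1 < 2 or n2 < 2:
        raise ValueError("cross-inhibition needs a relay inside each chain")
    delta_ = delta
    circuit = _assemble(
        [
            ("in1", n1, t1, 1.0, EXCITATORY),
            ("in2", n2, t2, 1.0, EXCITATORY),
        ],
        delta=delta_,
        window=window,
    )
    # inhibited relays: first relay of chain 1, last relay of chain 2
    relay1 = "in1_r1"
    relay2 = f"in2_r{n2 - 1}"
    l0 = circuit.neurons["in1"].l0
    circuit.links.append(
        LinkSpec("in2", relay1, delay=inhibitory_delay - l0, strength=1.0, sign=INHIBITORY)
    )
    circuit.links.append(
        LinkSpec("in1", relay2, delay=inhibitory_delay - l0, strength=1.0, sign=INHIBITORY)
    )
    # park chain 1 permanently inside the veto window (parallel lines, gap 4)
    a, b = circuit.inhibition_window
    _set_relay_arrival(circuit, "in1", relay1, inhibitory_delay + (a + b) / 2)
    # start chain 2's relay 2 ms ahead of the veto so its faster stretching
    # sweeps it through the whole window
    _set_relay_arrival(circuit, "in2", relay2, inhibitory_delay - 2.0)
    circuit.validate()
    return circuit


def build_generalized_and(
    chain_lengths: Sequence[int] = (1, 2, 5),
    taus: Sequence[float] = (30.0, 27.0, 25.0),
    strengths: Sequence[float] | None = None,
    *,
    delta: float = 0.006,
    window: float = 0.4,
    threshold: float = 1.0,
) -> CircuitSpec:
    """Coincidence gate with k weak input chains of chosen lengths and delays.

    With equal strengths of 0.5 any two coinciding chains fire the output, so
    every pairwise delay-line crossing opens an AND region for that pair — up
    to k(k-1)/2 of them.  Unequal strengths prune crossings whose summed
    strength stays below threshold.
    """
    if len(chain_lengths) != len(taus):
        raise ValueError("need one initial delay per chain")
    if strengths is None:
        strengths = [0.5] * len(chain_lengths)
    if len(strengths) != len(chain_lengths):
        raise ValueError("need one strength per chain")
    chains = [
        (f"in{i + 1}", n, tau, s, EXCITATORY)
        for i, (n, tau, s) in enumerate(zip(chain_lengths, taus, strengths))
    ]
    return _assemble(chains, delta=delta, window=window, threshold=threshold)


def build_multimode(
    inhibition_taus: tuple[float, float] = (30.0, 42.0),
    outer_tau: float = 40.0,
    outer_relay_tau: float = 10.0,
    chain_lengths: tuple[int, int, int] = (4, 1, 2),
    *,
    delta: float = 0.006,
    window: float = 0.4,
) -> CircuitSpec:
    """Two-input gate traversing five modes: TRUE, NOT(in1), NOR, NOT(in2), TRUE.

    An outer excitatory chain (initial delay ``outer_tau``, with its first
    relay reached at ``outer_relay_tau``) fires the output on every
    computation.  Each input drives an inhibitory chain; the first inhibition
    chain is longer than the outer chain, which is longer than the second
    (``chain_lengths`` = (inh1, inh2, outer)), so as stimulation history
    accumulates the first veto sweeps *into* the window while the second is
    swept into it from the other side.  The two veto intervals are validated
    at build time to be staggered — overlapping in the middle — which is what
    produces the five-mode sequence.
    """
    n_inh1, n_inh2, n_outer = chain_lengths
    t_inh1, t_inh2 = inhibition_taus
    if n_outer < 2:
        raise ValueError("outer chain needs at least two neurons (a relay stage)")
    circuit = _assemble(
        [
            ("in1", n_inh1, t_inh1, 1.0, INHIBITORY),
            ("in2", n_inh2, t_inh2, 1.0, INHIBITORY),
            ("outer", n_outer, outer_tau, 1.0, EXCITATORY),
        ],
        delta=delta,
        window=window,
        outer=["outer"],
    )
    # pin the outer chain's first relay arrival to outer_relay_tau
    _set_relay_arrival(circuit, "outer", "outer_r1", outer_relay_tau)

    # validate the five-mode structure from the closed forms
    lines = {l.chain_id: l for l in build_lines(circuit, delta)}
    exc = lines["outer"]
    v1 = inhibition_regions(exc, lines["in1~out"], circuit.inhibition_window, 1e9)
    v2 = inhibition_regions(exc, lines["in2~out"], circuit.inhibition_window, 1e9)
    ok = bool(v1) and bool(v2)
    if ok:
        (lo1, hi1), (lo2, hi2) = v1[0], v2[0]
        ok = 0 < lo1 < lo2 < hi1 < hi2
    if not ok:
        raise ValueError(
            "chain lengths/delays do not stagger the two veto intervals; "
            "the five-mode sequence would not occur"
        )
    return circuit


def _set_relay_arrival(
    circuit: CircuitSpec, chain: str, relay: str, arrival: float
) -> None:
    """Redistribute a chain's link delays so its ``relay`` is reached at
    ``arrival`` while the chain's total delay at the output is unchanged.

    The links upstream of the relay are set equal so the cumulative delay
    (initial latencies plus links) at the relay is ``arrival``; downstream
    links absorb the remainder.  Raises if that would need a non-positive
    link delay.
    """
    # walk the excitatory spine of the chain
    names = [chain]
    while True:
        nxt = next(
            (l.target for l in circuit.links
             if l.source == names[-1] and l.target != circuit.output
             and l.sign == EXCITATORY and l.target.startswith(chain)),
            None,
        )
        if nxt is None:
            break
        names.append(nxt)
    if relay not in names[1:]:
        raise ValueError(f"{relay!r} is not a relay of chain {chain!r}")
    j = names.index(relay)
    total = sum(circuit.neurons[n].l0 for n in names) + sum(
        l.delay for l in circuit.links
        if l.source in names and (l.target in names or l.target == circuit.output)
        and l.sign == EXCITATORY
    )
    l0_prefix = sum(circuit.neurons[n].l0 for n in names[:j])
    l0_suffix = sum(circuit.neurons[n].l0 for n in names[j:])
    n_pre, n_post = j, len(names) - j
    pre = (arrival - l0_prefix) / n_pre
    post = (total - arrival - l0_suffix) / n_post
    if pre <= 0 or post <= 0:
        raise ValueError("cannot retime relay arrival with positive link delays")
    spine = list(zip(names, names[1:])) + [(names[-1], circuit.output)]
    for i, link in enumerate(circuit.links):
        if (link.source, link.target) in spine and link.sign == EXCITATORY:
            idx = spine.index((link.source, link.target))
            d = pre if idx < j else post
            circuit.links[i] = LinkSpec(link.source, link.target, d, link.strength, link.sign)


# ---------------------------------------------------------------------------

def random_coincidence_gate(
    rng: np.random.Generator,
    max_inputs: int = 4,
    *,
    delta: float = 0.006,
    window: float = 0.4,
) -> CircuitSpec:
    """Random general-position coincidence gate for property testing.

    Chain lengths are drawn distinct (distinct slopes), initial delays
    strictly decreasing with length and jittered off any concurrency, and
    strengths drawn so that at least one pair can reach threshold.
    """
    k = int(rng.integers(2, max_inputs + 1))
    lengths = sorted(rng.choice(np.arange(1, 8), size=k, replace=False).tolist())
    base = float(rng.uniform(28.0, 40.0))
    taus = [base - i * float(rng.uniform(1.5, 4.0)) + float(rng.uniform(-0.2, 0.2))
            for i in range(k)]
    strengths = [float(rng.uniform(0.4, 0.8)) for _ in range(k)]
    strengths[int(rng.integers(0, k))] = 0.6  # guarantee a viable pair exists
    strengths[int(rng.integers(0, k))] = 0.6
    return build_generalized_and(
        lengths, taus, strengths, delta=delta, window=window
    )
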