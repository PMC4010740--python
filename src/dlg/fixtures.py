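"""Named reference configurations used by the test and acceptance suites.

Each fixture reconstructs one canonical gate or population setup
programmatically (no stored data files) and pairs it with the stimulation
protocol it is meant to run under.  Most fixtures return ``(CircuitSpec,
StimulationProtocol)``; the edge-detector fixture returns an
:class:`~dlg.applications.EdgeDetector` and the population fixture a
:class:`~dlg.hh.PopulationSpec` as the first element, since those setups are
not single-output circuits.
"""

from __future__ import annotations

from typing import Callable

from .applications import EdgeDetector
from .events import StimulationProtocol
from .gates import (
    build_and,
    build_generalized_and,
    build_multimode,
    build_not,
    build_or,
    build_xor,
)
from .hh import PopulationSpec

__all__ = ["fixture", "fixture_names", "FIXTURES"]


def _fig2_and():
    # two-chain AND: 1.3 ms initial delay gap, 0.5 ms window, 0.005 ms/spike
    return (
        build_and(gap=1.3, delta=0.005, window=0.5),
        StimulationProtocol(count=400, seed=0),
    )


def _fig3_or():
    return build_or(), StimulationProtocol(count=400, seed=0)


def _fig4_not():
    return build_not(), StimulationProtocol(count=1000, seed=0)


def _fig6c():
    return (
        build_generalized_and(
            chain_lengths=(1, 2, 5), taus=(30.0, 27.0, 25.0), delta=0.004
        ),
        StimulationProtocol(count=1000, seed=0),
    )


def _fig6d():
    return (
        build_generalized_and(
            chain_lengths=(1, 2, 5), taus=(30.0, 27.0, 25.0), delta=0.006
        ),
        StimulationProtocol(count=700, seed=0),
    )


def _fig6e():
    # shortening the steepest chain from 5 to 3 merges the three AND regions
    return (
        build_generalized_and(
            chain_lengths=(1, 2, 3), taus=(30.0, 27.0, 25.0), delta=0.006
        ),
        StimulationProtocol(count=700, seed=0),
    )


def _fig7a():
    # four chains in general position: all six crossings at distinct counts
    return (
        build_generalized_and(
            chain_lengths=(1, 2, 4, 6), taus=(30.0, 27.8, 25.2, 22.1), delta=0.006
        ),
        StimulationProtocol(count=600, seed=0),
    )


def _fig7b():
    # weighted stimulations: the 0.3 + 0.5 pair stays below threshold 1
    return (
        build_generalized_and(
            chain_lengths=(1, 2, 5),
            taus=(30.0, 27.0, 25.0),
            strengths=(0.3, 0.75, 0.5),
            delta=0.004,
        ),
        StimulationProtocol(count=900, seed=0),
    )


def _fig8_xor():
    return build_xor(), StimulationProtocol(count=1000, seed=0)


def _fig9_multimode():
    return build_multimode(), StimulationProtocol(count=1800, seed=0)


def _fig10_varying():
    circuit = build_generalized_and(
        chain_lengths=(3, 6), taus=(30.0, 27.3), delta=0.006
    )
    protocol = StimulationProtocol(
        count=800, moderation={"in2": (250, 475, 0.1)}, seed=0
    )
    return circuit, protocol


def _fig11_edges():
    # eight-position row of 3-neuron chains; 500-round charging budget
    return EdgeDetector(n_inputs=8), StimulationProtocol(count=500, seed=0)


def _fig12a():
    return (
        build_generalized_and(
            chain_lengths=(1, 2, 5), taus=(30.0, 27.0, 25.0), delta=0.006
        ),
        StimulationProtocol(count=700, seed=0),
    )


def _fig12b():
    # long chains of short synaptic delays: identical pairwise differences of
    # chain lengths (1, 4, 3) and of initial delays (3, 5, 2) as the short gate
    return (
        build_generalized_and(
            chain_lengths=(26, 27, 30), taus=(135.0, 132.0, 130.0), delta=0.006
        ),
        StimulationProtocol(count=700, seed=0),
    )


def _fig13_population():
    return PopulationSpec(), StimulationProtocol(count=60, seed=0)


FIXTURES: dict[str, Callable[[], tuple]] = {
    "fig2_and": _fig2_and,
    "fig3_or": _fig3_or,
    "fig4_not": _fig4_not,
    "fig6c": _fig6c,
    "fig6d": _fig6d,
    "fig6e": _fig6e,
    "fig7a": _fig7a,
    "fig7b": _fig7b,
    "fig8_xor": _fig8_xor,
    "fig9_multimode": _fig9_multimode,
    "fig10_varying": _fig10_varying,
    "fig11_edges": _fig11_edges,
    "fig12a": _fig12a,
    "fig12b": _fig12b,
    "fig13_population": _fig13_population,
}


def fixture_names() -> list[str]:
    return sorted(FIXTURES)


def fixture(name: str) -> tuple:
    """Return the named reference configuration and its protocol.

    Raises ``KeyError`` listing the available names when unknown.
    """
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return builder()
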