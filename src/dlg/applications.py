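"""History-based edge detection with a bank of dynamic AND-gates.

A brightness vector is rate-coded onto a row of identical relay chains: during
a charging period each input neuron is stimulated a number of times
proportional to the brightness at its position, so each chain's delay
stretches proportionally to its local brightness.  Neighbouring chains share a
dynamic AND-gate.  A probe — one simultaneous stimulation of all inputs —
then fires every gate whose two arrival times still coincide within the
summation window; gates spanning a brightness discontinuity have drifted
apart and stay silent (NULL).  The silent gates mark the edges.

The detection criterion is exactly the core temporal-summation rule
(:func:`dlg.core.summation_decision`); there is no separate threshold.
Resetting the latencies restores the uncharged detector for reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import summation_decision

__all__ = [
    "BrightnessVector",
    "EdgeDetector",
    "EdgeReport",
    "PairReport",
    "charge",
    "probe",
    "reset",
]


@dataclass(frozen=True)
class BrightnessVector:
    """Ordered non-negative brightness values along a 1-D input row."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("a brightness vector needs at least two positions")
        if any(v < 0 for v in self.values):
            raise ValueError("brightness values must be non-negative")
        if max(self.values) == 0:
            raise ValueError("at least one brightness value must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_sequence(cls, values: Sequence[float]) -> "BrightnessVector":
        return cls(tuple(float(v) for v in values))


@dataclass(frozen=True)
class EdgeDetector:
    """A row of identical relay chains; neighbours share a dynamic AND-gate.

    ``q`` holds the accumulated evoked-spike count of each chain (every
    charging stimulation relays 1:1 through the chain, so all neurons of a
    chain share one count).  The chain delay seen by a gate is
    ``tau0 + chain_length * q_i * delta``.
    """

    n_inputs: int
    chain_length: int = 3
    tau0: float = 30.0
    delta: float = 0.006
    window: float = 0.4
    threshold: float = 1.0
    strength: float = 0.5
    q: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_inputs < 2:
            raise ValueError("an edge detector needs at least two inputs")
        if self.chain_length < 1:
            raise ValueError("chain length must be >= 1")
        if not self.q:
            object.__setattr__(self, "q", (0.0,) * self.n_inputs)
        if len(self.q) != self.n_inputs:
            raise ValueError("q must hold one count per input chain")
        if not 0 < self.strength < self.threshold:
            raise ValueError(
                "pair strengths must be individually sub-threshold "
                "(0 < strength < threshold) for AND behaviour"
            )
        if 2 * self.strength < self.threshold:
            raise ValueError("two coincident inputs must reach threshold")

    @property
    def delays(self) -> np.ndarray:
        """Current input-to-gate delay of every chain (ms)."""
        return self.tau0 + self.chain_length * np.asarray(self.q) * self.delta


@dataclass(frozen=True)
class PairReport:
    pair_index: int
    mode: str  # "AND" or "NULL"
    delay_diff_ms: float


@dataclass(frozen=True)
class EdgeReport:
    """Per adjacent pair: gate mode after charging and final delay gap."""

    pairs: tuple[PairReport, ...]

    @property
    def edges(self) -> list[int]:
        return [p.pair_index for p in self.pairs if p.mode == "NULL"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pair_index": p.pair_index, "mode": p.mode,
                 "delay_diff_ms": p.delay_diff_ms}
                for p in self.pairs
            ]
        )


def charge(
    detector: EdgeDetector,
    brightness: BrightnessVector,
    duration: int,
    method: Literal["deterministic", "stochastic"] = "deterministic",
    seed: int = 0,
) -> EdgeDetector:
    """Stimulate each input proportionally to its brightness.

    ``deterministic`` delivers ``round(duration * b_i / max(b))`` stimulations
    to input i; ``stochastic`` keeps a single global clock of ``duration``
    rounds and delivers each round to input i with probability
    ``b_i / max(b)`` (counts are then binomial around the same mean).
    Charging accumulates on top of any existing state; use :func:`reset`
    first for a fresh exposure.
    """
    if len(brightness) != detector.n_inputs:
        raise ValueError(
            f"brightness vector length {len(brightness)} != detector inputs "
            f"{detector.n_inputs}"
        )
    if duration < 0:
        raise ValueError("charging duration must be >= 0")
    b = np.asarray(brightness.values, dtype=float)
    p = b / b.max()
    if method == "deterministic":
        counts = np.round(duration * p)
    elif method == "stochastic":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        counts = rng.binomial(duration, p).astype(float)
    else:
        raise ValueError(f"unknown charging method {method!r}")
    new_q = tuple(float(qi + ci) for qi, ci in zip(detector.q, counts))
    return replace(detector, q=new_q)


def probe(detector: EdgeDetector) -> EdgeReport:
    """One simultaneous stimulation of all inputs; report each gate's mode.

    A pair gate fires (AND) when both arrivals fall within one summation
    window and their strengths sum to threshold; otherwise it is NULL — an
    edge.  The probe evaluates a cloned state and does not perturb the
    detector (the single probe stimulation is excluded from the recorded
    charge so repeated probes agree).
    """
    delays = detector.delays
    pairs = []
    for i in range(detector.n_inputs - 1):
        arrivals = [
            (float(delays[i]), detector.strength),
            (float(delays[i + 1]), detector.strength),
        ]
        fires, _ = summation_decision(
            arrivals, theta=detector.threshold, w=detector.window
        )
        pairs.append(
            PairReport(
                pair_index=i,
                mode="AND" if fires else "NULL",
                delay_diff_ms=float(abs(delays[i + 1] - delays[i])),
            )
        )
    return EdgeReport(tuple(pairs))


def reset(detector: EdgeDetector) -> EdgeDetector:
    """Restore all chain latencies to their initial values (reusable sensor)."""
    return replace(detector, q=(0.0,) * detector.n_inputs)


def minimal_detectable_contrast(
    detector: EdgeDetector,
    duration: int,
    contrasts: Sequence[float] = tuple(np.linspace(1.0, 10.0, 91)),
) -> float:
    """Smallest step contrast (bright/dark ratio) the detector reports.

    Charges a fresh clone with a two-level step at each candidate contrast and
    returns the first one whose step pair goes NULL; ``inf`` if none does.
    Sensitivity grows with charging duration: a longer exposure lets a smaller
    contrast accumulate the same delay divergence.
    """
    n = detector.n_inputs
    half = n // 2
    for c in contrasts:
        vec = BrightnessVector.from_sequence([1.0] * half + [c] * (n - half))
        report = probe(charge(reset(detector), vec, duration))
        if c > 1.0 and report.edges == [half - 1]:
            return float(c)
    return float("inf")
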