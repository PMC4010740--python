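"""Truth tables and the logic-mode classifier.

A gate's instantaneous behaviour at a given stimulation count is summarised
by a :class:`TruthTable`: for each of the ``2**k`` input combinations, whether
the output fires and with how many spikes.  :func:`classify` maps a table onto
the canonical operating-mode labels used throughout the package:

``NULL, AND, OR, XOR, NOT, NOR, TRUE, IDENTITY, DOUBLE, OTHER``

``AND``/``IDENTITY``/``NOT`` labels carry the participating input(s), e.g.
``AND(in1,in3)`` for a sub-AND over two of three inputs or ``NOT(in1)``.
``DOUBLE`` flags any combination answered with two or more output spikes —
two temporally independent relays rather than one logical response.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

__all__ = ["TruthTable", "classify", "canonical_table"]

Combo = tuple[int, ...]


@dataclass(frozen=True)
class TruthTable:
    """Complete mapping combo -> (fires, spike multiplicity) for k inputs."""

    arity: int
    entries: tuple[tuple[Combo, int], ...]  # ((bits...), multiplicity), sorted

    @classmethod
    def from_mapping(cls, mapping: Mapping[Combo, int]) -> "TruthTable":
        combos = list(product((0, 1), repeat=len(next(iter(mapping)))))
        if set(mapping) != set(combos):
            raise ValueError("truth table must cover all 2^k input combinations")
        if any(m < 0 for m in mapping.values()):
            raise ValueError("spike multiplicities must be >= 0")
        arity = len(combos[0])
        return cls(arity, tuple((c, int(mapping[c])) for c in sorted(combos)))

    def multiplicity(self, combo: Combo) -> int:
        return dict(self.entries)[tuple(combo)]

    def fires(self, combo: Combo) -> bool:
        return self.multiplicity(combo) > 0

    @property
    def boolean(self) -> dict[Combo, bool]:
        return {c: m > 0 for c, m in self.entries}


def canonical_table(label: str, arity: int) -> TruthTable:
    """Build the canonical truth table for a (possibly parameterised) label.

    Accepts ``NULL, TRUE, AND, OR, XOR, NOR`` and the parameterised forms
    ``NOT(in_i)``, ``IDENTITY(in_i)``, ``AND(in_i,in_j,...)`` where inputs are
    named ``in1..ink``.
    """
    combos = list(product((0, 1), repeat=arity))

    def idxs(args: str) -> list[int]:
        out = []
        for tok in args.split(","):
            tok = tok.strip()
            if not tok.startswith("in"):
                raise ValueError(f"bad input name {tok!r}")
            out.append(int(tok[2:]) - 1)
        return out

    if label.startswith("NOT(") and label.endswith(")"):
        (i,) = idxs(label[4:-1])
        fn = lambda c: c[i] == 0
    elif label.startswith("IDENTITY(") and label.endswith(")"):
        (i,) = idxs(label[9:-1])
        fn = lambda c: c[i] == 1
    elif label.startswith("AND(") and label.endswith(")"):
        sel = idxs(label[4:-1])
        fn = lambda c: all(c[i] == 1 for i in sel)
    elif label == "NULL":
        fn = lambda c: False
    elif label == "TRUE":
        fn = lambda c: True
    elif label == "AND":
        fn = lambda c: all(c)
    elif label == "OR":
        fn = lambda c: any(c)
    elif label == "NOR":
        fn = lambda c: not any(c)
    elif label == "XOR":
        fn = lambda c: sum(c) % 2 == 1
    elif label == "NOT":
        if arity != 1:
            raise ValueError("bare NOT is only canonical for a single input")
        fn = lambda c: c[0] == 0
    else:
        raise ValueError(f"unknown canonical label {label!r}")
    return TruthTable.from_mapping({c: int(fn(c)) for c in combos})


def classify(table: TruthTable) -> str:
    """Map a truth table to its operating-mode label.

    Matching is exact.  Any combination with multiplicity >= 2 short-circuits
    to ``DOUBLE``; unknown boolean patterns are labelled ``OTHER`` rather than
    dropped.
    """
    if any(m >= 2 for _, m in table.entries):
        return "DOUBLE"
    k = table.arity
    bits = table.boolean
    combos = [c for c, _ in table.entries]

    if not any(bits.values()):
        return "NULL"
    if all(bits.values()):
        return "TRUE"
    # single-input determinations: output == in_i or == not in_i
    for i in range(k):
        if all(bits[c] == (c[i] == 1) for c in combos):
            return f"IDENTITY(in{i + 1})" if k > 1 else "IDENTITY"
        if all(bits[c] == (c[i] == 0) for c in combos):
            return f"NOT(in{i + 1})" if k > 1 else "NOT"
    # conjunctions over a subset of >= 2 inputs
    on = [c for c in combos if bits[c]]
    common = [i for i in range(k) if all(c[i] == 1 for c in on)]
    if len(common) >= 2 and all(
        bits[c] == all(c[i] == 1 for i in common) for c in combos
    ):
        if len(common) == k:
            return "AND"
        names = ",".join(f"in{i + 1}" for i in common)
        return f"AND({names})"
    if all(bits[c] == (not any(c)) for c in combos):
        return "NOR"
    if all(bits[c] == any(c) for c in combos):
        return "OR"
    if all(bits[c] == (sum(c) % 2 == 1) for c in combos):
        return "XOR"
    return "OTHER"
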