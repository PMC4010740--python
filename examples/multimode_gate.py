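"""A single circuit that traverses five logic modes as it is used.

Two inhibition chains and one outer excitatory drive compete at the output.
Because each chain stretches at a rate proportional to its length, the
inhibition windows sweep across the excitatory arrivals at different speeds,
and the gate's effective truth table changes with the stimulation count
alone — no rewiring.
"""

from dlg import build_multimode, mode_timeline, truth_table_at
from dlg.logic import classify

gate = build_multimode()
timeline = mode_timeline(gate, 1800)

print("operating-mode timeline:")
for interval in timeline.intervals:
    print(f"  [{interval.q_start:5d}, {interval.q_end:5d}]  {interval.label}")

print("\ntruth table in the middle of each interval:")
for interval in timeline.intervals:
    q = (interval.q_start + interval.q_end) // 2
    table = truth_table_at(gate, q)
    rows = ", ".join(
        f"{''.join(str(b) for b in combo)}->{multiplicity}"
        for combo, multiplicity in table.entries
    )
    print(f"  q = {q:5d}: {classify(table):9s}  [{rows}]")
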