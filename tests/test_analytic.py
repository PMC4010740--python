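"""Closed-form delay-line geometry, firing regions and mode timelines."""

import pytest

from dlg.analytic import (
    DelayLine,
    build_lines,
    evaluate_once,
    firing_regions,
    inhibition_regions,
    merge_regions,
    mode_timeline,
    pairwise_intersections,
    rescale_check,
    synfire_equivalent,
    truth_table_at,
)
from dlg.core import EXCITATORY
from dlg.gates import (
    build_generalized_and,
    build_multimode,
    build_not,
    build_xor,
)
from dlg.logic import classify


@pytest.fixture(scope="module")
def three_chain_gate():
    # chains of 1/2/5 neurons, initial delays 30/27/25 ms, 0.006 ms/spike
    return build_generalized_and(
        chain_lengths=(1, 2, 5), taus=(30.0, 27.0, 25.0), delta=0.006
    )


class TestDelayLines:
    def test_lines_carry_chain_geometry(self, three_chain_gate):
        lines = {l.chain_id: l for l in build_lines(three_chain_gate)}
        assert lines["in1"].intercept == pytest.approx(30.0)
        assert lines["in1"].slope == pytest.approx(1 * 0.006)
        assert lines["in2"].intercept == pytest.approx(27.0)
        assert lines["in2"].slope == pytest.approx(2 * 0.006)
        assert lines["in3"].intercept == pytest.approx(25.0)
        assert lines["in3"].slope == pytest.approx(5 * 0.006)
        assert all(l.sign == EXCITATORY for l in lines.values())

    def test_pairwise_intersections_closed_form(self, three_chain_gate):
        lines = build_lines(three_chain_gate)
        xs = pairwise_intersections(lines, horizon=1000)
        got = {frozenset(pair): q for pair, q in xs}
        # q* = (tau0_i - tau0_j) / (slope_j - slope_i)
        assert got[frozenset(("in2", "in3"))] == pytest.approx(2.0 / 0.018)
        assert got[frozenset(("in1", "in3"))] == pytest.approx(5.0 / 0.024)
        assert got[frozenset(("in1", "in2"))] == pytest.approx(3.0 / 0.006)
        # sorted by crossing count
        assert [q for _, q in xs] == sorted(q for _, q in xs)

    def test_parallel_lines_do_not_intersect(self):
        a = DelayLine("a", 30.0, 0.006, 0.5, EXCITATORY, "out")
        b = DelayLine("b", 27.0, 0.006, 0.5, EXCITATORY, "out")
        assert pairwise_intersections([a, b], horizon=1000) == []


class TestFiringRegions:
    def test_pair_regions_have_window_width(self, three_chain_gate):
        lines = build_lines(three_chain_gate)
        regions = firing_regions(lines, theta=1.0, w=0.4, horizon=1000)
        by_members = {r.members: r for r in regions}
        r23 = by_members[frozenset({"in2", "in3"})]
        # width = 2w / |slope difference|
        assert r23.q_end - r23.q_start == pytest.approx(2 * 0.4 / 0.018)
        assert (r23.q_start + r23.q_end) / 2 == pytest.approx(2.0 / 0.018)

    def test_regions_disjoint_for_well_separated_crossings(self, three_chain_gate):
        lines = build_lines(three_chain_gate)
        regions = sorted(
            firing_regions(lines, theta=1.0, w=0.4, horizon=1000),
            key=lambda r: r.q_start,
        )
        assert len(regions) == 3
        for a, b in zip(regions, regions[1:]):
            assert a.q_end < b.q_start

    def test_subthreshold_strength_pair_suppressed(self):
        weighted = build_generalized_and(
            chain_lengths=(1, 2, 5),
            taus=(30.0, 27.0, 25.0),
            strengths=(0.3, 0.75, 0.5),
            delta=0.004,
        )
        lines = build_lines(weighted)
        regions = firing_regions(lines, theta=1.0, w=0.4, horizon=2000)
        assert frozenset({"in1", "in3"}) not in {r.members for r in regions}
        assert {r.members for r in regions} == {
            frozenset({"in1", "in2"}),
            frozenset({"in2", "in3"}),
        }

    def test_merge_regions_joins_overlaps(self):
        merged_gate = build_generalized_and(
            chain_lengths=(1, 2, 3), taus=(30.0, 27.0, 25.0), delta=0.006
        )
        lines = build_lines(merged_gate)
        regions = firing_regions(lines, theta=1.0, w=0.4, horizon=1000)
        assert len(regions) == 3
        assert len(merge_regions(regions)) == 1


class TestInhibitionRegions:
    def test_sweeping_veto_interval(self):
        exc = DelayLine("exc", 50.0, 5 * 0.004, 1.0, EXCITATORY, "out")
        inh = DelayLine("inh", 48.0, 2 * 0.004, 1.0, "inhibitory", "out")
        # offset d0 = 2, slope s = 0.012: veto while d0 + s q in [1+2?]  —
        # here the gap starts at 2 (inside [1, 7]) and grows, leaving at 7
        (lo, hi), = inhibition_regions(exc, inh, (1.0, 7.0), horizon=1e6)
        assert lo == pytest.approx(0.0)
        assert hi == pytest.approx((7.0 - 2.0) / 0.012)

    def test_parallel_lines_inside_window_veto_everywhere(self):
        exc = DelayLine("exc", 36.0, 0.004, 1.0, EXCITATORY, "out")
        inh = DelayLine("inh", 32.0, 0.004, 1.0, "inhibitory", "out")
        assert inhibition_regions(exc, inh, (1.0, 7.0), 1000.0) == [(0.0, 1000.0)]

    def test_parallel_lines_outside_window_never_veto(self):
        exc = DelayLine("exc", 50.0, 0.004, 1.0, EXCITATORY, "out")
        inh = DelayLine("inh", 32.0, 0.004, 1.0, "inhibitory", "out")
        assert inhibition_regions(exc, inh, (1.0, 7.0), 1000.0) == []


class TestSingleRoundEvaluation:
    def test_truth_table_inside_and_region(self, three_chain_gate):
        t = truth_table_at(three_chain_gate, 111)
        assert classify(t) == "AND(in2,in3)"
        assert t.fires((0, 1, 1)) and t.fires((1, 1, 1))
        assert not t.fires((1, 1, 0)) and not t.fires((1, 0, 1))

    def test_no_input_no_spike(self, three_chain_gate):
        mult, times = evaluate_once(three_chain_gate, [], 111)
        assert mult == 0 and times == []

    def test_unknown_input_label_rejected(self, three_chain_gate):
        with pytest.raises(ValueError, match="unknown"):
            evaluate_once(three_chain_gate, ["in9"], 0)

    def test_output_trigger_time_matches_chain_delay(self, three_chain_gate):
        q = 500  # in1 x in2 crossing
        mult, times = evaluate_once(three_chain_gate, ["in1", "in2"], q)
        assert mult == 1
        assert times[0] == pytest.approx(30.0 + 1 * q * 0.006, abs=1e-9)


class TestModeTimelines:
    def test_three_and_entries(self, three_chain_gate):
        tl = mode_timeline(three_chain_gate, horizon=700)
        assert tl.count("AND") == 3
        assert tl.labels() == [
            "NULL",
            "AND(in2,in3)",
            "NULL",
            "AND(in1,in3)",
            "NULL",
            "AND(in1,in2)",
            "NULL",
        ]

    def test_interval_boundaries_bracket_closed_forms(self, three_chain_gate):
        tl = mode_timeline(three_chain_gate, horizon=700)
        first_and = tl.intervals[1]
        assert first_and.q_start == 89  # ceil of 111.11 - 22.22
        assert first_and.q_end == 133  # floor of 111.11 + 22.22
        assert tl.label_at(111) == "AND(in2,in3)"
        assert tl.label_at(0) == "NULL"

    def test_not_gate_timeline(self):
        tl = mode_timeline(build_not(), horizon=1000)
        assert tl.labels() == ["TRUE", "NOT", "TRUE"]
        # veto interval: gap d0 = 10 - 2 ms initial... closed form from lines
        assert tl.intervals[1].q_start == 250
        assert tl.intervals[1].q_end == 750

    def test_xor_gate_timeline(self):
        tl = mode_timeline(build_xor(), horizon=1000)
        assert tl.labels() == ["OR", "XOR", "OR"]
        assert tl.intervals[1].q_start == 250
        assert tl.intervals[1].q_end == 750

    def test_multimode_five_modes(self):
        tl = mode_timeline(build_multimode(), horizon=1800)
        assert tl.labels() == ["TRUE", "NOT(in1)", "NOR", "NOT(in2)", "TRUE"]


class TestStructuralChecks:
    def test_rescaling_invariance_between_increments(self):
        gate = build_generalized_and(delta=0.004)
        assert rescale_check(gate, 0.004, 0.006, horizon=2000)

    def test_horizon_clipping_breaks_rescaling(self):
        # a horizon cutting through a region truncates boundaries that would
        # otherwise scale exactly, so the check honestly reports False
        gate = build_generalized_and(delta=0.004)
        assert not rescale_check(gate, 0.004, 0.006, horizon=500)

    def test_synfire_equivalence_of_long_and_short_chains(self):
        short = build_generalized_and(
            chain_lengths=(1, 2, 5), taus=(30.0, 27.0, 25.0), delta=0.006
        )
        long = build_generalized_and(
            chain_lengths=(26, 27, 30), taus=(135.0, 132.0, 130.0), delta=0.006
        )
        assert synfire_equivalent(short, long, 0.006, horizon=700)
        tl_a = mode_timeline(short, 700)
        tl_b = mode_timeline(long, 700)
        assert tl_a.transition_counts() == tl_b.transition_counts()

    def test_synfire_equivalence_fails_for_mismatched_differences(self):
        short = build_generalized_and(
            chain_lengths=(1, 2, 5), taus=(30.0, 27.0, 25.0), delta=0.006
        )
        other = build_generalized_and(
            chain_lengths=(1, 3, 5), taus=(30.0, 27.0, 25.0), delta=0.006
        )
        assert not synfire_equivalent(short, other, 0.006, horizon=700)
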