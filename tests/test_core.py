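"""Elementary latency, summation, inhibition and circuit-model rules."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlg.core import (
    EXCITATORY,
    INHIBITORY,
    ChainSpec,
    CircuitSpec,
    CircuitValidationError,
    LinkSpec,
    NeuronSpec,
    NeuronState,
    chain_delay,
    fit_delta,
    graded_inhibition_strength,
    inhibition_covers,
    is_physiological_delta,
    latency_of,
    refractory_blocks,
    summation_decision,
)


class TestLatencyRule:
    def test_latency_is_affine_in_spike_count(self):
        n = NeuronSpec("a", l0=2.0, delta=0.006)
        assert latency_of(n, 0) == 2.0
        assert latency_of(n, 100) == pytest.approx(2.6)
        assert latency_of(n, 101) - latency_of(n, 100) == pytest.approx(0.006)

    def test_negative_spike_count_rejected(self):
        with pytest.raises(ValueError):
            latency_of(NeuronSpec("a"), -1)

    def test_chain_delay_accumulates_over_members(self):
        chain = ChainSpec(n=5, tau0=25.0)
        assert chain_delay(chain, 0.006, 0) == 25.0
        assert chain_delay(chain, 0.006, 100) == pytest.approx(28.0)

    @given(
        q1=st.integers(0, 5000),
        q2=st.integers(0, 5000),
        delta=st.floats(0.001, 0.05),
        n=st.integers(1, 30),
    )
    @settings(deadline=None, max_examples=50)
    def test_chain_delay_difference_scales_with_count_gap(self, q1, q2, delta, n):
        chain = ChainSpec(n=n, tau0=30.0)
        d = chain_delay(chain, delta, q2) - chain_delay(chain, delta, q1)
        assert d == pytest.approx(n * delta * (q2 - q1))

    def test_physiological_increment_range(self):
        assert is_physiological_delta(0.004)
        assert not is_physiological_delta(0.04)
        assert not is_physiological_delta(0.001)


class TestSummation:
    def test_two_weak_coincident_arrivals_fire(self):
        fires, t = summation_decision([(10.0, 0.5), (10.3, 0.5)], theta=1.0, w=0.4)
        assert fires and t == 10.3

    def test_lag_equal_to_window_does_not_sum(self):
        fires, _ = summation_decision([(10.0, 0.5), (10.4, 0.5)], theta=1.0, w=0.4)
        assert not fires

    def test_lag_just_inside_window_sums(self):
        fires, _ = summation_decision([(10.0, 0.5), (10.399, 0.5)], theta=1.0, w=0.4)
        assert fires

    def test_single_strong_arrival_fires_immediately(self):
        fires, t = summation_decision([(5.0, 1.0)], theta=1.0, w=0.4)
        assert fires and t == 5.0

    def test_subthreshold_sum_stays_silent(self):
        fires, _ = summation_decision([(10.0, 0.3), (10.1, 0.5)], theta=1.0, w=0.4)
        assert not fires

    def test_three_way_summation(self):
        fires, t = summation_decision(
            [(10.0, 0.4), (10.1, 0.3), (10.2, 0.3)], theta=1.0, w=0.4
        )
        assert fires and t == 10.2


class TestInhibitionAndRefractoriness:
    def test_veto_interval_is_closed(self):
        assert inhibition_covers(0.0, 1.0)
        assert inhibition_covers(0.0, 7.0)
        assert not inhibition_covers(0.0, 0.999)
        assert not inhibition_covers(0.0, 7.001)

    def test_refractory_blocks_strictly_smaller_gaps(self):
        assert refractory_blocks(100.0, 103.999, 4.0)
        assert not refractory_blocks(100.0, 104.0, 4.0)

    def test_graded_profile_shape(self):
        assert graded_inhibition_strength(-1.0) == 0.0
        assert graded_inhibition_strength(3.0) == 1.0
        assert graded_inhibition_strength(5.0) == 1.0
        assert graded_inhibition_strength(7.5) == pytest.approx(0.5)
        assert graded_inhibition_strength(10.0) == 0.0

    def test_state_tracks_inhibition_intervals(self):
        s = NeuronState()
        s.add_inhibition(11.0, 17.0)
        assert s.inhibited_at(11.0) and s.inhibited_at(17.0)
        assert not s.inhibited_at(10.999)


def _two_neuron_circuit(**link_kwargs) -> CircuitSpec:
    return CircuitSpec(
        neurons={"a": NeuronSpec("a"), "out": NeuronSpec("out")},
        links=[LinkSpec("a", "out", delay=10.0, **link_kwargs)],
        inputs=["a"],
        output="out",
    )


class TestCircuitModel:
    def test_valid_circuit_builds(self):
        c = _two_neuron_circuit()
        assert c.topological_order() == ["a", "out"]

    def test_cycle_rejected(self):
        with pytest.raises(CircuitValidationError, match="cycle"):
            CircuitSpec(
                neurons={"a": NeuronSpec("a"), "b": NeuronSpec("b")},
                links=[LinkSpec("a", "b", 1.0), LinkSpec("b", "a", 1.0)],
                inputs=["a"],
                output="b",
            )

    def test_unknown_link_target_named_in_error(self):
        with pytest.raises(CircuitValidationError, match="a->ghost.*ghost"):
            CircuitSpec(
                neurons={"a": NeuronSpec("a"), "out": NeuronSpec("out")},
                links=[LinkSpec("a", "ghost", 1.0), LinkSpec("a", "out", 1.0)],
                inputs=["a"],
                output="out",
            )

    def test_unreachable_neuron_rejected(self):
        with pytest.raises(CircuitValidationError, match="unreachable"):
            CircuitSpec(
                neurons={
                    "a": NeuronSpec("a"),
                    "stray": NeuronSpec("stray"),
                    "out": NeuronSpec("out"),
                },
                links=[LinkSpec("a", "out", 1.0), LinkSpec("stray", "out", 1.0)],
                inputs=["a"],
                output="out",
            )

    def test_dict_round_trip(self):
        c = _two_neuron_circuit(strength=0.5, sign=EXCITATORY)
        again = CircuitSpec.from_dict(c.to_dict())
        assert again.to_dict() == c.to_dict()

    def test_with_delta_replaces_every_increment(self):
        c = _two_neuron_circuit()
        c2 = c.with_delta(0.004)
        assert all(n.delta == 0.004 for n in c2.neurons.values())
        assert all(n.delta != 0.004 for n in c.neurons.values())

    def test_link_validation(self):
        with pytest.raises(ValueError):
            LinkSpec("a", "b", delay=-1.0)
        with pytest.raises(ValueError):
            LinkSpec("a", "b", delay=1.0, strength=0.0)
        with pytest.raises(ValueError):
            LinkSpec("a", "b", delay=1.0, sign="modulatory")

    def test_neuron_validation(self):
        with pytest.raises(ValueError):
            NeuronSpec("a", l0=-1.0)
        with pytest.raises(ValueError):
            NeuronSpec("a", window=0.0)
        with pytest.raises(ValueError):
            NeuronSpec("a", delta=-0.001)


class TestDeltaFit:
    def test_exact_recovery_on_linear_series(self):
        qs = list(range(200))
        lat = [2.0 + 0.006 * q for q in qs]
        assert fit_delta(qs, lat) == pytest.approx(0.006, abs=1e-12)

    def test_rejects_degenerate_series(self):
        with pytest.raises(ValueError):
            fit_delta([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_delta([1.0, 1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            fit_delta([1.0, 2.0], [2.0])

    @given(
        delta=st.floats(0.001, 0.05),
        l0=st.floats(0.5, 10.0),
        n=st.integers(5, 200),
    )
    @settings(deadline=None, max_examples=50)
    def test_recovery_property(self, delta, l0, n):
        qs = list(range(n))
        lat = [l0 + delta * q for q in qs]
        assert math.isclose(fit_delta(qs, lat), delta, rel_tol=0, abs_tol=1e-9)
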