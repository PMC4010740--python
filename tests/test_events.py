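"""Event-driven engine: delivery, vetoes, refractoriness, stochastic drive."""

import numpy as np
import pytest

from dlg.analytic import evaluate_once
from dlg.core import NeuronState
from dlg.events import (
    CAUSES,
    StimulationProtocol,
    estimate_delta,
    reset_latencies,
    simulate,
    varying_input_run,
)
from dlg.gates import (
    build_and,
    build_generalized_and,
    build_not,
    build_or,
    build_xor,
)


@pytest.fixture(scope="module")
def and_gate():
    return build_and()


class TestProtocol:
    def test_period_from_rate(self):
        assert StimulationProtocol(count=10).period == 100.0
        assert StimulationProtocol(count=10, rate_hz=20.0).period == 50.0

    def test_moderation_applies_inside_interval_only(self):
        p = StimulationProtocol(count=600, moderation={"in2": (250, 475, 0.1)})
        assert p.probability("in2", 249) == 1.0
        assert p.probability("in2", 250) == 0.1
        assert p.probability("in2", 474) == 0.1
        assert p.probability("in2", 475) == 1.0
        assert p.probability("in1", 300) == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            StimulationProtocol(count=-1)
        with pytest.raises(ValueError):
            StimulationProtocol(count=1, probabilities={"a": 1.5})
        with pytest.raises(ValueError):
            StimulationProtocol(count=1, times={"a": (2.0, 1.0)})


class TestDeterministicRuns:
    def test_chain_delays_follow_closed_form(self, and_gate):
        res = simulate(and_gate, StimulationProtocol(count=300, seed=0))
        s = res.summary
        # delay(q) = tau0 + n q delta, and observed arrivals agree exactly
        assert s["delay_in1"].iloc[0] == pytest.approx(78.4)
        assert s["delay_in1"].iloc[200] == pytest.approx(78.4 + 3 * 200 * 0.005)
        np.testing.assert_allclose(s["observed_in1"], s["delay_in1"], atol=1e-9)
        np.testing.assert_allclose(s["observed_in2"], s["delay_in2"], atol=1e-9)

    def test_output_fires_exactly_inside_coincidence_region(self, and_gate):
        res = simulate(and_gate, StimulationProtocol(count=300, seed=0))
        fired = res.summary.loc[res.summary["output_spikes"] > 0, "stim_index"]
        # crossing at q = 1.6 / 0.01 = 160, half-width 0.5 / 0.01 = 50
        assert fired.min() == 111 and fired.max() == 209

    def test_agrees_with_analytic_engine_round_by_round(self, and_gate):
        res = simulate(and_gate, StimulationProtocol(count=300, seed=0))
        ana = [evaluate_once(and_gate, set(and_gate.inputs), q)[0] for q in range(300)]
        assert ana == list(res.summary["output_spikes"])

    def test_every_record_carries_known_cause(self, and_gate):
        res = simulate(and_gate, StimulationProtocol(count=50, seed=0))
        assert all(r.cause in CAUSES for r in res.records)

    def test_arrival_conservation(self, and_gate):
        # every evoked spike spawns one record per outgoing link, plus one
        # record per external stimulation
        res = simulate(and_gate, StimulationProtocol(count=50, seed=0))
        external = sum(1 for r in res.records if r.origin == r.neuron and r.arrival % 100 == 0 and r.neuron in and_gate.inputs)
        assert external == 50 * len(and_gate.inputs)
        n_links_from = {n: len(and_gate.links_from(n)) for n in and_gate.neurons}
        expected_deliveries = sum(
            n_links_from[r.neuron] for r in res.records if r.evoked
        )
        assert len(res.records) == external + expected_deliveries

    def test_seed_reproducibility(self, and_gate):
        p = StimulationProtocol(count=80, probabilities={"in1": 0.7}, seed=11)
        a = simulate(and_gate, p).summary
        b = simulate(and_gate, p).summary
        assert a.equals(b)

    def test_different_seeds_differ(self, and_gate):
        pa = StimulationProtocol(count=80, probabilities={"in1": 0.5}, seed=1)
        pb = StimulationProtocol(count=80, probabilities={"in1": 0.5}, seed=2)
        a = simulate(and_gate, pa).records_frame()
        b = simulate(and_gate, pb).records_frame()
        assert not a.equals(b)


class TestFiringRules:
    def test_refractoriness_merges_double_or_response(self):
        gate = build_or()
        res = simulate(gate, StimulationProtocol(count=300, seed=0))
        s = res.summary
        # initial delay gap 8 ms > refractory: two output spikes per round;
        # once the gap shrinks below 4 ms the second spike is blocked
        assert s["output_spikes"].iloc[0] == 2
        assert s["output_spikes"].iloc[-1] == 1
        blocked = [r for r in res.records if r.cause == "blocked-refractory"]
        assert blocked and all(r.neuron == gate.output for r in blocked)

    def test_inhibition_vetoes_outer_drive(self):
        gate = build_not()
        res = simulate(gate, StimulationProtocol(count=400, seed=0))
        s = res.summary
        # NOT mode begins at q = 250: output silent despite the outer drive
        assert (s.loc[s["stim_index"] < 250, "output_spikes"] == 1).all()
        assert (s.loc[s["stim_index"] >= 250, "output_spikes"] == 0).all()
        causes = {r.cause for r in res.records if r.neuron == gate.output}
        assert "blocked-inhibition" in causes

    def test_skipped_inputs_recorded_not_delivered(self, and_gate):
        p = StimulationProtocol(count=200, probabilities={"in1": 0.3}, seed=5)
        res = simulate(and_gate, p)
        skipped = [r for r in res.records if r.cause == "skipped-input"]
        assert skipped
        frac = 1 - len(skipped) / 200
        assert 0.2 < frac < 0.45  # Bernoulli(0.3) delivery fraction
        # skipped stimulations must not stretch the chain
        assert res.states["in1"].q == 200 - len(skipped)

    def test_latency_stretches_only_per_evoked_spike(self, and_gate):
        p = StimulationProtocol(count=100, probabilities={"in1": 0.0}, seed=0)
        res = simulate(and_gate, p)
        assert res.states["in1"].q == 0
        assert res.states["in2"].q == 100

    def test_freeze_output_keeps_output_latency_fixed(self, and_gate):
        res = simulate(
            and_gate, StimulationProtocol(count=250, seed=0), freeze_output=True
        )
        assert res.states[and_gate.output].q == 0
        assert res.states["in1"].q == 250

    def test_state_resumption_continues_history(self, and_gate):
        first = simulate(and_gate, StimulationProtocol(count=100, seed=0))
        second = simulate(
            and_gate, StimulationProtocol(count=100, seed=0), states=first.states
        )
        full = simulate(and_gate, StimulationProtocol(count=200, seed=0))
        assert second.states["in1"].q == full.states["in1"].q == 200

    def test_reset_latencies_restores_uncharged_state(self, and_gate):
        res = simulate(and_gate, StimulationProtocol(count=100, seed=0))
        fresh = reset_latencies(res.states)
        assert all(st.q == 0 for st in fresh.values())
        assert set(fresh) == set(res.states)


class TestXorEventBehaviour:
    def test_xor_silent_only_inside_window(self):
        gate = build_xor()
        res = simulate(gate, StimulationProtocol(count=1000, seed=0))
        s = res.summary
        silent = s.loc[s["output_spikes"] == 0, "stim_index"]
        assert silent.min() == 250 and silent.max() == 750
        assert len(silent) == 501


class TestVaryingInput:
    def test_moderation_creates_reentrant_coincidence_regions(self):
        gate = build_generalized_and(
            chain_lengths=(3, 6), taus=(30.0, 27.3), delta=0.006
        )
        regions, summary = varying_input_run(gate, ((250, 475), 0.1), count=800, seed=5)
        assert len(regions) == 3
        # first region is the deterministic crossing at q = 2.7/0.018 = 150
        assert regions[0].q_start == pytest.approx(150 - 0.4 / 0.018, abs=2)
        # second region sits inside the moderation interval, third after it
        assert 250 < regions[1].q_start < 475
        assert regions[2].q_start > 475

    def test_without_moderation_single_region(self):
        gate = build_generalized_and(
            chain_lengths=(3, 6), taus=(30.0, 27.3), delta=0.006
        )
        regions, _ = varying_input_run(gate, ((0, 0), 1.0), count=800, seed=5)
        assert len(regions) == 1

    def test_requires_two_inputs(self):
        gate = build_generalized_and()
        with pytest.raises(ValueError):
            varying_input_run(gate, ((250, 475), 0.1))


class TestDeltaEstimation:
    def test_recovers_increment_from_simulated_delays(self):
        gate = build_generalized_and()
        res = simulate(gate, StimulationProtocol(count=150, seed=1))
        s = res.summary
        # observed chain delay slope = n * delta for an n-neuron chain
        for inp, n in (("in1", 1), ("in2", 2), ("in3", 5)):
            slope = estimate_delta(zip(s["stim_index"], s[f"observed_{inp}"]))
            assert slope / n == pytest.approx(0.006, abs=1e-9)
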