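"""LIF integration, STDP rule and raster plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from empathnet.snn_core import (
    LIFParameters,
    NeuronPopulation,
    STDPParameters,
    SpikeRaster,
    SynapseMatrix,
    apply_stdp,
    lif_step,
    read_raster,
    record_raster,
    stdp_delta,
    write_raster,
)

LIF = LIFParameters()
STDP = STDPParameters()


def _run_constant_current(current, params, duration):
    pop = NeuronPopulation.at_rest(1, params)
    spikes, trace = [], []
    steps = int(round(duration / params.dt))
    for k in range(1, steps + 1):
        _, fired = lif_step(pop, np.array([current]), params, t=k * params.dt)
        trace.append(pop.potentials[0])
        if fired.size:
            spikes.append(k * params.dt)
    return np.array(trace), spikes


class TestLIF:
    def test_rest_is_steady_state(self):
        trace, spikes = _run_constant_current(0.0, LIF, 100)
        assert np.all(trace == 0.0)
        assert spikes == []

    def test_reset_after_spike(self):
        pop = NeuronPopulation.at_rest(1, LIF)
        # one-step to-threshold impulse: u_th * tau_m / dt
        _, fired = lif_step(pop, np.array([1800.0]), LIF, t=1.0)
        assert list(fired) == [0]
        assert pop.potentials[0] == LIF.u_reset == 0.0
        assert pop.last_spike_times[0] == 1.0

    def test_time_to_first_spike_matches_closed_form(self):
        # u(t) = R*I*(1 - exp(-t/tau_m)) reaches 60 at t = 30*ln2 ~ 20.79 ms
        _, spikes = _run_constant_current(120.0, LIF, 100)
        assert spikes, "neuron should fire under twice-threshold drive"
        assert abs(spikes[0] - 30.0 * math.log(2.0)) <= LIF.dt

    @pytest.mark.parametrize("dt,tol", [(1.0, 1.0), (0.1, 0.1)])
    def test_subthreshold_trajectory_matches_closed_form(self, dt, tol):
        params = LIFParameters(dt=dt)
        current = 50.0  # steady state below threshold: never spikes
        trace, spikes = _run_constant_current(current, params, 150)
        assert spikes == []
        t = np.arange(1, len(trace) + 1) * dt
        exact = current * (1.0 - np.exp(-t / params.tau_m))
        assert np.max(np.abs(trace - exact)) <= tol  # O(dt) Euler error

    def test_input_validation(self):
        pop = NeuronPopulation.at_rest(3, LIF)
        with pytest.raises(ValueError, match="shape"):
            lif_step(pop, np.zeros(2), LIF)
        with pytest.raises(ValueError, match="finite"):
            lif_step(pop, np.array([0.0, np.nan, 0.0]), LIF)

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            LIFParameters(u_th=-1.0)
        with pytest.raises(ValueError):
            LIFParameters(dt=40.0)  # dt must stay below tau_m


class TestSTDPDelta:
    def test_printed_rule_values(self):
        # pre 10 ms before post: A+ e^-1;  post 10 ms before pre: -A- e^-1
        assert stdp_delta(100.0, 110.0, STDP) == pytest.approx(0.25 * math.exp(-1.0))
        assert stdp_delta(110.0, 100.0, STDP) == pytest.approx(-0.01 * math.exp(-1.0))

    def test_truncation_and_coincidence(self):
        assert stdp_delta(0.0, 100.0, STDP) == 0.0  # beyond the 5-tau window
        assert stdp_delta(50.0, 50.0, STDP) == 0.0  # coincident pair

    @given(dt_pair=st.floats(min_value=0.25, max_value=49.0))
    @settings(deadline=None, derandomize=True)
    def test_sign_antisymmetry_and_decay(self, dt_pair):
        pot = stdp_delta(100.0 - dt_pair, 100.0, STDP)
        dep = stdp_delta(100.0 + dt_pair, 100.0, STDP)
        assert pot > 0 > dep
        # magnitude decreases monotonically with the pair separation
        assert abs(stdp_delta(100.0 - dt_pair - 0.5, 100.0, STDP)) < pot
        assert abs(stdp_delta(100.0 + dt_pair + 0.5, 100.0, STDP)) < abs(dep)

    def test_nonfinite_times_rejected(self):
        with pytest.raises(ValueError):
            stdp_delta(float("nan"), 0.0, STDP)


def _brute_force_stdp(weights, pre, post, params):
    """All-pairs oracle: literal double loop over spike events."""
    w = weights.copy()
    for i, tp in zip(pre.neurons, pre.times):
        for j, tq in zip(post.neurons, post.times):
            w[i, j] += stdp_delta(float(tp), float(tq), params)
    return np.clip(w, params.w_min, params.w_max)


events_strategy = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0.0, max_value=150.0, allow_nan=False),
    ),
    max_size=10,
)


class TestApplySTDP:
    def _matrix(self, w0=0.5, n=4):
        return SynapseMatrix(np.full((n, n), w0), "excitatory", plastic=True)

    def test_empty_rasters_leave_weights_unchanged(self):
        syn = self._matrix()
        before = syn.weights.copy()
        apply_stdp(syn, SpikeRaster(), SpikeRaster(), STDP)
        assert np.array_equal(syn.weights, before)

    def test_single_pair_accumulation(self):
        syn = self._matrix(w0=0.1)
        pre = record_raster([("p", 0, 100.0)])
        post = record_raster([("m", 1, 110.0)])
        apply_stdp(syn, pre, post, STDP)
        assert syn.weights[0, 1] == pytest.approx(0.1 + 0.25 * math.exp(-1.0))
        assert syn.weights[2, 3] == 0.1  # untouched synapse

    def test_clamped_at_w_max(self):
        syn = self._matrix(w0=STDP.w_max)
        pre = record_raster([("p", 0, 100.0)])
        post = record_raster([("m", 0, 101.0)])
        apply_stdp(syn, pre, post, STDP)
        assert syn.weights[0, 0] == STDP.w_max

    def test_non_plastic_matrix_rejected(self):
        syn = SynapseMatrix(np.zeros((2, 2)), "excitatory", plastic=False)
        with pytest.raises(ValueError, match="plastic"):
            apply_stdp(syn, SpikeRaster(), SpikeRaster(), STDP)

    @given(pre_events=events_strategy, post_events=events_strategy)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_brute_force_oracle(self, pre_events, post_events):
        pre = record_raster([("p", i, t) for i, t in pre_events])
        post = record_raster([("m", i, t) for i, t in post_events])
        syn = self._matrix(w0=0.5)
        expected = _brute_force_stdp(syn.weights, pre, post, STDP)
        apply_stdp(syn, pre, post, STDP)
        assert np.allclose(syn.weights, expected, atol=1e-12)

    @given(
        batches=st.lists(
            st.tuples(events_strategy, events_strategy), min_size=1, max_size=5
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_weight_bounds_never_violated(self, batches):
        syn = self._matrix(w0=0.5)
        for pre_events, post_events in batches:
            apply_stdp(
                syn,
                record_raster([("p", i, t) for i, t in pre_events]),
                record_raster([("m", i, t) for i, t in post_events]),
                STDP,
            )
            assert np.all(syn.weights >= STDP.w_min)
            assert np.all(syn.weights <= STDP.w_max)


class TestRasterIO:
    def test_round_trip_identity(self, tmp_path):
        raster = record_raster(
            [("emotion", 3, 5.0), ("motor", 1, 2.0), ("motor", 1, 7.0)]
        )
        path = write_raster(raster, tmp_path / "spikes.csv")
        back = read_raster(path)
        assert np.array_equal(back.neurons, raster.neurons)
        assert np.array_equal(back.times, raster.times)
        assert list(back.modules) == list(raster.modules)

    def test_empty_raster_writes_header_only(self, tmp_path):
        path = write_raster(SpikeRaster(), tmp_path / "empty.csv")
        lines = path.read_text().strip().splitlines()
        assert lines == ["module,neuron_index,time_ms"]

    def test_events_sorted_by_time(self):
        raster = record_raster([("m", 0, 9.0), ("m", 0, 1.0), ("m", 1, 5.0)])
        assert list(raster.times) == [1.0, 5.0, 9.0]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            record_raster([("m", 0, -1.0)])
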