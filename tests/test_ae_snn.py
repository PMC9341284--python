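"""Mirror-neuron emergence, gating and empathy in the AE-SNN."""

import numpy as np
import pytest

from empathnet.ae_snn import (
    EMOTIONS,
    ModuleSpec,
    TrainingSchedule,
    build_network,
    classify_neurons,
    empathy_test,
    execute_emotion,
    infer_emotion_from_motor,
    observe_other,
    run_execution_epoch,
    train,
)

SHORT = TrainingSchedule(epochs=3)


class TestConstruction:
    def test_m1_receives_input_only_from_sma(self):
        net = build_network()
        m1 = net.spec.m1_indices()
        # no fixed emotion projection onto M1
        assert np.all(net.W_emotion_motor.weights[:, m1] == 0.0)
        # no plastic synapse terminates on M1
        assert not net.W_perception_motor.mask[:, m1].any()
        # SMA->M1 wiring exists and comes exclusively from SMA rows
        sm = net.W_sma_m1.weights
        assert sm[:, m1].sum() > 0
        non_sma = np.setdiff1d(np.arange(net.spec.n_motor), net.spec.sma_indices())
        assert np.all(sm[non_sma, :] == 0.0)

    def test_plastic_weights_start_near_zero(self):
        net = build_network()
        assert float(np.max(net.W_perception_motor.weights)) <= 0.01

    def test_emotion_motor_wiring_is_never_trained(self):
        net = build_network()
        fixed_before = net.W_emotion_motor.weights.copy()
        train(net, EMOTIONS, SHORT)
        assert np.array_equal(net.W_emotion_motor.weights, fixed_before)

    def test_overlapping_partition_rejected(self):
        partition = ModuleSpec().motor_partition.copy()
        partition["sma:pain"] = (0, 1, 2, 3, 5)  # collides with sma:normal
        with pytest.raises(ValueError, match="overlap"):
            ModuleSpec(motor_partition=partition)

    def test_unknown_labels_rejected(self):
        net = build_network()
        with pytest.raises(ValueError, match="emotion"):
            run_execution_epoch(net, "joy", SHORT)
        with pytest.raises(ValueError, match="percept"):
            observe_other(net, "perceive-blue")


class TestExecutionEpoch:
    def test_pain_epoch_population_coding_and_timing(self):
        net = build_network()
        raster = run_execution_epoch(net, "pain", SHORT, learn=False)
        # pain is carried by exactly the first 20 emotion neurons
        assert list(raster.fired_neurons("emotion")) == list(range(20))
        # re-afference: perception onset lags motor onset by the full delay
        lag = raster.onset("perception") - raster.onset("motor")
        assert lag == SHORT.total_delay == 200.0
        assert raster.onset("emotion") < raster.onset("motor")
        assert set(raster.fired_neurons("perception")) == set(range(20))

    def test_m1_spikes_gated_by_sma(self):
        net = build_network()
        raster = run_execution_epoch(net, "pain", SHORT, learn=False)
        motor = raster.select("motor")
        m1 = set(net.spec.m1_indices().tolist())
        sma_times = motor.times[np.isin(motor.neurons, net.spec.sma_indices())]
        for neuron, t in zip(motor.neurons, motor.times):
            if neuron in m1:
                # a connected SMA neuron fired within one synaptic delay
                assert np.any(np.isclose(sma_times, t - net.lif.dt))

    def test_learning_flag_controls_plasticity(self):
        net = build_network()
        before = net.W_perception_motor.weights.copy()
        run_execution_epoch(net, "pain", SHORT, learn=False)
        assert np.array_equal(net.W_perception_motor.weights, before)
        run_execution_epoch(net, "pain", SHORT, learn=True)
        pain_mirror = net.spec.part("mirror:pain")
        rows = net.spec.percept_block("perceive-red")
        grown = net.W_perception_motor.weights[np.ix_(rows, pain_mirror)]
        assert np.all(grown > before[np.ix_(rows, pain_mirror)])

    def test_zero_epochs_leave_network_unchanged(self):
        net = build_network()
        before = net.W_perception_motor.weights.copy()
        _, traj = train(net, EMOTIONS, TrainingSchedule(epochs=0))
        assert np.array_equal(net.W_perception_motor.weights, before)
        assert len(traj) == 1  # only the pre-training row


class TestTrainingTrajectories:
    def test_short_run_shapes(self):
        net = build_network()
        _, traj = train(net, EMOTIONS, SHORT)
        assert list(traj["epoch"]) == [0, 1, 2, 3]
        assert traj["w_perception_m1"].max() == 0.0
        assert traj["w_perception_mirror"].is_monotonic_increasing

    def test_determinism_same_config_same_weights(self):
        nets = []
        for _ in range(2):
            net = build_network()
            train(net, EMOTIONS, SHORT)
            nets.append(net)
        assert np.array_equal(
            nets[0].W_perception_motor.weights, nets[1].W_perception_motor.weights
        )
        r0 = run_execution_epoch(nets[0], "pain", SHORT, learn=False)
        r1 = run_execution_epoch(nets[1], "pain", SHORT, learn=False)
        assert np.array_equal(r0.neurons, r1.neurons)
        assert np.array_equal(r0.times, r1.times)


class TestObservation:
    def test_untrained_network_shows_no_empathy(self):
        net = build_network()
        obs = observe_other(net, "perceive-red")
        assert not any(obs.emotion_active.values())
        assert obs.raster.fired_neurons("motor").size == 0

    def test_empty_percept_is_inert(self, trained_net):
        obs = observe_other(trained_net, "")
        assert not any(obs.emotion_active.values())
        assert obs.emotion_spike_counts.sum() == 0

    @pytest.mark.parametrize("emotion", EMOTIONS)
    def test_empathy_is_specific(self, trained_net, emotion):
        result = empathy_test(trained_net, emotion)
        assert result["passed"], result

    @pytest.mark.parametrize("emotion", EMOTIONS)
    def test_self_other_signature(self, trained_net, emotion):
        """Executing and observing the same action fire different motor sets:
        execution adds SMA and M1 (and the dual-emotion candidates reachable
        only from the other percept); observation adds nothing."""
        spec = trained_net.spec
        _, exec_raster = execute_emotion(trained_net, emotion)
        from empathnet.ae_snn import PERCEPT_OF_EMOTION

        obs = observe_other(trained_net, PERCEPT_OF_EMOTION[emotion])
        exec_fired = set(exec_raster.fired_neurons("motor").tolist())
        obs_fired = set(obs.raster.fired_neurons("motor").tolist())
        assert exec_fired != obs_fired
        gated = set(spec.sma_indices(emotion)) | set(spec.m1_indices(emotion))
        assert gated <= exec_fired - obs_fired
        assert obs_fired <= exec_fired

    def test_overt_action_only_during_execution(self, trained_net):
        color, _ = execute_emotion(trained_net, "pain")
        assert color == "red"
        color, _ = execute_emotion(trained_net, "normal")
        assert color == "green"
        obs = observe_other(trained_net, "perceive-red")
        assert obs.overt_action is None


class TestEmotionReadout:
    def test_zero_activation_gives_zero_emotion(self, trained_net):
        out = infer_emotion_from_motor(trained_net, np.zeros(trained_net.spec.n_motor))
        assert np.all(out == 0.0)

    def test_shape_mismatch_rejected(self, trained_net):
        with pytest.raises(ValueError, match="shape"):
            infer_emotion_from_motor(trained_net, np.zeros(7))

    def test_full_execution_and_mirror_only_agree(self, trained_net):
        """M1 has no emotion projection, so the emotion implied by a full
        execution pattern matches the mirror-only (observation) pattern."""
        spec = trained_net.spec
        full = np.zeros(spec.n_motor)
        full[spec.motor_ensemble("pain")] = 1.0
        mirror_only = np.zeros(spec.n_motor)
        mirror_only[spec.part("mirror:pain")] = 1.0

        def dominant_block(vec):
            means = {
                label: vec[spec.emotion_block(label)].mean()
                for label in spec.emotion_coding
            }
            return max(means, key=means.get)

        assert dominant_block(infer_emotion_from_motor(trained_net, full)) == "pain"
        assert dominant_block(infer_emotion_from_motor(trained_net, mirror_only)) == "pain"


class TestCensus:
    def test_eight_profiles_with_expected_semantics(self, trained_net):
        labels, census = classify_neurons(trained_net)
        assert census.shape[0] == 8
        by_type = dict(zip(census["type"], census["count"]))
        # mirror neurons fire in matched execute+observe probes
        assert by_type["MN(1)"] > 0 and by_type["MN(2)"] > 0
        # anti-mirror neurons fire in both executions and neither observation
        assert by_type["ANTI-MN"] > 0
        anti = census[census["type"] == "ANTI-MN"].iloc[0]
        assert anti[["exec_1", "exec_2"]].all() and not anti[["observe_1", "observe_2"]].any()
        assert sum(by_type.values()) == trained_net.spec.n_motor
        # every ANTI-MN sits in M1
        m1 = set(trained_net.spec.m1_indices().tolist())
        assert {i for i, l in enumerate(labels) if l == "ANTI-MN"} <= m1
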