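"""Contrastive Hebbian learning, lesions and training schedules."""

import numpy as np
import pytest

from hippolearn.netcore import (build_network, default_layer_specs,
                                default_projection_specs, net_input, settle)
from hippolearn.plasticity import (LESIONED_SCHEDULE, StoppingRule,
                                   TrainingSchedule, TrialRecord, apply_lesion,
                                   check_stop, chl_delta, hebbian_delta,
                                   run_trial, schedule_for, train)

from conftest import tiny_layers


class TestChlDelta:
    def test_matched_coactivities_are_a_fixed_point(self):
        cop = np.outer([0.2, 0.9, 0.4], [0.7, 0.1])
        w = np.full((3, 2), 0.5)
        delta = chl_delta(cop, [cop.copy(), cop.copy()], 0.1, w,
                          np.ones((3, 2), bool))
        assert np.allclose(delta, 0.0)

    def test_zero_learning_rate(self):
        plus = np.outer([1.0, 0.0, 1.0], [1.0, 0.0])
        minus = np.outer([0.0, 1.0, 0.0], [0.0, 1.0])
        delta = chl_delta(plus, [minus], 0.0, np.full((3, 2), 0.5),
                          np.ones((3, 2), bool))
        assert np.allclose(delta, 0.0)

    def test_toy_projection_matches_elementwise_formula(self):
        """3x2 toy case evaluated by an independent elementwise loop."""
        rng = np.random.default_rng(0)
        pre_p, post_p = rng.uniform(0, 1, 3), rng.uniform(0, 1, 2)
        pre_m1, post_m1 = rng.uniform(0, 1, 3), rng.uniform(0, 1, 2)
        pre_m2, post_m2 = rng.uniform(0, 1, 3), rng.uniform(0, 1, 2)
        w = rng.uniform(0, 1, (3, 2))
        mask = np.array([[1, 0], [1, 1], [0, 1]], bool)
        lr = 0.07
        delta = chl_delta(np.outer(pre_p, post_p),
                          [np.outer(pre_m1, post_m1), np.outer(pre_m2, post_m2)],
                          lr, w, mask)
        for i in range(3):
            for j in range(2):
                raw = lr * (pre_p[i] * post_p[j]
                            - 0.5 * (pre_m1[i] * post_m1[j]
                                     + pre_m2[i] * post_m2[j]))
                bounded = raw * (1 - w[i, j]) if raw > 0 else raw * w[i, j]
                expected = bounded if mask[i, j] else 0.0
                assert delta[i, j] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            chl_delta(np.zeros((2, 2)), [np.zeros((2, 2))], 0.1,
                      np.zeros((3, 2)), np.ones((3, 2), bool))


def test_hebbian_delta_matches_cpca_formula():
    rng = np.random.default_rng(1)
    pre, post = rng.uniform(0, 1, 4), rng.uniform(0, 1, 3)
    w = rng.uniform(0, 1, (4, 3))
    mask = rng.uniform(size=(4, 3)) > 0.3
    delta = hebbian_delta(pre, post, 0.2, w, mask)
    for i in range(4):
        for j in range(3):
            expected = 0.2 * post[j] * (pre[i] - w[i, j]) if mask[i, j] else 0.0
            assert delta[i, j] == pytest.approx(expected)


class TestRunTrial:
    def test_single_pattern_sse_does_not_increase(self, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=2)
        x = sat_dataset.items[1].vector

        def recon_sse():
            st = settle(net, {"Input": x}, "test")
            return float(np.sum((st["EC_out"] - x) ** 2))

        before = recon_sse()
        run_trial(net, x)
        assert recon_sse() <= before + 1e-9

    def test_fixed_projections_unchanged(self, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=2)
        fixed = {(p.src, p.dst): p.weights.copy()
                 for p in net.projections if not p.spec.learnable}
        run_trial(net, sat_dataset.items[0].vector)
        for p in net.projections:
            if not p.spec.learnable:
                assert np.array_equal(p.weights, fixed[(p.src, p.dst)])

    def test_zero_rates_leave_weights_unchanged(self, sat_dataset):
        import dataclasses
        specs = [dataclasses.replace(s, hebbian_rate=0.0)
                 for s in default_projection_specs(0.0, 0.0, 0.0)]
        net = build_network(default_layer_specs(27, 5), specs, seed=2)
        h = net.weights_hash()
        run_trial(net, sat_dataset.items[0].vector)
        assert net.weights_hash() == h

    def test_pattern_length_validated(self, default_net):
        with pytest.raises(ValueError, match="length"):
            run_trial(default_net, np.zeros(5))

    def test_weights_stay_bounded_under_fuzzed_trials(self):
        """Soft bounding keeps every learnable weight in [0, 1]."""
        net = build_network(tiny_layers(), default_projection_specs(0.5, 0.05),
                            seed=6)
        rng = np.random.default_rng(6)
        for t in range(1000):
            x = (rng.uniform(0, 1, 6) > 0.5).astype(float)
            run_trial(net, x, max_cycles=6)
            if t % 100 == 0 or t == 999:
                for p in net.learnable_projections():
                    assert p.weights.min() >= 0.0
                    assert p.weights.max() <= 1.0


class TestLesions:
    def test_tsp_only_silences_direct_path(self, default_net):
        net = apply_lesion(default_net, "TSP-only")
        rng = np.random.default_rng(0)
        acts = {n: rng.uniform(0, 1, sp.size) for n, sp in net.layers.items()}
        d1 = net_input("CA1", net, acts, "test")
        acts2 = dict(acts)
        acts2["EC_in"] = rng.uniform(0, 1, 27)
        assert np.allclose(d1, net_input("CA1", net, acts2, "test"))

    def test_msp_only_silences_schaffer_path(self, default_net):
        net = apply_lesion(default_net, "MSP-only")
        rng = np.random.default_rng(0)
        acts = {n: rng.uniform(0, 1, sp.size) for n, sp in net.layers.items()}
        d1 = net_input("CA1", net, acts, "test")
        acts2 = dict(acts)
        acts2["CA3"] = rng.uniform(0, 1, 80)
        assert np.allclose(d1, net_input("CA1", net, acts2, "test"))

    def test_intact_is_identity(self, default_net):
        assert apply_lesion(default_net, "intact").weights_hash() \
            == default_net.weights_hash()

    def test_unknown_condition_rejected(self, default_net):
        with pytest.raises(ValueError, match="condition"):
            apply_lesion(default_net, "both-gone")

    def test_lesioned_nets_use_single_minus_phase(self):
        assert len(schedule_for("intact").minus_phases) == 2
        assert len(schedule_for("TSP-only").minus_phases) == 1
        assert schedule_for("MSP-only") is LESIONED_SCHEDULE

    def test_lesion_exclusivity_during_training(self, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=7)
        net = apply_lesion(net, "TSP-only")
        msp_before = net.projection("EC_in", "CA1").weights.copy()
        sch_before = net.projection("CA3", "CA1").weights.copy()
        net, _ = train(net, sat_dataset, TrainingSchedule(30),
                       condition="TSP-only", seed=7)
        assert np.array_equal(net.projection("EC_in", "CA1").weights,
                              msp_before)
        assert not np.array_equal(net.projection("CA3", "CA1").weights,
                                  sch_before)


class TestCheckStop:
    rule = StoppingRule()

    def test_minimum_trial_count_enforced(self):
        assert not check_stop([0.0] * 24, self.rule)

    def test_fires_at_trial_25_with_clean_window(self):
        assert check_stop([2.0] * 20 + [1.0] * 5, self.rule)

    def test_broken_window_blocks(self):
        hist = [1.0] * 45 + [1.0, 1.0, 1.3, 1.0, 1.0]
        assert not check_stop(hist, self.rule)

    def test_no_rule_never_stops(self):
        assert not check_stop([0.0] * 100, None)


class TestTrain:
    def test_satellite_schedule_runs_140_trials(self, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=1)
        _, records = train(net, sat_dataset, TrainingSchedule(140), seed=1)
        assert len(records) == 140

    def test_typicality_epochs_each_item_five_times(self, typ_dataset):
        net = build_network(default_layer_specs(30, 15), seed=1)
        _, records = train(net, typ_dataset, TrainingSchedule(100), seed=1)
        ids = [r.item_id for r in records]
        assert len(ids) == 100
        for item in typ_dataset.items:
            assert ids.count(item.id) == 5

    def test_stop_fires_at_trial_25_with_forced_low_sse(self, weather_dataset,
                                                        monkeypatch):
        from hippolearn import plasticity
        monkeypatch.setattr(
            plasticity, "run_trial",
            lambda net, x, phase_schedule, max_cycles, tolerance, item_id,
            trial: TrialRecord(trial, item_id, 0.0, {}))
        ds, _ = weather_dataset
        net = build_network(default_layer_specs(8, 4), seed=1)
        _, records = train(net, ds,
                           TrainingSchedule(50, stopping_rule=StoppingRule()),
                           seed=1)
        assert len(records) == 25

    def test_empty_dataset_rejected(self, sat_dataset, default_net):
        import dataclasses
        empty = dataclasses.replace(sat_dataset, items=[])
        with pytest.raises(ValueError, match="empty"):
            train(default_net, empty, TrainingSchedule(10), seed=0)

    def test_interim_tests_fire_at_scheduled_trials(self, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=1)
        seen = []
        train(net, sat_dataset,
              TrainingSchedule(20, interim_test_trials=(0, 10, 20)),
              seed=1, interim_test=lambda t, n: seen.append(t))
        assert seen == [0, 10, 20]

    def test_seed_reproducibility_bit_exact(self, sat_dataset):
        hashes = []
        for _ in range(2):
            net = build_network(default_layer_specs(27, 5), seed=13)
            net, _ = train(net, sat_dataset, TrainingSchedule(40), seed=13)
            hashes.append(net.weights_hash())
        assert hashes[0] == hashes[1]


def test_default_rates_keep_tsp_msp_ratio_exactly_ten():
    specs = {(p.src, p.dst): p for p in default_projection_specs()}
    tsp = specs[("CA3", "CA1")].learning_rate
    msp = specs[("EC_in", "CA1")].learning_rate
    assert tsp / msp == 10.0
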