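"""Circuit construction, k-winner-take-all dynamics and settling."""

import numpy as np
import pytest

from hippolearn.netcore import (STRONG_ACTIVITY, LayerSpec, ProjectionSpec,
                                apply_kwta, build_network,
                                default_layer_specs, default_projection_specs,
                                load_network, net_input, save_network, settle)
from hippolearn.plasticity import TrainingSchedule, train

from conftest import tiny_layers


class TestBuildNetwork:
    def test_hidden_layer_sizes(self, default_net):
        assert default_net.layer("DG").size == 400
        assert default_net.layer("CA3").size == 80
        assert default_net.layer("CA1").size == 100

    def test_sparse_fan_in_counts(self, default_net):
        # DG and CA3 receive from 25% of EC_in; CA3 from 5% of DG
        assert np.all(default_net.projection("EC_in", "DG").fan_in
                      == round(0.25 * 27))
        assert np.all(default_net.projection("EC_in", "CA3").fan_in
                      == round(0.25 * 27))
        assert np.all(default_net.projection("DG", "CA3").fan_in
                      == round(0.05 * 400))

    def test_recurrent_collaterals_exclude_self(self, default_net):
        mask = default_net.projection("CA3", "CA3").mask
        assert not np.any(np.diag(mask))
        off = mask.copy()
        np.fill_diagonal(off, True)
        assert off.all()

    def test_same_seed_bit_identical(self):
        a = build_network(default_layer_specs(27, 5), seed=11)
        b = build_network(default_layer_specs(27, 5), seed=11)
        for pa, pb in zip(a.projections, b.projections):
            assert np.array_equal(pa.mask, pb.mask)
            assert np.array_equal(pa.weights, pb.weights)

    def test_seed_changes_masks_and_weights(self):
        a = build_network(default_layer_specs(27, 5), seed=1)
        b = build_network(default_layer_specs(27, 5), seed=2)
        pa, pb = a.projection("EC_in", "DG"), b.projection("EC_in", "DG")
        assert not np.array_equal(pa.mask, pb.mask)
        assert not np.array_equal(pa.weights, pb.weights)

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError, match="unknown layer"):
            build_network(default_layer_specs(27, 5),
                          [ProjectionSpec("EC_in", "CA7")], seed=0)

    def test_bad_connectivity_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ProjectionSpec("EC_in", "DG", connectivity_fraction=1.5)

    def test_identity_requires_equal_sizes(self):
        layers = default_layer_specs(27, 5)
        bad = [ProjectionSpec("EC_in", "DG", identity=True, learnable=False)]
        with pytest.raises(ValueError, match="identity"):
            build_network(layers, bad, seed=0)

    def test_layer_spec_validation(self):
        with pytest.raises(ValueError):
            LayerSpec("DG", 0, 1)
        with pytest.raises(ValueError):
            LayerSpec("DG", 10, 11)
        with pytest.raises(ValueError):
            LayerSpec("nope", 10, 2)


class TestNetInput:
    def test_zero_activity_gives_zero_drive(self, tiny_net):
        acts = {n: np.zeros(sp.size) for n, sp in tiny_net.layers.items()}
        drive = net_input("CA1", tiny_net, acts)
        assert np.allclose(drive, 0.0)

    def test_single_unit_drive_proportional_to_weight(self, tiny_net):
        p = tiny_net.projection("CA3", "CA1")
        acts = {n: np.zeros(sp.size) for n, sp in tiny_net.layers.items()}
        acts["CA3"][4] = 1.0
        drive = net_input("CA1", tiny_net, acts)
        expected = (p.weights[4] * p.spec.strength) / p.norm
        assert np.allclose(drive, expected)

    def test_matches_brute_force_sum(self, tiny_net):
        """Drives equal an elementwise loop over mask x weight x activity."""
        rng = np.random.default_rng(0)
        acts = {n: rng.uniform(0, 1, sp.size)
                for n, sp in tiny_net.layers.items()}
        for dst in ("CA1", "CA3", "EC_out"):
            drive = net_input(dst, tiny_net, acts, phase="test")
            expected = np.zeros(tiny_net.layer(dst).size)
            for p in tiny_net.incoming(dst):
                g = p.spec.gate("test") * p.spec.strength
                for j in range(p.weights.shape[1]):
                    s = 0.0
                    for i in range(p.weights.shape[0]):
                        if p.mask[i, j]:
                            s += p.weights[i, j] * acts[p.src][i]
                    expected[j] += g * s / p.norm[j]
            assert np.allclose(drive, expected)

    def test_missing_source_layer_raises(self, tiny_net):
        with pytest.raises(KeyError, match="source layer"):
            net_input("CA1", tiny_net, {"CA3": np.zeros(10)})


class TestKwta:
    def test_top_k_strongly_active(self):
        drives = np.array([1.0, 0.8, 0.3, 0.2, 0.1])
        acts = apply_kwta(drives, k_active=2)
        assert np.sum(acts > STRONG_ACTIVITY) == 2
        assert np.argsort(acts)[-2:].tolist() == [1, 0]

    def test_equal_drives_equal_activations(self):
        acts = apply_kwta(np.full(8, 0.6), k_active=3)
        assert np.allclose(acts, acts[0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        drives = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        assert np.allclose(apply_kwta(drives, 5)[perm],
                           apply_kwta(drives[perm], 5))

    def test_monotone_in_drive(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            drives = rng.uniform(0, 1, 25)
            acts = apply_kwta(drives, 4)
            order = np.argsort(drives)
            assert np.all(np.diff(acts[order]) >= -1e-12)

    def test_set_point_within_one_of_k(self):
        """~k units end up active; in the sharp-gain limit, ~k are strong."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            drives = rng.uniform(0.2, 1.0, 40)
            n_active = int(np.sum(apply_kwta(drives, 4) > 0))
            assert abs(n_active - 4) <= 1
            n_strong = int(np.sum(apply_kwta(drives, 4, gain=2000)
                                  > STRONG_ACTIVITY))
            assert abs(n_strong - 4) <= 1

    def test_non_finite_drives_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            apply_kwta(np.array([1.0, np.nan, 0.2]), 1)

    def test_bounds(self):
        rng = np.random.default_rng(4)
        acts = apply_kwta(rng.normal(0, 2, 50), 6)
        assert acts.min() >= 0.0 and acts.max() <= 1.0


class TestSettle:
    def test_clamped_layers_held_exactly(self, default_net):
        x = np.zeros(27)
        x[[1, 5, 9, 13, 17]] = 1.0
        st = settle(default_net, {"Input": x}, "test")
        assert np.array_equal(st["Input"], x)

    def test_settle_deterministic(self, default_net):
        x = np.zeros(27)
        x[:5] = 1.0
        a = settle(default_net, {"Input": x}, "trough")
        b = settle(default_net, {"Input": x}, "trough")
        for layer in a.activations:
            assert np.array_equal(a[layer], b[layer])

    def test_zero_weight_network_baseline(self):
        specs = default_projection_specs()
        net = build_network(default_layer_specs(27, 5), specs, seed=0)
        for p in net.projections:
            if not p.spec.identity:
                p.weights[:] = 0.0
        st = settle(net, {"Input": np.zeros(27)}, "test")
        for layer in ("DG", "CA3", "CA1", "EC_out"):
            assert np.allclose(st[layer], 0.0)

    def test_activations_bounded_every_cycle(self, tiny_net):
        rng = np.random.default_rng(5)
        for cycles in (1, 2, 5, 30):
            x = (rng.uniform(0, 1, 6) > 0.5).astype(float)
            st = settle(tiny_net, {"Input": x}, "test", max_cycles=cycles)
            for layer, acts in st.activations.items():
                assert acts.min() >= 0.0 and acts.max() <= 1.0

    def test_unconverged_state_flagged_not_raised(self, default_net):
        x = np.zeros(27)
        x[:5] = 1.0
        st = settle(default_net, {"Input": x}, "test", max_cycles=1)
        assert st.cycles == 1 and not st.converged

    def test_clamp_length_validated(self, default_net):
        with pytest.raises(ValueError, match="length"):
            settle(default_net, {"Input": np.zeros(5)}, "test")


class TestPhaseGating:
    def test_trough_suppresses_ca3_influence_on_ca1(self, default_net):
        rng = np.random.default_rng(6)
        acts = {n: rng.uniform(0, 1, sp.size)
                for n, sp in default_net.layers.items()}
        d1 = net_input("CA1", default_net, acts, "trough")
        acts2 = dict(acts)
        acts2["CA3"] = rng.uniform(0, 1, 80)
        d2 = net_input("CA1", default_net, acts2, "trough")
        assert np.allclose(d1, d2)

    def test_peak_suppresses_ec_in_influence_on_ca1(self, default_net):
        rng = np.random.default_rng(7)
        acts = {n: rng.uniform(0, 1, sp.size)
                for n, sp in default_net.layers.items()}
        d1 = net_input("CA1", default_net, acts, "peak")
        acts2 = dict(acts)
        acts2["EC_in"] = rng.uniform(0, 1, 27)
        d2 = net_input("CA1", default_net, acts2, "peak")
        assert np.allclose(d1, d2)


class TestMaskConservation:
    def test_masks_conserved_under_training(self, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=9)
        before = {(p.src, p.dst): p.mask.copy() for p in net.projections}
        net, _ = train(net, sat_dataset, TrainingSchedule(100), seed=9)
        for p in net.projections:
            assert np.array_equal(p.mask, before[(p.src, p.dst)])
            assert np.all(p.weights[~p.mask] == 0.0)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, sat_dataset):
        net = build_network(default_layer_specs(27, 5), seed=4)
        net, _ = train(net, sat_dataset, TrainingSchedule(5), seed=4)
        path = tmp_path / "net.npz"
        save_network(net, path)
        loaded = load_network(path)
        assert loaded.weights_hash() == net.weights_hash()
        for pa, pb in zip(net.projections, loaded.projections):
            assert np.array_equal(pa.mask, pb.mask)
            assert pa.lesioned == pb.lesioned
        x = sat_dataset.items[0].vector
        a = settle(net, {"Input": x}, "test")
        b = settle(loaded, {"Input": x}, "test")
        assert np.array_equal(a["EC_out"], b["EC_out"])
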