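"""Generator correctness: determinism, rate calibration, contact geometry."""

import dataclasses

import numpy as np
import pytest

from spinesync import synthgen
from spinesync.errors import InvalidConfigError
from spinesync.synthgen import SimulationConfig, simulate_contact_stack
from spinesync.traces import event_frequency


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rate_local_hz": -0.01},
            {"noise_sd": float("nan")},
            {"frame_interval_s": 0.0},
            {"amplitude_dff": float("inf")},
            {"p_join_at_zero": 1.5},
            {"n_frames": 0},
            {"kernel_rise_s": -1.0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kwargs)

    def test_infinite_decay_length_allowed(self):
        cfg = SimulationConfig(assembly_decay_length_um=float("inf"))
        assert np.isinf(cfg.assembly_decay_length_um)


class TestSpineRecording:
    def test_zero_rates_zero_noise_gives_flat_traces(self):
        cfg = SimulationConfig(
            seed=1, n_frames=200, rate_local_hz=0.0, rate_bp_hz=0.0,
            noise_sd=0.0, drift_amplitude=0.0,
        )
        spine, dend, truth = synthgen.simulate_spine_recording(cfg)
        assert np.all(spine.values == 0.0)
        assert np.all(dend.values == 0.0)
        assert len(truth.local_event_times_s["spine0"]) == 0

    def test_same_seed_reproduces_bitwise(self, spine_cfg):
        a = synthgen.simulate_spine_recording(spine_cfg)
        b = synthgen.simulate_spine_recording(spine_cfg)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
        assert np.array_equal(
            a[2].local_event_times_s["spine0"], b[2].local_event_times_s["spine0"]
        )

    def test_bp_events_shared_local_events_spine_only(self):
        cfg = SimulationConfig(
            seed=3, n_frames=2000, rate_bp_hz=0.05, rate_local_hz=0.05,
            noise_sd=0.0, drift_amplitude=0.0,
        )
        spine, dend, truth = synthgen.simulate_spine_recording(cfg)
        # dendrite responds only at BP times: strip BP kernel from spine and
        # the residual must be exactly the local-event signal (nonnegative)
        assert dend.values.max() > 0
        resid = spine.values - dend.values
        assert resid.min() > -1e-9
        assert len(truth.bp_event_times_s["dendrite0"]) > 0

    def test_event_times_inside_recording(self, spine_cfg):
        _, _, truth = synthgen.simulate_spine_recording(spine_cfg)
        for times in (*truth.local_event_times_s.values(), *truth.bp_event_times_s.values()):
            assert np.all((times >= 0) & (times < spine_cfg.duration_s))

    def test_bad_epoch_rejected(self, spine_cfg):
        with pytest.raises(InvalidConfigError):
            synthgen.simulate_spine_recording(spine_cfg, [(-1.0, 10.0)])

    def test_contact_epoch_doubles_local_rate(self):
        """Realized within-epoch rate converges to multiplier x base rate.

        0.010 Hz outside vs 0.020 Hz inside a contact epoch, checked
        against the closed-form Poisson mean within 3 SE over replicates.
        """
        n_rep = 200
        epoch = (200.0, 500.0)
        counts_in = counts_out = 0
        for s in range(n_rep):
            cfg = SimulationConfig(
                seed=s, n_frames=3000, rate_local_hz=0.010,
                contact_rate_multiplier=2.0, rate_bp_hz=0.0,
                amplitude_dff=0.0, noise_sd=0.0, drift_amplitude=0.0,
            )
            _, _, truth = synthgen.simulate_spine_recording(cfg, [epoch])
            ev = truth.local_event_times_s["spine0"]
            counts_in += int(((ev >= epoch[0]) & (ev < epoch[1])).sum())
            counts_out += int((ev < epoch[0]).sum()) + int((ev >= epoch[1]).sum())
        t_in = (epoch[1] - epoch[0]) * n_rep
        t_out = (3000 * 0.242 - (epoch[1] - epoch[0])) * n_rep
        for count, t, rate in ((counts_in, t_in, 0.020), (counts_out, t_out, 0.010)):
            se = np.sqrt(rate / t)
            assert abs(count / t - rate) <= 3 * se

    def test_truth_frequency_identity(self, spine_cfg):
        _, _, truth = synthgen.simulate_spine_recording(spine_cfg)
        ev = truth.local_event_times_s["spine0"]
        assert event_frequency(ev, spine_cfg.duration_s) == len(ev) / spine_cfg.duration_s


class TestPopulation:
    def test_requires_two_neurons(self):
        with pytest.raises(InvalidConfigError):
            synthgen.simulate_population(SimulationConfig(n_neurons=1))

    def test_determinism(self):
        cfg = SimulationConfig.population(seed=5, n_neurons=6, n_frames=200)
        ta, pa, _ = synthgen.simulate_population(cfg)
        tb, pb, _ = synthgen.simulate_population(cfg)
        assert np.array_equal(pa, pb)
        for x, y in zip(ta, tb):
            assert np.array_equal(x.values, y.values)

    def test_positions_inside_field(self):
        cfg = SimulationConfig.population(seed=2, n_neurons=30, n_frames=50)
        _, pos, _ = synthgen.simulate_population(cfg)
        assert pos.shape == (30, 2)
        assert pos.min() >= 0 and pos.max() <= cfg.field_size_um

    def test_infinite_decay_full_join_shares_all_events(self):
        """No spatial decay + p_join 1 means every neuron fires every event."""
        cfg = SimulationConfig.population(
            seed=4, n_neurons=5, n_frames=300, rate_local_hz=0.0,
            assembly_decay_length_um=float("inf"), p_join_at_zero=1.0,
        )
        _, _, truth = synthgen.simulate_population(cfg)
        ref = truth.local_event_times_s["n000"]
        assert len(ref) > 0
        for times in truth.local_event_times_s.values():
            assert np.array_equal(times, ref)

    def test_membership_decays_with_distance(self):
        cfg = SimulationConfig.population(seed=9, n_neurons=40, n_frames=50)
        _, pos, truth = synthgen.simulate_population(cfg)
        for members in truth.assembly_memberships:
            assert np.all((members >= 0) & (members < 40))


class TestContactStack:
    def test_needs_three_z_sections(self):
        with pytest.raises(InvalidConfigError):
            simulate_contact_stack(SimulationConfig(), [], shape_zyx=(2, 16, 16))

    def test_no_epochs_no_multi_z_overlap(self):
        stack, truth = simulate_contact_stack(SimulationConfig(seed=1), [], n_frames=50)
        assert truth.contact_z_overlap.max() <= 1

    def test_epoch_out_of_span_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_contact_stack(SimulationConfig(), [(10, 100)], n_frames=50)

    def test_truth_overlap_matches_noiseless_brute_force(self):
        """Truth Z-counts equal a voxelwise intersection of noiseless masks.

        The oracle reconstructs the noiseless channels from very-high-photon
        renders (shot noise negligible after scaling) and counts overlap
        sections per frame with plain loops.
        """
        cfg = SimulationConfig(seed=6)
        scale = 4e6
        stack, truth = simulate_contact_stack(
            cfg, [(20, 40)], n_frames=60, photon_scale=scale, background_photons=0.0
        )
        red = stack[:, 0].astype(float) / scale
        green = stack[:, 1].astype(float) / scale
        level = synthgen.MASK_LEVEL
        for t in range(60):
            n_z = 0
            for z in range(stack.shape[2]):
                ok = (
                    (red[t, z] > level) & (green[t, z] > level) & truth.spine_mask[z]
                ).any()
                n_z += bool(ok)
            assert n_z == truth.contact_z_overlap[t]

    def test_during_epoch_at_least_two_z(self):
        _, truth = simulate_contact_stack(SimulationConfig(seed=2), [(10, 30)], n_frames=60)
        assert truth.contact_z_overlap[10:31].min() >= 2
        outside = np.r_[truth.contact_z_overlap[:10], truth.contact_z_overlap[31:]]
        assert outside.max() <= 1

    def test_single_z_variant_confined_to_one_section(self):
        _, truth = simulate_contact_stack(
            SimulationConfig(seed=2), [(10, 30)], n_frames=60, single_z=True
        )
        assert truth.contact_z_overlap[10:31].max() == 1

    def test_determinism(self):
        cfg = SimulationConfig(seed=11)
        a, _ = simulate_contact_stack(cfg, [(5, 15)], n_frames=30)
        b, _ = simulate_contact_stack(cfg, [(5, 15)], n_frames=30)
        assert np.array_equal(a, b)


def test_writers_round_trip(tmp_path):
    cfg = SimulationConfig(seed=1, n_frames=100)
    spine, dend, truth = synthgen.simulate_spine_recording(cfg)
    synthgen.write_spine_recording(tmp_path, spine, dend, truth, cfg)
    stack, ctruth = simulate_contact_stack(cfg, [(10, 20)], n_frames=40)
    synthgen.write_contact_stack(tmp_path, stack, ctruth, cfg)
    import pandas as pd
    import tifffile

    table = pd.read_csv(tmp_path / "spine_traces.csv")
    assert set(table["roi_id"]) == {"spine0", "dendrite0"}
    red = tifffile.imread(tmp_path / "contact_red.tif")
    assert red.shape == (40, 7, 32, 32)
    assert (tmp_path / "config.json").exists()
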