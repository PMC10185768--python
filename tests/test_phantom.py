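"""Synthetic nerve, physiology, traffic and recording generators."""

import numpy as np
import pytest

from vagusmap import phantom as ph
from vagusmap import sigproc as sp
from vagusmap.geometry import NerveGeometry, electrode_angles_deg


class TestMakePhantom:
    def test_default_three_groups_at_clock_positions(self, geometry):
        p = ph.make_phantom(geometry, seed=7)
        angles = {g.organ: g.center_angle for g in p.groups}
        assert angles == {"laryngeal": 0.0, "pulmonary": 210.0, "cardiac": 90.0}
        assert set(p.fascicles.organ) == {"laryngeal", "pulmonary", "cardiac"}

    def test_empty_groups_valid(self, geometry):
        p = ph.make_phantom(geometry, groups=[], seed=0)
        assert len(p.fascicles) == 0

    def test_determinism(self, geometry):
        a = ph.make_phantom(geometry, seed=123)
        b = ph.make_phantom(geometry, seed=123)
        assert (a.fascicles[["x", "y"]].to_numpy()
                == b.fascicles[["x", "y"]].to_numpy()).all()

    def test_fascicles_inside_nerve(self, default_phantom):
        f = default_phantom.fascicles
        r = np.hypot(f.x, f.y) + f.radius
        assert (r < default_phantom.geometry.nerve_radius).all()

    def test_no_overlap(self, default_phantom):
        f = default_phantom.fascicles
        xy = f[["x", "y"]].to_numpy()
        rr = f.radius.to_numpy()
        for i in range(len(f)):
            d = np.hypot(*(xy - xy[i]).T)
            d[i] = np.inf
            assert (d > rr + rr[i]).all()

    def test_impossible_packing_raises(self, geometry):
        crowded = [ph.FascicleGroupSpec("laryngeal", 0.0, 0.6, 200, 300e-6,
                                        angle_spread_deg=2.0,
                                        radius_spread_fraction=0.01)]
        with pytest.raises(ph.PlacementError):
            ph.make_phantom(geometry, crowded, seed=0, max_attempts=50)

    def test_duplicate_organ_rejected(self, geometry):
        gs = [ph.FascicleGroupSpec("cardiac", 0.0),
              ph.FascicleGroupSpec("cardiac", 90.0)]
        with pytest.raises(ValueError):
            ph.make_phantom(geometry, gs, seed=0)


class TestSimulatePhysio:
    def test_beat_count(self):
        p = ph.simulate_physio(60.0, heart_rate=100, breath_rate=12, seed=0,
                               sampling_rate=2000.0)
        assert abs(len(p.beat_times) - 100) <= 1

    def test_breath_count(self):
        p = ph.simulate_physio(60.0, heart_rate=100, breath_rate=12, seed=0,
                               sampling_rate=2000.0)
        assert abs(len(p.breath_midpoints) - 12) <= 1

    def test_seeds_change_noise_not_counts(self):
        a = ph.simulate_physio(30.0, 90, 12, seed=1, sampling_rate=2000.0)
        b = ph.simulate_physio(30.0, 90, 12, seed=2, sampling_rate=2000.0)
        assert abs(len(a.beat_times) - len(b.beat_times)) <= 1
        assert not np.allclose(a.beat_times, b.beat_times)

    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError):
            ph.simulate_physio(0.3, heart_rate=60, breath_rate=12, seed=0)


class TestNeuralTraffic:
    def test_evoked_latency(self, default_phantom):
        """0.4 m at 40 m/s: the perturbation peaks 10 ms after each pulse."""
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 1.0, stim_times=np.array([0.3, 0.5]),
            conduction_velocity=40.0, travel_distance=0.4, seed=0)
        x = np.abs(traffic.values["laryngeal"])
        fs = traffic.sampling_rate
        t_peak = np.argmax(x[:int(0.45 * fs)]) / fs
        assert t_peak == pytest.approx(0.310, abs=1e-4)

    def test_zero_amplitude_zero_traffic(self, geometry):
        gs = [ph.FascicleGroupSpec("laryngeal", 0.0, 0.6, 3,
                                   perturbation_amplitude=0.0)]
        p = ph.make_phantom(geometry, gs, seed=1)
        traffic = ph.simulate_neural_traffic(
            p, "evoked", 0.5, stim_times=np.array([0.2]), seed=0)
        assert np.allclose(traffic.values["laryngeal"], 0.0)

    def test_cardiac_gated_phase(self, default_phantom):
        physio = ph.simulate_physio(10.0, 60, 12, seed=3)
        traffic = ph.simulate_neural_traffic(
            default_phantom, "cardiac_gated", 10.0, physio=physio, seed=0,
            cycle_cv=0.0)
        env = np.abs(traffic.values["cardiac"])
        fs = traffic.sampling_rate
        t = physio.beat_times[3]
        seg = env[int((t + 0.05) * fs):int((t + 0.25) * fs)]
        # burst energy concentrates 150 ms after the BP peak
        prof = np.convolve(seg ** 2, np.ones(500), mode="same")
        t_peak = (np.argmax(prof) + int((t + 0.05) * fs)) / fs - t
        assert t_peak == pytest.approx(0.150, abs=0.03)

    def test_gated_mode_requires_physio(self, default_phantom):
        with pytest.raises(ValueError):
            ph.simulate_neural_traffic(default_phantom, "cardiac_gated", 1.0)

    def test_only_target_group_perturbed(self, default_phantom):
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 0.5, stim_times=np.array([0.2]), seed=0)
        assert np.allclose(traffic.values["cardiac"], 0.0)
        assert np.allclose(traffic.values["pulmonary"], 0.0)
        assert np.abs(traffic.values["laryngeal"]).max() > 0


class TestSynthesizeRecording:
    def test_zero_traffic_pure_carrier(self, default_phantom, voxel_jacobian,
                                       small_mesh, small_sigma):
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 0.1, stim_times=np.array([0.05]),
            seed=0, dilution=0.0)
        rec = ph.synthesize_recording(default_phantom, voxel_jacobian, V0,
                                      traffic, noise_rms=0.0, seed=0)
        tr = rec.pair_traces(0)
        t = np.arange(rec.n_samples) / rec.sampling_rate
        carrier = np.sin(2 * np.pi * 6000 * t)
        for e in (0, 5, 11):
            assert np.allclose(tr[e], V0[e] * carrier, atol=1e-15)

    def test_single_voxel_closed_loop(self, default_phantom, voxel_jacobian,
                                      small_mesh, small_sigma):
        """Demodulating a noiseless recording recovers J-column modulation
        within 5% at the perturbation peak."""
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        fs = 50000.0
        dur = 1.0
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", dur,
            stim_times=np.arange(0.3, 0.8, 0.05), seed=0, dilution=0.005)
        rec = ph.synthesize_recording(default_phantom, voxel_jacobian, V0,
                                      traffic, noise_rms=0.0, seed=0)
        p = default_phantom.voxel_perturbation(voxel_jacobian.grid, "laryngeal")
        jp = voxel_jacobian.matrix @ p * 0.005
        m = int(np.argmax(np.abs(jp)))
        k, e = divmod(m, 14)
        filt = sp.bandpass_carrier(rec.pair_traces(k)[e], fs, halfwidth=1000)
        trim = 5000      # drop filter edge transients before demodulation
        env = sp.demodulate(filt[trim:-trim], fs).values
        trig = sp.TriggerSeries(times=traffic.trigger_times[2:-2] - trim / fs,
                                source="stimulus")
        avg, taxis, _ = sp.coherent_average(env, 1 / fs, trig, 0.005, 0.03)
        x = sp.baseline_subtract(avg, (0, 200))
        peak = x[np.argmax(np.abs(x))]
        expect = np.sign(V0[m]) * jp[m] * 1e6
        assert peak == pytest.approx(expect, rel=0.05)

    def test_196_traces(self, default_phantom, voxel_jacobian, small_mesh,
                        small_sigma):
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 0.1, stim_times=np.array([0.05]), seed=0)
        rec = ph.synthesize_recording(default_phantom, voxel_jacobian, V0,
                                      traffic, seed=0)
        total = sum(rec.pair_traces(k).shape[0]
                    for k in range(len(rec.injection_pairs)))
        assert total == 196

    def test_zero_perturbation_conservation(self, default_phantom,
                                            voxel_jacobian, small_mesh,
                                            small_sigma):
        """With no perturbation, demodulated dV after baseline subtraction
        is zero-mean within noise tolerance."""
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 1.0, stim_times=np.array([0.5]),
            seed=0, dilution=0.0)
        rec = ph.synthesize_recording(default_phantom, voxel_jacobian, V0,
                                      traffic, noise_rms=1e-6, seed=1)
        fs = rec.sampling_rate
        filt = sp.bandpass_carrier(rec.pair_traces(3)[4], fs, halfwidth=2000)
        env = sp.demodulate(filt[10000:-10000], fs).values
        dev = env - env.mean()
        assert np.abs(dev.mean()) < 0.05 * env.std() + 1e-12


class TestCorruptTraces:
    def _recording(self, default_phantom, voxel_jacobian, V0, seed=0):
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 0.2, stim_times=np.array([0.1]),
            seed=seed)
        return ph.synthesize_recording(default_phantom, voxel_jacobian, V0,
                                       traffic, noise_rms=0.0, seed=seed)

    def test_empty_plan_bit_identical(self, default_phantom, voxel_jacobian,
                                      small_mesh, small_sigma):
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        rec = self._recording(default_phantom, voxel_jacobian, V0)
        rec2 = ph.corrupt_traces(rec, {})
        assert (rec.pair_traces(2) == rec2.pair_traces(2)).all()

    def test_amplitude_artifact_violates_criterion_1(self, default_phantom,
                                                     voxel_jacobian,
                                                     small_mesh, small_sigma):
        """A 0.5 uV amplitude artifact exceeds the 0.2 uV dV-RMS rule."""
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        traffic = ph.simulate_neural_traffic(
            default_phantom, "evoked", 4.0, stim_times=np.array([2.0]),
            seed=0, dilution=0.0)
        rec = ph.synthesize_recording(default_phantom, voxel_jacobian, V0,
                                      traffic, noise_rms=0.0, seed=0)
        rec = ph.corrupt_traces(rec, {(1, 3): ("amplitude", 0.5e-6)})
        fs = rec.sampling_rate
        tr = rec.pair_traces(1)
        rows = []
        for e in range(14):
            filt = sp.bandpass_carrier(tr[e], fs, halfwidth=2000)
            env = sp.demodulate(filt[25000:-25000], fs).values
            rms = sp.rms_convert(sp.DemodTrace(values=env, dt=1 / fs),
                                 window=0.1)
            rows.append(rms.values[25000:-25000][::20])
        rep = sp.exclude_spontaneous(np.asarray(rows), dt=20 / fs)
        assert "amplitude" in rep.reasons[3]
        assert sum("amplitude" in r for r in rep.reasons) == 1

    def test_invalid_plan_rejected(self, default_phantom, voxel_jacobian,
                                   small_mesh, small_sigma):
        from vagusmap.forward import protocol_voltages
        V0, _ = protocol_voltages(small_mesh, small_sigma)
        rec = self._recording(default_phantom, voxel_jacobian, V0)
        with pytest.raises(ValueError):
            ph.corrupt_traces(rec, {(99, 3): ("amplitude", 1e-6)})


class TestSSResponses:
    def test_aligned_pair_has_max_hr_drop(self, default_phantom):
        angles = electrode_angles_deg()
        table = ph.simulate_ss_responses(default_phantom, angles, seed=0,
                                         noise_sd={"cardiac": 0.0,
                                                   "pulmonary": 0.0,
                                                   "laryngeal": 0.0})
        card = table[table.organ == "cardiac"].set_index("pair")
        cx, cy = default_phantom.group_center("cardiac")
        target = np.degrees(np.arctan2(cy, cx)) % 360
        best = card.response.abs().idxmax()
        diff = abs((angles[best] - target + 180) % 360 - 180)
        assert diff <= 360 / 14

    def test_antipodal_pair_negligible(self):
        k = ph.angular_kernel(np.array([180.0]), spread_deg=26.0)
        assert k[0] < 0.01

    def test_kernel_half_width(self):
        k = ph.angular_kernel(np.array([13.0]), spread_deg=26.0)
        assert k[0] == pytest.approx(0.5, rel=1e-9)

    def test_default_cardiac_amplitude(self, default_phantom):
        """The best-aligned pair shows the study-scale ~-10.1% HR drop."""
        angles = electrode_angles_deg()
        table = ph.simulate_ss_responses(default_phantom, angles, seed=0,
                                         noise_sd={"cardiac": 0.0,
                                                   "pulmonary": 0.0,
                                                   "laryngeal": 0.0})
        card = table[table.organ == "cardiac"]
        best = card.loc[card.response.abs().idxmax()]
        assert best.response == pytest.approx(-10.1, abs=1.5)


class TestMicroCT:
    def test_identity_deformation(self, default_phantom):
        tab = ph.simulate_microct_fascicles(default_phantom, ellipse_ratio=1.0,
                                            rotation_deg=0.0, jitter_um=0.0,
                                            seed=0)
        expect = default_phantom.fascicles[["x", "y"]].to_numpy() * 1e6
        assert np.allclose(tab.points(), expect, atol=1e-9)
        assert tab.cuff_opening_deg == pytest.approx(90.0)

    def test_ratio_scales_extent(self, default_phantom):
        a = ph.simulate_microct_fascicles(default_phantom, 1.0, 0.0, 0.0, 0)
        b = ph.simulate_microct_fascicles(default_phantom, 1.3, 0.0, 0.0, 0)
        ratio_a = np.ptp(a.points()[:, 0]) / np.ptp(a.points()[:, 1])
        ratio_b = np.ptp(b.points()[:, 0]) / np.ptp(b.points()[:, 1])
        assert ratio_b / ratio_a == pytest.approx(1.3, rel=1e-9)

    def test_cardiac_count_one_to_two(self, default_phantom):
        tab = ph.simulate_microct_fascicles(default_phantom, 1.2, 30.0, 20.0, 1)
        n = (tab.table.organ == "cardiac").sum()
        assert 1 <= n <= 2

    def test_determinism(self, default_phantom):
        a = ph.simulate_microct_fascicles(default_phantom, 1.2, 45.0, 25.0, 9)
        b = ph.simulate_microct_fascicles(default_phantom, 1.2, 45.0, 25.0, 9)
        assert np.allclose(a.points(), b.points())


class TestStimProtocol:
    def test_rest_must_equal_train(self):
        with pytest.raises(ValueError):
            ph.StimProtocol(train_duration=5.0, rest_duration=10.0)

    def test_organ_defaults(self):
        lar = ph.StimProtocol.for_organ("laryngeal")
        card = ph.StimProtocol.for_organ("cardiac")
        pulm = ph.StimProtocol.for_organ("pulmonary")
        assert (lar.pulse_width, card.pulse_width, pulm.pulse_width) == \
            (50e-6, 1e-3, 50e-6)
        assert (lar.amplitude, card.amplitude, pulm.amplitude) == \
            (100e-6, 1000e-6, 400e-6)
        assert lar.pulse_rate == 20.0
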