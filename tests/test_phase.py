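"""Wavelet phase: ridge extraction against an FFT oracle, phase advance,
singularity detection by winding numbers, charge conservation, and
pinning classification."""

import numpy as np
import pytest

from memwave.phase import (
    Singularity,
    WaveletConfig,
    find_singularities,
    morlet_transform,
    net_charge,
    phase_map,
    ridge_phase,
    track_and_classify,
)
from memwave.reconstruction import SignalField
from memwave.synthetic_cell import SceneSpec, make_signal

TWO_PI = 2 * np.pi


def fft_dominant_period(x, dt):
    """Independent oracle for the dominant oscillation period."""
    x = x - x.mean()
    amp = np.abs(np.fft.rfft(x))
    f = np.fft.rfftfreq(len(x), d=dt)
    return 1.0 / f[np.argmax(amp[1:]) + 1]


class TestMorletTransform:
    def test_sinusoid_ridge_at_its_period(self):
        t = 10.0 * np.arange(120)
        x = np.cos(TWO_PI * t / 200.0)
        cfg = WaveletConfig()
        W, _ = morlet_transform(x, 10.0, cfg)
        _, per, _ = ridge_phase(W, cfg)
        mid = slice(40, 80)
        grid_step = cfg.scales[1] / cfg.scales[0]
        oracle = fft_dominant_period(x, 10.0)
        assert np.median(per[mid]) == pytest.approx(oracle, rel=grid_step - 1 + 0.02)

    def test_constant_series_zero_coefficients(self):
        W, _ = morlet_transform(np.full(80, 3.0), 10.0)
        assert np.allclose(np.abs(W), 0.0, atol=1e-12)

    def test_two_tone_shows_two_ridges(self):
        t = 10.0 * np.arange(240)
        x = np.cos(TWO_PI * t / 150.0) + np.cos(TWO_PI * t / 300.0)
        cfg = WaveletConfig()
        W, _ = morlet_transform(x, 10.0, cfg)
        amp = np.abs(W)[:, 100:140].mean(axis=1)
        # local maxima of the scale spectrum sit near both tones
        peaks = [k for k in range(1, len(amp) - 1)
                 if amp[k] > amp[k - 1] and amp[k] > amp[k + 1]]
        peak_periods = cfg.scales[peaks]
        assert any(abs(p - 150) / 150 < 0.1 for p in peak_periods)
        assert any(abs(p - 300) / 300 < 0.1 for p in peak_periods)

    def test_matches_pywavelets_ridge(self):
        # cross-check the ridge location against an independent CWT engine
        pywt = pytest.importorskip("pywt")
        t = 10.0 * np.arange(120)
        x = np.cos(TWO_PI * t / 200.0)
        cfg = WaveletConfig()
        W, _ = morlet_transform(x, 10.0, cfg)
        our_period = np.median(ridge_phase(W, cfg)[1][40:80])
        scales = pywt.frequency2scale("cmor1.5-1.0", 10.0 / cfg.scales)
        coeffs, freqs = pywt.cwt(x, scales, "cmor1.5-1.0", sampling_period=10.0)
        k = np.argmax(np.abs(coeffs[:, 40:80]).mean(axis=1))
        ref_period = 1.0 / freqs[k]
        assert our_period == pytest.approx(ref_period, rel=0.1)


class TestRidgePhase:
    def test_phase_advances_2pi_per_period(self):
        t = 10.0 * np.arange(120)
        T = 200.0
        cfg = WaveletConfig()
        W, _ = morlet_transform(np.cos(TWO_PI * t / T), 10.0, cfg)
        ph, _, _ = ridge_phase(W, cfg)
        mid = slice(30, 90)
        slope = np.polyfit(t[mid], np.unwrap(ph[mid]), 1)[0]
        assert slope == pytest.approx(TWO_PI / T, rel=0.05)

    def test_wave_front_at_intensity_peak(self):
        # the 0/2pi wrap coincides with the signal maximum
        t = 10.0 * np.arange(120)
        cfg = WaveletConfig()
        W, _ = morlet_transform(np.cos(TWO_PI * t / 200.0), 10.0, cfg)
        ph, _, _ = ridge_phase(W, cfg)
        peaks = [20, 40, 60, 80]  # cos maxima at multiples of 200 s
        for p in peaks:
            assert min(ph[p], TWO_PI - ph[p]) < 0.6

    def test_amplitude_tie_prefers_lower_frequency(self):
        cfg = WaveletConfig(scales=np.array([100.0, 200.0]))
        coeffs = np.ones((2, 5), complex)  # exact tie at every time point
        _, per, _ = ridge_phase(coeffs, cfg)
        assert np.all(per == 200.0)


class TestPhaseMap:
    def test_horizontal_wave_isophase_meridians(self, sphere_mesh):
        # at fixed time the phase varies with azimuth only: phase + phi is
        # circularly concentrated across the equatorial band
        spec = SceneSpec(radius=3.0, pattern="horizontal_wave", period=200.0,
                         noise_sd=0.0, duration=600.0)
        sig, _ = make_signal(sphere_mesh, spec)
        pmap = phase_map(sig, sphere_mesh)
        band = np.abs(sphere_mesh.theta) < 0.4
        for t in (5, 10, 15):
            ph = pmap.phase[band, t]
            R = max(abs(np.mean(np.exp(1j * (ph - sphere_mesh.phi[band])))),
                    abs(np.mean(np.exp(1j * (ph + sphere_mesh.phi[band])))))
            assert R > 0.8

    def test_vertical_wave_phase_front_at_intensity_peak(self, sphere_mesh):
        # per node, the extracted phase sits at the 0/2pi wave front when the
        # intensity peaks (stripe patterns of the two kymographs coincide)
        spec = SceneSpec(radius=3.0, pattern="vertical_wave", period=200.0,
                         noise_sd=0.05, duration=600.0, seed=21)
        sig, _ = make_signal(sphere_mesh, spec)
        pmap = phase_map(sig, sphere_mesh)
        win = (sig.times >= pmap.times[0]) & (sig.times <= pmap.times[-1])
        vals = sig.values[:, win]
        sel = np.flatnonzero(np.abs(sphere_mesh.theta) < 0.3)
        dist = []
        for i in sel:
            tpk = np.argmax(vals[i, 3:-3]) + 3   # interior peak
            ph = pmap.phase[i, tpk]
            dist.append(min(ph, TWO_PI - ph))
        assert np.median(dist) < 0.8

    def test_quiet_scene_flagged_undefined(self, sphere_mesh):
        spec = SceneSpec(radius=3.0, pattern="quiet", noise_sd=0.0, duration=600.0)
        sig, _ = make_signal(sphere_mesh, spec)
        pmap = phase_map(sig, sphere_mesh)
        assert not pmap.valid.any()


class TestSingularities:
    def test_uniform_phase_has_none(self, sphere_mesh):
        from memwave.phase import PhaseMap

        n, nt = sphere_mesh.n_nodes, 5
        pmap = PhaseMap(phase=np.full((n, nt), 1.0), period=np.full((n, nt), 200.0),
                        amplitude=np.ones((n, nt)), times=10.0 * np.arange(nt),
                        valid=np.ones((n, nt), bool),
                        low_amplitude=np.zeros(n, bool))
        assert find_singularities(pmap, sphere_mesh, 0) == []

    def test_pinned_spiral_two_opposite_charges(self, spiral_scene):
        _, mesh, signal, truth = spiral_scene
        pmap = phase_map(signal, mesh)
        for t in range(0, pmap.phase.shape[1], 4):
            sings = find_singularities(pmap, mesh, t)
            assert len(sings) == 2
            assert net_charge(sings) == 0

    def test_singularity_near_prescribed_position(self, spiral_scene):
        _, mesh, signal, truth = spiral_scene
        pmap = phase_map(signal, mesh)
        target = np.asarray(truth.params["pinned_position"])
        tol = 2.0 * mesh.mean_edge_length()
        for t in range(pmap.phase.shape[1]):
            sings = find_singularities(pmap, mesh, t)
            d = min(np.linalg.norm(s.position - target) for s in sings)
            assert d < tol

    def test_two_spiral_pairs_give_four_singularities(self, sphere_mesh):
        # brute-force winding over all faces for a prescribed 2-pair field
        from memwave.phase import PhaseMap

        u = sphere_mesh.nodes / np.linalg.norm(sphere_mesh.nodes, axis=1)[:, None]
        a1 = np.array([0.0, 0.0, 1.0])
        a2 = np.array([1.0, 0.0, 0.0])

        def spiral_phase(axis):
            e1 = np.array([axis[2], 0.0, -axis[0]]) if abs(axis[1]) < 0.9 \
                else np.array([1.0, 0.0, 0.0])
            e1 = e1 - (e1 @ axis) * axis
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            return np.arctan2(u @ e2, u @ e1)

        ph = np.mod(spiral_phase(a1) + spiral_phase(a2), TWO_PI)
        n = sphere_mesh.n_nodes
        pmap = PhaseMap(phase=ph[:, None], period=np.full((n, 1), 200.0),
                        amplitude=np.ones((n, 1)), times=np.zeros(1),
                        valid=np.ones((n, 1), bool),
                        low_amplitude=np.zeros(n, bool))
        sings = find_singularities(pmap, sphere_mesh, 0)
        assert len(sings) == 4
        assert net_charge(sings) == 0

    def test_charge_conservation_every_frame(self, spiral_scene):
        _, mesh, signal, _ = spiral_scene
        pmap = phase_map(signal, mesh)
        for t in range(pmap.phase.shape[1]):
            assert net_charge(find_singularities(pmap, mesh, t)) == 0


class TestTracking:
    def test_pinned_spiral_classified(self, spiral_scene):
        _, mesh, signal, truth = spiral_scene
        pmap = phase_map(signal, mesh)
        per_frame = [find_singularities(pmap, mesh, t)
                     for t in range(pmap.phase.shape[1])]
        tracks = track_and_classify(per_frame, mesh)
        assert len(tracks) == 2
        pinned = [tr for tr in tracks if tr.pinned]
        free = [tr for tr in tracks if not tr.pinned]
        assert len(pinned) == 1 and len(free) == 1
        target = np.asarray(truth.params["pinned_position"])
        assert np.linalg.norm(pinned[0].positions.mean(axis=0) - target) < 1.0

    def test_horizontal_wave_has_no_pinned_tracks(self, trunc_mesh):
        spec = SceneSpec(radius=2.5, contact_angle=np.pi / 3,
                         pattern="horizontal_wave", period=200.0,
                         noise_sd=0.05, duration=600.0, seed=22)
        sig, _ = make_signal(trunc_mesh, spec)
        pmap = phase_map(sig, trunc_mesh)
        per_frame = []
        for t in range(pmap.phase.shape[1]):
            try:
                per_frame.append(find_singularities(pmap, trunc_mesh, t))
            except ValueError:
                per_frame.append([])
        tracks = track_and_classify(per_frame, trunc_mesh)
        assert sum(tr.pinned for tr in tracks) == 0

    def test_guidance_front_parallel_to_perimeter(self, trunc_mesh):
        # a vertically propagating wave carries fronts parallel to the
        # contact perimeter while crossing it -> guidance events; a band wave
        # circulating azimuthally has meridional fronts -> none
        from memwave.phase import detect_guidance

        down = SceneSpec(radius=2.5, contact_angle=np.pi / 3,
                         pattern="vertical_wave", period=200.0,
                         noise_sd=0.02, duration=600.0, seed=5)
        sig, _ = make_signal(trunc_mesh, down)
        events = detect_guidance(phase_map(sig, trunc_mesh), trunc_mesh, band=1.0)
        assert len(events) >= 1
        assert all(e - s + 1 >= 3 for s, e in events)

        around = SceneSpec(radius=2.5, contact_angle=np.pi / 3,
                           pattern="horizontal_wave", period=200.0,
                           theta_band=-np.pi / 2 + np.pi / 3 + 0.15,
                           wave_width=0.4, noise_sd=0.02, duration=600.0, seed=5)
        sig2, _ = make_signal(trunc_mesh, around)
        assert detect_guidance(phase_map(sig2, trunc_mesh), trunc_mesh, band=1.0) == []

    def test_two_frame_flicker_rejected(self, sphere_mesh):
        p = np.zeros(3)
        flick = [Singularity(0, p, 1, 2), Singularity(1, p + 0.1, -1, 2)]
        flick2 = [Singularity(0, p, 1, 3), Singularity(1, p + 0.1, -1, 3)]
        per_frame = [[], [], flick, flick2, [], []]
        tracks = track_and_classify(per_frame, sphere_mesh)
        assert tracks == []
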