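import numpy as np
import pytest

from curtainkit import (
    InvalidParameterError,
    MotorParams,
    OpticsParams,
    SegmentationThresholds,
    UndefinedVelocityError,
    annotate_track,
    compute_distance,
    compute_velocity,
    detect_tracks,
    render_kymograph,
    simulate_tracks,
)
from curtainkit.simulate import KymographTriplet

from conftest import make_spike_kymograph


class TestThresholdRules:
    def test_stationary_emitter_no_start_terminated(self, thresholds, optics):
        track = annotate_track(0, np.full(50, 7.0), thresholds)
        assert track.start_frame is None
        assert track.terminated
        assert compute_velocity(track, optics) is None
        assert compute_distance(track, optics) == 0.0

    def test_start_frame_at_third_pixel_of_displacement(self, thresholds):
        # moving 1 px/frame from pixel 5: displacement exceeds 2 px at frame 3
        positions = np.arange(5.0, 25.0)
        track = annotate_track(0, positions, thresholds)
        assert track.start_frame == 3
        assert track.start_pixel == 8
        assert track.binding_pixel == 5

    def test_short_stall_is_pause_not_termination(self, thresholds):
        # 3-frame stall inside a moving track
        positions = np.concatenate([np.arange(5.0, 15.0), [14.0] * 3, np.arange(15.0, 25.0)])
        track = annotate_track(0, positions, thresholds)
        stall_start = 10 - 1  # the stall run includes the last moving frame
        assert any(p0 <= stall_start + 3 and p1 >= stall_start for p0, p1 in track.pause_intervals)
        assert not track.terminated or track.stop_frame > 15

    def test_long_final_static_run_terminates(self, thresholds):
        positions = np.concatenate([np.arange(5.0, 15.0), [14.0] * 15])
        track = annotate_track(0, positions, thresholds)
        assert track.terminated
        assert track.stop_frame == 9  # first frame of the final static run
        assert track.stop_pixel == 14

    def test_threshold_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            SegmentationThresholds(pause_max_frames=12)
        with pytest.raises(InvalidParameterError):
            SegmentationThresholds(start_displacement_px=0)


class TestVelocityFormula:
    def make_track(self, positions, thresholds=None):
        return annotate_track(0, np.asarray(positions, dtype=float),
                              thresholds or SegmentationThresholds())

    def test_direct_formula_evaluation(self):
        # 10 px over 250 frames at 0.4 s/frame (100 s) and 1000 bp/px -> 100 bp/s
        positions = np.repeat(np.arange(5.0, 16.0), 25)[:275]
        track = self.make_track(positions)
        optics = OpticsParams(n_frames=300)
        v = compute_velocity(track, optics)
        assert v == pytest.approx(10 * 1000 / (250 * 0.4), rel=0.05)

    def test_zero_displacement_zero_velocity(self):
        # out past the start threshold then straight back to where
        # movement began: Yi == Yf, velocity 0
        positions = np.concatenate([[5] * 2, [6, 7, 8, 8, 8, 7], [6.0] * 20])
        track = self.make_track(positions)
        optics = OpticsParams()
        assert compute_velocity(track, optics) == 0.0

    def test_coincident_endpoints_raise(self):
        track = self.make_track(np.arange(5.0, 25.0))
        track.stop_frame = track.onset_frame
        with pytest.raises(UndefinedVelocityError):
            compute_velocity(track, OpticsParams())

    def test_distance_direct(self):
        positions = np.concatenate([np.repeat(np.arange(5.0, 10.0), 6), [9.0] * 15])
        track = self.make_track(positions)
        # onset at pixel 6, stop at pixel 9 -> 3 px -> 3 kb at 1000 bp/px
        assert compute_distance(track, OpticsParams()) == pytest.approx(3.0, abs=0.6)

    def test_velocity_distance_consistency_identity(self):
        positions = np.repeat(np.arange(5.0, 14.0), 8)
        track = self.make_track(positions)
        optics = OpticsParams()
        v = compute_velocity(track, optics)
        d = compute_distance(track, optics)
        elapsed_s = (track.stop_frame - track.onset_frame) * optics.frame_interval_s
        assert d * 1000.0 / elapsed_s == pytest.approx(v)

    def test_pause_excluded_velocity_is_faster(self):
        positions = np.concatenate([np.arange(5.0, 12.0), [11.0] * 3, np.arange(12.0, 18.0), [17.0] * 15])
        track = self.make_track(positions)
        optics = OpticsParams()
        v_incl = compute_velocity(track, optics)
        v_excl = compute_velocity(track, optics, exclude_pauses=True)
        assert v_excl >= v_incl


class TestDetection:
    def test_all_background_kymograph_yields_no_tracks(self, thresholds):
        optics = OpticsParams(n_frames=40)
        rng = np.random.default_rng(0)
        img = rng.normal(100, 5, (40, optics.n_pixels))
        kymo = KymographTriplet(green=np.abs(img), blue=np.abs(img), magenta=np.abs(img),
                                optics=optics)
        assert detect_tracks(kymo, thresholds=thresholds) == []

    def test_negative_intensities_rejected(self, thresholds, optics):
        img = np.full((optics.n_frames, optics.n_pixels), -1.0)
        with pytest.raises(Exception):
            kymo = KymographTriplet(green=img, blue=img, magenta=img, optics=optics)
            detect_tracks(kymo, thresholds=thresholds)

    def test_spike_track_recovered(self, thresholds):
        pixels = [5] * 5 + list(range(5, 20)) + [19] * 20
        kymo = make_spike_kymograph(pixels)
        tracks = detect_tracks(kymo, thresholds=thresholds)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.binding_pixel == 5
        assert t.terminated
        assert t.stop_pixel == 19

    def test_raising_snr_never_increases_track_count(self):
        optics = OpticsParams(n_frames=100)
        motor = MotorParams(binding_rate=0.03)
        tracks = simulate_tracks(motor, optics, n_dna=3, seed=1)
        kymo = render_kymograph(tracks, [], optics, seed=2)
        counts = []
        for snr in (3.0, 5.0, 8.0, 15.0, 40.0):
            th = SegmentationThresholds(detection_snr=snr)
            counts.append(len(detect_tracks(kymo, thresholds=th)))
        assert counts == sorted(counts, reverse=True)


class TestRoundTrip:
    def simulate_and_segment(self, seed=0, noise_sd=0.0):
        optics = OpticsParams(n_frames=150, background_sd=noise_sd)
        motor = MotorParams(
            mixture_weights=(1.0,), mixture_means_bp_s=(394.0,), mixture_sds_bp_s=(120.0,),
            track_len_weights=(1.0,), track_len_means_kb=(6.0,), track_len_sds_kb=(1.0,),
            pause_prob_per_frame=0.0, binding_rate=0.02,
        )
        by_dna = {}
        for t in simulate_tracks(motor, optics, n_dna=40, seed=seed,
                                 binding_window_frames=40):
            by_dna.setdefault(t.dna_id, []).append(t)
        pairs = []
        for dna_id, dna_tracks in by_dna.items():
            if len(dna_tracks) != 1:
                continue
            kymo = render_kymograph(dna_tracks, [], optics, seed=seed + dna_id)
            found = detect_tracks(kymo)
            pairs.append((dna_tracks[0], found))
        return pairs, optics

    def test_noiseless_round_trip_recovers_tracks_exactly(self):
        pairs, optics = self.simulate_and_segment(seed=3, noise_sd=0.0)
        assert pairs
        for truth, found in pairs:
            assert len(found) == 1
            seg = found[0]
            assert abs(seg.frame_of_first_detection - truth.bind_frame) <= 1
            assert abs(seg.last_frame - min(truth.termination_frame, optics.n_frames - 1)) <= 1
            # per-frame positions within 1 pixel of ground truth
            for i, px in enumerate(seg.rounded_positions):
                frame = seg.frame_of_first_detection + i
                true_px = truth.position_at(frame) / optics.bp_per_pixel
                assert abs(px - true_px) <= 1.0

    def test_recovered_velocity_tracks_drawn_velocity(self):
        pairs, optics = self.simulate_and_segment(seed=4, noise_sd=5.0)
        rels = []
        for truth, found in pairs:
            if len(found) != 1 or found[0].velocity_bp_s is None:
                continue
            rels.append(found[0].velocity_bp_s / truth.drawn_velocity_bp_s)
        assert len(rels) >= 10
        assert np.median(rels) == pytest.approx(1.0, abs=0.1)


class TestInvariances:
    def test_velocity_invariant_to_time_translation(self, thresholds):
        pixels = [5] * 3 + list(range(5, 20)) + [19] * 20
        kymo_a = make_spike_kymograph(pixels)
        kymo_b = make_spike_kymograph([5] * 10 + pixels[:-10])
        va = detect_tracks(kymo_a, thresholds=thresholds)[0].velocity_bp_s
        vb = detect_tracks(kymo_b, thresholds=thresholds)[0].velocity_bp_s
        assert va == pytest.approx(vb)

    def test_velocity_invariant_to_position_reflection(self, thresholds):
        pixels = [5] * 3 + list(range(5, 20)) + [19] * 20
        kymo = make_spike_kymograph(pixels)
        flipped = KymographTriplet(
            green=kymo.green[:, ::-1].copy(), blue=kymo.blue[:, ::-1].copy(),
            magenta=kymo.magenta[:, ::-1].copy(), optics=kymo.optics,
        )
        va = detect_tracks(kymo, thresholds=thresholds)[0].velocity_bp_s
        vb = detect_tracks(flipped, thresholds=thresholds)[0].velocity_bp_s
        assert va == pytest.approx(vb)
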