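import numpy as np
import pytest

from curtainkit import (
    ContractViolationError,
    Distribution,
    InvalidParameterError,
    MotorParams,
    OpticsParams,
    RPAEvent,
    RPAGenParams,
    association_times,
    detect_colocalization,
    detect_tracks,
    estimate_stoichiometry,
    fraction_dissociated,
    render_kymograph,
    simulate_rpa,
    simulate_tracks,
)


def make_event(track_id=0, bind=0, assoc=5, dissoc=None, censored=False,
               peak=1000.0, bg=900.0):
    if dissoc is None:
        dissoc = assoc + 15
    return RPAEvent(
        track_id=track_id, track_bind_frame=bind, assoc_frame=assoc,
        dissoc_frame=None if censored else dissoc, censored=censored,
        assoc_delay_s=(assoc - bind) * 0.4,
        lifetime_s=None if censored else (dissoc - assoc) * 0.4,
        peak_intensity=peak, background_estimate=bg,
    )


class TestDetectColocalization:
    def stationary_setup(self, with_rpa=True, n_frames=60):
        optics = OpticsParams(background_sd=0.0, n_frames=n_frames)
        motor = MotorParams(
            mixture_weights=(1.0,), mixture_means_bp_s=(0.0,), mixture_sds_bp_s=(0.0,),
            binding_rate=1.0,
        )
        tracks = simulate_tracks(motor, optics, n_dna=1, seed=0,
                                 binding_window_frames=1)
        rpa_events = []
        if with_rpa:
            rpa = RPAGenParams(
                stoich_distribution=Distribution.point(2),
                association_delay_s_distribution=Distribution.point(4.0),
                lifetime_s_distribution=Distribution.point(8.0),
            )
            rpa_events = simulate_rpa(tracks, rpa, optics, seed=1)
        kymo = render_kymograph(tracks, rpa_events, optics, seed=2)
        seg = detect_tracks(kymo)
        return kymo, seg, rpa_events, optics

    def test_no_magenta_signal_no_events(self):
        kymo, seg, _, _ = self.stationary_setup(with_rpa=False)
        assert detect_colocalization(seg, kymo) == []

    def test_noiseless_round_trip_matches_truth(self):
        kymo, seg, truth, optics = self.stationary_setup()
        assert len(truth) == 1
        events = detect_colocalization(seg, kymo)
        assert len(events) == 1
        ev, tr = events[0], truth[0]
        assert abs(ev.assoc_frame - tr.assoc_frame) <= 1
        assert not ev.censored
        assert abs(ev.dissoc_frame - tr.dissoc_frame) <= 1

    def test_event_running_to_record_end_is_censored(self):
        optics = OpticsParams(background_sd=0.0, n_frames=40)
        motor = MotorParams(
            mixture_weights=(1.0,), mixture_means_bp_s=(0.0,), mixture_sds_bp_s=(0.0,),
            binding_rate=1.0,
        )
        tracks = simulate_tracks(motor, optics, n_dna=1, seed=0,
                                 binding_window_frames=1)
        rpa = RPAGenParams(
            association_delay_s_distribution=Distribution.point(0.0),
            lifetime_s_distribution=Distribution.point(1e5),
        )
        truth = simulate_rpa(tracks, rpa, optics, seed=1)
        kymo = render_kymograph(tracks, truth, optics, seed=2)
        events = detect_colocalization(detect_tracks(kymo), kymo)
        assert len(events) == 1
        assert events[0].censored
        assert events[0].lifetime_s is None

    def test_channel_shape_mismatch_rejected(self):
        kymo, seg, _, _ = self.stationary_setup()
        kymo.magenta = kymo.magenta[:-5]
        with pytest.raises(Exception):
            detect_colocalization(seg, kymo)


class TestAssociationTimes:
    def test_frame_to_seconds_conversion(self):
        # 21 frames at 0.4 s/frame -> 8.4 s (0.14 min)
        events = [make_event(assoc=21, bind=0)]
        delays, median = association_times(events, 0.4)
        assert delays[0] == pytest.approx(8.4)
        assert median == pytest.approx(8.4)
        assert median / 60.0 == pytest.approx(0.14)

    def test_association_at_binding_is_zero(self):
        _, median = association_times([make_event(assoc=3, bind=3)], 0.4)
        assert median == 0.0

    def test_event_before_binding_violates_contract(self):
        ev = make_event(assoc=5, bind=2)
        ev.track_bind_frame = 10
        with pytest.raises(ContractViolationError):
            association_times([ev], 0.4)


class TestFractionDissociated:
    def test_all_censored_gives_zero(self):
        events = [make_event(censored=True) for _ in range(5)]
        assert fraction_dissociated(events) == 0.0

    def test_printed_count_fraction(self):
        events = [make_event(censored=i >= 11) for i in range(20)]
        assert fraction_dissociated(events) == pytest.approx(0.55)

    def test_matches_exponential_cdf_on_simulation(self):
        # stationary PSCs observed for T seconds; lifetimes exponential
        # with mean L: expected dissociated fraction = 1 - exp(-T/L)
        optics = OpticsParams(n_frames=200)
        motor = MotorParams(
            mixture_weights=(1.0,), mixture_means_bp_s=(0.0,), mixture_sds_bp_s=(0.0,),
            binding_rate=1.0,
        )
        tracks = simulate_tracks(motor, optics, n_dna=800, seed=0,
                                 binding_window_frames=1)
        L = 40.0
        rpa = RPAGenParams(
            association_delay_s_distribution=Distribution.point(0.0),
            lifetime_s_distribution=Distribution.exponential(L),
        )
        truth = simulate_rpa(tracks, rpa, optics, seed=1)
        frac = sum(1 for ev in truth if not ev.censored) / len(truth)
        T = (optics.n_frames - 1) * optics.frame_interval_s
        expected = 1.0 - np.exp(-T / L)
        se = np.sqrt(expected * (1 - expected) / len(truth))
        assert abs(frac - expected) < 4 * se

    def test_longer_window_never_decreases_fraction(self):
        motor = MotorParams(
            mixture_weights=(1.0,), mixture_means_bp_s=(0.0,), mixture_sds_bp_s=(0.0,),
            binding_rate=1.0,
        )
        rpa = RPAGenParams(
            association_delay_s_distribution=Distribution.point(0.0),
            lifetime_s_distribution=Distribution.exponential(60.0),
        )
        fracs = []
        for n_frames in (50, 150, 400):
            optics = OpticsParams(n_frames=n_frames)
            tracks = simulate_tracks(motor, optics, n_dna=300, seed=0,
                                     binding_window_frames=1)
            truth = simulate_rpa(tracks, rpa, optics, seed=1)
            fracs.append(sum(1 for ev in truth if not ev.censored) / len(truth))
        assert fracs == sorted(fracs)


class TestStoichiometry:
    def test_peak_equal_background_zero_molecules(self):
        est = estimate_stoichiometry(900.0, 900.0, unit_intensity=200.0)
        assert est.estimated_molecules == 0.0
        assert est.quantized_range == (0, 0)
        assert est.underwound_nt_range == (0.0, 0.0)

    def test_two_and_a_half_units_quantizes_to_wild_type_range(self):
        est = estimate_stoichiometry(900.0 + 2.5 * 200.0, 900.0, 200.0, footprint_nt=30)
        assert est.estimated_molecules == pytest.approx(2.5)
        assert est.quantized_range == (2, 3)
        assert est.underwound_nt_range == (60.0, 90.0)

    def test_mutant_scale_range(self):
        est = estimate_stoichiometry(900.0 + 1.4 * 200.0, 900.0, 200.0, footprint_nt=30)
        assert est.quantized_range == (1, 2)
        assert est.underwound_nt_range == (30.0, 60.0)

    def test_exact_integer_recovery_on_noiseless_render(self):
        optics = OpticsParams(background_sd=0.0, n_frames=60)
        motor = MotorParams(
            mixture_weights=(1.0,), mixture_means_bp_s=(0.0,), mixture_sds_bp_s=(0.0,),
            binding_rate=1.0,
        )
        tracks = simulate_tracks(motor, optics, n_dna=1, seed=0,
                                 binding_window_frames=1)
        rpa = RPAGenParams(
            stoich_distribution=Distribution.point(3),
            association_delay_s_distribution=Distribution.point(2.0),
            lifetime_s_distribution=Distribution.point(15.0),
        )
        truth = simulate_rpa(tracks, rpa, optics, seed=1)
        kymo = render_kymograph(tracks, truth, optics, seed=2)
        events = detect_colocalization(detect_tracks(kymo), kymo)
        assert len(events) == 1
        est = estimate_stoichiometry(
            events[0].peak_intensity, events[0].background_estimate,
            unit_intensity=optics.unit_intensity,
        )
        assert est.estimated_molecules == pytest.approx(3.0, abs=0.05)
        assert est.quantized_range in ((3, 3), (2, 3), (3, 4))

    def test_nonpositive_unit_intensity_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_stoichiometry(1000.0, 900.0, unit_intensity=0.0)
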