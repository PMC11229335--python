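"""End-to-end parameter-recovery harnesses.

Each harness generates synthetic curtain or plate data at the documented
wild-type (or Rad54-alone) population parameters, runs the full analysis
pipeline on the rendered observations -- never on the ground truth -- and
reports the recovered quantity. They are the package's self-checks that
simulation, rendering, segmentation and fitting compose correctly.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mixtures import MixtureFit, fit_mixture
from .outcomes import tally_outcomes
from .params import MotorParams, OpticsParams, RPAGenParams
from .rpa import detect_colocalization, estimate_stoichiometry
from .segmentation import SegmentationThresholds, SegmentedTrack, detect_tracks
from .simulate import (
    TrueRPAEvent,
    TrueTrack,
    render_kymograph,
    simulate_colony_assay,
    simulate_rpa,
    simulate_tracks,
)

WT_VELOCITY_MIXTURE = dict(
    mixture_weights=(0.5, 0.5),
    mixture_means_bp_s=(114.3, 394.0),
    mixture_sds_bp_s=(73.0, 183.0),
)
RAD54_ALONE_VELOCITY = dict(
    mixture_weights=(1.0,),
    mixture_means_bp_s=(65.0,),
    mixture_sds_bp_s=(67.0,),
)
RAD54_ALONE_TRACK_LEN = dict(
    track_len_weights=(1.0,),
    track_len_means_kb=(3.7,),
    track_len_sds_kb=(2.5,),
)


def segment_simulation(
    tracks: Sequence[TrueTrack],
    optics: OpticsParams,
    seed: int,
    rpa_events: Sequence[TrueRPAEvent] = (),
    thresholds: Optional[SegmentationThresholds] = None,
    channel: str = "green",
) -> Tuple[List[SegmentedTrack], Dict[int, object]]:
    """Render each DNA molecule's kymograph and segment it.

    Returns the pooled segmented tracks and the kymographs keyed by
    dna_id. Rendering is per molecule, which is both how the instrument
    produces kymographs and keeps memory flat.
    """
    thresholds = thresholds or SegmentationThresholds()
    by_dna: Dict[int, List[TrueTrack]] = {}
    for t in tracks:
        by_dna.setdefault(t.dna_id, []).append(t)
    events_by_dna: Dict[int, List[TrueRPAEvent]] = {}
    track_dna = {t.track_id: t.dna_id for t in tracks}
    for ev in rpa_events:
        events_by_dna.setdefault(track_dna[ev.track_id], []).append(ev)

    rng = np.random.default_rng(seed)
    segmented: List[SegmentedTrack] = []
    kymos: Dict[int, object] = {}
    next_id = 0
    for dna_id in sorted(by_dna):
        kymo = render_kymograph(
            by_dna[dna_id],
            events_by_dna.get(dna_id, []),
            optics,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        found = detect_tracks(kymo, channel=channel, thresholds=thresholds)
        for tr in found:
            tr.track_id = next_id
            tr.dna_id = dna_id
            next_id += 1
        segmented.extend(found)
        kymos[dna_id] = kymo
    return segmented, kymos


def recover_wt_velocity_mixture(
    seed: int = 0,
    n_tracks: int = 500,
    n_frames: int = 400,
) -> Dict[str, object]:
    """Recover the two-component WT velocity mixture through the pipeline.

    Simulates at least ``n_tracks`` PSC trajectories at the wild-type
    mixture (means 114.3 and 394 bp/s, SDs 73 and 183, equal weights),
    renders noisy kymographs at default optics, segments with the stated
    thresholds, computes endpoint velocities and fits a sum of two
    Gaussians. The fast-component mean is the headline recovery.
    """
    optics = OpticsParams(n_frames=n_frames)
    # sparse binding: ~0.6 tracks per DNA keeps trajectories from crossing,
    # the standard condition for reliable single-particle linking
    motor = MotorParams(**WT_VELOCITY_MIXTURE, binding_rate=0.006)
    window = n_frames // 4
    n_dna = int(np.ceil(n_tracks / (motor.binding_rate * window) * 1.2))
    tracks = simulate_tracks(
        motor, optics, n_dna=n_dna, seed=seed, binding_window_frames=window
    )
    segmented, _ = segment_simulation(tracks, optics, seed=seed + 1)
    velocities = np.array(
        [t.velocity_bp_s for t in segmented if t.velocity_bp_s is not None]
    )
    fit: MixtureFit = fit_mixture(velocities, k=2, seed=seed)
    return {
        "n_true_tracks": len(tracks),
        "n_measured": velocities.size,
        "velocities": velocities,
        "fit": fit,
        "slow_mean_bp_s": fit.means[0],
        "fast_mean_bp_s": fit.means[-1],
    }


def recover_rad54_alone_mean(
    seed: int = 0,
    n_tracks: int = 800,
    n_frames: int = 2500,
) -> Dict[str, object]:
    """Recover the Rad54-alone mean velocity (65 bp/s scale) end to end.

    Rad54 translocates slowly, so the record is long (1000 s at 0.4
    s/frame) and binding is restricted to its first tenth; the sample
    mean of the measured endpoint velocities is reported. Tracks that
    never exceed the 2-pixel start threshold are unmeasurable and
    excluded, as they are for the real mutant data.
    """
    optics = OpticsParams(n_frames=n_frames)
    motor = MotorParams(
        **RAD54_ALONE_VELOCITY, **RAD54_ALONE_TRACK_LEN, binding_rate=0.004
    )
    window = n_frames // 10
    n_dna = int(np.ceil(n_tracks / (motor.binding_rate * window) * 1.2))
    tracks = simulate_tracks(
        motor, optics, n_dna=n_dna, seed=seed, binding_window_frames=window
    )
    segmented, _ = segment_simulation(tracks, optics, seed=seed + 1)
    velocities = np.array(
        [t.velocity_bp_s for t in segmented if t.velocity_bp_s is not None]
    )
    return {
        "n_true_tracks": len(tracks),
        "n_measured": velocities.size,
        "velocities": velocities,
        "mean_bp_s": float(velocities.mean()),
    }


def recover_rpa_stoichiometry(
    seed: int = 0,
    n_events: int = 200,
    n_frames: int = 250,
) -> Dict[str, object]:
    """Recover the mean RPA molecule count (2.5) by intensity division.

    Simulates WT trajectories with RPA episodes whose molecule counts are
    drawn from the 2.5 +/- 1.5 stoichiometry law, renders all three
    channels with camera noise, detects colocalized episodes on the
    magenta channel and estimates each episode's stoichiometry from its
    background-subtracted intensity over the known single-fluorophore
    intensity.
    """
    optics = OpticsParams(n_frames=n_frames)
    motor = MotorParams(binding_rate=0.02)
    rpa = RPAGenParams()
    window = n_frames // 2
    n_dna = int(np.ceil(n_events / (motor.binding_rate * window) * 1.6))
    tracks = simulate_tracks(
        motor, optics, n_dna=n_dna, seed=seed, binding_window_frames=window
    )
    true_events = simulate_rpa(tracks, rpa, optics, seed=seed + 1)
    segmented, kymos = segment_simulation(
        tracks, optics, seed=seed + 2, rpa_events=true_events
    )

    by_dna: Dict[int, List[SegmentedTrack]] = {}
    for tr in segmented:
        by_dna.setdefault(tr.dna_id, []).append(tr)
    estimates = []
    for dna_id, kymo in kymos.items():
        dna_tracks = by_dna.get(dna_id, [])
        if not dna_tracks:
            continue
        for ev in detect_colocalization(dna_tracks, kymo):
            est = estimate_stoichiometry(
                ev.peak_intensity,
                ev.background_estimate,
                unit_intensity=optics.unit_intensity,
                footprint_nt=rpa.footprint_nt,
            )
            estimates.append(est.estimated_molecules)
    estimates = np.asarray(estimates)
    return {
        "n_true_events": len(true_events),
        "n_detected": estimates.size,
        "estimates": estimates,
        "mean_molecules": float(estimates.mean()),
    }


def recover_sectored_co(
    seed: int = 0,
    n_replicates: int = 6,
    n_colonies: int = 500,
    co_probability: float = 0.504,
) -> Dict[str, object]:
    """Recover the sectored-colony crossover percentage (50.4% scale).

    Simulates six replicates of sectored colonies at the configured CO
    probability, classifies every record from its phenotype alone, and
    tallies per-replicate fractions.
    """
    probs = {
        ("CO", "sectored"): co_probability,
        ("NCO", "sectored"): (1.0 - co_probability) * 0.9,
        ("BIR", "sectored"): (1.0 - co_probability) * 0.1,
    }
    records = simulate_colony_assay(
        probs, n_colonies=n_colonies, n_replicates=n_replicates, seed=seed
    )
    tally = tally_outcomes(records, population="sectored")
    return {
        "tally": tally,
        "co_percent_mean": float(tally.mean["CO"] * 100.0),
        "co_percent_sd": float(tally.sd["CO"] * 100.0),
        "n_replicates": tally.n_replicates,
    }
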