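"""Synthetic DNA-curtain data generator.

Produces ground-truth motor trajectories, RPA recruitment events, rendered
three-color kymographs and red/white colony-assay records with the
statistical structure the downstream analyses assume, so every stage of
the pipeline can be exercised without microscope or plate data.

The simulated geometry is a doubly tethered lambda DNA (48,502 bp) imaged
as a 1-pixel-wide line at 1 kb/pixel. Presynaptic complexes (PSCs) bind,
translocate with mixture-distributed velocities, pause briefly, and stop
after travelling a drawn distance; on homology-carrying DNA they can be
captured at the target site either while sliding past it (1D) or directly
from solution at binding (3D). RPA joins a translocating PSC after an
association delay and stays for a finite lifetime; its fluorophore count
is drawn from a configurable stoichiometry law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ContractViolationError, InvalidParameterError
from .params import (
    LAMBDA_DNA_BP,
    Distribution,
    MotorParams,
    OpticsParams,
    RPAGenParams,
    sample_zero_truncated_normal,
    zero_truncated_normal_params,
)

CAPTURE_NONE = "none"
CAPTURE_1D = "1D"
CAPTURE_3D = "3D"


@dataclass
class TrueTrack:
    """Ground-truth trajectory of one PSC on one DNA molecule.

    positions_bp[i] is the position at absolute frame bind_frame + i; the
    trajectory ends at termination_frame (inclusive), after which the
    molecule has left the DNA or the record ends.
    """

    track_id: int
    dna_id: int
    bind_frame: int
    positions_bp: np.ndarray
    drawn_velocity_bp_s: float
    drawn_track_len_bp: float
    pause_intervals: List[Tuple[int, int]]
    termination_frame: int
    captured_at_target: bool = False
    capture_mode: str = CAPTURE_NONE
    capture_frame: Optional[int] = None
    pre_capture_distance_bp: float = 0.0
    released: bool = False

    def __post_init__(self) -> None:
        if self.termination_frame < self.bind_frame:
            raise ContractViolationError("termination_frame < bind_frame")
        if (self.capture_mode == CAPTURE_NONE) == self.captured_at_target:
            raise ContractViolationError("capture_mode inconsistent with captured_at_target")

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.bind_frame, self.termination_frame + 1)

    def position_at(self, frame: int) -> float:
        return float(self.positions_bp[frame - self.bind_frame])


@dataclass
class TrueRPAEvent:
    """Ground-truth RPA recruitment episode on one track."""

    track_id: int
    n_molecules: int
    assoc_frame: int
    dissoc_frame: Optional[int]
    censored: bool

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ContractViolationError("n_molecules must be >= 1")
        if not self.censored and (
            self.dissoc_frame is None or self.dissoc_frame <= self.assoc_frame
        ):
            raise ContractViolationError("uncensored event needs dissoc_frame > assoc_frame")


@dataclass
class KymographTriplet:
    """Three co-registered time x position intensity matrices.

    green: GFP-Rad54, blue: Atto647N-labelled 90-mer ssDNA (carried by the
    PSC), magenta: RPA-mCherry. All share shape (n_frames, n_pixels).
    """

    green: np.ndarray
    blue: np.ndarray
    magenta: np.ndarray
    optics: OpticsParams
    provenance: Dict[str, object] = field(default_factory=dict)
    truth_tracks: Optional[List[TrueTrack]] = None
    truth_rpa_events: Optional[List[TrueRPAEvent]] = None

    def __post_init__(self) -> None:
        shapes = {self.green.shape, self.blue.shape, self.magenta.shape}
        if len(shapes) != 1:
            raise ContractViolationError("channel shapes differ")
        if min(arr.min() for arr in (self.green, self.blue, self.magenta)) < 0:
            raise ContractViolationError("negative intensities")

    @property
    def channels(self) -> Dict[str, np.ndarray]:
        return {"green": self.green, "blue": self.blue, "magenta": self.magenta}

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.green.shape[1]


# ---------------------------------------------------------------------------
# Motor trajectories
# ---------------------------------------------------------------------------


def _component_truncnorm_params(means, sds):
    return [zero_truncated_normal_params(m, s) if m > 0 or s > 0 else (m, s)
            for m, s in zip(means, sds)]


def _simulate_one_track(
    rng: np.random.Generator,
    motor: MotorParams,
    optics: OpticsParams,
    dna_length_bp: float,
    vel_params,
    len_params,
    track_id: int,
    dna_id: int,
    bind_frame: int,
) -> TrueTrack:
    dt = optics.frame_interval_s
    n_frames = optics.n_frames

    # velocity and total travel drawn from their (truncated-normal) mixtures
    ci = rng.choice(len(motor.mixture_weights), p=np.asarray(motor.mixture_weights))
    mu, sigma = vel_params[ci]
    velocity = float(sample_zero_truncated_normal(rng, mu, sigma))
    li = rng.choice(len(motor.track_len_weights), p=np.asarray(motor.track_len_weights))
    lmu, lsigma = len_params[li]
    track_len_bp = 1000.0 * float(sample_zero_truncated_normal(rng, lmu, lsigma))

    target = motor.target_pos_bp
    captured = False
    capture_mode = CAPTURE_NONE
    capture_frame: Optional[int] = None
    pre_capture_bp = 0.0
    released = False

    # 3D capture: a fraction of initial bindings lands directly on target
    if target is not None and rng.random() < motor.p_capture_3d:
        pos = float(target)
        captured = True
        capture_mode = CAPTURE_3D
        capture_frame = bind_frame
    else:
        pos = float(rng.uniform(0.0, dna_length_bp))

    direction = 1.0 if rng.random() < 0.5 else -1.0
    positions = [pos]
    pauses: List[Tuple[int, int]] = []

    traveled = 0.0
    pause_left = 0
    pause_start: Optional[int] = None
    stopped = False
    stop_dwell_left = 0
    release_at: Optional[int] = None
    if captured:
        if rng.random() < motor.p_transient_release:
            release_at = bind_frame + max(1, int(round(motor.dwell_release_s / dt)))

    end_frame = bind_frame
    for frame in range(bind_frame + 1, n_frames):
        if captured:
            if release_at is not None and frame >= release_at:
                released = True
                break
            positions.append(pos)
            end_frame = frame
            continue
        if stopped:
            if stop_dwell_left <= 0:
                break
            stop_dwell_left -= 1
            positions.append(pos)
            end_frame = frame
            continue
        if pause_left > 0:
            pause_left -= 1
            if pause_left == 0 and pause_start is not None:
                pauses.append((pause_start, frame))
                pause_start = None
            positions.append(pos)
            end_frame = frame
            continue
        if motor.pause_prob_per_frame > 0 and rng.random() < motor.pause_prob_per_frame:
            lo, hi = motor.pause_len_frames_range
            length = int(rng.integers(lo, hi + 1))
            pause_start = frame
            pause_left = length - 1
            if pause_left == 0:
                pauses.append((frame, frame))
                pause_start = None
            positions.append(pos)
            end_frame = frame
            continue

        step = direction * velocity * dt
        new_pos = pos + step
        hit_end = new_pos < 0.0 or new_pos > dna_length_bp
        if hit_end:
            if motor.end_behavior == "reflect":
                if new_pos < 0.0:
                    new_pos = -new_pos
                else:
                    new_pos = 2.0 * dna_length_bp - new_pos
                direction = -direction
            else:
                # the tether point stalls the motor
                new_pos = min(max(new_pos, 0.0), dna_length_bp)
        # capture while sliding across the homologous site
        if target is not None and min(pos, new_pos) <= target <= max(pos, new_pos):
            if rng.random() < motor.p_capture_1d:
                pre_capture_bp = traveled + abs(target - pos)
                traveled = pre_capture_bp
                pos = float(target)
                captured = True
                capture_mode = CAPTURE_1D
                capture_frame = frame
                if rng.random() < motor.p_transient_release:
                    release_at = frame + max(1, int(round(motor.dwell_release_s / dt)))
                positions.append(pos)
                end_frame = frame
                continue
        traveled += abs(new_pos - pos)
        pos = new_pos
        positions.append(pos)
        end_frame = frame
        if (hit_end and motor.end_behavior == "terminate") or traveled >= track_len_bp:
            stopped = True
            if motor.stop_dwell_mean_frames > 0:
                stop_dwell_left = int(rng.geometric(1.0 / motor.stop_dwell_mean_frames))
            else:
                stop_dwell_left = 0

    if pause_start is not None:
        pauses.append((pause_start, end_frame))

    return TrueTrack(
        track_id=track_id,
        dna_id=dna_id,
        bind_frame=bind_frame,
        positions_bp=np.asarray(positions, dtype=float),
        drawn_velocity_bp_s=velocity,
        drawn_track_len_bp=track_len_bp,
        pause_intervals=pauses,
        termination_frame=end_frame,
        captured_at_target=captured,
        capture_mode=capture_mode,
        capture_frame=capture_frame,
        pre_capture_distance_bp=pre_capture_bp,
        released=released,
    )


def simulate_tracks(
    motor: MotorParams,
    optics: OpticsParams,
    dna_length_bp: float = LAMBDA_DNA_BP,
    n_dna: int = 100,
    seed: int = 0,
    binding_window_frames: Optional[int] = None,
) -> List[TrueTrack]:
    """Simulate PSC trajectories on ``n_dna`` independent DNA molecules.

    New binders arrive per DNA per frame at ``motor.binding_rate``;
    ``binding_window_frames`` optionally restricts arrivals to the start of
    the record (protein is injected at the start of a curtain experiment).
    Reproducible for a fixed seed.
    """
    if n_dna <= 0:
        raise InvalidParameterError("n_dna must be > 0")
    if optics.fov_length_bp < dna_length_bp:
        raise InvalidParameterError("field of view shorter than the DNA")
    if motor.target_pos_bp is not None and not 0 <= motor.target_pos_bp <= dna_length_bp:
        raise InvalidParameterError("target_pos_bp outside the DNA")

    rng = np.random.default_rng(seed)
    vel_params = _component_truncnorm_params(motor.mixture_means_bp_s, motor.mixture_sds_bp_s)
    len_params = _component_truncnorm_params(motor.track_len_means_kb, motor.track_len_sds_kb)
    window = optics.n_frames if binding_window_frames is None else min(
        binding_window_frames, optics.n_frames
    )

    tracks: List[TrueTrack] = []
    track_id = 0
    for dna_id in range(n_dna):
        arrivals = np.flatnonzero(rng.random(window) < motor.binding_rate)
        for bind_frame in arrivals:
            tracks.append(
                _simulate_one_track(
                    rng, motor, optics, dna_length_bp, vel_params, len_params,
                    track_id, dna_id, int(bind_frame),
                )
            )
            track_id += 1
    return tracks


# ---------------------------------------------------------------------------
# RPA recruitment
# ---------------------------------------------------------------------------


def simulate_rpa(
    tracks: Sequence[TrueTrack],
    rpa: RPAGenParams,
    optics: OpticsParams,
    seed: int = 0,
) -> List[TrueRPAEvent]:
    """Attach at most one RPA episode to each track.

    The episode starts an association delay after the PSC binds dsDNA and
    lasts a drawn lifetime; episodes still bound when the track's record
    ends (the PSC leaves or the movie ends) are flagged censored, because
    their dissociation cannot be observed.
    """
    rng = np.random.default_rng(seed)
    dt = optics.frame_interval_s
    events: List[TrueRPAEvent] = []
    for track in tracks:
        if rng.random() >= rpa.episode_prob:
            continue
        n_mol = int(rpa.stoich_distribution.sample(rng))
        if n_mol < 1:
            continue
        delay_s = float(rpa.association_delay_s_distribution.sample(rng))
        assoc = track.bind_frame + int(round(delay_s / dt))
        observed_end = min(track.termination_frame, optics.n_frames - 1)
        if assoc > observed_end:
            continue  # RPA never colocalized while the PSC was observable
        lifetime_s = float(rpa.lifetime_s_distribution.sample(rng))
        dissoc = assoc + max(1, int(round(lifetime_s / dt)))
        censored = dissoc > observed_end
        events.append(
            TrueRPAEvent(
                track_id=track.track_id,
                n_molecules=n_mol,
                assoc_frame=assoc,
                dissoc_frame=None if censored else dissoc,
                censored=censored,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Kymograph rendering
# ---------------------------------------------------------------------------


def _bleach_profile(rng, rate, n_frames, n_fluors):
    """Per-frame count of unbleached fluorophores (geometric survival)."""
    if rate <= 0.0:
        return np.full(n_frames, float(n_fluors))
    lifetimes = rng.geometric(rate, size=n_fluors)  # frames survived
    alive = np.zeros(n_frames)
    for lt in lifetimes:
        alive[: min(int(lt), n_frames)] += 1.0
    return alive


def _paint(image, frames, x_px, amplitudes, psf_sigma, edges):
    """Add PSF-spread emitter intensity into image[frames]."""
    z = (edges[None, :] - x_px[:, None]) / psf_sigma
    mass = np.diff(stats.norm.cdf(z), axis=1)
    image[frames] += amplitudes[:, None] * mass


def render_kymograph(
    tracks: Sequence[TrueTrack],
    rpa_events: Sequence[TrueRPAEvent],
    optics: OpticsParams,
    seed: int = 0,
    dna_length_bp: float = LAMBDA_DNA_BP,
) -> KymographTriplet:
    """Render the three-channel kymograph for one DNA molecule.

    Pixel p covers [p*bp_per_pixel, (p+1)*bp_per_pixel) (0-based); each
    fluorophore contributes unit_intensity spread by a 1-D Gaussian PSF.
    RPA events contribute n_molecules fluorophores that bleach
    independently. Gaussian camera background is added and clipped at 0.
    """
    rng = np.random.default_rng(seed)
    shape = (optics.n_frames, optics.n_pixels)
    green = np.zeros(shape)
    blue = np.zeros(shape)
    magenta = np.zeros(shape)
    edges = np.arange(optics.n_pixels + 1, dtype=float)

    track_by_id = {t.track_id: t for t in tracks}
    for track in tracks:
        if np.any(track.positions_bp < 0) or np.any(track.positions_bp > dna_length_bp):
            raise ContractViolationError("track position outside the DNA")
        frames = track.frames
        frames = frames[frames < optics.n_frames]
        if frames.size == 0:
            continue
        x_px = track.positions_bp[: frames.size] / optics.bp_per_pixel
        for image in (green, blue):
            alive = _bleach_profile(rng, optics.bleach_rate_per_frame, frames.size, 1)
            _paint(image, frames, x_px, optics.unit_intensity * alive,
                   optics.psf_sigma_px, edges)

    for event in rpa_events:
        track = track_by_id.get(event.track_id)
        if track is None:
            raise ContractViolationError(f"RPA event for unknown track {event.track_id}")
        last = event.dissoc_frame if event.dissoc_frame is not None else min(
            track.termination_frame, optics.n_frames - 1
        )
        last = min(last, track.termination_frame, optics.n_frames - 1)
        frames = np.arange(event.assoc_frame, last + 1)
        if frames.size == 0:
            continue
        x_px = np.array([track.position_at(f) for f in frames]) / optics.bp_per_pixel
        alive = _bleach_profile(rng, optics.bleach_rate_per_frame, frames.size,
                                event.n_molecules)
        _paint(magenta, frames, x_px, optics.unit_intensity * alive,
               optics.psf_sigma_px, edges)

    for image in (green, blue, magenta):
        image += rng.normal(optics.background_mean, optics.background_sd, size=shape)
        np.clip(image, 0.0, None, out=image)

    return KymographTriplet(
        green=green,
        blue=blue,
        magenta=magenta,
        optics=optics,
        provenance={"seed": seed, "dna_length_bp": dna_length_bp},
        truth_tracks=list(tracks),
        truth_rpa_events=list(rpa_events),
    )


# ---------------------------------------------------------------------------
# Colony assay
# ---------------------------------------------------------------------------


def simulate_colony_assay(
    probs: Dict[Tuple[str, str], float],
    n_colonies: int,
    n_replicates: int,
    seed: int = 0,
    strain: str = "WT",
):
    """Simulate red/white assay colonies with known generating outcomes.

    ``probs`` maps (outcome, color_class) pairs -- outcome in {"NCO",
    "CO", "BIR", "chromosome_loss"}, color_class in {"sectored",
    "solid_red", "white"} -- to probabilities summing to 1. Each colony's
    phenotype is built by inverting the outcome decision tree, so the
    classifier maps every simulated record back to its generating outcome.
    BIR is only identifiable in sectored colonies (an unsectored colony
    resistant to both antibiotics reads as NCO), so BIR probability mass
    on unsectored classes is rejected.

    Replicate labels are assigned round-robin.
    """
    from .outcomes import OUTCOMES, phenotype_for_outcome  # local import: avoid cycle

    if n_colonies <= 0 or n_replicates <= 0:
        raise InvalidParameterError("n_colonies and n_replicates must be > 0")
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InvalidParameterError("outcome probabilities must be >= 0 and sum to 1")
    for (outcome, color_class) in keys:
        if outcome not in OUTCOMES:
            raise InvalidParameterError(f"unknown outcome {outcome!r}")
        if color_class not in ("sectored", "solid_red", "white"):
            raise InvalidParameterError(f"unknown color class {color_class!r}")
        if outcome == "BIR" and color_class != "sectored" and probs[(outcome, color_class)] > 0:
            raise InvalidParameterError("BIR is only identifiable in sectored colonies")

    rng = np.random.default_rng(seed)
    records = []
    total = n_colonies * n_replicates
    draws = rng.choice(len(keys), size=total, p=p / p.sum())
    for i in range(total):
        outcome, color_class = keys[draws[i]]
        record = phenotype_for_outcome(
            outcome, color_class, rng,
            replicate_id=i % n_replicates, strain=strain,
        )
        records.append(record)
    return records
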