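"""Kymograph track recovery and translocation annotation.

Implements the kymograph reading rules used for curtain data: a molecule
has started translocating once its net displacement from the binding
pixel exceeds 2 pixels; momentary stalls of 2-4 frames are pauses;
a molecule that sits still for more than 10 frames at the end of its
record has terminated, and the stop time is the first frame of that
static run. Velocity is endpoint-based,

    v = |Yf - Yi| * bp_per_pixel / ((Xf - Xi) * frame_interval_s),

with (Xi, Yi) the initial position of the translocation phase and
(Xf, Yf) its stop; pauses are included in the elapsed time. The >2 pixel
rule decides WHETHER a molecule translocated; the measurement origin
(Xi, Yi) is the movement onset -- the first departure from the binding
pixel -- because both the onset and the stop are then pixel-entry
events, which makes the endpoint slope an unbiased velocity estimate
(measuring instead from the frame the 2-pixel criterion is met would
discard the first ~3 pixels of every track and collapse short tracks
to zero velocity). Sub-pixel centroids are computed but rounded to
whole pixels for rule evaluation, because all thresholds are stated in
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import InputValidationError, InvalidParameterError, UndefinedVelocityError
from .params import OpticsParams
from .simulate import KymographTriplet


@dataclass(frozen=True)
class SegmentationThresholds:
    """Pixel/frame thresholds for start, pause and termination calls.

    start_displacement_px: net displacement (strictly greater than) that
        marks the start of translocation.
    pause_min_frames..pause_max_frames: duration window of a stall that
        counts as a pause.
    termination_min_frames: a final static run strictly longer than this
        marks termination.
    detection_snr: peak threshold in robust noise SDs above background.
    link_gate_px_per_frame: maximum pixel step per frame when linking
        detections into tracks (covers the fastest expected velocity at
        default optics).
    """

    start_displacement_px: int = 2
    pause_min_frames: int = 2
    pause_max_frames: int = 4
    termination_min_frames: int = 10
    detection_snr: float = 5.0
    link_gate_px_per_frame: float = 3.0
    max_gap_frames: int = 2
    min_track_frames: int = 5

    def __post_init__(self) -> None:
        if not (self.pause_min_frames <= self.pause_max_frames < self.termination_min_frames):
            raise InvalidParameterError("need pause_min <= pause_max < termination_min")
        if self.start_displacement_px < 1:
            raise InvalidParameterError("start_displacement_px must be >= 1")
        if self.link_gate_px_per_frame <= 0 or self.max_gap_frames < 0:
            raise InvalidParameterError("invalid linking parameters")


@dataclass
class SegmentedTrack:
    """A track recovered from a kymograph, with translocation annotations.

    pixel_positions may contain NaN at frames where the peak was missed;
    rounded_positions is gap-filled (last observed pixel) for rule
    evaluation. start/stop fields are the Xi, Yi, Xf, Yf of the endpoint
    velocity formula.
    """

    track_id: int
    frame_of_first_detection: int
    pixel_positions: np.ndarray  # float, NaN where missed
    rounded_positions: np.ndarray  # int, gap-filled
    binding_pixel: int
    start_frame: Optional[int]
    stop_frame: int
    start_pixel: Optional[int]
    stop_pixel: int
    onset_frame: Optional[int]
    onset_pixel: Optional[int]
    pause_intervals: List[Tuple[int, int]]
    terminated: bool
    onset_subpixel: Optional[float] = None
    stop_subpixel: Optional[float] = None
    dna_id: Optional[int] = None
    velocity_bp_s: Optional[float] = None
    distance_kb: float = 0.0

    @property
    def last_frame(self) -> int:
        return self.frame_of_first_detection + len(self.rounded_positions) - 1

    @property
    def n_frames(self) -> int:
        return len(self.rounded_positions)

    def pixel_at(self, frame: int) -> int:
        return int(self.rounded_positions[frame - self.frame_of_first_detection])


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------


def _detect_peaks_frame_image(image: np.ndarray, snr: float):
    """Per-frame 1-D local maxima above a robust global threshold.

    Returns (frame_idx, subpixel_position) arrays. The threshold is
    background + snr * noise, with background the image median and noise
    the scaled median absolute deviation.
    """
    bg = float(np.median(image))
    noise = 1.4826 * float(np.median(np.abs(image - bg)))
    threshold = bg + snr * noise
    padded = np.pad(image, ((0, 0), (1, 1)), constant_values=-np.inf)
    is_max = (padded[:, 1:-1] > padded[:, :-2]) & (padded[:, 1:-1] >= padded[:, 2:])
    candidates = is_max & (image > threshold)
    frames, pixels = np.nonzero(candidates)

    # centroid refinement in a +/-2 px window, background subtracted
    n_px = image.shape[1]
    subpix = np.empty(frames.size)
    offsets = np.arange(-2, 3)
    for i, (t, p) in enumerate(zip(frames, pixels)):
        win = np.clip(p + offsets, 0, n_px - 1)
        w = np.clip(image[t, win] - bg, 0.0, None)
        total = w.sum()
        subpix[i] = p if total == 0 else float(np.dot(w, win) / total)
    return frames, subpix


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


def _link_detections(frames, subpix, thresholds):
    """Greedy nearest-position frame-to-frame linking.

    Returns a list of (first_frame, positions) with NaN for missed frames.
    """
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    subpix = subpix[order]
    active: List[dict] = []
    done: List[dict] = []
    unique_frames = np.unique(frames)
    for t in unique_frames:
        dets = subpix[frames == t]
        # retire tracks that have been dark too long
        still_active = []
        for tr in active:
            if t - tr["last_frame"] > thresholds.max_gap_frames + 1:
                done.append(tr)
            else:
                still_active.append(tr)
        active = still_active

        pairs = []
        for ti, tr in enumerate(active):
            gap = t - tr["last_frame"]
            gate = thresholds.link_gate_px_per_frame * gap
            for di, d in enumerate(dets):
                dist = abs(d - tr["last_pos"])
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            tr["frames"].append(t)
            tr["positions"].append(dets[di])
            tr["last_frame"] = t
            tr["last_pos"] = dets[di]
        for di, d in enumerate(dets):
            if di not in used_d:
                active.append(
                    {"frames": [t], "positions": [d], "last_frame": t, "last_pos": d}
                )
    done.extend(active)

    linked = []
    for tr in done:
        f = np.asarray(tr["frames"])
        p = np.asarray(tr["positions"])
        if f.size < thresholds.min_track_frames:
            continue
        full = np.full(f[-1] - f[0] + 1, np.nan)
        full[f - f[0]] = p
        linked.append((int(f[0]), full))
    linked.sort(key=lambda item: (item[0], item[1][np.isfinite(item[1])][0]))
    return linked


# ---------------------------------------------------------------------------
# Rule annotation
# ---------------------------------------------------------------------------


def _runs(values: np.ndarray):
    """(start_index, length) of maximal constant runs."""
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [values.size - 1]))
    return list(zip(starts.tolist(), (ends - starts + 1).tolist()))


def annotate_track(
    first_frame: int,
    pixel_positions: np.ndarray,
    thresholds: SegmentationThresholds,
    track_id: int = 0,
    dna_id: Optional[int] = None,
) -> SegmentedTrack:
    """Apply the start/pause/termination rules to one pixel trajectory."""
    pix = np.asarray(pixel_positions, dtype=float)
    # gap-fill with the last observed position, round to whole pixels
    filled = pix.copy()
    for i in range(1, filled.size):
        if np.isnan(filled[i]):
            filled[i] = filled[i - 1]
    # 3-frame median suppresses single-frame localization flicker, which
    # would otherwise break static runs and shift termination calls
    if filled.size >= 3:
        filled = ndimage.median_filter(filled, size=3, mode="nearest")
    rounded = np.round(filled).astype(int)

    binding_px = int(rounded[0])
    moved = np.abs(rounded - binding_px) > thresholds.start_displacement_px
    start_idx = int(np.argmax(moved)) if moved.any() else None
    # movement onset: first departure from the binding pixel (a pixel-entry
    # event, which pairs with the stop pixel-entry for unbiased velocities)
    departed = rounded != binding_px
    onset_idx = int(np.argmax(departed)) if departed.any() else None

    runs = _runs(rounded)
    final_start, final_len = runs[-1]
    terminated = final_len > thresholds.termination_min_frames
    # the stop endpoint is the entry into the final pixel (a pixel-entry
    # event, like the onset); the >10-frame rule only decides whether the
    # molecule terminated there or the record simply ended
    stop_idx = final_start
    if start_idx is not None:
        stop_idx = max(stop_idx, start_idx)

    pauses: List[Tuple[int, int]] = []
    if start_idx is not None:
        for run_start, run_len in runs[:-1]:
            if run_start < start_idx or run_start + run_len - 1 >= stop_idx:
                continue
            if thresholds.pause_min_frames <= run_len <= thresholds.pause_max_frames:
                pauses.append(
                    (first_frame + run_start, first_frame + run_start + run_len - 1)
                )

    return SegmentedTrack(
        track_id=track_id,
        dna_id=dna_id,
        frame_of_first_detection=first_frame,
        pixel_positions=pix,
        rounded_positions=rounded,
        binding_pixel=binding_px,
        start_frame=None if start_idx is None else first_frame + start_idx,
        stop_frame=first_frame + stop_idx,
        start_pixel=None if start_idx is None else int(rounded[start_idx]),
        stop_pixel=int(rounded[stop_idx]),
        onset_frame=None if onset_idx is None else first_frame + onset_idx,
        onset_pixel=None if onset_idx is None else int(rounded[onset_idx]),
        onset_subpixel=None if onset_idx is None else float(filled[onset_idx]),
        stop_subpixel=float(filled[stop_idx]),
        pause_intervals=pauses,
        terminated=terminated,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def detect_tracks(
    kymo: KymographTriplet,
    channel: str = "green",
    thresholds: Optional[SegmentationThresholds] = None,
) -> List[SegmentedTrack]:
    """Recover annotated tracks from one channel of a kymograph."""
    thresholds = thresholds or SegmentationThresholds()
    image = kymo.channels[channel]
    if image.size == 0:
        raise InputValidationError("empty kymograph")
    if not np.all(np.isfinite(image)) or np.any(image < 0):
        raise InputValidationError("kymograph intensities must be finite and >= 0")

    frames, subpix = _detect_peaks_frame_image(image, thresholds.detection_snr)
    tracks: List[SegmentedTrack] = []
    for track_id, (first_frame, positions) in enumerate(
        _link_detections(frames, subpix, thresholds)
    ):
        track = annotate_track(first_frame, positions, thresholds, track_id=track_id)
        try:
            track.velocity_bp_s = compute_velocity(track, kymo.optics)
        except UndefinedVelocityError:
            # start and stop coincide: translocation too brief to measure
            track.velocity_bp_s = None
        track.distance_kb = compute_distance(track, kymo.optics)
        tracks.append(track)
    return tracks


def compute_velocity(
    track: SegmentedTrack,
    optics: OpticsParams,
    exclude_pauses: bool = False,
) -> Optional[float]:
    """Endpoint translocation velocity in bp/s.

    Returns None for tracks that never started translocating (their
    velocity cannot be measured). By default pauses are included in the
    elapsed time, matching the endpoint formula; ``exclude_pauses``
    subtracts annotated pause frames.
    """
    if track.start_frame is None or track.onset_frame is None:
        return None
    elapsed_frames = track.stop_frame - track.onset_frame
    if elapsed_frames <= 0:
        raise UndefinedVelocityError("track start and stop coincide")
    if exclude_pauses:
        for p0, p1 in track.pause_intervals:
            lo = max(p0, track.onset_frame)
            hi = min(p1, track.stop_frame)
            if hi >= lo:
                elapsed_frames -= hi - lo + 1
        if elapsed_frames <= 0:
            raise UndefinedVelocityError("no non-paused frames between start and stop")
    dy_px = _endpoint_span_px(track)
    return dy_px * optics.bp_per_pixel / (elapsed_frames * optics.frame_interval_s)


def _endpoint_span_px(track: SegmentedTrack) -> float:
    """|Yf - Yi| from the sub-pixel centroids (rounded-pixel fallback).

    Threshold rules are evaluated on rounded pixels, but the endpoint
    positions themselves are measured at centroid resolution, which
    removes pixel-quantization noise from velocities of short tracks.
    """
    if track.onset_subpixel is not None and track.stop_subpixel is not None:
        return abs(track.stop_subpixel - track.onset_subpixel)
    return float(abs(track.stop_pixel - track.onset_pixel))


def compute_distance(track: SegmentedTrack, optics: OpticsParams) -> float:
    """Net translocation distance in kb (0 for tracks that never start)."""
    if track.start_frame is None or track.onset_pixel is None:
        return 0.0
    return _endpoint_span_px(track) * optics.bp_per_pixel / 1000.0
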