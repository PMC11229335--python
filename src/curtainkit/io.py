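"""Reading and writing kymographs, track tables and colony tables.

Kymographs travel as multi-page TIFF (pages ordered frame-major, three
channel pages per frame) or as one plain CSV matrix per channel; track
and event tables as CSV with one row per track/event; run configuration
as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InputValidationError
from .outcomes import ColonyRecord, SectorPhenotype
from .params import MotorParams, OpticsParams, RPAGenParams
from .rpa import RPAEvent
from .segmentation import SegmentedTrack
from .simulate import KymographTriplet, TrueRPAEvent, TrueTrack

CHANNEL_ORDER = ("green", "blue", "magenta")


def save_kymograph_tiff(kymo: KymographTriplet, path) -> None:
    stack = np.stack([kymo.channels[c] for c in CHANNEL_ORDER], axis=1)
    # pages: frame-major, one page per frame per channel
    tifffile.imwrite(path, stack.reshape(-1, 1, kymo.n_pixels).astype(np.float32))


def load_kymograph_tiff(path, optics: OpticsParams) -> KymographTriplet:
    pages = tifffile.imread(path)
    flat = np.asarray(pages, dtype=float).reshape(-1, pages.shape[-1])
    if flat.shape[0] % len(CHANNEL_ORDER) != 0:
        raise InputValidationError("TIFF page count is not a multiple of 3 channels")
    stack = flat.reshape(-1, len(CHANNEL_ORDER), flat.shape[-1])
    channels = {c: stack[:, i, :] for i, c in enumerate(CHANNEL_ORDER)}
    return KymographTriplet(
        green=channels["green"], blue=channels["blue"], magenta=channels["magenta"],
        optics=optics, provenance={"source": str(path)},
    )


def save_kymograph_csv(kymo: KymographTriplet, out_dir, prefix: str = "kymo") -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in CHANNEL_ORDER:
        p = out_dir / f"{prefix}_{c}.csv"
        np.savetxt(p, kymo.channels[c], delimiter=",", fmt="%.4f")
        paths.append(p)
    return paths


def load_kymograph_csv(out_dir, optics: OpticsParams, prefix: str = "kymo") -> KymographTriplet:
    out_dir = Path(out_dir)
    channels = {
        c: np.loadtxt(out_dir / f"{prefix}_{c}.csv", delimiter=",", ndmin=2)
        for c in CHANNEL_ORDER
    }
    return KymographTriplet(
        green=channels["green"], blue=channels["blue"], magenta=channels["magenta"],
        optics=optics, provenance={"source": str(out_dir)},
    )


def segmented_tracks_to_frame(tracks: Sequence[SegmentedTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        rows.append(
            {
                "track_id": t.track_id,
                "dna_id": t.dna_id,
                "frame_of_first_detection": t.frame_of_first_detection,
                "binding_pixel": t.binding_pixel,
                "start_frame": t.start_frame,
                "stop_frame": t.stop_frame,
                "start_pixel": t.start_pixel,
                "stop_pixel": t.stop_pixel,
                "terminated": t.terminated,
                "n_pauses": len(t.pause_intervals),
                "velocity_bp_s": t.velocity_bp_s,
                "distance_kb": t.distance_kb,
                "last_frame": t.last_frame,
            }
        )
    return pd.DataFrame(rows)


def true_tracks_to_frame(tracks: Sequence[TrueTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        rows.append(
            {
                "track_id": t.track_id,
                "dna_id": t.dna_id,
                "bind_frame": t.bind_frame,
                "termination_frame": t.termination_frame,
                "drawn_velocity_bp_s": t.drawn_velocity_bp_s,
                "drawn_track_len_bp": t.drawn_track_len_bp,
                "captured_at_target": t.captured_at_target,
                "capture_mode": t.capture_mode,
                "pre_capture_distance_bp": t.pre_capture_distance_bp,
                "released": t.released,
                "n_pauses": len(t.pause_intervals),
            }
        )
    return pd.DataFrame(rows)


def rpa_events_to_frame(events: Sequence[RPAEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "track_id": ev.track_id,
                "track_bind_frame": ev.track_bind_frame,
                "assoc_frame": ev.assoc_frame,
                "dissoc_frame": ev.dissoc_frame,
                "censored": ev.censored,
                "assoc_delay_s": ev.assoc_delay_s,
                "lifetime_s": ev.lifetime_s,
                "peak_intensity": ev.peak_intensity,
                "background_estimate": ev.background_estimate,
            }
        )
    return pd.DataFrame(rows)


def true_rpa_events_to_frame(events: Sequence[TrueRPAEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": ev.track_id,
                "n_molecules": ev.n_molecules,
                "assoc_frame": ev.assoc_frame,
                "dissoc_frame": ev.dissoc_frame,
                "censored": ev.censored,
            }
            for ev in events
        ]
    )


def colony_records_to_frame(records: Sequence[ColonyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "replicate_id": r.replicate_id,
            "strain": r.strain,
            "color": r.color,
            "ura_met_growth": r.ura_met_growth,
            "generating_outcome": r.generating_outcome,
        }
        for i in range(2):
            if i < len(r.sectors):
                s = r.sectors[i]
                row[f"sector{i + 1}_color"] = s.color
                row[f"sector{i + 1}_hyg"] = s.hyg_resistant
                row[f"sector{i + 1}_nat"] = s.nat_resistant
            else:
                row[f"sector{i + 1}_color"] = None
                row[f"sector{i + 1}_hyg"] = None
                row[f"sector{i + 1}_nat"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def colony_records_from_frame(df: pd.DataFrame) -> List[ColonyRecord]:
    records = []
    for _, row in df.iterrows():
        sectors = []
        for i in (1, 2):
            color = row.get(f"sector{i}_color")
            if color is None or (isinstance(color, float) and np.isnan(color)):
                continue
            sectors.append(
                SectorPhenotype(
                    color=str(color),
                    hyg_resistant=bool(row[f"sector{i}_hyg"]),
                    nat_resistant=bool(row[f"sector{i}_nat"]),
                )
            )
        outcome = row.get("generating_outcome")
        if isinstance(outcome, float) and np.isnan(outcome):
            outcome = None
        records.append(
            ColonyRecord(
                replicate_id=int(row["replicate_id"]),
                strain=str(row["strain"]),
                color=str(row["color"]),
                sectors=tuple(sectors),
                ura_met_growth=bool(row["ura_met_growth"]),
                generating_outcome=outcome,
            )
        )
    return records


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def params_from_config(cfg: dict):
    """(OpticsParams, MotorParams, RPAGenParams) from a config mapping."""
    optics = OpticsParams(**cfg.get("optics", {}))
    motor = MotorParams(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.get("motor", {}).items()
        }
    )
    rpa = RPAGenParams(**cfg.get("rpa", {})) if "rpa" in cfg else RPAGenParams()
    return optics, motor, rpa
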