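"""End-to-end orchestration: channel files / signals -> feature table.

Mirrors the full preprocessing chain: 60-s segmentation of both channels,
PPG band-pass + peak detection + PP validation + segment acceptance, EDA
upsampling + Gaussian smoothing + SCR detection, then feature assembly.
Per-stage segment counts are logged at INFO, so the raw -> accepted
accounting of a session is always visible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import eda as eda_mod
from . import ppg as ppg_mod
from .features import assemble_feature_table
from .io import ProtocolSchedule, SampledSignal, read_e4_channel, schedule_from_dict

__all__ = ["PipelineResult", "process_recording", "process_files"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineResult:
    """Feature table plus the per-stage accounting of one session."""

    table: pd.DataFrame
    n_segments_raw: int
    n_segments_accepted: int
    accepted_window_indices: tuple[int, ...]


def process_recording(
    bvp: SampledSignal,
    eda: SampledSignal,
    schedule: ProtocolSchedule,
    subject_id: str = "S00",
    window_s: float = 60.0,
    max_abnormal_fraction: float = 0.15,
    fraction_mode: str = "count",
) -> PipelineResult:
    """Run the full preprocessing + feature chain on one session."""
    bvp_segments = ppg_mod.segment_signal(bvp, schedule, window_s, subject_id)
    eda64 = eda_mod.upsample_eda(eda, target_rate_hz=bvp.rate_hz)
    eda_smooth = eda_mod.gaussian_smooth(eda64)
    eda_segments = ppg_mod.segment_signal(eda_smooth, schedule, window_s, subject_id)
    if len(bvp_segments) != len(eda_segments):
        raise ValueError("BVP and EDA segmentations disagree; check durations")
    logger.info("%s: %d raw segments per channel", subject_id, len(bvp_segments))

    kept_bvp, kept_pp, kept_scr, kept_eda = [], [], [], []
    for bvp_seg, eda_seg in zip(bvp_segments, eda_segments):
        filtered = ppg_mod.bandpass_filter_ppg(bvp_seg)
        peaks = ppg_mod.detect_pulse_peaks(filtered)
        raw = ppg_mod.compute_pp_intervals(peaks)
        pp = ppg_mod.validate_pp_intervals(raw, peak_times_s=peaks)
        if not ppg_mod.accept_ppg_segment(pp, max_abnormal_fraction, fraction_mode):
            continue
        scrs = eda_mod.detect_scrs(
            SampledSignal(eda_seg.values, eda_seg.rate_hz, eda.start_utc_s)
        )
        kept_bvp.append(filtered)
        kept_pp.append(pp)
        kept_scr.append(scrs)
        kept_eda.append(eda_seg)
    logger.info(
        "%s: %d/%d segments accepted by the abnormal-interval rule",
        subject_id, len(kept_bvp), len(bvp_segments),
    )
    table = assemble_feature_table(kept_bvp, kept_pp, kept_scr, kept_eda)
    return PipelineResult(
        table=table,
        n_segments_raw=len(bvp_segments),
        n_segments_accepted=len(kept_bvp),
        accepted_window_indices=tuple(s.window_index for s in kept_bvp),
    )


def process_files(
    bvp_path: str | Path,
    eda_path: str | Path,
    schedule_path: str | Path,
    subject_id: str = "S00",
    **kwargs,
) -> PipelineResult:
    """File-based entry point: E4-dialect channel CSVs + JSON schedule."""
    bvp = read_e4_channel(bvp_path, expected_rate_hz=64)
    eda = read_e4_channel(eda_path, expected_rate_hz=4)
    schedule = schedule_from_dict(json.loads(Path(schedule_path).read_text()))
    return process_recording(bvp, eda, schedule, subject_id=subject_id, **kwargs)
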