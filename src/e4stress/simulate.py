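"""Synthetic wrist PPG/EDA recordings with known ground truth.

The generator emulates the physiological contrast the acquisition protocol
is designed to elicit: during task (stress) intervals mean pulse rate rises
and beat-to-beat variability narrows, while skin-conductance responses
(SCRs) fire more often. Signals are rendered in the same shapes the real
device exports — a 64-Hz pulse-train BVP and a 4-Hz tonic-plus-phasic EDA —
with controllable motion-artifact corruption, and every quantity the
downstream pipeline estimates (per-segment mean HR, PP jitter, SCR events,
artifact positions) is recorded as ground truth.

Defaults are the study conditions: rest HR 65 bpm with +15 bpm under
stress, PP jitter 40 ms at rest vs 25 ms under stress, SCR rates 2/min at
rest vs 6/min under stress with amplitudes 0.1–0.8 µS on a 2 µS tonic
level, and one motion artifact per minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .io import ProtocolSchedule, SampledSignal, schedule_to_dict, write_e4_channel

__all__ = [
    "SubjectModel",
    "GroundTruth",
    "generate_ppg",
    "generate_eda",
    "generate_feature_table",
    "write_recording",
]


@dataclass(frozen=True)
class SubjectModel:
    """Physiological parameters of one simulated subject."""

    rest_hr_bpm: float = 65.0
    stress_hr_delta_bpm: float = 15.0
    hr_sd_rest_ms: float = 40.0  # PP-interval jitter SD at rest
    hr_sd_stress_ms: float = 25.0  # sympathetic activation narrows variability
    scr_rate_rest_per_min: float = 2.0
    scr_rate_stress_per_min: float = 6.0
    scr_amp_range_uS: tuple[float, float] = (0.1, 0.8)
    tonic_uS: float = 2.0
    artifact_rate_per_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.scr_rate_rest_per_min, self.scr_rate_stress_per_min) < 0:
            raise ValueError("SCR rates must be >= 0")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact rate must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator injected, aligned with the 60-s window tiling.

    ``per_window`` has one row per window the pipeline will cut (same
    tiling rule: windows inside schedule intervals, boundary-straddlers
    dropped) with the true per-window mean HR / PP SD / artifact and SCR
    counts and the label. ``scr_events`` lists every injected SCR.
    """

    per_window: pd.DataFrame
    beat_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    scr_events: tuple[dict, ...] = ()


def _window_starts(schedule: ProtocolSchedule, window_s: float = 60.0):
    starts = []
    for iv in schedule:
        t = iv.start_s
        while t + window_s <= iv.end_s + 1e-9:
            starts.append((t, iv.label))
            t += window_s
    return starts


def _pulse_template(t: np.ndarray, beat_t: float) -> np.ndarray:
    # systolic peak + smaller, later dicrotic bump; the bump is <= 0.4 of
    # the main peak so the 0.4-s minimum-distance rule suppresses it
    main = np.exp(-0.5 * ((t - beat_t) / 0.045) ** 2)
    dicrotic = 0.35 * np.exp(-0.5 * ((t - beat_t - 0.28) / 0.08) ** 2)
    return main + dicrotic


def generate_ppg(
    subject: SubjectModel,
    schedule: ProtocolSchedule,
    rate_hz: float = 64.0,
    window_s: float = 60.0,
    start_utc_s: float = 1_600_000_000.0,
) -> tuple[SampledSignal, GroundTruth]:
    """Pulse-train BVP over the whole schedule, plus per-window truth.

    Beat times are drawn sequentially: PP = 60000/HR(label at current time)
    plus Gaussian jitter, truncated to > 300 ms. Each beat is rendered as a
    fixed two-Gaussian pulse; baseline wander below 0.5 Hz, white noise,
    and high-amplitude motion-artifact transients are added on top.
    """
    rng = np.random.default_rng(subject.seed)
    total = schedule.end_s
    beats: list[float] = []
    t = float(rng.uniform(0.1, 0.6))
    while t < total:
        label = schedule.label_at(t) or 0
        hr = subject.rest_hr_bpm + subject.stress_hr_delta_bpm * label
        sd = subject.hr_sd_stress_ms if label else subject.hr_sd_rest_ms
        pp_ms = rng.normal(60000.0 / hr, sd)
        while pp_ms <= 300.0:
            pp_ms = rng.normal(60000.0 / hr, sd)
        beats.append(t)
        t += pp_ms / 1000.0
    beat_times = np.array(beats)

    n = int(round(total * rate_hz))
    times = np.arange(n) / rate_hz
    x = np.zeros(n)
    half = int(round(0.6 * rate_hz))
    for bt in beat_times:
        c = int(round(bt * rate_hz))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += _pulse_template(times[lo:hi], bt)

    # baseline wander (below the 0.5 Hz passband edge) + sensor noise
    x += 0.15 * np.sin(2 * np.pi * 0.18 * times + rng.uniform(0, 2 * np.pi))
    x += 0.10 * np.sin(2 * np.pi * 0.31 * times + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0, 0.03, n)

    # motion artifacts: high-amplitude oscillatory bursts inside the 0.5-5 Hz
    # passband, so they both spawn spurious peaks and mask true beats
    n_art = rng.poisson(subject.artifact_rate_per_min * total / 60.0)
    artifact_times = np.sort(rng.uniform(0, total, n_art))
    for at in artifact_times:
        amp = rng.uniform(2.0, 4.0)
        freq = rng.uniform(3.0, 5.0)
        width = rng.uniform(0.4, 1.2)
        c = int(round(at * rate_hz))
        w = int(round(3 * width * rate_hz))
        lo, hi = max(0, c - w), min(n, c + w + 1)
        tt = times[lo:hi] - at
        x[lo:hi] += amp * np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi)) * np.exp(
            -0.5 * (tt / width) ** 2
        )

    pp_all = np.diff(beat_times) * 1000.0
    rows = []
    for start, label in _window_starts(schedule, window_s):
        end = start + window_s
        in_win = (beat_times[:-1] >= start) & (beat_times[1:] <= end)
        pp_win = pp_all[in_win]
        rows.append(
            {
                "start_s": start,
                "label": label,
                "true_mean_hr_bpm": float(np.mean(60000.0 / pp_win)) if pp_win.size else np.nan,
                "true_pp_sd_ms": float(np.std(pp_win, ddof=1)) if pp_win.size > 1 else np.nan,
                "n_artifacts": int(np.sum((artifact_times >= start) & (artifact_times < end))),
            }
        )
    truth = GroundTruth(
        per_window=pd.DataFrame(rows),
        beat_times_s=beat_times,
        artifact_times_s=artifact_times,
    )
    signal = SampledSignal(values=x, rate_hz=rate_hz, start_utc_s=start_utc_s)
    return signal, truth


def _scr_shape(t: np.ndarray, onset: float, amp: float, rise_s: float, decay_s: float) -> np.ndarray:
    # bi-exponential transient normalized to peak at `amp`
    dt = np.clip(t - onset, 0.0, None)
    shape = np.exp(-dt / decay_s) - np.exp(-dt / rise_s)
    shape[t < onset] = 0.0
    peak_t = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-peak_t / decay_s) - np.exp(-peak_t / rise_s)
    return amp * shape / peak


def generate_eda(
    subject: SubjectModel,
    schedule: ProtocolSchedule,
    rate_hz: float = 4.0,
    window_s: float = 60.0,
    start_utc_s: float = 1_600_000_000.0,
    min_event_spacing_s: float = 6.0,
    noise_sd_uS: float = 0.003,
) -> tuple[SampledSignal, GroundTruth]:
    """Tonic-plus-phasic EDA with SCR events at label-dependent Poisson rates.

    Each SCR is a fast-rise (1–3 s) / slow-decay (4–10 s) transient with
    amplitude uniform over ``scr_amp_range_uS``. Inter-event gaps are
    redrawn until they exceed ``min_event_spacing_s`` so every injected
    event is individually identifiable ground truth. A slow tonic drift and
    measurement noise are added.
    """
    # independent stream, offset so PPG and EDA noise are uncorrelated
    rng = np.random.default_rng(subject.seed + 104729)
    total = schedule.end_s
    n = int(round(total * rate_hz))
    times = np.arange(n) / rate_hz

    events: list[dict] = []
    t = 0.0
    while True:
        label = schedule.label_at(t)
        rate = (
            subject.scr_rate_stress_per_min if label else subject.scr_rate_rest_per_min
        ) / 60.0
        if rate <= 0:
            # jump to the next interval with a nonzero rate
            nxt = [iv.start_s for iv in schedule if iv.start_s > t]
            if not nxt:
                break
            t = min(nxt)
            continue
        # shifted-exponential gaps: mean is exactly 1/rate while every gap
        # is >= min_event_spacing_s, so nominal rates are honored and
        # injected events stay individually identifiable
        excess = max(1.0 / rate - min_event_spacing_s, 1e-6)
        gap = min_event_spacing_s + rng.exponential(excess)
        t += gap
        if t >= total - 15.0:  # leave room for the transient to develop
            break
        if schedule.label_at(t) is None:
            continue
        events.append(
            {
                "onset_s": float(t),
                "amplitude_uS": float(rng.uniform(*subject.scr_amp_range_uS)),
                "rise_s": float(rng.uniform(1.0, 3.0)),
                "decay_s": float(rng.uniform(4.0, 10.0)),
                "label": int(schedule.label_at(t) or 0),
            }
        )

    x = np.full(n, subject.tonic_uS)
    x += 0.03 * np.sin(2 * np.pi * times / max(total, 1.0) + rng.uniform(0, 2 * np.pi))
    x += 0.015 * np.sin(2 * np.pi * 0.004 * times + rng.uniform(0, 2 * np.pi))
    for ev in events:
        x += _scr_shape(times, ev["onset_s"], ev["amplitude_uS"], ev["rise_s"], ev["decay_s"])
    x += rng.normal(0, noise_sd_uS, n)

    rows = []
    onsets = np.array([ev["onset_s"] for ev in events])
    for start, label in _window_starts(schedule, window_s):
        end = start + window_s
        rows.append(
            {
                "start_s": start,
                "label": label,
                "n_scr_true": int(np.sum((onsets >= start) & (onsets < end))) if onsets.size else 0,
            }
        )
    truth = GroundTruth(per_window=pd.DataFrame(rows), scr_events=tuple(events))
    signal = SampledSignal(values=x, rate_hz=rate_hz, start_utc_s=start_utc_s)
    return signal, truth


def generate_feature_table(
    n_rest: int = 320,
    n_stress: int = 523,
    separation: float = 1.0,
    n_informative: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a 27-column feature table directly, bypassing the signal chain.

    The first ``n_informative`` columns (in the canonical feature order) are
    class-shifted Gaussians with |Δμ| = separation·σ; the remaining columns
    are label-independent standard normals. The default 320:523 rest:stress
    imbalance mirrors the segment counts of the wearable study protocol.
    """
    if not 0 <= n_informative <= len(FEATURE_COLUMNS):
        raise ValueError("n_informative must be within the 27-column set")
    rng = np.random.default_rng(seed)
    y = np.array([0] * n_rest + [1] * n_stress)
    n = y.size
    X = rng.standard_normal((n, len(FEATURE_COLUMNS)))
    X[:, :n_informative] += separation * y[:, None]
    table = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    table["label"] = y
    table["subject"] = "SIM"
    table["window_index"] = np.arange(n)
    return table


def write_recording(
    out_dir: str | Path,
    subject: SubjectModel,
    schedule: ProtocolSchedule,
) -> dict[str, Path]:
    """Write one full synthetic session as files: E4-dialect BVP.csv and
    EDA.csv, the schedule (JSON), and the ground truth (JSON).

    Returns the paths, so the whole pipeline can be run from files exactly
    as on a real export.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bvp, bvp_truth = generate_ppg(subject, schedule)
    eda, eda_truth = generate_eda(subject, schedule)
    paths = {
        "bvp": out_dir / "BVP.csv",
        "eda": out_dir / "EDA.csv",
        "schedule": out_dir / "schedule.json",
        "truth": out_dir / "truth.json",
    }
    write_e4_channel(bvp, paths["bvp"])
    write_e4_channel(eda, paths["eda"])
    paths["schedule"].write_text(json.dumps(schedule_to_dict(schedule), indent=1))
    truth = {
        "ppg_per_window": bvp_truth.per_window.to_dict(orient="records"),
        "eda_per_window": eda_truth.per_window.to_dict(orient="records"),
        "scr_events": list(eda_truth.scr_events),
        "artifact_times_s": bvp_truth.artifact_times_s.tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def subject_with(subject: SubjectModel, **changes) -> SubjectModel:
    """Convenience: a copy of ``subject`` with fields replaced."""
    return replace(subject, **changes)
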