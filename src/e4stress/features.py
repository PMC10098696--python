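"""The 27-feature vector per accepted segment, and z-score standardization.

Sixteen features derive from the PPG chain — four time-domain
pulse-rate-variability (PRV) statistics of the validated PP series, the
high-frequency (0.15–0.40 Hz) tachogram power, the Poincaré SD2, and ten
statistics of the filtered BVP waveform and its first/second differences —
six are statistics of the smoothed EDA trace, and five summarize the
detected SCR events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .eda import SCREventList
from .ppg import LabeledSegment, PPSeries

__all__ = [
    "FEATURE_COLUMNS",
    "PPG_COLUMNS",
    "EDA_COLUMNS",
    "SCR_COLUMNS",
    "prv_time_features",
    "prv_hf_power",
    "prv_sd2",
    "signal_statistics",
    "scr_features",
    "assemble_feature_table",
    "zscore_standardize",
    "apply_standardization",
    "StandardizationParams",
]

logger = logging.getLogger(__name__)

PPG_COLUMNS: tuple[str, ...] = (
    "Mean_PP", "std_PP", "M_HR", "std_HR",  # PRV time domain
    "HF",  # PRV frequency domain
    "SD2",  # PRV non-linear
    "Mean_BVP", "Median_BVP", "Mode_BVP", "Min_BVP", "Max_BVP", "Std_BVP",
    "M_d1", "Std_d1", "M_d2", "Std_d2",
)
EDA_COLUMNS: tuple[str, ...] = (
    "Mean_EDA", "Median_EDA", "Mode_EDA", "Max_EDA", "Min_EDA", "Std_EDA",
)
SCR_COLUMNS: tuple[str, ...] = ("M_D", "M_Amp", "M_RT", "N_PEAKS", "M_SCR")

#: The fixed, ordered 27-column feature set.
FEATURE_COLUMNS: tuple[str, ...] = PPG_COLUMNS + EDA_COLUMNS + SCR_COLUMNS

PROVENANCE_COLUMNS: tuple[str, ...] = ("subject", "window_index")


def _sd(x: np.ndarray) -> float:
    """Sample standard deviation (n − 1 denominator)."""
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def prv_time_features(pp: PPSeries) -> tuple[float, float, float, float]:
    """(Mean_PP, std_PP, M_HR, std_HR) from the retained PP series.

    The heart-rate series is 60000 / PP(ms) per beat; means are arithmetic,
    standard deviations use the n − 1 denominator.
    """
    ints = pp.pp_intervals_ms
    if ints.size < 2:
        raise ValueError("need at least 2 retained intervals")
    hr = 60000.0 / ints
    return float(ints.mean()), _sd(ints), float(hr.mean()), _sd(hr)


def prv_hf_power(
    pp: PPSeries,
    band: tuple[float, float] = (0.15, 0.40),
    resample_hz: float = 4.0,
    welch_segment_s: float = 32.0,
) -> float:
    """High-frequency tachogram power (ms²) in the 0.15–0.40 Hz band.

    The unevenly sampled tachogram (PP interval against cumulative beat
    time) is cubic-interpolated onto a uniform 4-Hz grid, mean-removed, its
    PSD estimated by Welch's method (32-s segments, 50% overlap), and the
    PSD integrated over the band.
    """
    ints = pp.pp_intervals_ms
    if ints.size < 8:
        raise ValueError("need at least 8 retained intervals for HF power")
    beat_times = np.cumsum(ints) / 1000.0  # s, time of each interval's end
    spline = CubicSpline(beat_times, ints)
    t = np.arange(beat_times[0], beat_times[-1], 1.0 / resample_hz)
    x = spline(t) - spline(t).mean()
    nperseg = min(x.size, int(welch_segment_s * resample_hz))
    freqs, psd = sps.welch(x, fs=resample_hz, nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def prv_sd2(pp: PPSeries, coefficient: float = 1.0 / np.sqrt(2.0)) -> float:
    """Poincaré major-axis dispersion: coefficient × SD of successive PP sums.

    SD2 = (1/√2) · std(PP_i + PP_{i+1}); pure beat-to-beat alternation
    cancels in the sums, so SD2 isolates the long-term variability.
    """
    ints = pp.pp_intervals_ms
    if ints.size < 3:
        raise ValueError("need at least 3 retained intervals")
    return coefficient * _sd(ints[:-1] + ints[1:])


def _mode(x: np.ndarray, decimals: int = 3) -> float:
    """Most frequent value after rounding; ties broken by the smallest value."""
    rounded = np.round(np.asarray(x, dtype=float), decimals)
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[np.argmax(counts)])  # unique() sorts, argmax takes first


def signal_statistics(
    segment: LabeledSegment, channel: str, mode_decimals: int = 3
) -> dict[str, float]:
    """Per-channel waveform statistics of a filtered/smoothed segment.

    ``channel`` is ``"BVP"`` (adds first/second-difference statistics) or
    ``"EDA"``. The median follows the middle-order-statistic convention
    (average of the two middle values for even n); the mode is computed after
    rounding to ``mode_decimals`` decimals, ties broken by the smallest
    value. Difference statistics are raw per-sample differences of the
    filtered waveform.
    """
    x = np.asarray(segment.values, dtype=float)
    stats = {
        f"Mean_{channel}": float(x.mean()),
        f"Median_{channel}": float(np.median(x)),
        f"Mode_{channel}": _mode(x, mode_decimals),
        f"Min_{channel}": float(x.min()),
        f"Max_{channel}": float(x.max()),
        f"Std_{channel}": _sd(x),
    }
    if channel == "BVP":
        d1 = np.diff(x)
        d2 = np.diff(x, 2)
        stats.update(
            M_d1=float(d1.mean()), Std_d1=_sd(d1),
            M_d2=float(d2.mean()), Std_d2=_sd(d2),
        )
    return stats


def scr_features(
    events: SCREventList, segment_duration_s: float | None = None
) -> dict[str, float]:
    """SCR summary features: mean duration/amplitude/rise time, count, driver mean.

    With no events the three means are zero-filled (rest segments
    legitimately have few SCRs); M_SCR is the mean of the driver (phasic)
    trace over the whole segment regardless.
    """
    n = len(events)
    if n > 0:
        m_d = float(np.mean([e.duration_s for e in events]))
        m_amp = float(np.mean([e.amplitude_uS for e in events]))
        m_rt = float(np.mean([e.rise_time_s for e in events]))
    else:
        m_d = m_amp = m_rt = 0.0
    m_scr = float(events.phasic_trace.mean()) if events.phasic_trace.size else 0.0
    return {"M_D": m_d, "M_Amp": m_amp, "M_RT": m_rt, "N_PEAKS": float(n), "M_SCR": m_scr}


def segment_features(
    bvp_segment: LabeledSegment,
    pp: PPSeries,
    eda_segment: LabeledSegment,
    scrs: SCREventList,
) -> dict[str, float] | None:
    """All 27 features of one accepted segment, or None if a PRV feature
    cannot be computed (too few retained intervals)."""
    try:
        mean_pp, std_pp, m_hr, std_hr = prv_time_features(pp)
        hf = prv_hf_power(pp)
        sd2 = prv_sd2(pp)
    except ValueError:
        return None
    row: dict[str, float] = {
        "Mean_PP": mean_pp, "std_PP": std_pp, "M_HR": m_hr, "std_HR": std_hr,
        "HF": hf, "SD2": sd2,
    }
    row.update(signal_statistics(bvp_segment, "BVP"))
    row.update(signal_statistics(eda_segment, "EDA"))
    row.update(scr_features(scrs, eda_segment.duration_s))
    return row


def assemble_feature_table(
    segments: list[LabeledSegment],
    pp_series: list[PPSeries],
    scr_lists: list[SCREventList],
    eda_segments: list[LabeledSegment],
) -> pd.DataFrame:
    """One 27-feature row per accepted segment, plus label and provenance.

    Inputs are parallel lists over the accepted segments only. Rows on which
    any feature is invalid (non-finite, or too few retained intervals) are
    dropped and logged; an empty result is an error.
    """
    if not len(segments) == len(pp_series) == len(scr_lists) == len(eda_segments):
        raise ValueError("inputs must be parallel lists over accepted segments")
    rows, labels, subjects, windows = [], [], [], []
    n_dropped = 0
    for seg, pp, scrs, eda_seg in zip(segments, pp_series, scr_lists, eda_segments):
        row = segment_features(seg, pp, eda_seg, scrs)
        if row is None or not all(np.isfinite(list(row.values()))):
            n_dropped += 1
            logger.info(
                "dropping segment %s/%d: invalid feature(s)",
                seg.subject_id, seg.window_index,
            )
            continue
        rows.append([row[c] for c in FEATURE_COLUMNS])
        labels.append(seg.label)
        subjects.append(seg.subject_id)
        windows.append(seg.window_index)
    if not rows:
        raise ValueError("no segment produced a valid feature row")
    if n_dropped:
        logger.info("feature table: %d rows kept, %d dropped", len(rows), n_dropped)
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    table["label"] = labels
    table["subject"] = subjects
    table["window_index"] = windows
    return table


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column mean/SD fitted on a training subset, reusable on held-out rows."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: tuple[str, ...] = ()


def zscore_standardize(
    table: pd.DataFrame,
    fit_rows: np.ndarray | None = None,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score each feature column: (x − mean_fit) / sd_fit.

    ``fit_rows`` (boolean mask or index array) selects the rows on which the
    transform is fitted — all rows by default. Zero-variance columns are
    flagged, left unscaled (mean-centered only would still be degenerate, so
    they are passed through), and reported in the returned parameters.
    """
    cols = [c for c in columns if c in table.columns]
    fit = table.loc[table.index if fit_rows is None else table.index[fit_rows], cols]
    if len(fit) == 0:
        raise ValueError("fit_rows selects no rows")
    mean = fit.mean()
    sd = fit.std(ddof=1)
    zero_var = tuple(sd.index[(sd == 0) | sd.isna()])
    if zero_var:
        logger.warning("zero-variance columns left unscaled: %s", zero_var)
    params = StandardizationParams(mean=mean, sd=sd, zero_variance=zero_var)
    return apply_standardization(table, params), params


def apply_standardization(
    table: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    """Apply previously fitted z-score parameters (e.g. to held-out rows)."""
    out = table.copy()
    for c in params.mean.index:
        if c in params.zero_variance:
            continue
        out[c] = (out[c] - params.mean[c]) / params.sd[c]
    return out
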