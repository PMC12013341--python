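"""Heart-rate-variability pipeline for 1 Hz wearable heart-rate exports.

The chain converts sampled heart rate (BPM) to an RR tachogram with the
60000/HR formula, linearly interpolates short gaps (participants with 20%
or more missing samples are excluded), and computes time-domain (SDNN,
RMSSD) and frequency-domain (VLF/LF/HF, LF/HF ratio) metrics over the
baseline and the session windows.

Each 1 Hz HR sample is treated as one tachogram point: the spectral axis is
the cumulative-RR time implied by the intervals themselves, resampled
uniformly before Welch estimation, which is the standard tachogram
treatment for frequency-domain HRV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .session import SessionTimeline

__all__ = [
    "HRV_BANDS",
    "HeartRateSeries",
    "RRSeries",
    "ExclusionRecord",
    "HRVWindowMetrics",
    "read_hr_csv",
    "write_hr_csv",
    "hr_to_rr",
    "interpolate_or_exclude",
    "time_domain",
    "frequency_domain",
    "windowed_metrics",
    "metrics_frame",
]

# Task Force of the European Society of Cardiology / NASPE band edges (Hz).
HRV_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: Physiologically plausible heart-rate range (BPM); values outside are rejected.
HR_RANGE = (20.0, 250.0)

#: Uniform resampling rate of the tachogram before Welch estimation (Hz).
TACHOGRAM_FS = 4.0

#: Welch segment cap for the tachogram, in seconds of resampled signal.
WELCH_MAX_SEGMENT_S = 256.0


@dataclass
class HeartRateSeries:
    """Timestamped heart-rate samples; missing samples are NaN."""

    participant_id: str
    t: np.ndarray  # seconds from recording start
    hr: np.ndarray  # BPM, NaN where the export had no value
    sample_rate: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.t.shape != self.hr.shape:
            raise ValueError("t and hr must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        present = self.hr[~np.isnan(self.hr)]
        if present.size and (present.min() <= HR_RANGE[0] or present.max() >= HR_RANGE[1]):
            raise ValueError(f"heart rate outside plausible range {HR_RANGE}")

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.hr).mean()) if self.hr.size else 0.0


@dataclass
class RRSeries:
    """RR-interval tachogram (ms) on the original sample timestamps.

    ``interpolated`` flags intervals filled by :func:`interpolate_or_exclude`
    rather than observed directly.
    """

    participant_id: str
    t: np.ndarray  # seconds, sample timestamps carried from the HR series
    rr: np.ndarray  # ms, NaN while gaps are still unfilled
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.rr.shape, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.rr).mean()) if self.rr.size else 0.0


@dataclass(frozen=True)
class ExclusionRecord:
    """A participant dropped by a screening rule, with the measured fraction."""

    participant_id: str
    reason: str
    fraction: float


@dataclass
class HRVWindowMetrics:
    window_label: str
    start: float
    end: float
    sdnn: float
    rmssd: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float
    truncated: bool = False
    vlf_reliable: bool = True


# ---------------------------------------------------------------------------
# I/O — the delimited dialect emitted by the synthetic writer and accepted
# here: two columns, elapsed seconds (or ISO-8601 timestamps) and HR in BPM;
# blank HR cells are missing samples.
# ---------------------------------------------------------------------------

def write_hr_csv(series: HeartRateSeries, path) -> None:
    df = pd.DataFrame({"time_s": series.t, "hr_bpm": series.hr})
    df.to_csv(path, index=False, float_format="%.6f")


def read_hr_csv(path, participant_id: str | None = None, sample_rate: float = 1.0) -> HeartRateSeries:
    """Read a Polar-Flow-style HR export: ``time_s`` (or ISO ``time``) + ``hr_bpm``."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" in cols:
        t = df[cols["time_s"]].to_numpy(dtype=float)
    elif "time" in cols:
        stamps = pd.to_datetime(df[cols["time"]])
        t = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()
    else:
        raise ValueError(f"no time column ('time_s' or 'time') in {path}")
    if "hr_bpm" not in cols:
        raise ValueError(f"no 'hr_bpm' column in {path}")
    hr = pd.to_numeric(df[cols["hr_bpm"]], errors="coerce").to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"non-monotone timestamps in {path}")
    pid = participant_id if participant_id is not None else str(getattr(path, "stem", path))
    return HeartRateSeries(pid, t, hr, sample_rate)


# ---------------------------------------------------------------------------
# HR -> RR tachogram
# ---------------------------------------------------------------------------

def hr_to_rr(series: HeartRateSeries) -> RRSeries:
    """RR interval per sample via 60000/HR (BPM -> ms); gaps stay NaN."""
    hr = series.hr
    present = ~np.isnan(hr)
    if np.any(hr[present] <= 0):
        raise ValueError("non-positive heart rate")
    rr = np.full_like(hr, np.nan)
    rr[present] = 60000.0 / hr[present]
    return RRSeries(series.participant_id, series.t, rr)


def interpolate_or_exclude(
    rr: RRSeries, max_missing_frac: float = 0.20
) -> RRSeries | ExclusionRecord:
    """Fill gaps by forward linear interpolation, or exclude the participant.

    Series with a missing fraction below ``max_missing_frac`` have gaps
    linearly interpolated between the nearest present neighbours (leading and
    trailing gaps take the nearest present value); series at or above the
    threshold produce an :class:`ExclusionRecord`.
    """
    frac = rr.missing_fraction
    if frac >= max_missing_frac or frac == 1.0:
        return ExclusionRecord(rr.participant_id, "missing_rr", frac)
    gaps = np.isnan(rr.rr)
    if not gaps.any():
        return RRSeries(rr.participant_id, rr.t, rr.rr.copy(), gaps)
    idx = np.arange(rr.rr.size)
    # np.interp clamps to the edge values, which fills leading/trailing gaps
    # with the nearest observation.
    filled = rr.rr.copy()
    filled[gaps] = np.interp(idx[gaps], idx[~gaps], rr.rr[~gaps])
    return RRSeries(rr.participant_id, rr.t, filled, gaps)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def time_domain(rr: np.ndarray) -> tuple[float, float]:
    """(SDNN, RMSSD) in ms over one window of RR intervals.

    SDNN is the sample standard deviation (N-1 denominator); RMSSD averages
    the squared successive differences over the N-1 diffs. Windows with
    fewer than two intervals yield NaN.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        return float("nan"), float("nan")
    sdnn = float(np.std(rr, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    return sdnn, rmssd


def frequency_domain(
    rr: np.ndarray,
    resample_fs: float = TACHOGRAM_FS,
    bands: dict[str, tuple[float, float]] = HRV_BANDS,
) -> dict[str, float]:
    """Band powers (ms^2) of the RR tachogram via cubic resampling + Welch.

    The cumulative-time axis is built from the intervals themselves, the
    tachogram is resampled uniformly at ``resample_fs`` by cubic spline,
    and band powers are trapezoid integrals of the Welch PSD over the
    Task Force bands; ``lf_hf`` is their ratio (NaN when HF is zero).
    """
    rr = np.asarray(rr, dtype=float)
    out = {k: float("nan") for k in bands}
    out["lf_hf"] = float("nan")
    if rr.size < 4 or np.isnan(rr).any():
        return out
    t = np.cumsum(rr) / 1000.0  # s, beat-time axis
    t = t - t[0]
    if t[-1] <= 0:
        return out
    n_uni = int(np.floor(t[-1] * resample_fs)) + 1
    if n_uni < 16:
        return out
    tu = np.arange(n_uni) / resample_fs
    x = CubicSpline(t, rr)(tu)
    x = x - x.mean()
    nperseg = min(n_uni, int(WELCH_MAX_SEGMENT_S * resample_fs))
    freqs, psd = signal.welch(
        x, fs=resample_fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(psd[m], freqs[m])) if m.sum() >= 2 else 0.0
    out["lf_hf"] = out["lf"] / out["hf"] if out["hf"] > 0 else float("nan")
    return out


def _window_metrics(rr: RRSeries, label: str, start: float, end: float) -> HRVWindowMetrics:
    m = (rr.t >= start) & (rr.t < end)
    vals = rr.rr[m]
    covered = vals.size >= (end - start) * 0.5  # flag windows under half-covered
    sdnn, rmssd = time_domain(vals)
    fd = frequency_domain(vals)
    return HRVWindowMetrics(
        window_label=label, start=start, end=end,
        sdnn=sdnn, rmssd=rmssd,
        vlf=fd["vlf"], lf=fd["lf"], hf=fd["hf"], lf_hf=fd["lf_hf"],
        truncated=not covered,
        vlf_reliable=(end - start) >= 300.0,
    )


def windowed_metrics(
    rr: RRSeries,
    timeline: SessionTimeline,
    sub_window_s: float = 300.0,
    minute_series: bool = True,
) -> list[HRVWindowMetrics]:
    """Metrics for the baseline, each 5-min sub-window and whole section,
    plus an optional 1-min-resolution series per section.

    VLF on windows shorter than 5 min is computed but flagged unreliable:
    the band's longest period exceeds such windows.
    """
    out: list[HRVWindowMetrics] = []
    out.append(_window_metrics(rr, "baseline", timeline.baseline_start, timeline.baseline_end))
    for sec in timeline.sections:
        n_sub = int(np.ceil(sec.dur / sub_window_s))
        for i in range(n_sub):
            w0 = sec.start + i * sub_window_s
            w1 = min(w0 + sub_window_s, sec.end)
            lo_min = int(i * sub_window_s // 60)
            hi_min = int(round((w1 - sec.start) / 60))
            out.append(_window_metrics(rr, f"{sec.label}/{lo_min}-{hi_min}", w0, w1))
        out.append(_window_metrics(rr, f"{sec.label}/whole", sec.start, sec.end))
        if minute_series:
            n_min = int(sec.dur // 60)
            for i in range(n_min):
                w0 = sec.start + i * 60.0
                out.append(_window_metrics(rr, f"{sec.label}/min{i:02d}", w0, w0 + 60.0))
    return out


def metrics_frame(
    metrics: list[HRVWindowMetrics], participant_id: str, session: str = "focus"
) -> pd.DataFrame:
    """Tidy long table: participant, session, window, metric, value."""
    rows = []
    for m in metrics:
        for name in ("sdnn", "rmssd", "vlf", "lf", "hf", "lf_hf"):
            rows.append(
                {
                    "participant": participant_id,
                    "session": session,
                    "window": m.window_label,
                    "metric": name,
                    "value": getattr(m, name),
                    "truncated": m.truncated,
                }
            )
    return pd.DataFrame(rows)
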