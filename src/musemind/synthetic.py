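"""Synthetic cohort generator with known ground truth.

Emulates the three data streams of a music-mindfulness session study so
every downstream stage is testable without real recordings:

* 1 Hz heart-rate samples whose underlying RR series is a mean plus LF and
  HF sinusoids plus white noise, with a configurable fraction of missing
  samples (app exports drop samples when the Bluetooth link stutters);
* 5-channel, 128 Hz EEG built from per-band sinusoids at band centres over
  a 1/f (pink) background, with raised-cosine blink events on the frontal
  channels and optional hard-saturated segments;
* item-level survey responses with configurable pre-to-post shifts.

Each generator takes a single seed and returns the artifact together with
its ground truth (true RR, true band powers, the blink source), so oracle
tests can compare recovered quantities against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .eeg import BANDS, CHANNELS, EEGRecording
from .hrv import HeartRateSeries
from .psychometrics import SCALES, ScaleDefinition
from .session import SessionTimeline, default_timeline

__all__ = [
    "HRSimParams",
    "EEGSimParams",
    "SurveySimParams",
    "simulate_hr",
    "simulate_eeg",
    "simulate_surveys",
    "band_center",
]


def band_center(band: str) -> float:
    lo, hi = BANDS[band]
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class HRSimParams:
    """RR model: mean_rr + a_lf sin(2 pi f_lf t) + a_hf sin(2 pi f_hf t) + noise.

    Defaults place the oscillations at canonical LF (0.1 Hz) and HF
    (0.25 Hz, respiratory) frequencies with amplitudes typical of a resting
    adult tachogram.
    """

    mean_rr: float = 800.0  # ms (75 BPM)
    a_lf: float = 25.0  # ms
    f_lf: float = 0.1  # Hz
    a_hf: float = 15.0  # ms
    f_hf: float = 0.25  # Hz
    sigma_noise: float = 5.0  # ms
    missing_frac: float = 0.05
    sample_rate: float = 1.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.mean_rr <= self.a_lf + self.a_hf + 4 * self.sigma_noise:
            raise ValueError("mean_rr too small: RR could go non-positive")
        if self.f_lf >= self.f_hf:
            raise ValueError("require f_lf < f_hf")


def simulate_hr(
    params: HRSimParams, timeline: SessionTimeline | None = None, participant_id: str = "sim"
) -> tuple[HeartRateSeries, dict]:
    """One HR sample per 1/sample_rate s over the timeline; HR = 60000/RR.

    Exactly ``round(missing_frac * n)`` samples are replaced by missing
    markers at uniformly random positions. Returns the series plus ground
    truth (the noise-free-of-gaps true RR in ms and the missing index set).
    """
    timeline = timeline or default_timeline()
    rng = np.random.default_rng(params.seed)
    n = int(round(timeline.total_dur * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    rr = (
        params.mean_rr
        + params.a_lf * np.sin(2 * np.pi * params.f_lf * t)
        + params.a_hf * np.sin(2 * np.pi * params.f_hf * t)
        + params.sigma_noise * rng.standard_normal(n)
    )
    hr = 60000.0 / rr
    n_missing = int(round(params.missing_frac * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False)
    hr_obs = hr.copy()
    hr_obs[missing_idx] = np.nan
    series = HeartRateSeries(participant_id, t, hr_obs, params.sample_rate)
    truth = {"rr_true": rr, "missing_idx": np.sort(missing_idx), "t": t}
    return series, truth


def _default_band_amps() -> dict[str, dict[str, float]]:
    # Rough resting-headset amplitudes: posterior alpha dominant, frontal
    # delta/theta present, small beta/gamma everywhere (uV).
    base = {"delta": 4.0, "theta": 3.0, "alpha": 2.0, "beta": 1.5, "gamma": 0.8}
    amps = {ch: dict(base) for ch in CHANNELS}
    amps["Pz"]["alpha"] = 5.0
    amps["T7"]["alpha"] = amps["T8"]["alpha"] = 3.0
    return amps


@dataclass(frozen=True)
class EEGSimParams:
    """Per-channel band sinusoids + pink noise + blinks + saturation."""

    channels: tuple[str, ...] = CHANNELS
    fs: float = 128.0
    band_amps: Mapping[str, Mapping[str, float]] = field(default_factory=_default_band_amps)
    pink_exponent: float = 1.0
    pink_amp: float = 3.0  # uV RMS of the 1/f background; 0 disables it
    blink_rate: float = 12.0  # events/min
    blink_amp: float = 80.0  # uV
    blink_channels: tuple[str, ...] = ("AF3", "AF4")
    blink_width: float = 0.4  # s, raised-cosine kernel support
    saturation_segments: tuple[tuple[float, float], ...] = ()
    saturation_value: float = 200.0  # uV rail during saturated spans
    seed: int = 0

    def __post_init__(self) -> None:
        top = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * top:
            raise ValueError(f"fs must exceed twice the top band edge ({top} Hz)")
        if not set(self.blink_channels) <= set(self.channels):
            raise ValueError("blink_channels must be a subset of channels")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float) -> np.ndarray:
    """Spectrally shaped white noise: amplitude ~ f^(-exponent/2), unit-free RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _blink_kernel(fs: float, width: float) -> np.ndarray:
    k = int(round(width * fs))
    u = np.arange(k) / max(k - 1, 1)
    return 0.5 * (1 - np.cos(2 * np.pi * u))


def simulate_eeg(
    params: EEGSimParams, timeline: SessionTimeline | None = None, participant_id: str = "sim"
) -> tuple[EEGRecording, dict]:
    """Generate the recording plus ground truth (band powers, blink source).

    Each channel is the sum of one sinusoid per band (at the band centre,
    random phase, planted amplitude), pink noise, and — on blink channels —
    a Poisson train of raised-cosine blink deflections. Saturation segments
    hold every channel at a constant rail value and are flagged missing.
    True band-integrated sinusoid power is amplitude^2 / 2.
    """
    timeline = timeline or default_timeline()
    rng = np.random.default_rng(params.seed)
    n = int(round(timeline.total_dur * params.fs))
    t = np.arange(n) / params.fs
    n_ch = len(params.channels)
    data = np.zeros((n_ch, n))
    true_power: dict[str, dict[str, float]] = {}
    for i, ch in enumerate(params.channels):
        amps = params.band_amps.get(ch, {})
        true_power[ch] = {}
        for band in BANDS:
            a = float(amps.get(band, 0.0))
            true_power[ch][band] = a * a / 2.0
            if a:
                phase = rng.uniform(0, 2 * np.pi)
                data[i] += a * np.sin(2 * np.pi * band_center(band) * t + phase)
        if params.pink_amp > 0:
            data[i] += _pink_noise(rng, n, params.fs, params.pink_exponent, params.pink_amp)

    # Blink train: Poisson event count over the recording, uniform times.
    blink_source = np.zeros(n)
    n_events = rng.poisson(params.blink_rate * timeline.total_dur / 60.0)
    kernel = _blink_kernel(params.fs, params.blink_width)
    event_times = np.sort(rng.uniform(0, timeline.total_dur - params.blink_width, n_events))
    for et in event_times:
        i0 = int(round(et * params.fs))
        blink_source[i0 : i0 + kernel.size] += kernel[: n - i0]
    for ch in params.blink_channels:
        data[params.channels.index(ch)] += params.blink_amp * blink_source

    missing = np.zeros(n, dtype=bool)
    for start, end in params.saturation_segments:
        i0, i1 = int(round(start * params.fs)), int(round(end * params.fs))
        data[:, i0:i1] = params.saturation_value
        missing[i0:i1] = True

    rec = EEGRecording(participant_id, tuple(params.channels), params.fs, data, missing)
    truth = {
        "band_power": true_power,
        "blink_source": blink_source,
        "blink_times": event_times,
        "n_blinks": int(n_events),
    }
    return rec, truth


@dataclass(frozen=True)
class SurveySimParams:
    """Item-level response model: integer draws around a per-scale item mean.

    ``pre_mean`` and ``post_shift`` are in item units per scale (missing
    scales default to the scale midpoint and zero shift). Responses are
    clipped to each scale's printed range.
    """

    n_participants: int = 20
    pre_mean: Mapping[str, float] = field(default_factory=dict)
    post_shift: Mapping[str, float] = field(default_factory=dict)
    item_sd: float = 1.0
    include_mid: bool = False
    scales: Mapping[str, ScaleDefinition] = field(default_factory=lambda: dict(SCALES))
    seed: int = 0


def simulate_surveys(params: SurveySimParams) -> pd.DataFrame:
    """Tidy table: participant, timepoint, scale, item, value."""
    rng = np.random.default_rng(params.seed)
    timepoints = ["pre", "mid", "post"] if params.include_mid else ["pre", "post"]
    rows = []
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        for scale in params.scales.values():
            mid = (scale.minimum + scale.maximum) / 2.0
            mu_pre = float(params.pre_mean.get(scale.name, mid))
            shift = float(params.post_shift.get(scale.name, 0.0))
            for tp in timepoints:
                frac = {"pre": 0.0, "mid": 0.5, "post": 1.0}[tp]
                mu = mu_pre + frac * shift
                draws = mu + params.item_sd * rng.standard_normal(scale.n_items)
                vals = np.clip(np.round(draws), scale.minimum, scale.maximum).astype(int)
                for item, v in enumerate(vals, start=1):
                    rows.append(
                        {
                            "participant": pid,
                            "timepoint": tp,
                            "scale": scale.name,
                            "item": item,
                            "value": int(v),
                        }
                    )
    return pd.DataFrame(rows)
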