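"""Measurement-side PPG processing: calibration, normalization, filtering,
ensemble averaging, waveform features and PPG imaging.

The chain mirrors how camera or spectrometer reflectance streams are turned
into pulse waveforms: dark/reference calibration (for spectroscopy), AC/DC
normalization (divide by the slowly varying illumination component), adaptive
bandpass filtering around the pulse-rate harmonics, trimmed-mean ensemble
averaging of cardiac cycles, ratio-of-ratios (R) and phase (P) features
between two wavelength channels, and per-pixel amplitude maps from video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import trim_mean

__all__ = [
    "PPGStream",
    "EAWaveform",
    "PPGImage",
    "drs_calibrate",
    "acdc_normalize",
    "abpf",
    "ensemble_average",
    "features_R_P",
    "ppg_image",
    "demarcation_precision",
    "estimate_pulse_rate",
]

#: samples per ensemble-averaged cardiac cycle
EA_TEMPLATE_SIZE = 31
#: trimmed-mean outlier rejection fraction (each tail)
EA_TRIM = 0.10
#: AC/DC low-pass cutoff: ~40 beats/min
ACDC_CUTOFF_HZ = 40.0 / 60.0
#: harmonics retained by the adaptive bandpass filter (fundamental + 6)
ABPF_HARMONICS = 7
ABPF_STRIDE = 256


@dataclass
class PPGStream:
    """A reflectance-intensity time series from one wavelength channel."""

    samples: np.ndarray
    fs: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stream contains non-finite samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class EAWaveform:
    """One ensemble-averaged cardiac cycle (31 samples, peak-aligned)."""

    cycle: np.ndarray
    n_cycles_used: int
    channel: str = ""

    def __post_init__(self) -> None:
        self.cycle = np.asarray(self.cycle, float)
        if len(self.cycle) != EA_TEMPLATE_SIZE:
            raise ValueError(f"EA template must have {EA_TEMPLATE_SIZE} samples")


@dataclass
class PPGImage:
    """Per-pixel AC/DC peak-to-peak pulse-amplitude map."""

    amplitude: np.ndarray
    downscale: int


def drs_calibrate(raw: np.ndarray, dark: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Dark/reference calibration of spectroscopy streams.

    ``raw`` is (n_samples, n_lambda) (or 1-D); ``dark`` is per-wavelength,
    ``reference`` per-sample-per-wavelength or per-wavelength.  Returns the
    normalized diffuse reflectance (raw - dark) / (reference - dark).
    """
    raw = np.asarray(raw, float)
    dark = np.asarray(dark, float)
    reference = np.asarray(reference, float)
    denom = reference - dark
    bad = np.where(~(denom > 0))
    if bad[0].size:
        raise ValueError(
            f"reference does not exceed dark at wavelength index {bad[-1][0]}"
        )
    return (raw - dark) / denom


def acdc_normalize(stream: PPGStream, cutoff_hz: float = ACDC_CUTOFF_HZ,
                   order: int = 4) -> PPGStream:
    """Zero-mean pulsatile component: raw / lowpass(raw) - 1.

    The slowly varying baseline is obtained with a zero-phase (forward-
    backward) Butterworth low-pass at ~40 beats/min, which makes the result
    exactly invariant to any positive gain on the input.
    """
    x = stream.samples
    n_min = int(3 * stream.fs / cutoff_hz)
    if len(x) < n_min:
        raise ValueError(
            f"stream too short for AC/DC normalization (need >= {n_min} samples)"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=stream.fs, output="sos")
    baseline = sps.sosfiltfilt(sos, x)
    if np.any(baseline <= 0):
        raise ValueError("non-physical illumination: low-pass baseline <= 0")
    return PPGStream(samples=x / baseline - 1.0, fs=stream.fs, channel=stream.channel)


def abpf(stream: PPGStream, pulse_rate_hz: float,
         n_harmonics: int = ABPF_HARMONICS, stride: int = ABPF_STRIDE) -> PPGStream:
    """Adaptive bandpass filter retaining pulse-rate harmonics only.

    Short-time transform with Hann analysis windows of ``stride`` samples and
    50% overlap, applied overlap-add; bins within +-1 bin of k * f_pulse for
    k = 1..n_harmonics are kept, everything else (including DC) is zeroed.
    In-band content is reconstructed essentially unchanged away from the
    stream edges.
    """
    if not 0.5 < pulse_rate_hz < 4.0:
        raise ValueError("pulse rate outside the plausible (0.5, 4) Hz range")
    x = stream.samples
    if len(x) < stride:
        raise ValueError(f"stream must have at least {stride} samples")
    noverlap = stride // 2
    sft = sps.ShortTimeFFT(
        sps.windows.hann(stride, sym=False), hop=stride - noverlap,
        fs=stream.fs, fft_mode="onesided",
    )
    S = sft.stft(x)
    freqs = sft.f
    df = freqs[1] - freqs[0]
    keep = np.zeros(len(freqs), bool)
    for k in range(1, n_harmonics + 1):
        center = k * pulse_rate_hz
        idx = int(round(center / df))
        for j in (idx - 1, idx, idx + 1):
            if 0 <= j < len(freqs):
                keep[j] = True
    S[~keep, :] = 0.0
    y = sft.istft(S, k1=len(x))
    return PPGStream(samples=np.asarray(y[: len(x)], float), fs=stream.fs,
                     channel=stream.channel)


def ensemble_average(stream: PPGStream, peak_times: np.ndarray,
                     min_cycles_warn: int = 100) -> EAWaveform:
    """Trimmed-mean template of the cardiac cycles between systolic peaks.

    Each inter-peak segment is resampled to 31 samples (linear interpolation)
    and the per-sample 10%-trimmed mean removes occasional corrupted cycles.
    Fewer than ``min_cycles_warn`` cycles triggers a warning, not an error.
    """
    peaks = np.asarray(peak_times, float)
    if len(peaks) < 3:
        raise ValueError("need at least 2 demarcated cycles (3 peak times)")
    t = stream.t
    cycles = []
    for t0, t1 in zip(peaks[:-1], peaks[1:]):
        ts = np.linspace(t0, t1, EA_TEMPLATE_SIZE)
        cycles.append(np.interp(ts, t, stream.samples))
    arr = np.array(cycles)
    if len(arr) < min_cycles_warn:
        import warnings

        warnings.warn(
            f"ensemble average built from {len(arr)} cycles "
            f"(< {min_cycles_warn} recommended)"
        )
    template = trim_mean(arr, EA_TRIM, axis=0)
    return EAWaveform(cycle=template, n_cycles_used=len(arr), channel=stream.channel)


def _fundamental(x: np.ndarray, fs: float, f0: float) -> complex:
    """Complex amplitude of the component at f0 (single-bin DFT projection)."""
    n = len(x)
    t = np.arange(n) / fs
    return 2.0 / n * np.sum((x - x.mean()) * np.exp(-2j * np.pi * f0 * t))


def features_R_P(a: PPGStream, b: PPGStream, pulse_rate_hz: float) -> tuple[float, float]:
    """Amplitude-ratio R and phase shift P (degrees) between two channels.

    Both are evaluated at the pulse-rate fundamental: R is the ratio of the
    fundamental-component standard deviations of channel a over channel b;
    P is the phase of a minus b in degrees, wrapped to (-180, 180].  Positive
    P means channel a leads.
    """
    if abs(a.fs - b.fs) > 1e-9 or len(a.samples) != len(b.samples):
        raise ValueError("channels must share a time base")
    ca = _fundamental(a.samples, a.fs, pulse_rate_hz)
    cb = _fundamental(b.samples, b.fs, pulse_rate_hz)
    if abs(cb) == 0:
        raise ZeroDivisionError("reference channel has no power at the fundamental")
    r = abs(ca) / abs(cb)
    p = math.degrees(np.angle(ca / cb))
    if p <= -180.0:
        p += 360.0
    return r, p


def _trimmed_frame_mean(frames: np.ndarray) -> np.ndarray:
    if len(frames) >= 3:
        return trim_mean(frames, EA_TRIM, axis=0)
    return frames.mean(axis=0)


def _register(frame: np.ndarray, ref: np.ndarray, max_shift: int = 8):
    """Integer-pixel translation of ``frame`` onto ``ref`` by cross-correlation."""
    f = frame - frame.mean()
    g = ref - ref.mean()
    # FFT cross-correlation, restricted to small shifts
    F = np.fft.rfft2(f)
    G = np.fft.rfft2(g)
    xc = np.fft.irfft2(G * np.conj(F), s=frame.shape)
    h, w = frame.shape
    best = (0, 0, -np.inf)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            v = xc[dy % h, dx % w]
            if v > best[2]:
                best = (dy, dx, v)
    dy, dx, score = best
    norm = math.sqrt((f ** 2).sum() * (g ** 2).sum())
    corr = score / norm if norm > 0 else 0.0
    return np.roll(frame, (dy, dx), axis=(0, 1)), corr


def ppg_image(frames: np.ndarray, peak_times: np.ndarray, valley_times: np.ndarray,
              fs: float, downscale: int = 4, register: bool = True,
              corr_threshold: float = 0.2) -> PPGImage:
    """Pulse-amplitude map from a video stack.

    Frames nearest the systolic peaks and diastolic valleys are registered
    (integer translation), combined with a per-pixel trimmed mean, and the
    normalized difference (diastolic - systolic) / diastolic is block-averaged
    down by ``downscale``.  Frames whose registration correlation falls below
    ``corr_threshold`` are excluded.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (time, height, width) stack")
    if len(peak_times) < 1 or len(valley_times) < 1:
        raise ValueError("need at least one peak and one valley instant")
    ref = frames[int(round(float(peak_times[0]) * fs))]

    def collect(times):
        sel = []
        for tt in np.asarray(times, float):
            idx = int(round(tt * fs))
            if 0 <= idx < len(frames):
                fr = frames[idx]
                if register:
                    fr, corr = _register(fr, ref)
                    if corr < corr_threshold:
                        continue
                sel.append(fr)
        if not sel:
            raise ValueError("no usable frames after registration")
        return _trimmed_frame_mean(np.array(sel))

    systolic = collect(peak_times)
    diastolic = collect(valley_times)
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(diastolic != 0, (diastolic - systolic) / diastolic, 0.0)
    h, w = amp.shape
    h2, w2 = h // downscale, w // downscale
    amp = amp[: h2 * downscale, : w2 * downscale]
    amp = amp.reshape(h2, downscale, w2, downscale).mean(axis=(1, 3))
    return PPGImage(amplitude=amp, downscale=downscale)


def demarcation_precision(fs: float) -> int:
    """Cycle-demarcation precision: one sample period in ms, rounded up."""
    if fs <= 0:
        raise ValueError("sampling rate must be > 0")
    return math.ceil(1000.0 / fs)


def estimate_pulse_rate(stream: PPGStream, window_s: float = 15.0,
                        band: tuple[float, float] = (0.5, 4.0)) -> float:
    """Average pulse rate (Hz): Fourier argmax per window, averaged."""
    x = stream.samples - stream.samples.mean()
    n_win = max(int(window_s * stream.fs), 16)
    rates = []
    for start in range(0, max(len(x) - n_win + 1, 1), n_win):
        seg = x[start: start + n_win]
        if len(seg) < 16:
            continue
        freqs = np.fft.rfftfreq(len(seg), 1.0 / stream.fs)
        spec = np.abs(np.fft.rfft(seg * np.hanning(len(seg))))
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if not mask.any():
            continue
        rates.append(freqs[mask][np.argmax(spec[mask])])
    if not rates:
        raise ValueError("stream too short for pulse-rate estimation")
    return float(np.mean(rates))
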