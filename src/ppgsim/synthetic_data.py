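"""Ground-truth generators for every measurement-side input.

Each generator emulates the statistical structure of real finger-pad
reflectance recordings — a periodic pulse near 1 Hz built from a fundamental
plus six harmonics, multiplicative slow illumination drift, additive Gaussian
sensor noise, wavelength-dependent amplitude/phase profiles (green much
larger than red, IR about twice red, a phase step near 600 nm) — and returns
the exact ground truth alongside, so every downstream recovery test is
closed-loop.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ppg_signal import PPGStream

__all__ = [
    "SynthSpec",
    "synth_stream",
    "synth_two_channel",
    "synth_drs",
    "synth_video",
    "mc_fixtures",
    "DEFAULT_HARMONICS",
]

#: relative harmonic amplitudes of the default pulse waveform (fundamental first)
DEFAULT_HARMONICS = np.array([1.0, 0.45, 0.25, 0.12, 0.06, 0.03, 0.015])


@dataclass
class SynthSpec:
    """Parameters of a synthetic reflectance stream."""

    fs: float = 20.0
    duration: float = 60.0
    pulse_rate: float = 1.1
    harmonics: np.ndarray = field(default_factory=lambda: DEFAULT_HARMONICS.copy())
    phases: np.ndarray | None = None
    modulation: float = 0.02  # AC/DC depth
    baseline: float = 1000.0
    noise_sigma: float = 0.0
    drift_amplitude: float = 0.0
    drift_period: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, float)
        if self.phases is None:
            self.phases = np.zeros_like(self.harmonics)
        self.phases = np.asarray(self.phases, float)
        if not 0.0 < self.modulation <= 0.1:
            raise ValueError("modulation depth must be in (0, 0.1]")
        if self.fs < 16:
            raise ValueError("sampling rate must be >= 16 Hz")
        if len(self.phases) != len(self.harmonics):
            raise ValueError("phases and harmonics must have equal length")


def _pulse_waveform(t: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Unit-normalized pulse: 0 at the (diastolic) baseline, 1 at the peak."""
    w = np.zeros_like(t)
    for k, (a, ph) in enumerate(zip(spec.harmonics, spec.phases), start=1):
        w += a * np.cos(2 * np.pi * k * spec.pulse_rate * t + ph)
    lo, hi = w.min(), w.max()
    return (w - lo) / (hi - lo)


def synth_stream(spec: SynthSpec) -> tuple[PPGStream, dict]:
    """Synthetic raw reflectance stream with exact ground truth.

    Model: ``baseline * (1 + drift(t)) * (1 - modulation * pulse(t)) + noise``
    where ``pulse`` is in [0, 1] and peaks at the systolic instants (maximal
    blood volume = reflectance minima).  Returns the stream plus a dict with
    the noise-free pulse, the systolic peak times and the drift curve.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    pulse = _pulse_waveform(t, spec)
    drift = (
        spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period)
        if spec.drift_amplitude
        else np.zeros_like(t)
    )
    clean = spec.baseline * (1.0 + drift) * (1.0 - spec.modulation * pulse)
    noise = rng.normal(0.0, spec.noise_sigma, n) if spec.noise_sigma else 0.0
    samples = clean + noise

    # exact systolic instants: maxima of the zero-phase harmonic sum at t = k/f
    dense_t = np.linspace(0, 1.0 / spec.pulse_rate, 2001)
    dense = _pulse_waveform(dense_t, spec)
    t_off = dense_t[np.argmax(dense)]
    n_cycles = int(np.floor((t[-1] - t_off) * spec.pulse_rate))
    peak_times = t_off + np.arange(n_cycles + 1) / spec.pulse_rate
    peak_times = peak_times[peak_times <= t[-1]]

    truth = {"pulse": pulse, "peak_times": peak_times, "drift": drift,
             "modulation": spec.modulation, "t": t}
    return PPGStream(samples=samples, fs=spec.fs), truth


def synth_two_channel(
    spec: SynthSpec, R: float, P_deg: float
) -> tuple[PPGStream, PPGStream, dict]:
    """Two-channel pair with a known fundamental amplitude ratio and phase.

    Channel b carries the spec's pulse; channel a's fundamental is ``R``
    times larger and leads by ``P_deg`` degrees (harmonics above the
    fundamental are shared).  Mirrors green-vs-IR camera recordings.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    f0 = spec.pulse_rate

    def channel(scale_fund, phase_lead):
        w = scale_fund * spec.harmonics[0] * np.cos(
            2 * np.pi * f0 * t + spec.phases[0] - phase_lead
        )
        for k, (a, ph) in enumerate(
            zip(spec.harmonics[1:], spec.phases[1:]), start=2
        ):
            w += a * np.cos(2 * np.pi * k * f0 * t + ph)
        return w

    phase = np.deg2rad(P_deg)
    # cos(wt - (-phase)) leads cos(wt) by `phase`
    pa = channel(R, -phase)
    pb = channel(1.0, 0.0)
    sa = spec.baseline * (1.0 - spec.modulation * pa) + rng.normal(
        0, spec.noise_sigma, n
    )
    sb = spec.baseline * (1.0 - spec.modulation * pb) + rng.normal(
        0, spec.noise_sigma, n
    )
    truth = {"R": R, "P_deg": P_deg, "pulse_rate": f0}
    return (
        PPGStream(samples=sa, fs=spec.fs, channel="a"),
        PPGStream(samples=sb, fs=spec.fs, channel="b"),
        truth,
    )


def _default_amplitude_profile(lam: np.ndarray, iror: float = 1.9) -> np.ndarray:
    """AC/DC amplitude vs wavelength: green peak, red minimum, IR ~ 2x red.

    Flat within the red (660-700 nm) and IR (800-840 nm) analysis bands so
    the generated band-mean IR-over-red ratio equals ``iror`` exactly.
    """
    red = 0.002
    anchors_lam = np.array(
        [450.0, 475.0, 520.0, 550.0, 577.0, 600.0, 625.0, 660.0, 700.0,
         750.0, 800.0, 840.0, 900.0, 1000.0]
    )
    anchors_amp = np.array(
        [0.004, 0.006, 0.010, 0.012, 0.010, 0.004, 0.0022, red, red,
         red * (1 + iror) / 2, red * iror, red * iror, red * iror, red * iror]
    )
    return np.interp(lam, anchors_lam, anchors_amp)


def _default_phase_profile(lam: np.ndarray, step_deg: float = 30.0) -> np.ndarray:
    """Phase vs wavelength: flat in VIS, stepping down by ``step_deg`` past 600 nm."""
    return np.where(lam < 600.0, 0.0, -step_deg)


def synth_drs(
    spec: SynthSpec,
    wavelengths: np.ndarray | None = None,
    amplitude_profile: np.ndarray | None = None,
    phase_profile_deg: np.ndarray | None = None,
    dark_level: float = 100.0,
    reference_span: float = 4000.0,
    iror: float = 1.9,
) -> dict:
    """Multi-wavelength spectroscopy streams with dark/reference calibration.

    All wavelength channels share one cardiac process; each gets its own
    AC/DC amplitude and fundamental phase from the given (or default)
    profiles.  Returns a dict with ``raw`` (n_samples, n_lam), ``dark``,
    ``reference``, the wavelength grid and the ground-truth profiles.
    """
    lam = (
        np.arange(475.0, 976.0, 25.0) if wavelengths is None
        else np.asarray(wavelengths, float)
    )
    if lam.min() < 475.0 or lam.max() > 975.0:
        raise ValueError("wavelength grid must lie within [475, 975] nm")
    amp = (
        _default_amplitude_profile(lam, iror) if amplitude_profile is None
        else np.asarray(amplitude_profile, float)
    )
    phase = (
        _default_phase_profile(lam) if phase_profile_deg is None
        else np.asarray(phase_profile_deg, float)
    )
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    f0 = spec.pulse_rate

    raw = np.empty((n, len(lam)))
    for j in range(len(lam)):
        ph = np.deg2rad(phase[j])
        w = spec.harmonics[0] * np.cos(2 * np.pi * f0 * t - ph)
        for k, (a, hph) in enumerate(
            zip(spec.harmonics[1:], spec.phases[1:]), start=2
        ):
            w += a * np.cos(2 * np.pi * k * f0 * t + hph)
        dc = dark_level + reference_span * (0.3 + 0.4 * j / max(len(lam) - 1, 1))
        raw[:, j] = dc * (1.0 - amp[j] * w) + rng.normal(0, spec.noise_sigma, n)

    dark = np.full(len(lam), dark_level)
    reference = dark_level + reference_span * np.ones(len(lam))
    return {
        "wavelengths": lam,
        "raw": raw,
        "dark": dark,
        "reference": reference,
        "amplitude_true": amp,
        "phase_true_deg": phase,
        "pulse_rate": f0,
    }


def synth_video(
    height: int,
    width: int,
    amplitude_map: np.ndarray,
    spec: SynthSpec,
    jitter_px: int = 0,
    texture_amplitude: float = 0.1,
) -> tuple[np.ndarray, dict]:
    """Modulated video stack for pulse-amplitude imaging.

    Per-pixel intensity ``baseline * texture * (1 - amplitude_map * pulse(t))``
    plus sensor noise, where ``texture`` is a static smooth spatial pattern
    (the vessel/skin structure real recordings have — and what frame
    registration locks onto); optional global integer-pixel jitter exercises
    the registration.  Returns the (time, height, width) stack and ground
    truth (peak/valley times, the amplitude map, applied shifts).
    """
    amplitude_map = np.asarray(amplitude_map, float)
    if amplitude_map.shape != (height, width):
        raise ValueError("amplitude map shape must match (height, width)")
    if amplitude_map.min() < 0 or amplitude_map.max() > 0.1:
        raise ValueError("amplitude map values must lie in [0, 0.1]")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    pulse = _pulse_waveform(t, spec)

    # static smooth texture: low-frequency random field, mean 1
    if texture_amplitude > 0:
        coarse = rng.normal(0.0, 1.0, (max(height // 4, 2), max(width // 4, 2)))
        yi = np.linspace(0, coarse.shape[0] - 1, height)
        xi = np.linspace(0, coarse.shape[1] - 1, width)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (np.arange(coarse.shape[0]), np.arange(coarse.shape[1])), coarse
        )
        yy, xx = np.meshgrid(yi, xi, indexing="ij")
        field = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(height, width)
        field = field / max(np.abs(field).max(), 1e-12)
        texture = 1.0 + texture_amplitude * field
    else:
        texture = np.ones((height, width))

    frames = np.empty((n, height, width))
    shifts = np.zeros((n, 2), int)
    for i in range(n):
        img = spec.baseline * texture * (1.0 - amplitude_map * pulse[i])
        if spec.noise_sigma:
            img = img + rng.normal(0, spec.noise_sigma, (height, width))
        if jitter_px:
            dy = int(rng.integers(-jitter_px, jitter_px + 1))
            dx = int(rng.integers(-jitter_px, jitter_px + 1))
            img = np.roll(img, (dy, dx), axis=(0, 1))
            shifts[i] = (dy, dx)
        frames[i] = img

    # valleys: pulse minima; peaks: maxima (systole = max blood = min intensity)
    dense_t = np.linspace(0, 1.0 / spec.pulse_rate, 2001)
    dense = _pulse_waveform(dense_t, spec)
    t_peak = dense_t[np.argmax(dense)]
    t_valley = dense_t[np.argmin(dense)]
    n_cycles = int(np.floor(t[-1] * spec.pulse_rate))
    peak_times = t_peak + np.arange(n_cycles) / spec.pulse_rate
    valley_times = t_valley + np.arange(n_cycles) / spec.pulse_rate
    peak_times = peak_times[peak_times <= t[-1]]
    valley_times = valley_times[valley_times <= t[-1]]
    truth = {
        "amplitude_map": amplitude_map,
        "peak_times": peak_times,
        "valley_times": valley_times,
        "shifts": shifts,
    }
    return frames, truth


def mc_fixtures() -> list[dict]:
    """Canonical transport-validation media with expected behaviors.

    Returns dicts with a name, a layer stack, ambient indices and an
    ``expect`` tag: a matched non-absorbing slab (conservation), a heavy
    absorber (total absorption), the radiative-transfer benchmark slab
    (albedo 0.9, g = 0.75, optical thickness 2: Rd 0.09739, Tt 0.66096) and
    a two-layer toy for penetration-depth monotonicity checks.
    """
    from .layer_optics import LayerOptics

    return [
        {
            "name": "conservation",
            "stack": [LayerOptics(mua=1e-9, mus=50.0, g=0.8, n=1.0, d=0.1)],
            "n_top": 1.0,
            "n_bottom": 1.0,
            "expect": {"RdT_plus_Tt": 1.0},
        },
        {
            "name": "total_absorption",
            "stack": [LayerOptics(mua=1e4, mus=1e-3, g=0.0, n=1.33, d=1.0)],
            "n_top": 1.0,
            "n_bottom": 1.0,
            "expect": {"absorbed_dominates": True},
        },
        {
            "name": "benchmark_slab",
            "stack": [LayerOptics(mua=10.0, mus=90.0, g=0.75, n=1.0, d=0.02)],
            "n_top": 1.0,
            "n_bottom": 1.0,
            "expect": {"RdT": 0.09739, "Tt": 0.66096},
        },
        {
            "name": "two_layer_toy",
            "stack": [
                LayerOptics(mua=5.0, mus=100.0, g=0.9, n=1.4, d=0.05),
                LayerOptics(mua=1.0, mus=100.0, g=0.9, n=1.4, d=0.2),
            ],
            "n_top": 1.0,
            "n_bottom": 1.0,
            "expect": {"pd_monotone_in_mua": True},
        },
    ]
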