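"""Membrane impedance (ZAP) profiling and sinusoidal spike phase locking.

A ZAP stimulus is a current chirp of fixed amplitude whose instantaneous
frequency rises linearly from ``f_start`` to ``f_end`` over the sweep.  The
chirp phase is computed as 2*pi*integral(f(t) dt); the naive reading
A*sin(2*pi*f(t)*t) would sweep the instantaneous frequency at twice the
intended rate (a comparison utility is provided).

The complex impedance is the ratio of Fourier-transformed voltage and
current, evaluated on the swept band; magnitude is reported in MOhm, phase
with the four-quadrant angle convention (voltage lag negative), and the
Bode gain as 20*log10 |Z| relative to the lowest tested frequency.  For a
passive cell the profile follows the first-order RC low-pass form
|Z(f)| = R / sqrt(1 + (2*pi*f*R*C)^2) with cutoff 1/(2*pi*R*C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert


@dataclass(frozen=True)
class ZapSpec:
    """Swept-sine current stimulus parameters."""

    amplitude: float = 40.0  # pA
    f_start: float = 0.5  # Hz
    f_end: float = 50.0  # Hz
    duration: float = 25.0  # s
    fs: float = 10000.0  # samples per second

    def __post_init__(self) -> None:
        if not self.f_start <= self.f_end:
            raise ValueError("require f_start <= f_end")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")


def make_zap(spec: ZapSpec = ZapSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Return (time in s, current in pA) for the chirp stimulus.

    Instantaneous frequency rises linearly; phase is the integral
    2*pi*(f0*t + (f1-f0)*t^2/(2*T)).  Peak amplitude is exactly A.
    """
    t = np.arange(0.0, spec.duration, 1.0 / spec.fs)
    sweep_rate = (spec.f_end - spec.f_start) / spec.duration
    phase = 2.0 * np.pi * (spec.f_start * t + 0.5 * sweep_rate * t**2)
    return t, spec.amplitude * np.sin(phase)


def make_zap_naive(spec: ZapSpec = ZapSpec()) -> tuple[np.ndarray, np.ndarray]:
    """The literal A*sin(2*pi*f(t)*t) waveform, for comparison only.

    Its instantaneous frequency sweeps from f_start to 2*f_end - f_start,
    twice the intended rate.
    """
    t = np.arange(0.0, spec.duration, 1.0 / spec.fs)
    f_t = spec.f_start + (spec.f_end - spec.f_start) * t / spec.duration
    return t, spec.amplitude * np.sin(2.0 * np.pi * f_t * t)


def instantaneous_frequency(t: np.ndarray, waveform: np.ndarray, fs: float) -> np.ndarray:
    """Analytic-signal estimate of instantaneous frequency (Hz)."""
    phase = np.unwrap(np.angle(hilbert(waveform)))
    return np.gradient(phase, 1.0 / fs) / (2.0 * np.pi)


def simulate_rc_response(
    r_mohm: float,
    c_pf: float,
    t_s: np.ndarray,
    i_pa: np.ndarray,
    v0: float = 0.0,
) -> np.ndarray:
    """Voltage response (mV, relative to rest) of a passive RC membrane.

    Integrates tau dv/dt = -v + R*I exactly per sample (current held over
    each step), tau = R*C.
    """
    if r_mohm <= 0 or c_pf <= 0:
        raise ValueError("R and C must be positive")
    tau_s = r_mohm * c_pf * 1e-6  # MOhm*pF = us -> s
    dt = t_s[1] - t_s[0]
    decay = np.exp(-dt / tau_s)
    drive = r_mohm * np.asarray(i_pa, dtype=float) * 1e-3  # MOhm*pA = uV -> mV
    # first-order recursion v[k] = (1-decay)*drive[k] + decay*v[k-1]
    from scipy.signal import lfilter

    v = lfilter([1.0 - decay], [1.0, -decay], drive, zi=[decay * v0])[0]
    return v


@dataclass
class ImpedanceProfile:
    """Frequency-resolved impedance magnitude, phase and Bode gain."""

    frequencies: np.ndarray  # Hz, increasing
    magnitude: np.ndarray  # MOhm
    phase: np.ndarray  # radians, four-quadrant; voltage lag negative
    gain_db: np.ndarray  # 20*log10 relative to the reference frequency
    f_ref: float

    def at(self, f: float) -> tuple[float, float]:
        """(magnitude, phase) at the frequency bin nearest ``f``."""
        i = int(np.argmin(np.abs(self.frequencies - f)))
        return float(self.magnitude[i]), float(self.phase[i])


def impedance_profile(
    v_mv: np.ndarray,
    i_pa: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.5, 50.0),
    smooth_hz: float = 0.25,
    f_ref: float | None = None,
) -> ImpedanceProfile:
    """Complex impedance V(f)/I(f) restricted to the swept band.

    Spectra are single-taper FFTs of the full sweep, optionally smoothed
    with a boxcar of width ``smooth_hz`` before the ratio is taken.
    Magnitude converts mV/pA to MOhm.  Raises if the current spectrum
    carries no power in the band.
    """
    v_mv = np.asarray(v_mv, dtype=float)
    i_pa = np.asarray(i_pa, dtype=float)
    if v_mv.shape != i_pa.shape:
        raise ValueError("voltage and current traces must have equal length")
    n = v_mv.size
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    vf = np.fft.rfft(v_mv - v_mv.mean())
    cf = np.fft.rfft(i_pa - i_pa.mean())
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel) or np.all(np.abs(cf[sel]) < 1e-12):
        raise ValueError("current spectrum has no power in the requested band")
    z = vf[sel] / cf[sel]  # mV / pA = GOhm
    if smooth_hz > 0:
        # smooth the complex ratio (slowly varying), never the raw spectra
        # (their chirp phase rotates fast and would bias the magnitude)
        df = freqs[1] - freqs[0]
        wlen = max(int(round(smooth_hz / df)), 1)
        if wlen > 1:
            box = np.ones(wlen)
            norm = np.convolve(np.ones(z.size), box, mode="same")
            z = np.convolve(z, box, mode="same") / norm
    mag = np.abs(z) * 1000.0  # MOhm
    phase = np.angle(z)
    f_sel = freqs[sel]
    if f_ref is None:
        f_ref = f_sel[0]
    ref_mag = mag[int(np.argmin(np.abs(f_sel - f_ref)))]
    gain = 20.0 * np.log10(mag / ref_mag)
    return ImpedanceProfile(f_sel, mag, phase, gain, float(f_ref))


def rc_impedance_magnitude(f_hz, r_mohm: float, c_pf: float) -> np.ndarray:
    """Closed-form first-order low-pass |Z(f)| in MOhm."""
    f_hz = np.asarray(f_hz, dtype=float)
    tau_s = r_mohm * c_pf * 1e-6
    return r_mohm / np.sqrt(1.0 + (2.0 * np.pi * f_hz * tau_s) ** 2)


def rc_cutoff(r_mohm: float, c_pf: float) -> float:
    """-3 dB cutoff frequency 1/(2*pi*R*C) in Hz."""
    if r_mohm <= 0 or c_pf <= 0:
        raise ValueError("R and C must be positive")
    return 1.0 / (2.0 * np.pi * r_mohm * c_pf * 1e-6)


def bode_gain(profile: ImpedanceProfile, f_ref: float = 0.5) -> np.ndarray:
    """Gain in dB relative to ``f_ref``: 20*log10(|Z(f)| / |Z(f_ref)|).

    (The power convention 10*log10 of the squared ratio is identical.)
    Exactly 0 dB at the reference bin.
    """
    ref = profile.magnitude[int(np.argmin(np.abs(profile.frequencies - f_ref)))]
    return 20.0 * np.log10(profile.magnitude / ref)


@dataclass(frozen=True)
class PhaseLockResult:
    phases: np.ndarray  # per-spike phase of the injected sinusoid, radians
    circular_mean: float
    vector_strength: float  # resultant length in [0, 1]


def phase_lock(
    spike_times_s: np.ndarray,
    stimulus: np.ndarray,
    fs: float,
) -> PhaseLockResult:
    """Register spike times to the phase of a sinusoidal current.

    Each spike is assigned the analytic (Hilbert) phase of the stimulus at
    its time, in the sine convention: a spike at a current peak maps to
    pi/2.  The circular mean and resultant vector length summarize locking;
    a single spike has vector strength 1 by definition.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    if spike_times_s.size == 0:
        return PhaseLockResult(np.array([]), np.nan, np.nan)
    analytic_phase = np.angle(hilbert(stimulus))
    idx = np.clip((spike_times_s * fs).astype(int), 0, stimulus.size - 1)
    # hilbert of sin gives phase (wt - pi/2); shift back to the sine argument
    phases = np.mod(analytic_phase[idx] + np.pi / 2.0, 2.0 * np.pi)
    vec = np.exp(1j * phases).mean()
    return PhaseLockResult(phases, float(np.angle(vec)) % (2.0 * np.pi), float(np.abs(vec)))
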