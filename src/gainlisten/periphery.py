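"""Cochlear front-end: gammatone filterbank cochleagrams.

The periphery maps a stereo sound waveform to a "cochleagram": the waveform
in each ear is convolved with an FIR approximation of a gammatone filterbank
whose center frequencies are uniformly spaced on the ERB-number scale,
half-wave rectified, compressed (power 0.3, emulating outer-hair-cell
compression), low-pass filtered and downsampled (emulating the phase-locking
limit of the auditory nerve), and finally the middle portion of the signal
is excerpted to avoid onset/offset artifacts.  The result is a nonnegative
``(2, n_freq, n_time)`` array that serves as input to the networks in
:mod:`gainlisten.gainnet`.

This stage is fixed (it has no trainable parameters) and fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import fftconvolve, resample_poly

__all__ = [
    "Waveform",
    "FilterBank",
    "Cochleagram",
    "erb_number",
    "erb_number_to_hz",
    "erb_bandwidth",
    "erb_space",
    "make_filterbank",
    "cochleagram",
    "read_wav",
    "write_wav",
    "save_cochleagram",
    "load_cochleagram",
]


# --------------------------------------------------------------------------
# Waveform container
# --------------------------------------------------------------------------

@dataclass
class Waveform:
    """Audio samples, shape (channels, time) with channels in {1, 2}."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2 or arr.shape[0] not in (1, 2):
            raise ValueError(f"expected (channels, time) with 1 or 2 channels, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = arr

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    def to_stereo(self) -> "Waveform":
        """Diotic presentation: duplicate a mono signal to both ears."""
        if self.n_channels == 2:
            return self
        return Waveform(np.vstack([self.samples, self.samples]), self.sample_rate)

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    if data.ndim == 2:  # (time, channels) -> (channels, time)
        data = data.T
    return Waveform(data, float(rate))


def write_wav(path, w: Waveform) -> None:
    wavfile.write(path, int(round(w.sample_rate)), w.samples.T.astype(np.float32))


# --------------------------------------------------------------------------
# ERB-number scale (Glasberg & Moore)
# --------------------------------------------------------------------------

def erb_number(f_hz):
    """Map frequency in Hz to ERB-number (cochlear place) units."""
    return 21.4 * np.log10(0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


def erb_number_to_hz(erbs):
    return (10.0 ** (np.asarray(erbs, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth at frequency f (Hz)."""
    return 24.7 * (0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """n frequencies uniformly spaced on the ERB-number scale, endpoints inclusive."""
    return erb_number_to_hz(np.linspace(erb_number(f_lo), erb_number(f_hi), n))


# --------------------------------------------------------------------------
# Filterbank
# --------------------------------------------------------------------------

@dataclass
class FilterBank:
    """FIR gammatone filterbank: (n_channels, n_taps) impulse responses."""

    center_freqs: np.ndarray
    impulse_responses: np.ndarray
    sample_rate: float

    @property
    def n_channels(self) -> int:
        return len(self.center_freqs)

    @property
    def n_taps(self) -> int:
        return self.impulse_responses.shape[1]


def make_filterbank(
    n_channels: int,
    f_lo: float = 40.0,
    f_hi: float = 20000.0,
    sample_rate: float = 44100.0,
    trunc: float = 0.025,
    order: int = 4,
) -> FilterBank:
    """Build an FIR gammatone filterbank on the ERB-number scale.

    Center frequencies are spaced uniformly on the ERB-number scale with
    inclusive endpoints ``[f_lo, f_hi]``.  Each impulse response is a
    gammatone g(t) = t^(order-1) exp(-2*pi*b*t) cos(2*pi*cf*t) with
    b = 1.019 * ERB(cf), truncated to ``trunc`` seconds
    (``floor(trunc * sample_rate)`` taps) and normalized to unit envelope
    peak.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not (0.0 < f_lo < f_hi < sample_rate / 2.0):
        raise ValueError(
            f"need 0 < f_lo < f_hi < Nyquist; got f_lo={f_lo}, f_hi={f_hi}, "
            f"sample_rate={sample_rate}"
        )
    if trunc <= 0:
        raise ValueError("trunc must be positive")
    cfs = erb_space(f_lo, f_hi, n_channels)
    n_taps = int(math.floor(trunc * sample_rate))
    t = np.arange(n_taps) / sample_rate
    irs = np.empty((n_channels, n_taps))
    for i, cf in enumerate(cfs):
        b = 1.019 * float(erb_bandwidth(cf))
        env = t ** (order - 1) * np.exp(-2.0 * np.pi * b * t)
        peak = env.max()
        irs[i] = env / peak * np.cos(2.0 * np.pi * cf * t)
    return FilterBank(center_freqs=cfs, impulse_responses=irs, sample_rate=sample_rate)


# --------------------------------------------------------------------------
# Kaiser-windowed-sinc polyphase resampling
# --------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=32)
def _kaiser_sinc_filter(up: int, down: int, width: int, roll_off: float, beta: float) -> np.ndarray:
    """Low-pass kernel for polyphase resampling at the intermediate rate.

    The cutoff is ``roll_off`` times the smaller Nyquist frequency and the
    kernel spans ``width`` zero-crossings of the sinc on each side.
    """
    # cutoff as a fraction of the intermediate rate (orig_rate * up)
    cutoff = roll_off * 0.5 / max(up, down)
    half = int(math.ceil(width / (2.0 * cutoff)))
    n = np.arange(-half, half + 1)
    h = 2.0 * cutoff * np.sinc(2.0 * cutoff * n)
    h *= np.kaiser(2 * half + 1, beta)
    return h


def resample_kaiser(
    x: np.ndarray,
    orig_rate: float,
    out_rate: float,
    width: int = 64,
    roll_off: float = 0.94759,
    beta: float = 14.76965,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Kaiser-windowed-sinc polyphase resampling along ``axis``."""
    if orig_rate == out_rate:
        return np.asarray(x, dtype=float)
    up_f, down_f = float(out_rate), float(orig_rate)
    if not (up_f.is_integer() and down_f.is_integer()):
        raise ValueError("sample rates must be integers for polyphase resampling")
    g = math.gcd(int(up_f), int(down_f))
    up, down = int(up_f) // g, int(down_f) // g
    h = _kaiser_sinc_filter(up, down, width, roll_off, beta)
    if up == 1:
        # pure decimation: same-mode FFT convolution with the (symmetric,
        # zero-phase) kernel followed by subsampling is equivalent to the
        # polyphase path and much faster for long kernels
        y = fftconvolve(np.asarray(x, dtype=float),
                        np.reshape(h, (1,) * (np.ndim(x) - 1) + (-1,)),
                        mode="same", axes=axis)
        sl = [slice(None)] * np.ndim(x)
        sl[axis] = slice(None, None, down)
        return y[tuple(sl)]
    # resample_poly scales an array window by `up` internally
    return resample_poly(x, up, down, axis=axis, window=h)


# --------------------------------------------------------------------------
# Cochleagram
# --------------------------------------------------------------------------

@dataclass
class Cochleagram:
    """Nonnegative (2, n_freq, n_time) representation of a binaural sound."""

    values: np.ndarray
    sample_rate: float
    freq_axis: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def shape(self):
        return self.values.shape


def cochleagram(
    w: Waveform,
    fb: FilterBank,
    compress_exp: float = 0.3,
    out_rate: float = 10000.0,
    excerpt: float = 2.0,
    resample_width: int = 64,
    resample_roll_off: float = 0.94759,
    resample_beta: float = 14.76965,
) -> Cochleagram:
    """Map a stereo waveform to a cochleagram.

    Per ear: 'same'-mode convolution with every gammatone filter, half-wave
    rectification, power-law compression, Kaiser-windowed-sinc low-pass
    resampling to ``out_rate``, and excerpting of the middle ``excerpt``
    seconds.  The two ears are stacked on the leading channel axis.
    """
    if w.n_channels != 2:
        raise ValueError("cochleagram expects a stereo (binaural) waveform; "
                         "use Waveform.to_stereo() for diotic presentation")
    if abs(w.sample_rate - fb.sample_rate) > 1e-9:
        raise ValueError(
            f"waveform rate {w.sample_rate} != filterbank rate {fb.sample_rate}"
        )
    if w.duration + 1e-12 < excerpt:
        raise ValueError(f"input duration {w.duration:.3f}s shorter than excerpt {excerpt}s")
    # (2, C, N) conv (2, C, taps) -> (2, C, N), center-aligned
    n = w.samples.shape[1]
    sig = np.broadcast_to(w.samples[:, None, :], (2, fb.n_channels, n))
    irs = np.broadcast_to(fb.impulse_responses[None, :, :], (2, fb.n_channels, fb.n_taps))
    sub = fftconvolve(sig, irs, mode="same", axes=-1)
    sub = np.maximum(sub, 0.0) ** compress_exp
    env = resample_kaiser(sub, w.sample_rate, out_rate, width=resample_width,
                          roll_off=resample_roll_off, beta=resample_beta, axis=-1)
    env = np.maximum(env, 0.0)  # resampling ripple can dip slightly below zero
    n_exc = int(round(excerpt * out_rate))
    if env.shape[-1] < n_exc:
        raise ValueError("resampled signal shorter than requested excerpt")
    start = (env.shape[-1] - n_exc) // 2
    vals = np.ascontiguousarray(env[:, :, start:start + n_exc])
    return Cochleagram(values=vals, sample_rate=out_rate, freq_axis=fb.center_freqs.copy())


# --------------------------------------------------------------------------
# HDF5 serialization
# --------------------------------------------------------------------------

def save_cochleagram(path, cg: Cochleagram) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("cochleagram", data=cg.values.astype(np.float32))
        d.attrs["sample_rate"] = cg.sample_rate
        d.attrs["axes"] = "ear,frequency,time"
        f.create_dataset("freq_axis", data=cg.freq_axis)


def load_cochleagram(path) -> Cochleagram:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["cochleagram"]
        return Cochleagram(
            values=np.asarray(d, dtype=np.float64),
            sample_rate=float(d.attrs["sample_rate"]),
            freq_axis=np.asarray(f["freq_axis"]),
        )
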