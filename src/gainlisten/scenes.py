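"""Synthetic talkers, stimulus manipulations, and cocktail-party scenes.

Real speech corpora are replaced by a parametric talker model operating at
desk scale: each talker has a fundamental frequency (f0) drawn from one of
two disjoint "sex-class" ranges and a talker-specific spectral envelope
(two formant-like resonances plus a spectral tilt).  A "word" is a
fixed-duration segment whose identity is carried by a word-specific
amplitude-modulation rate and a word-specific spectral-emphasis trajectory,
both derived deterministically from the word label, so a word is
recognizable across talkers.  Utterances are sums of harmonics of f0 shaped
by these envelopes, with per-word boundaries tiling the clip.

The module also provides the stimulus manipulations used in the behavioral
experiments (inharmonic jittering of the partials, whispered/noise-excited
resynthesis, speech-shaped and pink noises), level (dB SPL) and SNR
arithmetic, the training-time signal augmentations (random Butterworth
band-pass, label-preserving time shifts), corpus balancing, and the full
scene-assembly procedure (target, same-talker cue centered on a different
word, 1-6 distractors split between speech and noise, per-source levels,
50% co-location, 10% silent-cue single-talker scenes, SNR mixing, RMS
normalization).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import butter, sosfilt

from .periphery import Waveform
from .spatial import RoomSpec, SourceLocation, default_elevations, render_binaural, \
    sample_room_and_listener

__all__ = [
    "SPL_REFERENCE_DB",
    "TalkerSpec",
    "Utterance",
    "ScenePlan",
    "SceneSpec",
    "SceneConfig",
    "make_talker",
    "make_toy_corpus",
    "synth_utterance",
    "jitter_harmonics",
    "whisper_filter",
    "whisper_transform",
    "shaped_noise",
    "measure_level",
    "set_level",
    "mix_at_snr",
    "augment_signal",
    "middle_word",
    "plan_scene",
    "assemble_scene",
    "balance_corpus",
]

# Digital full-scale convention: an RMS of 1.0 corresponds to 100 dB SPL.
# The constant is arbitrary (all SPL arithmetic is relative) but fixed, and
# keeps 50-70 dB SPL sources in well-conditioned float range.
SPL_REFERENCE_DB = 100.0

SEX_CLASS_F0_RANGES = {"A": (80.0, 160.0), "B": (170.0, 320.0)}


# --------------------------------------------------------------------------
# Talkers and utterances
# --------------------------------------------------------------------------

@dataclass
class TalkerSpec:
    """A synthetic voice: f0 plus a fixed spectral envelope."""

    talker_id: str
    sex_class: str  # "A" or "B"; the two classes have disjoint f0 ranges
    f0: float
    envelope_params: dict
    language_class: str = "L1"

    def __post_init__(self):
        lo, hi = SEX_CLASS_F0_RANGES[self.sex_class]
        if not (lo <= self.f0 <= hi):
            raise ValueError(f"f0 {self.f0} outside {self.sex_class} range [{lo}, {hi}]")


def make_talker(talker_id: str, sex_class: str, rng: np.random.Generator,
                language_class: str = "L1") -> TalkerSpec:
    lo, hi = SEX_CLASS_F0_RANGES[sex_class]
    f0 = float(rng.uniform(lo, hi))
    env = {
        "f1": float(rng.uniform(250.0, 750.0)),
        "f2": float(rng.uniform(900.0, 1700.0)),
        "bw1": float(rng.uniform(80.0, 160.0)),
        "bw2": float(rng.uniform(150.0, 300.0)),
        "tilt_db_oct": float(rng.uniform(-9.0, -3.0)),
    }
    return TalkerSpec(talker_id, sex_class, f0, env, language_class)


def make_toy_corpus(n_words: int = 8, n_talkers: int = 2, seed: int = 0,
                    language_class: str = "L1"):
    """Vocabulary plus talkers for desk-scale experiments.

    Talkers alternate between the two sex classes so that same/different-sex
    contrasts are available even at n_talkers=2.
    """
    rng = np.random.default_rng(seed)
    vocabulary = [f"word{i:02d}" for i in range(n_words)]
    talkers = [
        make_talker(f"talker{i:02d}", "A" if i % 2 == 0 else "B", rng, language_class)
        for i in range(n_talkers)
    ]
    return vocabulary, talkers


def _word_signature(word: str) -> dict:
    """Deterministic word identity: AM rate/depth and spectral emphasis."""
    h = zlib.crc32(word.encode("utf-8"))
    r = np.random.default_rng(h)
    return {
        "am_rate": float(r.uniform(3.0, 14.0)),
        "am_depth": float(r.uniform(0.5, 0.9)),
        "emph_lo": float(r.uniform(0.1, 0.8)),  # fraction of the component band
        "emph_hi": float(r.uniform(0.1, 0.8)),
        "emph_width": float(r.uniform(0.08, 0.25)),
    }


def _talker_envelope(freqs: np.ndarray, env: dict) -> np.ndarray:
    tilt = 10.0 ** (env["tilt_db_oct"] * np.log2(np.maximum(freqs, 1.0) / 200.0) / 20.0)
    bump1 = np.exp(-0.5 * ((freqs - env["f1"]) / env["bw1"]) ** 2)
    bump2 = np.exp(-0.5 * ((freqs - env["f2"]) / env["bw2"]) ** 2)
    return tilt * (0.15 + bump1 + 0.7 * bump2)


@dataclass
class Utterance:
    """A labeled synthetic utterance with full resynthesis provenance."""

    waveform: Waveform
    word_sequence: list[str]
    word_boundaries: list[tuple[float, float]]
    talker: TalkerSpec
    harmonicity: str = "harmonic"  # harmonic | inharmonic | whispered
    jitter_pattern: np.ndarray | None = None  # per-component shifts, units of f0
    _recipe: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        bnds = self.word_boundaries
        if len(bnds) != len(self.word_sequence):
            raise ValueError("one boundary pair per word required")
        last = 0.0
        for s, e in bnds:
            if s < last - 1e-9 or e <= s or e > self.waveform.duration + 1e-9:
                raise ValueError("word boundaries must be sorted, non-overlapping, in range")
            last = e

    @property
    def duration(self) -> float:
        return self.waveform.duration


def middle_word(u: Utterance, excerpt: float = 2.0) -> str:
    """The word overlapping the 1-second mark of the middle `excerpt`."""
    mark = (u.duration - excerpt) / 2.0 + 1.0
    for w, (s, e) in zip(u.word_sequence, u.word_boundaries):
        if s <= mark < e:
            return w
    raise ValueError(f"no word overlaps t={mark:.3f}s")


def _component_band(sample_rate: float, cap_hz: float | None) -> float:
    return min(cap_hz, 0.45 * sample_rate) if cap_hz else 0.45 * sample_rate


def _synth_core(talker: TalkerSpec, words: Sequence[str], duration: float,
                sample_rate: float, seed: int, cap_hz: float | None,
                jitter: np.ndarray | None) -> np.ndarray:
    """Harmonic (optionally jittered) synthesis of a word sequence."""
    cap = _component_band(sample_rate, cap_hz)
    n_comp = int(cap // talker.f0)
    if n_comp < 1:
        raise ValueError("f0 above the component band")
    k = np.arange(1, n_comp + 1)
    freqs = k * talker.f0
    if jitter is not None:
        freqs = freqs + np.concatenate([[0.0], jitter[: n_comp - 1]]) * talker.f0
    amps0 = _talker_envelope(freqs, talker.envelope_params)
    phase_rng = np.random.default_rng(seed)
    phases = phase_rng.uniform(0.0, 2.0 * np.pi, size=n_comp)

    n = int(round(duration * sample_rate))
    n_words = len(words)
    seg_len = n // n_words
    out = np.zeros(n)
    for wi, word in enumerate(words):
        sig = _word_signature(word)
        i0 = wi * seg_len
        i1 = (wi + 1) * seg_len if wi < n_words - 1 else n
        t = np.arange(i0, i1) / sample_rate
        t_rel = (t - t[0]) / max(t[-1] - t[0], 1e-9)
        am = 1.0 + sig["am_depth"] * np.cos(2.0 * np.pi * sig["am_rate"] * (t - t[0]))
        # spectral emphasis drifts linearly from emph_lo to emph_hi
        c = (sig["emph_lo"] + (sig["emph_hi"] - sig["emph_lo"]) * t_rel) * cap
        width = sig["emph_width"] * cap
        # (n_comp, seg) emphasis
        emph = 0.25 + np.exp(-0.5 * ((freqs[:, None] - c[None, :]) / width) ** 2)
        seg = np.zeros(i1 - i0)
        for ci in range(n_comp):
            seg += amps0[ci] * emph[ci] * np.cos(2.0 * np.pi * freqs[ci] * t + phases[ci])
        # Tukey-style ramps to avoid clicks at word boundaries
        ramp = max(4, int(0.01 * sample_rate))
        win = np.ones(i1 - i0)
        win[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        win[-ramp:] = win[:ramp][::-1]
        out[i0:i1] = seg * am * win
    peak = np.abs(out).max()
    if peak > 0:
        out = out / peak * 0.5
    return out


def synth_utterance(talker: TalkerSpec, words: Sequence[str], duration: float,
                    rng: np.random.Generator, sample_rate: float = 44100.0,
                    cap_hz: float | None = None) -> Utterance:
    """Synthesize a harmonic utterance; deterministic given (talker, words, seed)."""
    if not words:
        raise ValueError("word list must be nonempty")
    if duration <= 0:
        raise ValueError("duration must be positive")
    seed = int(rng.integers(0, 2**31 - 1))
    samples = _synth_core(talker, list(words), duration, sample_rate, seed, cap_hz, None)
    n_words = len(words)
    bounds = [(i * duration / n_words, (i + 1) * duration / n_words) for i in range(n_words)]
    return Utterance(
        waveform=Waveform(samples, sample_rate),
        word_sequence=list(words),
        word_boundaries=bounds,
        talker=talker,
        harmonicity="harmonic",
        _recipe={"seed": seed, "duration": duration, "sample_rate": sample_rate,
                 "cap_hz": cap_hz},
    )


# --------------------------------------------------------------------------
# Harmonicity manipulations
# --------------------------------------------------------------------------

def sample_jitter_pattern(talker: TalkerSpec, rng: np.random.Generator,
                          max_shift: float = 0.30, min_spacing: float = 30.0,
                          n_components: int | None = None,
                          sample_rate: float = 44100.0,
                          cap_hz: float | None = None,
                          max_attempts: int = 10000) -> np.ndarray:
    """Draw per-component relative shifts (units of f0) for components above f0.

    Rejection-sampled so that all adjacent component spacings stay at or
    above ``min_spacing`` Hz.
    """
    f0 = talker.f0
    if n_components is None:
        n_components = int(_component_band(sample_rate, cap_hz) // f0)
    if min_spacing > (1.0 - 2.0 * max_shift) * f0:
        raise ValueError(
            f"min_spacing {min_spacing} Hz infeasible for f0 {f0:.1f} Hz with "
            f"max_shift {max_shift}"
        )
    n_jit = max(n_components - 1, 0)
    for _ in range(max_attempts):
        jit = rng.uniform(-max_shift, max_shift, size=n_jit)
        freqs = np.arange(1, n_components + 1) * f0
        freqs = freqs + np.concatenate([[0.0], jit]) * f0
        if n_components < 2 or np.min(np.diff(np.sort(freqs))) >= min_spacing:
            return jit
    raise ValueError("could not satisfy the spacing constraint")


def jitter_harmonics(u: Utterance, max_shift: float = 0.30, min_spacing: float = 30.0,
                     rng: np.random.Generator | None = None,
                     pattern: np.ndarray | None = None) -> Utterance:
    """Inharmonic resynthesis: shift each partial above f0 by a random amount.

    Shifts are relative (fractions of f0) so a stored ``pattern`` can be
    reapplied to the other utterances of a trial.  With ``max_shift=0`` the
    output is identical to the input.
    """
    if u.harmonicity != "harmonic":
        raise ValueError("jitter_harmonics requires a harmonic utterance")
    r = u._recipe
    if pattern is None:
        if max_shift == 0.0:
            n_comp = int(_component_band(r["sample_rate"], r["cap_hz"]) // u.talker.f0)
            pattern = np.zeros(max(n_comp - 1, 0))
        else:
            if rng is None:
                raise ValueError("rng required when no pattern is supplied")
            pattern = sample_jitter_pattern(
                u.talker, rng, max_shift, min_spacing,
                sample_rate=r["sample_rate"], cap_hz=r["cap_hz"])
    samples = _synth_core(u.talker, u.word_sequence, r["duration"], r["sample_rate"],
                          r["seed"], r["cap_hz"], np.asarray(pattern, dtype=float))
    return Utterance(
        waveform=Waveform(samples, r["sample_rate"]),
        word_sequence=list(u.word_sequence),
        word_boundaries=list(u.word_boundaries),
        talker=u.talker,
        harmonicity="inharmonic" if np.any(np.asarray(pattern) != 0) else "harmonic",
        jitter_pattern=np.asarray(pattern, dtype=float),
        _recipe=dict(r),
    )


def whisper_filter(sample_rate: float, cutoff: float = 1200.0,
                   zero_shrink: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Breath-noise high-pass: 2nd-order Butterworth with shrunken zeros.

    A standard second-order high-pass Butterworth (3-dB cutoff ``cutoff``)
    has a double zero at z=1 and therefore no energy at DC; moving the zeros
    toward the origin (multiplying them by ``zero_shrink``) leaves a little
    low-frequency energy, which better approximates whispering.  Returns
    (b, a) coefficients.
    """
    b, a = butter(2, cutoff / (sample_rate / 2.0), btype="highpass")
    zeros = np.roots(b)
    b_new = np.real(b[0] * np.poly(zero_shrink * zeros))
    return b_new, a


def whisper_transform(u: Utterance, rng: np.random.Generator) -> Utterance:
    """Noise-excited resynthesis: replace harmonic excitation with filtered noise.

    White noise is shaped by the whisper high-pass filter, then by the
    utterance's spectral envelope (talker envelope x word emphasis) in the
    frequency domain per word segment, and by the word's amplitude
    modulation in the time domain.  Word boundaries, duration, and per-word
    RMS are preserved.
    """
    from scipy.signal import lfilter

    r = u._recipe
    sr = r["sample_rate"]
    cap = _component_band(sr, r["cap_hz"])
    b, a = whisper_filter(sr)
    n = u.waveform.samples.shape[1]
    out = np.zeros(n)
    n_words = len(u.word_sequence)
    seg_len = n // n_words
    for wi, word in enumerate(u.word_sequence):
        sig = _word_signature(word)
        i0 = wi * seg_len
        i1 = (wi + 1) * seg_len if wi < n_words - 1 else n
        m = i1 - i0
        noise = lfilter(b, a, rng.standard_normal(m))
        # impose the segment-average spectral envelope in the frequency domain
        freqs = np.fft.rfftfreq(m, 1.0 / sr)
        c = 0.5 * (sig["emph_lo"] + sig["emph_hi"]) * cap
        width = sig["emph_width"] * cap
        emph = 0.25 + np.exp(-0.5 * ((freqs - c) / width) ** 2)
        env = _talker_envelope(freqs, u.talker.envelope_params) * emph
        seg = np.fft.irfft(np.fft.rfft(noise) * env, n=m)
        t = np.arange(m) / sr
        am = 1.0 + sig["am_depth"] * np.cos(2.0 * np.pi * sig["am_rate"] * t)
        seg = seg * am
        ref_rms = float(np.sqrt(np.mean(u.waveform.samples[0, i0:i1] ** 2)))
        seg_rms = float(np.sqrt(np.mean(seg**2)))
        if seg_rms > 0 and ref_rms > 0:
            seg *= ref_rms / seg_rms
        out[i0:i1] = seg
    return Utterance(
        waveform=Waveform(out, sr),
        word_sequence=list(u.word_sequence),
        word_boundaries=list(u.word_boundaries),
        talker=u.talker,
        harmonicity="whispered",
        _recipe=dict(r),
    )


# --------------------------------------------------------------------------
# Noises, levels, SNR
# --------------------------------------------------------------------------

def shaped_noise(kind: str, duration: float, rng: np.random.Generator,
                 reference: Waveform | None = None, sample_rate: float = 44100.0,
                 rms: float = 0.02) -> Waveform:
    """Speech-shaped (reference power spectrum imposed on white noise) or pink noise."""
    if kind not in ("speech-shaped", "pink"):
        raise ValueError(f"unknown noise kind {kind!r}")
    if kind == "speech-shaped":
        if reference is None:
            raise ValueError("speech-shaped noise requires a reference waveform")
        sample_rate = reference.sample_rate
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    if kind == "speech-shaped":
        ref = reference.samples.mean(axis=0)
        mag = np.abs(np.fft.rfft(ref, n=n))
    else:
        f = np.fft.rfftfreq(n, 1.0 / sample_rate)
        f[0] = f[1] if n > 1 else 1.0
        mag = 1.0 / np.sqrt(f)
    x = np.fft.irfft(spec * mag, n=n)
    x_rms = np.sqrt(np.mean(x**2))
    if x_rms > 0:
        x = x / x_rms * rms
    return Waveform(x, sample_rate)


def measure_level(w: Waveform) -> float:
    """Level in dB SPL under the package reference (RMS 1.0 = 100 dB SPL)."""
    r = w.rms
    if r == 0:
        return -np.inf
    return SPL_REFERENCE_DB + 20.0 * np.log10(r)


def set_level(w: Waveform, level_db: float) -> Waveform:
    """Scale so the measured level equals ``level_db`` dB SPL."""
    r = w.rms
    if r == 0:
        raise ValueError("cannot set the level of an all-zero waveform")
    target_rms = 10.0 ** ((level_db - SPL_REFERENCE_DB) / 20.0)
    return Waveform(w.samples * (target_rms / r), w.sample_rate)


def mix_at_snr(target: Waveform, distractor_sum: Waveform, snr_db: float,
               normalize_rms: float | None = 0.02,
               return_components: bool = False):
    """Scale the target against the summed distractors and mix.

    The target is scaled so 20*log10(rms_target / rms_distractors) equals
    ``snr_db``; the signals are summed; the mixture is RMS-normalized to
    ``normalize_rms`` (skip with None).
    """
    if target.samples.shape != distractor_sum.samples.shape:
        raise ValueError("target and distractor must share shape and rate")
    d_rms = distractor_sum.rms
    if d_rms == 0:
        raise ValueError("silent distractor with finite SNR")
    t_rms = target.rms
    if t_rms == 0:
        raise ValueError("silent target")
    scale = d_rms / t_rms * 10.0 ** (snr_db / 20.0)
    scaled_target = Waveform(target.samples * scale, target.sample_rate)
    mix = scaled_target.samples + distractor_sum.samples
    if normalize_rms is not None:
        m_rms = np.sqrt(np.mean(mix**2))
        if m_rms > 0:
            mix = mix / m_rms * normalize_rms
    out = Waveform(mix, target.sample_rate)
    if return_components:
        return out, scaled_target
    return out


# --------------------------------------------------------------------------
# Augmentations
# --------------------------------------------------------------------------

def _labeled_word_index(u: Utterance, excerpt: float = 2.0) -> int:
    mark = (u.duration - excerpt) / 2.0 + 1.0
    for i, (s, e) in enumerate(u.word_boundaries):
        if s <= mark < e:
            return i
    raise ValueError("no labeled word")


def augment_signal(u: Utterance, rng: np.random.Generator, kind: str,
                   apply_prob: float = 0.5,
                   low_cut_range: tuple[float, float] = (40.0, 400.0),
                   high_cut_range: tuple[float, float] = (4000.0, 16000.0),
                   order_range: tuple[int, int] = (1, 4),
                   excerpt: float = 2.0) -> Utterance:
    """Training-time augmentation: random band-pass or label-preserving shift.

    ``bandpass`` applies (with probability ``apply_prob``) a Butterworth
    band-pass with uniformly sampled cutoffs and order.  ``timeshift``
    shifts the waveform forward or backward (equiprobable) by up to 50% of
    the labeled word's duration, constrained so that the labeled word still
    overlaps the 1-second mark of the excerpt.
    """
    sr = u.waveform.sample_rate
    if kind == "bandpass":
        if rng.random() >= apply_prob:
            return u
        lo = rng.uniform(*low_cut_range)
        hi = rng.uniform(*high_cut_range)
        hi = min(hi, 0.95 * sr / 2.0)
        order = int(rng.integers(order_range[0], order_range[1] + 1))
        sos = butter(order, [lo, hi], btype="bandpass", fs=sr, output="sos")
        filt = sosfilt(sos, u.waveform.samples, axis=-1)
        return Utterance(Waveform(filt, sr), list(u.word_sequence),
                         list(u.word_boundaries), u.talker, u.harmonicity,
                         u.jitter_pattern, _recipe=dict(u._recipe))
    if kind != "timeshift":
        raise ValueError(f"unknown augmentation kind {kind!r}")
    idx = _labeled_word_index(u, excerpt)
    s, e = u.word_boundaries[idx]
    mark = (u.duration - excerpt) / 2.0 + 1.0
    max_mag = 0.5 * (e - s)
    for _ in range(1000):
        shift = float(rng.uniform(0.0, max_mag)) * (1.0 if rng.random() < 0.5 else -1.0)
        if s + shift <= mark < e + shift:
            break
    else:
        shift = 0.0
    n_shift = int(round(shift * sr))
    x = u.waveform.samples
    if n_shift > 0:
        shifted = np.pad(x, ((0, 0), (n_shift, 0)))[:, : x.shape[1]]
    elif n_shift < 0:
        shifted = np.pad(x, ((0, 0), (0, -n_shift)))[:, -n_shift:]
    else:
        shifted = x.copy()
    actual = n_shift / sr
    bounds = [(s0 + actual, e0 + actual) for (s0, e0) in u.word_boundaries]
    # clip to the clip extent; drop words shifted fully outside
    keep = [(w, (max(s0, 0.0), min(e0, u.duration)))
            for w, (s0, e0) in zip(u.word_sequence, bounds) if e0 > 0 and s0 < u.duration]
    return Utterance(Waveform(shifted, sr), [w for w, _ in keep],
                     [b for _, b in keep], u.talker, u.harmonicity,
                     u.jitter_pattern, _recipe=dict(u._recipe))


# --------------------------------------------------------------------------
# Scene assembly
# --------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Study conditions for scene generation.

    Defaults are the training-distribution conditions: 1-6 distractors,
    per-source levels 50-70 dB SPL, SNR -10..10 dB, 50% co-location, 10%
    silent-cue single-talker scenes, 2.5-s source material (from which the
    middle 2 s is excerpted after the cochlear stage).
    """

    vocabulary: list[str]
    talkers: list[TalkerSpec]
    sample_rate: float = 44100.0
    clip_duration: float = 2.5
    n_words: int = 5
    excerpt: float = 2.0
    n_distractor_range: tuple[int, int] = (1, 6)
    n_speech_range: tuple[int, int] | None = None  # None: uniform over 0..n
    level_range_db: tuple[float, float] = (50.0, 70.0)
    snr_range_db: tuple[float, float] = (-10.0, 10.0)
    co_locate_prob: float = 0.5
    silence_cue_prob: float = 0.1
    mixture_rms: float = 0.02
    spatialize: bool = True
    augment: bool = True
    bandpass_low_range: tuple[float, float] = (40.0, 400.0)
    bandpass_high_range: tuple[float, float] = (4000.0, 16000.0)
    cap_hz: float | None = None
    noise_kinds: tuple[str, ...] = ("pink", "speech-shaped")


@dataclass
class ScenePlan:
    """Sampled scene metadata (no audio): the seven-step draw."""

    target_talker_id: str
    target_words: list[str]
    cue_words: list[str]
    label: str
    n_distractors: int
    n_speech: int
    distractor_talker_ids: list[str]
    distractor_noise_kinds: list[str]
    distractor_levels_db: list[float]
    snr_db: float
    co_located: bool
    silence_cue: bool
    target_location: SourceLocation | None
    distractor_locations: list[SourceLocation] | None
    room: RoomSpec | None


@dataclass
class SceneSpec:
    """Full provenance of one assembled trial."""

    cue: Utterance | None
    target: Utterance
    distractors: list[tuple[object, SourceLocation | None, float]]
    snr: float
    co_located: bool
    silence_cue: bool
    label: str
    target_render: Waveform | None = None
    distractor_render: Waveform | None = None
    norm_scale: float = 1.0


def _sample_location(rng: np.random.Generator, room: RoomSpec | None,
                     elevations: np.ndarray) -> SourceLocation:
    az = float(rng.integers(0, 72)) * 5.0
    el = float(rng.choice(elevations))
    if rng.random() < 0.5:
        dist = 1.4
    else:
        hi = (room.wall_distance(az) - 0.1) if room is not None else 1.35
        dist = float(rng.uniform(1.0, max(hi, 1.0 + 1e-6)))
    return SourceLocation(az, el, dist)


def _draw_words(cfg: SceneConfig, rng: np.random.Generator) -> list[str]:
    return [str(rng.choice(cfg.vocabulary)) for _ in range(cfg.n_words)]


def plan_scene(cfg: SceneConfig, rng: np.random.Generator) -> ScenePlan:
    """Sample all stochastic scene parameters without synthesizing audio."""
    if not cfg.vocabulary or not cfg.talkers:
        raise ValueError("scene config needs a nonempty vocabulary and talker list")
    elevations = default_elevations()
    target_talker = cfg.talkers[int(rng.integers(len(cfg.talkers)))]
    target_words = _draw_words(cfg, rng)
    mid = len(target_words) // 2
    label = target_words[mid]
    # cue: same talker, centered on a different word
    cue_words = _draw_words(cfg, rng)
    others = [w for w in cfg.vocabulary if w != label]
    if not others:
        raise ValueError("vocabulary too small for a distinct cue word")
    cue_words[mid] = str(rng.choice(others))

    silence_cue = rng.random() < cfg.silence_cue_prob
    lo, hi = cfg.n_distractor_range
    n_distractors = int(rng.integers(lo, hi + 1))
    if cfg.n_speech_range is None:
        n_speech = int(rng.integers(0, n_distractors + 1))
    else:
        s_lo, s_hi = cfg.n_speech_range
        n_speech = int(rng.integers(s_lo, min(s_hi, n_distractors) + 1))
    other_talkers = [t for t in cfg.talkers if t.talker_id != target_talker.talker_id]
    if n_speech > 0 and not other_talkers:
        raise ValueError("need at least two talkers for speech distractors")
    d_talkers = [str(other_talkers[int(rng.integers(len(other_talkers)))].talker_id)
                 for _ in range(n_speech)]
    d_noises = [str(rng.choice(cfg.noise_kinds)) for _ in range(n_distractors - n_speech)]
    levels = [float(rng.uniform(*cfg.level_range_db)) for _ in range(n_distractors)]
    snr = float(rng.uniform(*cfg.snr_range_db))
    co_located = rng.random() < cfg.co_locate_prob

    room = sample_room_and_listener(rng) if cfg.spatialize else None
    if cfg.spatialize:
        t_loc = _sample_location(rng, room, elevations)
        d_locs = [t_loc if co_located else _sample_location(rng, room, elevations)
                  for _ in range(n_distractors)]
    else:
        t_loc, d_locs = None, None
    return ScenePlan(
        target_talker_id=target_talker.talker_id,
        target_words=target_words, cue_words=cue_words, label=label,
        n_distractors=n_distractors, n_speech=n_speech,
        distractor_talker_ids=d_talkers, distractor_noise_kinds=d_noises,
        distractor_levels_db=levels, snr_db=snr, co_located=co_located,
        silence_cue=silence_cue, target_location=t_loc,
        distractor_locations=d_locs, room=room,
    )


def _render_or_diotic(w: Waveform, loc: SourceLocation | None) -> Waveform:
    if loc is None:
        return w.to_stereo()
    return render_binaural(w, loc)


def assemble_scene(cfg: SceneConfig, rng: np.random.Generator):
    """Sample and synthesize one trial.

    Returns ``(spec, cue_waveform, mixture_waveform, label)``.  The cue and
    mixture are stereo, ``cfg.clip_duration`` long, and RMS-normalized to
    ``cfg.mixture_rms`` (the cue is all zeros in silent-cue scenes).  The
    label is the target word overlapping the 1-second mark of the excerpt.
    """
    plan = plan_scene(cfg, rng)
    talker_map = {t.talker_id: t for t in cfg.talkers}
    target_talker = talker_map[plan.target_talker_id]
    target = synth_utterance(target_talker, plan.target_words, cfg.clip_duration,
                             rng, cfg.sample_rate, cfg.cap_hz)
    cue_utt = synth_utterance(target_talker, plan.cue_words, cfg.clip_duration,
                              rng, cfg.sample_rate, cfg.cap_hz)
    if cfg.augment:
        target = augment_signal(target, rng, "timeshift", excerpt=cfg.excerpt)
        which = target if rng.random() < 0.5 else cue_utt
        out = augment_signal(which, rng, "bandpass",
                             low_cut_range=cfg.bandpass_low_range,
                             high_cut_range=cfg.bandpass_high_range)
        if which is target:
            target = out
        else:
            cue_utt = out
    label = middle_word(target, cfg.excerpt)

    target_r = _render_or_diotic(target.waveform, plan.target_location)
    cue_r = _render_or_diotic(cue_utt.waveform, plan.target_location)

    if plan.silence_cue:
        # single-talker scene: target alone, silent cue
        mix = Waveform(target_r.samples.copy(), cfg.sample_rate)
        m_rms = mix.rms
        if m_rms > 0:
            mix = Waveform(mix.samples / m_rms * cfg.mixture_rms, cfg.sample_rate)
        cue_w = Waveform(np.zeros_like(cue_r.samples), cfg.sample_rate)
        spec = SceneSpec(cue=None, target=target, distractors=[], snr=np.inf,
                         co_located=plan.co_located, silence_cue=True, label=label,
                         target_render=target_r, distractor_render=None)
        return spec, cue_w, mix, label

    distractor_sum = np.zeros_like(target_r.samples)
    distractors: list[tuple[object, SourceLocation | None, float]] = []
    locs = plan.distractor_locations or [None] * plan.n_distractors
    sources: list[object] = []
    for tid in plan.distractor_talker_ids:
        d_utt = synth_utterance(talker_map[tid], _draw_words(cfg, rng),
                                cfg.clip_duration, rng, cfg.sample_rate, cfg.cap_hz)
        sources.append(d_utt)
    for kind in plan.distractor_noise_kinds:
        ref = target.waveform if kind == "speech-shaped" else None
        sources.append(shaped_noise(kind, cfg.clip_duration, rng, reference=ref,
                                    sample_rate=cfg.sample_rate))
    for src, loc, lvl in zip(sources, locs, plan.distractor_levels_db):
        w = src.waveform if isinstance(src, Utterance) else src
        w = set_level(w, lvl)
        r = _render_or_diotic(w, loc)
        distractor_sum += r.samples
        distractors.append((src, loc, lvl))
    d_wave = Waveform(distractor_sum, cfg.sample_rate)
    mix, _scaled = mix_at_snr(target_r, d_wave, plan.snr_db,
                              normalize_rms=cfg.mixture_rms, return_components=True)
    c_rms = cue_r.rms
    if c_rms > 0:
        cue_r = Waveform(cue_r.samples / c_rms * cfg.mixture_rms, cfg.sample_rate)
    spec = SceneSpec(cue=cue_utt, target=target, distractors=distractors,
                     snr=plan.snr_db, co_located=plan.co_located, silence_cue=False,
                     label=label, target_render=target_r, distractor_render=d_wave)
    return spec, cue_r, mix, label


# --------------------------------------------------------------------------
# Corpus balancing
# --------------------------------------------------------------------------

def balance_corpus(examples: Sequence, max_per_class: int,
                   class_key: Callable, group_key: Callable | None = None,
                   quota: int | None = None,
                   rng: np.random.Generator | None = None) -> list:
    """Cap, upsample, and group-balance a labeled example list.

    Per-class counts are capped at ``max_per_class`` (random subsample),
    every class is then resampled with replacement to ``quota`` examples
    (default: ``max_per_class``), and finally, if ``group_key`` is given,
    group counts are equalized by downsampling every group to the minimum
    group size.  Classes with zero examples are reported and excluded.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if quota is None:
        quota = max_per_class
    by_class: dict = {}
    for ex in examples:
        by_class.setdefault(class_key(ex), []).append(ex)
    balanced: list = []
    for cls in sorted(by_class, key=str):
        items = by_class[cls]
        if not items:
            continue
        if len(items) > max_per_class:
            idx = rng.choice(len(items), size=max_per_class, replace=False)
            items = [items[i] for i in idx]
        idx = rng.choice(len(items), size=quota, replace=True)
        balanced.extend(items[i] for i in idx)
    if group_key is None:
        return balanced
    by_group: dict = {}
    for ex in balanced:
        by_group.setdefault(group_key(ex), []).append(ex)
    n_min = min(len(v) for v in by_group.values())
    out: list = []
    for grp in sorted(by_group, key=str):
        items = by_group[grp]
        if len(items) > n_min:
            idx = rng.choice(len(items), size=n_min, replace=False)
            items = [items[i] for i in idx]
        out.extend(items)
    return out
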