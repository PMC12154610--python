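"""Synthetic talkers, stimulus manipulations, levels, scene assembly."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import freqz

from gainlisten.periphery import Waveform
from gainlisten.scenes import (
    SceneConfig,
    assemble_scene,
    augment_signal,
    balance_corpus,
    jitter_harmonics,
    make_talker,
    make_toy_corpus,
    measure_level,
    middle_word,
    mix_at_snr,
    plan_scene,
    sample_jitter_pattern,
    set_level,
    shaped_noise,
    synth_utterance,
    whisper_filter,
    whisper_transform,
)

SR = 8000.0


@pytest.fixture(scope="module")
def talker():
    return make_talker("t0", "B", np.random.default_rng(0))


@pytest.fixture(scope="module")
def utterance(talker):
    rng = np.random.default_rng(1)
    return synth_utterance(talker, ["word00", "word01", "word02", "word03", "word04"],
                           2.5, rng, sample_rate=SR, cap_hz=3500.0)


class TestSynthUtterance:
    def test_spectral_peaks_at_harmonics(self, talker, utterance):
        """Oracle: peak-picking on the magnitude spectrum finds components
        at integer multiples of f0 within 1 Hz."""
        x = utterance.waveform.samples[0]
        n = len(x)
        mag = np.abs(np.fft.rfft(x * np.hanning(n)))
        freqs = np.fft.rfftfreq(n, 1.0 / SR)
        f0 = talker.f0
        for k in range(1, 6):
            lo, hi = np.searchsorted(freqs, [k * f0 - 30.0, k * f0 + 30.0])
            peak = freqs[lo + np.argmax(mag[lo:hi])]
            assert abs(peak - k * f0) < 1.0

    def test_deterministic_given_seed(self, talker):
        words = ["word00", "word01", "word02"]
        u1 = synth_utterance(talker, words, 1.5, np.random.default_rng(9), SR)
        u2 = synth_utterance(talker, words, 1.5, np.random.default_rng(9), SR)
        assert np.array_equal(u1.waveform.samples, u2.waveform.samples)

    def test_distinct_talkers_distinct_waveforms(self):
        rng = np.random.default_rng(3)
        t1 = make_talker("a", "A", rng)
        t2 = make_talker("b", "B", rng)
        words = ["word00", "word01"]
        u1 = synth_utterance(t1, words, 1.0, np.random.default_rng(4), SR)
        u2 = synth_utterance(t2, words, 1.0, np.random.default_rng(4), SR)
        assert not np.allclose(u1.waveform.samples, u2.waveform.samples)

    def test_empty_inputs_rejected(self, talker):
        with pytest.raises(ValueError):
            synth_utterance(talker, [], 1.0, np.random.default_rng(0), SR)
        with pytest.raises(ValueError):
            synth_utterance(talker, ["word00"], 0.0, np.random.default_rng(0), SR)

    def test_middle_word_is_label(self, utterance):
        # 5 words tiling 2.5 s: the third word spans [1.0, 1.5], and the
        # 1-second mark of the middle 2-s excerpt falls at t=1.25 s
        assert middle_word(utterance, excerpt=2.0) == "word02"


class TestJitterHarmonics:
    def test_zero_shift_is_identity(self, utterance):
        out = jitter_harmonics(utterance, max_shift=0.0)
        assert np.array_equal(out.waveform.samples, utterance.waveform.samples)

    def test_spacing_constraint_satisfied(self, talker):
        """All adjacent component spacings stay at or above 30 Hz."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            jit = sample_jitter_pattern(talker, rng, 0.30, 30.0,
                                        sample_rate=SR, cap_hz=3500.0)
            n = len(jit) + 1
            freqs = np.arange(1, n + 1) * talker.f0
            freqs = freqs + np.concatenate([[0.0], jit]) * talker.f0
            assert np.min(np.diff(np.sort(freqs))) >= 30.0

    def test_pattern_reapplication_reproduces_frequencies(self, talker):
        """Oracle: frequency tracks of two same-f0 utterances under the same
        stored pattern coincide."""
        rng = np.random.default_rng(12)
        u1 = synth_utterance(talker, ["word00"], 2.0, rng, SR, cap_hz=3500.0)
        u2 = synth_utterance(talker, ["word00"], 2.0, rng, SR, cap_hz=3500.0)
        pat = sample_jitter_pattern(talker, rng, sample_rate=SR, cap_hz=3500.0)
        j1 = jitter_harmonics(u1, pattern=pat)
        j2 = jitter_harmonics(u2, pattern=pat)

        def peaks(u):
            x = u.waveform.samples[0]
            mag = np.abs(np.fft.rfft(x * np.hanning(len(x))))
            freqs = np.fft.rfftfreq(len(x), 1.0 / SR)
            f = np.arange(1, len(pat) + 2, dtype=float) * talker.f0
            f[1:] += pat * talker.f0
            out = []
            for fk in f[:6]:
                lo, hi = np.searchsorted(freqs, [fk - 25, fk + 25])
                out.append(freqs[lo + np.argmax(mag[lo:hi])])
            return np.array(out)

        assert np.allclose(peaks(j1), peaks(j2), atol=1.0)
        assert j1.harmonicity == "inharmonic"

    def test_infeasible_constraint_raises(self):
        low = make_talker("lo", "A", np.random.default_rng(0))
        low.f0 = 80.0
        with pytest.raises(ValueError, match="infeasible"):
            # (1 - 2*0.45) * 80 = 8 Hz < required 30 Hz spacing
            sample_jitter_pattern(low, np.random.default_rng(1), max_shift=0.45,
                                  min_spacing=30.0, sample_rate=SR)


class TestWhisper:
    def test_filter_zeros_shrunk_to_0p95(self):
        b, a = whisper_filter(44100.0)
        zeros = np.sort_complex(np.roots(b))
        assert np.allclose(zeros, 0.95, atol=1e-6)  # double zero, real axis

    def test_dc_gain_positive(self):
        b, a = whisper_filter(44100.0)
        w, h = freqz(b, a, worN=[0.0], fs=44100.0)
        assert np.abs(h[0]) > 0.0

    def test_magnitude_monotone_100hz_to_4khz(self):
        """Oracle: frequency-response sweep is nondecreasing over the band."""
        b, a = whisper_filter(44100.0)
        w, h = freqz(b, a, worN=np.linspace(100.0, 4000.0, 400), fs=44100.0)
        mag = np.abs(h)
        assert np.all(np.diff(mag) >= -1e-4 * mag.max())

    def test_transform_preserves_structure(self, utterance):
        out = whisper_transform(utterance, np.random.default_rng(5))
        assert out.harmonicity == "whispered"
        assert out.word_boundaries == utterance.word_boundaries
        assert out.waveform.samples.shape == utterance.waveform.samples.shape
        # excitation is noise: waveform decorrelated from the harmonic original
        c = np.corrcoef(out.waveform.samples[0], utterance.waveform.samples[0])[0, 1]
        assert abs(c) < 0.2


class TestShapedNoise:
    def test_speech_shaped_matches_reference_spectrum(self, utterance):
        """Oracle: third-octave band energies match the reference within 3 dB
        (expected spectrum estimated by averaging 10 realizations)."""
        rng = np.random.default_rng(8)
        ref = utterance.waveform.samples[0]
        px = None
        for _ in range(10):
            noise = shaped_noise("speech-shaped", 2.5, rng,
                                 reference=utterance.waveform)
            p = np.abs(np.fft.rfft(noise.samples[0])) ** 2
            px = p if px is None else px + p
        freqs = np.fft.rfftfreq(len(ref), 1.0 / SR)
        pr = np.abs(np.fft.rfft(ref)) ** 2 * 10.0
        centers = 250.0 * 2.0 ** (np.arange(0, 11) / 3.0)
        ratios = []
        for fc in centers:
            if fc * 2 ** (1 / 6) > SR / 2:
                break
            band = (freqs >= fc * 2 ** (-1 / 6)) & (freqs < fc * 2 ** (1 / 6))
            if band.sum() < 8:
                continue
            ratios.append(10 * np.log10(px[band].sum() / pr[band].sum()))
        ratios = np.array(ratios) - np.mean(ratios)
        assert np.all(np.abs(ratios) < 3.0)

    def test_pink_noise_flat_per_octave(self):
        """Oracle: octave-band energies constant within 1.5 dB, 100 Hz-4 kHz."""
        noise = shaped_noise("pink", 4.0, np.random.default_rng(9),
                             sample_rate=16000.0)
        x = noise.samples[0]
        freqs = np.fft.rfftfreq(len(x), 1.0 / 16000.0)
        p = np.abs(np.fft.rfft(x)) ** 2
        bands = [(100, 200), (200, 400), (400, 800), (800, 1600), (1600, 3200)]
        energies = [10 * np.log10(p[(freqs >= lo) & (freqs < hi)].sum())
                    for lo, hi in bands]
        energies = np.array(energies) - np.mean(energies)
        assert np.all(np.abs(energies) < 1.5)

    def test_duration_rate_and_rms_exact(self):
        noise = shaped_noise("pink", 1.25, np.random.default_rng(0),
                             sample_rate=SR, rms=0.02)
        assert noise.samples.shape[1] == round(1.25 * SR)
        assert noise.sample_rate == SR
        assert noise.rms == pytest.approx(0.02, rel=1e-9)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            shaped_noise("speech-shaped", 1.0, np.random.default_rng(0))


class TestLevelsAndSnr:
    def test_independent_sources_sum_to_65db(self):
        """Two uncorrelated sources at 61.99 dB SPL sum to 65.0 +/- 0.1 dB."""
        rng = np.random.default_rng(0)
        sums = []
        for _ in range(20):
            a = set_level(Waveform(rng.standard_normal(int(SR)), SR), 61.99)
            b = set_level(Waveform(rng.standard_normal(int(SR)), SR), 61.99)
            sums.append(measure_level(Waveform(a.samples + b.samples, SR)))
        assert abs(np.mean(sums) - 65.0) < 0.1

    def test_doubling_amplitude_adds_6db(self):
        w = set_level(Waveform(np.sin(np.arange(8000) / 5.0), SR), 60.0)
        assert measure_level(Waveform(w.samples * 2, SR)) == pytest.approx(
            60.0 + 20 * np.log10(2), abs=1e-9)

    def test_set_level_idempotent(self):
        w = Waveform(np.random.default_rng(1).standard_normal(4000), SR)
        w1 = set_level(w, 55.0)
        w2 = set_level(w1, 55.0)
        assert np.allclose(w1.samples, w2.samples, atol=1e-12)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            set_level(Waveform(np.zeros(100), SR), 60.0)

    @pytest.mark.parametrize("snr", [0.0, 10.0, -7.5])
    def test_snr_scaling(self, snr):
        rng = np.random.default_rng(2)
        t = Waveform(rng.standard_normal(4000), SR)
        d = Waveform(rng.standard_normal(4000), SR)
        mix, scaled = mix_at_snr(t, d, snr, return_components=True)
        assert 20 * np.log10(scaled.rms / d.rms) == pytest.approx(snr, abs=1e-6)
        assert mix.rms == pytest.approx(0.02, abs=1e-9)

    def test_silent_distractor_rejected(self):
        t = Waveform(np.ones(100), SR)
        with pytest.raises(ValueError, match="[Ss]ilent"):
            mix_at_snr(t, Waveform(np.zeros(100), SR), 0.0)


class _ZeroShiftRng:
    """Stub generator that always draws a zero-magnitude shift."""

    def uniform(self, lo, hi):
        return 0.0

    def random(self):
        return 0.3


class TestAugmentations:
    def test_bandpass_application_frequency(self, talker):
        """Distributional oracle: the filter applies on half of draws."""
        u = synth_utterance(talker, ["word00"], 0.2, np.random.default_rng(0), SR)
        rng = np.random.default_rng(33)
        n = 4000
        applied = sum(
            not np.array_equal(
                augment_signal(u, rng, "bandpass",
                               high_cut_range=(1500.0, 3000.0)).waveform.samples,
                u.waveform.samples)
            for _ in range(n)
        )
        ci = stats.binomtest(applied, n, 0.5).proportion_ci(0.99)
        assert ci.low <= 0.5 <= ci.high

    def test_timeshift_keeps_label_on_mark(self, talker):
        words = [f"word{i:02d}" for i in range(5)]
        u = synth_utterance(talker, words, 2.5, np.random.default_rng(0), SR)
        rng = np.random.default_rng(44)
        for _ in range(50):
            shifted = augment_signal(u, rng, "timeshift")
            assert middle_word(shifted, excerpt=2.0) == middle_word(u, excerpt=2.0)

    def test_zero_magnitude_shift_is_identity(self, talker):
        u = synth_utterance(talker, ["word00", "word01", "word02"], 1.5,
                            np.random.default_rng(0), SR)
        out = augment_signal(u, _ZeroShiftRng(), "timeshift", excerpt=1.0)
        assert np.array_equal(out.waveform.samples, u.waveform.samples)
        assert out.word_boundaries == u.word_boundaries


@pytest.fixture(scope="module")
def cfg():
    vocab, talkers = make_toy_corpus(8, 4, seed=0)
    return SceneConfig(vocabulary=vocab, talkers=talkers, sample_rate=SR,
                       cap_hz=3500.0, bandpass_high_range=(1500.0, 3000.0))


class TestSceneAssembly:
    def test_sampling_distributions(self, cfg):
        """10,000 seeded draws: distractor counts uniform on 1..6 (chi^2),
        co-location ~0.5, silent-cue ~0.1."""
        rng = np.random.default_rng(7)
        plans = [plan_scene(cfg, rng) for _ in range(10000)]
        counts = np.bincount([p.n_distractors for p in plans], minlength=7)[1:7]
        assert stats.chisquare(counts).pvalue > 0.01
        co = np.mean([p.co_located for p in plans])
        ci = stats.binomtest(int(co * 10000), 10000, 0.5).proportion_ci(0.99)
        assert ci.low <= 0.5 <= ci.high
        sil = np.mean([p.silence_cue for p in plans])
        ci = stats.binomtest(int(sil * 10000), 10000, 0.1).proportion_ci(0.99)
        assert ci.low <= 0.1 <= ci.high
        # speech/non-speech split covers the full range
        assert {p.n_speech for p in plans} >= {0, 1, 2, 3, 4, 5, 6}

    def test_plan_reproducible(self, cfg):
        p1 = plan_scene(cfg, np.random.default_rng(5))
        p2 = plan_scene(cfg, np.random.default_rng(5))
        assert p1 == p2

    def test_cue_colocated_with_target(self, cfg):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = plan_scene(cfg, rng)
            # cue and target share the single stored location by construction
            assert p.target_location is not None
            if p.co_located:
                for loc in p.distractor_locations:
                    assert loc == p.target_location

    def test_assembled_scene_contract(self, cfg):
        rng = np.random.default_rng(9)
        for _ in range(8):
            spec, cue, mix, label = assemble_scene(cfg, rng)
            assert mix.n_channels == 2
            assert mix.rms == pytest.approx(cfg.mixture_rms, rel=1e-6)
            assert label in cfg.vocabulary
            assert label == middle_word(spec.target, cfg.excerpt)
            if spec.silence_cue:
                assert np.all(cue.samples == 0.0)
                assert spec.distractors == []
            else:
                assert cue.rms == pytest.approx(cfg.mixture_rms, rel=1e-6)

    def test_mixture_linearity_audit(self, cfg):
        """The mixture equals the scaled sum of its rendered components."""
        rng = np.random.default_rng(10)
        spec, cue, mix, label = None, None, None, None
        while spec is None or spec.silence_cue:
            spec, cue, mix, label = assemble_scene(cfg, rng)
        t = spec.target_render.samples
        d = spec.distractor_render.samples
        t_rms = np.sqrt(np.mean(t**2))
        d_rms = np.sqrt(np.mean(d**2))
        scale = d_rms / t_rms * 10 ** (spec.snr / 20.0)
        raw = t * scale + d
        raw = raw / np.sqrt(np.mean(raw**2)) * cfg.mixture_rms
        assert np.allclose(mix.samples, raw, atol=1e-12)


class TestLevelProperties:
    """Invariants of the level/SNR arithmetic over arbitrary settings."""

    from hypothesis import given, settings, strategies as st

    @given(level=st.floats(40.0, 80.0), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_set_level_hits_target_and_is_idempotent(self, level, seed):
        w = Waveform(np.random.default_rng(seed).standard_normal(2000), SR)
        out = set_level(w, level)
        assert measure_level(out) == pytest.approx(level, abs=1e-9)
        again = set_level(out, level)
        assert np.allclose(again.samples, out.samples, atol=1e-12)

    @given(snr=st.floats(-10.0, 10.0), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mix_at_snr_rms_contract(self, snr, seed):
        rng = np.random.default_rng(seed)
        t = Waveform(rng.standard_normal(2000), SR)
        d = Waveform(rng.standard_normal(2000), SR)
        mix, scaled = mix_at_snr(t, d, snr, return_components=True)
        assert 20 * np.log10(scaled.rms / d.rms) == pytest.approx(snr, abs=1e-6)
        assert mix.rms == pytest.approx(0.02, abs=1e-9)


class TestBalanceCorpus:
    def test_cap_and_quota(self):
        examples = [("a", i) for i in range(7)] + [("b", i) for i in range(3)]
        out = balance_corpus(examples, max_per_class=5, class_key=lambda e: e[0],
                             rng=np.random.default_rng(0))
        counts = {c: sum(1 for e in out if e[0] == c) for c in "ab"}
        assert counts == {"a": 5, "b": 5}

    def test_group_counts_equal_after_balancing(self):
        rng = np.random.default_rng(1)
        examples = [(f"w{i % 4}", "F" if i % 5 < 1 else "M", i) for i in range(100)]
        out = balance_corpus(examples, max_per_class=20,
                             class_key=lambda e: e[0], group_key=lambda e: e[1],
                             rng=rng)
        groups = {g: sum(1 for e in out if e[1] == g) for g in "FM"}
        assert groups["F"] == groups["M"]

    def test_deterministic_under_seed(self):
        examples = [("a", i) for i in range(10)] + [("b", i) for i in range(2)]
        o1 = balance_corpus(examples, 5, class_key=lambda e: e[0],
                            rng=np.random.default_rng(3))
        o2 = balance_corpus(examples, 5, class_key=lambda e: e[0],
                            rng=np.random.default_rng(3))
        assert o1 == o2
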