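"""Optimization and evaluation harness for the attention networks.

Networks are trained with AdamW on softmax cross-entropy over the middle
word of the cued talker, with the gain-function parameters and the
convolutional features optimized jointly.  The cochlear front-end is fixed
and never updated.  Training stops when validation accuracy stops
improving.

The module also provides desk-scale "toy" study conditions — a small
vocabulary, two synthetic talkers, diotic presentation, a single speech
distractor at 0 dB SNR — together with dataset builders that precompute
cochleagrams, cue-swap evaluation trials (the cue drawn from the distractor
talker), matched target/distractor/mixture triplets for the locus-of-
selection analysis, and condition-grid enumeration for factorial
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scenes
from ._tensor import softmax_cross_entropy
from .gainnet import GainNet, _ForwardContext, _forward_logits, \
    init_network, toy_network_spec
from .periphery import FilterBank, Waveform, cochleagram, make_filterbank
from .scenes import SceneConfig, assemble_scene, make_toy_corpus, middle_word, \
    mix_at_snr, synth_utterance

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalTrial",
    "EvalResult",
    "TrainingDiverged",
    "train_model",
    "evaluate_model",
    "enumerate_condition_grid",
    "toy_periphery",
    "toy_scene_config",
    "ToyDataset",
    "make_toy_dataset",
    "make_cue_swap_trials",
    "make_selection_trials",
    "train_toy_model",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during optimization."""


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults are the full-scale reference values (AdamW, learning rate
    5e-5, batch 288, dropout 0.5); desk-scale runs override them.
    """

    learning_rate: float = 5e-5
    batch_size: int = 288
    optimizer: str = "adamw"
    weight_decay: float = 0.01
    max_epochs: int = 10
    seed: int = 0
    dropout_p: float = 0.5
    patience: int = 3  # epochs without validation improvement before stopping
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adamw":
            raise ValueError("only the adamw optimizer is supported")


@dataclass
class TrainResult:
    loss_trace: list[float]
    val_accuracy: list[float]
    n_epochs: int
    stopped_early: bool


@dataclass
class EvalTrial:
    """One evaluation trial: cochleagram inputs plus scoring metadata."""

    scene_id: int
    cue: np.ndarray
    mixture: np.ndarray
    target_words: list[str]
    distractor_words: list[str]
    label: str
    condition: dict = field(default_factory=dict)


@dataclass
class EvalResult:
    """Per-trial evaluation table plus the full probability vectors."""

    table: pd.DataFrame
    probabilities: np.ndarray  # (n_trials, n_classes); NaN rows on error


# --------------------------------------------------------------------------
# AdamW
# --------------------------------------------------------------------------

class _AdamW:
    """Decoupled-weight-decay Adam on a name -> array/scalar parameter set."""

    def __init__(self, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict, decay_names: set[str]) -> dict:
        """Update arrays in place; return new values for scalar params."""
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        scalar_updates: dict[str, float] = {}
        for name, g in grads.items():
            if g is None:
                continue
            g = np.asarray(g, dtype=np.float64)
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g**2
            update = (self.m[name] / b1t) / (np.sqrt(self.v[name] / b2t) + self.eps)
            if name in params:  # array parameter, update in place
                p = params[name]
                decay = self.wd * p if name in decay_names else 0.0
                p -= (self.lr * (update + decay)).astype(p.dtype)
            else:  # scalar (gain) parameter
                scalar_updates[name] = float(self.lr * update)
        return scalar_updates


def _apply_gain_updates(net: GainNet, updates: dict[str, float]) -> None:
    for name, delta in updates.items():
        stage, theta = name.split(".")
        g = net.gains[int(stage[4:])]
        setattr(g, theta, float(getattr(g, theta)) - delta)


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

def train_model(net: GainNet, dataset, cfg: TrainConfig) -> TrainResult:
    """Train a network on (cues, mixtures, labels) arrays.

    ``dataset`` is a tuple of arrays: cues (N,C,F,T), mixtures (N,C,F,T),
    integer labels (N,).  A validation split is held out deterministically;
    training stops after ``cfg.patience`` epochs without validation
    improvement or at ``cfg.max_epochs``.
    """
    cues, mixes, labels = dataset
    cues = np.asarray(cues, dtype=np.float32)
    mixes = np.asarray(mixes, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    net.spec.dropout_p = cfg.dropout_p
    opt = _AdamW(cfg.learning_rate, cfg.weight_decay)
    decay_names = {k for k in net.parameters() if k.endswith((".kernels", ".w"))}
    loss_trace: list[float] = []
    val_acc: list[float] = []
    best, since_best = -np.inf, 0
    stopped_early = False
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            ctx = _ForwardContext(net, trainable=True)
            logits = _forward_logits(ctx, cues[idx], mixes[idx],
                                     train_mode=True, rng=rng)
            loss, _ = softmax_cross_entropy(logits, labels[idx])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            loss_trace.append(lval)
            loss.backward()
            scalars = opt.step(net.parameters(), ctx.grads(), decay_names)
            _apply_gain_updates(net, scalars)
        acc = _accuracy(net, cues[val_idx], mixes[val_idx], labels[val_idx],
                        cfg.batch_size)
        val_acc.append(acc)
        if acc > best + 1e-9:
            best, since_best = acc, 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                stopped_early = True
                break
    return TrainResult(loss_trace=loss_trace, val_accuracy=val_acc,
                       n_epochs=len(val_acc), stopped_early=stopped_early)


def _batched_probs(net: GainNet, cues: np.ndarray, mixes: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    from ._tensor import softmax

    out = []
    for start in range(0, len(cues), batch_size):
        ctx = _ForwardContext(net, trainable=False)
        logits = _forward_logits(ctx, cues[start:start + batch_size],
                                 mixes[start:start + batch_size],
                                 train_mode=False, rng=None)
        out.append(softmax(logits.data, axis=1))
    return np.concatenate(out, axis=0)


def _accuracy(net, cues, mixes, labels, batch_size) -> float:
    probs = _batched_probs(net, cues, mixes, batch_size)
    return float(np.mean(np.argmax(probs, axis=1) == labels))


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def evaluate_model(net: GainNet, trials: list[EvalTrial],
                   vocabulary: list[str]) -> EvalResult:
    """Deterministic evaluation-mode forward passes over a trial list.

    Responses are the argmax word (ties resolve to the lowest class index);
    correct/confusion flags are scored against the trial transcripts with
    :func:`gainlisten.analysis.score_response`.  Per-trial shape errors are
    recorded (``error`` column) without aborting the run.
    """
    from .analysis import score_response

    rows = []
    probs_out = np.full((len(trials), net.spec.n_classes), np.nan)
    for i, tr in enumerate(trials):
        rec = {"scene_id": tr.scene_id, "label": tr.label, "error": None}
        rec.update(tr.condition)
        try:
            p = _batched_probs(net, tr.cue[None], tr.mixture[None])[0]
            probs_out[i] = p
            response = vocabulary[int(np.argmax(p))]
            correct, confusion = score_response(
                response, tr.target_words, tr.distractor_words, vocabulary)
            rec.update(response=response, correct=correct, confusion=confusion)
        except (ValueError, IndexError) as e:
            rec.update(response=None, correct=False, confusion=False, error=str(e))
        rows.append(rec)
    return EvalResult(table=pd.DataFrame(rows), probabilities=probs_out)


def enumerate_condition_grid(target_ids, distractor_types, snrs,
                             include_no_distractor: bool = True) -> pd.DataFrame:
    """Full factorial trial grid: targets x distractor types x SNRs, plus
    one no-distractor trial per target when requested."""
    rows = [
        {"target_id": t, "distractor_type": d, "snr": s}
        for t in target_ids for d in distractor_types for s in snrs
    ]
    if include_no_distractor:
        rows.extend(
            {"target_id": t, "distractor_type": "none", "snr": np.inf}
            for t in target_ids
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Desk-scale (toy) study conditions
# --------------------------------------------------------------------------

TOY_SAMPLE_RATE = 4000.0
TOY_N_CHANNELS = 16
TOY_F_LO = 50.0
TOY_F_HI = 1800.0
TOY_OUT_RATE = 125.0
TOY_EXCERPT = 2.0


def toy_periphery() -> tuple[FilterBank, dict]:
    """Scaled-down cochlear stage for desk-scale experiments."""
    fb = make_filterbank(TOY_N_CHANNELS, TOY_F_LO, TOY_F_HI, TOY_SAMPLE_RATE)
    kwargs = dict(out_rate=TOY_OUT_RATE, excerpt=TOY_EXCERPT)
    return fb, kwargs


def toy_scene_config(vocabulary, talkers) -> SceneConfig:
    """Two-talker diotic selection task: one speech distractor at 0 dB SNR."""
    return SceneConfig(
        vocabulary=list(vocabulary), talkers=list(talkers),
        sample_rate=TOY_SAMPLE_RATE, cap_hz=TOY_F_HI,
        n_distractor_range=(1, 1), n_speech_range=(1, 1),
        snr_range_db=(0.0, 0.0), spatialize=False, augment=False,
        silence_cue_prob=0.1,
    )


@dataclass
class ToyDataset:
    cues: np.ndarray  # (N, 2, F, T) cochleagrams
    mixtures: np.ndarray
    labels: np.ndarray  # (N,) integer word indices
    vocabulary: list[str]
    meta: list[dict]

    @property
    def input_shape(self) -> tuple[int, int]:
        return self.cues.shape[2], self.cues.shape[3]


def _cg(w: Waveform, fb: FilterBank, kwargs: dict) -> np.ndarray:
    return cochleagram(w.to_stereo(), fb, **kwargs).values.astype(np.float32)


def make_toy_dataset(n_scenes: int = 2000, seed: int = 0,
                     n_words: int = 8, n_talkers: int = 4) -> ToyDataset:
    """Generate the toy selection task and precompute cochleagrams."""
    vocabulary, talkers = make_toy_corpus(n_words, n_talkers, seed=seed)
    cfg = toy_scene_config(vocabulary, talkers)
    fb, kw = toy_periphery()
    rng = np.random.default_rng(seed + 1)
    cues, mixes, labels, meta = [], [], [], []
    for i in range(n_scenes):
        spec, cue_w, mix_w, label = assemble_scene(cfg, rng)
        cues.append(_cg(cue_w, fb, kw))
        mixes.append(_cg(mix_w, fb, kw))
        labels.append(vocabulary.index(label))
        d_words: list[str] = []
        d_talker = None
        for src, _, _ in spec.distractors:
            if hasattr(src, "word_sequence"):
                d_words.extend(src.word_sequence)
                d_talker = src.talker.talker_id
        meta.append({
            "scene_id": i,
            "target_talker": spec.target.talker.talker_id,
            "target_words": list(spec.target.word_sequence),
            "distractor_words": d_words,
            "distractor_talker": d_talker,
            "silence_cue": spec.silence_cue,
        })
    return ToyDataset(cues=np.stack(cues), mixtures=np.stack(mixes),
                      labels=np.asarray(labels), vocabulary=vocabulary, meta=meta)


def _toy_trial_pair(cfg: SceneConfig, talkers, rng, same_class: bool | None = None):
    """One matched trial: target and distractor utterances from different
    talkers, optionally constrained to same/different sex-class pairs."""
    t_idx = int(rng.integers(len(talkers)))
    t_talker = talkers[t_idx]
    pool = [t for i, t in enumerate(talkers) if i != t_idx]
    if same_class is not None:
        match = [t for t in pool if (t.sex_class == t_talker.sex_class) == same_class]
        pool = match or pool
    d_talker = pool[int(rng.integers(len(pool)))]
    t_words = [str(rng.choice(cfg.vocabulary)) for _ in range(cfg.n_words)]
    d_words = [str(rng.choice(cfg.vocabulary)) for _ in range(cfg.n_words)]
    mid = cfg.n_words // 2
    while d_words[mid] == t_words[mid]:
        d_words[mid] = str(rng.choice(cfg.vocabulary))
    target = synth_utterance(t_talker, t_words, cfg.clip_duration, rng,
                             cfg.sample_rate, cfg.cap_hz)
    distractor = synth_utterance(d_talker, d_words, cfg.clip_duration, rng,
                                 cfg.sample_rate, cfg.cap_hz)
    cue_t_words = list(t_words)
    cue_t_words[mid] = str(rng.choice([w for w in cfg.vocabulary if w != t_words[mid]]))
    cue_d_words = list(d_words)
    cue_d_words[mid] = str(rng.choice([w for w in cfg.vocabulary if w != d_words[mid]]))
    cue_t = synth_utterance(t_talker, cue_t_words, cfg.clip_duration, rng,
                            cfg.sample_rate, cfg.cap_hz)
    cue_d = synth_utterance(d_talker, cue_d_words, cfg.clip_duration, rng,
                            cfg.sample_rate, cfg.cap_hz)
    return target, distractor, cue_t, cue_d


def make_cue_swap_trials(n_trials: int, seed: int,
                         vocabulary=None, talkers=None) -> list[dict]:
    """Matched trial pairs for the selection-direction analysis.

    Each record holds cochleagrams for the mixture, a cue from the target
    talker, and a cue from the distractor talker, plus both transcripts.
    """
    if vocabulary is None or talkers is None:
        vocabulary, talkers = make_toy_corpus()
    cfg = toy_scene_config(vocabulary, talkers)
    fb, kw = toy_periphery()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trials):
        target, distractor, cue_t, cue_d = _toy_trial_pair(
            cfg, talkers, rng, same_class=bool(i % 2))
        t_n = scenes.set_level(target.waveform, 65.0)
        d_n = scenes.set_level(distractor.waveform, 65.0)
        mix = mix_at_snr(t_n, d_n, 0.0, normalize_rms=cfg.mixture_rms)
        def norm(w):
            return Waveform(w.samples / max(w.rms, 1e-12) * cfg.mixture_rms,
                            w.sample_rate)
        out.append({
            "scene_id": i,
            "mixture": _cg(mix, fb, kw),
            "cue_target": _cg(norm(cue_t.waveform), fb, kw),
            "cue_distractor": _cg(norm(cue_d.waveform), fb, kw),
            "target_label": middle_word(target, cfg.excerpt),
            "distractor_label": middle_word(distractor, cfg.excerpt),
            "target_words": list(target.word_sequence),
            "distractor_words": list(distractor.word_sequence),
        })
    return out


def make_selection_trials(n_trials: int, seed: int,
                          vocabulary=None, talkers=None, snr: float = 0.0) -> list[tuple]:
    """(cue, target, distractor, mixture) cochleagram tuples for
    :func:`gainlisten.analysis.selection_profile` (diotic, RMS 0.02)."""
    if vocabulary is None or talkers is None:
        vocabulary, talkers = make_toy_corpus()
    cfg = toy_scene_config(vocabulary, talkers)
    fb, kw = toy_periphery()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trials):
        # half same-class, half different-class pairs
        target, distractor, cue_t, _ = _toy_trial_pair(
            cfg, talkers, rng, same_class=bool(i % 2))
        def norm(w):
            return Waveform(w.samples / max(w.rms, 1e-12) * cfg.mixture_rms,
                            w.sample_rate)
        t_n, d_n = norm(target.waveform), norm(distractor.waveform)
        mix = mix_at_snr(t_n, d_n, snr, normalize_rms=cfg.mixture_rms)
        out.append((_cg(norm(cue_t.waveform), fb, kw), _cg(t_n, fb, kw),
                    _cg(d_n, fb, kw), _cg(mix, fb, kw)))
    return out


def train_toy_model(dataset: ToyDataset, seed: int = 0,
                    variant: str = "feature-gain",
                    max_epochs: int = 12,
                    learning_rate: float = 2e-3,
                    batch_size: int = 32) -> tuple[GainNet, TrainResult]:
    """Initialize and train a toy network on a precomputed toy dataset.

    The desk-scale epoch budget is small and validation accuracy can
    plateau for several epochs before the gain path engages, so the run
    uses the full epoch cap rather than the plateau-based stopping rule.
    """
    spec = toy_network_spec(n_classes=len(dataset.vocabulary), variant=variant)
    net = init_network(spec, dataset.input_shape, np.random.default_rng(seed))
    cfg = TrainConfig(learning_rate=learning_rate, batch_size=batch_size,
                      max_epochs=max_epochs, seed=seed, dropout_p=0.5,
                      patience=max_epochs)
    result = train_model(net, (dataset.cues, dataset.mixtures, dataset.labels), cfg)
    return net, result
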