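"""Behavioral scoring, psychometric thresholds, and representational analyses.

Covers the analyses applied identically to human and model responses:
correct/confusion scoring against target and distractor transcripts,
speech-reception-threshold (SRT) estimation from performance-by-SNR curves
via a second-order polynomial fit, a subject-level permutation test for
factorial interactions in threshold tables, aggregate human-model
similarity (RMSE and Pearson r^2, with sign tests across architectures),
and the layer-wise "locus of selection" analysis that correlates a
network's mixture representation with its target-alone and distractor-alone
representations at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gainnet import GainNet, forward_with_activations

__all__ = [
    "ThresholdEstimate",
    "InteractionTestResult",
    "SelectionProfile",
    "score_response",
    "estimate_threshold",
    "interaction_permutation_test",
    "human_model_similarity",
    "selection_profile",
]


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def score_response(response: str, target_words, distractor_words,
                   vocabulary) -> tuple[bool, bool]:
    """Correct/confusion flags for one trial.

    A response is correct iff it matches any in-vocabulary word of the
    target transcript, and a confusion iff it matches any in-vocabulary
    word of the distractor transcript(s).  Both flags can be true (the word
    occurred in both transcripts) or both false.  The same function scores
    human and model reports.
    """
    vocab = set(vocabulary)
    if response not in vocab:
        raise ValueError(f"response {response!r} not in vocabulary")
    correct = response in (set(target_words) & vocab)
    confusion = response in (set(distractor_words) & vocab)
    return correct, confusion


# --------------------------------------------------------------------------
# Speech reception thresholds
# --------------------------------------------------------------------------

@dataclass
class ThresholdEstimate:
    srt: float  # dB SNR at criterion
    criterion: str  # "fraction-of-max" or "absolute-50"
    criterion_level: float  # performance level defining the threshold
    poly_coeffs: np.ndarray  # quadratic fit coefficients (highest power first)
    bootstrap_sd: float | None = None
    n_boot: int = 0
    extrapolated: bool = False


def _crossing(coeffs: np.ndarray, level: float, lo: float, hi: float) -> tuple[float, bool]:
    """SNR where the quadratic crosses `level`, preferring an in-span,
    rising (positive-slope) crossing; falls back to the nearest real root."""
    a, b, c = coeffs
    roots = np.roots([a, b, c - level])
    roots = roots[np.abs(roots.imag) < 1e-9].real
    if roots.size == 0:
        # no real crossing: report the SNR nearest the criterion, flagged
        grid = np.linspace(lo, hi, 201)
        vals = np.polyval(coeffs, grid)
        return float(grid[np.argmin(np.abs(vals - level))]), True
    slopes = 2 * a * roots + b
    in_span = (roots >= lo - 1e-9) & (roots <= hi + 1e-9)
    rising = slopes > 0
    for mask in (in_span & rising, in_span, rising):
        if mask.any():
            cand = roots[mask]
            mid = 0.5 * (lo + hi)
            pick = float(cand[np.argmin(np.abs(cand - mid))])
            return pick, not bool((in_span & (roots == pick)).any())
    nearest = float(roots[np.argmin(np.minimum(np.abs(roots - lo), np.abs(roots - hi)))])
    return nearest, True


def estimate_threshold(snr_levels, performance, criterion: str = "fraction-of-max",
                       subject_matrix: np.ndarray | None = None,
                       n_boot: int = 0,
                       rng: np.random.Generator | None = None) -> ThresholdEstimate:
    """Fit performance-by-SNR with a quadratic and solve for the criterion SNR.

    ``criterion`` is either ``"fraction-of-max"`` (50% of the maximum of
    the measured curve) or ``"absolute-50"`` (50% correct).  If a
    (subjects x SNRs) ``subject_matrix`` is given, the fit uses the mean
    across subjects and the bootstrap resamples subjects.
    """
    snr = np.asarray(snr_levels, dtype=float)
    if snr.size < 3:
        raise ValueError("need at least 3 SNR levels")
    order = np.argsort(snr)
    snr = snr[order]
    if subject_matrix is not None:
        mat = np.asarray(subject_matrix, dtype=float)[:, order]
        perf = mat.mean(axis=0)
    else:
        mat = None
        perf = np.asarray(performance, dtype=float)[order]
    if np.any((perf < 0) | (perf > 1)):
        raise ValueError("performance values must be in [0, 1]")

    def fit_one(p):
        coeffs = np.polyfit(snr, p, 2)
        if criterion == "fraction-of-max":
            level = 0.5 * float(np.max(p))
        elif criterion == "absolute-50":
            level = 0.5
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        srt, extrap = _crossing(coeffs, level, snr[0], snr[-1])
        return srt, level, coeffs, extrap

    srt, level, coeffs, extrap = fit_one(perf)
    boot_sd = None
    if n_boot > 0:
        if mat is None:
            raise ValueError("bootstrap requires a subject matrix")
        if rng is None:
            rng = np.random.default_rng(0)
        n_sub = mat.shape[0]
        samples = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n_sub, size=n_sub)
            samples[i], _, _, _ = fit_one(mat[idx].mean(axis=0))
        boot_sd = float(samples.std(ddof=1))
    return ThresholdEstimate(srt=float(srt), criterion=criterion,
                             criterion_level=float(level),
                             poly_coeffs=np.asarray(coeffs),
                             bootstrap_sd=boot_sd, n_boot=n_boot,
                             extrapolated=bool(extrap))


# --------------------------------------------------------------------------
# Permutation test for factorial interactions
# --------------------------------------------------------------------------

@dataclass
class InteractionTestResult:
    observed_statistic: float
    null_samples: np.ndarray
    p_value: float
    n_permutations: int


def _interaction_statistic(table: np.ndarray) -> float:
    """Sum of squared interaction residuals of a (A x B) mean table."""
    mu_a = table.mean(axis=1, keepdims=True)
    mu_b = table.mean(axis=0, keepdims=True)
    mu = table.mean()
    inter = table - mu_a - mu_b + mu
    return float(np.sum(inter**2))


def interaction_permutation_test(thresholds: np.ndarray, n_perm: int = 10000,
                                 rng: np.random.Generator | None = None
                                 ) -> InteractionTestResult:
    """Subject-level permutation test of the A x B interaction.

    ``thresholds`` has shape (subjects, levels_A, levels_B) with no missing
    cells.  The statistic is the sum of squared interaction terms of the
    across-subject mean table; the null is built by independently permuting
    each subject's cell labels.  The p-value uses the add-one convention,
    p = (1 + #{null >= observed}) / (1 + n_perm), and so is never zero.
    """
    data = np.asarray(thresholds, dtype=float)
    if data.ndim != 3:
        raise ValueError("thresholds must be (subjects, A, B)")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing or non-finite cells are not supported")
    if rng is None:
        rng = np.random.default_rng(0)
    n_sub, n_a, n_b = data.shape
    flat = data.reshape(n_sub, n_a * n_b)
    observed = _interaction_statistic(flat.mean(axis=0).reshape(n_a, n_b))
    idx = np.tile(np.arange(n_a * n_b), (n_perm, n_sub, 1))
    idx = rng.permuted(idx, axis=2)
    perm = np.take_along_axis(flat[None, :, :], idx, axis=2)  # (P, S, AB)
    tables = perm.mean(axis=1).reshape(n_perm, n_a, n_b)
    mu_a = tables.mean(axis=2, keepdims=True)
    mu_b = tables.mean(axis=1, keepdims=True)
    mu = tables.mean(axis=(1, 2), keepdims=True)
    null = np.sum((tables - mu_a - mu_b + mu) ** 2, axis=(1, 2))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return InteractionTestResult(observed_statistic=observed, null_samples=null,
                                 p_value=float(p), n_permutations=n_perm)


# --------------------------------------------------------------------------
# Human-model similarity
# --------------------------------------------------------------------------

def human_model_similarity(human_means, model_means,
                           paired_scores: np.ndarray | None = None,
                           reference_scores: np.ndarray | None = None) -> dict:
    """RMSE and squared Pearson correlation between condition-mean vectors.

    With ``paired_scores`` and ``reference_scores`` (per-architecture score
    distributions for an alternative and the reference model), adds a
    two-tailed sign test on the paired differences and their mean.
    Zero-variance inputs yield ``r2 = None``.
    """
    h = np.asarray(human_means, dtype=float)
    m = np.asarray(model_means, dtype=float)
    if h.shape != m.shape:
        raise ValueError("condition vectors must have equal length")
    if h.size < 3:
        raise ValueError("need at least 3 conditions")
    rmse = float(np.sqrt(np.mean((h - m) ** 2)))
    if h.std() == 0 or m.std() == 0:
        r2 = None
    else:
        r2 = float(np.corrcoef(h, m)[0, 1] ** 2)
    out = {"rmse": rmse, "r2": r2}
    if paired_scores is not None:
        a = np.asarray(paired_scores, dtype=float)
        b = np.asarray(reference_scores, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired score vectors must have equal length")
        diffs = a - b
        nz = diffs[diffs != 0]
        if nz.size:
            k = int(np.sum(nz > 0))
            out["sign_test_p"] = float(stats.binomtest(k, nz.size, 0.5).pvalue)
        else:
            out["sign_test_p"] = 1.0
        out["difference_of_means"] = float(diffs.mean())
    return out


# --------------------------------------------------------------------------
# Locus of selection
# --------------------------------------------------------------------------

@dataclass
class SelectionProfile:
    """Per-stage mean correlations of mixture with target / distractor."""

    stage_names: list[str]
    target_mixture_corr: np.ndarray
    distractor_mixture_corr: np.ndarray
    n_pairs: int
    snr: float
    n_excluded: int = 0


def _flat_corr(x: np.ndarray, y: np.ndarray) -> float:
    xf = x.reshape(-1).astype(np.float64)
    yf = y.reshape(-1).astype(np.float64)
    xs, ys = xf.std(), yf.std()
    if xs == 0 or ys == 0:
        return np.nan
    return float(np.corrcoef(xf, yf)[0, 1])


def selection_profile(net: GainNet, trials, snr: float = 0.0) -> SelectionProfile:
    """Layer-wise target/distractor-vs-mixture correlations.

    ``trials`` is a sequence of (cue, target, distractor, mixture)
    cochleagram tuples, all presented diotically and produced with the same
    RMS normalization and SNR.  For each trial the three signals (target
    alone, distractor alone, mixture) are passed through the network with
    the *same* cue (so the same gains apply to all three), and the flattened
    activations are correlated per stage.  Stages with constant activation
    for a pair are excluded from the average, with the count reported.
    """
    sums_t = sums_d = None
    counts_t = counts_d = None
    names: list[str] = []
    n_excluded = 0
    n_pairs = 0
    for cue, target, distractor, mixture in trials:
        acts_m = forward_with_activations(cue, mixture, net)
        acts_t = forward_with_activations(cue, target, net)
        acts_d = forward_with_activations(cue, distractor, net)
        if sums_t is None:
            names = ["cochleagram"] + [f"block{i}" for i in range(len(acts_m) - 1)]
            sums_t = np.zeros(len(acts_m))
            sums_d = np.zeros(len(acts_m))
            counts_t = np.zeros(len(acts_m), dtype=int)
            counts_d = np.zeros(len(acts_m), dtype=int)
        for li, (am, at, ad) in enumerate(zip(acts_m, acts_t, acts_d)):
            ct = _flat_corr(at.activation, am.activation)
            cd = _flat_corr(ad.activation, am.activation)
            if np.isnan(ct):
                n_excluded += 1
            else:
                sums_t[li] += ct
                counts_t[li] += 1
            if np.isnan(cd):
                n_excluded += 1
            else:
                sums_d[li] += cd
                counts_d[li] += 1
        n_pairs += 1
    if sums_t is None:
        raise ValueError("no trials supplied")
    with np.errstate(invalid="ignore"):
        mean_t = sums_t / np.maximum(counts_t, 1)
        mean_d = sums_d / np.maximum(counts_d, 1)
    return SelectionProfile(stage_names=names, target_mixture_corr=mean_t,
                            distractor_mixture_corr=mean_d, n_pairs=n_pairs,
                            snr=snr, n_excluded=n_excluded)
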