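"""Device-quality and agreement metrics, plus cohort nonparametrics.

Per-signal quality: SNR defined on the HR series itself,
``10 log10(mean(HR^2) / var(HR))`` with the population variance as the
noise power.  Paired agreement between the wrist and chest HR on the
shared 4 Hz grid: Pearson/Spearman correlation, MAE/RMSE (chest device as
reference) and Bland-Altman bias with 1.96-sd limits of agreement
(differences taken wrist minus chest).  Cohort comparisons use the
Wilcoxon signed-rank test (exact two-sided p for n <= 25) with Cliff's
delta as the effect size, |delta| >= 0.474 reading as a large effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

BA_MULTIPLIER = 1.96
CLIFF_NEGLIGIBLE = 0.147
CLIFF_SMALL = 0.33
CLIFF_MEDIUM = 0.474
EXACT_WILCOXON_MAX_N = 25


@dataclass
class AgreementReport:
    """Paired-comparison statistics for one subject x scene."""

    snr_ref_db: float
    snr_test_db: float
    pearson_r: float
    spearman_rho: float
    mae_bpm: float
    rmse_bpm: float
    ba_bias_bpm: float
    ba_loa_low_bpm: float
    ba_loa_high_bpm: float
    n_samples: int


def snr_db(values) -> float:
    """HR signal-to-noise ratio: ``10 log10(mean(x^2) / popvar(x))`` in dB.

    A constant series has zero noise power; +inf is returned with a
    warning in that case.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("SNR needs at least 2 values")
    p_signal = float(np.mean(x * x))
    p_noise = float(np.var(x))  # population variance (divide by N)
    if p_noise == 0.0:
        warnings.warn("zero-variance series: SNR is infinite")
        return float("inf")
    return 10.0 * np.log10(p_signal / p_noise)


def correlations(ref, test):
    """Pearson r and Spearman rho between paired series."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape or len(ref) < 3:
        raise ValueError("need equal-length series of at least 3 values")
    if np.var(ref) == 0 or np.var(test) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = float(stats.pearsonr(ref, test).statistic)
    rho = float(stats.spearmanr(ref, test).statistic)
    return r, rho


def error_metrics(ref, test):
    """MAE and RMSE of ``test`` against ``ref``, same units as the input."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape or len(ref) == 0:
        raise ValueError("need equal-length non-empty series")
    d = test - ref
    return float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d * d)))


def bland_altman(ref, test, multiplier: float = BA_MULTIPLIER):
    """Bland-Altman bias and limits of agreement.

    Differences are ``test - ref``; limits are ``bias +/- 1.96 * sd`` with
    the sample sd (n-1).  Returns ``(bias, loa_low, loa_high, points)``
    where ``points`` are (pair mean, difference) rows for plotting.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape or len(ref) < 2:
        raise ValueError("need equal-length series of at least 2 values")
    d = test - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    points = np.column_stack([(ref + test) / 2.0, d])
    return bias, bias - multiplier * sd, bias + multiplier * sd, points


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample p
# ---------------------------------------------------------------------------

def _exact_signed_rank_cdf(ranks: np.ndarray, w: float) -> float:
    """P(W- <= w) over all 2^n equiprobable sign assignments.

    Computed by subset-sum dynamic programming on doubled ranks (average
    ranks from ties are half-integers, so doubling makes them integral).
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r]
    target = int(np.floor(round(2 * w, 6)))
    return float(counts[: target + 1].sum() / 2 ** len(ranks))


def wilcoxon_signed_rank(a, b):
    """Paired Wilcoxon signed-rank test; returns ``(statistic, p_two_sided)``.

    Zero differences are dropped; |differences| are ranked with average
    ties; the statistic is ``min(W+, W-)``.  The two-sided p is exact
    (full sign-pattern enumeration via DP) for n <= 25 and a tie-corrected
    normal approximation beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= EXACT_WILCOXON_MAX_N:
        p = min(1.0, 2.0 * _exact_signed_rank_cdf(ranks, w))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        z = (w - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return w, p


def cliffs_delta(a, b):
    """Cliff's delta effect size and its magnitude label.

    ``delta = (#{a_i > b_j} - #{a_i < b_j}) / (n * m)`` over all cross
    pairs; magnitude thresholds on |delta|: 0.147 / 0.33 / 0.474 separate
    negligible, small, medium and large.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    delta = float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(a) * len(b)))
    mag = abs(delta)
    if mag < CLIFF_NEGLIGIBLE:
        label = "negligible"
    elif mag < CLIFF_SMALL:
        label = "small"
    elif mag < CLIFF_MEDIUM:
        label = "medium"
    else:
        label = "large"
    return delta, label


def agreement_report(ref_hr, test_hr) -> AgreementReport:
    """Full device-agreement report for one paired 4 Hz HR series."""
    ref = np.asarray(ref_hr, dtype=float)
    test = np.asarray(test_hr, dtype=float)
    r, rho = correlations(ref, test)
    mae, rmse = error_metrics(ref, test)
    bias, lo, hi, _ = bland_altman(ref, test)
    return AgreementReport(
        snr_ref_db=snr_db(ref),
        snr_test_db=snr_db(test),
        pearson_r=r,
        spearman_rho=rho,
        mae_bpm=mae,
        rmse_bpm=rmse,
        ba_bias_bpm=bias,
        ba_loa_low_bpm=lo,
        ba_loa_high_bpm=hi,
        n_samples=len(ref),
    )
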