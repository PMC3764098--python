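"""On/off epiallele inference from per-clone methylation counts.

In a haploid nucleus each sequenced clone reports one allele, so the
fraction of "on" (densely methylated) clones estimates the methylated-
epiallele fraction directly. Three layers formalize the on/off pattern:

1. Per-clone classification. An "off" clone retains cytosines only through
   incomplete bisulfite conversion, so retained-C counts of off clones are
   Binomial(n_cytosines, conversion_failure). A clone is called "on" when
   its exact binomial tail probability under that null falls below alpha —
   a statistical-incompatibility rule, not a hard fraction cutoff.
2. Fraction estimation. The on-clone count over total clones, with an exact
   (Clopper–Pearson) 95% confidence interval.
3. Bimodality assessment. A two-component binomial mixture fitted by EM,
   compared against a single binomial by BIC; a preferred two-component fit
   with well-separated retention probabilities is what "on/off" looks like
   in clone data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "CloneCounts",
    "OnOffEstimate",
    "MixtureFit",
    "classify_on_off",
    "estimate_fraction",
    "clopper_pearson",
    "fit_binomial_mixture",
]

# per-clone (n_methylated, n_cytosines) pairs
CloneCounts = Sequence[tuple[int, int]]


@dataclass
class OnOffEstimate:
    n_on: int
    n_total: int
    f_hat: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


@dataclass
class MixtureFit:
    weight_on: float
    p_off: float
    p_on: float
    loglik_1comp: float
    loglik_2comp: float
    bic_1comp: float
    bic_2comp: float
    prefers_two: bool
    posteriors_on: np.ndarray  # per-clone posterior P(on)
    n_iter: int


def _validate_counts(counts: CloneCounts) -> tuple[np.ndarray, np.ndarray]:
    k = np.array([c[0] for c in counts], dtype=int)
    n = np.array([c[1] for c in counts], dtype=int)
    if ((k < 0) | (n < 0) | (k > n)).any():
        raise ValueError("need 0 <= n_methylated <= n_cytosines for every clone")
    return k, n


def classify_on_off(
    counts: CloneCounts,
    conversion_failure: float,
    alpha: float = 0.01,
) -> tuple[list[str], list[float]]:
    """Label each clone "on"/"off" by an exact binomial tail test.

    The null: every retained C is a conversion failure, so n_methylated ~
    Binomial(n_cytosines, conversion_failure). The clone is "on" when
    P(X >= n_methylated) < alpha. ``conversion_failure`` should be
    1 - measured conversion rate from an unmethylated control locus.
    Clones with zero assessable cytosines are labelled "unclassifiable".
    """
    if not 0.0 <= conversion_failure < 1.0:
        raise ValueError(f"conversion_failure must be in [0,1), got {conversion_failure}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    k, n = _validate_counts(counts)
    labels, pvals = [], []
    for ki, ni in zip(k, n):
        if ni == 0:
            labels.append("unclassifiable")
            pvals.append(math.nan)
            continue
        # P(X >= k) under the conversion-failure null
        p_tail = float(stats.binom.sf(ki - 1, ni, conversion_failure))
        labels.append("on" if p_tail < alpha else "off")
        pvals.append(p_tail)
    return labels, pvals


def clopper_pearson(
    n_success: int, n_total: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from the beta quantiles."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_success <= n_total:
        raise ValueError("need 0 <= n_success <= n_total")
    alpha = 1.0 - confidence
    low = (
        0.0
        if n_success == 0
        else float(stats.beta.ppf(alpha / 2, n_success, n_total - n_success + 1))
    )
    high = (
        1.0
        if n_success == n_total
        else float(stats.beta.ppf(1 - alpha / 2, n_success + 1, n_total - n_success))
    )
    return low, high


def estimate_fraction(
    n_on: int | Sequence[str],
    n_total: int | None = None,
    confidence: float = 0.95,
) -> OnOffEstimate:
    """Methylated-epiallele fraction with an exact confidence interval.

    Accepts either (n_on, n_total) counts or a sequence of labels from
    :func:`classify_on_off` (unclassifiable clones are excluded).
    """
    if n_total is None:
        labels = list(n_on)  # type: ignore[arg-type]
        usable = [lab for lab in labels if lab in ("on", "off")]
        n_on = sum(lab == "on" for lab in usable)
        n_total = len(usable)
    n_on = int(n_on)
    n_total = int(n_total)
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    low, high = clopper_pearson(n_on, n_total, confidence)
    return OnOffEstimate(
        n_on=n_on,
        n_total=n_total,
        f_hat=n_on / n_total,
        ci_low=low,
        ci_high=high,
        confidence=confidence,
    )


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: float) -> float:
    return float(stats.binom.logpmf(k, n, p).sum())


_P_EPS = 1e-9


def _em_once(
    k: np.ndarray,
    n: np.ndarray,
    w: float,
    p_lo: float,
    p_hi: float,
    max_iter: int,
    tol: float,
) -> tuple[float, float, float, float, np.ndarray, int]:
    """One EM run; returns (loglik, weight_hi, p_lo, p_hi, resp_hi, n_iter).

    The log-likelihood is non-decreasing across iterations by EM's ascent
    property; a tiny numerical slack is tolerated when asserting it.
    """
    prev_ll = -math.inf
    resp_hi = np.full(k.shape, w)
    it = 0
    for it in range(1, max_iter + 1):
        log_hi = math.log(w) + stats.binom.logpmf(k, n, p_hi)
        log_lo = math.log1p(-w) + stats.binom.logpmf(k, n, p_lo)
        log_norm = logsumexp(np.stack([log_hi, log_lo]), axis=0)
        ll = float(log_norm.sum())
        if ll + 1e-9 < prev_ll:
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        resp_hi = np.exp(log_hi - log_norm)
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll
        w = float(np.clip(resp_hi.mean(), _P_EPS, 1 - _P_EPS))
        denom_hi = float((resp_hi * n).sum())
        denom_lo = float(((1 - resp_hi) * n).sum())
        p_hi = float(np.clip((resp_hi * k).sum() / denom_hi, _P_EPS, 1 - _P_EPS)) if denom_hi > 0 else _P_EPS
        p_lo = float(np.clip(((1 - resp_hi) * k).sum() / denom_lo, _P_EPS, 1 - _P_EPS)) if denom_lo > 0 else _P_EPS
    return prev_ll, w, p_lo, p_hi, resp_hi, it


def fit_binomial_mixture(
    counts: CloneCounts,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    n_restarts: int = 5,
) -> MixtureFit:
    """Two-component binomial mixture over per-clone retained-C counts.

    EM with ``n_restarts`` random starts plus one quantile-based start
    (component retention rates initialized at the means of the lower and
    upper halves of per-clone rates); the best log-likelihood wins, the
    earliest start breaking ties. The two-component model is compared to a
    single binomial by BIC (3 vs 1 free parameters); degenerate data with no
    structure simply prefer one component, which is not an error.

    Components are reported in canonical order p_off <= p_on, with
    ``weight_on`` and posteriors attached to the high-retention component.
    """
    k, n = _validate_counts(counts)
    if len(k) < 2:
        raise ValueError("need at least 2 clones to fit a mixture")
    N = len(k)

    p_pool = float(np.clip(k.sum() / max(n.sum(), 1), _P_EPS, 1 - _P_EPS))
    ll1 = _binom_loglik(k, n, p_pool)
    bic1 = -2 * ll1 + 1 * math.log(N)

    rates = k / np.maximum(n, 1)
    order = np.argsort(rates)
    half = N // 2 or 1
    lo_start = float(np.clip(rates[order[:half]].mean(), _P_EPS, 1 - _P_EPS))
    hi_start = float(np.clip(rates[order[half:]].mean() if N > half else lo_start,
                             _P_EPS, 1 - _P_EPS))
    starts = [(0.5, min(lo_start, hi_start), max(lo_start, hi_start))]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        a, b = np.sort(rng.uniform(_P_EPS, 1 - _P_EPS, size=2))
        starts.append((float(rng.uniform(0.1, 0.9)), float(a), float(b)))

    best = None
    for w0, plo0, phi0 in starts:
        ll, w, plo, phi, resp, n_iter = _em_once(k, n, w0, plo0, phi0, max_iter, tol)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, w, plo, phi, resp, n_iter)
    ll2, w_hi, p_lo, p_hi, resp_hi, n_iter = best

    # canonical ordering: the "on" component is the high-retention one
    if p_lo > p_hi:
        p_lo, p_hi = p_hi, p_lo
        w_hi = 1 - w_hi
        resp_hi = 1 - resp_hi

    bic2 = -2 * ll2 + 3 * math.log(N)
    return MixtureFit(
        weight_on=w_hi,
        p_off=p_lo,
        p_on=p_hi,
        loglik_1comp=ll1,
        loglik_2comp=ll2,
        bic_1comp=bic1,
        bic_2comp=bic2,
        prefers_two=bic2 < bic1,
        posteriors_on=resp_hi,
        n_iter=n_iter,
    )
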