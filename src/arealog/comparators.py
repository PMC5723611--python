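"""Classical richness estimators and rarefaction baselines.

Nonparametric estimators (Chao1, ACE, first-order jackknife) estimate
richness from the rare tail of the frequency counts; they are known
lower-bound-style estimators and are included for side-by-side
comparison with the parametric area-based model.  Hurlbert's
individual-based and Coleman's area-based rarefaction provide the
classical interpolation baselines, and :func:`fisher_alpha` recovers the
original (area-free) Fisher's alpha index.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import norm

from .counts import FrequencyCounts
from .richness import RichnessEstimate

__all__ = [
    "chao1",
    "ace",
    "jackknife1",
    "hurlbert_rarefy",
    "coleman_rarefy",
    "fisher_alpha",
]

_Z95 = norm.ppf(0.975)


def _log_ci(s_obs: float, point: float, var: float) -> tuple[float, float]:
    """Log-transformed CI on the estimated excess ``point - S_obs``.

    Standard construction for lower-bound richness estimators: the CI is
    built on ``T = point - S_obs`` assuming ``ln T`` is approximately
    normal, which keeps the lower limit above the observed richness.
    """
    excess = point - s_obs
    if excess <= 0 or var <= 0:
        return (point, point)
    k = np.exp(_Z95 * np.sqrt(np.log1p(var / excess**2)))
    return (s_obs + excess / k, s_obs + excess * k)


def chao1(counts: FrequencyCounts) -> RichnessEstimate:
    """Chao1 richness estimator with log-transformed 95% CI.

    ``S + f1**2 / (2 f2)`` when doubletons exist, otherwise the
    bias-corrected fallback ``S + f1(f1 - 1)/2``.
    """
    s = counts.n_species
    f1 = counts.singletons
    f2 = counts.doubletons
    if f1 == 0:
        point, var = float(s), 0.0
    elif f2 > 0:
        r = f1 / f2
        point = s + f1**2 / (2.0 * f2)
        var = f2 * (r**2 / 2.0 + r**3 + r**4 / 4.0)
    else:
        point = s + f1 * (f1 - 1) / 2.0
        var = (
            f1 * (f1 - 1) / 2.0
            + f1 * (2 * f1 - 1) ** 2 / 4.0
            - f1**4 / (4.0 * point)
        )
    lo, hi = _log_ci(s, point, var)
    return RichnessEstimate(
        method="chao1",
        target=float(counts.n_individuals),
        point=float(point),
        se=float(np.sqrt(var)),
        ci_low=lo,
        ci_high=hi,
    )


def ace(counts: FrequencyCounts, rare_cutoff: int = 10) -> RichnessEstimate:
    """Abundance-based coverage estimator (ACE).

    Species with abundance <= ``rare_cutoff`` form the rare group whose
    sample coverage ``C = 1 - f1/n_rare`` and squared CV drive the
    correction.  The variance propagates multinomial uncertainty in the
    rare frequency counts through a numerical gradient of the estimator,
    and the CI uses the same log transform as Chao1.
    """
    rare = {k: f for k, f in counts.counts.items() if k <= rare_cutoff}
    if not rare:
        s = counts.n_species
        return RichnessEstimate(
            method="ace", target=float(counts.n_individuals),
            point=float(s), se=0.0, ci_low=float(s), ci_high=float(s),
        )
    s_abund = sum(f for k, f in counts.counts.items() if k > rare_cutoff)

    def point_from(freqs: np.ndarray) -> float:
        # freqs[j] is f_{j+1} for the rare classes only
        ks = np.arange(1, len(freqs) + 1)
        s_rare = freqs.sum()
        n_rare = (ks * freqs).sum()
        f1 = freqs[0]
        cov = 1.0 - f1 / n_rare
        if cov <= 0:
            raise ValueError(
                "zero sample coverage (all rare species are singletons); "
                "use chao1 instead"
            )
        gamma2 = max(
            s_rare / cov * (ks * (ks - 1) * freqs).sum() / (n_rare * (n_rare - 1.0))
            - 1.0,
            0.0,
        )
        return s_abund + s_rare / cov + f1 / cov * gamma2

    freqs = np.array([rare.get(k, 0) for k in range(1, rare_cutoff + 1)], dtype=float)
    point = point_from(freqs)
    # delta method over the rare frequency counts: cov(f_i, f_j) from the
    # multinomial approximation with total ~ point
    grad = np.zeros_like(freqs)
    h = 1e-5
    for j in range(len(freqs)):
        bumped = freqs.copy()
        bumped[j] += h
        lowered = freqs.copy()
        lowered[j] -= h
        grad[j] = (point_from(bumped) - point_from(lowered)) / (2 * h)
    cov_f = np.diag(freqs) - np.outer(freqs, freqs) / point
    var = float(grad @ cov_f @ grad)
    var = max(var, 0.0)
    lo, hi = _log_ci(counts.n_species, point, var)
    return RichnessEstimate(
        method="ace",
        target=float(counts.n_individuals),
        point=float(point),
        se=float(np.sqrt(var)),
        ci_low=min(lo, point),
        ci_high=max(hi, point),
    )


def jackknife1(counts: FrequencyCounts) -> RichnessEstimate:
    """First-order jackknife, abundance form ``S + f1``, with normal CI.

    The variance follows the classical jackknife expression
    ``sum(a_k**2 f_k) - S_hat`` with weights ``a_1 = 2`` and ``a_k = 1``
    for ``k >= 2``, which reduces to ``2 f1``.
    """
    s = counts.n_species
    f1 = counts.singletons
    point = float(s + f1)
    var = 2.0 * f1
    se = float(np.sqrt(var))
    return RichnessEstimate(
        method="jackknife1",
        target=float(counts.n_individuals),
        point=point,
        se=se,
        ci_low=max(point - _Z95 * se, 0.0),
        ci_high=point + _Z95 * se,
    )


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hurlbert_rarefy(counts: FrequencyCounts, m: int) -> RichnessEstimate:
    """Hurlbert's individual-based rarefaction to ``m`` individuals.

    ``E[S_m] = sum_k f_k * (1 - C(M-k, m)/C(M, m))`` with the variance of
    Heck et al.; binomial coefficients are evaluated through log-gamma.
    """
    m = int(m)
    M = counts.n_individuals
    if not 1 <= m <= M:
        raise ValueError(f"subsample size m = {m} outside [1, M = {M}]")
    log_cmm = _log_binom(M, m)

    def p_miss(k: int) -> float:
        # probability a species with abundance k is absent from the subsample
        if M - k < m:
            return 0.0
        return float(np.exp(_log_binom(M - k, m) - log_cmm))

    classes = sorted(counts.counts)
    miss = {k: p_miss(k) for k in classes}
    point = sum(f * (1.0 - miss[k]) for k, f in counts.counts.items())

    # Heck et al. variance: species-pair inclusion probabilities, grouped
    # by abundance class to stay O(tau^2)
    var = sum(f * miss[k] * (1.0 - miss[k]) for k, f in counts.counts.items())
    for i, ki in enumerate(classes):
        for kj in classes[i:]:
            if M - ki - kj >= m:
                joint = float(np.exp(_log_binom(M - ki - kj, m) - log_cmm))
            else:
                joint = 0.0
            cov_pair = joint - miss[ki] * miss[kj]
            if ki == kj:
                npairs = counts[ki] * (counts[ki] - 1) / 2.0
            else:
                npairs = counts[ki] * counts[kj]
            var += 2.0 * npairs * cov_pair
    var = max(var, 0.0)
    se = float(np.sqrt(var))
    return RichnessEstimate(
        method="hurlbert",
        target=float(m),
        point=float(point),
        se=se,
        ci_low=max(point - _Z95 * se, 0.0),
        ci_high=point + _Z95 * se,
    )


def coleman_rarefy(
    counts: FrequencyCounts, target_area: float, a: float
) -> RichnessEstimate:
    """Coleman's area-based (random placement) rarefaction.

    ``E[S] = sum_k f_k * (1 - (1 - A*/a)**k)`` for a subplot of area
    ``A* <= a``; the variance is the sum of the per-species Bernoulli
    inclusion variances.
    """
    if not 0 < target_area <= a:
        raise ValueError(f"target area {target_area} outside (0, a = {a}]")
    q = 1.0 - target_area / a
    point = sum(f * (1.0 - q**k) for k, f in counts.counts.items())
    var = sum(f * q**k * (1.0 - q**k) for k, f in counts.counts.items())
    se = float(np.sqrt(var))
    return RichnessEstimate(
        method="coleman",
        target=float(target_area),
        point=float(point),
        se=se,
        ci_low=max(point - _Z95 * se, 0.0),
        ci_high=point + _Z95 * se,
    )


def fisher_alpha(s_obs: int, m_obs: int) -> float:
    """Original (area-free) Fisher's alpha from ``S = alpha ln(1 + M/alpha)``.

    Retained for comparison with the normalized, area-dependent alpha of
    the area-based model; it has no associated area or pmf.
    """
    if s_obs < 1:
        raise ValueError("need at least one species")
    if m_obs <= s_obs:
        raise ValueError("M <= S: Fisher's alpha unidentifiable")

    def h(alpha: float) -> float:
        return alpha * np.log1p(m_obs / alpha) - s_obs

    # S = alpha ln(1 + M/alpha) is increasing in alpha with limit M
    lo, hi = 1e-10, 10.0
    while h(hi) < 0:
        hi *= 4
        if hi > 1e12:  # pragma: no cover
            raise RuntimeError("failed to bracket Fisher's alpha")
    return float(brentq(h, lo, hi, xtol=1e-12, rtol=8.9e-16))
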