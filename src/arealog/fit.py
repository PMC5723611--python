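"""Maximum-likelihood fitting of the area-based logseries.

The full likelihood of a local sample factorises so that the observed
species richness ``S_a`` and individual count ``M_a`` are sufficient for
``(S_A, omega)``: the frequency profile ``f_1, f_2, ...`` only
contributes additive constants.  The MLEs therefore solve the moment
equations

    M_a / S_a = alpha_a * (e**(1/alpha_a) - 1)        (mean abundance)
    S_A       = S_a * alpha_a / alpha_A               (thinning balance)

with ``alpha_area = 1 / ln(1 + area/omega)``.  The first equation is a
one-dimensional root problem in ``t = 1/alpha_a`` — ``(e**t - 1)/t`` is
strictly increasing, so the root is unique — and omega follows from
``omega = a / (e**t - 1)``.

Variances come from the inverse of the observed information matrix (the
negative Hessian of the log likelihood at the MLE), with ``S_A`` relaxed
to a continuous value through the log-gamma function so the Hessian is
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .core import alpha_of_area
from .counts import FrequencyCounts, SurveyDesign

__all__ = ["LogseriesFit", "fit_omega", "loglik", "fit_full"]

# Relative step for the central finite-difference Hessian.
_FD_REL_STEP = 1e-5


@dataclass(frozen=True)
class LogseriesFit:
    """Fitted area-based logseries model for one local sample."""

    omega: float
    s_regional: float
    var_omega: float
    var_s_regional: float
    cov_omega_s: float
    loglik: float
    design: SurveyDesign
    s_obs: int
    m_obs: int

    @property
    def alpha_local(self) -> float:
        return alpha_of_area(self.design.a, self.omega)

    @property
    def alpha_regional(self) -> float:
        return alpha_of_area(self.design.A, self.omega)

    @property
    def x_local(self) -> float:
        """Logseries parameter at the sampled area, ``1 - e**(-1/alpha_a)``."""
        return float(-np.expm1(-1.0 / self.alpha_local))

    @property
    def se_omega(self) -> float:
        return float(np.sqrt(self.var_omega))

    @property
    def se_s_regional(self) -> float:
        return float(np.sqrt(self.var_s_regional))

    def ci_omega(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return (self.omega - z * self.se_omega, self.omega + z * self.se_omega)


def _split_stats(counts) -> tuple[int, int, FrequencyCounts | None]:
    """Accept a FrequencyCounts or a bare (S, M) pair."""
    if isinstance(counts, FrequencyCounts):
        return counts.n_species, counts.n_individuals, counts
    s, m = counts
    return int(s), int(m), None


def fit_omega(s_obs: int, m_obs: int, a: float) -> float:
    """MLE of the scale parameter omega from (S, M) at local area ``a``.

    Solves ``(e**t - 1)/t = M/S`` for ``t = 1/alpha_a`` by bracketed
    root-finding, then ``omega = a / (e**t - 1)``.

    Raises
    ------
    ValueError
        If ``M <= S`` (mean abundance must exceed 1 for omega to be
        identifiable) or inputs are out of domain.
    """
    if s_obs < 1:
        raise ValueError(f"need at least one observed species, got S = {s_obs}")
    if m_obs < s_obs:
        raise ValueError(f"M = {m_obs} < S = {s_obs}: impossible sample")
    if m_obs == s_obs:
        raise ValueError(
            "mean abundance 1 (every species a singleton): omega unidentifiable"
        )
    if a <= 0:
        raise ValueError(f"local area must be positive, got {a}")
    ratio = m_obs / s_obs

    def h(t: float) -> float:
        return np.expm1(t) / t - ratio

    # (e^t - 1)/t increases from 1 at t=0+, so expand the bracket until
    # it straddles the target ratio.
    lo, hi = 1e-8, 64.0
    while h(hi) < 0:
        lo, hi = hi, hi * 2
        if hi > 1e4:  # ratio astronomically large; cannot bracket
            raise RuntimeError(f"failed to bracket mean-abundance root for M/S={ratio}")
    t = brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16)
    resid = abs(np.expm1(t) / t - ratio)
    if resid > 1e-10 * ratio:
        raise RuntimeError(f"root residual {resid:g} too large for M/S = {ratio}")
    return float(a / np.expm1(t))


def loglik(s_regional: float, omega: float, counts, design: SurveyDesign) -> float:
    """Log likelihood of ``(S_A, omega)`` given a local sample.

    ``counts`` may be a :class:`FrequencyCounts` or a plain ``(S, M)``
    pair; in the latter case the frequency-profile constants (which do
    not involve the parameters) are dropped.  ``S_A`` may be any real
    value ``>= S`` — the binomial coefficient is continued through
    log-gamma.
    """
    s_obs, m_obs, fc = _split_stats(counts)
    if s_regional < s_obs:
        raise ValueError(f"S_A = {s_regional} below observed richness {s_obs}")
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    alpha_a = alpha_of_area(design.a, omega)
    alpha_A = alpha_of_area(design.A, omega)
    if alpha_A >= alpha_a and design.a < design.A:  # pragma: no cover - guarded by types
        raise ValueError("alpha_A >= alpha_a: inconsistent areas")
    ratio = alpha_A / alpha_a
    ll = (
        gammaln(s_regional + 1.0)
        - gammaln(s_regional - s_obs + 1.0)
        + s_obs * np.log(ratio)
        + s_obs * np.log(alpha_a)
        + m_obs * np.log(-np.expm1(-1.0 / alpha_a))
    )
    if s_regional > s_obs:
        ll += (s_regional - s_obs) * np.log1p(-ratio)
    if fc is not None:
        ll -= sum(gammaln(f + 1.0) for f in fc.counts.values())
        ll -= sum(f * np.log(k) for k, f in fc.counts.items())
    return float(ll)


def _hessian(fun, p0: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian with relative steps."""
    steps = np.abs(p0) * _FD_REL_STEP
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                fun(p0 + ei + ej)
                - fun(p0 + ei - ej)
                - fun(p0 - ei + ej)
                + fun(p0 - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def fit_full(counts, design: SurveyDesign) -> LogseriesFit:
    """Fit ``(omega, S_A)`` by maximum likelihood with observed-information
    variances.

    Parameters
    ----------
    counts
        :class:`FrequencyCounts` or a ``(S, M)`` pair of sufficient
        statistics.
    design
        Local and regional areas.

    Returns
    -------
    LogseriesFit
        Point estimates, the 2x2 covariance of ``(S_A, omega)`` from the
        inverse observed information, and the log likelihood at the MLE.
    """
    s_obs, m_obs, _ = _split_stats(counts)
    omega = fit_omega(s_obs, m_obs, design.a)
    alpha_a = alpha_of_area(design.a, omega)
    alpha_A = alpha_of_area(design.A, omega)
    s_regional = s_obs * alpha_a / alpha_A

    def negll(p: np.ndarray) -> float:
        return -loglik(p[0], p[1], (s_obs, m_obs), design)

    if design.a == design.A:
        # census: S_A = S_a with no binomial thinning; only omega varies
        def negll_omega(om: float) -> float:
            return -loglik(s_obs, om, (s_obs, m_obs), design)

        h = omega * _FD_REL_STEP
        d2 = (negll_omega(omega + h) - 2 * negll_omega(omega) + negll_omega(omega - h)) / h**2
        var_omega = 1.0 / d2
        return LogseriesFit(
            omega=omega,
            s_regional=float(s_obs),
            var_omega=float(var_omega),
            var_s_regional=0.0,
            cov_omega_s=0.0,
            loglik=loglik(s_obs, omega, counts, design),
            design=design,
            s_obs=s_obs,
            m_obs=m_obs,
        )

    p0 = np.array([s_regional, omega])
    H = _hessian(negll, p0)
    det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
    cond_ok = np.isfinite(det) and det > 0 and H[0, 0] > 0
    if not cond_ok:
        raise RuntimeError(
            "observed information matrix is singular or indefinite: "
            f"H = {H.tolist()}, det = {det}"
        )
    cov = np.linalg.inv(H)
    return LogseriesFit(
        omega=omega,
        s_regional=float(s_regional),
        var_omega=float(cov[1, 1]),
        var_s_regional=float(cov[0, 0]),
        cov_omega_s=float(cov[0, 1]),
        loglik=loglik(s_regional, omega, counts, design),
        design=design,
        s_obs=s_obs,
        m_obs=m_obs,
    )
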