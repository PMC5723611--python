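"""Probability mass functions of the area-based logseries and its parents.

The regional abundance ``N_A`` of a species present in a region of area
``A`` is modelled by a zero-truncated negative binomial (a truncated
gamma-Poisson mixture) with aggregation parameter ``k`` and scale
``omega``.  Letting ``k -> 0`` yields the *area-based logseries*

    phi(n | A, omega) = alpha_A * x_A**n / n,    n = 1, 2, ...

where ``x_A = A / (omega + A)`` and ``alpha_A = 1 / ln(1 + A / omega)``
is the *normalized* Fisher's alpha: unlike the classical index it is a
genuine pmf parameter that decreases as the area grows.  A local sample
of area ``a <= A`` thinned from the region has abundance distribution

    phi(0) = 1 - alpha_A / alpha_a
    phi(n) = alpha_A * x_a**n / n,    n >= 1,

whose zero class vanishes when ``a = A`` (a full census).

All gamma ratios are evaluated in log space so the pmfs remain usable at
abundances of 1e4 and beyond; every pmf has a log variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "AreaAlpha",
    "TnbdParams",
    "TplnParams",
    "alpha_of_area",
    "x_of_area",
    "logseries_mean",
    "pmf_regional",
    "logpmf_regional",
    "pmf_local",
    "pmf_tnbd",
    "logpmf_tnbd",
    "pmf_tnbd_local",
]


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value}")
    return value


def alpha_of_area(area: float, omega: float) -> float:
    """Normalized Fisher's alpha for a given area: ``1 / ln(1 + area/omega)``.

    Strictly decreasing in ``area`` and increasing in ``omega``.
    """
    area = _check_positive("area", area)
    omega = _check_positive("omega", omega)
    return 1.0 / np.log1p(area / omega)


def x_of_area(area: float, omega: float) -> float:
    """Logseries parameter ``x = area / (omega + area)``, in (0, 1)."""
    area = _check_positive("area", area)
    omega = _check_positive("omega", omega)
    return area / (omega + area)


def logseries_mean(alpha: float) -> float:
    """Mean abundance ``alpha * (e**(1/alpha) - 1)`` of the regional pmf."""
    alpha = _check_positive("alpha", alpha)
    return alpha * np.expm1(1.0 / alpha)


@dataclass(frozen=True)
class AreaAlpha:
    """Scale parameter omega evaluated at a concrete area.

    Bundles the two derived quantities that parameterise the logseries:
    ``alpha = 1/ln(1 + area/omega)`` and ``x = area/(omega + area)``,
    which satisfy the identity ``x = 1 - exp(-1/alpha)`` exactly.
    """

    omega: float
    area: float

    def __post_init__(self) -> None:
        _check_positive("omega", self.omega)
        _check_positive("area", self.area)

    @property
    def alpha(self) -> float:
        return alpha_of_area(self.area, self.omega)

    @property
    def x(self) -> float:
        return x_of_area(self.area, self.omega)


@dataclass(frozen=True)
class TnbdParams:
    """Zero-truncated negative binomial (gamma-Poisson) parameters.

    ``k`` is the aggregation (gamma shape) parameter, ``omega`` the gamma
    rate, ``area`` the region over which abundance is counted.  The
    truncation normalizer is ``C = 1 / (1 - (omega/(omega+area))**k)``.
    """

    k: float
    omega: float
    area: float

    def __post_init__(self) -> None:
        _check_positive("k", self.k)
        _check_positive("omega", self.omega)
        _check_positive("area", self.area)

    @property
    def log_p_zero(self) -> float:
        # log of the untruncated NBD zero mass (omega/(omega+area))**k
        return self.k * (np.log(self.omega) - np.log(self.omega + self.area))

    @property
    def C(self) -> float:
        return 1.0 / -np.expm1(self.log_p_zero)


def _as_counts(n, minimum: int):
    n = np.asarray(n)
    if not np.issubdtype(n.dtype, np.integer):
        if not np.all(np.equal(np.mod(n, 1), 0)):
            raise ValueError("abundance n must be integer-valued")
        n = n.astype(np.int64)
    if np.any(n < minimum):
        raise ValueError(f"abundance n must be >= {minimum}")
    return n


def logpmf_regional(n, alpha_A: float):
    """Log pmf of the area-based logseries, ``ln(alpha * x**n / n)``.

    ``x`` is tied to ``alpha`` through ``x = 1 - exp(-1/alpha)``, so the
    distribution has a single free parameter.
    """
    alpha_A = _check_positive("alpha_A", alpha_A)
    n = _as_counts(n, 1)
    log_x = np.log(-np.expm1(-1.0 / alpha_A))
    return np.log(alpha_A) + n * log_x - np.log(n)


def pmf_regional(n, alpha_A: float):
    """Pmf of the regional (zero-free) area-based logseries."""
    return np.exp(logpmf_regional(n, alpha_A))


def pmf_local(n, omega: float, a: float, A: float):
    """Pmf of a species' abundance in a local sample of area ``a <= A``.

    The zero class ``1 - alpha_A/alpha_a`` is the probability that a
    species present somewhere in the region is missed by the local
    sample; it is exactly zero when ``a = A``.
    """
    if a > A:
        raise ValueError(f"local area a = {a} exceeds regional area A = {A}")
    alpha_a = alpha_of_area(a, omega)
    alpha_A = alpha_of_area(A, omega)
    n = _as_counts(n, 0)
    out = np.zeros(np.shape(n), dtype=float)
    pos = n >= 1
    n_pos = np.atleast_1d(n)[np.atleast_1d(pos)]
    if n_pos.size:
        log_x = np.log(-np.expm1(-1.0 / alpha_a))
        vals = np.exp(np.log(alpha_A) + n_pos * log_x - np.log(n_pos))
        if out.ndim == 0:
            out = vals[0]
        else:
            out[pos] = vals
    zero_mass = 1.0 - alpha_A / alpha_a
    if out.ndim == 0:
        if n == 0:
            out = zero_mass
    else:
        out[~pos] = zero_mass
    return out


def logpmf_tnbd(n, params: TnbdParams):
    """Log pmf of the zero-truncated negative binomial over ``n >= 1``."""
    k, omega, A = params.k, params.omega, params.area
    n = _as_counts(n, 1)
    log_ratio = gammaln(k + n) - gammaln(k) - gammaln(n + 1)
    return (
        np.log(params.C)
        + log_ratio
        + k * (np.log(omega) - np.log(omega + A))
        + n * (np.log(A) - np.log(omega + A))
    )


def pmf_tnbd(n, params: TnbdParams):
    """Pmf of the zero-truncated negative binomial (regional abundance)."""
    return np.exp(logpmf_tnbd(n, params))


def pmf_tnbd_local(n, k: float, omega: float, a: float, A: float):
    """Local-sample abundance pmf under the truncated negative binomial.

    Zero class: ``C * ((omega/(omega+a))**k - (omega/(omega+A))**k)``;
    positive classes follow the untruncated NBD at area ``a`` rescaled by
    the regional truncation constant ``C``.  Its ``k -> 0`` limit is
    :func:`pmf_local`.
    """
    if a > A:
        raise ValueError(f"local area a = {a} exceeds regional area A = {A}")
    regional = TnbdParams(k=k, omega=omega, area=A)
    local = TnbdParams(k=k, omega=omega, area=a)
    n = _as_counts(n, 0)
    out = np.zeros(np.shape(n), dtype=float)
    pos = n >= 1
    n_pos = np.atleast_1d(n)[np.atleast_1d(pos)]
    if n_pos.size:
        log_ratio = gammaln(k + n_pos) - gammaln(k) - gammaln(n_pos + 1)
        vals = np.exp(
            np.log(regional.C)
            + log_ratio
            + k * (np.log(omega) - np.log(omega + a))
            + n_pos * (np.log(a) - np.log(omega + a))
        )
        if out.ndim == 0:
            out = vals[0]
        else:
            out[pos] = vals
    # exp(k ln(w/(w+a))) - exp(k ln(w/(w+A))), kept in log space pieces
    zero_mass = regional.C * (np.exp(local.log_p_zero) - np.exp(regional.log_p_zero))
    if out.ndim == 0:
        if n == 0:
            out = zero_mass
    else:
        out[~pos] = zero_mass
    return out
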