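"""Seeded generators of local-sample abundance data.

Three community models are supported, matching the likelihood's
factorisation into "which species are observed" times "their
abundances":

* ``logseries``: the number of observed species is
  ``Binomial(S_A, alpha_A/alpha_a)`` and each observed species draws an
  abundance i.i.d. from the zero-truncated logseries with parameter
  ``x_a = 1 - e**(-1/alpha_a)``;
* ``tnbd``: each species draws an intensity ``lambda ~ Gamma(k, rate
  omega)`` and a regional abundance ``N_A ~ Poisson(A*lambda)``, with the
  pair redrawn while ``N_A = 0`` (the truncated mixture); the local
  abundance is ``Binomial(N_A, a/A)``;
* ``tpln``: as ``tnbd`` but ``lambda = exp(Normal(mu, sigma))`` and
  ``N_A`` zero-truncated Poisson given ``lambda``.

All samplers take a :class:`numpy.random.Generator` (or an integer seed)
and are bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import logser, poisson

from .core import alpha_of_area
from .counts import FrequencyCounts, SurveyDesign

__all__ = [
    "CommunityConfig",
    "sample_local_logseries",
    "sample_local_tnbd",
    "sample_local_tpln",
    "sample_local",
]


@dataclass(frozen=True)
class CommunityConfig:
    """A simulated community: true richness, abundance model, geometry.

    ``model`` is one of ``"logseries"`` (params: omega), ``"tnbd"``
    (params: k, omega) or ``"tpln"`` (params: mu, sigma).
    """

    s_regional: int
    design: SurveyDesign
    model: str = "logseries"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.s_regional < 1:
            raise ValueError("true regional richness must be >= 1")
        if self.model not in ("logseries", "tnbd", "tpln"):
            raise ValueError(f"unknown community model {self.model!r}")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_local_logseries(
    s_regional: int, omega: float, design: SurveyDesign, rng=None
) -> FrequencyCounts:
    """One local sample under the area-based logseries community model."""
    rng = _rng(rng)
    alpha_a = alpha_of_area(design.a, omega)
    alpha_A = alpha_of_area(design.A, omega)
    n_obs = rng.binomial(s_regional, alpha_A / alpha_a)
    while n_obs == 0:  # resample pathological empty surveys
        n_obs = rng.binomial(s_regional, alpha_A / alpha_a)
    x_a = -np.expm1(-1.0 / alpha_a)
    abundances = logser.rvs(x_a, size=n_obs, random_state=rng)
    return FrequencyCounts.from_abundances(abundances)


def _zt_poisson(mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson draws by CDF inversion, vectorised over mu."""
    p0 = np.exp(-mu)
    u = rng.uniform(p0, 1.0)
    return poisson.ppf(u, mu).astype(np.int64)


def sample_local_tnbd(
    s_regional: int, k: float, omega: float, design: SurveyDesign, rng=None
) -> FrequencyCounts:
    """One local sample under the truncated negative binomial community.

    The regional abundance of each species is the gamma-Poisson mixture
    conditioned on being positive: both lambda and the Poisson draw are
    rejected together while the count is zero, which reproduces the
    truncated-mixture pmf exactly.  Acceptance probability is
    ``1 - (omega/(omega+A))**k``; a warning is logged when it falls
    below 1e-3 and a ValueError raised below 1e-8 (rejection hopeless).
    """
    rng = _rng(rng)
    accept = -np.expm1(k * (np.log(omega) - np.log(omega + design.A)))
    if accept < 1e-8:
        raise ValueError(
            f"TNBD zero-truncation acceptance {accept:.2e} is hopeless; "
            "increase k, omega or A"
        )
    if accept < 1e-3:
        logging.getLogger("arealog").warning(
            "TNBD zero-truncation acceptance %.2e: rejection sampling "
            "will be slow", accept,
        )
    n_regional = np.zeros(s_regional, dtype=np.int64)
    todo = np.arange(s_regional)
    while todo.size:
        lam = rng.gamma(shape=k, scale=1.0 / omega, size=todo.size)
        draws = rng.poisson(design.A * lam)
        n_regional[todo] = draws
        todo = todo[draws == 0]
    n_local = rng.binomial(n_regional, design.a / design.A)
    n_local = n_local[n_local > 0]
    if n_local.size == 0:
        raise RuntimeError("simulated survey observed no species; enlarge a or S_A")
    return FrequencyCounts.from_abundances(n_local)


def sample_local_tpln(
    s_regional: int, mu: float, sigma: float, design: SurveyDesign, rng=None
) -> FrequencyCounts:
    """One local sample under the truncated Poisson-lognormal community.

    Each species' intensity is ``lambda = exp(Normal(mu, sigma))``; its
    regional abundance is zero-truncated Poisson(A*lambda) and the local
    abundance binomially thinned by ``a/A``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = _rng(rng)
    lam = np.exp(rng.normal(mu, sigma, size=s_regional))
    n_regional = _zt_poisson(design.A * lam, rng)
    n_local = rng.binomial(n_regional, design.a / design.A)
    n_local = n_local[n_local > 0]
    if n_local.size == 0:
        raise RuntimeError("simulated survey observed no species; enlarge a or S_A")
    return FrequencyCounts.from_abundances(n_local)


def sample_local(config: CommunityConfig, rng=None) -> FrequencyCounts:
    """Dispatch on ``config.model``; uses ``config.seed`` if no rng given."""
    if rng is None:
        rng = _rng(config.seed)
    if config.model == "logseries":
        return sample_local_logseries(
            config.s_regional, config.params["omega"], config.design, rng
        )
    if config.model == "tnbd":
        return sample_local_tnbd(
            config.s_regional,
            config.params["k"],
            config.params["omega"],
            config.design,
            rng,
        )
    return sample_local_tpln(
        config.s_regional,
        config.params["mu"],
        config.params["sigma"],
        config.design,
        rng,
    )
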