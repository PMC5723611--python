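"""Goodness-of-fit tests for the fitted conditional logseries.

Only species present in the sample are observable, so both tests target
the conditional-on-presence distribution ``alpha_a * x_a**n / n``
(``n >= 1``), which is a proper pmf.

* :func:`ks_discrete` compares step CDFs (the discrete analogue of the
  Kolmogorov-Smirnov test) and calibrates the p value by a parametric
  bootstrap that refits omega in every replicate, so that parameter
  estimation is accounted for.
* :func:`chisq_gof` is the classical Pearson chi-squared test on binned
  frequency counts, with right-to-left pooling of the tail until each
  expected count reaches ``min_expected``, and one degree of freedom
  deducted for the estimated omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, logser

from .counts import FrequencyCounts
from .fit import LogseriesFit, fit_omega
from .core import alpha_of_area

__all__ = ["GofResult", "ks_discrete", "chisq_gof"]


@dataclass(frozen=True)
class GofResult:
    method: str
    statistic: float
    p_value: float
    detail: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p value {self.p_value} outside [0, 1]")
        if self.statistic < 0:
            raise ValueError(f"negative statistic {self.statistic}")


def _ks_statistic(counts: FrequencyCounts, x_a: float) -> float:
    """Sup distance between empirical and fitted step CDFs on n = 1..tau.

    Beyond the largest observed abundance the empirical CDF is 1 and the
    fitted CDF only increases, so the supremum over all integers is
    attained at or before tau.
    """
    tau = counts.tau
    support = np.arange(1, tau + 1)
    obs = np.array([counts[k] for k in support], dtype=float)
    emp_cdf = np.cumsum(obs) / counts.n_species
    fit_cdf = logser.cdf(support, x_a)
    return float(np.max(np.abs(emp_cdf - fit_cdf)))


def ks_discrete(
    counts: FrequencyCounts,
    fit: LogseriesFit,
    B: int = 999,
    seed: int | None = None,
) -> GofResult:
    """Discrete KS test with a parametric-bootstrap p value.

    Each of the ``B`` replicates simulates ``S_a`` abundances from the
    fitted conditional logseries, refits omega, and recomputes the
    statistic; the p value is ``(1 + #{D* >= D}) / (B + 1)``.
    """
    if B < 199:
        raise ValueError("use at least 199 bootstrap replicates")
    if not np.isfinite(fit.x_local) or not 0 < fit.x_local < 1:
        raise ValueError("degenerate fit: x_local outside (0, 1)")
    rng = np.random.default_rng(seed)
    d_obs = _ks_statistic(counts, fit.x_local)
    s_obs = counts.n_species
    a = fit.design.a
    n_ge = 0
    for _ in range(B):
        while True:
            ab = logser.rvs(fit.x_local, size=s_obs, random_state=rng)
            m_star = int(np.sum(ab))
            if m_star > s_obs:  # omega identifiable (not all singletons)
                break
        boot = FrequencyCounts.from_abundances(ab)
        omega_star = fit_omega(s_obs, m_star, a)
        x_star = -np.expm1(-np.log1p(a / omega_star))
        if _ks_statistic(boot, x_star) >= d_obs:
            n_ge += 1
    p = (1 + n_ge) / (B + 1)
    return GofResult(
        method="ks_discrete",
        statistic=d_obs,
        p_value=p,
        detail={"bootstrap_replicates": B},
        seed=seed,
    )


def chisq_gof(
    counts: FrequencyCounts, fit: LogseriesFit, min_expected: float = 5.0
) -> GofResult:
    """Pearson chi-squared test of the fitted conditional logseries.

    Expected counts are ``S_a * alpha_a * x_a**n / n`` for ``n = 1..tau``
    plus a pooled ``n > tau`` tail; adjacent bins are pooled right to
    left until every expected count is at least ``min_expected``.
    Degrees of freedom: ``bins - 1 - 1`` (one parameter estimated).
    """
    x_a = fit.x_local
    alpha_a = alpha_of_area(fit.design.a, fit.omega)
    s = counts.n_species
    tau = counts.tau
    support = np.arange(1, tau + 1)
    expected = s * alpha_a * x_a**support / support
    observed = np.array([counts[k] for k in support], dtype=float)
    # open tail bin n > tau carries the remaining probability mass
    tail_exp = s * (1.0 - logser.cdf(tau, x_a))
    expected = np.append(expected, tail_exp)
    observed = np.append(observed, 0.0)
    edges = list(support) + [None]  # None marks the open tail

    # pool right-to-left until all expected >= min_expected
    exp_b = list(expected)
    obs_b = list(observed)
    lab_b = [[e] for e in edges]
    i = len(exp_b) - 1
    while i > 0:
        if exp_b[i] < min_expected:
            exp_b[i - 1] += exp_b.pop(i)
            obs_b[i - 1] += obs_b.pop(i)
            lab_b[i - 1].extend(lab_b.pop(i))
        i -= 1
    if exp_b and exp_b[0] < min_expected and len(exp_b) > 1:
        exp_b[0] += exp_b.pop(1)
        obs_b[0] += obs_b.pop(1)
        lab_b[0].extend(lab_b.pop(1))
    if len(exp_b) < 3:
        raise ValueError(
            f"only {len(exp_b)} bins with expected >= {min_expected}: "
            "too few for a chi-squared test"
        )
    exp_arr = np.array(exp_b)
    obs_arr = np.array(obs_b)
    stat = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    dof = len(exp_b) - 2
    p = float(chi2.sf(stat, dof))
    return GofResult(
        method="chisq",
        statistic=stat,
        p_value=p,
        detail={
            "bins": [
                {"abundances": [e for e in lab if e is not None]
                 + (["tail"] if lab[-1] is None or None in lab else []),
                 "observed": o, "expected": e}
                for lab, o, e in zip(lab_b, obs_b, exp_b)
            ],
            "dof": dof,
        },
    )
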