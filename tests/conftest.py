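"""Shared fixtures: empirical survey statistics and tail completion.

The Atlantic-forest frequency tables publish only the rare classes
f_1..f_7, while the survey totals (S, M) cover all species.
``complete_counts`` deterministically fills in a synthetic abundant tail
consistent with the totals so that estimators needing a full frequency
profile can run on these samples.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import logser

from arealog import FrequencyCounts, SurveyDesign, fit_full, fit_omega, load_survey
from arealog.io import load_fixture_counts


@pytest.fixture(scope="session")
def surveys():
    return {name: load_survey(name) for name in
            ("interior", "edge", "combined", "L1", "L2", "L3")}


@pytest.fixture(scope="session")
def interior_fit(surveys):
    s, m, design = surveys["interior"]
    return fit_full((s, m), design)


def complete_counts(name: str) -> FrequencyCounts:
    """Published f_1..f_7 plus a synthetic abundant tail hitting (S, M).

    The missing species are allocated to abundance classes >= 8 in
    proportion to the fitted conditional logseries, with one final
    species taking whatever abundance balances the individual total.
    """
    partial = load_fixture_counts(name)
    s, m, design = load_survey(name)
    omega = fit_omega(s, m, design.a)
    x = design.a / (design.a + omega)
    n_missing = s - partial.n_species
    m_missing = m - partial.n_individuals
    assert n_missing > 0 and m_missing > 0
    lo = partial.tau + 1
    support = np.arange(lo, 400)
    probs = logser.pmf(support, x)
    probs /= probs.sum()
    alloc = np.floor(probs * (n_missing - 1)).astype(int)
    # largest remainders take the leftover species
    short = (n_missing - 1) - alloc.sum()
    order = np.argsort(-(probs * (n_missing - 1) - alloc))
    alloc[order[:short]] += 1
    counts = dict(partial.counts)
    for k, f in zip(support, alloc):
        if f > 0:
            counts[int(k)] = counts.get(int(k), 0) + int(f)
    used = int((support * alloc).sum())
    balance = m_missing - used
    assert balance >= lo, f"balancing species would need abundance {balance}"
    counts[balance] = counts.get(balance, 0) + 1
    out = FrequencyCounts(counts)
    assert out.n_species == s and out.n_individuals == m
    return out


@pytest.fixture(scope="session")
def interior_complete():
    return complete_counts("interior")


@pytest.fixture(scope="session")
def toy_counts():
    # 3 species with abundances (1, 1, 3): S = 3, M = 5
    return FrequencyCounts({1: 2, 3: 1})


@pytest.fixture
def small_design():
    return SurveyDesign(a=1.0, A=100.0)
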