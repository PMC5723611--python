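"""Replicated simulation experiments: bias, SE and coverage of richness
estimators.

For each replicate a local sample is generated from a community model,
every requested estimator produces a point estimate and 95% CI for the
true regional richness, and the study aggregates per estimator:

* the average estimate,
* the sample SE (SD of the point estimates across replicates),
* the mean of the estimated SEs (a good variance estimator makes this
  track the sample SE), and
* the coverage percentage CP (how often the 95% CI contains truth).

Rows for the fitted omega and the observed local richness ``S_a`` are
always included, mirroring the usual presentation of such experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import comparators
from .counts import SurveyDesign
from .fit import fit_full
from .richness import estimate_at_area
from .simulate import CommunityConfig, sample_local

__all__ = ["SimStudySummary", "run_study", "summarize_table", "load_grid"]

DEFAULT_ESTIMATORS = ("area_logseries", "chao1", "ace", "jackknife1")


@dataclass(frozen=True)
class SimStudySummary:
    """Aggregated results of one simulation configuration."""

    config: CommunityConfig
    reps: int
    seed: int
    rows: pd.DataFrame  # index: quantity; columns: average, sample_se, est_se, cp
    failures: dict = field(default_factory=dict)

    def __getitem__(self, quantity: str) -> pd.Series:
        return self.rows.loc[quantity]


def _area_estimator(counts, design: SurveyDesign):
    fit = fit_full(counts, design)
    est = estimate_at_area(fit, design.A)
    return est, fit


def run_study(
    config: CommunityConfig,
    reps: int = 500,
    seed: int = 0,
    estimators=DEFAULT_ESTIMATORS,
) -> SimStudySummary:
    """Run ``reps`` independent replicates of one community configuration.

    Each replicate uses its own RNG stream seeded ``seed + replicate``,
    so any single replicate can be reproduced in isolation.  Estimator
    failures on a replicate are logged, excluded from the averages, and
    counted as non-covering for CP.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    truth = float(config.s_regional)
    design = config.design
    records: dict[str, list] = {name: [] for name in estimators}
    omega_rec: list[tuple[float, float, bool]] = []
    sa_rec: list[tuple[float, float, bool]] = []
    failures: dict[str, int] = {name: 0 for name in estimators}
    true_omega = config.params.get("omega")
    from .core import alpha_of_area

    if config.model == "logseries" and true_omega is not None:
        expected_sa = truth * (
            alpha_of_area(design.A, true_omega) / alpha_of_area(design.a, true_omega)
        )
    else:
        expected_sa = None

    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        counts = sample_local(config, rng)
        fit = None
        for name in estimators:
            try:
                if name == "area_logseries":
                    est, fit = _area_estimator(counts, design)
                elif name == "chao1":
                    est = comparators.chao1(counts)
                elif name == "ace":
                    est = comparators.ace(counts)
                elif name == "jackknife1":
                    est = comparators.jackknife1(counts)
                elif callable(name):
                    est = name(counts, design)
                else:
                    raise ValueError(f"unknown estimator {name!r}")
            except (ValueError, RuntimeError):
                failures[name] += 1
                records[name].append((np.nan, np.nan, False))
                continue
            covered = est.ci_low <= truth <= est.ci_high
            records[name].append((est.point, est.se, covered))
        if fit is None:
            try:
                fit = fit_full(counts, design)
            except (ValueError, RuntimeError):
                fit = None
        if fit is not None and true_omega is not None:
            lo, hi = fit.ci_omega()
            omega_rec.append((fit.omega, fit.se_omega, lo <= true_omega <= hi))
        if fit is not None and expected_sa is not None:
            se_sa = float(np.sqrt(counts.n_species * (1 - counts.n_species / fit.s_regional)))
            s = counts.n_species
            sa_rec.append(
                (s, se_sa, s - 1.96 * se_sa <= expected_sa <= s + 1.96 * se_sa)
            )

    def summarise(rows: list[tuple[float, float, bool]]):
        pts = np.array([r[0] for r in rows], dtype=float)
        ses = np.array([r[1] for r in rows], dtype=float)
        cov = np.array([r[2] for r in rows], dtype=bool)
        ok = np.isfinite(pts)
        return {
            "average": float(np.mean(pts[ok])) if ok.any() else np.nan,
            "sample_se": float(np.std(pts[ok], ddof=1)) if ok.sum() > 1 else np.nan,
            "est_se": float(np.mean(ses[ok])) if ok.any() else np.nan,
            "cp": 100.0 * float(np.mean(cov)),
            "n_ok": int(ok.sum()),
        }

    table: dict[str, dict] = {}
    est_names = [n if isinstance(n, str) else getattr(n, "__name__", "custom")
                 for n in estimators]
    if omega_rec:
        table["omega_hat"] = summarise(omega_rec)
    if sa_rec:
        table["s_obs"] = summarise(sa_rec)
    for name, key in zip(estimators, est_names):
        table[key] = summarise(records[name])
    rows = pd.DataFrame(table).T[["average", "sample_se", "est_se", "cp", "n_ok"]]
    return SimStudySummary(
        config=config, reps=reps, seed=seed, rows=rows, failures=failures
    )


def summarize_table(summaries: list[SimStudySummary]) -> pd.DataFrame:
    """Stack study summaries into one long report table.

    One block per configuration with columns (average, sample SE, mean
    estimated SE, CP); the configuration is echoed in index columns.
    """
    if not summaries:
        raise ValueError("no summaries to tabulate")
    blocks = []
    for s in summaries:
        block = s.rows.copy()
        block.insert(0, "model", s.config.model)
        block.insert(1, "S_A", s.config.s_regional)
        for i, (key, val) in enumerate(sorted(s.config.params.items())):
            block.insert(2 + i, key, val)
        block.insert(len(block.columns), "a", s.config.design.a)
        block.insert(len(block.columns), "A", s.config.design.A)
        block.insert(len(block.columns), "reps", s.reps)
        block.index.name = "quantity"
        blocks.append(block.reset_index())
    return pd.concat(blocks, ignore_index=True)


def load_grid(path) -> list[CommunityConfig]:
    """Read a study grid from a YAML config.

    The file holds a mapping with list-valued keys ``S_A``, ``A`` and the
    model parameters (``omega`` for logseries, ``k``/``omega`` for tnbd,
    ``mu``/``sigma`` for tpln), plus scalars ``a``, ``model``, ``reps``
    and ``seed``; the cartesian product of the list-valued keys is
    enumerated.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    model = raw.get("model", "logseries")
    a = float(raw.get("a", 1.0))

    def as_list(key, default=None):
        v = raw.get(key, default)
        if v is None:
            return [None]
        return list(v) if isinstance(v, (list, tuple)) else [v]

    configs = []
    param_keys = {"logseries": ["omega"], "tnbd": ["k", "omega"],
                  "tpln": ["mu", "sigma"]}[model]
    from itertools import product

    grids = [as_list("S_A"), as_list("A")] + [as_list(k) for k in param_keys]
    for s_regional, A, *pvals in product(*grids):
        params = dict(zip(param_keys, [float(v) for v in pvals]))
        configs.append(
            CommunityConfig(
                s_regional=int(s_regional),
                design=SurveyDesign(a=a, A=float(A)),
                model=model,
                params=params,
                seed=raw.get("seed"),
            )
        )
    return configs
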