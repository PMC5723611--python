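"""Containers for species abundance data and survey geometry.

A local sample is summarised by its *frequency counts*: the number of
species ``f_k`` observed with exactly ``k`` individuals.  The pair
(observed species richness ``S``, observed individual count ``M``) is a
sufficient statistic for the area-based logseries model, so most
estimators in this package accept either a full :class:`FrequencyCounts`
or just those two numbers.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

__all__ = ["FrequencyCounts", "SurveyDesign"]


@dataclass(frozen=True)
class FrequencyCounts:
    """Abundance histogram of a local sample: ``{abundance k -> f_k}``.

    Only strictly positive abundances with at least one species are
    stored; species unseen in the sample (the ``f_0`` class) are by
    construction unobservable and never appear here.

    Parameters
    ----------
    counts
        Mapping from abundance ``k >= 1`` to the number of species
        observed with exactly ``k`` individuals (``f_k >= 1``).
    """

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for k, f in sorted(self.counts.items()):
            k = int(k)
            f = int(f)
            if k < 1:
                raise ValueError(f"abundance class must be >= 1, got {k}")
            if f < 0:
                raise ValueError(f"species count must be >= 0, got f_{k} = {f}")
            if f > 0:
                clean[k] = f
        if not clean:
            raise ValueError("empty sample: no species with positive abundance")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_abundances(cls, abundances: Iterable[int]) -> "FrequencyCounts":
        """Build counts from a per-species abundance vector."""
        counts: dict[int, int] = {}
        for n in abundances:
            n = int(n)
            if n < 1:
                raise ValueError(f"species abundance must be >= 1, got {n}")
            counts[n] = counts.get(n, 0) + 1
        return cls(counts)

    def to_abundances(self) -> list[int]:
        """Per-species abundance vector (sorted ascending)."""
        out: list[int] = []
        for k, f in sorted(self.counts.items()):
            out.extend([k] * f)
        return out

    def __getitem__(self, k: int) -> int:
        return self.counts.get(int(k), 0)

    @property
    def n_species(self) -> int:
        """Observed species richness ``S`` (sum of all f_k)."""
        return sum(self.counts.values())

    @property
    def n_individuals(self) -> int:
        """Observed community size ``M`` (sum of k * f_k)."""
        return sum(k * f for k, f in self.counts.items())

    @property
    def tau(self) -> int:
        """Largest observed abundance class."""
        return max(self.counts)

    @property
    def singletons(self) -> int:
        return self.counts.get(1, 0)

    @property
    def doubletons(self) -> int:
        return self.counts.get(2, 0)


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling geometry: local sampled area ``a`` inside region ``A``.

    Both areas must be expressed in the same unit; only the ratios
    ``area / omega`` enter the model, so the scale parameter omega
    inherits whatever unit is used here.
    """

    a: float
    A: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = self.A if self.A is not None else self.a
        object.__setattr__(self, "A", float(A))
        object.__setattr__(self, "a", float(self.a))
        if not self.a > 0:
            raise ValueError(f"local area must be positive, got a = {self.a}")
        if self.A < self.a:
            raise ValueError(
                f"regional area A = {self.A} smaller than local area a = {self.a}"
            )
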