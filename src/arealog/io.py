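"""Reading and writing frequency-count files; packaged fixtures.

The native format is a two-column tab-separated file with header
``abundance<TAB>species`` and one row per occupied abundance class, in
strictly increasing abundance order.  A single-column file (no header or
a one-field header) is auto-detected as a per-species abundance list.
Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

from .counts import FrequencyCounts, SurveyDesign

__all__ = ["read_counts", "write_counts", "load_fixture_counts", "load_survey"]

log = logging.getLogger("arealog")


def read_counts(path) -> FrequencyCounts:
    """Parse a counts file (frequency table or abundance list)."""
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    if not rows:
        raise ValueError(f"{path}: empty counts file")

    header = rows[0][1]
    is_table = [h.lower() for h in header[:2]] == ["abundance", "species"]
    if is_table:
        counts: dict[int, int] = {}
        last_k = 0
        for lineno, fields in rows[1:]:
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                k, f = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer entry") from exc
            if k <= last_k:
                raise ValueError(
                    f"{path}:{lineno}: abundance {k} not strictly increasing"
                )
            if k < 1 or f < 1:
                raise ValueError(f"{path}:{lineno}: entries must be positive")
            counts[k] = f
            last_k = k
        if not counts:
            raise ValueError(f"{path}: no data rows")
        out = FrequencyCounts(counts)
    else:
        abundances = []
        for lineno, fields in rows:
            if len(fields) != 1:
                raise ValueError(
                    f"{path}:{lineno}: expected a single abundance per line"
                )
            try:
                abundances.append(int(fields[0]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer abundance") from exc
        out = FrequencyCounts.from_abundances(abundances)
    log.info(
        "read %s: S = %d species, M = %d individuals, tau = %d",
        path, out.n_species, out.n_individuals, out.tau,
    )
    return out


def write_counts(counts: FrequencyCounts, path) -> None:
    """Write the two-column frequency-table dialect (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("abundance\tspecies\n")
        for k in sorted(counts.counts):
            fh.write(f"{k}\t{counts.counts[k]}\n")


def _data_file(name: str):
    return resources.files("arealog").joinpath("data", name)


def load_fixture_counts(name: str) -> FrequencyCounts:
    """Load a packaged frequency-count fixture (``interior``, ``edge``,
    ``combined``).

    The Atlantic-forest fixtures carry only the published rare-abundance
    classes (f_1..f_7); the totals of the full surveys are available via
    :func:`load_survey`.
    """
    ref = _data_file(f"{name}.tsv")
    with resources.as_file(ref) as p:
        return read_counts(p)


def load_survey(name: str) -> tuple[int, int, SurveyDesign]:
    """Load packaged survey summary statistics: ``(S, M, design)``.

    Available surveys: ``interior``, ``edge``, ``combined`` (Brazilian
    Atlantic forest transects) and the hypothetical sites ``L1``, ``L2``,
    ``L3``.
    """
    with _data_file("surveys.json").open() as fh:
        surveys = json.load(fh)
    if name not in surveys:
        raise KeyError(f"unknown survey {name!r}; have {sorted(surveys)}")
    rec = surveys[name]
    return rec["S"], rec["M"], SurveyDesign(a=rec["a"], A=rec["A"])
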