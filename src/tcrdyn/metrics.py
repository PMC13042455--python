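"""Repertoire diversity and clonality statistics.

For a repertoire with N distinct clonotypes and clone frequencies
p_i = copy_i / sum(copy):

* richness — N, the number of unique clonotypes;
* clonality — 1 minus Pielou's evenness, i.e. 1 − H / log N with Shannon
  entropy H = −Σ p_i log p_i.  The logarithm base cancels between H and
  log N, so clonality is base-invariant.  A singleton repertoire (N = 1)
  is perfectly even; its clonality is 0 by convention (configurable to NaN).
* Gini coefficient — mean absolute difference of clone frequencies
  normalised by twice the mean:  G = Σ_i Σ_j |p_i − p_j| / (2 N² p̄).
  0 for uniform repertoires, approaching 1 as one clone dominates;
  independent of richness.
* copy-number spectrum — clonotype counts and cell-weighted proportions in
  copy-number bins; the default bins {1}, [2,10], [11,50], [51,∞) follow the
  convention of calling clones with copy number > 10 or > 50 highly expanded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .vdj_io import CellClonotype, CloneTable

__all__ = [
    "RepertoireSummary",
    "CopyNumberSpectrum",
    "richness",
    "clonality",
    "gini",
    "copy_number_spectrum",
    "DEFAULT_BIN_EDGES",
    "summarize_strata",
]

DEFAULT_BIN_EDGES = (1, 2, 11, 51)
LOW_CONFIDENCE_RICHNESS = 3  # strata below this are flagged in summaries


@dataclass(frozen=True)
class RepertoireSummary:
    richness: int
    clonality: float
    gini: float
    total_cells: int
    patient: str | None = None
    timepoint: str | None = None
    response: str | None = None
    subset: str | None = None
    low_confidence: bool = False


@dataclass(frozen=True)
class CopyNumberSpectrum:
    """Clonotypes per copy-number bin and the fraction of cells they hold."""

    bins: tuple[str, ...]
    counts: tuple[int, ...]
    proportions: tuple[float, ...]


def _copies(table: CloneTable) -> np.ndarray:
    return np.asarray(list(table.counts.values()), dtype=float)


def richness(table: CloneTable) -> int:
    """Number of unique clonotypes (0 for an empty table)."""
    return len(table.counts)


def clonality(table: CloneTable, singleton_value: float = 0.0) -> float:
    """1 − Pielou's evenness = 1 − H / log N.

    Parameters
    ----------
    singleton_value
        Value returned for N = 1 repertoires, where H / log N is 0/0;
        default 0.0 (a single clone is trivially even), set to ``nan``
        to propagate missingness instead.
    """
    n = richness(table)
    if n == 0:
        raise ValueError("clonality undefined for an empty repertoire")
    if n == 1:
        return singleton_value
    p = _copies(table)
    p = p / p.sum()
    h = -float(np.sum(p * np.log(p)))
    return 1.0 - h / math.log(n)


def gini(table: CloneTable) -> float:
    """Gini coefficient of clone frequencies, mean-absolute-difference form.

    G = Σ_i Σ_j |p_i − p_j| / (2 N² p̄), computed via the equivalent
    sorted form Σ_i (2i − N − 1) p_(i) / (N² p̄) in O(N log N).
    """
    n = richness(table)
    if n == 0:
        raise ValueError("gini undefined for an empty repertoire")
    p = np.sort(_copies(table))
    p = p / p.sum()
    i = np.arange(1, n + 1, dtype=float)
    mean_p = p.mean()
    return float(np.sum((2 * i - n - 1) * p) / (n * n * mean_p))


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = []
    for lo, nxt in zip(edges, list(edges[1:]) + [None]):
        hi = None if nxt is None else nxt - 1
        if hi is None:
            labels.append(f">={lo}" if lo > 1 else "all")
        elif hi == lo:
            labels.append(str(lo))
        else:
            labels.append(f"{lo}-{hi}")
    return labels


def copy_number_spectrum(
    table: CloneTable, bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> CopyNumberSpectrum:
    """Bin clonotypes by copy number.

    ``bin_edges`` are the strictly increasing lower edges of the bins; bin k
    covers [edges[k], edges[k+1] − 1], the last bin is open above.  The
    default (1, 2, 11, 51) yields {1}, [2,10], [11,50], [51,∞).  Counts sum
    to richness; proportions are cell-weighted and sum to 1 (all zero for an
    empty table).
    """
    edges = list(bin_edges)
    if not edges or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be non-empty and strictly increasing")
    labels = _bin_labels(edges)
    copies = _copies(table)
    if copies.size and copies.min() < edges[0]:
        raise ValueError(
            f"copy number {int(copies.min())} below lowest bin edge {edges[0]}"
        )
    counts = [0] * len(edges)
    cells = [0.0] * len(edges)
    for c in copies:
        k = int(np.searchsorted(edges, c, side="right")) - 1
        counts[k] += 1
        cells[k] += c
    total = copies.sum()
    props = [x / total if total else 0.0 for x in cells]
    return CopyNumberSpectrum(tuple(labels), tuple(counts), tuple(props))


def summarize_strata(
    cells: Iterable[CellClonotype],
    by: Sequence[str] = ("response", "timepoint"),
    per_subset: bool = False,
) -> pd.DataFrame:
    """Long-format diversity summary, one row per stratum.

    ``by`` selects the pooling labels (subsets of patient/timepoint/response);
    ``per_subset`` additionally stratifies by T-cell subset.  Cells of a
    stratum are pooled into one clone table (per-patient summaries are the
    ``by=("patient", "timepoint")`` special case).  Strata with fewer than
    3 clonotypes are flagged low-confidence.
    """
    valid = {"patient", "timepoint", "response", "subset"}
    keys = list(by) + (["subset"] if per_subset and "subset" not in by else [])
    if not set(keys) <= valid:
        raise ValueError(f"stratum labels must be among {sorted(valid)}")

    groups: dict[tuple, list[CellClonotype]] = {}
    for cell in cells:
        key = tuple(getattr(cell, k) for k in keys)
        groups.setdefault(key, []).append(cell)

    rows = []
    for key in sorted(groups):
        group = groups[key]
        # pool into a pseudo-specimen table; specimen identity is the stratum
        table = CloneTable(specimen=("pooled", "pooled"))
        for cell in group:
            table.counts[cell.clonotype] = table.counts.get(cell.clonotype, 0) + 1
        n = richness(table)
        row = dict(zip(keys, key))
        row.update(
            richness=n,
            clonality=clonality(table),
            gini=gini(table),
            total_cells=table.total_cells(),
            low_confidence=n < LOW_CONFIDENCE_RICHNESS,
        )
        rows.append(row)
    return pd.DataFrame(rows)
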