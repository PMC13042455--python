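"""T-cell composition dynamics and subset/condition enrichment (Ro/e).

Composition dynamics report, per specimen, the fraction of T cells among
nonmalignant cells and among all cells, and per patient the post − pre
difference.  Specimens with fewer than ``min_t_cells`` T cells (default 20)
are excluded to avoid imprecise estimates.

Ro/e is the ratio of observed to expected cell counts in a subset ×
condition contingency table, with expected counts under the chi-square
independence model: E_ij = row_i · col_j / grand total.  Ro/e > 1 marks a
subset preferring that condition; by construction the expected-count-
weighted row mean of Ro/e is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

__all__ = ["CompositionRecord", "RoeMatrix", "composition_change", "roe", "roe_difference"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_T_CELLS = 20


@dataclass(frozen=True)
class CompositionRecord:
    patient: str
    timepoint: str
    t_fraction_nonmalignant: float
    t_fraction_all: float
    delta_nonmalignant: float | None = None  # post − pre, reported on post rows
    delta_all: float | None = None


@dataclass
class RoeMatrix:
    """Observed, expected and observed/expected counts, subsets × conditions."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    roe: pd.DataFrame

    def long_format(self) -> pd.DataFrame:
        rows = []
        for subset in self.observed.index:
            for cond in self.observed.columns:
                rows.append(
                    {
                        "subset": subset,
                        "condition": cond,
                        "observed": self.observed.loc[subset, cond],
                        "expected": self.expected.loc[subset, cond],
                        "roe": self.roe.loc[subset, cond],
                    }
                )
        return pd.DataFrame(rows, columns=["subset", "condition", "observed", "expected", "roe"])


def composition_change(
    cell_annotations: pd.DataFrame,
    min_t_cells: int = DEFAULT_MIN_T_CELLS,
) -> list[CompositionRecord]:
    """Per-specimen T-cell fractions and per-patient post − pre deltas.

    ``cell_annotations`` has one row per cell with columns ``patient``,
    ``timepoint`` (pre/post), ``is_t_cell`` (bool) and ``is_malignant``
    (bool).  Specimens with fewer than ``min_t_cells`` T cells are excluded
    (and logged).  A patient with only one retained timepoint gets a missing
    delta, not an error.
    """
    required = {"patient", "timepoint", "is_t_cell", "is_malignant"}
    missing = required - set(cell_annotations.columns)
    if missing:
        raise ValueError(f"cell annotations missing column(s): {sorted(missing)}")

    by_spec: dict[tuple[str, str], dict[str, float]] = {}
    for (patient, timepoint), grp in cell_annotations.groupby(["patient", "timepoint"]):
        n_t = int(grp["is_t_cell"].sum())
        if n_t < min_t_cells:
            logger.info(
                "excluding specimen (%s, %s): %d T cells < %d",
                patient, timepoint, n_t, min_t_cells,
            )
            continue
        n_nonmalignant = int((~grp["is_malignant"].astype(bool)).sum())
        by_spec[(str(patient), str(timepoint))] = {
            "t_nonmal": n_t / n_nonmalignant if n_nonmalignant else float("nan"),
            "t_all": n_t / len(grp),
        }

    records = []
    for (patient, timepoint), frac in sorted(by_spec.items()):
        delta_nonmal = delta_all = None
        if timepoint == "post" and (patient, "pre") in by_spec:
            pre = by_spec[(patient, "pre")]
            delta_nonmal = frac["t_nonmal"] - pre["t_nonmal"]
            delta_all = frac["t_all"] - pre["t_all"]
        records.append(
            CompositionRecord(
                patient=patient,
                timepoint=timepoint,
                t_fraction_nonmalignant=frac["t_nonmal"],
                t_fraction_all=frac["t_all"],
                delta_nonmalignant=delta_nonmal,
                delta_all=delta_all,
            )
        )
    return records


def roe(counts: pd.DataFrame) -> RoeMatrix:
    """Observed/expected enrichment of subsets (rows) across conditions (columns).

    Expected counts follow the independence model E_ij = row_i · col_j / N.
    Cells with E_ij = 0 (an all-zero row or column) get Ro/e = NaN
    (undefined); an observed 0 with positive expected gives Ro/e = 0.
    """
    obs = counts.astype(float)
    if (obs.values < 0).any():
        raise ValueError("contingency table must be non-negative")
    if obs.values.sum() == 0:
        raise ValueError("contingency table is all zero")
    row = obs.values.sum(axis=1)
    col = obs.values.sum(axis=0)
    if (row > 0).all() and (col > 0).all():
        exp = expected_freq(obs.values)
    else:  # expected_freq requires positive margins; fall back to the formula
        exp = np.outer(row, col) / obs.values.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp > 0, obs.values / np.where(exp > 0, exp, 1.0), np.nan)
    expected = pd.DataFrame(exp, index=obs.index, columns=obs.columns)
    roe_df = pd.DataFrame(ratio, index=obs.index, columns=obs.columns)
    return RoeMatrix(observed=obs, expected=expected, roe=roe_df)


def roe_difference(pre: RoeMatrix, post: RoeMatrix) -> pd.DataFrame:
    """Interpretive post − pre shift of Ro/e per subset.

    The difference of two observed/expected ratios has no canonical
    definition; this export is a descriptive convenience, not a statistic.
    Rows are aligned on the union of subsets (missing entries NaN).
    """
    pre_r = pre.roe
    post_r = post.roe
    subsets = sorted(set(pre_r.index) | set(post_r.index))
    rows = []
    for subset in subsets:
        for cond in sorted(set(pre_r.columns) | set(post_r.columns)):
            a = pre_r.loc[subset, cond] if subset in pre_r.index and cond in pre_r.columns else float("nan")
            b = post_r.loc[subset, cond] if subset in post_r.index and cond in post_r.columns else float("nan")
            rows.append(
                {"subset": subset, "condition": cond,
                 "roe_pre": a, "roe_post": b, "roe_post_minus_pre": b - a}
            )
    return pd.DataFrame(rows)
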