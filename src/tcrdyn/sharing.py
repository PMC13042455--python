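"""Clonal sharing between T-cell subsets with a permutation-based p-value.

The statistic is the number of clonotypes present in both subsets.  The
null model shuffles subset labels across the supplied cell pool, keeping
subset sizes and the clone structure fixed, and recomputes the shared count
each time; the reported p-value uses the add-one permutation estimator
p = (1 + #{null >= observed}) / (1 + n_permutations), so its attainable
minimum is 1/(n_permutations + 1).  A Spearman rank correlation between the
shared clones' cell counts in the two subsets is reported alongside as a
secondary descriptive statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .vdj_io import CellClonotype, ClonotypeKey

__all__ = ["SharingResult", "shared_clonotypes", "sharing_significance", "pairwise_sharing"]


@dataclass(frozen=True)
class SharingResult:
    subset_a: str
    subset_b: str
    shared_count: int
    clonotypes: tuple[ClonotypeKey, ...]
    p_value: float
    n_permutations: int
    seed: int
    freq_spearman_rho: float
    freq_spearman_p: float


def _subset_clones(
    cells: Sequence[CellClonotype], subset: str
) -> set[ClonotypeKey]:
    return {c.clonotype for c in cells if c.subset == subset}


def shared_clonotypes(
    cells: Iterable[CellClonotype], subset_a: str, subset_b: str
) -> tuple[int, list[ClonotypeKey]]:
    """Clonotypes observed in both subsets; symmetric in its arguments."""
    cells = list(cells)
    subsets = {c.subset for c in cells}
    for s in (subset_a, subset_b):
        if s not in subsets:
            raise ValueError(f"unknown subset {s!r}; have {sorted(subsets)}")
    shared = _subset_clones(cells, subset_a) & _subset_clones(cells, subset_b)
    ordered = sorted(shared, key=lambda k: k.as_string())
    return len(ordered), ordered


def sharing_significance(
    cells: Sequence[CellClonotype],
    subset_a: str,
    subset_b: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SharingResult:
    """Permutation test of the shared-clonotype count between two subsets.

    The permutation pool is the full list of cells passed in (restrict it to
    one response × timepoint group upstream to test within that group).
    Deterministic given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    cells = list(cells)
    n_obs, shared = shared_clonotypes(cells, subset_a, subset_b)

    # integer-encode clones and labels once; permute labels vectorised
    keys = sorted({c.clonotype for c in cells}, key=lambda k: k.as_string())
    key_idx = {k: i for i, k in enumerate(keys)}
    clone_ids = np.array([key_idx[c.clonotype] for c in cells], dtype=np.int64)
    in_a = np.array([c.subset == subset_a for c in cells])
    in_b = np.array([c.subset == subset_b for c in cells])
    if not in_a.any() or not in_b.any():
        raise ValueError("both subsets must have at least one cell")

    rng = np.random.default_rng(seed)
    n_cells = len(cells)
    n_clones = len(keys)
    # permute cells under the fixed label positions, in blocks to bound memory
    exceed = 0
    block = max(1, min(n_permutations, 256))
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perm = np.argsort(rng.random((b, n_cells)), axis=1)
        permuted = clone_ids[perm]  # (b, n_cells)
        pa = np.zeros((b, n_clones), dtype=bool)
        pb = np.zeros((b, n_clones), dtype=bool)
        rows_a = np.repeat(np.arange(b), int(in_a.sum()))
        rows_b = np.repeat(np.arange(b), int(in_b.sum()))
        pa[rows_a, permuted[:, in_a].ravel()] = True
        pb[rows_b, permuted[:, in_b].ravel()] = True
        exceed += int(((pa & pb).sum(axis=1) >= n_obs).sum())
        done += b
    p_value = (1 + exceed) / (1 + n_permutations)

    # secondary: rank correlation of shared clones' cell counts in a vs b
    if len(shared) >= 2:
        fa = [sum(1 for c in cells if c.subset == subset_a and c.clonotype == k) for k in shared]
        fb = [sum(1 for c in cells if c.subset == subset_b and c.clonotype == k) for k in shared]
        if len(set(fa)) > 1 and len(set(fb)) > 1:
            res = stats.spearmanr(fa, fb)
            rho, rho_p = float(res.statistic), float(res.pvalue)
        else:  # constant counts: correlation undefined
            rho, rho_p = float("nan"), float("nan")
    else:
        rho, rho_p = float("nan"), float("nan")

    return SharingResult(
        subset_a=subset_a,
        subset_b=subset_b,
        shared_count=n_obs,
        clonotypes=tuple(shared),
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        freq_spearman_rho=rho,
        freq_spearman_p=rho_p,
    )


def pairwise_sharing(
    cells: Sequence[CellClonotype],
    subsets: Sequence[str] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[SharingResult]:
    """Sharing test for every unordered subset pair (long-format output)."""
    cells = list(cells)
    if subsets is None:
        subsets = sorted({c.subset for c in cells})
    results = []
    for i, a in enumerate(subsets):
        for b in subsets[i + 1 :]:
            results.append(
                sharing_significance(cells, a, b, n_permutations=n_permutations, seed=seed)
            )
    return results
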