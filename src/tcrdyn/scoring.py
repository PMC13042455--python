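"""Rank-based per-cell gene-set activity scoring and group comparisons.

For each cell, genes are ordered by descending expression (ties broken by
gene name, giving a deterministic total order) and the score is the area
under the gene-set recovery curve over the top-ranked genes:

    AUC = sum_{r=1..k} c(r) / sum_{r=1..k} c_max(r)

where c(r) is the cumulative number of gene-set members among the top r
genes, c_max(r) = min(r, |S|) is the recovery curve with all set genes at
the very top, and k = ceil(top_fraction * n_genes) (default top 5%).  The
score is in [0, 1], depends only on ranks (invariant to monotone transforms
of a cell's expression values), and rises as set genes move up in rank.

Group-level summaries z-score the per-group mean AUC across groups
(sample standard deviation); two-group contrasts use a two-sided unpaired
Welch t-test on the per-cell scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread

__all__ = [
    "ExpressionMatrix",
    "GroupScoreSummary",
    "GroupComparison",
    "aucell_score",
    "zscore_group_means",
    "compare_groups",
    "significance_tier",
    "pdcd1_groups",
    "clone_size_strata",
    "read_gmt",
    "write_gmt",
    "read_expression_bundle",
]

DEFAULT_TOP_FRACTION = 0.05


@dataclass
class ExpressionMatrix:
    """Cell × gene expression counts with aligned cell and gene name lists."""

    matrix: sparse.csr_matrix  # cells × genes
    cells: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )


@dataclass(frozen=True)
class GroupScoreSummary:
    group: str
    mean_auc: float
    z_mean: float  # NaN when only one group
    n_cells: int


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    tier: str
    n_a: int
    n_b: int


def aucell_score(
    expression: ExpressionMatrix,
    gene_set: Sequence[str],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    gene_set_name: str = "gene_set",
) -> pd.DataFrame:
    """Per-cell recovery-curve AUC of a gene set.

    Returns a DataFrame with columns cell, gene_set, auc, threshold_rank.

    Raises
    ------
    ValueError
        If no gene of the set is present in the matrix (the error names the
        missing genes), or top_fraction is outside (0, 1].
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    genes = list(expression.genes)
    present = [g for g in gene_set if g in set(genes)]
    if not present:
        raise ValueError(
            f"gene set {gene_set_name!r} has no overlap with the matrix; "
            f"missing genes: {sorted(set(gene_set))}"
        )
    n_genes = len(genes)
    k = math.ceil(top_fraction * n_genes)
    s = len(present)

    # Reorder columns alphabetically once, then a stable descending sort on
    # expression resolves ties by gene name.
    name_order = np.argsort(np.asarray(genes, dtype=object), kind="stable")
    x = expression.matrix.toarray()[:, name_order].astype(float)
    membership = np.zeros(n_genes, dtype=bool)
    present_set = set(present)
    for j, gi in enumerate(name_order):
        if genes[gi] in present_set:
            membership[j] = True

    order = np.argsort(-x, axis=1, kind="stable")  # (cells, genes)
    hits_top = membership[order[:, :k]]  # (cells, k)
    numerator = np.cumsum(hits_top, axis=1).sum(axis=1).astype(float)
    r = np.arange(1, k + 1)
    denominator = float(np.minimum(r, s).sum())
    auc = numerator / denominator
    return pd.DataFrame(
        {
            "cell": expression.cells,
            "gene_set": gene_set_name,
            "auc": auc,
            "threshold_rank": k,
        }
    )


def zscore_group_means(
    scores: pd.DataFrame, grouping: Mapping[str, str]
) -> list[GroupScoreSummary]:
    """Mean AUC per group, z-scored across groups (sample SD, ddof=1).

    Cells absent from ``grouping`` are ignored.  With a single group the
    mean is returned and the z-score is NaN (undefined); with equal group
    means (zero SD) all z-scores are 0.
    """
    df = scores.copy()
    df["group"] = df["cell"].map(grouping)
    df = df.dropna(subset=["group"])
    if df.empty:
        raise ValueError("no scored cell maps to a group")
    means = df.groupby("group")["auc"].agg(["mean", "size"]).sort_index()
    if len(means) >= 2:
        sd = means["mean"].std(ddof=1)
        z = (means["mean"] - means["mean"].mean()) / sd if sd > 0 else means["mean"] * 0.0
    else:
        z = pd.Series(float("nan"), index=means.index)
    return [
        GroupScoreSummary(
            group=str(g),
            mean_auc=float(means.loc[g, "mean"]),
            z_mean=float(z.loc[g]),
            n_cells=int(means.loc[g, "size"]),
        )
        for g in means.index
    ]


def significance_tier(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    scores: pd.DataFrame,
    grouping: Mapping[str, str],
    groups: tuple[str, str],
) -> GroupComparison:
    """Welch two-sided unpaired t-test on per-cell AUC between two groups.

    Degenerate input (zero variance in both groups, equal means) returns
    p = 1 by convention.
    """
    a_label, b_label = groups
    df = scores.copy()
    df["group"] = df["cell"].map(grouping)
    a = df.loc[df["group"] == a_label, "auc"].to_numpy(dtype=float)
    b = df.loc[df["group"] == b_label, "auc"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 cells")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_a=a_label,
        group_b=b_label,
        statistic=stat,
        p_value=p,
        tier=significance_tier(p),
        n_a=len(a),
        n_b=len(b),
    )


def pdcd1_groups(
    expression: ExpressionMatrix, gene: str = "PDCD1"
) -> dict[str, str]:
    """Stratify cells by marker expression: positive (> 0) vs negative (= 0)."""
    if gene not in expression.genes:
        raise ValueError(f"gene {gene!r} not in the expression matrix")
    j = expression.genes.index(gene)
    values = np.asarray(expression.matrix[:, j].todense()).ravel()
    return {
        cell: f"{gene}+" if v > 0 else f"{gene}-"
        for cell, v in zip(expression.cells, values)
    }


def clone_size_strata(
    copy_numbers: Mapping[str, int],
    expanded_threshold: int = 2,
) -> dict[str, str]:
    """Stratify cells by their clone's copy number.

    ``expanded`` for copy number strictly above ``expanded_threshold``
    (default > 2), ``novel_nonexpanded`` for singletons (copy number 1),
    ``intermediate`` otherwise.  ``copy_numbers`` maps cell barcode to its
    clone's specimen-level copy number.
    """
    out = {}
    for cell, n in copy_numbers.items():
        if n > expanded_threshold:
            out[cell] = "expanded"
        elif n == 1:
            out[cell] = "novel_nonexpanded"
        else:
            out[cell] = "intermediate"
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_expression_bundle(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix (genes × cells, 10x layout) plus lists."""
    m = sparse.csr_matrix(mmread(matrix_path))
    genes = [line.split("\t")[0].strip() for line in open(genes_path) if line.strip()]
    cells = [line.strip() for line in open(barcodes_path) if line.strip()]
    if m.shape == (len(genes), len(cells)):
        m = m.T.tocsr()  # store cells × genes internally
    elif m.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {m.shape} matches neither genes x cells nor cells x genes"
        )
    return ExpressionMatrix(matrix=m, cells=cells, genes=genes)
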