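"""Paired pre/post-treatment clonotype tracking and expansion classification.

Clonotypes are matched across the two timepoints of a patient by exact key
equality, and each clone is classified from its whole-specimen copy numbers:

* novel expanded — absent before treatment, expanded after (pre = 0, post >= 2)
* persistent expanded — present before and further expanded after
  (pre >= 1, post >= 2, post > pre)
* novel nonexpanded — absent before, a single cell after (pre = 0, post = 1)
* other — everything else (unchanged, contracted, or lost clones)

Clones with pre >= 1 and post = 0 fall in "other" but carry an additional
``lost`` tag, so pre-treatment-only expansion remains visible downstream.
Classes are assigned at the whole-specimen level and then projected onto
T-cell subsets: a clone spanning two subsets keeps one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .vdj_io import CellClonotype, CloneTable, ClonotypeKey

__all__ = [
    "NOVEL_EXPANDED",
    "PERSISTENT_EXPANDED",
    "NOVEL_NONEXPANDED",
    "OTHER",
    "EXPANSION_CLASSES",
    "PairedClone",
    "SubsetExpansionProfile",
    "classify_expansion",
    "pair_repertoires",
    "subset_expansion_profile",
    "paired_to_frame",
]

NOVEL_EXPANDED = "novel_expanded"
PERSISTENT_EXPANDED = "persistent_expanded"
NOVEL_NONEXPANDED = "novel_nonexpanded"
OTHER = "other"
EXPANSION_CLASSES = (NOVEL_EXPANDED, PERSISTENT_EXPANDED, NOVEL_NONEXPANDED, OTHER)


@dataclass(frozen=True)
class PairedClone:
    """One clonotype's pre/post copy numbers and expansion class."""

    clonotype: ClonotypeKey
    patient: str
    pre_copies: int
    post_copies: int
    expansion_class: str
    lost: bool = False


@dataclass(frozen=True)
class SubsetExpansionProfile:
    """Post-treatment expansion-class composition of one T-cell subset."""

    subset: str
    class_cell_counts: dict[str, int]
    class_clone_counts: dict[str, int]
    mean_post_copies: dict[str, float]


def classify_expansion(pre_copies: int, post_copies: int) -> str:
    """Deterministic expansion class of a (pre, post) copy-number pair."""
    if pre_copies < 0 or post_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    if pre_copies == 0 and post_copies == 0:
        raise ValueError("clone absent at both timepoints has no class")
    if pre_copies == 0 and post_copies >= 2:
        return NOVEL_EXPANDED
    if pre_copies >= 1 and post_copies >= 2 and post_copies > pre_copies:
        return PERSISTENT_EXPANDED
    if pre_copies == 0 and post_copies == 1:
        return NOVEL_NONEXPANDED
    return OTHER


def pair_repertoires(pre: CloneTable, post: CloneTable) -> list[PairedClone]:
    """Union pre and post clone tables of one patient, zero-filling absences.

    Copy totals are conserved: summed pre_copies equal the pre specimen's
    cell count and likewise for post.
    """
    if pre.specimen[0] != post.specimen[0]:
        raise ValueError(
            f"cannot pair specimens of different patients: "
            f"{pre.specimen[0]!r} vs {post.specimen[0]!r}"
        )
    patient = pre.specimen[0]
    keys = set(pre.counts) | set(post.counts)
    paired = []
    for key in sorted(keys, key=lambda k: k.as_string()):
        pre_n = pre.counts.get(key, 0)
        post_n = post.counts.get(key, 0)
        paired.append(
            PairedClone(
                clonotype=key,
                patient=patient,
                pre_copies=pre_n,
                post_copies=post_n,
                expansion_class=classify_expansion(pre_n, post_n),
                lost=pre_n >= 1 and post_n == 0,
            )
        )
    return paired


def subset_expansion_profile(
    paired: Sequence[PairedClone],
    cells: Iterable[CellClonotype],
    subset: str,
) -> SubsetExpansionProfile:
    """Project specimen-level expansion classes onto one subset's post cells.

    ``cells`` must be post-treatment cells; each cell of the subset
    contributes to the class of its clone.  Clone counts and mean post copy
    numbers are over the distinct clones observed in the subset.
    """
    cells = list(cells)
    known_subsets = {c.subset for c in cells}
    if subset not in known_subsets:
        raise ValueError(f"unknown subset {subset!r}; have {sorted(known_subsets)}")
    class_by_key = {pc.clonotype: pc for pc in paired}

    cell_counts = {cls: 0 for cls in EXPANSION_CLASSES}
    clones_seen: dict[str, set[ClonotypeKey]] = {cls: set() for cls in EXPANSION_CLASSES}
    for cell in cells:
        if cell.subset != subset:
            continue
        pc = class_by_key.get(cell.clonotype)
        if pc is None:
            raise ValueError(
                f"cell {cell.barcode!r} carries a clonotype absent from the paired table"
            )
        cell_counts[pc.expansion_class] += 1
        clones_seen[pc.expansion_class].add(cell.clonotype)

    clone_counts = {cls: len(clones_seen[cls]) for cls in EXPANSION_CLASSES}
    mean_post = {}
    for cls in EXPANSION_CLASSES:
        keys = clones_seen[cls]
        mean_post[cls] = (
            sum(class_by_key[k].post_copies for k in keys) / len(keys) if keys else 0.0
        )
    return SubsetExpansionProfile(
        subset=subset,
        class_cell_counts=cell_counts,
        class_clone_counts=clone_counts,
        mean_post_copies=mean_post,
    )


def paired_to_frame(paired: Sequence[PairedClone]) -> pd.DataFrame:
    """Per-clone paired table (stable column order)."""
    rows = [
        {
            "patient": pc.patient,
            "clonotype": pc.clonotype.as_string(),
            "pre_copies": pc.pre_copies,
            "post_copies": pc.post_copies,
            "expansion_class": pc.expansion_class,
            "lost": pc.lost,
        }
        for pc in paired
    ]
    return pd.DataFrame(
        rows,
        columns=["patient", "clonotype", "pre_copies", "post_copies", "expansion_class", "lost"],
    )
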