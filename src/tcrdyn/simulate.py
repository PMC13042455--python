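"""Synthetic paired pre/post TCR repertoires with planted ground truth.

The generator emulates the statistical structure of a small neoadjuvant
immunochemotherapy cohort: ~5 patients labelled PCR / MPR / non-MPR, one
pre- and one post-treatment specimen each, 14 T-cell subsets with a fixed
baseline composition, and clone sizes drawn from a truncated discrete power
law (exponent alpha, default 2.5).

Treatment effect is planted explicitly.  Each specimen pair receives a
configured number of novel expanded (pre 0, post >= 2), persistent expanded
(pre >= 1, post > pre, post >= 2) and novel nonexpanded (pre 0, post 1)
clones; planted clones' cells are concentrated in the response-appropriate
target subset (a CD8 Tem-like subset for responders, the Treg subset for
nonresponders) with odds multiplied by the boost factor b.  Background
clones persist by subsampling: the post-treatment background is a
multivariate-hypergeometric draw of surviving cells from the pre-treatment
cell pool, so a background clone's post copy number never exceeds its pre
copy number and contracted/lost clones arise naturally, while clonal
expansion arises only from the planted proliferating clones.

The expression simulator draws negative-binomial background counts,
multiplies planted pathway genes' means by (1 + delta) in designated cells,
and elevates a PDCD1-like marker in a configured subpopulation.

Everything is reproducible from the configuration seed, including the
emitted 10x-dialect contig tables, so fixture bundles are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .scoring import ExpressionMatrix, write_gmt

__all__ = [
    "DEFAULT_SUBSETS",
    "DEFAULT_PROPORTIONS",
    "SimulationConfig",
    "SimulatedRepertoire",
    "SimulatedExpression",
    "simulate_repertoire",
    "simulate_expression",
    "designated_pathway_cells",
    "write_fixture_bundle",
]

# 14 T-cell subset labels: four CD4, seven CD8, two NKT and one proliferating
# cluster, named <cluster>_<lineage>_<state>-<marker gene>.
DEFAULT_SUBSETS = (
    "c01_CD4_Tn-CCR7",
    "c02_CD4_Tem-CXCR4",
    "c03_CD4_Treg-FOXP3",
    "c04_CD4_Tex-CXCL13",
    "c05_CD8_Tem-GZMA",
    "c06_CD8_Tem-EGR1",
    "c07_CD8_Teff-IFNG",
    "c08_CD8_Trm-ZNF683",
    "c09_CD8_Tex-HAVCR2",
    "c10_CD8-HSPA1A",
    "c11_CD8-IFI6",
    "c12_NKT-GNLY",
    "c13_NKT-FGFBP2",
    "c14_T_MKI67",
)
DEFAULT_PROPORTIONS = (
    0.12, 0.10, 0.10, 0.05, 0.12, 0.08, 0.08, 0.07, 0.07, 0.05, 0.04, 0.05, 0.04, 0.03,
)

_TRA_V = tuple(f"TRAV{i}" for i in range(1, 9))
_TRA_J = tuple(f"TRAJ{i}" for i in range(1, 7))
_TRB_V = tuple(f"TRBV{i}" for i in range(1, 9))
_TRB_J = tuple(f"TRBJ{i}" for i in range(1, 3))

_CONTIG_COLUMNS = [
    "barcode", "is_cell", "high_confidence", "chain", "v_gene", "j_gene",
    "cdr3", "cdr3_nt", "reads", "umis", "productive", "full_length",
]

# Deterministic pseudo-translation for synthetic CDR3s: each codon maps to
# one of 20 letters by its base-4 index modulo 20 (degenerate like the real
# code, but not the real code).
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pseudo_translate(nt: str) -> str:
    return "".join(
        _AA_ALPHABET[
            (_NT_INDEX[nt[i]] * 16 + _NT_INDEX[nt[i + 1]] * 4 + _NT_INDEX[nt[i + 2]]) % 20
        ]
        for i in range(0, len(nt) - len(nt) % 3, 3)
    )


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults: 2 PCR + 1 MPR + 2 non-MPR patients, 2000 cells per specimen,
    power-law clone sizes with alpha = 2.5 capped at 100 copies, boost
    b = 5 concentrating planted expansion in the CD8 Tem-like subset for
    responders (PCR/MPR) and the Treg subset for nonresponders, and
    50 novel expanded + 50 persistent expanded + 100 novel nonexpanded
    clones planted per specimen pair.
    """

    n_patients: Mapping[str, int] = field(
        default_factory=lambda: {"PCR": 2, "MPR": 1, "nonMPR": 2}
    )
    n_cells: int = 2000
    subsets: Sequence[str] = DEFAULT_SUBSETS
    proportions: Sequence[float] = DEFAULT_PROPORTIONS
    alpha: float = 2.5
    max_copy: int = 100
    boost: float = 5.0
    target_subsets: Mapping[str, str] = field(
        default_factory=lambda: {
            "PCR": "c05_CD8_Tem-GZMA",
            "MPR": "c05_CD8_Tem-GZMA",
            "nonMPR": "c03_CD4_Treg-FOXP3",
        }
    )
    n_novel_expanded: int = 50
    n_persistent_expanded: int = 50
    n_novel_nonexpanded: int = 100
    noise_contig_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if len(self.subsets) != len(self.proportions):
            raise ValueError("subsets and proportions must have equal length")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("subset proportions must sum to 1")
        if self.alpha <= 1:
            raise ValueError("power-law exponent alpha must exceed 1")
        if self.boost < 1:
            raise ValueError("boost factor must be >= 1")
        for name in ("n_cells", "n_novel_expanded", "n_persistent_expanded",
                     "n_novel_nonexpanded", "max_copy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for resp in self.n_patients:
            if resp not in self.target_subsets:
                raise ValueError(f"no target subset configured for response {resp!r}")
            if self.target_subsets[resp] not in self.subsets:
                raise ValueError(
                    f"target subset {self.target_subsets[resp]!r} not in subsets"
                )


@dataclass
class SimulatedRepertoire:
    """Contig tables per specimen, cell metadata, and the planted truth.

    ``ground_truth`` is clone-level (one row per clonotype and patient);
    ``cell_ground_truth`` maps each cell barcode to its clonotype and its
    clone's planted class.  Both are generator bookkeeping, not pipeline
    inputs.
    """

    contigs: dict[tuple[str, str], pd.DataFrame]
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame
    cell_ground_truth: pd.DataFrame
    config: SimulationConfig


@dataclass
class SimulatedExpression:
    expression: ExpressionMatrix
    gene_sets: dict[str, list[str]]
    boosted_cells: tuple[str, ...]
    pdcd1_positive_cells: tuple[str, ...]


def _draw_power_law(rng: np.random.Generator, n: int, alpha: float, cap: int) -> np.ndarray:
    """Truncated zeta (Zipf) clone sizes via rejection of values above cap."""
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.zipf(alpha, size=max(n, 64))
        out = np.concatenate([out, draw[draw <= cap]])
    return out[:n]


def _new_key(rng: np.random.Generator, used: set[str]) -> tuple[str, ...]:
    while True:
        tra_len = 3 * int(rng.integers(9, 16))   # 27..45 nt
        trb_len = 3 * int(rng.integers(9, 16))
        tra_nt = "".join(rng.choice(list("ACGT"), size=tra_len))
        trb_nt = "".join(rng.choice(list("ACGT"), size=trb_len))
        key = (
            str(rng.choice(_TRA_V)), str(rng.choice(_TRA_J)), tra_nt,
            str(rng.choice(_TRB_V)), str(rng.choice(_TRB_J)), trb_nt,
        )
        flat = "|".join(key)
        if flat not in used:
            used.add(flat)
            return key


def _subset_probs(
    config: SimulationConfig, target: str, boosted: bool
) -> np.ndarray:
    p = np.asarray(config.proportions, dtype=float)
    if not boosted:
        return p
    t = list(config.subsets).index(target)
    w = p.copy()
    w[t] *= config.boost
    return w / w.sum()


def simulate_repertoire(config: SimulationConfig | None = None) -> SimulatedRepertoire:
    """Generate the full synthetic cohort; reproducible from ``config.seed``."""
    config = config or SimulationConfig()
    config.validate()

    patients = [
        (f"{resp}{i + 1}", resp)
        for resp in sorted(config.n_patients)
        for i in range(config.n_patients[resp])
    ]

    contigs: dict[tuple[str, str], pd.DataFrame] = {}
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    cell_truth_rows: list[dict] = []

    for p_index, (patient, response) in enumerate(patients):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, p_index]))
        target = config.target_subsets[response]
        used_keys: set[str] = set()

        # --- planted clones ------------------------------------------------
        planted: list[dict] = []
        for _ in range(config.n_persistent_expanded):
            pre = int(rng.integers(1, 4))
            post = max(2, pre + 1 + int(rng.poisson((config.boost - 1) * pre)))
            planted.append(
                {"key": _new_key(rng, used_keys), "pre": pre, "post": post,
                 "class": "persistent_expanded", "boosted": True}
            )
        for _ in range(config.n_novel_expanded):
            post = 2 + int(rng.poisson(config.boost - 1))
            planted.append(
                {"key": _new_key(rng, used_keys), "pre": 0, "post": post,
                 "class": "novel_expanded", "boosted": True}
            )
        for _ in range(config.n_novel_nonexpanded):
            planted.append(
                {"key": _new_key(rng, used_keys), "pre": 0, "post": 1,
                 "class": "novel_nonexpanded", "boosted": True}
            )

        pre_planted = sum(c["pre"] for c in planted)
        post_planted = sum(c["post"] for c in planted)
        if pre_planted > config.n_cells or post_planted > config.n_cells:
            raise ValueError(
                f"planted cells ({pre_planted} pre / {post_planted} post) exceed "
                f"n_cells = {config.n_cells}"
            )

        # --- background: power-law pre sizes, hypergeometric carry-forward --
        pre_bg_target = config.n_cells - pre_planted
        sizes: list[int] = []
        total = 0
        while total < pre_bg_target:
            s = int(_draw_power_law(rng, 1, config.alpha, config.max_copy)[0])
            s = min(s, pre_bg_target - total)
            sizes.append(s)
            total += s
        pre_bg = np.asarray(sizes, dtype=np.int64)
        post_bg_depth = config.n_cells - post_planted
        if post_bg_depth > pre_bg.sum():
            raise ValueError(
                "planted post cells leave more background cells than the "
                "pre-treatment background can supply"
            )
        post_bg = rng.multivariate_hypergeometric(pre_bg, post_bg_depth)

        background = [
            {"key": _new_key(rng, used_keys), "pre": int(a), "post": int(b),
             "class": "background", "boosted": False}
            for a, b in zip(pre_bg, post_bg)
        ]
        clones = planted + background

        for clone in clones:
            truth_rows.append(
                {
                    "patient": patient,
                    "response": response,
                    "clonotype": "|".join(clone["key"]),
                    "planted_class": clone["class"],
                    "pre_copies": clone["pre"],
                    "post_copies": clone["post"],
                    "target_boosted": clone["boosted"],
                }
            )

        # --- cells, subsets, contigs ---------------------------------------
        for timepoint in ("pre", "post"):
            cell_clones: list[dict] = []
            for clone in clones:
                copies = clone["pre"] if timepoint == "pre" else clone["post"]
                probs = _subset_probs(config, target, clone["boosted"])
                for _ in range(copies):
                    subset = str(rng.choice(np.asarray(config.subsets), p=probs))
                    cell_clones.append({"clone": clone, "subset": subset})
            order = rng.permutation(len(cell_clones))
            rows = []
            for new_idx, old_idx in enumerate(order):
                entry = cell_clones[old_idx]
                barcode = f"{patient}_{timepoint}_{new_idx:05d}-1"
                meta_rows.append(
                    {
                        "barcode": barcode,
                        "patient": patient,
                        "timepoint": timepoint,
                        "response": response,
                        "subset": entry["subset"],
                    }
                )
                cell_truth_rows.append(
                    {
                        "barcode": barcode,
                        "patient": patient,
                        "timepoint": timepoint,
                        "response": response,
                        "subset": entry["subset"],
                        "clonotype": "|".join(entry["clone"]["key"]),
                        "planted_class": entry["clone"]["class"],
                    }
                )
                rows.extend(_contig_rows(rng, barcode, entry["clone"]["key"], config))
            contigs[(patient, timepoint)] = pd.DataFrame(rows, columns=_CONTIG_COLUMNS)

    metadata = pd.DataFrame(
        meta_rows, columns=["barcode", "patient", "timepoint", "response", "subset"]
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient", "response", "clonotype", "planted_class",
            "pre_copies", "post_copies", "target_boosted",
        ],
    )
    cell_ground_truth = pd.DataFrame(
        cell_truth_rows,
        columns=[
            "barcode", "patient", "timepoint", "response", "subset",
            "clonotype", "planted_class",
        ],
    )
    return SimulatedRepertoire(
        contigs=contigs,
        metadata=metadata,
        ground_truth=ground_truth,
        cell_ground_truth=cell_ground_truth,
        config=config,
    )


def designated_pathway_cells(
    repertoire: SimulatedRepertoire,
    classes: Sequence[str] = ("novel_expanded", "persistent_expanded"),
) -> set[str]:
    """Post-treatment nonresponder cells of planted clones in the Treg-like
    target subset — the cells whose pathway genes the expression simulator
    boosts."""
    truth = repertoire.cell_ground_truth
    targets = repertoire.config.target_subsets
    mask = (
        (truth["timepoint"] == "post")
        & (truth["response"] == "nonMPR")
        & (truth["planted_class"].isin(classes))
        & (truth["subset"] == truth["response"].map(targets))
    )
    return set(truth.loc[mask, "barcode"])


def _contig_rows(
    rng: np.random.Generator, barcode: str, key: tuple[str, ...], config: SimulationConfig
) -> list[dict]:
    tra_v, tra_j, tra_nt, trb_v, trb_j, trb_nt = key
    rows = []
    for chain, v, j, nt in (("TRA", tra_v, tra_j, tra_nt), ("TRB", trb_v, trb_j, trb_nt)):
        umis = int(rng.integers(3, 30))
        rows.append(
            {
                "barcode": barcode,
                "is_cell": "True",
                "high_confidence": "True",
                "chain": chain,
                "v_gene": v,
                "j_gene": j,
                "cdr3": _pseudo_translate(nt),
                "cdr3_nt": nt,
                "reads": umis * int(rng.integers(5, 15)),
                "umis": umis,
                "productive": "True",
                "full_length": "True",
            }
        )
    # occasional nonproductive extra contig, dropped by step-1 QC
    if rng.random() < config.noise_contig_rate:
        nt = "".join(rng.choice(list("ACGT"), size=30))
        rows.append(
            {
                "barcode": barcode,
                "is_cell": "True",
                "high_confidence": "True",
                "chain": "TRA",
                "v_gene": str(rng.choice(_TRA_V)),
                "j_gene": str(rng.choice(_TRA_J)),
                "cdr3": _pseudo_translate(nt),
                "cdr3_nt": nt,
                "reads": int(rng.integers(10, 100)),
                "umis": 1,
                "productive": "False",
                "full_length": "True",
            }
        )
    # occasional weaker secondary productive TRA, resolved by dominance
    if rng.random() < config.noise_contig_rate / 2:
        nt = "".join(rng.choice(list("ACGT"), size=33))
        umis = max(1, int(rows[0]["umis"]) - int(rng.integers(1, 3)))
        rows.append(
            {
                "barcode": barcode,
                "is_cell": "True",
                "high_confidence": "True",
                "chain": "TRA",
                "v_gene": str(rng.choice(_TRA_V)),
                "j_gene": str(rng.choice(_TRA_J)),
                "cdr3": _pseudo_translate(nt),
                "cdr3_nt": nt,
                "reads": max(1, umis * 4),
                "umis": umis,
                "productive": "True",
                "full_length": "True",
            }
        )
    return rows


def simulate_expression(
    metadata: pd.DataFrame,
    boosted_barcodes: set[str] | Sequence[str],
    delta: float = 2.0,
    seed: int = 0,
    n_background_genes: int = 150,
    pathway_size: int = 25,
    marker_gene: str = "PDCD1",
    marker_positive_rate: Mapping[str, float] | None = None,
) -> SimulatedExpression:
    """Toy expression matrix with planted pathway activity.

    Counts are negative-binomial (dispersion 2) around gene-specific
    lognormal means; the two planted pathway gene sets (synthetic IL-2/STAT5
    and TGF-beta/SMAD analogues) have their means multiplied by (1 + delta)
    in ``boosted_barcodes``.  The PDCD1-like marker is positive in a
    subset-dependent fraction of cells (default 40% in Treg/Tex subsets,
    10% elsewhere) and exactly zero in the rest.
    """
    if delta < 0:
        raise ValueError("pathway effect delta must be >= 0")
    if pathway_size < 1:
        raise ValueError("pathway gene list must be non-empty")
    rng = np.random.default_rng(seed)
    cells = metadata["barcode"].tolist()
    boosted = set(boosted_barcodes)

    set_a = [f"IL2S{i:03d}" for i in range(pathway_size)]
    set_b = [f"TGFB{i:03d}" for i in range(pathway_size)]
    background = [f"BG{i:04d}" for i in range(n_background_genes)]
    genes = background + set_a + set_b + [marker_gene]
    gene_sets = {"IL2_STAT5_SYNTHETIC": set_a, "TGFB_SMAD_SYNTHETIC": set_b}

    n_cells, n_genes = len(cells), len(genes)
    base_mu = rng.lognormal(mean=-0.3, sigma=0.8, size=n_genes)
    base_mu[-1] = 0.0  # marker handled separately

    mu = np.tile(base_mu, (n_cells, 1))
    boost_mask = np.array([bc in boosted for bc in cells])
    pw_cols = np.arange(n_background_genes, n_background_genes + 2 * pathway_size)
    mu[np.ix_(boost_mask, pw_cols)] *= 1.0 + delta

    r = 2.0  # NB dispersion (size)
    p = r / (r + np.maximum(mu, 1e-12))
    counts = rng.negative_binomial(r, p).astype(np.int64)
    counts[:, -1] = 0

    rates = marker_positive_rate or {"Treg": 0.4, "Tex": 0.4}
    subset_rate = np.array(
        [
            next((v for k, v in rates.items() if k in s), 0.1)
            for s in metadata["subset"].tolist()
        ]
    )
    positive = rng.random(n_cells) < subset_rate
    counts[positive, -1] = 1 + rng.poisson(1.0, size=int(positive.sum()))

    expr = ExpressionMatrix(
        matrix=sparse.csr_matrix(counts), cells=cells, genes=genes
    )
    return SimulatedExpression(
        expression=expr,
        gene_sets=gene_sets,
        boosted_cells=tuple(bc for bc in cells if bc in boosted),
        pdcd1_positive_cells=tuple(np.asarray(cells)[positive]),
    )


def write_fixture_bundle(
    repertoire: SimulatedRepertoire,
    directory: str | Path,
    expression: SimulatedExpression | None = None,
) -> dict[str, Path]:
    """Write the synthetic bundle as plain-text files; same seed, same bytes.

    Emits one 10x-dialect contig CSV per specimen, the metadata and
    ground-truth tables, and (optionally) a MatrixMarket expression matrix
    with gene/barcode lists and a GMT of the planted gene sets.  Re-reading
    the contig files through :mod:`tcrdyn.vdj_io` reproduces the generator's
    cell counts exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    for (patient, timepoint), frame in sorted(repertoire.contigs.items()):
        path = directory / f"contigs_{patient}_{timepoint}.csv"
        frame.to_csv(path, index=False)
        files[f"contigs_{patient}_{timepoint}"] = path
    meta_path = directory / "metadata.tsv"
    repertoire.metadata.to_csv(meta_path, sep="\t", index=False)
    files["metadata"] = meta_path
    truth_path = directory / "ground_truth.tsv"
    repertoire.ground_truth.to_csv(truth_path, sep="\t", index=False)
    files["ground_truth"] = truth_path
    cell_truth_path = directory / "cell_ground_truth.tsv"
    repertoire.cell_ground_truth.to_csv(cell_truth_path, sep="\t", index=False)
    files["cell_ground_truth"] = cell_truth_path

    if expression is not None:
        mtx_path = directory / "matrix.mtx"
        # genes x cells orientation, 10x layout
        mmwrite(str(mtx_path), expression.expression.matrix.T.tocoo(), field="integer")
        files["matrix"] = mtx_path
        genes_path = directory / "genes.tsv"
        genes_path.write_text("".join(f"{g}\t{g}\n" for g in expression.expression.genes))
        files["genes"] = genes_path
        barcodes_path = directory / "barcodes.tsv"
        barcodes_path.write_text("".join(f"{b}\n" for b in expression.expression.cells))
        files["barcodes"] = barcodes_path
        gmt_path = directory / "gene_sets.gmt"
        write_gmt(expression.gene_sets, gmt_path)
        files["gene_sets"] = gmt_path
    return files
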