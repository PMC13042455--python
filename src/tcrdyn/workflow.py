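"""End-to-end pipeline orchestration and run manifests.

Stages: clonotype calling -> repertoire metrics -> paired expansion
dynamics -> subset enrichment (Ro/e) -> clonal sharing -> optional pathway
scoring.  Each stage writes tab-delimited tables into the output directory;
a JSON manifest records the parameters, the seed, input digests and a
SHA-256 digest of every output file, so re-running with identical inputs
and config is checkable by digest equality.  A failing stage aborts the run
with the stage name; tables already written are kept alongside a FAILED
marker file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .dynamics import (
    EXPANSION_CLASSES,
    pair_repertoires,
    paired_to_frame,
    subset_expansion_profile,
)
from .enrichment import roe
from .metrics import DEFAULT_BIN_EDGES, copy_number_spectrum, summarize_strata
from .scoring import aucell_score, read_expression_bundle, read_gmt, zscore_group_means
from .sharing import pairwise_sharing
from .vdj_io import (
    call_clonotypes,
    cells_to_frame,
    clone_tables_by_specimen,
    read_contigs,
    read_metadata,
)

__all__ = ["RunConfig", "run_pipeline", "summarize_report"]

logger = logging.getLogger(__name__)

STAGES = ("clonotypes", "metrics", "dynamics", "roe", "sharing", "score")


@dataclass
class RunConfig:
    """Plain-text run configuration (loadable from YAML)."""

    contig_paths: Sequence[str]
    metadata_path: str
    out_dir: str
    expression_matrix: str | None = None
    expression_genes: str | None = None
    expression_barcodes: str | None = None
    gene_sets: str | None = None
    key_mode: str = "nt"
    min_t_cells: int = 20
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
    top_fraction: float = 0.05
    n_permutations: int = 300
    min_subset_cells_for_sharing: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def has_expression(self) -> bool:
        return all(
            p is not None
            for p in (self.expression_matrix, self.expression_genes,
                      self.expression_barcodes, self.gene_sets)
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; return the manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tcrdyn_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {},
        "stages": [],
        "outputs": {},
    }
    for p in list(config.contig_paths) + [config.metadata_path]:
        manifest["inputs"][str(p)] = _sha256(Path(p))

    outputs: dict[str, Path] = {}
    current_stage = "clonotypes"
    try:
        # --- clonotypes ----------------------------------------------------
        contigs = []
        for path in config.contig_paths:
            contigs.extend(read_contigs(path))
        metadata = read_metadata(config.metadata_path)
        cells = call_clonotypes(contigs, metadata, key_mode=config.key_mode)
        tables = clone_tables_by_specimen(cells)
        cell_frame = cells_to_frame(cells)
        outputs["cell_clonotypes.tsv"] = out / "cell_clonotypes.tsv"
        cell_frame.to_csv(outputs["cell_clonotypes.tsv"], sep="\t", index=False)
        clone_rows = [
            {
                "patient": spec[0],
                "timepoint": spec[1],
                "clonotype": key.as_string(),
                "copies": n,
            }
            for spec, table in tables.items()
            for key, n in sorted(table.counts.items(), key=lambda kv: kv[0].as_string())
        ]
        outputs["clone_tables.tsv"] = out / "clone_tables.tsv"
        pd.DataFrame(clone_rows).to_csv(outputs["clone_tables.tsv"], sep="\t", index=False)
        manifest["stages"].append("clonotypes")

        # --- metrics -------------------------------------------------------
        current_stage = "metrics"
        pooled = summarize_strata(cells, by=("response", "timepoint"))
        per_patient = summarize_strata(cells, by=("patient", "timepoint"))
        per_subset = summarize_strata(
            cells, by=("response", "timepoint"), per_subset=True
        )
        outputs["metrics_pooled.tsv"] = out / "metrics_pooled.tsv"
        pooled.to_csv(outputs["metrics_pooled.tsv"], sep="\t", index=False)
        outputs["metrics_per_patient.tsv"] = out / "metrics_per_patient.tsv"
        per_patient.to_csv(outputs["metrics_per_patient.tsv"], sep="\t", index=False)
        outputs["metrics_per_subset.tsv"] = out / "metrics_per_subset.tsv"
        per_subset.to_csv(outputs["metrics_per_subset.tsv"], sep="\t", index=False)
        spec_rows = []
        for spec, table in tables.items():
            spectrum = copy_number_spectrum(table, config.bin_edges)
            for b, c, p in zip(spectrum.bins, spectrum.counts, spectrum.proportions):
                spec_rows.append(
                    {
                        "patient": spec[0],
                        "timepoint": spec[1],
                        "bin": b,
                        "clonotypes": c,
                        "cell_proportion": p,
                    }
                )
        outputs["copy_number_spectra.tsv"] = out / "copy_number_spectra.tsv"
        pd.DataFrame(spec_rows).to_csv(
            outputs["copy_number_spectra.tsv"], sep="\t", index=False
        )
        manifest["stages"].append("metrics")

        # --- dynamics ------------------------------------------------------
        current_stage = "dynamics"
        paired_frames = []
        profile_rows = []
        patients = sorted({spec[0] for spec in tables})
        for patient in patients:
            if (patient, "pre") not in tables or (patient, "post") not in tables:
                logger.info("patient %s lacks a paired specimen; skipped", patient)
                continue
            paired = pair_repertoires(tables[(patient, "pre")], tables[(patient, "post")])
            paired_frames.append(paired_to_frame(paired))
            post_cells = [
                c for c in cells if c.patient == patient and c.timepoint == "post"
            ]
            for subset in sorted({c.subset for c in post_cells}):
                profile = subset_expansion_profile(paired, post_cells, subset)
                for cls in EXPANSION_CLASSES:
                    profile_rows.append(
                        {
                            "patient": patient,
                            "subset": subset,
                            "expansion_class": cls,
                            "cells": profile.class_cell_counts[cls],
                            "clones": profile.class_clone_counts[cls],
                            "mean_post_copies": profile.mean_post_copies[cls],
                        }
                    )
        outputs["paired_clones.tsv"] = out / "paired_clones.tsv"
        (
            pd.concat(paired_frames, ignore_index=True)
            if paired_frames
            else paired_to_frame([])
        ).to_csv(outputs["paired_clones.tsv"], sep="\t", index=False)
        outputs["subset_expansion_profiles.tsv"] = out / "subset_expansion_profiles.tsv"
        pd.DataFrame(profile_rows).to_csv(
            outputs["subset_expansion_profiles.tsv"], sep="\t", index=False
        )
        manifest["stages"].append("dynamics")

        # --- roe -----------------------------------------------------------
        current_stage = "roe"
        counts = (
            cell_frame.assign(condition=lambda d: d["response"] + "_" + d["timepoint"])
            .groupby(["subset", "condition"])
            .size()
            .unstack(fill_value=0)
        )
        roe_long = roe(counts).long_format()
        outputs["roe.tsv"] = out / "roe.tsv"
        roe_long.to_csv(outputs["roe.tsv"], sep="\t", index=False)
        manifest["stages"].append("roe")

        # --- sharing -------------------------------------------------------
        current_stage = "sharing"
        sharing_rows = []
        for (response, timepoint), group in sorted(
            pd.Series(range(len(cells))).groupby(
                [pd.Series([c.response for c in cells]),
                 pd.Series([c.timepoint for c in cells])]
            )
        ):
            pool = [cells[i] for i in group]
            sizes = pd.Series([c.subset for c in pool]).value_counts()
            eligible = sorted(
                sizes[sizes >= config.min_subset_cells_for_sharing].index
            )
            if len(eligible) < 2:
                continue
            for result in pairwise_sharing(
                pool, eligible, n_permutations=config.n_permutations, seed=config.seed
            ):
                sharing_rows.append(
                    {
                        "response": response,
                        "timepoint": timepoint,
                        "subset_a": result.subset_a,
                        "subset_b": result.subset_b,
                        "shared_count": result.shared_count,
                        "p_value": result.p_value,
                        "n_permutations": result.n_permutations,
                        "seed": result.seed,
                        "freq_spearman_rho": result.freq_spearman_rho,
                    }
                )
        outputs["sharing.tsv"] = out / "sharing.tsv"
        pd.DataFrame(
            sharing_rows,
            columns=[
                "response", "timepoint", "subset_a", "subset_b", "shared_count",
                "p_value", "n_permutations", "seed", "freq_spearman_rho",
            ],
        ).to_csv(outputs["sharing.tsv"], sep="\t", index=False)
        manifest["stages"].append("sharing")

        # --- score (optional) ----------------------------------------------
        current_stage = "score"
        if config.has_expression():
            expr = read_expression_bundle(
                config.expression_matrix,
                config.expression_genes,
                config.expression_barcodes,
            )
            gene_sets = read_gmt(config.gene_sets)
            score_frames = []
            summary_rows = []
            grouping = dict(
                zip(
                    cell_frame["barcode"],
                    cell_frame["response"] + "_" + cell_frame["timepoint"],
                )
            )
            for name, members in gene_sets.items():
                scores = aucell_score(
                    expr, members, top_fraction=config.top_fraction, gene_set_name=name
                )
                score_frames.append(scores)
                for summary in zscore_group_means(scores, grouping):
                    summary_rows.append(
                        {
                            "gene_set": name,
                            "group": summary.group,
                            "mean_auc": summary.mean_auc,
                            "z_mean": summary.z_mean,
                            "n_cells": summary.n_cells,
                        }
                    )
            outputs["pathway_scores.tsv"] = out / "pathway_scores.tsv"
            pd.concat(score_frames, ignore_index=True).to_csv(
                outputs["pathway_scores.tsv"], sep="\t", index=False
            )
            outputs["pathway_group_summary.tsv"] = out / "pathway_group_summary.tsv"
            pd.DataFrame(summary_rows).to_csv(
                outputs["pathway_group_summary.tsv"], sep="\t", index=False
            )
            manifest["stages"].append("score")
        else:
            logger.info("expression inputs not configured; score stage skipped")
            manifest["stages"].append("score:skipped")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current_stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    for name, path in outputs.items():
        manifest["outputs"][name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize_report(out_dir: str | Path) -> str:
    """Human-readable digest of a finished (or partial) run."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        return "0 stages completed (no manifest found)"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    done = [s for s in manifest["stages"] if not s.endswith(":skipped")]
    lines = [
        f"tcrdyn {manifest['tcrdyn_version']} run, seed {manifest['seed']}: "
        f"{len(done)} stages completed",
    ]
    missing = [s for s in STAGES if s not in done and f"{s}:skipped" not in manifest["stages"]]
    if missing:
        lines.append(f"missing stages: {', '.join(missing)}")

    pooled_path = out / "metrics_pooled.tsv"
    if pooled_path.exists():
        pooled = pd.read_csv(pooled_path, sep="\t")
        lines.append("diversity by response x timepoint:")
        for _, row in pooled.iterrows():
            lines.append(
                f"  {row['response']:>7} {row['timepoint']:>4}: "
                f"richness {int(row['richness'])}, clonality {row['clonality']:.3f}, "
                f"gini {row['gini']:.3f} ({int(row['total_cells'])} cells)"
            )
    profiles_path = out / "subset_expansion_profiles.tsv"
    if profiles_path.exists():
        prof = pd.read_csv(profiles_path, sep="\t")
        expanded = prof[prof["expansion_class"].isin(["novel_expanded", "persistent_expanded"])]
        top = (
            expanded.groupby("subset")["cells"].sum().sort_values(ascending=False).head(3)
        )
        lines.append("top subsets by expanded post-treatment cells:")
        for subset, n in top.items():
            lines.append(f"  {subset}: {int(n)} cells")
    else:
        lines.append("expansion section absent")
    roe_path = out / "roe.tsv"
    if roe_path.exists():
        roe_df = pd.read_csv(roe_path, sep="\t").sort_values("roe", ascending=False)
        lines.append("top Ro/e (subset, condition):")
        for _, row in roe_df.head(3).iterrows():
            lines.append(f"  {row['subset']} @ {row['condition']}: {row['roe']:.2f}")
    sharing_path = out / "sharing.tsv"
    if sharing_path.exists():
        sh = pd.read_csv(sharing_path, sep="\t")
        sig = sh[sh["p_value"] < 0.05]
        lines.append(f"sharing pairs with p < 0.05: {len(sig)}")
    else:
        lines.append("sharing section absent")
    return "\n".join(lines)
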