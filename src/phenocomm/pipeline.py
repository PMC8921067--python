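"""End-to-end orchestration: assign → abundance → phenotype → differential.

Runs the full analysis from on-disk inputs to on-disk outputs and records
a JSON manifest (input/output SHA-256 hashes, parameter values, seed) so
that reruns over identical inputs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as pio
from .abundance import AbundanceTable, aggregate_to_rank, copy_number_renormalize, to_relative
from .community import (
    bray_curtis_matrix,
    differential_table,
    pcoa,
    shannon_diversity,
    summarize_modulation,
)
from .phenotypes import cpi_matrix, probability_table_by_rank, probability_table_by_refs
from .taxonomy import MultiTaxonomyClassifier

logger = logging.getLogger("phenocomm")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(stage)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    asv_fasta: str
    reference_fasta: str
    lineage_tsv: str
    copy_number_tsv: str
    bpm_tsv: str
    counts_tsv: str
    metadata_tsv: str
    outdir: str
    identity_tsv: str | None = None  # precomputed identities instead of aligning
    rank: str = "species"  # analysis rank; "phylotype" keeps ASV resolution
    fold_threshold: float = 5.0
    detection_limit: float = 0.0
    control: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold threshold must exceed 1")
        required = [
            self.asv_fasta,
            self.reference_fasta,
            self.lineage_tsv,
            self.copy_number_tsv,
            self.bpm_tsv,
            self.counts_tsv,
            self.metadata_tsv,
        ]
        if self.identity_tsv:
            required.append(self.identity_tsv)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise ValueError(f"missing input files: {missing}")

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**mapping)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, message: str) -> None:
    logger.info(message, extra={"stage": stage})


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "assign"
    try:
        _log(stage, "reading inputs")
        asvs = pio.read_fasta(cfg.asv_fasta)
        ref_seqs = pio.read_fasta(cfg.reference_fasta)
        lineages = pio.read_lineage_tsv(cfg.lineage_tsv)
        cn_rank, copy_numbers = pio.read_copy_number_tsv(cfg.copy_number_tsv)
        bpm = pio.read_bpm_tsv(cfg.bpm_tsv)
        metadata = pio.read_metadata_tsv(cfg.metadata_tsv)
        counts = pio.read_counts_tsv(cfg.counts_tsv, metadata)
        if cfg.identity_tsv:
            identities = pd.read_csv(cfg.identity_tsv, sep="\t", dtype={"asv_id": str, "strain_id": str})
            classifier = MultiTaxonomyClassifier(identities=identities)
        else:
            classifier = MultiTaxonomyClassifier()
        assignments = classifier.fit(ref_seqs, lineages).predict(asvs)
        outputs["assignments"] = outdir / "assignments.tsv"
        pio.write_assignments_tsv(assignments, outputs["assignments"])
        _log(stage, f"assigned {len(assignments)} ASVs against {len(ref_seqs)} references")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    stage = "abundance"
    try:
        relative = to_relative(counts)
        taxon_names = {a: assignments[a].lineage.at(cn_rank) for a in relative.taxon_ids}
        corrected = copy_number_renormalize(relative, copy_numbers, taxon_names)
        if cfg.rank == "phylotype":
            analysis = corrected
            diff_input = relative  # phylotype-level contrasts stay uncorrected
        else:
            analysis = aggregate_to_rank(corrected, assignments, cfg.rank)
            diff_input = analysis
        outputs["relative"] = outdir / "relative.tsv"
        pio.write_counts_tsv(relative, outputs["relative"])
        outputs["abundance"] = outdir / f"abundance_{cfg.rank}.tsv"
        pio.write_counts_tsv(analysis, outputs["abundance"])

        alpha = pd.DataFrame(
            {"shannon": [shannon_diversity(relative.data.loc[s]) for s in relative.sample_ids]},
            index=relative.sample_ids,
        )
        outputs["alpha_diversity"] = outdir / "alpha_diversity.tsv"
        alpha.to_csv(outputs["alpha_diversity"], sep="\t", index_label="sample_id")
        distances = bray_curtis_matrix(relative.data)
        outputs["bray_curtis"] = outdir / "bray_curtis.tsv"
        distances.to_csv(outputs["bray_curtis"], sep="\t", index_label="sample_id")
        ordination = pcoa(distances)
        outputs["pcoa"] = outdir / "pcoa_coordinates.tsv"
        ordination.coordinates.to_csv(outputs["pcoa"], sep="\t", index_label="sample_id")
        _log(stage, f"{analysis.data.shape[1]} taxa at rank {cfg.rank!r}")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    stage = "phenotype"
    try:
        if cfg.rank == "phylotype":
            if bpm.strain_of is None:
                raise ValueError("phylotype-level CPI needs a genome→strain mapping in the BPM")
            probs = probability_table_by_refs(
                {a: assignments[a] for a in analysis.taxon_ids}, bpm
            )
        else:
            probs = probability_table_by_rank(analysis.taxon_ids, bpm, cfg.rank)
        cpi, excluded = cpi_matrix(analysis, probs)
        outputs["phenotype_probabilities"] = outdir / "phenotype_probabilities.tsv"
        pio.write_probability_tsv(probs, outputs["phenotype_probabilities"])
        outputs["cpi"] = outdir / "cpi.tsv"
        pio.write_cpi_tsv(cpi, outputs["cpi"])
        outputs["cpi_excluded_mass"] = outdir / "cpi_excluded_mass.tsv"
        excluded.rename("excluded_mass").to_csv(
            outputs["cpi_excluded_mass"], sep="\t", index_label="sample_id"
        )
        _log(stage, f"CPI over {cpi.shape[1]} phenotypes")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    stage = "diff"
    try:
        taxa_diff = differential_table(
            diff_input.data, metadata, cfg.control, cfg.fold_threshold, cfg.detection_limit
        )
        outputs["differential_taxa"] = outdir / "differential_taxa.tsv"
        taxa_diff.to_csv(outputs["differential_taxa"], sep="\t", index=False)
        outputs["modulation_summary"] = outdir / "modulation_summary.tsv"
        summarize_modulation(taxa_diff).to_csv(outputs["modulation_summary"], sep="\t")
        cpi_diff = differential_table(
            cpi, metadata, cfg.control, cfg.fold_threshold, cfg.detection_limit
        )
        outputs["differential_cpi"] = outdir / "differential_cpi.tsv"
        cpi_diff.to_csv(outputs["differential_cpi"], sep="\t", index=False)
        _log(stage, f"{len(taxa_diff)} taxon contrasts, {len(cpi_diff)} CPI contrasts")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    manifest = {
        "parameters": {
            "rank": cfg.rank,
            "fold_threshold": cfg.fold_threshold,
            "detection_limit": cfg.detection_limit,
            "control": cfg.control,
            "seed": cfg.seed,
        },
        "inputs": {
            name: _sha256(Path(path))
            for name, path in (
                ("asv_fasta", cfg.asv_fasta),
                ("reference_fasta", cfg.reference_fasta),
                ("lineage_tsv", cfg.lineage_tsv),
                ("copy_number_tsv", cfg.copy_number_tsv),
                ("bpm_tsv", cfg.bpm_tsv),
                ("counts_tsv", cfg.counts_tsv),
                ("metadata_tsv", cfg.metadata_tsv),
            )
        },
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log("run", f"manifest written to {manifest_path}")
    return manifest
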