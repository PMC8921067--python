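"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-delimited UTF-8 with a header row and '.' decimals.
Abundance tables carry a ``#mode=counts|relative`` comment line so that
counts and closed compositions cannot be silently confused on disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import AbundanceTable
from .lineage import RANKS, Lineage
from .phenotypes import BinaryPhenotypeMatrix, PhenotypeProbabilityTable
from .simulate import GenomeRecord, ReferenceDatabase, StrainRecord
from .taxonomy import MultiTaxonomyAssignment, assignments_to_frame


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered id → sequence mapping; duplicate ids are rejected."""
    path = Path(path)
    with path.open() as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: line 1: expected FASTA header starting with '>'")
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_lineage_tsv(path: str | Path) -> dict[str, Lineage]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(path, frame, ["strain_id", "lineage"])
    out: dict[str, Lineage] = {}
    for row in frame.itertuples():
        if row.strain_id in out:
            raise ValueError(f"{path}: duplicate strain_id {row.strain_id!r}")
        out[row.strain_id] = Lineage.from_string(row.lineage)
    return out


def write_lineage_tsv(lineages: Mapping[str, Lineage], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"strain_id": list(lineages), "lineage": [l.to_string() for l in lineages.values()]}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_copy_number_tsv(path: str | Path) -> tuple[str, dict[str, float]]:
    """Copy-number table ``(rank, name, mean_copies)``; returns (rank, mapping)."""
    frame = pd.read_csv(path, sep="\t", dtype={"rank": str, "name": str})
    _require_columns(path, frame, ["rank", "name", "mean_copies"])
    ranks = frame["rank"].unique()
    if len(ranks) != 1:
        raise ValueError(f"{path}: copy-number table mixes ranks {list(ranks)}")
    if (frame["mean_copies"] < 1).any():
        bad = frame.loc[frame["mean_copies"] < 1, "name"].tolist()
        raise ValueError(f"{path}: copy numbers below 1 for {bad}")
    return str(ranks[0]), dict(zip(frame["name"], frame["mean_copies"].astype(float)))


def write_copy_number_tsv(rank: str, copy_numbers: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"rank": rank, "name": list(copy_numbers), "mean_copies": list(copy_numbers.values())}
    ).to_csv(path, sep="\t", index=False)


def read_bpm_tsv(path: str | Path) -> BinaryPhenotypeMatrix:
    """BPM TSV: genome_id, lineage, optional strain_id, one column per phenotype."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(path, frame, ["genome_id", "lineage"])
    if frame["genome_id"].duplicated().any():
        dup = frame.loc[frame["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"{path}: duplicate genome ids {dup}")
    phenotype_cols = [c for c in frame.columns if c not in ("genome_id", "lineage", "strain_id")]
    if not phenotype_cols:
        raise ValueError(f"{path}: no phenotype columns found")
    for col in phenotype_cols:
        bad = ~frame[col].isin(["0", "1"])
        if bad.any():
            row = frame.loc[bad].iloc[0]
            raise ValueError(
                f"{path}: non-binary BPM cell {row[col]!r} at genome {row['genome_id']!r}, "
                f"column {col!r}"
            )
    data = frame.set_index("genome_id")[phenotype_cols].astype(int)
    data.index.name = None
    lineages = {
        row.genome_id: Lineage.from_string(row.lineage) for row in frame.itertuples()
    }
    strain_of = (
        dict(zip(frame["genome_id"], frame["strain_id"])) if "strain_id" in frame else None
    )
    return BinaryPhenotypeMatrix(data, lineages, strain_of)


def write_bpm_tsv(bpm: BinaryPhenotypeMatrix, path: str | Path) -> None:
    frame = bpm.data.copy()
    frame.insert(0, "lineage", [bpm.lineages[g].to_string() for g in frame.index])
    if bpm.strain_of is not None:
        frame.insert(1, "strain_id", [bpm.strain_of[g] for g in frame.index])
    frame.index.name = "genome_id"
    frame.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, metadata: pd.DataFrame | None = None) -> AbundanceTable:
    """Samples × taxa table with a ``#mode=`` comment line (default counts)."""
    path = Path(path)
    mode = "counts"
    with path.open() as handle:
        offset = 0
        for line in handle:
            if line.startswith("#"):
                offset += 1
                if line.strip().startswith("#mode="):
                    mode = line.strip().split("=", 1)[1]
            else:
                break
    frame = pd.read_csv(path, sep="\t", index_col=0, skiprows=offset)
    frame.index.name = None
    if mode == "counts":
        if (frame.to_numpy() < 0).any():
            negative = frame.columns[(frame < 0).any()].tolist()
            raise ValueError(f"{path}: negative counts in columns {negative}")
        frame = frame.astype(int)
    return AbundanceTable(frame, mode, metadata)


def write_counts_tsv(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write(f"#mode={table.mode}\n")
        table.data.to_csv(handle, sep="\t", index_label="sample_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    _require_columns(path, frame, ["sample_id", "condition", "replicate"])
    return frame.set_index("sample_id")


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def write_probability_tsv(table: PhenotypeProbabilityTable, path: str | Path) -> None:
    frame = table.probs.copy()
    frame.insert(0, "supporting_genomes", table.support)
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t", na_rep="NA")


def write_cpi_tsv(cpi: pd.DataFrame, path: str | Path) -> None:
    cpi.round(4).to_csv(path, sep="\t", index_label="sample_id")


def write_reference_database(ref_db: ReferenceDatabase, outdir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, lineage TSV, copy-number TSV and genome map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_fasta": outdir / "reference.fasta",
        "lineage_tsv": outdir / "lineage.tsv",
        "copy_number_tsv": outdir / "copy_numbers.tsv",
    }
    write_fasta(ref_db.sequences, paths["reference_fasta"])
    write_lineage_tsv(ref_db.lineages, paths["lineage_tsv"])
    write_copy_number_tsv("species", ref_db.copy_numbers_by_species, paths["copy_number_tsv"])
    return paths


def read_reference_database(
    fasta_path: str | Path,
    lineage_path: str | Path,
    copy_number_path: str | Path,
) -> ReferenceDatabase:
    sequences = read_fasta(fasta_path)
    lineages = read_lineage_tsv(lineage_path)
    _, copy_numbers = read_copy_number_tsv(copy_number_path)
    strains, genomes = [], []
    for strain_id, seq in sequences.items():
        if strain_id not in lineages:
            raise ValueError(f"strain {strain_id!r} has no lineage entry")
        lineage = lineages[strain_id]
        cn = copy_numbers.get(lineage.at("species"))
        if cn is None:
            raise ValueError(f"no copy number for species {lineage.at('species')!r}")
        strains.append(StrainRecord(strain_id, seq, lineage, int(cn)))
        genomes.append(GenomeRecord(f"genome_of_{strain_id}", lineage, strain_id))
    return ReferenceDatabase(strains, genomes)


def write_assignments_tsv(
    assignments: Mapping[str, MultiTaxonomyAssignment], path: str | Path
) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path: str | Path) -> dict[str, MultiTaxonomyAssignment]:
    frame = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "accepted_refs": str})
    _require_columns(path, frame, ["asv_id", "M", "tau", "accepted_refs", *RANKS])
    out: dict[str, MultiTaxonomyAssignment] = {}
    for _, row in frame.iterrows():
        out[row["asv_id"]] = MultiTaxonomyAssignment(
            asv_id=row["asv_id"],
            max_identity=float(row["M"]),
            threshold=float(row["tau"]),
            accepted_refs=tuple(str(row["accepted_refs"]).split(";")),
            lineage=Lineage(tuple(str(row[rank]) for rank in RANKS)),
        )
    return out


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def _require_columns(path, frame: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
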