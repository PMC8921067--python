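"""Synthetic pooled-fecal-community experiments with planted SCFA effects.

Emulates the statistical structure of an in-vitro supplementation study:
a strain-resolved 16S reference (strain phylotypes nested in species
groups, species nested in genera), per-species 16S copy numbers, a binary
phenotype matrix over one genome per strain, and a replicated culture
experiment — one control plus nine SCFA conditions, four technical
replicates each — in which chosen strains' abundances are multiplied by
planted fold-change effects.  Effects are planted at strain level because
SCFA response is treated as a strain-dependent phenotype.

Counts are drawn from a multinomial (optionally Dirichlet-overdispersed)
over 16S-weighted abundances: a strain's sampling weight is its cell
abundance times its 16S copy number, so the downstream copy-number
renormalization stage is exercised for real.  The returned ground truth
(cell-level relative abundances and planted multipliers) lets every
pipeline stage be checked against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .lineage import Lineage
from .phenotypes import BinaryPhenotypeMatrix

ALPHABET = np.array(list("ACGT"))
SEQUENCE_LENGTH = 450  # V3–V4-sized amplicon
SPECIES_DIVERGENCE = 0.03  # minimum between-species distance, fraction of sites
MAX_STRAIN_SUBSTITUTIONS = 5

SCFA_CONDITIONS = (
    "formate",
    "acetate",
    "propionate",
    "butyrate",
    "valerate",
    "isobutyrate",
    "isovalerate",
    "lactate",
    "succinate",
)

DEFAULT_PHENOTYPES = (
    "butyrate_production",
    "propionate_production",
    "acetate_production",
    "formate_production",
    "L-lactate_production",
    "D-lactate_production",
    "ethanol_production",
    "B1_biosynthesis",
    "B2_biosynthesis",
    "B6_biosynthesis",
    "B12_biosynthesis",
    "folate_biosynthesis",
)


@dataclass(frozen=True)
class StrainRecord:
    strain_id: str
    sequence: str
    lineage: Lineage
    copy_number: int


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    lineage: Lineage
    strain_id: str


@dataclass
class ReferenceDatabase:
    """Strain-level 16S reference with one sequenced genome per strain."""

    strains: list[StrainRecord]
    genomes: list[GenomeRecord]

    def __post_init__(self) -> None:
        strain_ids = [s.strain_id for s in self.strains]
        genome_ids = [g.genome_id for g in self.genomes]
        if len(set(strain_ids)) != len(strain_ids):
            raise ValueError("duplicate strain ids")
        if len(set(genome_ids)) != len(genome_ids):
            raise ValueError("duplicate genome ids")
        for s in self.strains:
            if not 1 <= s.copy_number <= 15:
                raise ValueError(f"copy number out of [1, 15] for {s.strain_id}")

    @property
    def sequences(self) -> dict[str, str]:
        return {s.strain_id: s.sequence for s in self.strains}

    @property
    def lineages(self) -> dict[str, Lineage]:
        return {s.strain_id: s.lineage for s in self.strains}

    @property
    def copy_numbers_by_species(self) -> dict[str, float]:
        return {s.lineage.at("species"): float(s.copy_number) for s in self.strains}

    @property
    def species_of_strain(self) -> dict[str, str]:
        return {s.strain_id: s.lineage.at("species") for s in self.strains}

    @property
    def strain_of_genome(self) -> dict[str, str]:
        return {g.genome_id: g.strain_id for g in self.genomes}


def _species_lineage(species_index: int) -> Lineage:
    # Binary grouping cascade: two species per genus, two genera per family, …
    genus = species_index // 2
    family = genus // 2
    order = family // 2
    klass = order // 2
    phylum = klass // 2
    return Lineage(
        (
            "Bacteria",
            f"Phylum{phylum + 1:02d}",
            f"Class{klass + 1:02d}",
            f"Order{order + 1:02d}",
            f"Family{family + 1:02d}",
            f"Genus{genus + 1:02d}",
            f"sp{species_index + 1:03d}",
        )
    )


def _mutate(sequence: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = sequence.copy()
    for pos in positions:
        choices = ALPHABET[ALPHABET != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def generate_reference_database(
    n_species: int, strains_per_species: int, seed: int
) -> ReferenceDatabase:
    """Generate a strain-resolved reference of ``n_species`` species groups.

    Species consensus sequences are derived from one ancestral sequence by
    ~30 substitutions each and redrawn until every between-species pair
    differs at ≥ 3% of positions plus a margin wide enough that strain
    variants (1–5 substitutions off their consensus) keep that divergence.
    """
    if n_species < 2 or strains_per_species < 1:
        raise ValueError("need n_species ≥ 2 and strains_per_species ≥ 1")
    rng = np.random.default_rng(seed)
    root = rng.choice(ALPHABET, size=SEQUENCE_LENGTH)
    min_hamming = math.ceil(SPECIES_DIVERGENCE * SEQUENCE_LENGTH) + 2 * MAX_STRAIN_SUBSTITUTIONS
    consensi: list[np.ndarray] = []
    for _ in range(n_species):
        for _attempt in range(1000):
            positions = rng.choice(SEQUENCE_LENGTH, size=30, replace=False)
            candidate = _mutate(root, positions, rng)
            if all((candidate != c).sum() >= min_hamming for c in consensi):
                consensi.append(candidate)
                break
        else:  # pragma: no cover - 30 random substitutions collide essentially never
            raise RuntimeError("could not place a sufficiently divergent species")

    strains: list[StrainRecord] = []
    genomes: list[GenomeRecord] = []
    for i, consensus in enumerate(consensi):
        lineage = _species_lineage(i)
        copy_number = int(rng.integers(1, 8))
        seen: set[str] = set()
        for j in range(strains_per_species):
            for _attempt in range(1000):
                k = int(rng.integers(1, MAX_STRAIN_SUBSTITUTIONS + 1))
                positions = rng.choice(SEQUENCE_LENGTH, size=k, replace=False)
                seq = "".join(_mutate(consensus, positions, rng))
                if seq not in seen:
                    seen.add(seq)
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw a distinct strain sequence")
            strain_id = f"S{i + 1:03d}.{j + 1}"
            strains.append(StrainRecord(strain_id, seq, lineage, copy_number))
            genomes.append(GenomeRecord(f"G{i + 1:03d}.{j + 1}", lineage, strain_id))
    return ReferenceDatabase(strains, genomes)


def generate_phenotype_matrix(
    ref_db: ReferenceDatabase,
    phenotypes: Sequence[str] = DEFAULT_PHENOTYPES,
    prevalence: float | Mapping[str, float] = 0.5,
    coherence: float = 0.9,
    seed: int = 0,
) -> BinaryPhenotypeMatrix:
    """Binary phenotype matrix with species-coherent genome states.

    For each phenotype a species-level majority state is drawn with the
    given prevalence; each genome then follows its species' majority with
    probability ``coherence`` and flips otherwise, so related strains
    mostly — but not always — share metabolic capabilities.
    """
    if isinstance(prevalence, Mapping):
        prev = {p: float(prevalence[p]) for p in phenotypes}
    else:
        prev = {p: float(prevalence) for p in phenotypes}
    for p, v in prev.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"prevalence for {p!r} outside [0, 1]")
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    species = sorted({g.lineage.at("species") for g in ref_db.genomes})
    data = {}
    for phenotype in phenotypes:
        majority = {sp: int(rng.random() < prev[phenotype]) for sp in species}
        column = []
        for genome in ref_db.genomes:
            state = majority[genome.lineage.at("species")]
            if rng.random() >= coherence:
                state = 1 - state
            column.append(state)
        data[phenotype] = column
    frame = pd.DataFrame(data, index=[g.genome_id for g in ref_db.genomes])
    return BinaryPhenotypeMatrix(
        frame,
        {g.genome_id: g.lineage for g in ref_db.genomes},
        strain_of=ref_db.strain_of_genome,
    )


@dataclass
class EffectConfig:
    """Design of a simulated supplementation experiment.

    ``conditions`` lists the control label first followed by the SCFA
    treatments; ``multiplier_low/high`` bound the log-uniform planted
    fold-change distribution; ``overdispersion`` is the Dirichlet scale
    (counts ~ multinomial over Dirichlet(p/θ) draws; θ = 0 degenerates to
    a plain multinomial).
    """

    conditions: tuple[str, ...] = ("control",) + SCFA_CONDITIONS
    control: str = "control"
    replicates: int = 4
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    fraction_affected: float = 0.1
    multiplier_low: float = 0.1
    multiplier_high: float = 10.0
    depth: int = 100_000
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.conditions:
            raise ValueError(f"control {self.control!r} missing from conditions")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.depth < 1000:
            raise ValueError("sequencing depth must be ≥ 1000")
        if self.multiplier_low <= 0 or self.multiplier_high <= 0:
            raise ValueError("multiplier bounds must be positive")
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ValueError("fraction_affected must lie in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "EffectConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted effects and true composition of a simulated experiment.

    ``multipliers`` is conditions × strains (control row all exactly 1);
    ``true_abundance`` is samples × strains cell-level relative abundance
    (identical across a condition's replicates by construction).
    """

    multipliers: pd.DataFrame
    true_abundance: pd.DataFrame

    def expected_cpi(self, bpm: BinaryPhenotypeMatrix) -> pd.DataFrame:
        """True CPI expectation per sample: 100 × Σ strain abundance × genome bit.

        Computed straight from the planted composition, independently of
        the assignment/normalization pipeline.
        """
        if bpm.strain_of is None:
            raise ValueError("BPM carries no genome→strain mapping")
        strain_bits = bpm.data.copy()
        strain_bits.index = [bpm.strain_of[g] for g in bpm.data.index]
        strain_bits = strain_bits.groupby(level=0).mean()
        aligned = strain_bits.reindex(self.true_abundance.columns)
        return 100.0 * self.true_abundance.dot(aligned)


def simulate_experiment(
    ref_db: ReferenceDatabase, cfg: EffectConfig
) -> tuple[AbundanceTable, GroundTruth]:
    """Simulate a replicated multi-condition culture experiment.

    Baseline strain abundances are drawn once (log-normal) and shared by
    every condition; each non-control condition multiplies a random
    ``fraction_affected`` of strains by log-uniform fold changes.  Read
    counts per replicate are multinomial at ``depth`` over 16S-weighted
    (copy-number-scaled) relative abundances, optionally Dirichlet-
    overdispersed.  Every sample's counts sum exactly to ``depth``.
    """
    rng = np.random.default_rng(cfg.seed)
    strain_ids = [s.strain_id for s in ref_db.strains]
    copy_numbers = np.array([s.copy_number for s in ref_db.strains], dtype=float)
    n = len(strain_ids)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)

    multipliers = pd.DataFrame(1.0, index=list(cfg.conditions), columns=strain_ids)
    n_affected = int(round(cfg.fraction_affected * n))
    for condition in cfg.conditions:
        if condition == cfg.control or n_affected == 0:
            continue
        affected = rng.choice(n, size=n_affected, replace=False)
        mults = np.exp(
            rng.uniform(
                math.log(cfg.multiplier_low), math.log(cfg.multiplier_high), n_affected
            )
        )
        multipliers.loc[condition, multipliers.columns[affected]] = mults

    counts_rows, truth_rows, sample_ids, meta_rows = [], [], [], []
    for condition in cfg.conditions:
        cells = baseline * multipliers.loc[condition].to_numpy()
        true_rel = cells / cells.sum()
        weights = cells * copy_numbers
        p = weights / weights.sum()
        for replicate in range(1, cfg.replicates + 1):
            if cfg.overdispersion > 0:
                q = rng.dirichlet(p / cfg.overdispersion)
            else:
                q = p
            counts_rows.append(rng.multinomial(cfg.depth, q))
            truth_rows.append(true_rel)
            sample_ids.append(f"{condition}_r{replicate}")
            meta_rows.append({"condition": condition, "replicate": replicate})

    counts = pd.DataFrame(counts_rows, index=sample_ids, columns=strain_ids, dtype=int)
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    table = AbundanceTable(counts, "counts", metadata)
    truth = GroundTruth(
        multipliers=multipliers,
        true_abundance=pd.DataFrame(truth_rows, index=sample_ids, columns=strain_ids),
    )
    return table, truth
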