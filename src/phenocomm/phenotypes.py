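"""Community phenotype profiling.

A binary phenotype matrix (BPM) marks, for every reference genome, the
presence (1) or absence (0) of a complete metabolic pathway — SCFA
fermentation products, vitamin biosynthesis, amino-acid biosynthesis or
degradation.  Genome bits are propagated to the taxa observed in 16S data
as probabilities: the probability P that a taxon carries a phenotype is
the mean of the bit over all reference genomes mapping to that taxon
(pooled unweighted across the constituents of a ``/``-joined multi-name,
since the multi-name encodes ambiguity rather than mixture proportions).

The Community Phenotype Index (CPI) for a sample is then

    CPI = 100 × Σ_taxa P(taxon, phenotype) × relative abundance(taxon)

i.e. the percentage of cells in the community predicted to carry the
pathway (0–100%).  Taxa with no reference genomes have undefined P; they
are excluded and the remaining abundances re-closed, with the excluded
mass reported, so that CPI is not biased toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .abundance import AbundanceTable
from .lineage import MULTI_NAME_SEPARATOR, Lineage
from .taxonomy import MultiTaxonomyAssignment


class BinaryPhenotypeMatrix:
    """Genomes × phenotypes binary matrix with genome lineages.

    ``strain_of`` optionally links each genome to the reference 16S strain
    it was assembled from, enabling phylotype-level profiling where taxa
    are matched through accepted reference strains instead of rank names.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        lineages: Mapping[str, Lineage],
        strain_of: Mapping[str, str] | None = None,
    ):
        values = data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("BPM entries must be strictly 0 or 1")
        missing = [g for g in data.index if g not in lineages]
        if missing:
            raise ValueError(f"genomes without lineage: {missing[:5]}")
        self.data = data.astype(np.int8)
        self.lineages = dict(lineages)
        self.strain_of = dict(strain_of) if strain_of else None

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PhenotypeProbabilityTable:
    """Per-taxon phenotype probabilities P ∈ [0, 1].

    ``probs`` holds NaN — an explicit missing marker, never a silent 0 —
    for taxa with zero supporting genomes; ``support`` counts the genomes
    pooled per taxon.
    """

    probs: pd.DataFrame
    support: pd.Series

    def __post_init__(self) -> None:
        values = self.probs.to_numpy()
        finite = values[~np.isnan(values)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("phenotype probabilities must lie in [0, 1]")


def _genomes_matching_names(
    bpm: BinaryPhenotypeMatrix, names: Sequence[str], rank: str
) -> list[str]:
    wanted = set(names)
    return [g for g in bpm.genome_ids if bpm.lineages[g].at(rank) in wanted]


def phenotype_probability(
    taxon_key: str,
    bpm: BinaryPhenotypeMatrix,
    rank: str = "species",
) -> tuple[pd.Series, int]:
    """P per phenotype for one taxon key, with supporting genome count.

    The key may be ``/``-joined; genomes matching *any* constituent name
    at ``rank`` are pooled and P is the unweighted mean of their bits.
    Returns an all-NaN series (support 0) when no genome matches.
    """
    genomes = _genomes_matching_names(
        bpm, taxon_key.split(MULTI_NAME_SEPARATOR), rank
    )
    if not genomes:
        return pd.Series(np.nan, index=bpm.data.columns), 0
    return bpm.data.loc[genomes].mean(axis=0), len(genomes)


def probability_table_by_rank(
    taxon_keys: Sequence[str],
    bpm: BinaryPhenotypeMatrix,
    rank: str = "species",
) -> PhenotypeProbabilityTable:
    """Probability table for taxa keyed by (multi-)name at ``rank``."""
    rows, support = {}, {}
    for key in taxon_keys:
        rows[key], support[key] = phenotype_probability(key, bpm, rank)
    return PhenotypeProbabilityTable(
        pd.DataFrame(rows).T.reindex(list(taxon_keys)),
        pd.Series(support, dtype=int).reindex(list(taxon_keys)),
    )


def probability_table_by_refs(
    assignments: Mapping[str, MultiTaxonomyAssignment],
    bpm: BinaryPhenotypeMatrix,
) -> PhenotypeProbabilityTable:
    """Phylotype-level probability table via accepted reference strains.

    Requires ``bpm.strain_of``: each ASV pools the genomes linked to its
    accepted reference strains.  This keeps strain-resolved phenotype
    signal that rank-name matching would average away.
    """
    if bpm.strain_of is None:
        raise ValueError("BPM carries no genome→strain mapping")
    by_strain: dict[str, list[str]] = {}
    for genome, strain in bpm.strain_of.items():
        by_strain.setdefault(strain, []).append(genome)
    rows, support = {}, {}
    for asv_id, a in assignments.items():
        genomes = [g for s in a.accepted_refs for g in by_strain.get(s, [])]
        if genomes:
            rows[asv_id] = bpm.data.loc[genomes].mean(axis=0)
            support[asv_id] = len(genomes)
        else:
            rows[asv_id] = pd.Series(np.nan, index=bpm.data.columns)
            support[asv_id] = 0
    keys = list(assignments)
    return PhenotypeProbabilityTable(
        pd.DataFrame(rows).T.reindex(keys), pd.Series(support, dtype=int).reindex(keys)
    )


def compute_cpi(
    abundances: pd.Series,
    probabilities: pd.Series,
) -> tuple[float, float]:
    """CPI (percent) for one sample and one phenotype.

    ``abundances`` is a closed composition over taxa; ``probabilities``
    gives P per taxon with NaN where undefined.  Undefined-P taxa are
    dropped and the rest re-closed before summing; the dropped mass is
    returned alongside so callers can report coverage.
    """
    probs = probabilities.reindex(abundances.index)
    defined = probs.notna()
    if not defined.any() or abundances[defined].sum() <= 0:
        raise ValueError("no taxon with defined phenotype probability")
    excluded_mass = float(abundances[~defined].sum())
    closed = abundances[defined] / abundances[defined].sum()
    return float(100.0 * (closed * probs[defined]).sum()), excluded_mass


def cpi_matrix(
    table: AbundanceTable,
    prob_table: PhenotypeProbabilityTable,
) -> tuple[pd.DataFrame, pd.Series]:
    """CPI for every (sample, phenotype); also per-sample excluded mass."""
    if table.mode != "relative":
        raise ValueError("CPI requires a relative-mode abundance table")
    cpi = pd.DataFrame(
        index=table.data.index, columns=prob_table.probs.columns, dtype=float
    )
    excluded = pd.Series(0.0, index=table.data.index)
    for sample in table.data.index:
        abund = table.data.loc[sample]
        for phenotype in prob_table.probs.columns:
            try:
                value, excl = compute_cpi(abund, prob_table.probs[phenotype])
            except ValueError as err:
                raise ValueError(
                    f"sample {sample!r}, phenotype {phenotype!r}: {err}"
                ) from err
            cpi.loc[sample, phenotype] = value
            excluded[sample] = excl
    return cpi, excluded


class PhenotypeProfiler(TransformerMixin, BaseEstimator):
    """Transform relative abundances into Community Phenotype Indices.

    Parameters
    ----------
    bpm:
        The binary phenotype matrix over reference genomes.
    rank:
        Taxonomic rank whose (multi-)names key the abundance columns;
        ignored when ``assignments`` is given.
    assignments:
        Optional ASV → assignment mapping for phylotype-level profiling
        through accepted reference strains (requires ``bpm.strain_of``).
    """

    def __init__(
        self,
        bpm: BinaryPhenotypeMatrix | None = None,
        rank: str = "species",
        assignments: Mapping[str, MultiTaxonomyAssignment] | None = None,
    ):
        self.bpm = bpm
        self.rank = rank
        self.assignments = assignments

    def fit(self, X: pd.DataFrame, y=None):
        if self.bpm is None:
            raise ValueError("a BinaryPhenotypeMatrix is required")
        if self.assignments is not None:
            sub = {t: self.assignments[t] for t in X.columns}
            self.probability_table_ = probability_table_by_refs(sub, self.bpm)
        else:
            self.probability_table_ = probability_table_by_rank(
                list(X.columns), self.bpm, self.rank
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        table = AbundanceTable(X, "relative")
        cpi, excluded = cpi_matrix(table, self.probability_table_)
        self.excluded_mass_ = excluded
        return cpi
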