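"""Abundance tables: closure, 16S copy-number correction, rank aggregation.

Amplicon read counts over-represent taxa carrying many 16S rRNA gene
copies, so relative abundances are renormalized by per-taxon mean copy
numbers (rrnDB-style) at a stated taxonomic rank and re-closed to sum to
one per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lineage import MULTI_NAME_SEPARATOR
from .taxonomy import MultiTaxonomyAssignment

CLOSURE_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Samples × taxa matrix with per-sample metadata.

    ``data`` is indexed by sample_id with one column per taxon;
    ``mode`` is ``"counts"`` or ``"relative"``; ``metadata`` (optional)
    is indexed by sample_id with columns ``condition`` and ``replicate``.
    """

    data: pd.DataFrame
    mode: str = "counts"
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative'; got {self.mode!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.mode == "relative":
            sums = self.data.sum(axis=1)
            bad = sums.index[(sums - 1.0).abs() > 1e-6]
            if len(bad):
                raise ValueError(f"relative-mode samples do not sum to 1: {list(bad)[:5]}")
        if self.metadata is not None:
            missing = self.data.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def condition_of(self, sample_id: str) -> str:
        if self.metadata is None:
            raise ValueError("table carries no sample metadata")
        return str(self.metadata.loc[sample_id, "condition"])


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to sum 1 (divide by its total count)."""
    totals = table.data.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero)}")
    return AbundanceTable(table.data.div(totals, axis=0), "relative", table.metadata)


def _copy_number_for(name: str, copy_numbers: Mapping[str, float]) -> float | None:
    """Mean copy number for a (possibly /-joined) taxon name; None if unmapped.

    Multi-names average over the constituents that are present — the
    multi-name encodes ambiguity, so the unweighted mean of the candidate
    taxa's copy numbers is the natural point estimate.
    """
    values = [
        float(copy_numbers[part])
        for part in name.split(MULTI_NAME_SEPARATOR)
        if part in copy_numbers
    ]
    return float(np.mean(values)) if values else None


class CopyNumberNormalizer(TransformerMixin, BaseEstimator):
    """Divide abundances by per-taxon mean 16S copy number, then re-close.

    Parameters
    ----------
    copy_numbers:
        Mapping from taxon name (at the copy-number table's rank) to mean
        16S gene copies per genome (≥ 1).
    taxon_names:
        Optional mapping from table column (e.g. a phylotype id) to its
        name at the copy-number rank; identity by default.
    fallback:
        ``"mean"`` substitutes the grand mean of the copy-number table for
        unmapped taxa (recorded in ``fallback_taxa_``); ``"error"`` raises.
    """

    def __init__(
        self,
        copy_numbers: Mapping[str, float] | None = None,
        taxon_names: Mapping[str, str] | None = None,
        fallback: str = "mean",
    ):
        self.copy_numbers = copy_numbers
        self.taxon_names = taxon_names
        self.fallback = fallback

    def fit(self, X: pd.DataFrame, y=None):
        if not self.copy_numbers:
            raise ValueError("copy_numbers mapping is required")
        bad = {k: v for k, v in self.copy_numbers.items() if v < 1}
        if bad:
            raise ValueError(f"copy numbers below 1: {bad}")
        if self.fallback not in ("mean", "error"):
            raise ValueError("fallback must be 'mean' or 'error'")
        grand_mean = float(np.mean(list(self.copy_numbers.values())))
        divisors, missing = {}, []
        for taxon in X.columns:
            name = self.taxon_names.get(taxon, taxon) if self.taxon_names else taxon
            cn = _copy_number_for(str(name), self.copy_numbers)
            if cn is None:
                missing.append(taxon)
                cn = grand_mean
            divisors[taxon] = cn
        if missing and self.fallback == "error":
            raise ValueError(f"taxa without copy number: {missing}")
        self.divisors_ = pd.Series(divisors, dtype=float)
        self.fallback_taxa_ = tuple(missing)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        corrected = X.div(self.divisors_.reindex(X.columns), axis=1)
        return corrected.div(corrected.sum(axis=1), axis=0)


def copy_number_renormalize(
    table: AbundanceTable,
    copy_numbers: Mapping[str, float],
    taxon_names: Mapping[str, str] | None = None,
    fallback: str = "mean",
) -> AbundanceTable:
    """Copy-number-correct a table (converted to relative mode if needed)."""
    rel = table if table.mode == "relative" else to_relative(table)
    normalizer = CopyNumberNormalizer(copy_numbers, taxon_names, fallback).fit(rel.data)
    out = AbundanceTable(normalizer.transform(rel.data), "relative", table.metadata)
    out.data.attrs["copy_number_fallback_taxa"] = normalizer.fallback_taxa_
    return out


def aggregate_to_rank(
    table: AbundanceTable,
    assignments: Mapping[str, MultiTaxonomyAssignment],
    rank: str,
) -> AbundanceTable:
    """Sum taxa sharing the same (possibly multi-) name at ``rank``.

    Per-sample totals are conserved exactly; output columns are sorted.
    """
    unassigned = [t for t in table.taxon_ids if t not in assignments]
    if unassigned:
        raise ValueError(f"taxa without assignment: {unassigned[:5]}")
    keys = {t: assignments[t].lineage.at(rank) for t in table.taxon_ids}
    grouped = table.data.T.groupby(table.data.columns.map(keys)).sum().T
    return AbundanceTable(grouped.sort_index(axis=1), table.mode, table.metadata)


def count_observed(
    table: AbundanceTable,
    samples: Sequence[str] | None = None,
    threshold: float = 0.0,
) -> int:
    """Number of taxa with mean abundance strictly above ``threshold``.

    ``samples`` restricts the mean to a subset (e.g. control cultures);
    the default threshold 0 with strict inequality counts any taxon seen
    at all, mirroring a detection-limit reading of zero counts.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    sub = table.data if samples is None else table.data.loc[list(samples)]
    if sub.shape[0] == 0:
        raise ValueError("empty sample subset")
    return int((sub.mean(axis=0) > threshold).sum())
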