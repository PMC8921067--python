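"""Multi-taxonomy assignment (MTA) of amplicon sequence variants.

Each ASV is scored against every reference 16S sequence; with the best
identity denoted ``M``, every reference whose identity strictly exceeds
the threshold ``M − (1 − M)/4`` is accepted, and the accepted references'
lineages are merged rank-by-rank into ``/``-joined multi-names.  A single
ASV can therefore legitimately carry several taxonomic names, encoding
ambiguity rather than forcing an arbitrary best hit.

Identity is computed by unit-cost global (Needleman–Wunsch) alignment:
``identity = matches / alignment length``, so gap columns count against
identity.  For large reference sets a precomputed identity table
(``asv_id, strain_id, identity``) can stand in for the built-in aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from sklearn.base import BaseEstimator

from .lineage import RANKS, Lineage, merge_lineages

_VALID_SEQ = re.compile(r"^[ACGT]+$")
_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


class AssignmentError(ValueError):
    """Raised when an ASV cannot be assigned (e.g. no hits)."""


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fractional identity between two nucleotide sequences.

    Global alignment with unit mismatch/gap cost; the identity denominator
    is the full alignment length (matches + mismatches + gap columns).
    Symmetric and bounded in [0, 1].
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        if not _VALID_SEQ.match(seq):
            raise ValueError(f"{name} contains characters outside A/C/G/T")
    result = edlib.align(seq_a, seq_b, mode="NW", task="path")
    alignment_length = sum(int(n) for n, _ in _CIGAR_OP.findall(result["cigar"]))
    matches = alignment_length - result["editDistance"]
    return matches / alignment_length


def mta_threshold(max_identity: float) -> float:
    """Acceptance threshold ``M − (1 − M)/4`` for best identity ``M``.

    The threshold tightens as the best hit improves: at M = 1 only perfect
    matches could pass, at M = 0.98 the window reaches down to 0.975.  For
    very low M the value can drop below zero, in which case every hit is
    accepted — a degenerate but well-defined regime.
    """
    if not 0.0 <= max_identity <= 1.0:
        raise ValueError(f"M must be in [0, 1]; got {max_identity}")
    return max_identity - (1.0 - max_identity) / 4.0


@dataclass(frozen=True)
class AlignmentHit:
    asv_id: str
    strain_id: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0, 1]; got {self.identity}")


@dataclass(frozen=True)
class MultiTaxonomyAssignment:
    """Accepted reference set and merged lineage for one ASV."""

    asv_id: str
    max_identity: float
    threshold: float
    accepted_refs: tuple[str, ...]
    lineage: Lineage


def assign_multi_taxonomy(
    asv_id: str,
    hits: Sequence[AlignmentHit],
    lineages: Mapping[str, Lineage],
) -> MultiTaxonomyAssignment:
    """Apply the MTA rule to one ASV's hit list.

    References with identity strictly greater than ``M − (1−M)/4`` are
    accepted; references tied at the maximum M are always accepted (an ASV
    keeps at least its best match even at M = 1, where the threshold
    equals M and the strict inequality alone would exclude everything).
    """
    hits = list(hits)
    if not hits:
        raise AssignmentError(f"ASV {asv_id!r} has no hits; cannot assign")
    best = max(h.identity for h in hits)
    tau = mta_threshold(best)
    accepted = sorted(
        {h.strain_id for h in hits if h.identity > tau or h.identity == best}
    )
    merged = merge_lineages([lineages[s] for s in accepted])
    return MultiTaxonomyAssignment(
        asv_id=asv_id,
        max_identity=best,
        threshold=tau,
        accepted_refs=tuple(accepted),
        lineage=merged,
    )


class MultiTaxonomyClassifier(BaseEstimator):
    """Assign ``/``-joined multi-taxonomies to ASVs against a 16S reference.

    Follows the scikit-learn estimator protocol: :meth:`fit` stores the
    reference, :meth:`predict` maps ASV sequences to
    :class:`MultiTaxonomyAssignment` objects.

    Parameters
    ----------
    identities:
        ``"align"`` to compute identities with the built-in global aligner,
        or a precomputed long-format table (DataFrame with columns
        ``asv_id, strain_id, identity``) for large references.
    """

    def __init__(self, identities: str | pd.DataFrame = "align"):
        self.identities = identities

    def fit(self, ref_seqs: Mapping[str, str], lineages: Mapping[str, Lineage]):
        """Store reference sequences and their lineages.

        ``ref_seqs`` maps strain_id → 16S sequence; ``lineages`` maps
        strain_id → :class:`~phenocomm.lineage.Lineage`.
        """
        missing = set(ref_seqs) - set(lineages)
        if missing:
            raise ValueError(f"reference strains without lineage: {sorted(missing)[:5]}")
        self.ref_seqs_ = dict(ref_seqs)
        self.lineages_ = dict(lineages)
        return self

    def _hits_for(self, asv_id: str, seq: str) -> list[AlignmentHit]:
        if isinstance(self.identities, pd.DataFrame):
            sub = self.identities[self.identities["asv_id"] == asv_id]
            return [
                AlignmentHit(asv_id, row.strain_id, float(row.identity))
                for row in sub.itertuples()
            ]
        return [
            AlignmentHit(asv_id, sid, pairwise_identity(seq, ref))
            for sid, ref in self.ref_seqs_.items()
        ]

    def predict(self, asv_seqs: Mapping[str, str]) -> dict[str, MultiTaxonomyAssignment]:
        """Assign every ASV; raises :class:`AssignmentError` on empty hits."""
        if not hasattr(self, "ref_seqs_"):
            raise ValueError("classifier is not fitted; call fit() first")
        out = {}
        for asv_id, seq in asv_seqs.items():
            out[asv_id] = assign_multi_taxonomy(
                asv_id, self._hits_for(asv_id, seq), self.lineages_
            )
        return out


def assignments_to_frame(
    assignments: Mapping[str, MultiTaxonomyAssignment] | Iterable[MultiTaxonomyAssignment],
) -> pd.DataFrame:
    """Tabular view: asv_id, M, tau, ';'-joined refs, one column per rank."""
    if isinstance(assignments, Mapping):
        assignments = assignments.values()
    rows = []
    for a in assignments:
        row = {
            "asv_id": a.asv_id,
            "M": a.max_identity,
            "tau": a.threshold,
            "accepted_refs": ";".join(a.accepted_refs),
        }
        row.update(dict(zip(RANKS, a.lineage.names)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["asv_id", "M", "tau", "accepted_refs", *RANKS])
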