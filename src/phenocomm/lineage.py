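"""Taxonomic lineages and multi-name merging.

A lineage is an ordered tuple of names over the seven canonical ranks
(domain through species).  Under the multi-taxonomy approach a rank may
carry several names joined by ``/`` (e.g. species ``obeum/wexlerae``)
whenever an amplicon cannot be resolved to a single reference taxon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

LINEAGE_SEPARATOR = ";"
MULTI_NAME_SEPARATOR = "/"


@dataclass(frozen=True)
class Lineage:
    """An ordered, rank-complete taxonomic lineage.

    Parameters
    ----------
    names:
        One name per rank in :data:`RANKS` order.  A name may itself be a
        ``/``-joined multi-name.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage must have {len(RANKS)} ranks ({', '.join(RANKS)}); "
                f"got {len(self.names)}"
            )
        for rank, name in zip(RANKS, self.names):
            if not name or not str(name).strip():
                raise ValueError(f"empty name at rank {rank!r}")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))

    @classmethod
    def from_string(cls, text: str, sep: str = LINEAGE_SEPARATOR) -> "Lineage":
        return cls(tuple(part.strip() for part in text.split(sep)))

    def to_string(self, sep: str = LINEAGE_SEPARATOR) -> str:
        return sep.join(self.names)

    def at(self, rank: str) -> str:
        """Name (possibly ``/``-joined) at a rank."""
        try:
            return self.names[RANKS.index(rank)]
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None

    def names_at(self, rank: str) -> tuple[str, ...]:
        """Constituent names at a rank, splitting multi-names."""
        return tuple(self.at(rank).split(MULTI_NAME_SEPARATOR))

    def __iter__(self):
        return iter(self.names)


def merge_lineages(lineages: Sequence[Lineage] | Iterable[Lineage]) -> Lineage:
    """Merge lineages rank-by-rank into a multi-name consensus.

    At every rank the distinct constituent names across all inputs are
    deduplicated, sorted alphabetically and joined by ``/``.  Ranks where
    all inputs agree therefore keep a single name.  Merging is idempotent
    and order-invariant.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("cannot merge an empty list of lineages")
    merged = []
    for i, rank in enumerate(RANKS):
        names: set[str] = set()
        for lin in lineages:
            names.update(lin.names[i].split(MULTI_NAME_SEPARATOR))
        merged.append(MULTI_NAME_SEPARATOR.join(sorted(names)))
    return Lineage(tuple(merged))
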