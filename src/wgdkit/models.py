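"""Shared positional data types.

A :class:`GeneModel` is the positional atom of every gene-order computation
(synteny chaining, tandem classification, fractionation windows): a gene with
its scaffold, ordinal rank along that scaffold, genomic coordinates and CDS.
Coordinates are stored 0-based half-open internally; GFF3 readers/writers
convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class GeneModel:
    """One protein-coding gene anchored on a scaffold.

    ``rank`` is the 0-based ordinal of the gene start among the genes of its
    scaffold, strand-ignorant — the unit in which synteny gaps, tandem
    distances and fractionation windows are measured.
    """

    gene_id: str
    scaffold: str
    rank: int
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str = "+"
    cds: str = ""
    cds_valid: bool = True  # False when CDS length is not a multiple of 3

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneHit:
    """A similarity hit between two genes (best record per unordered pair)."""

    query: str
    subject: str
    score: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.query == self.subject:
            raise ValueError(f"self-hit retained for {self.query}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.query, self.subject))


def rank_index(genes: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """Map gene id -> (scaffold, rank) for a set of gene models."""
    return {g.gene_id: (g.scaffold, g.rank) for g in genes}


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Recompute per-scaffold ranks in place, ordered by start position.

    Ties on start are broken by gene id so ranks are deterministic.
    """
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for members in by_scaffold.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(members):
            g.rank = i
    return genes
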