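"""Family and genomic-location classes for duplicate pairs.

Family class: *strict* duplicates arose from a single duplication (the
fused event has exactly two members); *expansions* have more than two.
Location class: *tandem* pairs are adjacent on a contig with no annotated
gene in between (rank order over all genes on the contig, strand-free);
other pairs are dispersed on the same or on different contigs.  A dispersed
pair in which exactly one copy is intronless is flagged a *retrocopy*
(mRNA-mediated origin); a dispersed pair where both copies are intronless
is ambiguous and flagged for review instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from dupfate.trees import DuplicationEvent


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: location, strand, exon count, contig rank."""

    gene: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exon_count: int
    rank: int = -1  # ordinal position along the contig, assigned by the reader

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene}: exon count must be >= 1")


def assign_ranks(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Assign per-contig rank by start coordinate (ties by end, then id)."""
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    out: dict[str, GeneModel] = {}
    for contig, ms in by_contig.items():
        ms.sort(key=lambda m: (m.start, m.end, m.gene))
        for rank, m in enumerate(ms):
            out[m.gene] = GeneModel(
                gene=m.gene,
                contig=m.contig,
                start=m.start,
                end=m.end,
                strand=m.strand,
                exon_count=m.exon_count,
                rank=rank,
            )
    return out


def classify_family(event: DuplicationEvent) -> str:
    """``"strict"`` for two-member (fused) events, ``"expansion"`` otherwise."""
    return "strict" if len(event.members) == 2 else "expansion"


@dataclass
class LocationClass:
    pair_id: str
    location: str  # tandem | dispersed-same-contig | dispersed-different-contig
    retrocopy: bool
    ambiguous_retrocopy: bool = False

    @property
    def tandem(self) -> bool:
        return self.location == "tandem"


def classify_location(
    gene_a: str,
    gene_b: str,
    models: Mapping[str, GeneModel],
    pair_id: str | None = None,
) -> LocationClass:
    """Tandem / dispersed-same-contig / dispersed-different-contig + retrocopy.

    Requires rank-annotated models (see :func:`assign_ranks`).  Symmetric in
    the two genes.
    """
    try:
        ma, mb = models[gene_a], models[gene_b]
    except KeyError as exc:
        raise KeyError(f"gene model missing for {exc.args[0]}") from exc
    pair_id = pair_id or f"{min(gene_a, gene_b)}|{max(gene_a, gene_b)}"

    if ma.contig == mb.contig and abs(ma.rank - mb.rank) == 1:
        return LocationClass(pair_id, "tandem", retrocopy=False)
    location = (
        "dispersed-same-contig"
        if ma.contig == mb.contig
        else "dispersed-different-contig"
    )
    intronless = [m.exon_count == 1 for m in (ma, mb)]
    if all(intronless):
        return LocationClass(pair_id, location, retrocopy=False,
                             ambiguous_retrocopy=True)
    return LocationClass(pair_id, location, retrocopy=any(intronless))
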